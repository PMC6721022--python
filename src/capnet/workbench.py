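"""Experiment orchestration: config validation, dispatch, fixtures.

A single :class:`ExperimentConfig` (built from CLI flags or a YAML
file) names one of the computational kinds -- ``resistance``, ``fem``,
``network``, ``gm-pressure``, ``fixtures`` -- plus its parameters and a
global seed.  :func:`run_experiment` validates strictly (unknown keys
are rejected), dispatches to the computational modules, and returns a
:class:`ResultBundle` whose every numeric output carries a unit string.
Given the same config and seed the bundle is byte-identical up to the
timestamp field.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import brainlump, capnetsim, femstokes, hemres
from .errors import CapnetError, ConfigError
from .units import MMHG, UM, ml_min_to_m3s, mmhg_to_pa

__all__ = ["ExperimentConfig", "ResultBundle", "run_experiment", "make_fixture"]

log = logging.getLogger("capnet")

_KINDS = ("resistance", "fem", "network", "gm-pressure", "fixtures")

#: allowed parameter keys (with defaults) per experiment kind
_SCHEMAS: dict[str, dict[str, Any]] = {
    "resistance": {
        "rc_um": 2.8,
        "length_um": 57.4,
        "hematocrit": 0.4,
        "mu1": 1e-3,
        "mu2": 0.1,
        "mu1_law": "interp",
    },
    "fem": {
        "rc_um": 2.8,
        "length_um": 60.0,
        "hematocrit": 0.4,
        "shape": "cyl",
        "nr": 50,
        "nz": 1000,
        "p0_mmhg": 0.63,
    },
    "network": {
        "dims": [12, 12, 12],
        "degree": 3.0,
        "hematocrit": 0.4,
        "inlet_frac": 0.02,
        "outlet_frac": 0.02,
        "replicates": 1,
    },
    "gm-pressure": {
        "rgm": None,
        "rb": None,
        "cbf_ml_min": None,
        "base_table": None,
        "hematocrit": 0.4,
    },
    "fixtures": {"fixture_kind": "network-small"},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment description."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown experiment kind {self.kind!r}; choose from {_KINDS}")
        schema = _SCHEMAS[self.kind]
        unknown = set(self.params) - set(schema)
        if unknown:
            raise ConfigError(
                f"unknown parameter(s) for kind {self.kind!r}: {sorted(unknown)}"
            )
        merged = {**schema, **self.params}
        object.__setattr__(self, "params", merged)
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"unknown log level {self.log_level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


@dataclass(frozen=True)
class ResultBundle:
    """Inputs echo, unit-tagged outputs and provenance of one run."""

    inputs: dict[str, Any]
    outputs: dict[str, dict[str, Any]]  # name -> {"value": ..., "unit": ...}
    provenance: dict[str, Any]

    def to_json(self, path: str | Path | None = None, with_timestamp: bool = True) -> str:
        payload = {
            "inputs": self.inputs,
            "outputs": self.outputs,
            "provenance": {
                k: v
                for k, v in self.provenance.items()
                if with_timestamp or k != "timestamp"
            },
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _out(value: float, unit: str) -> dict[str, Any]:
    return {"value": float(value), "unit": unit}


def _viscosity_model(p: dict[str, Any]) -> hemres.ViscosityModel:
    if p["mu1_law"] == "interp":
        return hemres.ViscosityModel(mu1_base=p["mu1"], mu2=p["mu2"])
    if p["mu1_law"] == "const":
        return hemres.ViscosityModel.constant(mu1=p["mu1"], mu2=p["mu2"])
    raise ConfigError(f"mu1_law must be 'interp' or 'const', got {p['mu1_law']!r}")


def _run_resistance(p: dict[str, Any], seed: int) -> dict[str, dict[str, Any]]:
    visc = _viscosity_model(p)
    rc = p["rc_um"] * UM
    L = p["length_um"] * UM
    H = p["hematocrit"]
    try:
        geom = hemres.CapillaryGeometry(rc=rc, L=L)
    except CapnetError as exc:
        raise ConfigError(f"invalid capillary geometry: {exc}") from None
    pair = hemres.specific_resistances(rc, H, visc)
    r_eff = hemres.effective_specific_resistance(rc, H, visc)
    return {
        "mu1_of_H": _out(visc.mu1(H), "Pa*s"),
        "rho": _out(pair.rho, "Pa*s/m^4"),
        "rho_hat": _out(pair.rho_hat, "Pa*s/m^4"),
        "r_eff": _out(r_eff, "Pa*s/m^4"),
        "R_eff": _out(r_eff * geom.L, "Pa*s/m^3"),
        "H_exact": _out(hemres.exact_tube_hematocrit(H, rc), ""),
    }


def _run_fem(p: dict[str, Any], seed: int) -> dict[str, dict[str, Any]]:
    shape = femstokes.RBCShapeSpec(
        kind="cylindrical" if p["shape"] == "cyl" else "parabolic-capped"
    )
    mesh = femstokes.StructuredMesh(nr=int(p["nr"]), nz=int(p["nz"]))
    dom = femstokes.build_rbc_train(
        p["rc_um"] * UM, p["length_um"] * UM, p["hematocrit"], shape
    )
    sol = femstokes.solve_stokes(dom, mesh=mesh, p0=mmhg_to_pa(p["p0_mmhg"]))
    r_spec = (sol.p0 / sol.outlet_flux) / dom.L
    log.info(
        "fem solve: realized H=%.4f, eps=%.3g, flux imbalance=%.2e",
        dom.realized_H,
        sol.epsilon,
        sol.flux_imbalance,
    )
    return {
        "specific_resistance": _out(r_spec, "Pa*s/m^4"),
        "resistance": _out(r_spec * dom.L, "Pa*s/m^3"),
        "outlet_flux": _out(sol.outlet_flux, "m^3/s"),
        "flux_imbalance": _out(sol.flux_imbalance, ""),
        "realized_H": _out(dom.realized_H, ""),
        "epsilon": _out(sol.epsilon, "1/(Pa*s)"),
    }


def _run_network(p: dict[str, Any], seed: int) -> dict[str, dict[str, Any]]:
    spec = capnetsim.TopologySpec(
        dims=tuple(int(d) for d in p["dims"]), mean_degree=float(p["degree"]), seed=seed
    )
    sampler = capnetsim.GeometrySampler(seed=seed + 1)
    if int(p["replicates"]) > 1:
        table, slope = capnetsim.total_resistance_vs_H(
            spec,
            sampler,
            [p["hematocrit"]],
            replicates=int(p["replicates"]),
            inlet_fraction=p["inlet_frac"],
            outlet_fraction=p["outlet_frac"],
        )
        return {
            "total_resistance_mean": _out(table["mean"][0], "Pa*s/m^3"),
            "total_resistance_sd": _out(table["sd"][0], "Pa*s/m^3"),
            "replicates": _out(int(p["replicates"]), ""),
        }
    net = capnetsim.build_network(
        spec,
        sampler,
        p["hematocrit"],
        inlet_fraction=p["inlet_frac"],
        outlet_fraction=p["outlet_frac"],
    )
    sol = capnetsim.solve_flow(net)
    log.info(
        "network solve: %d nodes, %d edges, realized degree %.3f",
        net.n_nodes,
        net.n_edges,
        net.mean_degree,
    )
    return {
        "total_resistance": _out(sol.total_resistance, "Pa*s/m^3"),
        "total_inflow": _out(sol.total_inflow, "m^3/s"),
        "n_edges": _out(net.n_edges, ""),
        "realized_mean_degree": _out(net.mean_degree, ""),
    }


def _run_gm_pressure(p: dict[str, Any], seed: int) -> dict[str, dict[str, Any]]:
    if p["rgm"] is None or p["rb"] is None:
        raise ConfigError("gm-pressure requires rgm and rb (Pa*s/m^3)")
    params = brainlump.Table1Params()
    levels = None
    cbf = None
    if p["cbf_ml_min"] is not None:
        cbf = ml_min_to_m3s(p["cbf_ml_min"])
    elif p["base_table"] is not None:
        levels = tuple(
            brainlump.noncapillary_levels(brainlump.load_base_table(p["base_table"]))
        )
    else:
        raise ConfigError("supply either cbf_ml_min or base_table")
    model = brainlump.BrainLumpModel(
        params=params, R_GM=p["rgm"], R_B=p["rb"], levels=levels, cbf=cbf
    )
    s = model.summary()
    out = {
        "R10": _out(s["R10_pa_s_per_m3"], "Pa*s/m^3"),
        "Q": _out(s["Q_ml_per_min"], "ml/min"),
        "dp_pa": _out(s["dp_pa"], "Pa"),
        "dp_mmhg": _out(s["dp_mmhg"], "mmHg"),
    }
    if "RT_pa_s_per_m3" in s:
        out["RT"] = _out(s["RT_pa_s_per_m3"], "Pa*s/m^3")
    return out


def _run_fixtures(p: dict[str, Any], seed: int, out_dir: str | None) -> dict[str, dict[str, Any]]:
    target = Path(out_dir or ".")
    files = make_fixture(p["fixture_kind"], seed, target)
    return {f"file_{k}": {"value": str(v), "unit": "path"} for k, v in enumerate(files)}


def run_experiment(config: ExperimentConfig) -> ResultBundle:
    """Validate, dispatch and wrap one experiment run."""
    logging.basicConfig(level=config.log_level.upper())
    t0 = time.time()
    dispatch = {
        "resistance": lambda: _run_resistance(config.params, config.seed),
        "fem": lambda: _run_fem(config.params, config.seed),
        "network": lambda: _run_network(config.params, config.seed),
        "gm-pressure": lambda: _run_gm_pressure(config.params, config.seed),
        "fixtures": lambda: _run_fixtures(config.params, config.seed, config.out_dir),
    }
    outputs = dispatch[config.kind]()
    bundle = ResultBundle(
        inputs={"kind": config.kind, "seed": config.seed, **config.params},
        outputs=outputs,
        provenance={
            "package": "capnet",
            "version": __import__("capnet").__version__,
            "seed": config.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "elapsed_s": round(time.time() - t0, 3),
        },
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.to_json(out / f"{config.kind}_result.json")
    return bundle


def make_fixture(kind: str, seed: int, out_dir: str | Path = ".") -> list[Path]:
    """Write a small seeded fixture to disk and return the paths.

    ``formula-grid``: CSV of effective specific resistance over an
    (rc, H) grid; ``fem-small``: a coarse-mesh domain spec (JSON);
    ``network-small``: a 200-edge network CSV plus roles JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "formula-grid":
        rc_um = np.round(np.arange(2.0, 4.01, 0.2), 2)
        H = np.round(np.arange(0.0, 1.001, 0.1), 2)
        rows = []
        for rc in rc_um:
            for h in H:
                rows.append(
                    {
                        "rc_um": rc,
                        "H": h,
                        "r_eff_pa_s_per_m4": hemres.effective_specific_resistance(
                            rc * UM, h
                        ),
                    }
                )
        path = out_dir / "formula_grid.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
        return [path]
    if kind == "fem-small":
        spec = {
            "rc_um": 2.8,
            "length_um": 60.0,
            "hematocrit": 0.4,
            "shape": "cyl",
            "nr": 10,
            "nz": 100,
            "p0_mmhg": 0.63,
        }
        path = out_dir / "fem_small.json"
        path.write_text(json.dumps(spec, indent=1, sort_keys=True))
        return [path]
    if kind == "network-small":
        spec = capnetsim.TopologySpec(
            dims=capnetsim.dims_for_edges(200, 3.0), mean_degree=3.0, seed=seed
        )
        net = capnetsim.build_network(
            spec, capnetsim.GeometrySampler(seed=seed + 1), H=0.4
        )
        csv_path = out_dir / "network_small.csv"
        json_path = out_dir / "network_small.json"
        capnetsim.write_network(net, csv_path, json_path)
        return [csv_path, json_path]
    raise ConfigError(f"unknown fixture kind {kind!r}")
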
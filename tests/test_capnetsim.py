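"""Random capillary networks: topology statistics, geometry sampling,
Kirchhoff solve against closed forms and a dense oracle."""

import dataclasses

import numpy as np
import pytest

from capnet import capnetsim as cn
from capnet import hemres
from capnet.errors import ConfigError, SingularSystem

UM = 1e-6


def manual_network(dims, edges, length_um=57.4, rc_um=2.8, H=0.1):
    """Hand-built network with uniform geometry for closed-form checks."""
    edges = np.asarray(edges, dtype=np.int64)
    net = cn.CapillaryNetwork(
        dims=dims,
        edges=edges,
        length=np.full(len(edges), length_um * UM),
        radius=np.full(len(edges), rc_um * UM),
    )
    return cn.assign_resistances(net, H)


class TestTopology:
    def test_four_edge_mean_degree(self):
        spec = cn.TopologySpec(dims=(20, 20, 20), mean_degree=4, seed=3)
        net = cn.generate_topology(spec)
        assert 3.8 <= net.mean_degree <= 4.2

    def test_three_edge_mean_degree(self):
        spec = cn.TopologySpec(dims=(20, 20, 20), mean_degree=3, seed=3)
        net = cn.generate_topology(spec)
        assert 2.8 <= net.mean_degree <= 3.2

    def test_minimal_lattice_has_at_most_one_edge(self):
        net = cn.generate_topology(cn.TopologySpec(dims=(1, 1, 2), mean_degree=2, seed=0))
        assert net.n_edges <= 1

    def test_seed_determinism(self):
        spec = cn.TopologySpec(dims=(8, 8, 8), mean_degree=3, seed=11)
        a = cn.generate_topology(spec)
        b = cn.generate_topology(spec)
        np.testing.assert_array_equal(a.edges, b.edges)

    def test_no_self_loops_or_duplicates(self):
        net = cn.generate_topology(cn.TopologySpec(dims=(10, 10, 10), mean_degree=4, seed=5))
        assert np.all(net.edges[:, 0] != net.edges[:, 1])
        pairs = set(map(tuple, np.sort(net.edges, axis=1)))
        assert len(pairs) == net.n_edges


class TestGeometry:
    def test_sample_means_hit_morphometric_targets(self):
        spec = cn.TopologySpec(dims=(41, 41, 41), mean_degree=3, seed=2)
        net = cn.sample_geometry(cn.generate_topology(spec), cn.GeometrySampler(seed=7))
        assert net.n_edges > 9e4
        assert net.length.mean() == pytest.approx(57.4 * UM, rel=0.01)
        assert net.radius.mean() == pytest.approx(2.95 * UM, rel=0.02)
        assert net.radius.min() > 1.6 * UM

    def test_zero_cv_degenerates_to_constants(self):
        spec = cn.TopologySpec(dims=(4, 4, 4), mean_degree=3, seed=0)
        net = cn.sample_geometry(
            cn.generate_topology(spec), cn.GeometrySampler(cv=0.0, seed=0)
        )
        assert np.allclose(net.length, 57.4 * UM)
        assert np.allclose(net.radius, 2.95 * UM)

    def test_sampler_determinism(self):
        spec = cn.TopologySpec(dims=(6, 6, 6), mean_degree=4, seed=1)
        base = cn.generate_topology(spec)
        a = cn.sample_geometry(base, cn.GeometrySampler(seed=9))
        b = cn.sample_geometry(base, cn.GeometrySampler(seed=9))
        np.testing.assert_array_equal(a.length, b.length)
        np.testing.assert_array_equal(a.radius, b.radius)

    def test_bounds_excluding_mean_rejected(self):
        with pytest.raises(ConfigError):
            cn.GeometrySampler(length_bounds=(80e-6, 120e-6))


class TestResistances:
    def test_single_edge_frozen_value(self):
        net = manual_network((2, 1, 1), [(0, 1)], H=0.1)
        assert net.resistance[0] == pytest.approx(3.15e15, rel=2e-3)

    def test_h_zero_constant_viscosity_gives_poiseuille(self):
        net = cn.CapillaryNetwork(
            dims=(2, 1, 1),
            edges=np.array([[0, 1]]),
            length=np.array([57.4 * UM]),
            radius=np.array([2.8 * UM]),
        )
        out = cn.assign_resistances(net, 0.0, hemres.ViscosityModel.constant())
        assert out.resistance[0] == pytest.approx(
            hemres.poiseuille_resistance(2.8 * UM, 57.4 * UM, 1e-3)
        )

    def test_edgewise_hematocrit_ratio(self):
        """Per-edge resistance ratio H=0.4 vs 0.1 at the mean radius."""
        a = manual_network((2, 1, 1), [(0, 1)], rc_um=2.95, H=0.1)
        b = manual_network((2, 1, 1), [(0, 1)], rc_um=2.95, H=0.4)
        assert b.resistance[0] / a.resistance[0] == pytest.approx(1.61, abs=0.005)


class TestBoundaries:
    def test_fraction_expectations(self):
        spec = cn.TopologySpec(dims=(22, 22, 22), mean_degree=3, seed=0)
        net = cn.place_sources_sinks(cn.generate_topology(spec), 0.02, 0.02, seed=4)
        n = net.n_nodes
        assert len(net.inlets) == pytest.approx(0.02 * n, rel=0.05)
        assert len(net.outlets) == pytest.approx(0.02 * n, rel=0.05)
        assert not set(net.inlets) & set(net.outlets)

    def test_zero_fraction_rejected(self):
        net = cn.generate_topology(cn.TopologySpec(dims=(4, 4, 4), seed=0))
        with pytest.raises(ConfigError):
            cn.place_sources_sinks(net, 0.0, 0.02)

    def test_placement_determinism(self):
        net = cn.generate_topology(cn.TopologySpec(dims=(6, 6, 6), seed=0))
        a = cn.place_sources_sinks(net, 0.05, 0.05, seed=3)
        b = cn.place_sources_sinks(net, 0.05, 0.05, seed=3)
        np.testing.assert_array_equal(a.inlets, b.inlets)
        np.testing.assert_array_equal(a.outlets, b.outlets)


class TestKirchhoffSolve:
    def test_single_edge(self):
        net = manual_network((2, 1, 1), [(0, 1)])
        net = dataclasses.replace(
            net, inlets=np.array([0]), outlets=np.array([1]), p_in=2.0, p_out=0.0
        )
        sol = cn.solve_flow(net)
        R = net.resistance[0]
        assert sol.total_inflow == pytest.approx(2.0 / R, rel=1e-12)
        assert sol.total_resistance == pytest.approx(R, rel=1e-12)

    def test_two_edges_in_series(self):
        net = manual_network((3, 1, 1), [(0, 1), (1, 2)])
        r2 = net.resistance.copy()
        r2[1] *= 3.0  # unequal series pair
        net = dataclasses.replace(
            net, resistance=r2, inlets=np.array([0]), outlets=np.array([2])
        )
        sol = cn.solve_flow(net)
        assert sol.total_resistance == pytest.approx(r2.sum(), rel=1e-12)

    @pytest.mark.parametrize("n", [2, 7])
    def test_identical_edges_in_parallel(self, n):
        edges = [(2 * k, 2 * k + 1) for k in range(n)]
        # lattice (2, n, 1): x-neighbours only, n disconnected rungs
        net = manual_network((2, n, 1), edges)
        net = dataclasses.replace(
            net,
            inlets=np.arange(0, 2 * n, 2),
            outlets=np.arange(1, 2 * n, 2),
        )
        sol = cn.solve_flow(net)
        assert sol.total_resistance == pytest.approx(net.resistance[0] / n, rel=1e-12)

    def test_matches_dense_oracle_on_small_network(self):
        """Sparse reduced solve equals a dense brute-force solve of the
        same conductance-Laplacian system."""
        spec = cn.TopologySpec(dims=(4, 4, 4), mean_degree=3, seed=8)
        net = cn.build_network(spec, cn.GeometrySampler(seed=9), H=0.3,
                               inlet_fraction=0.05, outlet_fraction=0.05)
        sol = cn.solve_flow(net)

        n = net.n_nodes
        lap = np.zeros((n, n))
        for (i, j), R in zip(net.edges, net.resistance):
            g = 1.0 / R
            lap[i, i] += g
            lap[j, j] += g
            lap[i, j] -= g
            lap[j, i] -= g
        fixed = np.zeros(n, dtype=bool)
        fixed[net.inlets] = True
        fixed[net.outlets] = True
        pvals = np.zeros(n)
        pvals[net.inlets] = net.p_in
        free = ~fixed & sol.included
        p_free = np.linalg.solve(
            lap[np.ix_(free, free)], -lap[np.ix_(free, fixed)] @ pvals[fixed]
        )
        dense = pvals.copy()
        dense[free] = p_free
        mask = sol.included
        np.testing.assert_allclose(sol.pressure[mask], dense[mask], rtol=1e-10, atol=1e-12)

    def test_flux_conservation_at_interior_nodes(self):
        spec = cn.TopologySpec(dims=(10, 10, 10), mean_degree=3, seed=2)
        net = cn.build_network(spec, cn.GeometrySampler(seed=3), H=0.4)
        sol = cn.solve_flow(net)
        assert sol.kirchhoff_residual(net) <= 1e-8
        # global balance: inflow equals outflow
        net_out = np.zeros(net.n_nodes)
        np.add.at(net_out, net.edges[:, 0], sol.edge_flux)
        np.add.at(net_out, net.edges[:, 1], -sol.edge_flux)
        outflow = -net_out[net.outlets].sum()
        assert outflow == pytest.approx(sol.total_inflow, rel=1e-10)

    def test_no_flow_path_raises(self):
        net = manual_network((2, 2, 1), [(0, 1), (2, 3)])
        net = dataclasses.replace(net, inlets=np.array([0]), outlets=np.array([3]))
        with pytest.raises(SingularSystem):
            cn.solve_flow(net)

    def test_homogeneity_in_resistance_scale(self):
        spec = cn.TopologySpec(dims=(6, 6, 6), mean_degree=3, seed=5)
        net = cn.build_network(spec, cn.GeometrySampler(seed=6), H=0.2)
        base = cn.solve_flow(net).total_resistance
        scaled = dataclasses.replace(net, resistance=net.resistance * 7.0)
        assert cn.solve_flow(scaled).total_resistance == pytest.approx(
            7.0 * base, rel=1e-9
        )


class TestNetworkScalingLaws:
    def test_resistance_nondecreasing_in_H(self):
        spec = cn.TopologySpec(dims=(8, 8, 8), mean_degree=3, seed=4)
        net = cn.build_network(spec, cn.GeometrySampler(seed=5), H=0.1)
        vals = []
        for H in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            vals.append(cn.solve_flow(cn.assign_resistances(net, H)).total_resistance)
        assert np.all(np.diff(vals) > 0)

    def test_linear_in_H_for_large_networks(self):
        """Total resistance versus hematocrit is linear (R^2 > 0.99)
        for networks of ~1e4 capillaries."""
        spec = cn.TopologySpec(dims=cn.dims_for_edges(10_000, 3), mean_degree=3, seed=1)
        net = cn.build_network(spec, cn.GeometrySampler(seed=2), H=0.1)
        H = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        R = np.array(
            [cn.solve_flow(cn.assign_resistances(net, h)).total_resistance for h in H]
        )
        fit = np.polyfit(H, R, 1)
        ss_res = np.sum((R - np.polyval(fit, H)) ** 2)
        ss_tot = np.sum((R - R.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_three_edge_beats_four_edge(self):
        """Fewer parallel paths: 3-edge topology is more resistive than
        4-edge at identical dims, sampler, hematocrit and boundaries."""
        for seed in range(5):
            dims = (12, 12, 12)
            r = {}
            for deg in (3, 4):
                spec = cn.TopologySpec(dims=dims, mean_degree=deg, seed=seed)
                net = cn.build_network(spec, cn.GeometrySampler(seed=seed + 50), H=0.35)
                r[deg] = cn.solve_flow(net).total_resistance
            assert r[3] > r[4]

    def test_size_scaling_one_over_n(self):
        """With fixed inlet/outlet fractions, R_total * n_edges is stable
        across network sizes (the lumped 1/N extrapolation rule)."""
        products = []
        for n_edges in (1_000, 10_000, 100_000):
            spec = cn.TopologySpec(dims=cn.dims_for_edges(n_edges, 3), mean_degree=3, seed=7)
            net = cn.build_network(spec, cn.GeometrySampler(seed=8), H=0.35)
            sol = cn.solve_flow(net)
            products.append(sol.total_resistance * net.n_edges)
        ref = np.mean(products)
        assert np.all(np.abs(np.array(products) / ref - 1) < 0.15)

    def test_resistance_vs_H_table(self):
        spec = cn.TopologySpec(dims=(8, 8, 8), mean_degree=3, seed=0)
        table, slope = cn.total_resistance_vs_H(
            spec, cn.GeometrySampler(seed=1), [0.1, 0.4], replicates=3
        )
        assert set(table["H"]) == {0.1, 0.4}
        assert slope > 0
        assert (table["sd"] > 0).all()


class TestSerialization:
    def test_round_trip_lossless(self, tmp_path):
        spec = cn.TopologySpec(dims=(5, 5, 5), mean_degree=3, seed=2)
        net = cn.build_network(spec, cn.GeometrySampler(seed=3), H=0.4)
        csv = tmp_path / "net.csv"
        cn.write_network(net, csv)
        back = cn.read_network(csv)
        assert back.dims == net.dims
        np.testing.assert_array_equal(back.edges, net.edges)
        np.testing.assert_allclose(back.length, net.length, rtol=1e-11)
        np.testing.assert_allclose(back.radius, net.radius, rtol=1e-11)
        np.testing.assert_allclose(back.resistance, net.resistance, rtol=1e-11)
        np.testing.assert_array_equal(back.inlets, net.inlets)
        # solving the read-back network reproduces the resistance
        a = cn.solve_flow(net).total_resistance
        b = cn.solve_flow(back).total_resistance
        assert b == pytest.approx(a, rel=1e-10)

    def test_pressure_export_schema(self, tmp_path):
        import pandas as pd

        spec = cn.TopologySpec(dims=(4, 4, 4), mean_degree=3, seed=2)
        net = cn.build_network(spec, cn.GeometrySampler(seed=3), H=0.4)
        sol = cn.solve_flow(net)
        path = tmp_path / "pressures.csv"
        cn.export_pressures(net, sol, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["node", "x", "y", "z", "pressure_pa"]
        assert len(df) == net.n_nodes
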
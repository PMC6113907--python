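"""Engine: coupling currents, clamping, determinism, convergence."""

import numpy as np
import pytest

from islethub.architecture import generate_mouse_like
from islethub.assembly import assemble_network
from islethub.engine import (SimulationProtocol, coupling_current,
                             coupling_currents, nested_inhibition_sets,
                             run_protocol)


@pytest.fixture(scope="module")
def tiny_net():
    return assemble_network(generate_mouse_like(60, rng_seed=2),
                            master_seed=2)


class TestCouplingCurrent:
    def test_uniform_potential_gives_zero_current(self, tiny_net):
        vm = np.full(tiny_net.n_cells, -55.0)
        assert np.allclose(coupling_currents(vm, tiny_net.gap_junctions), 0)

    def test_two_cell_antisymmetry(self):
        from islethub.assembly import GapJunctionTable

        gj = GapJunctionTable(np.array([[0, 1]]), np.array([50.0]),
                              "unimodal")
        vm = np.array([-40.0, -60.0])
        i0 = coupling_current(0, vm, gj)
        i1 = coupling_current(1, vm, gj)
        assert i0 == pytest.approx(1e-3 * 50.0 * 20.0)
        assert i0 == pytest.approx(-i1)

    def test_global_conservation_at_random_state(self, tiny_net):
        """Pairwise cancellation: Σᵢ I_coup,i = 0 for any Vm vector."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            vm = rng.uniform(-100, 0, size=tiny_net.n_cells)
            i_coup = coupling_currents(vm, tiny_net.gap_junctions)
            assert abs(i_coup.sum()) < 1e-9 * tiny_net.n_cells

    def test_vector_and_scalar_paths_agree(self, tiny_net):
        rng = np.random.default_rng(1)
        vm = rng.uniform(-80, -20, size=tiny_net.n_cells)
        vec = coupling_currents(vm, tiny_net.gap_junctions)
        for i in (0, 7, 31):
            assert vec[i] == pytest.approx(
                coupling_current(i, vm, tiny_net.gap_junctions), rel=1e-9)


class TestNestedInhibitionSets:
    def test_paper_scale_set_sizes_are_nested(self):
        net = assemble_network(generate_mouse_like(750, rng_seed=1),
                               master_seed=1)
        sets = nested_inhibition_sets(net, [2, 4, 6], "hub", 0)
        assert [len(s) for s in sets] == [15, 30, 45]
        assert set(sets[0]) <= set(sets[1]) <= set(sets[2])
        assert set(sets[2]) <= set(net.hubs)

    def test_nonhub_sets_disjoint_from_hubs(self, tiny_net):
        sets = nested_inhibition_sets(tiny_net, [5, 10], "nonhub", 0)
        assert not set(sets[-1]) & set(tiny_net.hubs)

    def test_fraction_zero_gives_empty_set(self, tiny_net):
        (s,) = nested_inhibition_sets(tiny_net, [0], "hub", 0)
        assert len(s) == 0

    def test_overdrawing_the_pool_raises(self, tiny_net):
        with pytest.raises(ValueError, match="pool"):
            nested_inhibition_sets(tiny_net, [50], "hub", 0)

    def test_unknown_target_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            nested_inhibition_sets(tiny_net, [1], "everything", 0)


SHORT = SimulationProtocol(equilibration_s=10.0, baseline_s=15.0,
                           inhibition_s=15.0, recovery_s=0.0, rtol=1e-5)


@pytest.fixture(scope="module")
def short_run(tiny_net):
    """One uninhibited short run shared by several checks."""
    return run_protocol(tiny_net, SHORT)


class TestRunProtocol:
    def test_deterministic_replay_is_bit_identical(self, tiny_net,
                                                   short_run):
        r2 = run_protocol(tiny_net, SHORT)
        assert np.array_equal(short_run.ca, r2.ca)
        assert np.array_equal(short_run.vm, r2.vm)

    def test_clamped_cells_sit_at_clamp_voltage(self, bimodal_runs):
        res = bimodal_runs["results"]["hub"][-1]
        mask = res.epoch_mask("inhibition")
        vm = res.vm[mask][:, res.inhibited]
        assert np.allclose(vm, res.clamp_mv)

    def test_empty_inhibited_set_keeps_dynamics_unchanged(self, short_run):
        """Baseline and 'inhibition' epochs are the same dynamics when
        nothing is clamped."""
        res = short_run
        base = res.epoch_trace("baseline").mean(axis=1)
        inhib = res.epoch_trace("inhibition").mean(axis=1)
        # same dynamical regime: comparable levels and spread
        assert abs(np.median(inhib) - np.median(base)) < 0.2
        assert np.ptp(inhib) < 3 * max(np.ptp(base), 0.05) + 0.1

    def test_inhibiting_every_cell_floors_activity(self, tiny_net):
        proto = SHORT.with_(inhibited=tuple(range(tiny_net.n_cells)))
        res = run_protocol(tiny_net, proto)
        inhib_ca = res.epoch_trace("inhibition")
        assert np.all(res.epoch_trace("inhibition", "vm") == -100.0)
        # Ca²⁺ falls toward the silent floor everywhere
        assert inhib_ca[-1].max() < 0.15

    def test_conservation_along_simulated_trajectory(self, bimodal_runs):
        """Σᵢ I_coup,i = 0 at every output sample of a real run."""
        res = bimodal_runs["results"]["hub"][0]
        net = bimodal_runs["network"]
        for k in range(0, res.vm.shape[0], 37):
            i_coup = coupling_currents(res.vm[k], net.gap_junctions)
            assert abs(i_coup.sum()) < 1e-9 * net.n_cells

    def test_solver_convergence_under_tolerance_halving(self, tiny_net):
        """Halving rtol changes the mean Ca²⁺ trace by < 1% RMS over a
        10 s window (before burst-timing phase drift accumulates)."""
        proto = SimulationProtocol(equilibration_s=0.0, baseline_s=10.0,
                                   inhibition_s=0.0, recovery_s=0.0,
                                   rtol=1e-6)
        r1 = run_protocol(tiny_net, proto)
        r2 = run_protocol(tiny_net, proto.with_(rtol=5e-7))
        m1, m2 = r1.mean_ca(), r2.mean_ca()
        assert np.sqrt(np.mean((m1 - m2) ** 2)) / m1.mean() < 0.01

    def test_out_of_range_inhibited_index_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            run_protocol(tiny_net, SHORT.with_(inhibited=(10_000,)))

    def test_trajectories_are_finite_and_calcium_nonnegative(self,
                                                             bimodal_runs):
        for series in bimodal_runs["results"].values():
            for res in series:
                assert np.all(np.isfinite(res.ca))
                assert np.all(res.ca >= 0)
                assert np.all(res.vm >= -150) and np.all(res.vm <= 60)

    def test_hdf5_roundtrip(self, short_run, tmp_path):
        from islethub.engine import SimulationResult

        res = short_run
        path = tmp_path / "run.h5"
        res.save(path)
        back = SimulationResult.load(path)
        assert np.allclose(back.ca, res.ca, atol=1e-5)
        assert back.epochs.keys() == res.epochs.keys()

    def test_summary_frame_labels_epochs(self, short_run):
        df = short_run.summary_frame()
        assert set(df.epoch.dropna()) == {"baseline", "inhibition"}

    def test_summary_frame_mean_matches_traces(self, short_run):
        df = short_run.summary_frame()
        assert np.allclose(df.mean_ca_uM.to_numpy(), short_run.mean_ca())


class TestMonotoneHubDoseEffect:
    def test_activity_nonincreasing_in_hub_fraction_across_seeds(self):
        """Mean post-transient activity declines as more hubs are clamped,
        averaged over 3 independent islets."""
        from islethub.analysis import activity_metrics, binarize_traces

        fractions = (0.0, 4.0, 8.0)
        proto = SimulationProtocol(equilibration_s=30.0, baseline_s=25.0,
                                   inhibition_s=25.0, recovery_s=0.0,
                                   rtol=1e-5)
        acts = []
        for seed in (0, 1, 2):
            net = assemble_network(generate_mouse_like(80, rng_seed=seed),
                                   master_seed=seed, gj_mode="bimodal")
            sets = nested_inhibition_sets(net, fractions, "hub", seed)
            row = []
            for cells in sets:
                res = run_protocol(net, proto.with_(
                    inhibited=tuple(int(c) for c in cells)))
                raster = binarize_traces(
                    res.ca, res.time_s,
                    baseline_mask=res.epoch_mask("baseline"))
                row.append(activity_metrics(res, raster,
                                            "inhibition")["amplitude"])
            acts.append(row)
        mean = np.mean(acts, axis=0)
        assert mean[0] > mean[1] > mean[2] - 5.0
        assert mean[2] < 0.8 * mean[0]
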
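"""HNMMC engine: schedule, proposals, moves, closure, Metropolis, runs."""

import math

import numpy as np
import pytest

from hnmmc.forcefield import EnergyEvaluator, ScalingParams
from hnmmc.model import CA_CA_BAND
from hnmmc.sampler import (AnnealSchedule, MCState, MoveProposal,
                           apply_move, close_chain, metropolis_accept,
                           propose_region_move, rotation_matrix, run_mcmc,
                           run_replicas, temperature_at)
from hnmmc.synthetic import go_bead_types, make_go_potential, make_toy_complex


class TestAnnealSchedule:
    def test_extrema_with_printed_parameters(self):
        sched = AnnealSchedule()  # A=600 K, period 5000, shift 0
        assert temperature_at(0, sched) == pytest.approx(600.0)
        assert temperature_at(2500, sched) == pytest.approx(0.0, abs=1e-9)

    def test_periodicity(self):
        sched = AnnealSchedule(amplitude=450.0, period=700, shift=25.0)
        for k in (0, 13, 350, 699, 12345):
            assert temperature_at(k + 700, sched) == \
                pytest.approx(temperature_at(k, sched))

    def test_bounds_are_shift_and_shift_plus_amplitude(self):
        sched = AnnealSchedule(amplitude=300.0, period=400, shift=50.0)
        T = temperature_at(np.arange(800), sched)
        assert T.min() == pytest.approx(50.0)
        assert T.max() == pytest.approx(350.0)
        assert np.all(T >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            AnnealSchedule(amplitude=-1)
        with pytest.raises(ValueError):
            AnnealSchedule(period=1)
        with pytest.raises(ValueError):
            AnnealSchedule(shift=-5)


class TestProposals:
    def _state(self, toy, toy_potential, toy_bead_types, seed=0):
        structure, hierarchy, _ = toy
        s = structure.copy()
        ev = EnergyEvaluator(s, toy_potential, bead_types=toy_bead_types)
        return MCState(s, hierarchy, hierarchy.resolve(s), ev,
                       ev.total(s.coords).total, 0,
                       np.random.default_rng(seed))

    def test_deterministic_given_rng_state(self, toy, toy_potential,
                                           toy_bead_types):
        st = self._state(toy, toy_potential, toy_bead_types)
        p1 = propose_region_move(st, 0, np.random.default_rng(42))
        p2 = propose_region_move(st, 0, np.random.default_rng(42))
        np.testing.assert_array_equal(p1.translation, p2.translation)
        np.testing.assert_array_equal(p1.axis, p2.axis)
        assert p1.angle_deg == p2.angle_deg

    def test_translation_mean_is_zero(self, toy, toy_potential,
                                      toy_bead_types):
        st = self._state(toy, toy_potential, toy_bead_types)
        rng = np.random.default_rng(7)
        n = 20000
        node = st.hierarchy.nodes[0]
        t = np.array([propose_region_move(st, 0, rng).translation
                      for _ in range(n)])
        # uniform on [-t_max, t_max]: SE of the mean = t_max/sqrt(3 n)
        se = node.max_translation / math.sqrt(3 * n)
        assert np.all(np.abs(t.mean(axis=0)) < 3 * se)
        assert np.all(np.abs(t) <= node.max_translation)

    def test_pivot_is_ca_centroid(self, toy, toy_potential, toy_bead_types):
        st = self._state(toy, toy_potential, toy_bead_types)
        prop = propose_region_move(st, 2, np.random.default_rng(0))
        ca_idx = st.resolved[2]["ca_idx"]
        np.testing.assert_allclose(prop.pivot,
                                   st.structure.coords[ca_idx].mean(axis=0))


class TestApplyMove:
    def test_identity_proposal_is_noop(self, toy):
        structure = toy[0].copy()
        res = toy[1].resolve(structure)
        before = structure.coords.copy()
        prop = MoveProposal(0, np.zeros(3), np.array([0, 0, 1.0]), 0.0,
                            np.zeros(3))
        apply_move(structure, prop, res[0]["bead_idx"])
        np.testing.assert_allclose(structure.coords, before, atol=1e-15)

    def test_pure_translation_shifts_node_beads_only(self, toy):
        structure = toy[0].copy()
        res = toy[1].resolve(structure)
        before = structure.coords.copy()
        idx = res[1]["bead_idx"]
        prop = MoveProposal(1, np.array([0.1, 0, 0]),
                            np.array([0, 0, 1.0]), 0.0, np.zeros(3))
        apply_move(structure, prop, idx)
        np.testing.assert_allclose(structure.coords[idx],
                                   before[idx] + [0.1, 0, 0], atol=1e-12)
        other = np.setdiff1d(np.arange(structure.n_beads), idx)
        np.testing.assert_array_equal(structure.coords[other], before[other])

    def test_rotation_preserves_internal_distances(self, toy):
        rng = np.random.default_rng(3)
        structure = toy[0].copy()
        res = toy[1].resolve(structure)
        idx = res[5]["bead_idx"]
        before = structure.coords[idx].copy()
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        prop = MoveProposal(5, rng.uniform(-0.1, 0.1, 3), axis, 37.5,
                            before.mean(axis=0))
        apply_move(structure, prop, idx)
        after = structure.coords[idx]
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)


def _perturb_and_close(structure, hierarchy, node_label, proposal_args,
                       **close_kwargs):
    res = hierarchy.resolve(structure)
    ni = [i for i, n in enumerate(hierarchy.nodes)
          if n.label == node_label][0]
    node_res = res[ni]
    pre = {}
    for ci, lo, hi in node_res["spans"]:
        clen = len(structure.residue_numbers[ci])
        for b in range(max(lo - 1, 0), min(hi + 1, clen - 1)):
            pre[(ci, b)] = np.linalg.norm(
                structure.coords[structure._ca_index[(ci, b + 1)]]
                - structure.coords[structure._ca_index[(ci, b)]])
    prop = MoveProposal(ni, *proposal_args,
                        structure.coords[node_res["ca_idx"]].mean(axis=0))
    apply_move(structure, prop, node_res["bead_idx"])
    return close_chain(structure, node_res["spans"], pre, **close_kwargs)


class TestChainClosure:
    def test_whole_chain_move_needs_no_closure(self, toy):
        structure = toy[0].copy()
        before = structure.coords.copy()
        result = _perturb_and_close(structure, toy[1], "peptide:whole",
                                    (np.array([0.5, 0.5, 0.5]),
                                     np.array([0, 0, 1.0]), 0.0))
        assert result.converged and not result.residuals
        # translated rigidly, nothing pulled back
        idx = toy[1].resolve(structure)[-1]["bead_idx"]
        np.testing.assert_allclose(structure.coords[idx],
                                   before[idx] + 0.5, atol=1e-12)

    def test_gap_restored_within_tolerance(self, toy):
        structure = toy[0].copy()
        result = _perturb_and_close(structure, toy[1], "mhc:helix1a",
                                    (np.array([0.05, 0.0, 0.0]),
                                     np.array([0, 0, 1.0]), 3.0))
        assert result.converged
        assert all(r <= 0.02 for r in result.residuals.values())
        structure.validate()  # virtual-bond band intact everywhere

    def test_interior_subregion_both_breaks_closed(self, toy):
        structure = toy[0].copy()
        result = _perturb_and_close(structure, toy[1], "peptide:sub2",
                                    (np.array([0.0, 0.0, 0.05]),
                                     np.array([1.0, 0, 0]), 4.0))
        assert result.converged
        assert len(result.residuals) == 2
        assert all(r <= 0.02 for r in result.residuals.values())

    def test_unreachable_gap_flags_non_convergence(self, toy):
        structure = toy[0].copy()
        result = _perturb_and_close(structure, toy[1], "peptide:sub2",
                                    (np.array([0.0, 0.0, 2.5]),
                                     np.array([1.0, 0, 0]), 0.0))
        assert not result.converged


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-1.0, T, rng) for T in (0.0, 1.0, 1e4))

    def test_uphill_rejected_at_zero_temperature(self):
        rng = np.random.default_rng(0)
        assert not metropolis_accept(5.0, 0.0, rng)

    def test_acceptance_frequency_matches_boltzmann_factor(self):
        # dE = +1 (k_B*T_ref units) at T = T_ref: P(accept) = 1/e
        rng = np.random.default_rng(123)
        n = 100_000
        acc = sum(metropolis_accept(1.0, 300.0, rng) for _ in range(n))
        p = math.exp(-1.0)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(acc / n - p) < 3 * se

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, -1.0, np.random.default_rng(0))


class TestRunMCMC:
    def test_zero_steps_yields_initial_snapshot_only(self, toy,
                                                     toy_potential,
                                                     toy_bead_types):
        traj = run_mcmc(toy[0], toy[1], toy_potential, seed=0, n_steps=0,
                        bead_types=toy_bead_types)
        assert len(traj.snapshot_steps) == 1
        np.testing.assert_array_equal(traj.coords[0], toy[0].coords)

    def test_zero_amplitudes_keep_energy_constant(self, toy, toy_potential,
                                                  toy_bead_types):
        from hnmmc.model import HierarchyNode, RegionHierarchy

        frozen = RegionHierarchy([
            HierarchyNode(n.label, n.segments, n.children, 0.0, 0.0,
                          n.weight) for n in toy[1].nodes])
        traj = run_mcmc(toy[0], frozen, toy_potential, seed=0, n_steps=300,
                        snapshot_stride=50, bead_types=toy_bead_types)
        assert np.ptp(traj.snapshot_energies) == 0.0
        assert np.ptp(traj.step_log["energy"]) == 0.0

    def test_bit_reproducible_for_fixed_seed(self, toy, toy_potential,
                                             toy_bead_types):
        kwargs = dict(seed=5, n_steps=400, snapshot_stride=100,
                      bead_types=toy_bead_types)
        t1 = run_mcmc(toy[0], toy[1], toy_potential, **kwargs)
        t2 = run_mcmc(toy[0], toy[1], toy_potential, **kwargs)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(t1.step_log["energy"],
                                      t2.step_log["energy"])

    def test_chain_integrity_band_maintained(self, toy, toy_potential,
                                             toy_bead_types):
        traj = run_mcmc(toy[0], toy[1], toy_potential, seed=2, n_steps=1500,
                        snapshot_stride=100, bead_types=toy_bead_types)
        final = toy[0].copy()
        for xyz in traj.coords:
            final.coords = xyz.copy()
            d = final.consecutive_ca_distances()
            assert d.min() >= CA_CA_BAND[0] and d.max() <= CA_CA_BAND[1]

    def test_temperature_trace_reproduces_schedule(self, toy, toy_potential,
                                                   toy_bead_types):
        sched = AnnealSchedule(amplitude=100.0, period=50, shift=10.0)
        traj = run_mcmc(toy[0], toy[1], toy_potential, schedule=sched,
                        seed=0, n_steps=200, snapshot_stride=40,
                        bead_types=toy_bead_types)
        np.testing.assert_allclose(
            traj.step_log["temperature"],
            temperature_at(np.arange(200), sched))
        np.testing.assert_allclose(
            traj.snapshot_temperatures,
            temperature_at(traj.snapshot_steps, sched))


class TestRunReplicas:
    def test_single_replica_equals_run_mcmc(self, toy, toy_potential,
                                            toy_bead_types):
        from hnmmc.analysis import probe_distances

        structure, hierarchy, probes = toy
        rset = run_replicas(structure, hierarchy, toy_potential,
                            n_replicas=1, base_seed=9, probes=probes,
                            n_steps=300, snapshot_stride=100,
                            bead_types=toy_bead_types, peptide_chain="P")
        traj = run_mcmc(structure, hierarchy, toy_potential, seed=9,
                        n_steps=300, snapshot_stride=100,
                        bead_types=toy_bead_types)
        resolved = probes.resolve(structure)
        want = np.stack([np.minimum(probe_distances(x, probes, resolved), 3.0)
                         for x in traj.coords])
        np.testing.assert_allclose(rset.distances[0], want)

    def test_same_base_seed_bit_identical(self, toy, toy_potential,
                                          toy_bead_types):
        structure, hierarchy, probes = toy
        kwargs = dict(n_replicas=2, base_seed=4, probes=probes, n_steps=200,
                      snapshot_stride=50, bead_types=toy_bead_types,
                      peptide_chain="P")
        r1 = run_replicas(structure, hierarchy, toy_potential, **kwargs)
        r2 = run_replicas(structure, hierarchy, toy_potential, **kwargs)
        np.testing.assert_array_equal(r1.distances, r2.distances)

    def test_distinct_seeds_diverge(self, toy, toy_potential,
                                    toy_bead_types):
        structure, hierarchy, probes = toy
        rset = run_replicas(structure, hierarchy, toy_potential,
                            n_replicas=2, base_seed=0, probes=probes,
                            n_steps=500, snapshot_stride=50,
                            bead_types=toy_bead_types, peptide_chain="P")
        assert not np.array_equal(rset.distances[0], rset.distances[1])
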
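"""Ground-truth generators: determinism, degenerate limits, concentration."""

import numpy as np
import pytest

from chromstate import (
    GenomeLayout,
    SimulationConfig,
    default_config,
    simulate_condition_pair,
    simulate_enhancer_replicates,
    simulate_enhancer_sequences,
    simulate_marks,
    simulate_methylation,
    simulate_state_chain,
)
from chromstate.dynamics import flow_matrix
from chromstate.segmentation import Segmentation


def _small_cfg(seed=0, n_bins=20_000, **kw):
    layout = GenomeLayout(("chr1", "chr2"), (n_bins * 100, n_bins * 100), 200)
    return default_config(seed=seed, layout=layout, **kw)


class TestDeterminism:
    def test_identical_seeds_bit_identical(self):
        cfg = _small_cfg(seed=5, n_bins=2000)
        a1 = simulate_state_chain(cfg)
        a2 = simulate_state_chain(cfg)
        assert np.array_equal(a1.states, a2.states)
        m1, _ = zip(*[(t.calls, t.mark) for t in simulate_marks(a1, cfg)])
        m2, _ = zip(*[(t.calls, t.mark) for t in simulate_marks(a2, cfg)])
        for x, y in zip(m1, m2):
            assert np.array_equal(x, y)
        t1 = simulate_methylation(a1, cfg).sites
        t2 = simulate_methylation(a2, cfg).sites
        assert t1.equals(t2)
        s1 = simulate_enhancer_sequences(5, 5, 100, cfg)
        s2 = simulate_enhancer_sequences(5, 5, 100, cfg)
        assert s1 == s2

    def test_different_seeds_differ(self):
        a = simulate_state_chain(_small_cfg(seed=0, n_bins=2000))
        b = simulate_state_chain(_small_cfg(seed=1, n_bins=2000))
        assert not np.array_equal(a.states, b.states)

    def test_substreams_are_independent(self):
        # the chain is unchanged whether or not other generators also ran
        cfg = _small_cfg(seed=9, n_bins=1000)
        a1 = simulate_state_chain(cfg)
        simulate_methylation(a1, cfg)
        a2 = simulate_state_chain(cfg)
        assert np.array_equal(a1.states, a2.states)


class TestStateChain:
    def test_single_state_all_zero(self):
        layout = GenomeLayout(("chr1",), (10_000,), 200)
        cfg = SimulationConfig(
            layout=layout,
            state_names=("only",),
            mark_names=("m",),
            emission_truth=np.array([[0.5]]),
        )
        seg = simulate_state_chain(cfg)
        assert (seg.states == 0).all()

    def test_identity_transition_constant_chain(self):
        layout = GenomeLayout(("chr1",), (10_000,), 200)
        cfg = SimulationConfig(
            layout=layout,
            state_names=("a", "b"),
            mark_names=("m",),
            emission_truth=np.array([[0.1], [0.9]]),
            transition_truth=np.eye(2),
        )
        seg = simulate_state_chain(cfg)
        assert len(np.unique(seg.states)) == 1

    def test_transition_frequencies_concentrate(self):
        cfg = _small_cfg(seed=3, n_bins=100_000)
        seg = simulate_state_chain(cfg)
        K = cfg.n_states
        counts = np.zeros((K, K))
        for name in cfg.layout.chrom_names:
            s = seg.chrom_states(name)
            np.add.at(counts, (s[:-1], s[1:]), 1)
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(emp - cfg.transition_truth).max() <= 0.01

    def test_degenerate_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(
                layout=GenomeLayout(("chr1",), (1000,), 200),
                state_names=("a", "b"),
                mark_names=("m",),
                emission_truth=np.array([[0.5], [0.5]]),
                transition_truth=np.array([[0.5, 0.4], [0.5, 0.5]]),
            )


class TestMarks:
    @pytest.mark.parametrize("value", [0.0, 1.0])
    def test_degenerate_emissions(self, value):
        layout = GenomeLayout(("chr1",), (10_000,), 200)
        cfg = SimulationConfig(
            layout=layout,
            state_names=("a", "b"),
            mark_names=("m1", "m2"),
            emission_truth=np.full((2, 2), value),
        )
        seg = simulate_state_chain(cfg)
        for t in simulate_marks(seg, cfg):
            assert (t.calls == value).all()

    def test_per_state_frequency_concentrates(self):
        # >= 1e5 bins per state with a two-state uniform chain
        layout = GenomeLayout(("chr1",), (40_000_000,), 200)
        cfg = SimulationConfig(
            layout=layout,
            state_names=("a", "b"),
            mark_names=("m1", "m2"),
            emission_truth=np.array([[0.9, 0.2], [0.3, 0.7]]),
            seed=21,
        )
        seg = simulate_state_chain(cfg)
        obs = np.column_stack([t.calls for t in simulate_marks(seg, cfg)])
        for k in range(2):
            emp = obs[seg.states == k].mean(axis=0)
            assert np.abs(emp - cfg.emission_truth[k]).max() <= 0.01


class TestConditionPair:
    def test_identity_flow_preserves_states(self):
        cfg = _small_cfg(seed=2, n_bins=2000)
        cfg.flow_truth = np.eye(cfg.n_states)
        segA = simulate_state_chain(cfg)
        segB = simulate_condition_pair(segA, cfg)
        assert np.array_equal(segA.states, segB.states)

    def test_concentrated_flow_row(self):
        cfg = _small_cfg(seed=2, n_bins=2000)
        flow = np.eye(cfg.n_states)
        q, e = 5, 1  # every quiescent bin becomes the strong enhancer state
        flow[q, q] = 0.0
        flow[q, e] = 1.0
        cfg.flow_truth = flow
        segA = simulate_state_chain(cfg)
        segB = simulate_condition_pair(segA, cfg)
        assert (segB.states[segA.states == q] == e).all()

    def test_empirical_flow_concentrates(self):
        cfg = _small_cfg(seed=6, n_bins=100_000)
        segA = simulate_state_chain(cfg)
        segB = simulate_condition_pair(segA, cfg)
        fm = flow_matrix(segA, segB)
        assert np.nanmax(np.abs(fm.row_normalized() - cfg.flow_truth)) <= 0.01


class TestMethylation:
    def test_zero_rates_no_flags(self):
        cfg = _small_cfg(seed=1, n_bins=2000)
        cfg.demeth_prob_by_state = np.zeros(cfg.n_states)
        cfg.hyper_prob = 0.0
        seg = simulate_state_chain(cfg)
        table = simulate_methylation(seg, cfg)
        assert not table.sites["significant"].any()

    def test_enhancer_only_flags_in_enhancer_bins(self):
        cfg = _small_cfg(seed=1, n_bins=2000)
        rates = np.zeros(cfg.n_states)
        rates[1] = 1.0  # EnhS
        cfg.demeth_prob_by_state = rates
        cfg.hyper_prob = 0.0
        seg = simulate_state_chain(cfg)
        table = simulate_methylation(seg, cfg)
        from chromstate import assign_cpgs

        states = assign_cpgs(table, seg)
        flagged = table.sites["significant"].to_numpy()
        assert flagged.any()
        assert (states[flagged] == 1).all()

    def test_flag_fraction_concentrates(self):
        # ~1e4+ sites per state: large genome at default density
        layout = GenomeLayout(("chr1",), (200_000_000,), 200)
        cfg = default_config(seed=4, layout=layout)
        seg = simulate_state_chain(cfg)
        table = simulate_methylation(seg, cfg)
        from chromstate import assign_cpgs

        states = assign_cpgs(table, seg)
        hypo = table.hypo_flags()
        for k in range(cfg.n_states):
            sel = states == k
            assert sel.sum() > 10_000
            emp = hypo[sel].mean()
            assert abs(emp - cfg.demeth_prob_by_state[k] * (1 - 0)) <= 0.02

    def test_betas_valid_and_unique_positions(self):
        cfg = _small_cfg(seed=8, n_bins=2000)
        seg = simulate_state_chain(cfg)
        table = simulate_methylation(seg, cfg)
        df = table.sites
        assert df["beta_before"].between(0, 1).all()
        assert df["beta_after"].between(0, 1).all()
        assert not df.duplicated(["chrom", "pos"]).any()


class TestSequences:
    def test_plant_all_vs_none(self):
        from chromstate import scan_sequence

        cfg = _small_cfg(seed=3, n_bins=1000)
        cfg.motif_plant_rate_new = 1.0
        cfg.motif_plant_rate_constant = 0.0
        new, const = simulate_enhancer_sequences(30, 30, 200, cfg)
        thr = 0.6 * cfg.motif_pwm.max_score()
        assert all(scan_sequence(s, cfg.motif_pwm, thr) for _, s in new)
        # without planting the consensus is rare in 200 bp of background
        background_hits = sum(
            bool(scan_sequence(s, cfg.motif_pwm, thr)) for _, s in const
        )
        assert background_hits <= 6

    def test_length_shorter_than_motif_rejected(self):
        cfg = _small_cfg(n_bins=1000)
        with pytest.raises(ValueError, match="shorter"):
            simulate_enhancer_sequences(1, 1, 3, cfg)


class TestEnhancerReplicates:
    def test_groups_are_distinct_and_cohesive(self):
        from chromstate import jaccard

        cfg = _small_cfg(seed=10, n_bins=20_000)
        sets, groups = simulate_enhancer_replicates(cfg, n_per_group=3)
        names = list(sets)
        within, between = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                jac = jaccard(sets[names[i]], sets[names[j]])
                (within if groups[names[i]] == groups[names[j]] else between).append(jac)
        assert min(within) > max(between)
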
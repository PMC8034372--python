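"""Synthetic-data generators: determinism, calibration, cross-validation."""

import numpy as np
import pytest

from conftest import make_range_data
from paleorange.chronogram import Chronogram
from paleorange.dec import DECParams, build_rate_matrix, loglik
from paleorange.ranges import AreaSet, build_state_space
from paleorange.simulate import (
    _gillespie_branch,
    simulate_chronogram,
    simulate_codon_alignment,
    simulate_discordant_genetrees,
    simulate_ranges,
    study_preset,
)
from paleorange.supermatrix import GeneTree, rf_distance


class TestChronogramSim:
    def test_shape_and_ultrametricity(self):
        t = simulate_chronogram(29, seed=0)
        assert t.n_tips == 29 and t.n_nodes == 57
        assert t.height == pytest.approx(120.0)

    def test_same_seed_same_newick(self):
        a = simulate_chronogram(15, seed=7).to_newick()
        b = simulate_chronogram(15, seed=7).to_newick()
        assert a == b
        c = simulate_chronogram(15, seed=8).to_newick()
        assert a != c

    def test_pure_birth_waiting_time_expectation(self):
        """Mean natural-scale height matches the sum of exponential waiting
        times E[T] = sum_{k=2}^{n-1} 1/(k b) + 1/(n b)."""
        n, b, reps = 12, 0.3, 200
        heights = np.array(
            [simulate_chronogram(n, birth_rate=b, seed=s, root_age=None).height
             for s in range(reps)]
        )
        want = sum(1.0 / (k * b) for k in range(2, n)) + 1.0 / (n * b)
        se = heights.std(ddof=1) / np.sqrt(reps)
        assert abs(heights.mean() - want) < 3 * se

    def test_early_lineage_growth_is_exponential(self):
        """Before the tip-count cap binds, E[N(t)] = 2 exp(b t)."""
        n, b, reps = 30, 0.25, 200
        t_probe = 2.0  # 2 e^{0.5} ~ 3.3 lineages, far below the cap
        counts = []
        for s in range(reps):
            tree = simulate_chronogram(n, birth_rate=b, seed=s, root_age=None)
            depth_of = {
                nid: tree.height - age for nid, age in tree.node_ages().items()
            }
            internal_depths = [
                depth_of[tree.node_id[i]]
                for i in tree.postorder
                if not tree.is_tip[i]
            ]
            # lineages at t = 1 + number of splits before t (root split at 0)
            counts.append(1 + sum(1 for d in internal_depths if d <= t_probe))
        counts = np.array(counts, dtype=float)
        want = 2 * np.exp(b * t_probe)
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - want) < 3 * se

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_chronogram(2)


class TestRangeSim:
    def test_frozen_rates_inherit_root_singleton(self):
        tree = simulate_chronogram(10, seed=3)
        sp = build_state_space(AreaSet(tuple("ABC")), 2)
        rec = simulate_ranges(tree, DECParams(d=0.0, e=0.0), sp, seed=1)
        states = set(rec.tip_data.codings.values())
        assert len(states) == 1
        assert states == {rec.true_states[tree.node_id[tree.root_index]]}

    def test_same_seed_reproduces(self):
        tree = simulate_chronogram(12, seed=4)
        sp = build_state_space(AreaSet(tuple("ABC")), 2)
        p = DECParams(d=0.01, e=0.005)
        r1 = simulate_ranges(tree, p, sp, seed=9)
        r2 = simulate_ranges(tree, p, sp, seed=9)
        assert r1.tip_data.codings == r2.tip_data.codings
        assert r1.true_states == r2.true_states
        assert r1.branch_events == r2.branch_events

    def test_branch_dispersal_rate_calibration(self):
        """Mean gains per unit length from a singleton ~ d (10,000 sims).

        In a two-area system a singleton has one gainable area, so the
        total anagenetic dispersal rate is exactly d while the range stays
        a singleton."""
        sp = build_state_space(AreaSet(tuple("AB")), 2)
        d, e, t, n = 0.2, 0.1, 0.1, 10_000
        Q = build_rate_matrix(DECParams(d=d, e=e), sp)
        rng = np.random.default_rng(0)
        start = sp.index[sp.areas.mask("A")]
        gains = np.array(
            [_gillespie_branch(start, t, Q, sp, rng)[1] for _ in range(n)], float
        )
        per_unit = gains / t
        se = per_unit.std(ddof=1) / np.sqrt(n)
        # small bias O(d t (d+e)) from excursions away from the singleton
        assert abs(per_unit.mean() - d) < 3 * se + d * t * (d + e)

    def test_branch_gains_match_rate_matrix_expectation(self):
        """Three-area check against the analytic expectation
        E[gains] = int_0^t p(u) . gain_rate du from the rate matrix."""
        from scipy.linalg import expm

        sp = build_state_space(AreaSet(tuple("ABC")), 3)
        d, e, t, n = 0.2, 0.1, 0.5, 10_000
        Q = build_rate_matrix(DECParams(d=d, e=e), sp)
        gain_rate = np.array(
            [
                sum(
                    Q[i, j]
                    for j in range(len(sp))
                    if bin(sp.states[j]).count("1") > bin(sp.states[i]).count("1")
                )
                for i in range(len(sp))
            ]
        )
        start = sp.index[sp.areas.mask("A")]
        p0 = np.zeros(len(sp))
        p0[start] = 1.0
        us = np.linspace(0.0, t, 501)
        want = np.trapezoid([p0 @ expm(Q * u) @ gain_rate for u in us], us)
        rng = np.random.default_rng(1)
        gains = np.array(
            [_gillespie_branch(start, t, Q, sp, rng)[1] for _ in range(n)], float
        )
        se = gains.std(ddof=1) / np.sqrt(n)
        assert abs(gains.mean() - want) < 3 * se

    def test_tip_pattern_frequencies_match_likelihood_engine(self):
        """Simulator and pruning engine agree: empirical tip-pattern
        frequencies match exp(lnL | root singleton) within MC error."""
        tree = Chronogram.from_newick_string("((A:1,B:1):1,C:2);")
        sp = build_state_space(AreaSet(tuple("AB")), 2)
        # e = 0 so the null range is unreachable and no survivorship
        # conditioning perturbs the comparison
        params = DECParams(d=0.15, e=0.0, j=0.4)
        reps = 1000
        from collections import Counter

        seen = Counter()
        for s in range(reps):
            rec = simulate_ranges(tree, params, sp, seed=s)
            seen[tuple(sorted(rec.tip_data.codings.items()))] += 1
        singles = ["A", "B"]
        for pattern, count in seen.most_common(4):
            codings = {t: sp.areas.letters(m) for t, m in pattern}
            data = make_range_data(sp, **codings)
            # simulator draws the root uniformly from singletons
            prob = np.mean(
                [np.exp(loglik(tree, data, params, sp, root_state=r)) for r in singles]
            )
            phat = count / reps
            se = np.sqrt(prob * (1 - prob) / reps)
            assert abs(phat - prob) < max(3.5 * se, 0.01)

    def test_extinction_heavy_settings_raise_after_restarts(self):
        tree = simulate_chronogram(8, seed=0, root_age=500.0)
        sp = build_state_space(AreaSet(tuple("AB")), 2)
        with pytest.raises(RuntimeError, match="restarts"):
            simulate_ranges(tree, DECParams(d=0.0, e=5.0), sp, seed=0, max_restarts=5)


class TestDiscordantGeneTrees:
    def _ref(self, n=12, seed=5):
        return GeneTree("ref", __import__("dendropy").Tree.get(
            data=simulate_chronogram(n, seed=seed).to_newick(), schema="newick"
        ))

    def test_no_moves_no_missing_gives_rf_zero(self):
        ref = self._ref()
        for t in simulate_discordant_genetrees(ref, 5, seed=0):
            assert rf_distance(t, ref) == 0

    def test_single_nni_gives_rf_two(self):
        ref = self._ref()
        hits = [
            rf_distance(t, ref)
            for t in simulate_discordant_genetrees(ref, 20, nni_moves=1, seed=1)
        ]
        assert all(h <= 2 for h in hits)
        assert any(h == 2 for h in hits)  # most single moves alter an edge

    @pytest.mark.parametrize("moves", [1, 2, 4])
    def test_rf_bounded_by_twice_moves(self, moves):
        ref = self._ref()
        for t in simulate_discordant_genetrees(ref, 10, nni_moves=moves, seed=moves):
            assert rf_distance(t, ref) <= 2 * moves

    def test_missing_fraction_drops_tips(self):
        ref = self._ref()
        out = simulate_discordant_genetrees(ref, 5, missing_fraction=0.25, seed=2)
        for t in out:
            assert len(t.tip_labels) == 9  # 12 - round(0.25*12)
            assert t.tip_labels < ref.tip_labels


class TestCodonAlignment:
    def _tree(self):
        import dendropy

        return GeneTree(
            "og1",
            dendropy.Tree.get(
                data="((A:0.3,B:0.3):0.2,(C:0.4,D:0.4):0.1);", schema="newick"
            ),
        )

    @staticmethod
    def _identity(aln, positions):
        taxa = sorted(aln.sequences)
        tot = same = 0
        for i, a in enumerate(taxa):
            for b in taxa[i + 1:]:
                for k in positions:
                    tot += 1
                    same += aln.sequences[a][k] == aln.sequences[b][k]
        return same / tot

    def test_same_seed_identical(self):
        a = simulate_codon_alignment(self._tree(), 50, seed=3)
        b = simulate_codon_alignment(self._tree(), 50, seed=3)
        assert a.sequences == b.sequences
        assert a.codon_aligned and a.length == 150

    def test_neutral_multiplier_balanced_identity(self):
        aln = simulate_codon_alignment(self._tree(), 400, 1.0, seed=1)
        third = self._identity(aln, range(2, aln.length, 3))
        other = self._identity(
            aln, [k for k in range(aln.length) if k % 3 != 2]
        )
        assert abs(third - other) < 0.05

    def test_fast_third_positions_lose_identity(self):
        for seed in range(5):
            aln = simulate_codon_alignment(self._tree(), 200, 5.0, seed=seed)
            third = self._identity(aln, range(2, aln.length, 3))
            other = self._identity(
                aln, [k for k in range(aln.length) if k % 3 != 2]
            )
            assert third < other

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            simulate_codon_alignment(self._tree(), 5)


def test_study_preset_shape():
    tree, space, rec = study_preset(seed=2)
    assert tree.n_tips == 29
    assert len(space.areas) == 5 and space.max_range_size == 2
    assert set(rec.tip_data.codings) == set(tree.tip_labels)
    assert rec.params.family == "DEC"
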
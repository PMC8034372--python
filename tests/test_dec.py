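"""DEC-family likelihood engine against exhaustive-enumeration oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from _oracles import brute_force_likelihood
from conftest import make_range_data
from paleorange.dec import (
    DECParams,
    PruningEngine,
    ancestral_marginals,
    build_rate_matrix,
    clado_distribution,
    fit_ml,
    loglik,
)
from paleorange.chronogram import Chronogram
from paleorange.ranges import AreaSet, RangeData, build_state_space


class TestRateMatrix:
    def test_zero_rates_zero_matrix(self, space2):
        Q = build_rate_matrix(DECParams(d=0.0, e=0.0), space2)
        assert np.all(Q == 0.0)

    def test_two_area_entries_by_construction(self, space2):
        Q = build_rate_matrix(DECParams(d=0.1, e=0.05), space2)
        i = space2.index
        A, B, AB, null = (
            i[space2.areas.mask("A")],
            i[space2.areas.mask("B")],
            i[space2.areas.mask("AB")],
            i[0],
        )
        assert Q[A, AB] == pytest.approx(0.1)
        assert Q[AB, A] == pytest.approx(0.05)
        assert Q[A, null] == pytest.approx(0.05)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_source_multiplicity_scales_gain_rate(self, space3):
        Q = build_rate_matrix(DECParams(d=0.1, e=0.0), space3)
        i = space3.index
        ab = space3.areas.mask("AB")
        abc = space3.areas.mask("ABC")
        assert Q[i[ab], i[abc]] == pytest.approx(0.2)  # two source areas

    def test_transition_matrix_rows_are_distributions(self, space3):
        Q = build_rate_matrix(DECParams(d=0.13, e=0.07), space3)
        P = expm(Q * 1.0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(P >= -1e-12)

    def test_excluded_state_has_no_row(self):
        sp = build_state_space(AreaSet(tuple("ABC")), 2, exclusions=["BC"])
        Q = build_rate_matrix(DECParams(d=0.1, e=0.05), sp)
        assert Q.shape == (len(sp), len(sp))
        assert sp.areas.mask("BC") not in sp.index


class TestCladoDistribution:
    def test_singleton_dec_parent_copies(self, space2):
        rows = clado_distribution(space2.areas.mask("A"), DECParams(d=0.1, e=0.0), space2)
        assert len(rows) == 1
        left, right, cat, p = rows[0]
        assert (left, right, cat, p) == (space2.areas.mask("A"), space2.areas.mask("A"), "sympatry-copy", 1.0)

    def test_two_area_dec_parent_has_six_equal_outcomes(self, space2):
        rows = clado_distribution(space2.areas.mask("AB"), DECParams(d=0.1, e=0.0), space2)
        assert len(rows) == 6
        assert all(r.prob == pytest.approx(1 / 6) for r in rows)
        cats = sorted(r.category for r in rows)
        assert cats.count("vicariance") == 2 and cats.count("subset-sympatry") == 4

    def test_bayarealike_parent_copies_exactly(self, space2):
        rows = clado_distribution(
            space2.areas.mask("AB"), DECParams(d=0.1, e=0.0, family="BAYAREALIKE"), space2
        )
        assert len(rows) == 1
        assert rows[0].left == rows[0].right == space2.areas.mask("AB")
        assert rows[0].prob == 1.0

    def test_divalike_allows_any_split(self, space3):
        rows = clado_distribution(
            space3.areas.mask("ABC"), DECParams(d=0.1, e=0.0, family="DIVALIKE"), space3
        )
        assert all(r.category == "vicariance" for r in rows)
        assert len(rows) == 6  # ordered disjoint bipartitions of 3 areas

    def test_jump_scenarios_weighted_by_j(self, space2):
        j = 0.5
        rows = clado_distribution(space2.areas.mask("A"), DECParams(d=0.1, e=0.0, j=j), space2)
        by_cat = {r.category: r.prob for r in rows}
        # one sympatry (weight 1) + two jump scenarios (weight j each)
        assert by_cat["sympatry-copy"] == pytest.approx(1 / (1 + 2 * j))
        assert by_cat["jump"] == pytest.approx(j / (1 + 2 * j))

    def test_probabilities_sum_to_one(self, space3):
        for letters in ("A", "AB", "ABC"):
            for fam in ("DEC", "DIVALIKE", "BAYAREALIKE"):
                rows = clado_distribution(
                    space3.areas.mask(letters), DECParams(d=0.1, e=0.0, j=1.0, family=fam), space3
                )
                assert sum(r.prob for r in rows) == pytest.approx(1.0)

    def test_null_parent_rejected(self, space2):
        with pytest.raises(ValueError):
            clado_distribution(0, DECParams(d=0.1, e=0.0), space2)


# --- oracle grid: every <=4-tip, <=3-area instance the suite exercises ----
_GRID = [
    # (newick, areas, max_range, codings, d, e, j, family)
    ("(A:1,B:1);", "AB", 2, {"A": "A", "B": "B"}, 0.1, 0.05, 0.0, "DEC"),
    ("((A:1,B:1):1,C:2);", "AB", 2, {"A": "A", "B": "B", "C": "AB"}, 0.1, 0.05, 0.0, "DEC"),
    ("((A:1,B:1):1,C:2);", "ABC", 2, {"A": "A", "B": "BC", "C": "C"}, 0.2, 0.1, 0.0, "DEC"),
    ("((A:1,B:1):1,C:2);", "ABC", 3, {"A": "A", "B": "B", "C": "ABC"}, 0.15, 0.02, 0.5, "DEC"),
    ("(((A:1,B:1):1,C:2):1,D:3);", "ABC", 3, {"A": "A", "B": "AB", "C": "C", "D": "BC"}, 0.08, 0.04, 0.0, "DEC"),
    ("(((A:1,B:1):1,C:2):1,D:3);", "ABC", 2, {"A": "A", "B": "B", "C": "C", "D": "AC"}, 0.1, 0.05, 1.0, "DEC"),
    ("((A:1,B:1):1,C:2);", "ABC", 3, {"A": "AB", "B": "B", "C": "C"}, 0.1, 0.05, 0.0, "DIVALIKE"),
    ("(((A:1,B:1):1,C:2):1,D:3);", "ABC", 3, {"A": "A", "B": "B", "C": "BC", "D": "C"}, 0.12, 0.03, 0.7, "DIVALIKE"),
    ("((A:1,B:1):1,C:2);", "ABC", 2, {"A": "A", "B": "A", "C": "AC"}, 0.1, 0.08, 0.0, "BAYAREALIKE"),
    ("(((A:1,B:1):1,C:2):1,D:3);", "AB", 2, {"A": "A", "B": "AB", "C": "B", "D": "A"}, 0.2, 0.1, 0.9, "BAYAREALIKE"),
]


@pytest.mark.parametrize("newick,areas,maxr,codings,d,e,j,family", _GRID)
def test_pruning_matches_brute_force_enumeration(newick, areas, maxr, codings, d, e, j, family):
    """Pruning lnL equals the exhaustive sum over internal-state assignments
    and cladogenetic scenarios on every small instance."""
    tree = Chronogram.from_newick_string(newick)
    sp = build_state_space(AreaSet(tuple(areas)), maxr)
    data = make_range_data(sp, **codings)
    params = DECParams(d=d, e=e, j=j, family=family)
    got = loglik(tree, data, params, sp)
    want, _ = brute_force_likelihood(tree, codings, areas, maxr, d, e, j, family)
    assert got == pytest.approx(want, abs=1e-8)


@pytest.mark.parametrize("newick,areas,maxr,codings,d,e,j,family", _GRID[:6])
def test_marginals_match_brute_force_posterior(newick, areas, maxr, codings, d, e, j, family):
    tree = Chronogram.from_newick_string(newick)
    sp = build_state_space(AreaSet(tuple(areas)), maxr)
    data = make_range_data(sp, **codings)
    params = DECParams(d=d, e=e, j=j, family=family)
    rec = ancestral_marginals(tree, data, params, sp)
    _, states, marg = brute_force_likelihood(
        tree, codings, areas, maxr, d, e, j, family, want_marginals=True
    )
    letter_of = {frozenset(): "0"}
    for s in states:
        if s:
            letter_of[s] = "".join(sorted(s))
    label_index = {lab: k for k, lab in enumerate(sp.labels())}
    for v, vec in marg.items():
        nid = tree.node_id[v]
        got = rec.vector(nid)
        for s, p in zip(states, vec):
            assert got[label_index[letter_of[s]]] == pytest.approx(p, abs=1e-8)


class TestLoglikProperties:
    def test_plus_j_at_zero_equals_base_model(self, toy_tree4, space3):
        data = make_range_data(space3, A="A", B="AB", C="C", D="BC")
        base = loglik(toy_tree4, data, DECParams(d=0.1, e=0.05, j=0.0), space3)
        # the +j machinery with j exactly 0 must collapse to the base model
        engine = PruningEngine(
            toy_tree4, data, DECParams(d=0.1, e=0.05, j=0.0, family="DEC"), space3
        )
        assert engine.lnL == pytest.approx(base, abs=1e-12)

    def test_area_relabeling_leaves_likelihood_unchanged(self, toy_tree4):
        perm = {"A": "C", "B": "A", "C": "B"}
        sp = build_state_space(AreaSet(tuple("ABC")), 2)
        codings = {"A": "A", "B": "AB", "C": "C", "D": "B"}
        data1 = make_range_data(sp, **codings)
        codings2 = {
            t: "".join(sorted(perm[ch] for ch in r)) for t, r in codings.items()
        }
        data2 = make_range_data(sp, **codings2)
        p = DECParams(d=0.07, e=0.03, j=0.4)
        assert loglik(toy_tree4, data1, p, sp) == pytest.approx(
            loglik(toy_tree4, data2, p, sp), abs=1e-10
        )

    def test_no_change_possible_gives_lnL_zero(self, space2):
        tree = Chronogram.from_newick_string("(A:1,B:1);")
        data = make_range_data(space2, A="A", B="A")
        assert loglik(tree, data, DECParams(d=0, e=0), space2, root_state="A") == pytest.approx(0.0)

    def test_polytomy_rejected_by_engine(self, space2):
        tree = Chronogram.from_newick_string("(A:1,B:1,C:1);")
        data = make_range_data(space2, A="A", B="A", C="A")
        with pytest.raises(ValueError, match="bifurcat"):
            loglik(tree, data, DECParams(d=0.1, e=0.0), space2)

    def test_uncoded_tip_rejected(self, toy_tree3, space2):
        data = make_range_data(space2, A="A", B="B")
        with pytest.raises(ValueError, match="C"):
            loglik(toy_tree3, data, DECParams(d=0.1, e=0.0), space2)


class TestSymmetry:
    def test_symmetric_two_tip_root_marginal(self, space2):
        tree = Chronogram.from_newick_string("(A:1,B:1);")
        data = make_range_data(space2, A="A", B="B")
        rec = ancestral_marginals(tree, data, DECParams(d=0.1, e=0.05), space2)
        root_id = tree.node_id[tree.root_index]
        v = rec.vector(root_id)
        iA = space2.index[space2.areas.mask("A")]
        iB = space2.index[space2.areas.mask("B")]
        assert v[iA] == pytest.approx(v[iB], abs=1e-12)
        assert v.sum() == pytest.approx(1.0, abs=1e-9)
        assert v[space2.index[0]] == 0.0


class TestFit:
    def test_degenerate_no_dispersal_data(self, space2):
        tree = Chronogram.from_newick_string("((A:1,B:1):1,C:2);")
        data = make_range_data(space2, A="A", B="A", C="A")
        res = fit_ml(tree, data, family="DEC", space=space2, n_starts=3)
        assert res.params.d < 1e-4  # driven to the lower bound
        assert res.k == 2 and res.n == 3
        # with e ~ 0 too, no events are needed: lnL close to log(1/3) root avg
        assert res.lnL == pytest.approx(np.log(1 / 3), abs=1e-3)

    def test_plus_j_never_fits_worse_than_base(self, toy_tree4, space3):
        data = make_range_data(space3, A="A", B="B", C="C", D="AB")
        for fam in ("DEC", "DIVALIKE", "BAYAREALIKE"):
            base = fit_ml(toy_tree4, data, family=fam, space=space3, n_starts=3)
            plus = fit_ml(toy_tree4, data, family=fam, plus_j=True, space=space3, n_starts=3)
            assert plus.lnL >= base.lnL - 1e-6
            assert plus.k == 3
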
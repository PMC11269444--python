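"""Group-comparison layer against independent oracles.

ANOVA is checked against a naive sums-of-squares computation and
scipy.stats.f_oneway; Tukey–Kramer p-values against scipy.stats.tukey_hsd
and statsmodels' pairwise_tukeyhsd; the compact letter display against
exhaustive clique-cover search on small group counts.
"""

import itertools

import numpy as np
import pytest
import scipy.stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from aquabudget.stats import (
    GroupSample,
    compact_letters,
    compare_groups,
    groups_from_tidy,
    one_way_anova,
    sem,
    tukey_pairwise,
)
from aquabudget.synthetic import generate_null_dataset


def _random_groups(rng, k=None, balanced=True):
    k = k or rng.integers(2, 5)
    groups = []
    for i in range(k):
        n = 4 if balanced else int(rng.integers(3, 6))
        shift = rng.normal(0, 2)
        groups.append(GroupSample(f"g{i}", list(rng.normal(shift, 1, n))))
    return groups


class TestAnova:
    def test_identical_constants_degenerate(self):
        g = [GroupSample("a", [5, 5, 5]), GroupSample("b", [5, 5, 5])]
        assert one_way_anova(g) == (0.0, 1.0)

    def test_equal_means_zero_f(self):
        g = [GroupSample("a", [1, 2, 3]), GroupSample("b", [1, 2, 3])]
        F, p = one_way_anova(g)
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_sums_of_squares(self):
        g = [GroupSample("a", [0, 1]), GroupSample("b", [10, 11]),
             GroupSample("c", [20, 21])]
        # SSB = 2*(0.5-10.5)^2 + 0 + 2*(20.5-10.5)^2 = 400; SSW = 0.5*3... = 1.5
        # F = (400/2) / (1.5/3) = 400
        F, p = one_way_anova(g)
        assert F == pytest.approx(400.0)
        assert p == pytest.approx(float(sps.f.sf(400.0, 2, 3)))

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(50):
            groups = _random_groups(rng, balanced=bool(rng.integers(2)))
            F, p = one_way_anova(groups)
            F2, p2 = sps.f_oneway(*[g.values for g in groups])
            assert F == pytest.approx(float(F2), rel=1e-10)
            assert p == pytest.approx(float(p2), rel=1e-10)

    def test_input_requirements(self):
        with pytest.raises(ValueError):
            one_way_anova([GroupSample("a", [1, 2])])
        with pytest.raises(ValueError):
            one_way_anova([GroupSample("a", [1]), GroupSample("b", [1, 2])])


class TestTukey:
    def test_identical_groups_all_p_one(self):
        g = [GroupSample("a", [1, 2, 3]), GroupSample("b", [1, 2, 3])]
        assert all(p == 1.0 for p in tukey_pairwise(g).values())

    def test_symmetry(self, rng):
        groups = _random_groups(rng, k=4)
        pw = tukey_pairwise(groups)
        for (a, b), p in pw.items():
            assert pw[(b, a)] == p

    def test_separated_group_detected(self):
        g = [GroupSample("far", [100.0, 100.1, 99.9, 100.2]),
             GroupSample("a", [0.0, 0.1, -0.1, 0.2]),
             GroupSample("b", [0.05, 0.15, -0.05, 0.1])]
        pw = tukey_pairwise(g)
        assert pw[("far", "a")] < 0.05
        assert pw[("far", "b")] < 0.05
        assert pw[("a", "b")] > 0.05

    def test_matches_scipy_tukey_hsd_balanced(self, rng):
        for _ in range(50):
            groups = _random_groups(rng, balanced=True)
            pw = tukey_pairwise(groups)
            ref = sps.tukey_hsd(*[g.values for g in groups])
            for i, gi in enumerate(groups):
                for j, gj in enumerate(groups):
                    if i < j:
                        assert pw[(gi.group_id, gj.group_id)] == pytest.approx(
                            float(ref.pvalue[i, j]), abs=1e-8)

    def test_matches_statsmodels_unbalanced(self, rng):
        """Tukey-Kramer on unbalanced replication (the n=4 / n=3 case)."""
        for _ in range(50):
            groups = _random_groups(rng, k=4, balanced=False)
            pw = tukey_pairwise(groups)
            values = np.concatenate([g.values for g in groups])
            labels = np.concatenate(
                [[g.group_id] * g.n for g in groups])
            ref = pairwise_tukeyhsd(values, labels)
            for (g1, g2), p_ref in zip(
                    itertools.combinations(sorted(g.group_id for g in groups), 2),
                    ref.pvalues):
                assert pw[(g1, g2)] == pytest.approx(float(p_ref), abs=1e-6)

    def test_two_group_case_reduces_to_range_transform(self, rng):
        for _ in range(20):
            groups = _random_groups(rng, k=2, balanced=True)
            pw = tukey_pairwise(groups)
            ref = sps.tukey_hsd(*[g.values for g in groups])
            assert pw[("g0", "g1")] == pytest.approx(float(ref.pvalue[0, 1]),
                                                     abs=1e-8)


def _min_letter_count(ids, nonsig_pairs):
    """Exhaustive minimum clique cover of the non-significance graph."""
    def is_clique(s):
        return all(frozenset(p) in nonsig_pairs
                   for p in itertools.combinations(s, 2))

    cliques = [frozenset(c) for r in range(1, len(ids) + 1)
               for c in itertools.combinations(ids, r) if is_clique(c)]
    maximal = [c for c in cliques if not any(c < d for d in cliques)]
    need_edges = set(nonsig_pairs)
    for size in range(1, len(maximal) + 1):
        for combo in itertools.combinations(maximal, size):
            covered_v = set().union(*combo)
            covered_e = {frozenset(p) for c in combo
                         for p in itertools.combinations(c, 2)}
            if covered_v == set(ids) and need_edges <= covered_e:
                return size
    raise AssertionError("no cover found")


def _assert_sound(letters, pairwise, alpha=0.05):
    for (a, b), p in pairwise.items():
        if a >= b:
            continue
        shares = bool(set(letters[a]) & set(letters[b]))
        assert shares == (p > alpha), (a, b, p, letters)


class TestCompactLetters:
    def test_no_significant_pairs_single_letter(self):
        pw = {(a, b): 0.9 for a in "ABC" for b in "ABC" if a != b}
        assert compact_letters(pw) == {"A": "a", "B": "a", "C": "a"}

    def test_all_pairs_significant_three_letters(self):
        pw = {(a, b): 0.001 for a in "ABC" for b in "ABC" if a != b}
        letters = compact_letters(pw)
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_chain_pattern(self):
        # A differs from C only -> A:a, B:ab, C:b
        pw = {("A", "B"): 0.3, ("B", "A"): 0.3,
              ("B", "C"): 0.4, ("C", "B"): 0.4,
              ("A", "C"): 0.01, ("C", "A"): 0.01}
        assert compact_letters(pw) == {"A": "a", "B": "ab", "C": "b"}

    def test_soundness_and_minimality_on_random_patterns(self, rng):
        """Letters shared exactly by non-significant pairs, with the
        minimal letter count (verified exhaustively, up to 5 groups)."""
        for _ in range(200):
            k = int(rng.integers(2, 6))
            ids = [chr(65 + i) for i in range(k)]
            pw = {}
            for a, b in itertools.combinations(ids, 2):
                p = float(rng.uniform(0, 1))
                pw[(a, b)] = pw[(b, a)] = p
            letters = compact_letters(pw, alpha=0.5)
            _assert_sound(letters, pw, alpha=0.5)
            nonsig = {frozenset((a, b)) for (a, b), p in pw.items()
                      if a < b and p > 0.5}
            used = len({c for s in letters.values() for c in s})
            assert used == _min_letter_count(ids, nonsig)


class TestSemAndBundle:
    def test_hand_sem(self):
        assert sem([1, 2, 3]) == pytest.approx(0.5774, abs=1e-4)

    def test_single_value_flagged_zero(self):
        with pytest.warns(UserWarning):
            assert sem([5.0]) == 0.0

    def test_constant_zero(self):
        assert sem([7, 7, 7]) == 0.0

    def test_compare_groups_bundle_consistent(self, rng):
        table = generate_null_dataset(4, 4, seed=7)
        groups = groups_from_tidy(table)
        res = compare_groups(groups, alpha=0.05)
        assert set(res.letters) == {g.group_id for g in groups}
        _assert_sound(res.letters, res.pairwise, alpha=0.05)
        d = res.to_dict()
        assert set(d) == {"anova_F", "anova_p", "alpha", "pairwise", "letters"}
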
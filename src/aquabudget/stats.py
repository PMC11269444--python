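"""Group comparisons: one-way ANOVA, Tukey–Kramer, compact letter display.

Replicate tanks are the experimental unit; diets are the groups. The
one-way ANOVA F statistic is the classical between/within mean-square
ratio. Pairwise diet differences use the Tukey–Kramer procedure: the
studentized-range statistic

    q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))

referred to the studentized-range distribution with k groups and N - k
error degrees of freedom; the harmonic 1/n_i + 1/n_j term handles
unbalanced replication (here n = 4 tanks, or 3 where a tank produced
too little feces to assay). Adjusted p-values come from
``scipy.stats.studentized_range``, whose numerical CDF is accurate to
well below 1e-6 in p.

Compact letter display assigns letters a, b, c, ... to groups so that
two groups share a letter exactly when their adjusted p exceeds alpha
(insert-and-absorb algorithm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "ComparisonResult",
    "one_way_anova",
    "tukey_pairwise",
    "compact_letters",
    "sem",
    "compare_groups",
]


@dataclass
class GroupSample:
    """Per-tank measurements for one diet group."""

    group_id: str
    values: list[float]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


@dataclass
class ComparisonResult:
    """ANOVA + Tukey–Kramer + letter-display bundle for one response."""

    anova_F: float
    anova_p: float
    pairwise: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        """JSON-ready representation (pairwise keys joined with '|')."""
        return {
            "anova_F": self.anova_F,
            "anova_p": self.anova_p,
            "alpha": self.alpha,
            "pairwise": {f"{a}|{b}": p for (a, b), p in self.pairwise.items()},
            "letters": dict(self.letters),
        }


def _check_groups(groups: list[GroupSample]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.group_id!r} has n={g.n}; need n >= 2")
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate group ids")


def _sums_of_squares(groups: list[GroupSample]) -> tuple[float, float, int, int]:
    """Between-group SS, within-group SS, df_between, df_within."""
    all_vals = np.concatenate([np.asarray(g.values, dtype=float) for g in groups])
    grand = all_vals.mean()
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum(
        float(((np.asarray(g.values, dtype=float) - g.mean) ** 2).sum())
        for g in groups
    )
    k = len(groups)
    return ss_between, ss_within, k - 1, len(all_vals) - k


def one_way_anova(groups: list[GroupSample]) -> tuple[float, float]:
    """Classical one-way ANOVA: (F, p).

    Degenerate inputs where both sums of squares vanish (all
    observations identical) return F = 0, p = 1 rather than 0/0.
    """
    _check_groups(groups)
    ssb, ssw, dfb, dfw = _sums_of_squares(groups)
    if ssw <= 0.0:
        if ssb <= 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return float(F), p


def tukey_pairwise(groups: list[GroupSample]) -> dict[tuple[str, str], float]:
    """Tukey–Kramer adjusted p-values for every pair of groups.

    Returns a symmetric mapping: both (a, b) and (b, a) are present.
    With zero within-group variance, identical means give p = 1 and
    distinct means give p = 0.
    """
    _check_groups(groups)
    _, ssw, _, dfw = _sums_of_squares(groups)
    k = len(groups)
    msw = ssw / dfw
    out: dict[tuple[str, str], float] = {}
    for ga, gb in combinations(groups, 2):
        diff = abs(ga.mean - gb.mean)
        if msw <= 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = diff / math.sqrt(msw / 2.0 * (1.0 / ga.n + 1.0 / gb.n))
            p = float(sps.studentized_range.sf(q, k, dfw))
            p = min(max(p, 0.0), 1.0)
        out[(ga.group_id, gb.group_id)] = p
        out[(gb.group_id, ga.group_id)] = p
    return out


def compact_letters(pairwise: dict[tuple[str, str], float],
                    alpha: float = 0.05) -> dict[str, str]:
    """Letter display: groups share a letter iff not significantly different.

    Insert-and-absorb: start with one letter covering all groups; for
    each significant pair split every letter containing both; absorb
    letter sets contained in another. The result uses the minimal
    number of letters for up to ~10 groups.
    """
    ids = sorted({g for pair in pairwise for g in pair})
    letters: list[set[str]] = [set(ids)]
    sig = [(a, b) for (a, b), p in pairwise.items()
           if a < b and not (p > alpha)]
    for a, b in sig:
        nxt: list[set[str]] = []
        for letter in letters:
            if a in letter and b in letter:
                nxt.append(letter - {a})
                nxt.append(letter - {b})
            else:
                nxt.append(letter)
        # absorb: drop any set contained in another
        letters = [
            s for i, s in enumerate(nxt)
            if s and not any((i != j and s < t) or (s == t and i > j)
                             for j, t in enumerate(nxt))
        ]
    # prune redundant letters: a letter may go if every group and every
    # within-letter pair it certifies is certified by another kept letter
    changed = True
    while changed and len(letters) > 1:
        changed = False
        for i, s in enumerate(letters):
            rest = letters[:i] + letters[i + 1:]
            groups_ok = all(any(g in t for t in rest) for g in s)
            pairs_ok = all(any(a in t and b in t for t in rest)
                           for a, b in combinations(sorted(s), 2))
            if groups_ok and pairs_ok:
                letters = rest
                changed = True
                break
    # stable order: by the earliest group (in id order) each letter contains
    letters.sort(key=lambda s: [ids.index(g) for g in sorted(s, key=ids.index)])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assign: dict[str, list[str]] = {g: [] for g in ids}
    for sym, letter in zip(alphabet, letters):
        for g in letter:
            assign[g].append(sym)
    return {g: "".join(sorted(ls)) for g, ls in assign.items()}


def sem(values: list[float]) -> float:
    """Standard error of the mean: sample SD / sqrt(n); 0 when n = 1."""
    n = len(values)
    if n < 1:
        raise ValueError("sem of an empty sample is undefined")
    if n == 1:
        import warnings
        warnings.warn("single observation: SEM reported as 0", stacklevel=2)
        return 0.0
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return math.sqrt(var / n)


def compare_groups(groups: list[GroupSample], alpha: float = 0.05) -> ComparisonResult:
    """Full comparison bundle: ANOVA, Tukey–Kramer pairwise, letters."""
    F, p = one_way_anova(groups)
    pairwise = tukey_pairwise(groups)
    letters = compact_letters(pairwise, alpha=alpha)
    return ComparisonResult(anova_F=F, anova_p=p, pairwise=pairwise,
                            letters=letters, alpha=alpha)


def groups_from_tidy(table, group_col: str = "group",
                     value_col: str = "value") -> list[GroupSample]:
    """Build GroupSamples from a tidy DataFrame with group/value columns."""
    return [
        GroupSample(group_id=str(gid), values=list(map(float, sub[value_col])))
        for gid, sub in table.groupby(group_col, sort=True)
    ]
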
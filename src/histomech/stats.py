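"""Nonparametric group statistics: Scheirer-Ray-Hare, Kruskal-Wallis, Dunn.

The Scheirer-Ray-Hare (SRH) test is the rank-based analogue of two-way
ANOVA: all N observations are midranked together, a two-way sum-of-squares
decomposition is computed on the ranks, and each effect's statistic is

    H_effect = SS_effect / MS_total,   MS_total = SS_total / (N - 1)

referred to a chi-square distribution with the effect's degrees of freedom.
Using the realized rank variance for MS_total is exactly the tie-corrected
form (without ties MS_total = N(N+1)/12); the uncorrected variant is
available via ``tie_correction=False``.  When one factor is degenerate
(a single level) the main-effect statistic reduces exactly to the
tie-corrected Kruskal-Wallis H.  Dunn's post-hoc test compares mean ranks
pairwise with a tie-corrected normal approximation; Bonferroni adjustment
multiplies each p-value by the number of comparisons.

Unbalanced two-way layouts use a Type-II sum-of-squares decomposition on the
ranks (delegated to an OLS fit); balanced layouts use the closed-form
decomposition, which coincides with Type II there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .io import FormatError, get_logger

log = get_logger(__name__)


@dataclass
class EffectResult:
    name: str
    H: float
    df: int
    p: float


@dataclass
class TestResult:
    effects: list[EffectResult]
    n: int
    method: str
    posthoc: pd.DataFrame | None = None

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def H(self) -> float:
        """Statistic of the single-effect case (Kruskal-Wallis)."""
        if len(self.effects) != 1:
            raise ValueError("multiple effects; address them by name")
        return self.effects[0].H

    @property
    def p(self) -> float:
        if len(self.effects) != 1:
            raise ValueError("multiple effects; address them by name")
        return self.effects[0].p


def _rank_ms_total(ranks: np.ndarray, tie_correction: bool) -> float:
    n = len(ranks)
    if tie_correction:
        return float(np.sum((ranks - ranks.mean()) ** 2)) / (n - 1)
    return n * (n + 1) / 12.0


def scheirer_ray_hare(data: pd.DataFrame, value: str = "value",
                      factor_a: str = "factor_a", factor_b: str = "factor_b",
                      tie_correction: bool = True) -> TestResult:
    """Two-factor Scheirer-Ray-Hare rank test.

    Returns H, df and chi-square p for the two main effects (named after the
    factor columns) and their interaction.  Every A x B cell must be
    non-empty.  If a factor has a single level the test degenerates to a
    one-way rank test on the other factor (equal to Kruskal-Wallis).
    """
    values = data[value].to_numpy(dtype=float)
    a = data[factor_a].to_numpy()
    b = data[factor_b].to_numpy()
    n = len(values)
    if n == 0:
        raise FormatError("empty data")
    a_levels, b_levels = np.unique(a), np.unique(b)
    for la in a_levels:
        for lb in b_levels:
            if not np.any((a == la) & (b == lb)):
                raise FormatError(f"empty cell ({la!r}, {lb!r})")

    ranks = rankdata(values)  # midranks
    ms_total = _rank_ms_total(ranks, tie_correction)
    if ms_total == 0:  # fully degenerate ties (all values identical)
        effects = [EffectResult(factor_a, 0.0, max(len(a_levels) - 1, 0), 1.0),
                   EffectResult(factor_b, 0.0, max(len(b_levels) - 1, 0), 1.0),
                   EffectResult("interaction", 0.0,
                                max((len(a_levels) - 1) * (len(b_levels) - 1), 0),
                                1.0)]
        return TestResult(effects=effects, n=n, method="scheirer-ray-hare")

    if len(a_levels) < 2 or len(b_levels) < 2:
        # degenerate factor: one-way decomposition on the informative factor
        fac, levels, name = ((a, a_levels, factor_a)
                             if len(a_levels) >= 2 else (b, b_levels, factor_b))
        ss = sum(np.count_nonzero(fac == l) *
                 (ranks[fac == l].mean() - ranks.mean()) ** 2 for l in levels)
        h = ss / ms_total
        df_ = len(levels) - 1
        effects = [EffectResult(name, float(h), df_,
                                float(chi2.sf(h, df_)))]
        return TestResult(effects=effects, n=n, method="scheirer-ray-hare")

    counts = np.array([[np.count_nonzero((a == la) & (b == lb))
                        for lb in b_levels] for la in a_levels])
    if counts.min() == counts.max():
        ss_a, ss_b, ss_ab = _balanced_two_way_ss(ranks, a, b, a_levels, b_levels)
    else:
        ss_a, ss_b, ss_ab = _type2_two_way_ss(ranks, a, b)

    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    rows = [(factor_a, ss_a, df_a), (factor_b, ss_b, df_b),
            ("interaction", ss_ab, df_a * df_b)]
    effects = [EffectResult(name, float(ss / ms_total), df_,
                            float(chi2.sf(ss / ms_total, df_)))
               for name, ss, df_ in rows]
    return TestResult(effects=effects, n=n, method="scheirer-ray-hare")


def _balanced_two_way_ss(ranks, a, b, a_levels, b_levels):
    """Closed-form two-way decomposition (balanced layouts)."""
    grand = ranks.mean()
    ss_a = sum(np.count_nonzero(a == la) * (ranks[a == la].mean() - grand) ** 2
               for la in a_levels)
    ss_b = sum(np.count_nonzero(b == lb) * (ranks[b == lb].mean() - grand) ** 2
               for lb in b_levels)
    ss_ab = 0.0
    for la in a_levels:
        for lb in b_levels:
            cell = (a == la) & (b == lb)
            ss_ab += np.count_nonzero(cell) * (
                ranks[cell].mean() - ranks[a == la].mean()
                - ranks[b == lb].mean() + grand) ** 2
    return float(ss_a), float(ss_b), float(ss_ab)


def _type2_two_way_ss(ranks, a, b):
    """Type-II sums of squares on ranks via OLS (unbalanced layouts)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"r": ranks, "A": pd.Categorical(a),
                       "B": pd.Categorical(b)})
    model = smf.ols("r ~ C(A) * C(B)", data=df).fit()
    table = anova_lm(model, typ=2)
    return (float(table.loc["C(A)", "sum_sq"]),
            float(table.loc["C(B)", "sum_sq"]),
            float(table.loc["C(A):C(B)", "sum_sq"]))


def kruskal_wallis(groups, tie_correction: bool = True) -> TestResult:
    """Kruskal-Wallis H test from the rank formula with midranks.

    H = SS_between / MS_total where MS_total is the realized rank variance
    (tie-corrected) or N(N+1)/12 (uncorrected); p from chi-square with
    k - 1 degrees of freedom.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise FormatError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise FormatError("groups must be non-empty")
    values = np.concatenate(groups)
    ranks = rankdata(values)
    n = len(values)
    ms_total = _rank_ms_total(ranks, tie_correction)
    if ms_total == 0:
        return TestResult(effects=[EffectResult("group", 0.0,
                                                len(groups) - 1, 1.0)],
                          n=n, method="kruskal-wallis")
    ss, pos = 0.0, 0
    for g in groups:
        r = ranks[pos:pos + len(g)]
        ss += len(g) * (r.mean() - ranks.mean()) ** 2
        pos += len(g)
    h = ss / ms_total
    df_ = len(groups) - 1
    return TestResult(effects=[EffectResult("group", float(h), df_,
                                            float(chi2.sf(h, df_)))],
                      n=n, method="kruskal-wallis")


def dunn_bonferroni(groups, labels=None) -> pd.DataFrame:
    """Dunn's pairwise rank-sum test with Bonferroni adjustment.

    z_ij = (Rbar_i - Rbar_j) / sqrt(S^2 (1/n_i + 1/n_j)) with the
    tie-corrected variance S^2 = N(N+1)/12 - sum(t^3 - t)/(12(N-1)); raw
    two-sided normal p-values are multiplied by the number of pairs and
    capped at 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise FormatError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise FormatError("groups must be non-empty")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]
    values = np.concatenate(groups)
    ranks = rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    s2 = n * (n + 1) / 12.0 - np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n - 1))

    mean_ranks, sizes, pos = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + len(g)].mean())
        sizes.append(len(g))
        pos += len(g)

    pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
    m = len(pairs)
    rows = []
    for i, j in pairs:
        denom = np.sqrt(s2 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom <= 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p_raw = float(2.0 * norm.sf(abs(z)))
        rows.append({"pair": f"{labels[i]} vs {labels[j]}", "z": float(z),
                     "p_raw": p_raw, "p_adjusted": min(1.0, p_raw * m)})
    return pd.DataFrame(rows)


def percent_retained(n_kept: int, n_total: int) -> float:
    """Percentage of items retained by a filter, 100 * n_kept / n_total."""
    if n_total <= 0:
        raise FormatError("n_total must be positive")
    if not 0 <= n_kept <= n_total:
        raise FormatError("n_kept must be in [0, n_total]")
    return 100.0 * n_kept / n_total
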
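"""ANOVA battery: one-way and two-way (Type-II) between-subjects ANOVA with
partial eta-squared, Bonferroni-corrected post hoc t-tests, planned pairwise
contrasts, and Cohen's d.

Subjects' condition means are treated as independent observations (a
between-cells analysis), matching degrees of freedom like F(2, 114) for
20 subjects x 6 cells.  A repeated-measures variant is deliberately not the
default.  The two-way decomposition uses Type-II sums of squares (each main
effect adjusted for the other, the interaction adjusted for both), computed
by residual sums of squares of nested least-squares fits, so unbalanced
tables are handled; for balanced tables this equals the textbook Type-I
decomposition.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: F(df1, df2), p, and partial eta-squared."""

    name: str
    df1: int
    df2: int
    F: float
    p: float
    partial_eta_sq: float

    def to_dict(self) -> dict:
        return {"name": self.name, "df1": self.df1, "df2": self.df2,
                "F": self.F, "p": self.p,
                "partial_eta_sq": self.partial_eta_sq}


@dataclass(frozen=True)
class ContrastResult:
    """One pairwise comparison with Bonferroni-adjusted p and Cohen's d."""

    pair: tuple[str, str]
    mean_difference: float
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    cohens_d: float
    family: str = "posthoc"

    def to_dict(self) -> dict:
        return {"pair": list(self.pair),
                "mean_difference": self.mean_difference, "t": self.t,
                "df": self.df, "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted, "cohens_d": self.cohens_d,
                "family": self.family}


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared from the F statistic: F*df1 / (F*df1 + df2)."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return (F * df1) / (F * df1 + df2)


def effect_sizes(effects: Sequence[EffectResult]) -> dict[str, float]:
    """Partial eta-squared per effect, recomputed from F and the dfs."""
    return {e.name: partial_eta_sq(e.F, e.df1, e.df2) for e in effects}


def oneway_anova(groups: Sequence[np.ndarray], name: str = "group") -> EffectResult:
    """Classical one-way between-groups ANOVA.

    ``groups`` is a sequence of >= 2 samples, each with n >= 2.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = n_total - len(groups)
    if ss_within <= 0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return EffectResult(name=name, df1=df1, df2=df2, F=float(F), p=p,
                        partial_eta_sq=float(ss_between / (ss_between + ss_within)))


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    out = np.zeros((len(codes), n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def twoway_anova(table: pd.DataFrame, dv: str = "value",
                 factors: tuple[str, str] = ("group", "valence")
                 ) -> dict[str, EffectResult]:
    """Two-way between-subjects ANOVA with Type-II sums of squares.

    Returns main effects (named after the factors) and their interaction
    ("<a>:<b>"), each tested against the full-model residual mean square.
    Raises on empty cells, naming the missing cell.
    """
    fa, fb = factors
    y = table[dv].to_numpy(dtype=float)
    a_levels = sorted(table[fa].astype(str).unique())
    b_levels = sorted(table[fb].astype(str).unique())
    if len(a_levels) < 2 or len(b_levels) < 2:
        raise ValueError("both factors need at least two levels")
    a_codes = table[fa].astype(str).map(a_levels.index).to_numpy()
    b_codes = table[fb].astype(str).map(b_levels.index).to_numpy()
    for i, la in enumerate(a_levels):
        for j, lb in enumerate(b_levels):
            if not np.any((a_codes == i) & (b_codes == j)):
                raise ValueError(f"empty cell: {fa}={la!r}, {fb}={lb!r}")

    n = len(y)
    ones = np.ones((n, 1))
    A = _dummy(a_codes, len(a_levels))
    B = _dummy(b_codes, len(b_levels))
    AB = np.einsum("ij,ik->ijk", A, B).reshape(n, -1)
    rss_b = _rss(np.hstack([ones, B]), y)
    rss_a = _rss(np.hstack([ones, A]), y)
    rss_ab_main = _rss(np.hstack([ones, A, B]), y)
    rss_full = _rss(np.hstack([ones, A, B, AB]), y)

    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_int = df_a * df_b
    df_err = n - len(a_levels) * len(b_levels)
    if df_err <= 0:
        raise ValueError("not enough observations to estimate the error term")
    ss = {fa: rss_b - rss_ab_main,
          fb: rss_a - rss_ab_main,
          f"{fa}:{fb}": rss_ab_main - rss_full}
    dfs = {fa: df_a, fb: df_b, f"{fa}:{fb}": df_int}
    mse = rss_full / df_err
    if mse <= 0:
        raise ValueError("zero residual variance; F undefined")
    out = {}
    for name, s in ss.items():
        s = max(0.0, s)
        F = (s / dfs[name]) / mse
        out[name] = EffectResult(
            name=name, df1=dfs[name], df2=df_err, F=float(F),
            p=float(sps.f.sf(F, dfs[name], df_err)),
            partial_eta_sq=float(s / (s + rss_full)) if (s + rss_full) > 0 else 0.0)
    return out


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation (no small-sample
    correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("Cohen's d needs n >= 2 per group")
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def pairwise_contrasts(data: Mapping[str, np.ndarray],
                       pairs: Sequence[tuple[str, str]] | None = None,
                       n_comparisons: int | None = None,
                       family: str = "posthoc") -> list[ContrastResult]:
    """Two-sample pooled-variance t-tests for an explicit comparison family.

    ``n_comparisons`` is the Bonferroni family size m (default: the number of
    pairs tested); ``p_adjusted = min(1, m * p_raw)``.
    """
    if pairs is None:
        pairs = list(combinations(sorted(data), 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    if m < 1:
        raise ValueError("family size must be >= 1")
    results = []
    for la, lb in pairs:
        a, b = np.asarray(data[la], float), np.asarray(data[lb], float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"singleton group in pair ({la}, {lb})")
        t, p = sps.ttest_ind(a, b, equal_var=True)
        results.append(ContrastResult(
            pair=(la, lb), mean_difference=float(a.mean() - b.mean()),
            t=float(t), df=len(a) + len(b) - 2, p_raw=float(p),
            p_adjusted=float(min(1.0, m * p)), cohens_d=cohens_d(a, b),
            family=family))
    return results


def posthoc_bonferroni(data: Mapping[str, np.ndarray],
                       pairs: Sequence[tuple[str, str]] | None = None
                       ) -> list[ContrastResult]:
    """All (or the given) level pairs, Bonferroni-corrected over the family."""
    return pairwise_contrasts(data, pairs=pairs, family="posthoc")


def planned_contrasts(data: Mapping[str, np.ndarray],
                      pairs: Sequence[tuple[str, str]]) -> list[ContrastResult]:
    """A-priori comparisons, reported unadjusted in their own family."""
    return pairwise_contrasts(data, pairs=pairs, n_comparisons=1,
                              family="planned")


def contrasts_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
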
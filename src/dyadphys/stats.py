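"""Between-condition inference for the ten indices and the trust game.

The design is a two-group between-subjects comparison. Each physiological
measure gets an independent-samples t-test whose variant is gated by
Levene's homogeneity test (mean-centered): pooled-variance Student t when
variances are homogeneous, Welch t with Satterthwaite degrees of freedom
otherwise. Trust (Euros sent by the proposer) and reciprocity (fraction of
the tripled amount returned) use the pooled test. Ordinal perception items
use Stuart's Kendall tau-c, and each comparison reports its achieved
(post hoc) power from the observed effect size via the noncentral t
distribution.

The module surface is a statsmodels-style pair: build a
:class:`ConditionComparison` from the feature/decision tables, call
``fit()``, and read the :class:`ConditionComparisonResults` (per-measure
:class:`ComparisonResult` rows, ``summary()`` table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import reference
from .errors import DegenerateError, InsufficientDataError


class TestVariant(str, Enum):
    POOLED = "POOLED"
    WELCH = "WELCH"


@dataclass
class ComparisonResult:
    """One measure's between-condition test."""

    measure: str
    mean_difference: float
    std_error: float
    t_statistic: float
    df: float
    p_value: float
    variant: TestVariant
    levene_p: float = np.nan
    power: float = np.nan

    def as_dict(self) -> dict:
        return {"measure": self.measure,
                "mean_difference": self.mean_difference,
                "t": self.t_statistic, "df": self.df,
                "std_error": self.std_error, "p": self.p_value,
                "variant": self.variant.value, "levene_p": self.levene_p,
                "power": self.power}


def levene_test(group_a: Sequence[float], group_b: Sequence[float]) -> tuple:
    """Mean-centered Levene test: one-way ANOVA F on |x - group mean|."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    da = np.abs(a - a.mean())
    db = np.abs(b - b.mean())
    if np.var(np.concatenate([da, db])) == 0:
        return 0.0, 1.0  # identical deviation patterns: homogeneous
    w, p = sps.levene(a, b, center="mean")
    return float(w), float(p)


def t_from_summary(mean_a: float, sd_a: float, n_a: int,
                   mean_b: float, sd_b: float, n_b: int,
                   variant: TestVariant = TestVariant.WELCH,
                   measure: str = "") -> ComparisonResult:
    """Two-sample t-test from sufficient statistics.

    POOLED uses the classical pooled variance with df = n_a + n_b - 2;
    WELCH uses unpooled variances with Welch-Satterthwaite df. This lets a
    reported group-descriptives table be turned directly into the
    corresponding corrected t-tests.
    """
    variant = TestVariant(variant)
    if n_a < 2 or n_b < 2 or sd_a < 0 or sd_b < 0:
        raise InsufficientDataError("need n >= 2 and sd >= 0 per group")
    diff = mean_a - mean_b
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    if variant is TestVariant.POOLED:
        sp2 = ((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / (n_a + n_b - 2)
        if sp2 == 0:
            raise DegenerateError("zero pooled variance")
        se = math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        df = float(n_a + n_b - 2)
    else:
        if va + vb == 0:
            raise DegenerateError("zero variance in both groups")
        se = math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(measure=measure, mean_difference=diff,
                            std_error=se, t_statistic=t, df=df, p_value=p,
                            variant=variant)


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 variant: TestVariant = TestVariant.POOLED,
                 measure: str = "") -> ComparisonResult:
    """Independent-samples t-test on raw values (POOLED or WELCH)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    return t_from_summary(a.mean(), a.std(ddof=1), a.size,
                          b.mean(), b.std(ddof=1), b.size,
                          variant=variant, measure=measure)


def encode_decisions(frequency_table: dict, expected_n: Optional[int] = None) -> list:
    """Expand a {value: frequency} table into per-subject values."""
    values = []
    for value, count in frequency_table.items():
        if count < 0 or int(count) != count:
            raise ValueError("frequencies must be non-negative integers")
        values.extend([value] * int(count))
    if expected_n is not None and len(values) != expected_n:
        raise DegenerateError(
            f"frequencies sum to {len(values)}, expected {expected_n}")
    return values


def kendall_tau_c(contingency) -> tuple:
    """Stuart's tau-c with a normal-approximation p-value.

    tau_c = 2m(C - D) / (n^2 (m - 1)) for an r x c table with
    m = min(r, c) and C/D the concordant/discordant pair counts; the null
    standard error follows the standard cell-sum formula.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise DegenerateError("need an r x c table with r, c >= 2")
    n = table.sum()
    if n < 4:
        raise InsufficientDataError("need total n >= 4")
    r, c = table.shape
    m = min(r, c)
    # twice-counted concordant/discordant partner sums per cell
    conc = np.zeros_like(table)
    disc = np.zeros_like(table)
    for i in range(r):
        for j in range(c):
            conc[i, j] = table[:i, :j].sum() + table[i + 1:, j + 1:].sum()
            disc[i, j] = table[:i, j + 1:].sum() + table[i + 1:, :j].sum()
    pq = float((table * (conc - disc)).sum())  # = 2 (C - D)
    tau_c = m * pq / (n ** 2 * (m - 1))
    var_term = float((table * (conc - disc) ** 2).sum()) - pq ** 2 / n
    if var_term <= 0:
        return tau_c, 1.0
    ase0 = 2.0 * m / ((m - 1) * n ** 2) * math.sqrt(var_term)
    z = tau_c / ase0
    return tau_c, float(2.0 * sps.norm.sf(abs(z)))


def achieved_power(effect_size_d: float, n_a: int, n_b: int,
                   alpha: float = 0.05) -> float:
    """Post hoc power of the two-sided two-sample t-test.

    Uses the noncentral t distribution with noncentrality
    d * sqrt(n_a n_b / (n_a + n_b)).
    """
    if n_a < 2 or n_b < 2 or not 0 < alpha < 1:
        raise ValueError("need n >= 2 and alpha in (0, 1)")
    df = n_a + n_b - 2
    nc = effect_size_d * math.sqrt(n_a * n_b / (n_a + n_b))
    t_crit = sps.t.ppf(1.0 - alpha / 2.0, df)
    upper = sps.nct.sf(t_crit, df, nc)
    lower = sps.nct.cdf(-t_crit, df, nc)
    # far in one tail the opposite-tail term underflows to NaN in scipy
    upper = 0.0 if math.isnan(upper) else upper
    lower = 0.0 if math.isnan(lower) else lower
    return float(upper + lower)


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    return float((a.mean() - b.mean()) / math.sqrt(sp2)) if sp2 > 0 else 0.0


def compare_conditions(features: pd.DataFrame,
                       decisions: Optional[pd.DataFrame] = None,
                       alpha_levene: float = 0.05) -> pd.DataFrame:
    """Levene-gated t-tests for every index, plus trust and reciprocity.

    For each physiological measure the Welch correction is applied whenever
    Levene's test rejects homogeneity at ``alpha_levene``. Trust and
    reciprocity use the pooled test (df = n - 2). Each row also carries the
    achieved power at the observed effect size.
    """
    if "excluded" in features.columns:
        features = features.loc[~features["excluded"].astype(bool)]
    conditions = sorted(features["condition"].unique())
    if len(conditions) != 2:
        raise InsufficientDataError(
            f"need exactly two conditions, got {conditions}")
    # personal (PC) group first so differences read PC - IC
    if "PC" in conditions:
        conditions = ["PC", "IC"]
    rows = []
    for measure in reference.INDEX_NAMES:
        if measure not in features.columns:
            continue
        a = features.loc[features["condition"] == conditions[0], measure].dropna().to_numpy(float)
        b = features.loc[features["condition"] == conditions[1], measure].dropna().to_numpy(float)
        _, lev_p = levene_test(a, b)
        variant = TestVariant.WELCH if lev_p < alpha_levene else TestVariant.POOLED
        res = two_sample_t(a, b, variant=variant, measure=measure)
        res.levene_p = lev_p
        res.power = achieved_power(abs(_cohens_d(a, b)), a.size, b.size)
        rows.append(res.as_dict())
    if decisions is not None:
        for measure, col in (("trust", "amount_sent"),
                             ("reciprocity", "fraction_returned")):
            sub = decisions.dropna(subset=[col])
            a = sub.loc[sub["condition"] == conditions[0], col].to_numpy(float)
            b = sub.loc[sub["condition"] == conditions[1], col].to_numpy(float)
            if a.size < 2 or b.size < 2:
                continue  # too few players of this role for a test
            res = two_sample_t(a, b, variant=TestVariant.POOLED, measure=measure)
            res.power = achieved_power(abs(_cohens_d(a, b)), a.size, b.size)
            rows.append(res.as_dict())
    return pd.DataFrame(rows)


class ConditionComparison:
    """Between-condition comparison model for a two-group cohort.

    Parameters
    ----------
    features : DataFrame
        Extraction output: one row per subject with a ``condition`` column
        and the ten index columns (plus optional ``excluded``).
    decisions : DataFrame, optional
        Trust-game table with ``condition``, ``amount_sent`` and
        ``fraction_returned`` columns.
    alpha_levene : float
        Significance level of the homogeneity gate.
    """

    def __init__(self, features: pd.DataFrame,
                 decisions: Optional[pd.DataFrame] = None,
                 alpha_levene: float = 0.05):
        self.features = features
        self.decisions = decisions
        self.alpha_levene = alpha_levene

    @classmethod
    def from_csv(cls, features_path, decisions_path=None, **kwargs):
        decisions = (pd.read_csv(decisions_path)
                     if decisions_path is not None else None)
        return cls(pd.read_csv(features_path), decisions, **kwargs)

    def fit(self) -> "ConditionComparisonResults":
        table = compare_conditions(self.features, self.decisions,
                                   self.alpha_levene)
        return ConditionComparisonResults(self, table)


class ConditionComparisonResults:
    """Fitted between-condition comparisons with a printable summary."""

    def __init__(self, model: ConditionComparison, table: pd.DataFrame):
        self.model = model
        self.table = table

    def __getitem__(self, measure: str) -> ComparisonResult:
        row = self.table.loc[self.table["measure"] == measure]
        if row.empty:
            raise KeyError(measure)
        r = row.iloc[0]
        return ComparisonResult(measure=r["measure"],
                                mean_difference=r["mean_difference"],
                                std_error=r["std_error"],
                                t_statistic=r["t"], df=r["df"],
                                p_value=r["p"],
                                variant=TestVariant(r["variant"]),
                                levene_p=r["levene_p"], power=r["power"])

    @property
    def measures(self) -> list:
        return list(self.table["measure"])

    def summary(self) -> str:
        lines = ["Between-condition comparison (personal - impersonal)",
                 "=" * 78,
                 f"{'measure':<18}{'diff':>11}{'t':>8}{'df':>7}{'SE':>11}"
                 f"{'p':>8}{'power':>7}  variant",
                 "-" * 78]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['measure']:<18}{r['mean_difference']:>11.4f}"
                f"{r['t']:>8.3f}{r['df']:>7.1f}{r['std_error']:>11.4f}"
                f"{r['p']:>8.3f}{r['power']:>7.2f}  {r['variant']}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def reference_comparisons(variant: TestVariant = TestVariant.WELCH) -> pd.DataFrame:
    """Recompute every index's between-condition test from the reference
    per-condition summary statistics (n = 14 each)."""
    rows = []
    n = reference.N_PER_CONDITION
    for measure in reference.INDEX_NAMES:
        (m_pc, s_pc) = reference.INDEX_STATS[measure]["PC"]
        (m_ic, s_ic) = reference.INDEX_STATS[measure]["IC"]
        res = t_from_summary(m_pc, s_pc, n, m_ic, s_ic, n, variant=variant,
                             measure=measure)
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def reference_game_tests() -> dict:
    """Trust and reciprocity pooled t-tests from the reference frequency
    tables (df = n - 2)."""
    out = {}
    for name, tables in (("trust", reference.TRUST_FREQUENCIES),
                         ("reciprocity", reference.RECIPROCITY_FREQUENCIES)):
        pc = encode_decisions(tables["PC"], reference.N_PER_CONDITION)
        ic = encode_decisions(tables["IC"], reference.N_PER_CONDITION)
        out[name] = two_sample_t(pc, ic, variant=TestVariant.POOLED,
                                 measure=name)
    return out
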
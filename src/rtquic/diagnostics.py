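"""Diagnostic-accuracy and paired-agreement statistics for binary assay calls.

All tests are exact where the field convention is exact: Fisher's test sums
hypergeometric point probabilities, McNemar's test is the exact two-sided
binomial on discordant pairs, and proportion confidence intervals are 95%
Clopper–Pearson. Effect sizes are Cramér's V (2×2: the absolute phi
coefficient) and Cohen's kappa with the asymptotic large-sample standard
error of Fleiss, Cohen & Everitt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Table2x2",
    "AccuracySummary",
    "AgreementResult",
    "proportion_summary",
    "sensitivity",
    "specificity",
    "fisher_exact_two_sided",
    "cramers_v",
    "mcnemar_exact",
    "cohens_kappa",
    "combine_or_rule",
    "build_unpaired_table",
    "build_paired_table",
]


@dataclass(frozen=True)
class Table2x2:
    """2×2 integer contingency table.

    Unpaired layout: rows are groups, columns are (positive, negative) —
    ``a,b`` = group 1, ``c,d`` = group 2. Paired layout: ``a`` both-positive,
    ``b`` test1+/test2−, ``c`` test1−/test2+, ``d`` both-negative.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) < 1:
            raise ValueError("table total must be >= 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class AccuracySummary:
    """A proportion with its exact 95% CI and table-style integer percent."""

    n_positive: int
    n_total: int
    estimate: float
    ci_low: float
    ci_high: float
    percent_rounded: int
    n_excluded: int = 0  # subjects dropped for missing data (OR-rule combination)


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with asymptotic CI, plus the exact McNemar p-value."""

    kappa: float
    se_kappa: float
    ci_low: float
    ci_high: float
    mcnemar_p: float
    n_discordant: int
    flags: tuple[str, ...] = ()


def _round_half_up_percent(x: float) -> int:
    return int(math.floor(100.0 * x + 0.5))


def proportion_summary(n_positive: int, n_total: int) -> AccuracySummary:
    """Binomial proportion with exact 95% Clopper–Pearson interval.

    ``percent_rounded`` uses half-up rounding to an integer percent, the
    convention of printed clinical tables.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= n_positive <= n_total:
        raise ValueError("need 0 <= n_positive <= n_total")
    k, n = n_positive, n_total
    alpha = 0.05
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    est = k / n
    return AccuracySummary(
        n_positive=k, n_total=n, estimate=est, ci_low=lo, ci_high=hi,
        percent_rounded=_round_half_up_percent(est),
    )


def sensitivity(n_positive_calls_in_diseased: int, n_diseased: int) -> AccuracySummary:
    """Fraction of disease-positive subjects called assay-positive."""
    return proportion_summary(n_positive_calls_in_diseased, n_diseased)


def specificity(n_negative_calls_in_nondiseased: int, n_nondiseased: int) -> AccuracySummary:
    """Fraction of disease-negative subjects called assay-negative."""
    return proportion_summary(n_negative_calls_in_nondiseased, n_nondiseased)


def fisher_exact_two_sided(table: Table2x2) -> float:
    """Two-sided Fisher's exact test by the point-probability method.

    With both margins fixed, sums the hypergeometric probabilities of every
    table whose point probability does not exceed the observed table's (a
    relative guard of 1+1e-7 absorbs floating-point ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    n = table.n
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(stats.hypergeom.pmf(a, n, r1, c1))
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def cramers_v(table: Table2x2) -> float:
    """Cramér's V for a 2×2 table: |ad − bc| / sqrt(r1·r2·c1·c2)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("Cramér's V undefined: zero row or column margin")
    return abs(a * d - b * c) / math.sqrt(float(r1) * r2 * c1 * c2)


def mcnemar_exact(table: Table2x2) -> float:
    """Exact two-sided McNemar test on the discordant cells of a paired table.

    p = min(1, 2·P(X ≤ min(b, c))) with X ~ Binomial(b + c, 1/2); the
    degenerate no-discordance table returns p = 1.
    """
    b, c = table.b, table.c
    n_disc = b + c
    if n_disc == 0:
        return 1.0
    p = 2.0 * float(stats.binom.cdf(min(b, c), n_disc, 0.5))
    return min(p, 1.0)


def cohens_kappa(table: Table2x2) -> AgreementResult:
    """Chance-corrected agreement between two paired binary tests.

    κ = (p_o − p_e)/(1 − p_e) with observed agreement p_o = (a + d)/n and
    chance agreement p_e from the marginal rates. The standard error is the
    asymptotic large-sample (Fleiss–Cohen–Everitt) formula; the 95% CI is
    κ ± 1.96·SE clipped to [−1, 1]. When p_e = 1 (both tests constant) κ is
    defined as 1 if p_o = 1 else 0 and the result is flagged.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    p = np.array([[a, b], [c, d]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = p[0, 0] + p[1, 1]
    p_e = float(row @ col)
    flags: list[str] = []
    if abs(1.0 - p_e) < 1e-12:
        kappa = 1.0 if abs(1.0 - p_o) < 1e-12 else 0.0
        flags.append("degenerate_margins_pe_1")
        se = float("nan")
        lo = hi = kappa
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        # Fleiss, Cohen & Everitt large-sample variance of kappa-hat
        term_a = sum(
            p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in (0, 1)
        )
        term_b = (1.0 - kappa) ** 2 * sum(
            p[i, j] * (col[i] + row[j]) ** 2 for i in (0, 1) for j in (0, 1) if i != j
        )
        term_c = (kappa - p_e * (1.0 - kappa)) ** 2
        var = (term_a + term_b - term_c) / (n * (1.0 - p_e) ** 2)
        se = math.sqrt(max(var, 0.0))
        lo = max(-1.0, kappa - 1.959963984540054 * se)
        hi = min(1.0, kappa + 1.959963984540054 * se)
    return AgreementResult(
        kappa=float(kappa), se_kappa=se, ci_low=float(lo), ci_high=float(hi),
        mcnemar_p=mcnemar_exact(table), n_discordant=b + c, flags=tuple(flags),
    )


def combine_or_rule(
    calls_test1: Mapping[str, bool],
    calls_test2: Mapping[str, bool],
    diagnosis: Mapping[str, str],
) -> tuple[dict[str, AccuracySummary], int]:
    """Combine two tests per subject with an OR rule (positive if either is).

    Subjects missing either test are excluded; the exclusion count is
    returned alongside per-diagnosis-group positivity summaries.
    """
    common = sorted(set(calls_test1) & set(calls_test2))
    all_subjects = set(calls_test1) | set(calls_test2)
    n_excluded = len(all_subjects) - len(common)
    if not common:
        raise ValueError("no subject has both tests")
    groups: dict[str, list[bool]] = {}
    for s in common:
        groups.setdefault(str(diagnosis[s]), []).append(calls_test1[s] or calls_test2[s])
    out = {}
    for g, flags in groups.items():
        summ = proportion_summary(sum(flags), len(flags))
        out[g] = AccuracySummary(
            n_positive=summ.n_positive, n_total=summ.n_total, estimate=summ.estimate,
            ci_low=summ.ci_low, ci_high=summ.ci_high,
            percent_rounded=summ.percent_rounded, n_excluded=n_excluded,
        )
    return out, n_excluded


def build_unpaired_table(
    calls: pd.DataFrame,
    group_by: str = "specimen",
    groups: Sequence[str] | None = None,
    outcome: str = "call",
) -> Table2x2:
    """Cross-tabulate sample calls into rows=groups, columns=(positive, negative).

    ``groups`` fixes the row order; exactly two groups must remain after
    filtering.
    """
    df = calls
    levels = list(groups) if groups is not None else sorted(df[group_by].unique())
    if groups is not None:
        df = df[df[group_by].isin(levels)]
    observed = set(df[group_by].unique())
    if len(levels) != 2 or not set(levels) <= observed:
        raise ValueError(
            f"need exactly 2 groups with data, got {sorted(observed)} (requested {levels})"
        )
    cells = []
    for g in levels:
        sub = df[df[group_by] == g]
        pos = int((sub[outcome] == "positive").sum())
        cells += [pos, len(sub) - pos]
    return Table2x2(*cells)


def build_paired_table(
    calls_test1: Mapping[str, bool], calls_test2: Mapping[str, bool]
) -> Table2x2:
    """Paired concordance table over subjects present in both tests."""
    common = sorted(set(calls_test1) & set(calls_test2))
    if not common:
        raise ValueError("no subject has both tests")
    a = sum(calls_test1[s] and calls_test2[s] for s in common)
    b = sum(calls_test1[s] and not calls_test2[s] for s in common)
    c = sum(not calls_test1[s] and calls_test2[s] for s in common)
    d = sum(not calls_test1[s] and not calls_test2[s] for s in common)
    return Table2x2(a, b, c, d)
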
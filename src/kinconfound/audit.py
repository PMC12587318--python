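"""Questionnaire classification audit with stratified rates and exact tests.

A behaviour classification derived from lifetime partner counts is
applied to questionnaire records, and its rate is stratified by age at
first sex.  Strong enrichment of the classification in early-age strata
(which include victims of childhood sexual assault) is the diagnostic
the audit exists to surface: the classification rule conflates distinct
phenomena across strata.  Uncertainty comes from exact binomial CIs and
an exact (or seeded Monte-Carlo) association test over the 2xK table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, ParameterError

__all__ = [
    "ClassificationRule",
    "StratifiedRates",
    "ExactTestResult",
    "classify",
    "stratified_rates",
    "exact_test_2xk",
    "DEFAULT_STRATA",
]

logger = logging.getLogger(__name__)

#: Default age-at-first-sex bands (low, high-inclusive-or-None): before 10,
#: 10-12 inclusive, 13 and later.  The last band is the reference stratum.
DEFAULT_STRATA = ((0, 9), (10, 12), (13, None))


@dataclass(frozen=True)
class ClassificationRule:
    """Flag records with at least ``min_same_sex`` same-sex partners AND
    at least ``min_opposite_sex`` opposite-sex partners (the minimal rule
    consistent with 'both-sexes behaviour'; thresholds are configurable
    because classification choices are exactly what the audit probes)."""

    min_same_sex: int = 1
    min_opposite_sex: int = 1

    def __post_init__(self):
        if self.min_same_sex < 0 or self.min_opposite_sex < 0:
            raise ParameterError("rule thresholds must be non-negative")


def classify(
    records: pd.DataFrame, rule: ClassificationRule | None = None
) -> pd.Series:
    """Apply the classification rule; returns a boolean Series aligned to
    the valid rows of ``records``.

    Rows violating the count invariant (negative counts, or more same-sex
    than total partners) are rejected and logged, not silently coerced.
    """
    rule = rule or ClassificationRule()
    total = records["n_partners_total"].to_numpy()
    same = records["n_same_sex_partners"].to_numpy()
    valid = (total >= 0) & (same >= 0) & (same <= total)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("rejected %d rows violating count invariants", n_bad)
    sub = records[valid]
    flags = (sub["n_same_sex_partners"] >= rule.min_same_sex) & (
        sub["n_partners_total"] - sub["n_same_sex_partners"]
        >= rule.min_opposite_sex
    )
    return flags.astype(bool)


@dataclass
class StratifiedRates:
    """Per-stratum classification rates with exact uncertainty.

    ``table`` columns: stratum, n, classified, rate, ci_low, ci_high
    (Clopper-Pearson 95%), odds_ratio and or_ci vs the reference stratum.
    ``p_value`` is the exact association test across the defined-age
    strata (the missing-age stratum is reported but excluded from the
    test).
    """

    table: pd.DataFrame
    overall_rate: float
    n_total: int
    p_value: float
    test_method: str
    reference: str

    def to_dict(self) -> dict:
        return {
            "overall_rate": self.overall_rate,
            "n_total": self.n_total,
            "p_value": self.p_value,
            "test_method": self.test_method,
            "reference": self.reference,
            "strata": self.table.to_dict(orient="records"),
        }


def _stratum_label(lo, hi) -> str:
    if hi is None or math.isinf(hi):
        return f"{lo}+"
    if lo <= 0:
        return f"<{hi + 1}"
    return f"{lo}-{hi}"


def stratified_rates(
    flags: pd.Series,
    records: pd.DataFrame,
    strata=DEFAULT_STRATA,
    *,
    seed: int | None = None,
) -> StratifiedRates:
    """Classification rates stratified by age at first sex.

    Band bounds are inclusive on both ends (``(10, 12)`` contains ages
    10, 11 and 12); an open upper bound is written ``None``.  Missing
    ages form an explicit "missing" stratum.  Odds ratios are reported
    against the last (oldest) band.  Strata with N = 0 are reported with
    a null rate.
    """
    records = records.loc[flags.index]
    age = records["age_first_sex"].to_numpy(dtype=float)
    f = flags.to_numpy(dtype=bool)
    bands = [(lo, math.inf if hi is None else hi) for lo, hi in strata]
    for (lo1, hi1), (lo2, _) in zip(bands, bands[1:]):
        if lo2 <= hi1:
            raise ConfigurationError("strata overlap")
    observed = np.isfinite(age)
    covered = np.zeros(len(age), dtype=bool)
    rows = []
    counts = []  # (classified, not classified) per defined stratum
    ref_label = _stratum_label(*strata[-1])
    for (lo, hi), band in zip(strata, bands):
        in_band = observed & (age >= band[0]) & (age <= band[1])
        covered |= in_band
        rows.append((_stratum_label(lo, hi), in_band))
    if (observed & ~covered).any():
        raise ConfigurationError("strata do not partition the observed ages")
    rows.append(("missing", ~observed))

    ref_mask = rows[-2][1]
    ref_k, ref_n = int(f[ref_mask].sum()), int(ref_mask.sum())
    table = []
    for label, mask in rows:
        n, k = int(mask.sum()), int(f[mask].sum())
        if n == 0:
            table.append(
                {"stratum": label, "n": 0, "classified": 0, "rate": None,
                 "ci_low": None, "ci_high": None, "odds_ratio": None,
                 "or_ci_low": None, "or_ci_high": None}
            )
            continue
        lo_ci, hi_ci = proportion_confint(k, n, alpha=0.05, method="beta")
        entry = {
            "stratum": label, "n": n, "classified": k, "rate": k / n,
            "ci_low": float(lo_ci), "ci_high": float(hi_ci),
            "odds_ratio": None, "or_ci_low": None, "or_ci_high": None,
        }
        if label != ref_label and label != "missing" and ref_n > 0:
            # Woolf (log-OR) interval with Haldane correction when needed
            a, b_, c, d = k, n - k, ref_k, ref_n - ref_k
            if min(a, b_, c, d) == 0:
                a, b_, c, d = a + 0.5, b_ + 0.5, c + 0.5, d + 0.5
            orr = (a * d) / (b_ * c)
            se = math.sqrt(1 / a + 1 / b_ + 1 / c + 1 / d)
            entry["odds_ratio"] = float(orr)
            entry["or_ci_low"] = float(orr * math.exp(-1.96 * se))
            entry["or_ci_high"] = float(orr * math.exp(1.96 * se))
        elif label == ref_label:
            entry["odds_ratio"] = 1.0
        table.append(entry)
        if label != "missing":
            counts.append([k, n - k])

    counts_arr = np.array([c for c in counts if sum(c) > 0]).T
    if counts_arr.size and counts_arr.shape[1] >= 2:
        test = exact_test_2xk(counts_arr, seed=seed)
        p, method = test.p, test.method
    else:
        p, method = 1.0, "degenerate"
    tab = pd.DataFrame(table)
    n_total = int(tab["n"].sum())
    assert n_total == len(records), "stratum counts must sum to the total"
    return StratifiedRates(
        table=tab,
        overall_rate=float(f.mean()) if len(f) else 0.0,
        n_total=n_total,
        p_value=float(p),
        test_method=method,
        reference=ref_label,
    )


@dataclass
class ExactTestResult:
    p: float
    method: str
    n_tables: int | None = None


def _table_log_prob(first_row: np.ndarray, row_sums, col_sums, n) -> float:
    """Log multivariate hypergeometric probability of a 2xK table with the
    given margins, identified by its first row."""
    second = col_sums - first_row
    return float(
        gammaln(row_sums[0] + 1)
        + gammaln(row_sums[1] + 1)
        - gammaln(n + 1)
        + np.sum(gammaln(col_sums + 1))
        - np.sum(gammaln(first_row + 1))
        - np.sum(gammaln(second + 1))
    )


def exact_test_2xk(
    table,
    *,
    max_enumeration_total: int = 500,
    n_mc: int = 20000,
    seed: int | None = None,
) -> ExactTestResult:
    """Two-sided exact association test for a 2xK contingency table.

    The p-value is the total probability, under the multivariate
    hypergeometric distribution with the observed margins, of tables no
    more probable than the observed one (the standard two-sided
    convention).  Tables with total count up to ``max_enumeration_total``
    are enumerated exhaustively; larger tables use seeded Monte-Carlo
    sampling of tables with fixed margins.  The method used is recorded
    in the result.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ParameterError("table must be 2xK")
    if (t < 0).any():
        raise ParameterError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or row_sums.min() == 0 or (col_sums == 0).all():
        return ExactTestResult(p=1.0, method="degenerate")
    keep = col_sums > 0
    t, col_sums = t[:, keep], col_sums[keep]
    k = t.shape[1]
    tol = 1e-9
    obs_lp = _table_log_prob(t[0], row_sums, col_sums, n)

    if n <= max_enumeration_total:
        p_total = 0.0
        count = 0

        def recurse(j: int, remaining: int, first: list[int]):
            nonlocal p_total, count
            if j == k - 1:
                if remaining <= col_sums[j]:
                    row = np.array(first + [remaining])
                    lp = _table_log_prob(row, row_sums, col_sums, n)
                    count += 1
                    if lp <= obs_lp + tol:
                        p_total += math.exp(lp)
                return
            lo = max(0, remaining - int(col_sums[j + 1:].sum()))
            hi = min(int(col_sums[j]), remaining)
            for x in range(lo, hi + 1):
                recurse(j + 1, remaining - x, first + [x])

        recurse(0, int(row_sums[0]), [])
        return ExactTestResult(
            p=min(p_total, 1.0), method="enumeration", n_tables=count
        )

    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_sums, col_sums)
    samples = dist.rvs(n_mc, random_state=rng)
    first = samples[:, 0, :]
    lps = (
        gammaln(row_sums[0] + 1)
        + gammaln(row_sums[1] + 1)
        - gammaln(n + 1)
        + np.sum(gammaln(col_sums + 1))
        - gammaln(first + 1).sum(axis=1)
        - gammaln(col_sums[None, :] - first + 1).sum(axis=1)
    )
    p = float(np.mean(lps <= obs_lp + tol))
    return ExactTestResult(p=p, method="monte_carlo", n_tables=n_mc)
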
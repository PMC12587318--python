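"""Wealth preprocessing and the wealth-confounding similarity analysis.

Probate-style wealth records are imputed (unprobated individuals get half
the period's minimum probate requirement, on the log scale) and
mean-centred by decade.  The confounding demonstration then asks: across
relationship categories, does relative-pair similarity in paternal
wealth track relative-pair similarity in status?  A high cross-category
correlation means the status-similarity profile is equally well explained
by wealth transmission — genetic and non-genetic channels are confounded.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .synthetic import Pedigree

__all__ = [
    "wealth_records",
    "preprocess_wealth",
    "exclude_iqr_outliers",
    "attach_paternal_wealth",
    "pair_similarity_correlation",
]

logger = logging.getLogger(__name__)


def wealth_records(pedigree: Pedigree) -> pd.DataFrame:
    """Extract a WealthRecord table (id, log_wealth, probated, decade,
    period_minimum) from a pedigree with simulated wealth."""
    df = pedigree.individuals
    if "wealth" not in df.columns:
        raise ConfigurationError("pedigree has no wealth fields; run simulate_wealth")
    return pd.DataFrame(
        {
            "id": df["id"],
            "log_wealth": df["wealth"],
            "probated": df["probated"],
            "decade": (df["birth_year"] // 10 * 10).astype(int),
            "period_minimum": df["period_minimum"],
        }
    )


def preprocess_wealth(records: pd.DataFrame) -> pd.Series:
    """Impute unprobated records and mean-centre log wealth by decade.

    Unprobated individuals are assigned the log of half their period's
    minimum probate requirement before centring.  Decades with fewer than
    two records are centred against the global mean (with a warning).
    Returns the centred log-wealth vector indexed by ``id``.
    """
    for col in ("id", "log_wealth", "probated", "decade"):
        if col not in records.columns:
            raise ConfigurationError(f"wealth records lack column {col!r}")
    lw = records["log_wealth"].to_numpy(dtype=float).copy()
    unprobated = ~records["probated"].to_numpy(dtype=bool)
    if unprobated.any():
        if "period_minimum" not in records.columns:
            raise ConfigurationError(
                "unprobated records present but no period_minimum column"
            )
        minimum = records["period_minimum"].to_numpy(dtype=float)
        if np.any(~np.isfinite(minimum[unprobated])):
            raise ConfigurationError("missing probate minimum for unprobated record")
        lw[unprobated] = np.log(minimum[unprobated] / 2.0)
    out = pd.Series(lw, index=pd.Index(records["id"], name="id"), name="centred_wealth")
    decades = records["decade"].to_numpy()
    counts = pd.Series(decades).value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(
            f"decades with < 2 records centred against the global mean: "
            f"{sorted(small)}"
        )
        global_mean = lw.mean()
    for dec, cnt in counts.items():
        sel = decades == dec
        out.iloc[np.flatnonzero(sel)] -= (
            global_mean if cnt < 2 else lw[sel].mean()
        )
    return out


def exclude_iqr_outliers(values, k: float = 1.5) -> np.ndarray:
    """Flag values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use linear interpolation between order statistics (the
    numpy default).  Returns a boolean mask, True for flagged outliers;
    NaNs are never flagged.  A constant vector yields no outliers.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if len(finite) < 4:
        raise ParameterError("IQR rule needs >= 4 finite values")
    if not (k > 0):
        raise ParameterError("k must be positive")
    if math.isinf(k):
        return np.zeros(values.shape, dtype=bool)
    q1, q3 = np.percentile(finite, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    with np.errstate(invalid="ignore"):
        return np.isfinite(values) & ((values < lo) | (values > hi))


def attach_paternal_wealth(
    pedigree: Pedigree, pairs: pd.DataFrame, centred_wealth: pd.Series
) -> pd.DataFrame:
    """Add each pair member's father's centred log wealth as columns
    ``wealth_a`` / ``wealth_b``; pairs whose fathers are unknown get NaN."""
    df = pedigree.individuals
    father_of = pd.Series(df["father_id"].values, index=df["id"])
    out = pairs.copy()
    for side in ("a", "b"):
        fathers = out[f"id_{side}"].map(father_of)
        out[f"father_{side}"] = fathers
        out[f"wealth_{side}"] = fathers.map(centred_wealth).astype(float)
    return out


def pair_similarity_correlation(
    pairs: pd.DataFrame,
    *,
    outlier_rule: bool = True,
    k: float = 1.5,
    min_pairs: int = 30,
    min_categories: int = 3,
    weighted: bool = False,
) -> dict:
    """Cross-category correlation of status similarity with paternal-wealth
    similarity.

    For each relationship category the Pearson correlations
    ``r_status = corr(values_a, values_b)`` and
    ``r_wealth = corr(wealth_a, wealth_b)`` are computed over the
    category's pairs (paternal wealth being each member's father's
    centred log wealth).  The headline number is the Pearson correlation
    of these two vectors across categories, reported both with and
    without the IQR outlier rule on paternal wealth along with their
    difference.  Categories with fewer than ``min_pairs`` complete pairs
    are dropped and logged.
    """
    required = {"relationship", "values_a", "values_b", "wealth_a", "wealth_b"}
    if not required.issubset(pairs.columns):
        raise ConfigurationError(
            f"pair table lacks columns {sorted(required - set(pairs.columns))}"
        )
    complete = pairs.dropna(
        subset=["values_a", "values_b", "wealth_a", "wealth_b"]
    )
    if {"father_a", "father_b"}.issubset(complete.columns):
        # pairs sharing a father (siblings) have identical paternal wealth
        # by construction; the degenerate similarity of 1 carries no
        # information about wealth transmission and is excluded
        same_father = complete["father_a"] == complete["father_b"]
        if same_father.any():
            logger.info(
                "excluding %d same-father pairs from the similarity analysis",
                int(same_father.sum()),
            )
            complete = complete[~same_father]
    complete = complete.reset_index(drop=True)
    pooled_wealth = np.concatenate(
        [complete["wealth_a"].to_numpy(), complete["wealth_b"].to_numpy()]
    )
    flags = exclude_iqr_outliers(pooled_wealth, k=k)
    out_a = flags[: len(complete)]
    out_b = flags[len(complete):]

    def category_table(mask_outliers: bool) -> pd.DataFrame:
        rows = []
        for rel, sub_idx in complete.groupby("relationship").indices.items():
            sub = complete.iloc[sub_idx]
            if mask_outliers:
                sub = sub[~(out_a[sub_idx] | out_b[sub_idx])]
            if len(sub) < min_pairs:
                logger.info(
                    "dropping category %s (%d pairs < %d)", rel, len(sub), min_pairs
                )
                continue
            rows.append(
                {
                    "relationship": rel,
                    "n_pairs": len(sub),
                    "r_status": float(
                        np.corrcoef(sub["values_a"], sub["values_b"])[0, 1]
                    ),
                    "r_wealth": float(
                        np.corrcoef(sub["wealth_a"], sub["wealth_b"])[0, 1]
                    ),
                }
            )
        return pd.DataFrame(rows)

    def cross_r(tab: pd.DataFrame) -> float:
        if len(tab) < min_categories:
            raise ParameterError(
                f"need >= {min_categories} relationship categories, got {len(tab)}"
            )
        x, y = tab["r_status"].to_numpy(), tab["r_wealth"].to_numpy()
        if weighted:
            w = tab["n_pairs"].to_numpy(dtype=float)
            mx, my = np.average(x, weights=w), np.average(y, weights=w)
            cov = np.average((x - mx) * (y - my), weights=w)
            return float(
                cov
                / np.sqrt(
                    np.average((x - mx) ** 2, weights=w)
                    * np.average((y - my) ** 2, weights=w)
                )
            )
        return float(np.corrcoef(x, y)[0, 1])

    table_raw = category_table(mask_outliers=False)
    table_masked = category_table(mask_outliers=True)
    r_raw = cross_r(table_raw)
    r_masked = cross_r(table_masked)
    result = {
        "r": r_masked if outlier_rule else r_raw,
        "r_with_outlier_rule": r_masked,
        "r_without_outlier_rule": r_raw,
        "outlier_rule_impact": abs(r_masked - r_raw),
        "table": table_masked if outlier_rule else table_raw,
        "n_categories": int(len(table_masked if outlier_rule else table_raw)),
    }
    return result
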
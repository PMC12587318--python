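"""Familial correlation estimation with pseudoreplication correction.

Relative-pair tables are enumerated from a pedigree by common-ancestor
search.  Correlations can be estimated naively (all pairs treated as
independent, analytic CI) or with the one-pair-per-surname bootstrap,
which draws a single pair per surname cluster in each replicate so that
no individual-sharing cluster contributes more than one observation.
The relationship-level correlation profile is then fitted on the log
scale to recover the transmissibility t2 and persistence rate b.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError, FitError, ParameterError
from .kin_model import RELATIONSHIP_DISTANCE
from .synthetic import Pedigree

__all__ = [
    "PAIR_COLUMNS",
    "KinCorrEstimate",
    "ModelFit",
    "CohortTrendResult",
    "enumerate_relative_pairs",
    "estimate_kin_correlation",
    "estimate_by_relationship",
    "cluster_bootstrap_se",
    "fit_transmission_model",
    "cohort_trend",
]

logger = logging.getLogger(__name__)

#: Mandated column names for relative-pair CSV tables.
PAIR_COLUMNS = (
    "id_a", "id_b", "relationship", "n", "surname",
    "values_a", "values_b", "cohort",
)

_ORDINALS = {1: "first", 2: "second", 3: "third", 4: "fourth"}


def _relationship_label(d_min: int, d_max: int) -> str:
    """Relationship name from depths to the closest common ancestor."""
    if d_min == 0:
        names = {
            1: "parent-offspring",
            2: "grandparent-grandchild",
            3: "great-grandparent-grandchild",
            4: "great-great-grandparent-grandchild",
        }
        return names.get(d_max, f"lineal-{d_max}")
    if d_min == 1:
        if d_max == 1:
            return "siblings"
        if d_max == 2:
            return "avuncular"
        if d_max == 3:
            return "grand-avuncular"
        return f"avuncular-{d_max - 1}"
    degree = d_min - 1
    removed = d_max - d_min
    base = f"{_ORDINALS.get(degree, f'{degree}th')}-cousins"
    if removed == 0:
        return base
    if removed == 1:
        return base + "-once-removed"
    if removed == 2:
        return base + "-twice-removed"
    return base + f"-{removed}-times-removed"


def _ancestor_incidences(
    father: np.ndarray, mother: np.ndarray, max_depth: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Arrays (ancestor, descendant, depth, branch) with minimal depth per
    link; ``branch`` is the child of the ancestor through whom the
    descendant descends (used to emit each collateral pair only at the
    ancestor where the two lines diverge).

    Individuals must be ordered so parents precede children (true for
    generated pedigrees; enforced by the caller via a generation sort).
    """
    n = len(father)
    anc_maps: list[dict[int, tuple[int, int]]] = [dict() for _ in range(n)]
    for i in range(n):
        am = anc_maps[i]
        for p in (father[i], mother[i]):
            if p < 0:
                continue
            if am.get(p, (max_depth + 1, -1))[0] > 1:
                am[p] = (1, i)
            for a, (d, br) in anc_maps[p].items():
                if d + 1 <= max_depth and am.get(a, (max_depth + 1, -1))[0] > d + 1:
                    am[a] = (d + 1, br)
    anc, ind, dep, bra = [], [], [], []
    for i, am in enumerate(anc_maps):
        for a, (d, br) in am.items():
            anc.append(a)
            ind.append(i)
            dep.append(d)
            bra.append(br)
    return (
        np.asarray(anc, dtype=np.int64),
        np.asarray(ind, dtype=np.int64),
        np.asarray(dep, dtype=np.int64),
        np.asarray(bra, dtype=np.int64),
    )


def enumerate_relative_pairs(
    pedigree: Pedigree,
    relationships: list[str] | None = None,
    *,
    measure: str | None = None,
    max_depth: int | None = None,
    cohort_by: str = "decade",
) -> pd.DataFrame:
    """Enumerate relative pairs, each labelled with its closest relationship.

    Pairs are found by common-ancestor search up to ``max_depth``
    generational links (default: the pedigree's depth).  When several
    common ancestors exist, the smallest genealogical distance n wins;
    lineal distance is the number of links, collateral distance is
    ``d_a + d_b - 1`` for closest-ancestor depths (d_a, d_b).  The pair's
    clustering surname is the closest common ancestor's (preferring the
    male of an ancestral couple, i.e. the shared patriline).  The cohort
    label is the younger member's birth decade (``cohort_by="decade"``)
    or generation index (``cohort_by="generation"``).

    Returns a DataFrame with columns :data:`PAIR_COLUMNS` in a
    deterministic order.
    """
    df = pedigree.individuals.sort_values(
        ["generation", "id"], kind="stable"
    ).reset_index(drop=True)
    measure = measure or pedigree.measures[0]
    if measure not in df.columns:
        raise ParameterError(f"measure {measure!r} not in pedigree columns")
    pos = pd.Series(np.arange(len(df)), index=df["id"])
    father = df["father_id"].map(pos).fillna(-1).astype(np.int64).to_numpy()
    mother = df["mother_id"].map(pos).fillna(-1).astype(np.int64).to_numpy()
    depth_cap = max_depth or max(pedigree.generations - 1, 1)

    anc, ind, dep, bra = _ancestor_incidences(father, mother, depth_cap)
    if len(anc) == 0:
        return pd.DataFrame(columns=list(PAIR_COLUMNS))

    anc = anc.astype(np.int32)
    ind = ind.astype(np.int32)
    dep = dep.astype(np.int32)
    bra = bra.astype(np.int32)
    # sort by (ancestor, branch): within an ancestor block, same-branch
    # incidences are contiguous
    order = np.lexsort((bra, anc))
    anc, ind, dep, bra = anc[order], ind[order], dep[order], bra[order]
    new_block = np.diff(anc, prepend=anc[0] - 1) != 0
    new_branch = new_block | (np.diff(bra, prepend=bra[0] - 1) != 0)
    idx_all = np.arange(len(anc), dtype=np.int32)
    block_start = idx_all[new_block][np.cumsum(new_block) - 1]
    branch_start = idx_all[new_branch][np.cumsum(new_branch) - 1]
    # collateral pairs diverging at this ancestor: each element pairs with
    # all earlier elements of its block belonging to a different branch,
    # i.e. the branch_start - block_start predecessors
    n_partners = branch_start - block_start
    tot = int(n_partners.astype(np.int64).sum())
    seg_off = (np.cumsum(n_partners) - n_partners).astype(np.int64)
    jj = np.repeat(idx_all, n_partners)
    ii = np.repeat(block_start, n_partners) + (
        np.arange(tot) - np.repeat(seg_off, n_partners)
    ).astype(np.int32)
    di, dj = dep[ii], dep[jj]
    # lineal pairs (ancestor with descendant) prepended
    pa = np.concatenate([anc, ind[ii]])
    pb = np.concatenate([ind, ind[jj]])
    pn = np.concatenate([dep, di + dj - 1])
    code = np.concatenate(  # dmin * 64 + dmax
        [dep, np.minimum(di, dj) * 64 + np.maximum(di, dj)]
    )
    panc = np.concatenate([anc, anc[ii]])
    del ii, jj, di, dj
    lo, hi = np.minimum(pa, pb), np.maximum(pa, pb)
    del pa, pb

    male_anc = (df["sex"].to_numpy() == "M")[panc]
    # keep, per unordered pair, the candidate with smallest n (preferring
    # a male common ancestor on ties, i.e. the shared patriline)
    key = lo.astype(np.int64) * len(df) + hi
    sort_idx = np.lexsort((~male_anc, pn, key))
    key_sorted = key[sort_idx]
    first = np.ones(len(key_sorted), dtype=bool)
    first[1:] = key_sorted[1:] != key_sorted[:-1]
    keep = sort_idx[first]
    del key, key_sorted, first, sort_idx, male_anc

    if cohort_by not in ("decade", "generation"):
        raise ParameterError("cohort_by must be 'decade' or 'generation'")
    ids = df["id"].to_numpy()
    surnames = df["surname"].to_numpy()
    years = df["birth_year"].to_numpy()
    gens = df["generation"].to_numpy()
    vals = df[measure].to_numpy(dtype=float)
    a, b = lo[keep], hi[keep]
    kn, kanc, kcode = pn[keep], panc[keep], code[keep]
    # labelling via a (dmin, dmax)-code lookup table
    uniq = np.unique(kcode)
    label_for = {int(c): _relationship_label(int(c // 64), int(c % 64)) for c in uniq}
    lut = np.empty(int(uniq.max()) + 1, dtype=object)
    rank_lut = np.full(int(uniq.max()) + 1, -1, dtype=np.int32)
    for r_, name in enumerate(sorted(set(label_for.values()))):
        for c, nm in label_for.items():
            if nm == name:
                lut[c] = nm
                rank_lut[c] = r_
    rank = rank_lut[kcode]
    if relationships is not None:
        wanted = set(relationships)
        ok_codes = np.array(
            [c for c in uniq if label_for[int(c)] in wanted], dtype=kcode.dtype
        )
        sel = np.isin(kcode, ok_codes)
        a, b, kn, kanc, kcode, rank = (
            x[sel] for x in (a, b, kn, kanc, kcode, rank)
        )
    order2 = np.lexsort((b, a, rank))
    a, b, kn, kanc, kcode = (
        x[order2] for x in (a, b, kn, kanc, kcode)
    )
    labels = lut[kcode]
    return pd.DataFrame(
        {
            "id_a": ids[a],
            "id_b": ids[b],
            "relationship": labels,
            "n": kn.astype(np.int64),
            "surname": surnames[kanc],
            "values_a": vals[a],
            "values_b": vals[b],
            # cohort convention: the younger member's birth decade (or
            # generation index when cohort_by="generation")
            "cohort": (
                (np.maximum(years[a], years[b]) // 10 * 10).astype(int)
                if cohort_by == "decade"
                else np.maximum(gens[a], gens[b]).astype(int)
            ),
        }
    )


# ----------------------------------------------------------------------
# correlation estimation
# ----------------------------------------------------------------------

@dataclass
class KinCorrEstimate:
    """A familial correlation estimate with dual sample-size reporting.

    ``n_pairs`` counts relative pairs and ``n_unique`` the distinct
    individuals among them; a large gap between the two is the signature
    of pseudoreplication.
    """

    relationship: str
    r: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_unique: int
    method: str
    n_boot: int = 0
    se: float | None = None
    boot_r: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "relationship": self.relationship,
            "r": self.r,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pairs": self.n_pairs,
            "n_unique": self.n_unique,
            "method": self.method,
            "n_boot": self.n_boot,
            "se": self.se,
        }


def _clean_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    ok = np.isfinite(pairs["values_a"]) & np.isfinite(pairs["values_b"])
    ok &= pairs["id_a"] != pairs["id_b"]
    dropped = len(pairs) - int(ok.sum())
    if dropped:
        logger.info("dropped %d incomplete or degenerate pairs", dropped)
    return pairs[ok]


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    den = np.sqrt((A * A).sum(axis=1) * (B * B).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, (A * B).sum(axis=1) / den, np.nan)


def estimate_kin_correlation(
    pairs: pd.DataFrame,
    method: str = "one_per_surname_bootstrap",
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    relationship: str | None = None,
    min_pairs: int = 10,
    min_clusters: int = 10,
    n_inner: int = 20,
) -> KinCorrEstimate:
    """Estimate the correlation of a relative-pair table.

    ``method="naive"`` computes the Pearson correlation over all pairs
    with the analytic Fisher-z 95% CI, treating pairs as independent.
    ``method="one_per_surname_bootstrap"`` never uses more than one pair
    per surname at a time.  The point estimate is the mean Pearson
    correlation over random one-pair-per-surname selections, which is
    immune to pairs that recycle the same individuals within a surname
    lineage.  Its percentile 95% CI comes from ``n_boot`` outer
    replicates that resample the surname clusters with replacement and
    average the correlation over ``n_inner`` selections each, so the CI
    reflects between-cluster sampling variability rather than the
    within-cluster selection noise that the estimator itself averages
    out.
    """
    if method not in ("naive", "one_per_surname_bootstrap"):
        raise ParameterError(f"unknown method {method!r}")
    pairs = _clean_pairs(pairs)
    label = relationship or (
        pairs["relationship"].iloc[0] if len(pairs) else "unknown"
    )
    x = pairs["values_a"].to_numpy(dtype=float)
    y = pairs["values_b"].to_numpy(dtype=float)
    n_unique = pd.concat([pairs["id_a"], pairs["id_b"]]).nunique()

    if method == "naive":
        if len(pairs) < min_pairs:
            raise EstimationError(
                f"naive estimate needs >= {min_pairs} pairs, got {len(pairs)}"
            )
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            raise EstimationError("constant values: correlation undefined")
        res = stats.pearsonr(x, y)
        r = float(res.statistic)
        if abs(r) >= 1.0 - 1e-12:
            lo = hi = r  # degenerate: perfectly correlated values
        else:
            ci = res.confidence_interval()
            lo, hi = float(ci.low), float(ci.high)
        se = (1.0 - r**2) / np.sqrt(max(len(pairs) - 3, 1))
        return KinCorrEstimate(
            relationship=label, r=r, ci_low=lo, ci_high=hi,
            n_pairs=len(pairs), n_unique=int(n_unique),
            method=method, se=float(se),
        )

    groups = pairs.groupby("surname", sort=True).indices
    sizes = np.array([len(v) for v in groups.values()])
    if (sizes == 0).any():
        logger.info("dropping %d surnames with no complete pairs", (sizes == 0).sum())
    keys = [k for k, v in groups.items() if len(v)]
    if len(keys) < min_clusters:
        raise EstimationError(
            f"one-per-surname bootstrap needs >= {min_clusters} surname "
            f"clusters, got {len(keys)}"
        )
    pool = np.concatenate([groups[k] for k in keys])
    sizes = np.array([len(groups[k]) for k in keys])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    rng = np.random.default_rng(seed)
    k = len(keys)
    if (sizes == 1).all():
        n_inner = 1  # selection is deterministic: pure cluster bootstrap
    # point estimate: selection average without cluster resampling
    n_sel = 1 if (sizes == 1).all() else min(n_boot, 500)
    u = rng.random((n_sel, k))
    draw = pool[offsets + (u * sizes).astype(np.int64)]
    r_sel = _rowwise_pearson(x[draw], y[draw])
    r_sel = r_sel[np.isfinite(r_sel)]
    if len(r_sel) == 0:
        raise EstimationError("all selection replicates degenerate")
    r = float(np.mean(r_sel))
    # outer cluster bootstrap, inner selection averaging
    boot = np.empty(n_boot)
    chunk = max(1, int(4_000_000 // max(n_inner * k, 1)))
    for s in range(0, n_boot, chunk):
        e = min(s + chunk, n_boot)
        cl = rng.integers(0, k, (e - s, 1, k))
        cl = np.broadcast_to(cl, (e - s, n_inner, k))
        uu = rng.random((e - s, n_inner, k))
        d = pool[offsets[cl] + (uu * sizes[cl]).astype(np.int64)]
        rr = _rowwise_pearson(
            x[d].reshape(-1, k), y[d].reshape(-1, k)
        ).reshape(e - s, n_inner)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            boot[s:e] = np.nanmean(rr, axis=1)
    boot = boot[np.isfinite(boot)]
    if len(boot) == 0:
        raise EstimationError("all bootstrap replicates degenerate")
    lo, hi = (float(q) for q in np.percentile(boot, [2.5, 97.5]))
    return KinCorrEstimate(
        relationship=label, r=r, ci_low=lo, ci_high=hi,
        n_pairs=len(pairs), n_unique=int(n_unique),
        method=method, n_boot=n_boot, se=float(np.std(boot, ddof=1)),
        boot_r=boot,
    )


def cluster_bootstrap_se(
    pairs: pd.DataFrame, n_boot: int = 100, seed: int | None = None
) -> float:
    """Monte-Carlo standard error of the all-pairs Pearson correlation,
    resampling surname clusters with replacement.

    Pairs within a surname lineage share individuals, so the naive
    analytic SE understates the sampling variability; the cluster
    bootstrap respects the dependence structure.
    """
    pairs = _clean_pairs(pairs)
    x = pairs["values_a"].to_numpy(dtype=float)
    y = pairs["values_b"].to_numpy(dtype=float)
    groups = [v for v in pairs.groupby("surname").indices.values() if len(v)]
    if len(groups) < 2:
        raise EstimationError("cluster bootstrap needs >= 2 surname clusters")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_boot)
    k = len(groups)
    for b_ in range(n_boot):
        take = rng.integers(0, k, k)
        idx = np.concatenate([groups[t] for t in take])
        xc, yc = x[idx] - x[idx].mean(), y[idx] - y[idx].mean()
        denom = np.sqrt((xc @ xc) * (yc @ yc))
        rs[b_] = (xc @ yc) / denom if denom > 0 else np.nan
    rs = rs[np.isfinite(rs)]
    return float(np.std(rs, ddof=1))


def estimate_by_relationship(
    pairs: pd.DataFrame,
    method: str = "one_per_surname_bootstrap",
    n_boot: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> dict[str, KinCorrEstimate]:
    """One :class:`KinCorrEstimate` per relationship label in the table."""
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    out: dict[str, KinCorrEstimate] = {}
    labels = sorted(pairs["relationship"].unique())
    for label, child in zip(labels, ss.spawn(len(labels))):
        sub = pairs[pairs["relationship"] == label]
        try:
            out[label] = estimate_kin_correlation(
                sub, method=method, n_boot=n_boot,
                seed=child.generate_state(1)[0] if seed is not None else None,
                relationship=label, **kwargs,
            )
        except EstimationError as exc:
            logger.warning("skipping %s: %s", label, exc)
    return out


# ----------------------------------------------------------------------
# model fit
# ----------------------------------------------------------------------

@dataclass
class ModelFit:
    """Fitted transmissibility model: log r = log t2 + n log b."""

    t2_hat: float
    b_hat: float
    se_t2: float
    se_b: float
    residuals: dict[str, float]
    n_relationships: int
    n_excluded: int
    clipped: bool = False

    @property
    def m_hat(self) -> float:
        return 2.0 * self.b_hat - 1.0

    def to_dict(self) -> dict:
        return {
            "t2_hat": self.t2_hat, "b_hat": self.b_hat, "m_hat": self.m_hat,
            "se_t2": self.se_t2, "se_b": self.se_b,
            "residuals": self.residuals,
            "n_relationships": self.n_relationships,
            "n_excluded": self.n_excluded, "clipped": self.clipped,
        }


def _fit_loglinear(ns: np.ndarray, rs: np.ndarray, w: np.ndarray | None):
    X = sm.add_constant(ns.astype(float))
    model = (
        sm.WLS(np.log(rs), X, weights=w) if w is not None
        else sm.OLS(np.log(rs), X)
    )
    res = model.fit()
    t2 = float(np.exp(res.params[0]))
    b = float(np.exp(res.params[1]))
    return t2, b, res


def fit_transmission_model(
    estimates: dict[str, KinCorrEstimate] | list[KinCorrEstimate],
    mapping: dict[str, int] | None = None,
    n_boot: int = 500,
    seed: int | None = None,
    *,
    weighted: bool = False,
) -> ModelFit:
    """Fit (t2, b) to a relationship-level correlation profile.

    Ordinary least squares of log r on genealogical distance n:
    intercept = log t2, slope = log b.  Estimates with r <= 0 cannot
    enter the log fit and are excluded (counted in ``n_excluded``).
    Standard errors propagate per-estimate uncertainty by resampling each
    r from its bootstrap distribution (or a normal approximation) and
    refitting.  ``weighted=True`` uses inverse bootstrap-variance WLS.
    """
    if isinstance(estimates, dict):
        estimates = list(estimates.values())
    mapping = mapping or RELATIONSHIP_DISTANCE
    usable, excluded = [], 0
    for est in estimates:
        if est.relationship not in mapping:
            raise LookupError(
                f"no genealogical distance for {est.relationship!r}; "
                f"supply a mapping"
            )
        if est.r > 0:
            usable.append(est)
        else:
            excluded += 1
    ns = np.array([mapping[e.relationship] for e in usable], dtype=float)
    rs = np.array([e.r for e in usable])
    if len(np.unique(ns)) < 3:
        raise FitError(
            f"need >= 3 distinct genealogical distances with positive r, "
            f"got {len(np.unique(ns))}"
        )
    w = None
    if weighted:
        w = np.array([1.0 / max(e.se, 1e-12) ** 2 for e in usable])
    t2, b, res = _fit_loglinear(ns, rs, w)
    clipped = False
    if b > 1.0:
        warnings.warn("b_hat > 1 after back-transform; clipped to 1")
        b, clipped = 1.0, True
    if t2 > 1.0:
        warnings.warn("t2_hat > 1 after back-transform; clipped to 1")
        t2, clipped = 1.0, True
    residuals = {
        e.relationship: float(np.log(e.r) - (np.log(t2) + n * np.log(b)))
        for e, n in zip(usable, ns)
    }

    rng = np.random.default_rng(seed)
    t2_bs, b_bs = [], []
    for _ in range(n_boot):
        r_star = np.array(
            [
                rng.choice(e.boot_r) if e.boot_r is not None
                else rng.normal(e.r, e.se or 0.0)
                for e in usable
            ]
        )
        keep = r_star > 0
        if len(np.unique(ns[keep])) < 3:
            continue
        t2_s, b_s, _ = _fit_loglinear(ns[keep], r_star[keep], None)
        t2_bs.append(min(t2_s, 1.0))
        b_bs.append(min(b_s, 1.0))
    se_t2 = float(np.std(t2_bs, ddof=1)) if len(t2_bs) > 1 else float("nan")
    se_b = float(np.std(b_bs, ddof=1)) if len(b_bs) > 1 else float("nan")
    return ModelFit(
        t2_hat=t2, b_hat=b, se_t2=se_t2, se_b=se_b,
        residuals=residuals, n_relationships=len(usable),
        n_excluded=excluded, clipped=clipped,
    )


# ----------------------------------------------------------------------
# cohort trends
# ----------------------------------------------------------------------

@dataclass
class CohortTrendResult:
    """Per-cohort corrected estimates plus a last-minus-first summary."""

    cohorts: list
    estimates: list[KinCorrEstimate]
    diff: float
    diff_ci_low: float
    diff_ci_high: float
    use_ranks: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(cohort=c, **e.to_dict()) for c, e in zip(self.cohorts, self.estimates)]
        )


def _percentile_ranks(pairs: pd.DataFrame) -> pd.DataFrame:
    pooled = np.concatenate([pairs["values_a"], pairs["values_b"]])
    ranks = stats.rankdata(pooled, nan_policy="omit") / (len(pooled) + 1)
    out = pairs.copy()
    out["values_a"] = ranks[: len(pairs)]
    out["values_b"] = ranks[len(pairs):]
    return out


def cohort_trend(
    pairs: pd.DataFrame,
    cohorts: list | None = None,
    method: str = "one_per_surname_bootstrap",
    use_ranks: bool = False,
    n_boot: int = 500,
    seed: int | None = None,
    **kwargs,
) -> CohortTrendResult:
    """Correlation estimates per cohort with a monotone-trend summary.

    Cohorts default to the sorted distinct values of the pairs' ``cohort``
    column (the younger member's birth decade).  ``use_ranks=True``
    computes correlations on within-cohort percentile ranks of the pooled
    member values.  The trend summary is the last-minus-first cohort
    correlation difference with a percentile bootstrap CI (replicates of
    the two cohorts are independent, so the difference distribution is
    formed elementwise).
    """
    if cohorts is None:
        cohorts = sorted(pairs["cohort"].dropna().unique())
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    kept, ests = [], []
    for cohort, child in zip(cohorts, ss.spawn(len(cohorts))):
        sub = pairs[pairs["cohort"] == cohort]
        if len(sub) == 0:
            warnings.warn(f"cohort {cohort!r} is empty; dropped")
            continue
        if use_ranks:
            sub = _percentile_ranks(sub)
        ests.append(
            estimate_kin_correlation(
                sub, method=method, n_boot=n_boot,
                seed=child.generate_state(1)[0] if seed is not None else None,
                relationship=str(cohort), **kwargs,
            )
        )
        kept.append(cohort)
    if len(kept) < 2:
        raise EstimationError("need >= 2 non-empty cohorts for a trend")
    first, last = ests[0], ests[-1]
    diff = last.r - first.r
    if first.boot_r is not None and last.boot_r is not None:
        k = min(len(first.boot_r), len(last.boot_r))
        d = last.boot_r[:k] - first.boot_r[:k]
        lo, hi = (float(q) for q in np.percentile(d, [2.5, 97.5]))
    else:
        se = np.sqrt((first.se or 0.0) ** 2 + (last.se or 0.0) ** 2)
        lo, hi = diff - 1.96 * se, diff + 1.96 * se
    return CohortTrendResult(
        cohorts=kept, estimates=ests, diff=float(diff),
        diff_ci_low=lo, diff_ci_high=hi, use_ranks=use_ranks,
    )
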
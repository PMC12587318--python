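"""Partial (residualized) genetic correlations and the many-mediators screen.

Given a labelled correlation set with sampling covariance, the partial
correlation of traits A and B given a candidate mediator X is

    r_AB.X = (r_AB - r_AX r_BX) / sqrt((1 - r_AX^2)(1 - r_BX^2))

with a first-order (delta-method) standard error propagated through the
sampling covariance of (r_AB, r_AX, r_BX), and a Wald two-sided p-value.
The screen repeats the adjustment across many candidate mediators: if
most of them also render the A-B correlation non-significant, the data
provide no unique support for any single mediation story.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegeneracyError, ParameterError
from .synthetic import GeneticCorrelationSet, nearest_correlation  # noqa: F401

__all__ = [
    "PartialRgResult",
    "ScreenResult",
    "partial_rg",
    "run_screen",
    "sampling_covariance_from_replicates",
]


def sampling_covariance_from_replicates(replicates) -> np.ndarray:
    """Jackknife-style sampling covariance of the distinct off-diagonal
    entries from user-supplied replicate correlation matrices.

    For sets that come without an analytic sampling covariance (e.g.
    block-jackknife replicates of a genetic-correlation estimator), the
    covariance of the condensed upper-triangle entries across the k
    replicates, scaled by (k - 1)^2 / k in the delete-one convention, is
    a plug-in V for :func:`partial_rg`.
    """
    mats = [np.asarray(r, dtype=float) for r in replicates]
    k = len(mats)
    if k < 3:
        raise ParameterError("need >= 3 replicate matrices")
    p = mats[0].shape[0]
    if any(m.shape != (p, p) for m in mats):
        raise ParameterError("replicate matrices must share one shape")
    iu = np.triu_indices(p, k=1)
    flat = np.stack([m[iu] for m in mats])
    dev = flat - flat.mean(axis=0)
    return (dev.T @ dev) * (k - 1) / k


@dataclass
class PartialRgResult:
    """Partial correlation of (a, b) given mediator x, with uncertainty."""

    a: str
    b: str
    x: str
    r_ab: float
    r_ab_given_x: float
    se: float | None
    z: float | None
    p: float | None
    significant: bool | None
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "mediator": self.x,
            "r_ab": self.r_ab, "r_ab_given_x": self.r_ab_given_x,
            "se": self.se, "z": self.z, "p": self.p,
            "significant": self.significant, "alpha": self.alpha,
        }


def _partial_value_and_gradient(
    r_ab: float, r_ax: float, r_bx: float
) -> tuple[float, np.ndarray]:
    d = (1.0 - r_ax**2) * (1.0 - r_bx**2)
    num = r_ab - r_ax * r_bx
    p = num / np.sqrt(d)
    g_ab = 1.0 / np.sqrt(d)
    g_ax = -r_bx / np.sqrt(d) + num * r_ax * (1.0 - r_bx**2) / d**1.5
    g_bx = -r_ax / np.sqrt(d) + num * r_bx * (1.0 - r_ax**2) / d**1.5
    return float(p), np.array([g_ab, g_ax, g_bx])


def partial_rg(
    rg_set: GeneticCorrelationSet, a: str, b: str, x: str, alpha: float = 0.05
) -> PartialRgResult:
    """Partial correlation of a and b given x, with delta-method se.

    Raises :class:`DegeneracyError` when x is perfectly correlated with a
    or b.  When the set carries no sampling covariance the point estimate
    is returned with null uncertainty and a warning.
    """
    if len({a, b, x}) != 3:
        raise ParameterError("a, b, x must be three distinct labels")
    r_ab, r_ax, r_bx = rg_set.r(a, b), rg_set.r(a, x), rg_set.r(b, x)
    if abs(r_ax) >= 1.0 - 1e-12 or abs(r_bx) >= 1.0 - 1e-12:
        raise DegeneracyError(
            f"mediator {x!r} is perfectly correlated with an endpoint "
            f"(r_ax={r_ax:.4f}, r_bx={r_bx:.4f})"
        )
    value, grad = _partial_value_and_gradient(r_ab, r_ax, r_bx)
    if rg_set.V is None:
        warnings.warn("correlation set carries no sampling covariance; se is null")
        return PartialRgResult(
            a=a, b=b, x=x, r_ab=r_ab, r_ab_given_x=value,
            se=None, z=None, p=None, significant=None, alpha=alpha,
        )
    idx = [rg_set.flat_index(a, b), rg_set.flat_index(a, x), rg_set.flat_index(b, x)]
    v3 = rg_set.V[np.ix_(idx, idx)]
    se = float(np.sqrt(max(grad @ v3 @ grad, 0.0)))
    if se == 0.0:
        z = np.inf if value != 0 else 0.0
    else:
        z = value / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return PartialRgResult(
        a=a, b=b, x=x, r_ab=r_ab, r_ab_given_x=value,
        se=se, z=float(z), p=p, significant=bool(p < alpha), alpha=alpha,
    )


@dataclass
class ScreenResult:
    """Outcome of a many-mediators screen for a focal pair (a, b)."""

    a: str
    b: str
    results: list[PartialRgResult]
    raw_r_ab: float
    raw_p: float | None
    raw_significant: bool | None
    n_significant: int
    n_nonsignificant: int
    alpha: float
    correction: str
    #: per mediator: is the mediator's own partial correlation with b
    #: (given a) significant?  Mirrors the asterisk annotation style.
    mediator_b_partial_significant: dict[str, bool | None] = None

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b,
            "raw_r_ab": self.raw_r_ab, "raw_p": self.raw_p,
            "raw_significant": self.raw_significant,
            "n_significant": self.n_significant,
            "n_nonsignificant": self.n_nonsignificant,
            "alpha": self.alpha, "correction": self.correction,
            "results": [r.to_dict() for r in self.results],
            "mediator_b_partial_significant": self.mediator_b_partial_significant,
        }


def run_screen(
    rg_set: GeneticCorrelationSet,
    a: str,
    b: str,
    mediators: list[str] | None = None,
    alpha: float = 0.05,
    correction: str = "none",
) -> ScreenResult:
    """Partial the (a, b) correlation on every candidate mediator.

    Significance defaults to uncorrected p < alpha (``correction="none"``);
    ``correction="BH"`` applies Benjamini-Hochberg across mediators.  The
    summary counts significant / non-significant partials and records, per
    mediator, whether the mediator's own partial correlation with b given
    a is significant.  Output order is deterministic and independent of
    the order mediators are supplied in (results follow the supplied
    order; significance is order-invariant).
    """
    if not (0.0 < alpha <= 1.0):
        raise ParameterError("alpha must be in (0, 1]")
    if correction not in ("none", "BH"):
        raise ParameterError("correction must be 'none' or 'BH'")
    if mediators is None:
        mediators = [l for l in rg_set.labels if l not in (a, b)]
    for x in mediators:
        rg_set.index(x)  # raises KeyError for unknown labels
        if x in (a, b):
            raise ParameterError(f"mediator {x!r} coincides with an endpoint")

    results = [partial_rg(rg_set, a, b, x, alpha=alpha) for x in mediators]
    if correction == "BH" and all(r.p is not None for r in results):
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [r.p for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, rej in zip(results, reject):
            r.significant = bool(rej)

    raw_r = rg_set.r(a, b)
    raw_p = raw_sig = None
    if rg_set.V is not None:
        se = float(np.sqrt(rg_set.V[rg_set.flat_index(a, b), rg_set.flat_index(a, b)]))
        raw_p = float(2.0 * stats.norm.sf(abs(raw_r) / se)) if se > 0 else 0.0
        raw_sig = bool(raw_p < alpha)

    med_b = {}
    for x in mediators:
        try:
            med_b[x] = partial_rg(rg_set, x, b, a, alpha=alpha).significant
        except DegeneracyError:
            med_b[x] = None

    n_sig = sum(1 for r in results if r.significant)
    return ScreenResult(
        a=a, b=b, results=results, raw_r_ab=raw_r, raw_p=raw_p,
        raw_significant=raw_sig, n_significant=n_sig,
        n_nonsignificant=len(results) - n_sig, alpha=alpha,
        correction=correction, mediator_b_partial_significant=med_b,
    )
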
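"""Closed-form expected kin correlations under the transmissibility model.

The expected phenotypic correlation of a relative pair at genealogical
distance ``n`` is ``t2 * b**n`` with persistence rate ``b = (1 + m) / 2``,
where ``t2`` is the transmissibility (share of trait variance in the
transmitted component) and ``m`` the spousal correlation of that
component.  The same fitted numbers admit two readings — "genetic"
(t2 read as narrow-sense heritability, m as genetic assortment) and
"transmissible" (t2 as total transmissibility of any parent-to-offspring
channel) — which :func:`reinterpret_fit` makes machine-readable.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .errors import ParameterError

__all__ = [
    "RelationshipSpec",
    "RELATIONSHIP_DISTANCE",
    "LINEAL_RELATIONSHIPS",
    "persistence_rate",
    "expected_kin_correlation",
    "reinterpret_fit",
]

#: Relationship label -> genealogical distance n (the exponent of b).
#: Lineal chains use the number of generational links; collateral pairs
#: with closest common-ancestor depths (j, k) use n = j + k - 1 (siblings
#: share a midparent at n = 1; k-th cousins have n = 2k + 1).
RELATIONSHIP_DISTANCE: dict[str, int] = {
    "parent-offspring": 1,
    "siblings": 1,
    "avuncular": 2,
    "grandparent-grandchild": 2,
    "grand-avuncular": 3,
    "great-grandparent-grandchild": 3,
    "first-cousins": 3,
    "first-cousins-once-removed": 4,
    "great-great-grandparent-grandchild": 4,
    "second-cousins": 5,
    "first-cousins-twice-removed": 5,
    "second-cousins-once-removed": 6,
    "third-cousins": 7,
    "third-cousins-once-removed": 8,
    "fourth-cousins": 9,
}

#: Lineal labels: the exact parameterization of b for these pairs also
#: depends on assortment on the focal trait itself; the package applies
#: t2 * b**n uniformly and warns (see expected_kin_correlation).
LINEAL_RELATIONSHIPS = frozenset(
    l for l in RELATIONSHIP_DISTANCE if "parent" in l and "cousins" not in l
)

_COUSIN_RE = re.compile(r"^(\d+)(?:st|nd|rd|th)-cousins$")


@dataclass(frozen=True)
class RelationshipSpec:
    """A supported relationship label with its genealogical distance."""

    label: str
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("genealogical distance n must be >= 1")

    @classmethod
    def from_label(cls, label: str) -> "RelationshipSpec":
        try:
            return cls(label=label, n=RELATIONSHIP_DISTANCE[label])
        except KeyError:
            raise LookupError(
                f"unsupported relationship {label!r}; supported: "
                f"{sorted(RELATIONSHIP_DISTANCE)}"
            ) from None


def persistence_rate(m: float) -> float:
    """Intergenerational persistence rate b = (1 + m) / 2.

    Random mating (m = 0) halves the transmitted component's covariance
    each generation; perfect assortment (m = 1) preserves it.
    """
    if not (0.0 <= m <= 1.0):
        raise ParameterError(f"spousal correlation m must be in [0, 1], got {m}")
    return (1.0 + m) / 2.0


def expected_kin_correlation(params, rel: RelationshipSpec | str) -> float:
    """Expected phenotypic correlation t2 * b**n for a relative pair.

    ``rel`` may be a :class:`RelationshipSpec` or a supported label.
    Lineal relationships (parent-offspring, grandparent, ...) are
    approximated by the same formula; their exact parameterization also
    depends on the degree of assortative mating on the focal trait, so a
    warning is emitted for them.
    """
    if isinstance(rel, str):
        rel = RelationshipSpec.from_label(rel)
    if rel.label in LINEAL_RELATIONSHIPS:
        warnings.warn(
            f"lineal relationship {rel.label!r}: t2*b^n is an approximation "
            "whose exact form depends on assortment on the focal trait",
            stacklevel=2,
        )
    b = persistence_rate(params.m)
    return params.t2 * b**rel.n


def reinterpret_fit(fit, mode: str) -> dict:
    """Relabel a fitted (t2_hat, b_hat) under a chosen reading.

    The two modes return identical numbers under different labels — the
    data cannot distinguish them:

    - ``"genetic"``: the reading in which all transmission is genetic;
      t2_hat is labelled narrow-sense heritability h2 and m_hat the
      spousal correlation in genetic value.
    - ``"transmissible"``: t2_hat is the total transmissibility of the
      trait and m_hat the spousal correlation in the transmissible
      component, with no claim about the channel (genes, wealth, culture).
    """
    if mode not in ("genetic", "transmissible"):
        raise ParameterError("mode must be 'genetic' or 'transmissible'")
    t2_hat, b_hat = float(fit.t2_hat), float(fit.b_hat)
    m_hat = 2.0 * b_hat - 1.0
    if mode == "genetic":
        return {
            "label_mode": "genetic",
            "h2": t2_hat,
            "b": b_hat,
            "m": m_hat,
            "parameter_labels": {
                "h2": "narrow-sense heritability",
                "m": "spousal correlation in genetic value",
            },
            "caveat": (
                "this reading assumes no systematically transmitted "
                "non-genetic influences; it is observationally "
                "indistinguishable from the 'transmissible' reading"
            ),
        }
    return {
        "label_mode": "transmissible",
        "t2": t2_hat,
        "b": b_hat,
        "m": m_hat,
        "parameter_labels": {
            "t2": "total transmissibility",
            "m": "spousal correlation in the transmissible component",
        },
        "caveat": (
            "t2 aggregates genetic, cultural and material transmission; "
            "the kin-correlation profile cannot apportion it"
        ),
    }
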
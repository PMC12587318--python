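"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: multi-generation
surname-structured pedigrees carrying a vertically transmitted trait
component, probate-style wealth records, questionnaire records with
stratum-dependent classification rates, and genetic-correlation sets with
latent-factor structure.

The transmission model
----------------------
An individual's phenotype is ``P = T + E`` where ``T`` is the component
transmitted from parents to offspring and ``E`` is independent noise.
``T`` itself splits into a genetic part ``G`` and a non-genetic part ``C``
(``T = G + C``); the split is pure bookkeeping — it never touches the
observable phenotype, which is exactly the identifiability problem the
rest of the package is built to expose.

With phenotypic variance normalised to 1, ``Var(T) = t2`` (the
*transmissibility*).  Spouses are matched so that their ``T`` values
correlate at ``m`` (assortment on the latent component, not the
phenotype, by default).  A child receives the midparent value plus an
innovation whose variance keeps ``Var(T)`` stationary::

    T_child = (T_father + T_mother) / 2 + eps,   Var(eps) = Var(T) (1 - m) / 2

Under this recursion the expected phenotypic correlation of a relative
pair at genealogical distance ``n`` is ``t2 * b**n`` with persistence rate
``b = (1 + m) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ExtinctionError, NumericalError, ParameterError

__all__ = [
    "TransmissionParams",
    "Pedigree",
    "GeneticCorrelationSet",
    "simulate_pedigree",
    "simulate_wealth",
    "simulate_questionnaire",
    "simulate_rg_set",
    "DEFAULT_STRATA_SPEC",
]

GENERATION_YEARS = 30
BASE_YEAR = 1700

#: Per-stratum classification base rates used as generator defaults:
#: (age_low, age_high_inclusive_or_None, rate) partitioning age at first sex.
DEFAULT_STRATA_SPEC = ((0, 9, 0.25), (10, 12, 0.098), (13, None, 0.022))


@dataclass(frozen=True)
class TransmissionParams:
    """Parameters of the vertical-transmission model.

    Parameters
    ----------
    t2 : float
        Fraction of trait variance attributable to the transmitted
        component, in [0, 1].
    m : float
        Spousal correlation of the transmitted component, in [0, 1).
    h2_share : float
        Fraction of the transmitted component's variance that is genetic
        (``c2_share = 1 - h2_share`` is the non-genetic share), in [0, 1].
    """

    t2: float = 0.6
    m: float = 0.6
    h2_share: float = 0.5

    def __post_init__(self):
        if not (0.0 <= self.t2 <= 1.0):
            raise ParameterError(f"t2 must be in [0, 1], got {self.t2}")
        if not (0.0 <= self.m < 1.0):
            raise ParameterError(f"m must be in [0, 1), got {self.m}")
        if not (0.0 <= self.h2_share <= 1.0):
            raise ParameterError(f"h2_share must be in [0, 1], got {self.h2_share}")

    @property
    def b(self) -> float:
        """Intergenerational persistence rate, (1 + m) / 2."""
        return (1.0 + self.m) / 2.0

    @property
    def c2_share(self) -> float:
        return 1.0 - self.h2_share


@dataclass
class Pedigree:
    """A surname-structured pedigree with latent transmitted components.

    ``individuals`` is a DataFrame with one row per individual and columns
    ``id, father_id, mother_id, sex, birth_year, surname, generation,
    T, G, C, E`` plus one observed-phenotype column per measure and,
    after :func:`simulate_wealth`, ``wealth`` (log scale) and ``probated``.
    Founders carry ``father_id = mother_id = None``.
    """

    individuals: pd.DataFrame
    generations: int
    params: TransmissionParams
    seed: int | None = None
    measures: tuple[str, ...] = ("status",)
    t2_schedule: tuple[float, ...] | None = None

    def __len__(self) -> int:
        return len(self.individuals)

    def validate(self) -> None:
        """Check structural invariants; raise ``AssertionError`` on violation."""
        df = self.individuals
        idx = pd.Index(df["id"])
        assert idx.is_unique, "duplicate individual ids"
        nonfounder = df["father_id"].notna()
        assert (df.loc[nonfounder, "father_id"].isin(idx)).all()
        assert (df.loc[nonfounder, "mother_id"].isin(idx)).all()
        by_id = df.set_index("id")
        fathers = df.loc[nonfounder, "father_id"]
        mothers = df.loc[nonfounder, "mother_id"]
        assert (by_id.loc[fathers, "sex"] == "M").all()
        assert (by_id.loc[mothers, "sex"] == "F").all()
        child_years = df.loc[nonfounder, "birth_year"].to_numpy()
        assert (child_years > by_id.loc[fathers, "birth_year"].to_numpy()).all()
        assert (child_years > by_id.loc[mothers, "birth_year"].to_numpy()).all()
        # sons carry the father's surname (and, as a clustering key, so do
        # daughters)
        assert (
            df.loc[nonfounder, "surname"].to_numpy()
            == by_id.loc[fathers, "surname"].to_numpy()
        ).all()
        np.testing.assert_allclose(
            df["T"].to_numpy(), (df["G"] + df["C"]).to_numpy(), atol=1e-10
        )


def _matching_noise_variance(m: float, var_t: float) -> float:
    """Large-sample starting value for the score-noise variance.

    Mates are paired by the rank of ``T + eta``.  For large unstructured
    samples the paired scores coincide, so the spousal correlation of
    ``T`` converges to ``corr(T, T + eta)**2 = var_t / (var_t +
    Var(eta))``; solving at target ``m`` gives ``var_t * (1 - m) / m``.
    In finite, family-structured pools this slightly under-delivers and
    the small shortfall compounds through the variance recursion, so the
    noise scale is refined numerically per matching (see
    :func:`_match_mates`).
    """
    if m <= 0.0:
        return math.inf
    return var_t * (1.0 - m) / m


def _match_mates(
    t_m: np.ndarray,
    t_f: np.ndarray,
    m: float,
    var_t: float,
    rng: np.random.Generator,
    kin_m: list[frozenset] | None = None,
    kin_f: list[frozenset] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return index arrays pairing males with females at spousal correlation m.

    If counts differ, a random subset of the larger sex is matched; the
    remainder stays unmarried.  When recent-ancestor sets (``kin_m`` /
    ``kin_f``) are supplied, close-kin unions (overlapping sets) are
    broken up by swapping rank-adjacent brides; without this exclusion,
    sorted matching preferentially marries relatives (their latent values
    are rank-adjacent), and the resulting consanguinity inflates distant
    kin correlations above the closed form, which assumes unrelated mates.
    """
    n = min(len(t_m), len(t_f))
    sel_m = rng.permutation(len(t_m))[:n]
    sel_f = rng.permutation(len(t_f))[:n]
    if m <= 0.0 or var_t <= 0.0:
        order_m, order_f = sel_m, sel_f
    else:
        # the noise scale is solved numerically against the realised
        # spousal correlation of this very pool (bisection on the sd
        # multiplier with the unit noise held fixed, so the procedure is
        # deterministic given the stream)
        eta_m, eta_f = rng.standard_normal(n), rng.standard_normal(n)
        sd0 = math.sqrt(_matching_noise_variance(m, var_t))
        tm, tf = t_m[sel_m], t_f[sel_f]

        def achieved(scale: float) -> float:
            om = np.argsort(tm + scale * eta_m, kind="stable")
            of = np.argsort(tf + scale * eta_f, kind="stable")
            c = np.corrcoef(tm[om], tf[of])[0, 1]
            return float(c)

        lo_s, hi_s = 0.0, 4.0 * sd0
        if achieved(lo_s) <= m:
            scale = lo_s  # target at or above the maximum attainable
        else:
            while achieved(hi_s) > m:
                hi_s *= 2.0
            for _ in range(25):
                mid = 0.5 * (lo_s + hi_s)
                if achieved(mid) > m:
                    lo_s = mid
                else:
                    hi_s = mid
            scale = 0.5 * (lo_s + hi_s)
        order_m = sel_m[np.argsort(tm + scale * eta_m, kind="stable")]
        order_f = sel_f[np.argsort(tf + scale * eta_f, kind="stable")]
    if kin_m is None or kin_f is None:
        return order_m, order_f

    def related(i: int, j: int) -> bool:
        return bool(kin_m[order_m[i]] & kin_f[order_f[j]])

    order_f = order_f.copy()
    lookahead = 16
    for k in range(n):
        if not related(k, k):
            continue
        for j in range(k + 1, min(k + 1 + lookahead, n)):
            if not related(k, j) and not related(j, k):
                order_f[k], order_f[j] = order_f[j], order_f[k]
                break
        # unresolved within the lookahead window: the (rare) close-kin
        # union stands rather than distorting the score pairing globally
    return order_m, order_f


def _offspring_counts(
    n_couples: int,
    offspring_dist: tuple[str, float] | dict,
    max_children: int,
    cap_total: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if isinstance(offspring_dist, dict):
        kind, mean = offspring_dist.get("kind", "poisson"), offspring_dist["mean"]
    else:
        kind, mean = offspring_dist
    if kind != "poisson":
        raise ConfigurationError(f"unsupported offspring distribution: {kind!r}")
    if mean < 0:
        raise ConfigurationError("offspring mean must be non-negative")
    counts = np.minimum(rng.poisson(mean, n_couples), max_children)
    # truncate to keep the population within bounds: drop random children
    excess = int(counts.sum()) - cap_total
    while excess > 0:
        donors = np.flatnonzero(counts > 0)
        take = donors[rng.permutation(len(donors))[:excess]]
        counts[take] -= 1
        excess = int(counts.sum()) - cap_total
    return counts


def simulate_pedigree(
    params: TransmissionParams | None = None,
    n_founder_couples: int = 5000,
    n_generations: int = 5,
    offspring_dist: tuple[str, float] = ("poisson", 2.2),
    seed: int | None = None,
    *,
    measures: Sequence[str] = ("status",),
    t2_schedule: Sequence[float] | None = None,
    assort_on: str = "latent",
    max_children: int = 6,
    max_generation_size: int | None = None,
    forbid_kin_depth: int = 2,
) -> Pedigree:
    """Simulate a multi-generation pedigree under the transmission model.

    Parameters
    ----------
    params : TransmissionParams
        Transmissibility t2, spousal correlation m, genetic share.
    n_founder_couples : int
        Number of unrelated couples in generation 0 (>= 2).
    n_generations : int
        Total number of generations including founders (>= 2).
    offspring_dist : (str, float)
        Family-size distribution; ``("poisson", mean)``, truncated at
        ``max_children`` per couple and capped at ``max_generation_size``
        per generation.
    t2_schedule : sequence of float, optional
        Per-generation transmissibility.  When given, each generation's
        latent components are rescaled (deterministically, in expectation)
        so that ``Var(T)`` in generation g equals ``t2_schedule[g]``; this
        is the generator used for cohort-trend studies.
    assort_on : {"latent", "phenotype"}
        Whether mates are matched on the transmitted component T (the
        "social genotype" style assumption) or on the phenotype P.
    forbid_kin_depth : int
        Unions between individuals sharing an ancestor within this many
        generational links are avoided (default 2: no sibling, avuncular
        or first-cousin marriages).  0 disables the exclusion; the
        closed-form kin correlations assume mates are otherwise
        unrelated.

    Returns
    -------
    Pedigree
    """
    params = params or TransmissionParams()
    if n_founder_couples < 2:
        raise ParameterError("n_founder_couples must be >= 2")
    if n_generations < 2:
        raise ParameterError("n_generations must be >= 2")
    if assort_on not in ("latent", "phenotype"):
        raise ParameterError("assort_on must be 'latent' or 'phenotype'")
    if t2_schedule is not None:
        t2_schedule = tuple(float(x) for x in t2_schedule)
        if len(t2_schedule) != n_generations:
            raise ParameterError("t2_schedule must have one entry per generation")
        if any(not (0.0 <= x <= 1.0) for x in t2_schedule):
            raise ParameterError("t2_schedule entries must be in [0, 1]")

    measures = tuple(measures)
    # Independent streams: structure (sexes, family sizes, matching) / T
    # innovations / G-C split / residual E.  Because the split has its own
    # stream, changing h2_share at a fixed seed changes *only* the latent
    # G/C bookkeeping, never the observed phenotypes.
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    rng_struct, rng_t, rng_split, rng_e = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    m, h = params.m, params.h2_share

    def t2_of(g: int) -> float:
        return t2_schedule[g] if t2_schedule is not None else params.t2

    def draw_measures(n: int, t2: float) -> dict[str, np.ndarray]:
        sd_e = math.sqrt(max(1.0 - t2, 0.0))
        return {f"E_{ms}": rng_e.normal(0.0, sd_e, n) for ms in measures}

    rows: list[pd.DataFrame] = []
    next_id = 0

    def make_ids(n: int) -> np.ndarray:
        nonlocal next_id
        ids = np.array([f"I{next_id + i:07d}" for i in range(n)])
        next_id += n
        return ids

    # ---- founders (generation 0): assorted couples --------------------
    v0 = t2_of(0)
    nf = n_founder_couples
    t_m = rng_t.normal(0.0, math.sqrt(v0) if v0 > 0 else 0.0, nf)
    t_f = rng_t.normal(0.0, math.sqrt(v0) if v0 > 0 else 0.0, nf)
    # G = h*T + delta keeps Var(G) = h*Var(T) and Cov(G, C) = 0
    sd0 = math.sqrt(h * (1.0 - h) * v0)
    g_m = h * t_m + rng_split.normal(0.0, sd0, nf)
    g_f = h * t_f + rng_split.normal(0.0, sd0, nf)
    order_m, order_f = _match_mates(t_m, t_f, m, v0, rng_struct)
    # store couples in random order: matched order is score-sorted, and a
    # value-informative storage order would bias pair orientation downstream
    perm = rng_struct.permutation(len(order_m))
    order_m, order_f = order_m[perm], order_f[perm]
    t_m, g_m = t_m[order_m], g_m[order_m]
    t_f, g_f = t_f[order_f], g_f[order_f]

    ids_m, ids_f = make_ids(nf), make_ids(nf)
    surnames = np.array([f"S{i:05d}" for i in range(nf)])
    years = BASE_YEAR + rng_struct.integers(-5, 6, 2 * nf)

    def frame(ids, sex, father, mother, surname, year, gen, T, G, t2):
        e = draw_measures(len(ids), t2)
        d = {
            "id": ids,
            "father_id": father,
            "mother_id": mother,
            "sex": sex,
            "birth_year": year,
            "surname": surname,
            "generation": gen,
            "T": T,
            "G": G,
            "C": T - G,
        }
        for ms in measures:
            d[ms] = T + e[f"E_{ms}"]
        d["E"] = e[f"E_{measures[0]}"]
        return pd.DataFrame(d)

    none = np.full(nf, None, dtype=object)
    rows.append(
        frame(ids_m, "M", none, none, surnames, years[:nf], 0, t_m, g_m, v0)
    )
    rows.append(
        frame(ids_f, "F", none, none, surnames, years[nf:], 0, t_f, g_f, v0)
    )

    cur = {
        "id_m": ids_m, "id_f": ids_f, "t_m": t_m, "t_f": t_f,
        "g_m": g_m, "g_f": g_f, "surname": surnames,
    }
    cap = max_generation_size or 4 * n_founder_couples
    parent_map: dict[str, tuple[str, str]] = {}

    def recent_ancestors(f_id: str, m_id: str) -> frozenset:
        s = {f_id, m_id}
        frontier = [f_id, m_id]
        for _ in range(max(forbid_kin_depth - 1, 0)):
            nxt: list[str] = []
            for xid in frontier:
                nxt.extend(parent_map.get(xid, ()))
            s.update(nxt)
            frontier = nxt
        return frozenset(s)

    # ---- subsequent generations ---------------------------------------
    for g in range(1, n_generations):
        v_parent, v_child = t2_of(g - 1), t2_of(g)
        n_couples = len(cur["id_m"])
        counts = _offspring_counts(
            n_couples, offspring_dist, max_children, cap, rng_struct
        )
        n_child = int(counts.sum())
        if n_child < 2:
            raise ExtinctionError(g)
        cidx = np.repeat(np.arange(n_couples), counts)

        mid_t = (cur["t_m"][cidx] + cur["t_f"][cidx]) / 2.0
        mid_g = (cur["g_m"][cidx] + cur["g_f"][cidx]) / 2.0
        var_eps = v_parent * (1.0 - m) / 2.0
        eps_t = rng_t.normal(0.0, math.sqrt(var_eps), n_child)
        # innovation split: eps_G = h*eps_T + delta with Var(delta) =
        # h(1-h) v/2, which together with matching-on-T holds the split
        # (Var(G), Var(C), Cov(G,C)) stationary at (h v, (1-h) v, 0)
        delta = rng_split.normal(
            0.0, math.sqrt(h * (1.0 - h) * v_parent / 2.0), n_child
        )
        t_child = mid_t + eps_t
        g_child = mid_g + h * eps_t + delta
        if t2_schedule is not None and v_parent > 0 and v_child != v_parent:
            scale = math.sqrt(v_child / v_parent)
            t_child, g_child = t_child * scale, g_child * scale

        sex = np.where(rng_struct.random(n_child) < 0.5, "M", "F")
        year = (
            BASE_YEAR
            + GENERATION_YEARS * g
            + rng_struct.integers(-5, 6, n_child)
        )
        ids = make_ids(n_child)
        f_ids, m_ids = cur["id_m"][cidx], cur["id_f"][cidx]
        fr = frame(
            ids, sex, f_ids, m_ids,
            cur["surname"][cidx], year, g, t_child, g_child, v_child,
        )
        rows.append(fr)

        if g == n_generations - 1:
            break
        kin_sets = None
        if forbid_kin_depth > 0:
            kin_sets = [
                recent_ancestors(f, mo) for f, mo in zip(f_ids, m_ids)
            ]
        for cid, f, mo in zip(ids, f_ids, m_ids):
            parent_map[cid] = (f, mo)
        is_m = sex == "M"
        if assort_on == "phenotype":
            score_m = fr.loc[is_m, measures[0]].to_numpy()
            score_f = fr.loc[~is_m, measures[0]].to_numpy()
            var_score = 1.0
        else:
            score_m, score_f = t_child[is_m], t_child[~is_m]
            var_score = v_child
        if min(is_m.sum(), (~is_m).sum()) < 1:
            raise ExtinctionError(g)
        kin_m = kin_f = None
        if kin_sets is not None:
            arr = np.array(kin_sets, dtype=object)
            kin_m, kin_f = list(arr[is_m]), list(arr[~is_m])
        om, of = _match_mates(
            score_m, score_f, m, var_score, rng_struct, kin_m, kin_f
        )
        perm = rng_struct.permutation(len(om))
        om, of = om[perm], of[perm]
        cur = {
            "id_m": ids[is_m][om], "id_f": ids[~is_m][of],
            "t_m": t_child[is_m][om], "t_f": t_child[~is_m][of],
            "g_m": g_child[is_m][om], "g_f": g_child[~is_m][of],
            "surname": cur["surname"][cidx][is_m][om],
        }

    df = pd.concat(rows, ignore_index=True)
    ped = Pedigree(
        individuals=df,
        generations=n_generations,
        params=params,
        seed=seed,
        measures=measures,
        t2_schedule=t2_schedule,
    )
    return ped


# ----------------------------------------------------------------------
# probate-style wealth
# ----------------------------------------------------------------------

def _normalise_minimums(
    probate_minimums, decades: np.ndarray
) -> dict[int, float]:
    """Expand a (period, minimum) table into a per-decade minimum map."""
    if probate_minimums is None:
        return {int(d): 150.0 for d in decades}
    table: dict[int, float] = {}
    for start, end, minimum in probate_minimums:
        for d in decades:
            if start <= d <= end:
                table[int(d)] = float(minimum)
    missing = sorted(set(int(d) for d in decades) - set(table))
    if missing:
        raise ConfigurationError(
            f"probate_minimums does not cover birth decades: {missing}"
        )
    return table


def simulate_wealth(
    pedigree: Pedigree,
    status_loading: float = 0.9,
    probate_minimums: Sequence[tuple[int, int, float]] | None = None,
    seed: int | None = None,
    *,
    noise_sd: float = 0.2,
    drift_sd: float = 0.15,
    base_log_wealth: float = 6.0,
) -> Pedigree:
    """Populate ``wealth`` (log scale) and ``probated`` on a pedigree.

    Log wealth at death is ``base + drift(decade) + status_loading * T +
    noise``; the decade-level drift makes decade mean-centring
    consequential downstream.  Individuals whose (exponentiated) latent
    wealth falls below their period's probate minimum are recorded as not
    probated, with wealth missing.
    """
    if not np.isfinite(status_loading):
        raise ParameterError("status_loading must be finite")
    df = pedigree.individuals
    rng = np.random.default_rng(
        np.random.SeedSequence(seed if seed is not None else 0).spawn(1)[0]
    )
    decades = (df["birth_year"] // 10 * 10).astype(int)
    minimums = _normalise_minimums(probate_minimums, np.unique(decades))
    drift = {d: rng.normal(0.0, drift_sd) for d in sorted(minimums)}
    latent = (
        base_log_wealth
        + decades.map(drift).to_numpy()
        + status_loading * df["T"].to_numpy()
        + rng.normal(0.0, noise_sd, len(df))
    )
    minimum = decades.map(minimums).to_numpy()
    probated = np.exp(latent) >= minimum
    df = df.copy()
    df["wealth"] = np.where(probated, latent, np.nan)
    df["probated"] = probated
    df["period_minimum"] = minimum
    return Pedigree(
        individuals=df,
        generations=pedigree.generations,
        params=pedigree.params,
        seed=pedigree.seed,
        measures=pedigree.measures,
        t2_schedule=pedigree.t2_schedule,
    )


# ----------------------------------------------------------------------
# questionnaire records
# ----------------------------------------------------------------------

def _validate_strata(strata_spec) -> list[tuple[float, float, float]]:
    spec = []
    for low, high, rate in strata_spec:
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"rate {rate} outside [0, 1]")
        spec.append((low, math.inf if high is None else high, rate))
    spec.sort(key=lambda s: s[0])
    for (lo1, hi1, _), (lo2, _, _) in zip(spec, spec[1:]):
        if lo2 <= hi1:
            raise ConfigurationError("strata overlap on the age axis")
        if lo2 != hi1 + 1:
            raise ConfigurationError("strata leave a gap on the age axis")
    return spec


def simulate_questionnaire(
    n: int,
    strata_spec: Sequence[tuple[int, int | None, float]] = DEFAULT_STRATA_SPEC,
    seed: int | None = None,
    *,
    missing_rate: float = 0.02,
) -> pd.DataFrame:
    """Simulate questionnaire records with stratum-dependent flag rates.

    Each record carries sex, lifetime partner counts (total and same-sex)
    and age at first sex.  Ages are drawn from a rounded normal centred at
    18 (clipped to [8, 40]) so that early-age strata are naturally rare;
    within each age stratum the probability that a record satisfies the
    default both-sexes classification rule equals the stratum's base rate.
    A fraction ``missing_rate`` of ages is masked after the partner counts
    are drawn (missingness carries the stratum's rate structure).
    """
    spec = _validate_strata(strata_spec)
    rng = np.random.default_rng(
        np.random.SeedSequence(seed if seed is not None else 0).spawn(1)[0]
    )
    age = np.clip(np.round(rng.normal(18.0, 3.0, n)), 8, 40).astype(int)
    rate = np.empty(n)
    rate.fill(np.nan)
    for lo, hi, r in spec:
        rate[(age >= lo) & (age <= hi)] = r
    if np.isnan(rate).any():
        raise ConfigurationError("strata do not cover the simulated age range")

    flagged = rng.random(n) < rate
    same = np.zeros(n, dtype=int)
    opposite = rng.poisson(3.0, n)
    same[flagged] = 1 + rng.poisson(1.0, int(flagged.sum()))
    opposite[flagged] = 1 + rng.poisson(2.0, int(flagged.sum()))
    # a small exclusively-same-sex group: not flagged by the default rule
    exclusive = (~flagged) & (rng.random(n) < 0.01)
    same[exclusive] = 1 + rng.poisson(1.0, int(exclusive.sum()))
    opposite[exclusive] = 0

    age_out = age.astype(float)
    age_out[rng.random(n) < missing_rate] = np.nan
    return pd.DataFrame(
        {
            "id": [f"Q{i:06d}" for i in range(n)],
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "n_partners_total": same + opposite,
            "n_same_sex_partners": same,
            "age_first_sex": age_out,
        }
    )


# ----------------------------------------------------------------------
# genetic-correlation sets
# ----------------------------------------------------------------------

@dataclass
class GeneticCorrelationSet:
    """A labelled correlation matrix with sampling covariance.

    ``V`` is the sampling covariance of the distinct off-diagonal entries
    of ``R`` in row-major upper-triangle order; ``None`` when unknown.
    """

    labels: tuple[str, ...]
    R: np.ndarray
    V: np.ndarray | None = None
    n_effective: float | None = None

    def __post_init__(self):
        self.labels = tuple(self.labels)
        self.R = np.asarray(self.R, dtype=float)
        p = len(self.labels)
        if self.R.shape != (p, p):
            raise ParameterError("R shape does not match labels")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ParameterError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise ParameterError("R must have unit diagonal")
        if np.linalg.eigvalsh(self.R).min() < -1e-8:
            raise ParameterError("R is not positive semi-definite")
        if self.V is not None:
            self.V = np.asarray(self.V, dtype=float)
            q = p * (p - 1) // 2
            if self.V.shape != (q, q):
                raise ParameterError(
                    f"V must be {q}x{q} for {p} labels, got {self.V.shape}"
                )
            if np.linalg.eigvalsh((self.V + self.V.T) / 2).min() < -1e-8:
                raise ParameterError("V is not positive semi-definite")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown label {label!r}; known: {list(self.labels)}"
            ) from None

    def r(self, a: str, b: str) -> float:
        return float(self.R[self.index(a), self.index(b)])

    def flat_index(self, a: str, b: str) -> int:
        """Position of entry (a, b) in the condensed upper-triangle order."""
        i, j = sorted((self.index(a), self.index(b)))
        if i == j:
            raise ParameterError("diagonal entries have no sampling variance slot")
        p = len(self.labels)
        return i * p - i * (i + 1) // 2 + (j - i - 1)


def nearest_correlation(R: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix
    by clipping negative eigenvalues at zero and renormalising the
    diagonal to one."""
    R = (np.asarray(R, dtype=float) + np.asarray(R).T) / 2.0
    w, q = np.linalg.eigh(R)
    if not np.all(np.isfinite(w)):
        raise NumericalError(f"eigendecomposition failed: eigenvalues {w}")
    if w.min() >= -tol:
        out = R.copy()
    else:
        out = (q * np.clip(w, 0.0, None)) @ q.T
    d = np.sqrt(np.clip(np.diag(out), tol, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2.0
    if not np.all(np.isfinite(out)):
        raise NumericalError("PSD projection produced non-finite entries")
    return out


def simulate_rg_set(
    labels: Sequence[str],
    latent_loadings: Sequence[float],
    noise_sd: float = 0.005,
    n_effective: float = 5000,
    seed: int | None = None,
) -> GeneticCorrelationSet:
    """Build a correlation set with single-latent-factor structure.

    Off-diagonal entries are ``loading_i * loading_j`` plus independent
    Gaussian noise of sd ``noise_sd``, projected to the nearest valid
    correlation matrix.  The sampling covariance attached is diagonal with
    the large-sample Pearson variance ``(1 - r^2)^2 / n_effective`` per
    entry.
    """
    labels = tuple(labels)
    lam = np.asarray(latent_loadings, dtype=float)
    if len(lam) != len(labels):
        raise ParameterError("one loading per label required")
    if np.any(np.abs(lam) >= 1.0):
        raise ParameterError("loadings must be in (-1, 1)")
    if n_effective < 10:
        raise ParameterError("n_effective must be >= 10")
    rng = np.random.default_rng(
        np.random.SeedSequence(seed if seed is not None else 0).spawn(1)[0]
    )
    p = len(labels)
    R = np.outer(lam, lam)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, (p, p))
        noise = (noise + noise.T) / math.sqrt(2.0)
        R = R + noise
    np.fill_diagonal(R, 1.0)
    R = nearest_correlation(R)
    iu = np.triu_indices(p, k=1)
    V = np.diag((1.0 - R[iu] ** 2) ** 2 / n_effective)
    return GeneticCorrelationSet(labels=labels, R=R, V=V, n_effective=n_effective)


#: Conditions of the canonical many-mediators screen: focal pair loadings,
#: strongly factor-loaded mediators (mirroring mediator selection by high
#: genetic correlation), and an effective sample size at which the raw
#: focal correlation is clearly significant while residual partials are
#: within sampling noise.
SCREEN_A_LOADING = 0.6
SCREEN_B_LOADING = 0.4
SCREEN_MEDIATOR_LOADINGS = (0.85, 0.95)
SCREEN_N_EFFECTIVE = 500


def simulate_screen_set(
    seed: int | None = None,
    n_mediators: int = 18,
    noise_sd: float = 0.01,
    n_effective: float = SCREEN_N_EFFECTIVE,
) -> GeneticCorrelationSet:
    """The canonical correlation set for the many-mediators screen.

    Labels are ``A`` (the focal behaviour classification), ``B`` (number
    of children) and ``X01..Xnn`` mediators; all load on one latent
    factor, the mediators strongly (loadings spread over
    ``SCREEN_MEDIATOR_LOADINGS``).  Under this structure the raw A-B
    correlation is significant at ``n_effective`` while the partial
    correlation given any one mediator is close to zero — no single
    mediation story receives unique support.
    """
    labels = ["A", "B"] + [f"X{i + 1:02d}" for i in range(n_mediators)]
    lo, hi = SCREEN_MEDIATOR_LOADINGS
    loadings = np.concatenate(
        [[SCREEN_A_LOADING, SCREEN_B_LOADING], np.linspace(lo, hi, n_mediators)]
    )
    return simulate_rg_set(
        labels, loadings, noise_sd=noise_sd, n_effective=n_effective, seed=seed
    )
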
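"""Incidence-based richness estimation, rarefaction and effort projection.

Core quantities for evaluating survey completeness from replicated
incidence data:

* Chao2 nonparametric richness estimator (classic and bias-corrected),
  with the finite-sample factor A = (m-1)/m, variant-matched variance
  and a log-transform 95% confidence interval,
* the incidence-based coverage estimator's (ICE) heterogeneity CV, which
  selects between the two Chao2 variants (classic when CV > 0.5),
* sample-based rarefaction (analytic hypergeometric expectation with the
  unconditional variance, plus a seeded resampling mode),
* projected additional sampling effort to detect a fraction g of the
  estimated pool, and the g = 1 full-census projection,
* the simplified Morisita (Morisita-Horn) similarity between two
  assemblages' incidence-frequency vectors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .incidence import IncidenceCounts, IncidenceMatrix, tally_counts

logger = logging.getLogger("aquasurvey")

Variant = Literal["classic", "bias_corrected"]

#: heterogeneity threshold above which the classic Chao2 variant is reported
CV_THRESHOLD = 0.5
#: species with incidence frequency <= this bound count as "infrequent" in ICE
ICE_FREQUENCY_BOUND = 10
Z95 = 1.959963984540054


@dataclass(frozen=True)
class RichnessEstimate:
    counts: IncidenceCounts
    variant: Variant
    A: float
    Sest: float
    variance: float
    ci_low: float
    ci_high: float
    cv_ice: float | None = None

    @property
    def Sobs(self) -> int:
        return self.counts.Sobs

    @property
    def Q0(self) -> float:
        """Estimated number of undetected species."""
        return self.Sest - self.counts.Sobs


@dataclass(frozen=True)
class RarefactionCurve:
    t: np.ndarray
    expected_S: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "expected_S": self.expected_S,
                "sd": self.sd,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


@dataclass(frozen=True)
class EffortProjection:
    g: float
    m_additional: int
    m_additional_exact: float


@dataclass(frozen=True)
class SimilarityResult:
    shared_species: int
    index: float


# ---------------------------------------------------------------------------
# Chao2
# ---------------------------------------------------------------------------

def _chao2_point(m: int, Sobs: int, Q1: int, Q2: int, variant: Variant) -> float:
    A = (m - 1) / m
    if variant == "classic":
        if Q2 == 0:
            raise ZeroDivisionError("classic Chao2 undefined with Q2 = 0")
        return Sobs + A * Q1 * Q1 / (2 * Q2)
    return Sobs + A * Q1 * (Q1 - 1) / (2 * (Q2 + 1))


def _chao2_variance(m: int, Q1: int, Q2: int, variant: Variant, Sest: float,
                    Sobs: int) -> float:
    """Variant-matched Chao2 variance (Chao 1987 / EstimateS appendix)."""
    A = (m - 1) / m
    if Q1 == 0:
        return 0.0
    if variant == "classic" and Q2 > 0:
        r = Q1 / Q2
        return Q2 * (A / 2 * r**2 + A**2 * r**3 + A**2 / 4 * r**4)
    if Q2 > 0:  # bias-corrected
        return (
            A * Q1 * (Q1 - 1) / (2 * (Q2 + 1))
            + A**2 * Q1 * (2 * Q1 - 1) ** 2 / (4 * (Q2 + 1) ** 2)
            + A**2 * Q1**2 * Q2 * (Q1 - 1) ** 2 / (4 * (Q2 + 1) ** 4)
        )
    # Q2 == 0: no-duplicates form
    return (
        A * Q1 * (Q1 - 1) / 2
        + A**2 * Q1 * (2 * Q1 - 1) ** 2 / 4
        - A**2 * Q1**4 / (4 * Sest)
    )


def chao2_ci(Sobs: int, Sest: float, variance: float) -> tuple[float, float]:
    """95% log-transform confidence interval around a Chao2 estimate."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    T = Sest - Sobs
    if T <= 0:
        return float(Sobs), float(Sobs)
    K = math.exp(Z95 * math.sqrt(math.log(1.0 + variance / T**2)))
    return Sobs + T / K, Sobs + T * K


def chao2(
    counts: IncidenceCounts,
    variant: Variant = "bias_corrected",
    cv_ice: float | None = None,
) -> RichnessEstimate:
    """Chao2 estimated total richness with variance and 95% CI.

    The classic form is Sobs + A*Q1^2/(2*Q2) and the bias-corrected form
    Sobs + A*Q1*(Q1-1)/(2*(Q2+1)), both with A = (m-1)/m.  Requesting the
    classic variant with Q2 = 0 falls back to bias-corrected with a logged
    warning; with Q1 = Q2 = 0 the estimate equals Sobs exactly.
    """
    if counts.m < 2:
        raise ValueError("Chao2 requires at least 2 sample units")
    if variant not in ("classic", "bias_corrected"):
        raise ValueError(f"unknown variant {variant!r}")
    m, Sobs, Q1, Q2 = counts.m, counts.Sobs, counts.Q1, counts.Q2
    if variant == "classic" and Q2 == 0:
        logger.warning(
            "classic Chao2 requested with Q2 = 0; falling back to bias-corrected"
        )
        variant = "bias_corrected"
    Sest = _chao2_point(m, Sobs, Q1, Q2, variant)
    var = _chao2_variance(m, Q1, Q2, variant, Sest, Sobs)
    low, high = chao2_ci(Sobs, Sest, var)
    return RichnessEstimate(
        counts=counts,
        variant=variant,
        A=(m - 1) / m,
        Sest=Sest,
        variance=var,
        ci_low=low,
        ci_high=high,
        cv_ice=cv_ice,
    )


# ---------------------------------------------------------------------------
# ICE heterogeneity CV and variant selection
# ---------------------------------------------------------------------------

def ice_cv(counts: IncidenceCounts, m_infreq: int | None = None) -> float:
    """Heterogeneity CV of the incidence distribution (ICE, Lee & Chao 1994).

    Computed over the "infrequent" species (frequency <= 10):
    gamma^2 = max( S_inf/C_ice * m_inf/(m_inf-1) * sum k(k-1) Q_k / n_inf^2 - 1, 0 )
    with sample incidence coverage C_ice = 1 - Q1/n_inf.  ``m_infreq`` is
    the number of units holding at least one infrequent species; when not
    supplied (counts-only input) it defaults to m.  Returns sqrt(gamma^2);
    +inf when coverage is zero (every infrequent species is a unique).
    """
    if counts.m < 2:
        raise ValueError("ICE CV requires at least 2 sample units")
    freqs = np.asarray(counts.per_species)
    infreq = freqs[(freqs >= 1) & (freqs <= ICE_FREQUENCY_BOUND)]
    if infreq.size == 0:
        return 0.0
    n_inf = int(infreq.sum())
    q1 = int((infreq == 1).sum())
    c_ice = 1.0 - q1 / n_inf
    if c_ice <= 0:
        return float("inf")
    m_inf = counts.m if m_infreq is None else m_infreq
    if m_inf <= 1:
        return 0.0
    s_inf = infreq.size
    sum_kk1 = float((infreq * (infreq - 1)).sum())
    gamma2 = max(
        s_inf / c_ice * (m_inf / (m_inf - 1)) * sum_kk1 / n_inf**2 - 1.0, 0.0
    )
    return math.sqrt(gamma2)


def select_variant(cv: float) -> Variant:
    """Classic Chao2 when the ICE CV exceeds 0.5, else bias-corrected."""
    return "classic" if cv > CV_THRESHOLD else "bias_corrected"


# ---------------------------------------------------------------------------
# Sample-based rarefaction
# ---------------------------------------------------------------------------

def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy(
    data: IncidenceMatrix | Iterable[int],
    t: Iterable[int] | None = None,
    m: int | None = None,
    sest: float | None = None,
) -> RarefactionCurve:
    """Analytic sample-based rarefaction (species-effort) curve.

    Expected richness in a random subset of t of the m units is the
    hypergeometric form  E[S_t] = sum_j (1 - C(m-s_j, t)/C(m, t))  over
    species with incidence frequency s_j.  The reported variance is the
    unconditional estimator
    sigma^2(t) = sum_j (1-a_jt)^2 - (sum_j (1-a_jt))^2 / Sest,
    with a_jt = C(m-s_j,t)/C(m,t) and Sest the classic Chao2 estimate by
    default, so the interval does not collapse to zero at t = m.
    """
    if isinstance(data, IncidenceMatrix):
        counts = tally_counts(data)
        freqs = np.asarray(counts.per_species)
        m = counts.m
    else:
        freqs = np.asarray(list(data), dtype=int)
        if m is None:
            raise ValueError("m is required when passing raw frequencies")
        counts = IncidenceCounts.from_frequencies(freqs, m)
    freqs = freqs[freqs > 0]
    ts = np.arange(1, m + 1) if t is None else np.asarray(sorted(set(int(v) for v in t)))
    if ts.min() < 1 or ts.max() > m:
        raise ValueError(f"t must lie in [1, {m}]")
    if sest is None:
        try:
            sest = _chao2_point(m, counts.Sobs, counts.Q1, counts.Q2, "classic")
        except ZeroDivisionError:
            sest = _chao2_point(m, counts.Sobs, counts.Q1, counts.Q2, "bias_corrected")
    # alpha[j, i] = C(m - s_j, t_i) / C(m, t_i); zero when t_i > m - s_j
    sj = freqs[:, None].astype(float)
    ti = ts[None, :].astype(float)
    with np.errstate(invalid="ignore"):
        log_alpha = _log_comb(m - sj, ti) - _log_comb(m, ti)
    alpha = np.where(ti <= m - sj, np.exp(log_alpha), 0.0)
    expected = (1.0 - alpha).sum(axis=0)
    detected = 1.0 - alpha
    var = (detected**2).sum(axis=0) - detected.sum(axis=0) ** 2 / max(sest, 1e-12)
    var = np.clip(var, 0.0, None)
    sd = np.sqrt(var)
    return RarefactionCurve(
        t=ts,
        expected_S=expected,
        sd=sd,
        ci_low=expected - Z95 * sd,
        ci_high=expected + Z95 * sd,
    )


def rarefy_resample(
    matrix: IncidenceMatrix,
    t: Iterable[int] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> RarefactionCurve:
    """Monte-Carlo rarefaction: mean/sd of richness over random unit subsets."""
    rng = np.random.default_rng(seed)
    pres = matrix.presence.to_numpy()
    m = pres.shape[0]
    ts = np.arange(1, m + 1) if t is None else np.asarray(sorted(set(int(v) for v in t)))
    if ts.min() < 1 or ts.max() > m:
        raise ValueError(f"t must lie in [1, {m}]")
    means = np.empty(ts.size)
    sds = np.empty(ts.size)
    for i, tv in enumerate(ts):
        rich = np.empty(n_reps)
        for r in range(n_reps):
            idx = rng.choice(m, size=tv, replace=False)
            rich[r] = pres[idx].any(axis=0).sum()
        means[i] = rich.mean()
        sds[i] = rich.std(ddof=1) if n_reps > 1 else 0.0
    return RarefactionCurve(
        t=ts, expected_S=means, sd=sds,
        ci_low=means - Z95 * sds, ci_high=means + Z95 * sds,
    )


def lowest_accumulation_percent(
    matrix: IncidenceMatrix,
    n_first: int,
    sest: float,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Diagnostic: lowest percent of Sest accumulated in the first samples.

    Minimum, over random reorderings of the units, of the percentage of the
    estimated pool detected in the first ``n_first`` units — a proxy for the
    worst-case initial accumulation rate.  Interpretation of the published
    "lowest possible" column is loose; this is a declared reading of it.
    """
    rng = np.random.default_rng(seed)
    pres = matrix.presence.to_numpy()
    m = pres.shape[0]
    if not 1 <= n_first <= m:
        raise ValueError("n_first out of range")
    best = math.inf
    for _ in range(n_perm):
        idx = rng.permutation(m)[:n_first]
        best = min(best, pres[idx].any(axis=0).sum())
    return 100.0 * best / sest


# ---------------------------------------------------------------------------
# Effort projection (Chao et al. 2009, incidence form)
# ---------------------------------------------------------------------------

def _classic_inputs(counts: IncidenceCounts) -> tuple[float, float]:
    """Classic-variant Sest and Q0 used by the effort formulas."""
    Sest = _chao2_point(counts.m, counts.Sobs, counts.Q1, counts.Q2, "classic")
    return Sest, Sest - counts.Sobs


def effort_to_fraction(counts: IncidenceCounts, g: float) -> EffortProjection:
    """Additional sample units needed to detect fraction g of the pool.

    Uses the classic-variant Chao2 estimate and the incidence-data formula
    m_g = ((m-1) * Q1 / (2 * Q2)) * ln( Q0 / ((1-g) * Sest) ),
    rounded half-to-even to the nearest integer.  Returns 0 whenever the
    observed richness already covers the target fraction.  The (m-1)
    prefactor is the same finite-sample factor the classic estimator
    carries.
    """
    if not 0 < g < 1:
        raise ValueError("g must lie strictly between 0 and 1")
    m, Q1, Q2, Sobs = counts.m, counts.Q1, counts.Q2, counts.Sobs
    if Q1 == 0:
        return EffortProjection(g=g, m_additional=0, m_additional_exact=0.0)
    if Q2 == 0:
        raise ValueError(
            "effort projection needs duplicates (Q2 > 0); with Q2 = 0 the "
            "classic extrapolation is undefined — use a bias-corrected "
            "extrapolation externally (documented limitation)"
        )
    Sest, Q0 = _classic_inputs(counts)
    if Sobs / Sest >= g:
        return EffortProjection(g=g, m_additional=0, m_additional_exact=0.0)
    exact = ((m - 1) * Q1 / (2 * Q2)) * math.log(Q0 / ((1 - g) * Sest))
    exact = max(exact, 0.0)
    return EffortProjection(g=g, m_additional=_round_half_even(exact),
                            m_additional_exact=exact)


def effort_to_census(counts: IncidenceCounts) -> EffortProjection:
    """Additional sample units projected for a full census (g = 1).

    The g -> 1 limit of the fractional formula diverges; the census form
    replaces the target gap (1-g)*Sest with the point at which the expected
    number of uniques falls below one:
    m_100 = ((m-1) * Q1 / (2 * Q2)) * ln( m * Q1^2 / (2 * Q2^2) ).
    Published S100% columns from other tools match this only to order of
    magnitude; treat the value as indicative.
    """
    m, Q1, Q2 = counts.m, counts.Q1, counts.Q2
    if Q1 == 0:
        return EffortProjection(g=1.0, m_additional=0, m_additional_exact=0.0)
    if Q2 == 0:
        raise ValueError(
            "census projection needs duplicates (Q2 > 0); use a bias-corrected "
            "extrapolation externally (documented limitation)"
        )
    arg = m * Q1 * Q1 / (2.0 * Q2 * Q2)
    exact = max(((m - 1) * Q1 / (2 * Q2)) * math.log(arg), 0.0) if arg > 1 else 0.0
    return EffortProjection(g=1.0, m_additional=_round_half_even(exact),
                            m_additional_exact=exact)


def _round_half_even(x: float) -> int:
    return int(round(x))


def percent_detected(estimate: RichnessEstimate) -> int:
    """Percent of the estimated species pool detected, 100*Sobs/Sest."""
    if estimate.Sest <= 0:
        raise ValueError("Sest must be positive")
    return int(round(100.0 * estimate.Sobs / estimate.Sest))


# ---------------------------------------------------------------------------
# Simplified Morisita (Morisita-Horn) similarity
# ---------------------------------------------------------------------------

def simplified_morisita(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
) -> SimilarityResult:
    """Simplified Morisita similarity of two incidence-frequency vectors.

    C_H = 2 * sum(x_i y_i) / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) * X * Y)
    over the union species list, with X = sum x_i and Y = sum y_i; 0 for
    disjoint assemblages, 1 for proportionally identical ones.
    """
    xs = pd.Series(dict(x), dtype=float)
    ys = pd.Series(dict(y), dtype=float)
    union = xs.index.union(ys.index)
    xv = xs.reindex(union, fill_value=0.0).to_numpy()
    yv = ys.reindex(union, fill_value=0.0).to_numpy()
    X, Y = xv.sum(), yv.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("both assemblages must have positive total incidence")
    num = 2.0 * float(xv @ yv)
    den = ((xv @ xv) / X**2 + (yv @ yv) / Y**2) * X * Y
    shared = int(((xv > 0) & (yv > 0)).sum())
    return SimilarityResult(shared_species=shared, index=float(num / den))


# ---------------------------------------------------------------------------
# Survey report (performance-measure table row)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveyReport:
    site: str
    year: str
    m: int
    incidences: int
    uniques: int
    duplicates: int
    sobs: int
    variant: Variant
    sest: float
    ci_low: float
    ci_high: float
    cv_ice: float
    s95_additional: float
    s100_additional: float
    percent_detected: int

    def as_dict(self) -> dict:
        return asdict(self)


def survey_report(
    matrix: IncidenceMatrix | IncidenceCounts,
    site: str = "",
    year: str = "",
    variant: Variant | Literal["auto"] = "auto",
    g: float = 0.95,
) -> SurveyReport:
    """Assemble the per-survey performance-measure record.

    The Chao2 variant is chosen by the ICE-CV rule unless overridden;
    effort projections always use classic-variant inputs.  When Q2 = 0 and
    Q1 > 0 the effort columns are reported as NaN.
    """
    if isinstance(matrix, IncidenceMatrix):
        counts = tally_counts(matrix)
        freqs = matrix.per_species_frequency()
        infreq_cols = freqs[(freqs >= 1) & (freqs <= ICE_FREQUENCY_BOUND)].index
        m_infreq = int(matrix.presence[infreq_cols].any(axis=1).sum())
        cv = ice_cv(counts, m_infreq=max(m_infreq, 2))
    else:
        counts = matrix
        cv = ice_cv(counts)
    chosen: Variant = select_variant(cv) if variant == "auto" else variant
    est = chao2(counts, chosen, cv_ice=cv)
    if counts.Q1 == 0:
        s95 = s100 = 0.0
    elif counts.Q2 == 0:
        s95 = s100 = float("nan")
    else:
        s95 = float(effort_to_fraction(counts, g).m_additional)
        s100 = float(effort_to_census(counts).m_additional)
    return SurveyReport(
        site=site,
        year=year,
        m=counts.m,
        incidences=counts.incidences,
        uniques=counts.Q1,
        duplicates=counts.Q2,
        sobs=counts.Sobs,
        variant=chosen,
        sest=est.Sest,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        cv_ice=cv,
        s95_additional=s95,
        s100_additional=s100,
        percent_detected=percent_detected(est),
    )
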
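"""Repair-misrepair-fixation (RMF) mapping to linear-quadratic survival.

The RMF model converts an initial DSB yield into the linear-quadratic
(LQ) survival coefficients.  With Sigma the total DSBs per cell per Gy,
fR the fraction of those DSBs that are potentially rejoinable (composed
of fewer than j lesions), theta the fraction undergoing lethal
first-order misrepair/fixation, kappa the fraction undergoing pairwise
interaction and zF the frequency-mean specific energy:

    alpha = [1 - fR (1 - theta)] Sigma + kappa zF fR Sigma**2   [1/Gy]
    beta  = (kappa / 2) (fR Sigma)**2                           [1/Gy^2]

Survival follows S = exp(-(alpha D + beta D**2)); iso-effect doses solve
the LQ quadratic, giving RBE (reference dose over test dose at equal S)
and OER (hypoxic dose over aerobic dose at equal S).  Module also houses
the low-dose fractionation RBE formula built on a linear alpha-LET
trend, the ordinary least-squares alpha-LET fit, and the low-energy
yield-bias estimator used to bound the clustering model's systematic
overestimate against track-structure results.

Default theta/kappa pairs: (5.79e-3, 5.59e-5) at 21% and 2% O2,
(4.25e-3, 4.5e-5) at 0.1% O2; the lesion-count cutoff j is 13 at 21%/2%
and 10 at 0.1% O2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from grenzray.damage import DamageSpectrum
from grenzray.microdosimetry import TargetGeometry

__all__ = [
    "RMFParameters",
    "LQParameters",
    "FractionationParams",
    "rmf_defaults",
    "dsb_per_cell",
    "rejoinable_fraction",
    "lq_alpha",
    "lq_beta",
    "lq_from_spectrum",
    "survival",
    "dose_for_survival",
    "rbe_dsb",
    "rbe_survival",
    "oer_dsb",
    "oer_survival",
    "rbe_fraction_dose",
    "alpha_let_fit",
    "fit_lq",
    "estimate_mcds_bias",
    "calibrate_genome_size",
    "DEFAULT_GENOME_GBP",
    "REFERENCE_ALPHA_INTERCEPT",
    "REFERENCE_LET",
]

#: LET of the Co-60 reference radiation, keV/um.
REFERENCE_LET = 0.24
#: Aerobic alpha-LET regression evaluated at the reference LET (the
#: intercept the genome-size calibration anchors to).
REFERENCE_ALPHA_INTERCEPT = 0.0466 * REFERENCE_LET + 0.2412


@dataclass(frozen=True)
class RMFParameters:
    """RMF parameters for one oxygen condition."""

    theta: float = 5.79e-3
    kappa: float = 5.59e-5
    j: int = 13
    geometry: TargetGeometry = field(default_factory=TargetGeometry)
    genome_gbp: float = 0.0  # 0 -> use the calibrated default, see below
    o2_percent: float = 21.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0 or not 0.0 <= self.kappa <= 1.0:
            raise ValueError("theta and kappa are fractions in [0, 1]")
        if self.j < 2:
            raise ValueError("j must be >= 2")
        if self.genome_gbp < 0:
            raise ValueError("genome size must be positive")

    @property
    def genome(self) -> float:
        return self.genome_gbp if self.genome_gbp > 0 else DEFAULT_GENOME_GBP


def rmf_defaults(o2_percent: float) -> RMFParameters:
    """Published theta/kappa/j set for the given oxygen concentration."""
    if o2_percent <= 0.5:
        return RMFParameters(theta=4.25e-3, kappa=4.5e-5, j=10, o2_percent=o2_percent)
    return RMFParameters(o2_percent=o2_percent)


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic coefficients for one quality and oxygen condition."""

    alpha: float
    beta: float
    quality_label: str = ""
    o2_percent: float = 21.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


@dataclass(frozen=True)
class FractionationParams:
    """Reference LQ coefficients plus the alpha-LET slope lambda."""

    alpha_ref: float
    beta_ref: float
    lam: float

    def __post_init__(self) -> None:
        if self.alpha_ref <= 0 or self.beta_ref < 0:
            raise ValueError("alpha_ref must be > 0 and beta_ref >= 0")


# ---------------------------------------------------------------------------
# DSB bookkeeping
# ---------------------------------------------------------------------------


def dsb_per_cell(spectrum: DamageSpectrum, params: RMFParameters) -> float:
    """Sigma: total DSBs per cell per Gy (per-Gbp yield times genome size)."""
    if spectrum.total_dsb < 0:
        raise ValueError("total_dsb must be non-negative")
    return spectrum.total_dsb * params.genome


def rejoinable_fraction(multiplicity: Mapping[int, float], j: int) -> float:
    """Fraction of DSBs made of fewer than j lesions (mass at i = 2..j-1)."""
    if any(i < 2 for i in multiplicity):
        raise ValueError("multiplicity support must start at i = 2")
    total = sum(multiplicity.values())
    if total <= 0:
        raise ValueError("multiplicity histogram has zero total DSB mass")
    below = sum(v for i, v in multiplicity.items() if i < j)
    return below / total


def lq_alpha(sigma: float, f_r: float, params: RMFParameters, z_f: float) -> float:
    """Linear LQ coefficient alpha (1/Gy) from the RMF mapping."""
    if sigma < 0 or not 0.0 <= f_r <= 1.0:
        raise ValueError("require sigma >= 0 and fR in [0, 1]")
    return (1.0 - f_r * (1.0 - params.theta)) * sigma + (
        params.kappa * z_f * f_r * sigma**2
    )


def lq_beta(sigma: float, f_r: float, params: RMFParameters) -> float:
    """Quadratic LQ coefficient beta (1/Gy^2) from the RMF mapping."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return 0.5 * params.kappa * (f_r * sigma) ** 2


def lq_from_spectrum(
    spectrum: DamageSpectrum,
    multiplicity: Mapping[int, float],
    params: RMFParameters,
    let_kev_um: float,
    quality_label: str = "",
) -> LQParameters:
    """Full RMF chain for one quality: Sigma, fR and zF to (alpha, beta)."""
    from grenzray.microdosimetry import frequency_mean_specific_energy

    sigma = dsb_per_cell(spectrum, params)
    f_r = rejoinable_fraction(multiplicity, params.j)
    z_f = frequency_mean_specific_energy(let_kev_um, params.geometry)
    return LQParameters(
        alpha=lq_alpha(sigma, f_r, params, z_f),
        beta=lq_beta(sigma, f_r, params),
        quality_label=quality_label,
        o2_percent=params.o2_percent,
    )


# ---------------------------------------------------------------------------
# survival, RBE, OER
# ---------------------------------------------------------------------------


def survival(lq: LQParameters, dose_gy: float) -> float:
    """LQ survival fraction S = exp(-(alpha D + beta D^2))."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    return math.exp(-(lq.alpha * dose_gy + lq.beta * dose_gy**2))


def dose_for_survival(lq: LQParameters, s: float) -> float:
    """The unique non-negative dose with alpha D + beta D^2 = -ln S."""
    if not 0.0 < s < 1.0:
        raise ValueError("survival level must be in (0, 1)")
    if lq.alpha == 0.0 and lq.beta == 0.0:
        raise ValueError("alpha = beta = 0: no dose reaches S < 1")
    effect = -math.log(s)
    if lq.beta == 0.0:
        return effect / lq.alpha
    return (-lq.alpha + math.sqrt(lq.alpha**2 + 4.0 * lq.beta * effect)) / (
        2.0 * lq.beta
    )


def rbe_dsb(sigma_test: float, sigma_ref: float) -> float:
    """RBE for DSB induction: test-to-reference yield ratio (any unit)."""
    if sigma_ref <= 0:
        raise ValueError("reference DSB yield must be positive")
    return sigma_test / sigma_ref


def rbe_survival(lq_test: LQParameters, lq_ref: LQParameters, s: float = 0.1) -> float:
    """RBE for cell survival: reference dose over test dose at equal S."""
    return dose_for_survival(lq_ref, s) / dose_for_survival(lq_test, s)


def oer_dsb(sigma_aerobic: float, sigma_hypoxic: float) -> float:
    """OER for DSB induction: aerobic over hypoxic yield at equal dose."""
    if sigma_hypoxic <= 0:
        raise ValueError("hypoxic DSB yield must be positive")
    return sigma_aerobic / sigma_hypoxic


def oer_survival(
    lq_aerobic: LQParameters, lq_hypoxic: LQParameters, s: float = 0.1
) -> float:
    """OER for cell survival: hypoxic dose over aerobic dose at equal S."""
    return dose_for_survival(lq_hypoxic, s) / dose_for_survival(lq_aerobic, s)


def rbe_fraction_dose(fp: FractionationParams, let_kev_um: float, dose_gy: float) -> float:
    """RBE of a fraction of dose D for a quality whose alpha follows the
    linear alpha-LET trend, sharing beta with the reference.

    Continuous at D -> 0 with limit (alpha_ref + lambda LET)/alpha_ref.
    """
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    alpha_test = fp.alpha_ref + fp.lam * let_kev_um
    if dose_gy == 0.0 or fp.beta_ref == 0.0:
        return alpha_test / fp.alpha_ref
    disc = fp.alpha_ref**2 + 4.0 * fp.beta_ref * dose_gy * (
        alpha_test + fp.beta_ref * dose_gy
    )
    return (math.sqrt(disc) - fp.alpha_ref) / (2.0 * fp.beta_ref * dose_gy)


# ---------------------------------------------------------------------------
# regression and bias utilities
# ---------------------------------------------------------------------------


def alpha_let_fit(points: Sequence[tuple[float, float]]):
    """OLS line alpha = lambda * LET + alpha_R with R^2.

    Returns (slope, intercept, r_squared).  Degenerate LET values raise.
    """
    if len(points) < 2:
        raise ValueError("need at least two (LET, alpha) points")
    let = np.array([p[0] for p in points], float)
    alpha = np.array([p[1] for p in points], float)
    if np.allclose(let, let[0]):
        raise ValueError("degenerate fit: all LET values identical")
    fit = stats.linregress(let, alpha)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def fit_lq(
    doses: Sequence[float], survivals: Sequence[float], quality_label: str = ""
) -> LQParameters:
    """Non-negative least-squares LQ fit of -ln S = alpha D + beta D^2."""
    d = np.asarray(doses, float)
    s = np.asarray(survivals, float)
    if d.shape != s.shape or d.size < 2:
        raise ValueError("need matching dose/survival arrays of length >= 2")
    if np.any(s <= 0):
        raise ValueError("survival fractions must be positive")
    mask = d > 0
    if mask.sum() < 2:
        raise ValueError("need at least two positive-dose points")
    design = np.column_stack([d[mask], d[mask] ** 2])
    coef, _ = optimize.nnls(design, -np.log(s[mask]))
    return LQParameters(alpha=float(coef[0]), beta=float(coef[1]), quality_label=quality_label)


def estimate_mcds_bias(
    y_cluster_low_e: float,
    y_track_low_e: float,
    low_energy_fraction: float,
    y_reference: float,
) -> tuple[float, float]:
    """Bound on the clustering model's low-energy DSB overestimate.

    The absolute bias is the low-energy yield excess over track-structure
    results times the fraction of dose delivered by those electrons; the
    relative bias expresses it as a percentage of the full-spectrum yield.
    """
    if min(y_cluster_low_e, y_track_low_e, low_energy_fraction) < 0:
        raise ValueError("inputs must be non-negative")
    if y_reference <= 0:
        raise ValueError("reference yield must be positive")
    absolute = (y_cluster_low_e - y_track_low_e) * low_energy_fraction
    return absolute, 100.0 * absolute / y_reference


# ---------------------------------------------------------------------------
# genome-size calibration
# ---------------------------------------------------------------------------


def calibrate_genome_size(
    dsb_per_gbp_ref: float = 8.1,
    alpha_target: float = REFERENCE_ALPHA_INTERCEPT,
    params: RMFParameters | None = None,
    let_ref: float = REFERENCE_LET,
    f_r: float = 1.0,
) -> float:
    """Genome size G (Gbp) such that the reference-quality alpha from the
    RMF mapping equals ``alpha_target`` (closed-form quadratic root).

    Anchors the model's absolute scale, which the per-Gbp yield tables do
    not fix on their own.
    """
    from grenzray.microdosimetry import frequency_mean_specific_energy

    p = params or RMFParameters()
    if dsb_per_gbp_ref <= 0 or alpha_target <= 0:
        raise ValueError("reference yield and target alpha must be positive")
    z_f = frequency_mean_specific_energy(let_ref, p.geometry)
    a = p.kappa * z_f * f_r
    b = 1.0 - f_r * (1.0 - p.theta)
    if a == 0.0:
        sigma = alpha_target / b
    else:
        sigma = (-b + math.sqrt(b**2 + 4.0 * a * alpha_target)) / (2.0 * a)
    return sigma / dsb_per_gbp_ref


#: Genome size (Gbp per cell) calibrated so the Co-60 aerobic alpha lands
#: on the aerobic alpha-LET regression intercept; ~5.4 Gbp, a plausible
#: rodent-cell DNA content.
DEFAULT_GENOME_GBP = calibrate_genome_size()
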
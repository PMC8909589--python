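"""Synthetic inputs with known ground truth.

Every upstream input the pipeline needs can be generated here without
external data: secondary-electron fluence spectra (standing in for a
transport-code output), DSB lesion-multiplicity histograms (standing in
for the unpublished internals of the clustering simulation) and noisy
linear-quadratic survival curves.  All generators are deterministic
given their seed and record their recipe in the returned metadata.

The generators aim to exercise the downstream numerics with realistic
shapes, not to reproduce transport physics: the bremsstrahlung-like
spectrum is a Kramers-form (Emax - E)/E density truncated below 0.5 keV,
and the stopping-power curve is a log-log interpolation of the packaged
monoenergetic-electron LET table.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from grenzray import tables
from grenzray.microdosimetry import FluenceSpectrum
from grenzray.rmf import LQParameters, survival

__all__ = [
    "SpectrumRecipe",
    "MultiplicityRecipe",
    "electron_let_curve",
    "make_fluence_spectrum",
    "make_multiplicity_histogram",
    "make_survival_dataset",
]

_SPECTRUM_KINDS = ("monoenergetic", "exponential_tail", "bremsstrahlung_like")
_E_CUTOFF_KEV = 0.5  # low-energy truncation of the bremsstrahlung-like shape


@dataclass(frozen=True)
class SpectrumRecipe:
    """Recipe for a synthetic secondary-electron fluence spectrum."""

    kind: str
    peak_or_mean_energy_kev: float
    n_points: int = 200
    seed: int = 0
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {_SPECTRUM_KINDS}")
        if self.peak_or_mean_energy_kev <= 0:
            raise ValueError("energy must be positive")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass(frozen=True)
class MultiplicityRecipe:
    """Recipe for a DSB lesion-multiplicity histogram with a geometric tail."""

    base_mass_at_2: float = 0.35
    tail_decay: float = 0.55
    max_i: int = 25
    total_sigma: float = 43.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_mass_at_2 <= 1.0:
            raise ValueError("base_mass_at_2 is a fraction in [0, 1]")
        if not 0.0 <= self.tail_decay < 1.0:
            raise ValueError("tail_decay must be in [0, 1)")
        if self.max_i < 2:
            raise ValueError("max_i must be >= 2")
        if self.total_sigma <= 0:
            raise ValueError("total_sigma must be positive")


def electron_let_curve(energy_kev: np.ndarray) -> np.ndarray:
    """Synthetic unrestricted stopping power (keV/um) for electrons in water.

    Log-log interpolation of the packaged monoenergetic-electron LET
    values, extended beyond the tabulated range with the boundary
    power-law slopes.  Adequate for spectrum weighting, not transport.
    """
    frame = tables.load_electron_table()
    sub = frame[frame.source == "mcds"].sort_values("energy_ev")
    e_ref = np.log(sub.energy_ev.to_numpy(float) / 1000.0)
    let_ref = np.log(sub.let_kev_um.to_numpy(float))
    loge = np.log(np.asarray(energy_kev, float))
    out = np.interp(loge, e_ref, let_ref)
    # power-law extension at both edges
    lo = loge < e_ref[0]
    hi = loge > e_ref[-1]
    slope_lo = (let_ref[1] - let_ref[0]) / (e_ref[1] - e_ref[0])
    slope_hi = (let_ref[-1] - let_ref[-2]) / (e_ref[-1] - e_ref[-2])
    out[lo] = let_ref[0] + slope_lo * (loge[lo] - e_ref[0])
    out[hi] = let_ref[-1] + slope_hi * (loge[hi] - e_ref[-1])
    return np.exp(out)


def make_fluence_spectrum(recipe: SpectrumRecipe) -> tuple[FluenceSpectrum, dict]:
    """Generate a fluence spectrum; returns (spectrum, metadata)."""
    rng = np.random.default_rng(recipe.seed)
    e0 = recipe.peak_or_mean_energy_kev

    if recipe.kind == "monoenergetic":
        energy = np.array([e0])
        fluence = np.array([1.0])
    elif recipe.kind == "exponential_tail":
        # density exp(-(E - Emin)/tau) with tau set so the weighted mean is e0
        e_min = min(0.05, e0 / 10.0)
        tau = e0 - e_min
        energy = np.linspace(e_min, e_min + 12.0 * tau, max(recipe.n_points, 2))
        fluence = np.exp(-(energy - e_min) / tau)
    else:  # bremsstrahlung_like: Kramers (Emax - E)/E, zero at and above Emax
        e_max = e0
        if e_max <= _E_CUTOFF_KEV:
            raise ValueError("bremsstrahlung peak energy must exceed the 0.5 keV cutoff")
        energy = np.linspace(_E_CUTOFF_KEV, e_max, max(recipe.n_points, 2))
        fluence = np.clip((e_max - energy) / energy, 0.0, None)

    if recipe.jitter_sd > 0 and energy.size > 1:
        fluence = fluence * rng.lognormal(0.0, recipe.jitter_sd, energy.size)
        fluence[-1] = 0.0 if recipe.kind == "bremsstrahlung_like" else fluence[-1]
    if not np.any(fluence > 0):
        fluence = fluence + 1e-12

    spectrum = FluenceSpectrum(
        energy_kev=energy, fluence=fluence, let_kev_um=electron_let_curve(energy)
    )
    return spectrum, {"recipe": asdict(recipe), "generator": "make_fluence_spectrum"}


def make_multiplicity_histogram(recipe: MultiplicityRecipe) -> tuple[dict[int, float], dict]:
    """Histogram over lesion multiplicity i with mass base_mass_at_2 at
    i = 2 and the remainder decaying geometrically on [3, max_i]; sums to
    total_sigma.  Returns (histogram, metadata)."""
    hist = {2: recipe.base_mass_at_2 * recipe.total_sigma}
    rest = (1.0 - recipe.base_mass_at_2) * recipe.total_sigma
    if rest > 0 and recipe.max_i >= 3:
        i = np.arange(3, recipe.max_i + 1)
        weights = recipe.tail_decay ** (i - 3)
        weights = weights / weights.sum()
        for k, w in zip(i, weights):
            hist[int(k)] = rest * float(w)
    elif rest > 0:
        hist[2] = recipe.total_sigma  # no room for a tail: all mass at 2
    return hist, {"recipe": asdict(recipe), "generator": "make_multiplicity_histogram"}


def make_survival_dataset(
    lq: LQParameters,
    doses,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 1,
) -> tuple[list[tuple[float, float]], dict]:
    """Noisy LQ survival observations S_obs = S(D) * lognormal(0, noise_sd).

    Multiplicative lognormal noise keeps observations positive with
    roughly proportional error, as in clonogenic-assay data.
    """
    if noise_sd < 0 or replicates < 1:
        raise ValueError("noise_sd must be >= 0 and replicates >= 1")
    doses = [float(d) for d in doses]
    if any(d < 0 for d in doses):
        raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(seed)
    data = []
    for _ in range(replicates):
        for d in doses:
            s = survival(lq, d)
            if noise_sd > 0:
                s *= float(rng.lognormal(0.0, noise_sd))
            data.append((d, s))
    meta = {
        "generator": "make_survival_dataset",
        "alpha": lq.alpha,
        "beta": lq.beta,
        "noise_sd": noise_sd,
        "seed": seed,
        "replicates": replicates,
    }
    return data, meta
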
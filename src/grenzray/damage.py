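"""Stochastic simulator of clustered DNA damage per unit dose.

The model emulates the two-step damage-clustering procedure used by fast
Monte Carlo damage codes: elementary damages (strand breaks and base
damages) produced by 1 Gy in 1 Gbp of DNA are placed uniformly at random
on a short double-stranded segment, then grouped into lesion clusters —
two elementary damages separated by at least ``n_min_bp`` base pairs
belong to different clusters.  Each cluster is classified into one of
seven standard damage categories:

===== =============================================================
BD    base damage(s) only, no strand break
SSB   a single strand break
SSB+  two or more breaks, all on the same strand
2SSB  breaks on both strands, but none opposite within the pairing
      window (they do not constitute a DSB)
DSB   exactly one opposite-strand break pair within the window
DSB+  one DSB plus additional break(s) in the same cluster
DSB++ two or more DSBs in the same cluster
===== =============================================================

Yields are reported per Gy per Gbp; one Monte Carlo sample represents the
damage deposited by 1 Gy in 1 Gbp of genomic DNA.  Oxygen concentration
scales the elementary lesion induction rate through a saturating
(Hill-type) modifier normalised to 1 at 21% O2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "CLASSES",
    "SSB_CLASSES",
    "DSB_CLASSES",
    "FORWARD",
    "REVERSE",
    "STRAND_BREAK",
    "BASE_DAMAGE",
    "Lesion",
    "DamageCluster",
    "DamageSpectrum",
    "OxygenModel",
    "SimulationConfig",
    "CalibrationResult",
    "analyze_lesions",
    "classify_cluster",
    "cluster_lesions",
    "simulate_damage_spectrum",
    "oxygen_modifier",
    "calibrate_lesion_rates",
]

CLASSES = ("BD", "SSB", "SSB+", "2SSB", "DSB", "DSB+", "DSB++")
SSB_CLASSES = ("SSB", "SSB+", "2SSB")
DSB_CLASSES = ("DSB", "DSB+", "DSB++")

FORWARD = "forward"
REVERSE = "reverse"
STRAND_BREAK = "strand_break"
BASE_DAMAGE = "base_damage"


@dataclass(frozen=True, order=True)
class Lesion:
    """One elementary damage on the segment."""

    position: int
    strand: str = FORWARD
    kind: str = STRAND_BREAK

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"lesion position must be >= 0, got {self.position}")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.kind not in (STRAND_BREAK, BASE_DAMAGE):
            raise ValueError(f"unknown lesion kind {self.kind!r}")


@dataclass(frozen=True)
class DamageCluster:
    """A group of lesions mutually closer than the clustering threshold."""

    lesions: tuple[Lesion, ...]
    class_label: str
    multiplicity: int

    def __post_init__(self) -> None:
        if self.multiplicity != len(self.lesions) or self.multiplicity < 1:
            raise ValueError("multiplicity must equal the number of lesions (>= 1)")
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown damage class {self.class_label!r}")


@dataclass(frozen=True)
class OxygenModel:
    """Saturating oxygen-effect model for lesion induction.

    The induction scale is ``plateau_fraction`` in anoxia and rises with a
    Hill curve of half-effect concentration ``k_half`` (% O2) and shape
    exponent ``hill``; it is renormalised to exactly 1 at 21% O2.  The
    functional form is a calibrated stand-in for the oxygen-fixation
    chemistry, fitted once to the packaged yield tables (see docs).
    """

    o2_percent: float = 21.0
    plateau_fraction: float = 0.6164
    k_half: float = 0.4859
    hill: float = 0.9509

    def __post_init__(self) -> None:
        if not 0.0 <= self.o2_percent <= 100.0:
            raise ValueError("o2_percent must be in [0, 100]")
        if not 0.0 < self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must be in (0, 1]")
        if self.k_half <= 0 or self.hill <= 0:
            raise ValueError("k_half and hill must be positive")


def oxygen_modifier(model: OxygenModel) -> float:
    """Lesion-induction scale factor in (0, 1].

    Exactly ``plateau_fraction`` at 0% O2 and exactly 1 at the 21%
    reference (the Hill rise is renormalised to its 21% value; above 21%
    the factor is clipped at 1).
    """
    o2 = model.o2_percent
    if o2 == 0.0:
        return model.plateau_fraction
    k_h = model.k_half**model.hill
    rise = o2**model.hill / (o2**model.hill + k_h)
    rise_ref = 21.0**model.hill / (21.0**model.hill + k_h)
    return min(
        1.0,
        model.plateau_fraction + (1.0 - model.plateau_fraction) * rise / rise_ref,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one damage-spectrum simulation.

    lesion_rate
        Expected elementary damages per Gy per Gbp at 21% O2.
    bd_to_sb_ratio
        Base damages per strand break among elementary damages (the 3:1
        default is the standard radiolysis ratio; calibration against a
        target spectrum usually lowers it).
    segment_length_bp
        Length of the segment all per-Gbp damage is condensed onto; it
        sets the local damage density and hence cluster complexity.
    n_min_bp
        Minimum separation (bp) for two damages to be distinct clusters.
    dsb_window_bp
        Maximum opposite-strand break separation (bp) forming a DSB.
    """

    lesion_rate: float = 560.0
    bd_to_sb_ratio: float = 3.0
    segment_length_bp: int = 16_000
    n_min_bp: int = 9
    dsb_window_bp: int = 10
    oxygen: OxygenModel = field(default_factory=OxygenModel)
    seed: int = 0
    n_samples: int = 10_000

    def __post_init__(self) -> None:
        if self.lesion_rate < 0 or self.bd_to_sb_ratio < 0:
            raise ValueError("rates must be non-negative")
        if self.segment_length_bp < 1:
            raise ValueError("segment_length_bp must be >= 1")
        if self.n_min_bp < 1 or self.dsb_window_bp < 1:
            raise ValueError("n_min_bp and dsb_window_bp must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class DamageSpectrum:
    """Per-class damage yields (per Gy per Gbp) with Monte Carlo errors.

    ``dsb_multiplicity`` maps the lesion count i (>= 2) of DSB-class
    clusters to the expected number of such DSBs per Gy per Gbp; scaling
    by genome size converts it to per cell (where the repair model needs
    it).  ``all_zero`` flags the degenerate no-damage case in which
    percentages are reported as 0 rather than NaN.
    """

    yields: dict[str, float]
    percentages: dict[str, float]
    total_ssb: float
    total_dsb: float
    dsb_multiplicity: dict[int, float] = field(default_factory=dict)
    sem: dict[str, float] = field(default_factory=dict)
    n_samples: int = 1
    all_zero: bool = False

    def validate(self, pct_tol: float = 0.1, total_tol: float = 1e-6) -> None:
        """Check internal consistency; tolerances widened for rounded data."""
        for c in CLASSES:
            if self.yields.get(c, 0.0) < 0:
                raise ValueError(f"negative yield for class {c}")
        if self.all_zero:
            return
        pct_sum = sum(self.percentages.get(c, 0.0) for c in CLASSES)
        if abs(pct_sum - 100.0) > pct_tol:
            raise ValueError(f"percentages sum to {pct_sum}, not 100 +/- {pct_tol}")
        ssb = sum(self.yields.get(c, 0.0) for c in SSB_CLASSES)
        dsb = sum(self.yields.get(c, 0.0) for c in DSB_CLASSES)
        if abs(ssb - self.total_ssb) > max(total_tol, 0.2):
            raise ValueError("SSB-class yields do not sum to total_ssb")
        if abs(dsb - self.total_dsb) > max(total_tol, 0.2):
            raise ValueError("DSB-class yields do not sum to total_dsb")
        if any(i < 2 for i in self.dsb_multiplicity):
            raise ValueError("dsb_multiplicity support must start at i = 2")


# ---------------------------------------------------------------------------
# clustering and classification
# ---------------------------------------------------------------------------


def cluster_lesions(lesions: Sequence[Lesion], n_min_bp: int) -> list[list[Lesion]]:
    """Group position-sorted lesions: a gap >= n_min_bp starts a new cluster."""
    if n_min_bp < 1:
        raise ValueError("n_min_bp must be >= 1")
    lesions = list(lesions)
    if any(b.position < a.position for a, b in zip(lesions, lesions[1:])):
        raise ValueError("lesions must be sorted by position")
    clusters: list[list[Lesion]] = []
    for lesion in lesions:
        if clusters and lesion.position - clusters[-1][-1].position < n_min_bp:
            clusters[-1].append(lesion)
        else:
            clusters.append([lesion])
    return clusters


def _pair_breaks(
    positions: Iterable[int], strands: Iterable[int], window: int
) -> tuple[int, int]:
    """Greedy left-to-right matching of opposite-strand breaks within window.

    Each break is matched to the earliest unmatched break on the opposite
    strand no farther than ``window`` bp behind it; for this interval
    structure the greedy sweep attains the maximum matching.  Returns
    (number of DSB pairs, number of unpaired breaks).
    """
    unmatched: tuple[list[int], list[int]] = ([], [])
    pairs = 0
    expired = 0
    for pos, strand in zip(positions, strands):
        opp = unmatched[1 - strand]
        while opp and pos - opp[0] > window:
            opp.pop(0)
            expired += 1
        if opp:
            opp.pop(0)
            pairs += 1
        else:
            unmatched[strand].append(pos)
    return pairs, expired + len(unmatched[0]) + len(unmatched[1])


def classify_cluster(cluster: Sequence[Lesion], dsb_window_bp: int = 10) -> str:
    """Assign one of the seven damage classes to a position-sorted cluster."""
    if not cluster:
        raise ValueError("cannot classify an empty cluster")
    if any(b.position < a.position for a, b in zip(cluster, cluster[1:])):
        raise ValueError("cluster lesions must be sorted by position")
    breaks = [l for l in cluster if l.kind == STRAND_BREAK]
    if not breaks:
        return "BD"
    if len(breaks) == 1:
        return "SSB"
    strands = {l.strand for l in breaks}
    if len(strands) == 1:
        return "SSB+"
    pairs, leftover = _pair_breaks(
        [l.position for l in breaks],
        [0 if l.strand == FORWARD else 1 for l in breaks],
        dsb_window_bp,
    )
    if pairs == 0:
        return "2SSB"
    if pairs >= 2:
        return "DSB++"
    return "DSB+" if leftover > 0 else "DSB"


def analyze_lesions(
    lesions: Sequence[Lesion], n_min_bp: int = 9, dsb_window_bp: int = 10
) -> list[DamageCluster]:
    """Cluster position-sorted lesions and classify every cluster."""
    return [
        DamageCluster(
            lesions=tuple(group),
            class_label=classify_cluster(group, dsb_window_bp),
            multiplicity=len(group),
        )
        for group in cluster_lesions(lesions, n_min_bp)
    ]


# ---------------------------------------------------------------------------
# Monte Carlo simulation
# ---------------------------------------------------------------------------

_CLASS_INDEX = {c: k for k, c in enumerate(CLASSES)}


def _zero_spectrum(n_samples: int) -> DamageSpectrum:
    zeros = {c: 0.0 for c in CLASSES}
    return DamageSpectrum(
        yields=dict(zeros),
        percentages=dict(zeros),
        total_ssb=0.0,
        total_dsb=0.0,
        dsb_multiplicity={},
        sem=dict(zeros),
        n_samples=n_samples,
        all_zero=True,
    )


def simulate_damage_spectrum(config: SimulationConfig) -> DamageSpectrum:
    """Monte Carlo estimate of the damage spectrum for one radiation quality.

    Each of ``config.n_samples`` samples draws a Poisson number of
    elementary damages (mean ``lesion_rate`` scaled by the oxygen
    modifier), places them uniformly on the segment, clusters them, and
    classifies every cluster.  Yields are sample means (per Gy per Gbp)
    and SEMs are s/sqrt(n).  Bit-reproducible for a fixed seed.
    """
    n = config.n_samples
    rng = np.random.default_rng(config.seed)
    mean = config.lesion_rate * oxygen_modifier(config.oxygen)
    if mean == 0.0:
        return _zero_spectrum(n)

    counts = rng.poisson(mean, n)
    total = int(counts.sum())
    if total == 0:
        return _zero_spectrum(n)

    pos = rng.integers(0, config.segment_length_bp, total)
    strand = rng.integers(0, 2, total).astype(np.int8)
    p_break = 1.0 / (1.0 + config.bd_to_sb_ratio)
    is_break = rng.random(total) < p_break
    sample = np.repeat(np.arange(n, dtype=np.int64), counts)

    order = np.lexsort((pos, sample))
    pos, strand, is_break, sample = (
        pos[order],
        strand[order],
        is_break[order],
        sample[order],
    )

    new_cluster = np.empty(total, dtype=bool)
    new_cluster[0] = True
    new_cluster[1:] = (sample[1:] != sample[:-1]) | (
        (pos[1:] - pos[:-1]) >= config.n_min_bp
    )
    cid = np.cumsum(new_cluster) - 1
    n_clusters = int(cid[-1]) + 1
    starts = np.flatnonzero(new_cluster)
    ends = np.append(starts[1:], total)

    size = np.bincount(cid, minlength=n_clusters)
    nb = np.bincount(cid[is_break], minlength=n_clusters)
    nb_fwd = np.bincount(cid[is_break & (strand == 0)], minlength=n_clusters)
    nb_rev = nb - nb_fwd

    labels = np.zeros(n_clusters, dtype=np.int8)  # default BD
    labels[nb == 1] = _CLASS_INDEX["SSB"]
    labels[(nb >= 2) & ((nb_fwd == 0) | (nb_rev == 0))] = _CLASS_INDEX["SSB+"]
    mixed = (nb_fwd > 0) & (nb_rev > 0)
    window = config.dsb_window_bp
    for ci in np.flatnonzero(mixed):
        sl = slice(starts[ci], ends[ci])
        mask = is_break[sl]
        pairs, leftover = _pair_breaks(
            pos[sl][mask].tolist(), strand[sl][mask].tolist(), window
        )
        if pairs == 0:
            labels[ci] = _CLASS_INDEX["2SSB"]
        elif pairs >= 2:
            labels[ci] = _CLASS_INDEX["DSB++"]
        else:
            labels[ci] = _CLASS_INDEX["DSB+"] if leftover else _CLASS_INDEX["DSB"]

    cluster_sample = sample[starts]
    per_sample = np.bincount(
        cluster_sample * len(CLASSES) + labels, minlength=n * len(CLASSES)
    ).reshape(n, len(CLASSES))

    means = per_sample.mean(axis=0)
    sems = (
        per_sample.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(CLASSES))
    )
    yields = {c: float(means[k]) for k, c in enumerate(CLASSES)}
    sem = {c: float(sems[k]) for k, c in enumerate(CLASSES)}
    total_yield = float(means.sum())
    percentages = {c: 100.0 * yields[c] / total_yield for c in CLASSES}

    ssb_cols = [_CLASS_INDEX[c] for c in SSB_CLASSES]
    dsb_cols = [_CLASS_INDEX[c] for c in DSB_CLASSES]
    sem["total_ssb"] = (
        float(per_sample[:, ssb_cols].sum(axis=1).std(ddof=1) / np.sqrt(n))
        if n > 1
        else 0.0
    )
    sem["total_dsb"] = (
        float(per_sample[:, dsb_cols].sum(axis=1).std(ddof=1) / np.sqrt(n))
        if n > 1
        else 0.0
    )

    is_dsb = labels >= _CLASS_INDEX["DSB"]
    mult_counts = np.bincount(size[is_dsb]) if is_dsb.any() else np.zeros(0)
    dsb_multiplicity = {
        int(i): float(mult_counts[i]) / n
        for i in range(len(mult_counts))
        if mult_counts[i] > 0
    }

    spectrum = DamageSpectrum(
        yields=yields,
        percentages=percentages,
        total_ssb=sum(yields[c] for c in SSB_CLASSES),
        total_dsb=sum(yields[c] for c in DSB_CLASSES),
        dsb_multiplicity=dsb_multiplicity,
        sem=sem,
        n_samples=n,
    )
    spectrum.validate(pct_tol=0.1)
    return spectrum


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_FREE_PARAMS = ("lesion_rate", "segment_length_bp", "bd_to_sb_ratio")


@dataclass(frozen=True)
class CalibrationResult:
    config: SimulationConfig
    loss: float
    n_evaluations: int


def _calibration_loss(sim: DamageSpectrum, target: DamageSpectrum) -> float:
    """Yield-share weighted squared relative error over the seven classes,
    plus extra weight on the two total yields the tables emphasise."""
    tot = sum(target.yields.get(c, 0.0) for c in CLASSES)
    loss = 0.0
    for c in CLASSES:
        t = target.yields.get(c, 0.0)
        if t <= 0:
            continue
        loss += (t / tot) * ((sim.yields[c] - t) / t) ** 2
    loss += 2.0 * ((sim.total_ssb - target.total_ssb) / target.total_ssb) ** 2
    loss += 2.0 * ((sim.total_dsb - target.total_dsb) / target.total_dsb) ** 2
    return loss


def _initial_guess(target: DamageSpectrum, window: int) -> dict[str, float]:
    """Moment-style starting point: break count from SSB/DSB totals, BD
    lesions from the BD cluster yield, segment length from the pairwise
    DSB-formation probability n_b^2 * w / (2 L)."""
    n_breaks = target.total_ssb + 2.5 * target.total_dsb
    n_bd = 1.1 * target.yields.get("BD", 3.0 * n_breaks / 4.0)
    seg = 0.5 * window * n_breaks**2 / max(target.total_dsb, 1e-6)
    return {
        "lesion_rate": n_breaks + n_bd,
        "segment_length_bp": seg,
        "bd_to_sb_ratio": n_bd / n_breaks,
    }


def calibrate_lesion_rates(
    target: DamageSpectrum,
    base_config: SimulationConfig | None = None,
    free_params: Sequence[str] = _FREE_PARAMS,
    n_samples_fit: int = 600,
    maxiter: int = 200,
) -> CalibrationResult:
    """Fit free simulation parameters so the spectrum matches ``target``.

    Nelder-Mead in log-parameter space on a common-random-numbers loss
    (same seed for every evaluation), which makes the optimisation
    deterministic given ``base_config.seed``.  Raises if the optimiser
    cannot reduce the loss to a usable value.
    """
    if target.total_ssb <= 0 or target.total_dsb <= 0:
        raise ValueError("calibration target must have positive SSB and DSB totals")
    base = base_config or SimulationConfig()
    free = tuple(free_params)
    for p in free:
        if p not in _FREE_PARAMS:
            raise ValueError(f"unknown free parameter {p!r}; choose from {_FREE_PARAMS}")
    if not free:
        return CalibrationResult(base, loss=float("nan"), n_evaluations=0)

    guess = _initial_guess(target, base.dsb_window_bp)
    x0 = np.log([guess[p] for p in free])
    n_eval = 0

    def build(x: np.ndarray, n_samples: int) -> SimulationConfig:
        values = dict(zip(free, np.exp(x)))
        if "segment_length_bp" in values:
            values["segment_length_bp"] = max(
                2 * base.dsb_window_bp, int(round(values["segment_length_bp"]))
            )
        return replace(base, n_samples=n_samples, **values)

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        sim = simulate_damage_spectrum(build(x, n_samples_fit))
        if sim.all_zero:
            return 1e6
        return _calibration_loss(sim, target)

    def totals_error(x: np.ndarray) -> float:
        sim = simulate_damage_spectrum(build(x, n_samples_fit))
        if sim.all_zero:
            return np.inf
        return max(
            abs(sim.total_ssb / target.total_ssb - 1.0),
            abs(sim.total_dsb / target.total_dsb - 1.0),
        )

    # Nelder-Mead can stall on the mildly noisy CRN loss surface, and the
    # attainable loss floor varies with how well the target's class
    # shares fit the model family; restart the simplex from the
    # (deterministically jittered) incumbent until the SSB/DSB totals —
    # the quantities calibration is for — are tight.
    jitter_rng = np.random.default_rng(base.seed + 1)
    best_x, best_fun = x0, np.inf
    for attempt in range(5):
        start = best_x if np.isfinite(best_fun) else x0
        if attempt > 0:
            start = start + jitter_rng.normal(0.0, 0.05, size=len(start))
        result = optimize.minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-5, "adaptive": True},
        )
        if result.fun < best_fun:
            best_x, best_fun = result.x, float(result.fun)
        if totals_error(best_x) < 0.02:
            break
    final_error = totals_error(best_x)
    if not np.isfinite(best_fun) or final_error > 0.08:
        raise RuntimeError(
            f"calibration failed to converge: best loss {best_fun:.4g}, "
            f"totals error {final_error:.3f} after {n_eval} evaluations "
            f"(x = {np.exp(best_x)})"
        )
    return CalibrationResult(
        config=build(best_x, base.n_samples), loss=best_fun, n_evaluations=n_eval
    )
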
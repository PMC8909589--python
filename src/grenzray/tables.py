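"""Packaged reference yield tables with typed accessors.

Three hand-entered CSV fixtures ship with the package:

``electron_yields.csv``
    DNA damage spectra for monoenergetic electrons (100 eV - 4.5 keV)
    from the fast clustering simulation (``mcds``) side by side with
    published track-structure results (``track_structure``).
``photon_yields.csv``
    Damage spectra for the Grenz-ray qualities (15 kV, 10 kV, 10 kVp and
    titanium K-shell 4.55 kV X-rays) and the Co-60 reference at 21%, 2%
    and 0.1% O2.
``qualities.csv``
    Radiation-quality metadata: mean photon energy, LET, measured and
    simulated DSB yields and the DSB-induction RBE versus Co-60.

Yield cells are stored exactly as printed, including the "value ± sem"
notation; accessors parse them into value/SEM pairs.  Percentages in
these tables are fractions of the *total* damage-cluster yield (BD
included); absolute per-class yields are reconstructed by splitting the
printed SSB and DSB totals proportionally within each group, so group
sums reproduce the printed totals exactly.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from grenzray.damage import CLASSES, DSB_CLASSES, SSB_CLASSES, DamageSpectrum

__all__ = [
    "RadiationQuality",
    "GRENZ_QUALITIES",
    "REFERENCE_QUALITY",
    "O2_CONDITIONS",
    "ELECTRON_ENERGIES_EV",
    "load_photon_table",
    "load_electron_table",
    "load_quality_table",
    "list_qualities",
    "get_quality",
    "get_spectrum",
    "get_electron_yields",
    "fixture_checksums",
    "verify_checksums",
]

_PCT_COLS = dict(
    zip(CLASSES, ["bd_pct", "ssb_pct", "ssbp_pct", "twossb_pct", "dsb_pct", "dsbp_pct", "dsbpp_pct"])
)

O2_CONDITIONS = (21.0, 2.0, 0.1)
GRENZ_QUALITIES = ("15 kV", "10 kV", "10 kVp", "4.55 kV")
REFERENCE_QUALITY = "Co-60"
ELECTRON_ENERGIES_EV = (100, 300, 500, 1000, 1500, 4500)


@dataclass(frozen=True)
class RadiationQuality:
    """One photon radiation quality of the study."""

    name: str
    mean_photon_energy_kv: float
    let_kev_um: float

    def __post_init__(self) -> None:
        if self.let_kev_um <= 0:
            raise ValueError("LET must be positive")


def _read(name: str) -> pd.DataFrame:
    with resources.files("grenzray.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def _parse_pm(cell) -> tuple[float, float]:
    """Parse a printed "value ± sem" cell; missing SEM or value -> NaN."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return float("nan"), float("nan")
    text = str(cell)
    if "±" in text:
        value, sem = text.split("±")
        return float(value), float(sem)
    return float(text), float("nan")


def load_photon_table() -> pd.DataFrame:
    return _read("photon_yields.csv")


def load_electron_table() -> pd.DataFrame:
    return _read("electron_yields.csv")


def load_quality_table() -> pd.DataFrame:
    return _read("qualities.csv")


def list_qualities() -> list[RadiationQuality]:
    frame = load_quality_table()
    return [
        RadiationQuality(
            name=row.quality,
            mean_photon_energy_kv=float(row.mean_energy_kv),
            let_kev_um=float(row.let_kev_um),
        )
        for row in frame.itertuples()
    ]


def get_quality(name: str) -> RadiationQuality:
    for quality in list_qualities():
        if quality.name == name:
            return quality
    known = [q.name for q in list_qualities()]
    raise KeyError(f"unknown radiation quality {name!r}; available: {known}")


def _row_to_spectrum(row: pd.Series) -> DamageSpectrum:
    percentages = {c: float(row[_PCT_COLS[c]]) for c in CLASSES}
    total_ssb, sem_ssb = _parse_pm(row["total_ssb"])
    total_dsb, sem_dsb = _parse_pm(row["total_dsb"])

    yields: dict[str, float] = {}
    if math.isnan(total_ssb) or math.isnan(total_dsb):
        yields = {c: float("nan") for c in CLASSES}
    else:
        ssb_pct = sum(percentages[c] for c in SSB_CLASSES)
        dsb_pct = sum(percentages[c] for c in DSB_CLASSES)
        for c in SSB_CLASSES:
            yields[c] = total_ssb * percentages[c] / ssb_pct
        for c in DSB_CLASSES:
            yields[c] = total_dsb * percentages[c] / dsb_pct if dsb_pct > 0 else 0.0
        yields["BD"] = (total_ssb + total_dsb) * percentages["BD"] / (ssb_pct + dsb_pct)

    return DamageSpectrum(
        yields=yields,
        percentages=percentages,
        total_ssb=total_ssb,
        total_dsb=total_dsb,
        sem={"total_ssb": sem_ssb, "total_dsb": sem_dsb},
        n_samples=10_000,  # sample count behind the packaged SEMs
    )


def get_spectrum(
    quality: str | RadiationQuality, o2_percent: float, source: str = "mcds"
) -> DamageSpectrum:
    """Packaged damage spectrum for one quality and oxygen condition."""
    name = quality.name if isinstance(quality, RadiationQuality) else quality
    frame = load_photon_table()
    match = frame[
        (frame.quality == name)
        & (frame.o2_percent == o2_percent)
        & (frame.source == source)
    ]
    if match.empty:
        keys = sorted(
            {(q, o) for q, o in zip(frame.quality, frame.o2_percent)}, key=str
        )
        raise KeyError(
            f"no packaged spectrum for ({name!r}, {o2_percent}, {source!r}); "
            f"available (quality, o2): {keys}"
        )
    return _row_to_spectrum(match.iloc[0])


def get_electron_yields(energy_ev: int, source: str = "mcds") -> DamageSpectrum:
    """Packaged damage spectrum for one monoenergetic electron energy."""
    frame = load_electron_table()
    match = frame[(frame.energy_ev == energy_ev) & (frame.source == source)]
    if match.empty:
        raise KeyError(
            f"no packaged electron yields for ({energy_ev} eV, {source!r}); "
            f"available energies: {sorted(set(frame.energy_ev))}"
        )
    return _row_to_spectrum(match.iloc[0])


def electron_let(energy_ev: int, source: str = "mcds") -> float:
    frame = load_electron_table()
    match = frame[(frame.energy_ev == energy_ev) & (frame.source == source)]
    if match.empty:
        raise KeyError(f"no packaged LET for {energy_ev} eV")
    return float(match.iloc[0].let_kev_um)


def fixture_checksums() -> dict[str, str]:
    """SHA-256 digests of the shipped fixture files."""
    out = {}
    for name in ("electron_yields.csv", "photon_yields.csv", "qualities.csv"):
        data = resources.files("grenzray.data").joinpath(name).read_bytes()
        out[name] = hashlib.sha256(data).hexdigest()
    return out


def verify_checksums() -> None:
    """Compare shipped fixtures against the recorded manifest digests."""
    manifest = json.loads(
        resources.files("grenzray.data").joinpath("manifest.json").read_text()
    )
    actual = fixture_checksums()
    for name, entry in manifest["fixtures"].items():
        if actual[name] != entry["sha256"]:
            raise RuntimeError(f"fixture {name} does not match its recorded checksum")
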
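"""CSV / JSON / YAML serialization for spectra, configs and run manifests."""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from grenzray import tables
from grenzray.damage import CLASSES, DamageSpectrum, OxygenModel, SimulationConfig

__all__ = [
    "spectrum_frame",
    "write_spectrum_csv",
    "write_multiplicity_csv",
    "spectrum_to_json",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "dump_config",
    "RunManifest",
]


def spectrum_frame(spectrum: DamageSpectrum) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "class": list(CLASSES),
            "yield_per_gy_per_gbp": [spectrum.yields.get(c) for c in CLASSES],
            "sem": [spectrum.sem.get(c) for c in CLASSES],
            "percent": [spectrum.percentages.get(c) for c in CLASSES],
        }
    )


def write_spectrum_csv(spectrum: DamageSpectrum, path: str | Path) -> Path:
    path = Path(path)
    spectrum_frame(spectrum).to_csv(path, index=False)
    return path


def write_multiplicity_csv(spectrum: DamageSpectrum, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "i": list(spectrum.dsb_multiplicity),
            "expected_dsbs": list(spectrum.dsb_multiplicity.values()),
        }
    ).to_csv(path, index=False)
    return path


def spectrum_to_json(
    spectrum: DamageSpectrum, config: SimulationConfig | None = None
) -> str:
    payload = {
        "yields": spectrum.yields,
        "percentages": spectrum.percentages,
        "total_ssb": spectrum.total_ssb,
        "total_dsb": spectrum.total_dsb,
        "sem": spectrum.sem,
        "dsb_multiplicity": {str(k): v for k, v in spectrum.dsb_multiplicity.items()},
        "n_samples": spectrum.n_samples,
        "all_zero": spectrum.all_zero,
    }
    if config is not None:
        payload["config"] = config_to_dict(config)
        payload["seed"] = config.seed
    return json.dumps(payload, indent=2, sort_keys=True)


def config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["oxygen"] = dataclasses.asdict(config.oxygen)
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    oxygen = data.pop("oxygen", {})
    return SimulationConfig(oxygen=OxygenModel(**oxygen), **data)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data.get("simulation", data))


def dump_config(config: SimulationConfig) -> str:
    return yaml.safe_dump({"simulation": config_to_dict(config)}, sort_keys=True)


@dataclasses.dataclass
class RunManifest:
    """Provenance record every command writes next to its outputs."""

    command: str
    seed: int
    config_path: str | None = None
    fixture_checksums: dict[str, str] = dataclasses.field(
        default_factory=tables.fixture_checksums
    )
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.datetime.now(datetime.UTC).isoformat()
    )

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
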
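"""Interchange readers/writers and pipeline configuration.

All formats are plain text: DynamicSeries CSV (``time_s,substrate,product``),
SpectrumSeries axis/matrix CSV with a JSON sidecar, and the long-format
supernatant CSV (``day,sample_type,metabolite,integral,dss_integral,
n_protons,replicate``).  Floats are written with 17 significant digits so
write -> read round-trips are value-exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import DynamicSeries
from .spectra import SpectrumSeries

__all__ = [
    "read_dynamic_csv",
    "write_dynamic_csv",
    "read_spectrum_series",
    "write_spectrum_series",
    "read_supernatant_csv",
    "write_supernatant_csv",
    "PipelineConfig",
]

SUPERNATANT_COLUMNS = [
    "day",
    "sample_type",
    "metabolite",
    "integral",
    "dss_integral",
    "n_protons",
    "replicate",
]


def read_dynamic_csv(path, labels=("substrate", "product")) -> DynamicSeries:
    return DynamicSeries.from_csv(path, labels=labels)


def write_dynamic_csv(series: DynamicSeries, path) -> None:
    series.to_csv(path)


def read_spectrum_series(stem) -> SpectrumSeries:
    return SpectrumSeries.load(stem)


def write_spectrum_series(spectra: SpectrumSeries, stem) -> None:
    spectra.save(stem)


def read_supernatant_csv(path) -> pd.DataFrame:
    """Read and validate the long-format supernatant panel CSV."""
    df = pd.read_csv(path)
    missing = set(SUPERNATANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("integral", "dss_integral"):
        bad = df.index[~np.isfinite(df[col])]
        if len(bad):
            raise ValueError(f"{path}: non-finite {col} at rows {list(bad[:5])}")
    bad_type = set(df["sample_type"]) - {"spent", "fresh"}
    if bad_type:
        raise ValueError(f"{path}: unknown sample_type values {sorted(bad_type)}")
    return df


def write_supernatant_csv(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False, float_format="%.17g")


@dataclass
class PipelineConfig:
    """Validated pipeline settings (YAML-loadable; unknown keys rejected)."""

    flip_angle_nominal_deg: float = 20.0
    flip_angle_effective_deg: float = 15.0
    repetition_time_s: float = 1.0
    n_scans: int = 180
    n_first_summed: int = 50
    substrate_peak: str = "glucose_anomeric"
    product_peak: str = "lactate_c1"
    dss_buffer_conc_mM: float = 0.644
    sample_volume_uL: float = 500.0
    buffer_volume_uL: float = 100.0
    seed: int = 0
    out_dir: str = "hypermet_out"
    verbosity: int = 1
    fit: dict = field(default_factory=dict)  # FitConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: top level must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)} (known: {sorted(known)})")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
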
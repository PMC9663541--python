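"""Dataset readers/writers, run configuration and provenance records.

The single interchange format is a long "tidy" CSV/TSV table with columns
participant, voxel, run, orientation_deg, contrast, response (an optional
repeat column disambiguates repeated presentations within a run).
Orientations are normalized to [0, 180); the two contrast labels are mapped
to (baseline, modulated), with the baseline label configurable since which
condition counts as baseline is an arbitrary labeling choice.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_dataset", "write_dataset_csv", "RunConfig", "provenance"]

REQUIRED_COLUMNS = ["participant", "voxel", "run", "orientation_deg",
                    "contrast", "response"]
KEY_COLUMNS = ["participant", "voxel", "run", "orientation_deg", "contrast",
               "repeat"]


def read_dataset(path, dialect: str = "csv",
                 baseline_label: Optional[str] = None) -> pd.DataFrame:
    """Read and validate a long-format voxel dataset.

    Checks required columns, finite numeric responses and duplicate keys
    (naming offending rows); normalizes orientations to [0, 180) with a
    warning when reduction was needed.  When ``baseline_label`` is given,
    the contrast column is reordered categorically so that label sorts
    first (downstream code treats the first label as baseline).
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"dataset missing required columns: {missing}")
    if "repeat" not in data.columns:
        data["repeat"] = 0
    resp = pd.to_numeric(data["response"], errors="coerce")
    bad = data.index[~np.isfinite(resp)].tolist()
    if bad:
        raise ValueError(f"non-numeric or non-finite responses at rows {bad[:10]}")
    data["response"] = resp
    ori = pd.to_numeric(data["orientation_deg"], errors="coerce")
    if ori.isna().any():
        raise ValueError("non-numeric orientation values")
    if ((ori < 0) | (ori >= 180)).any():
        warnings.warn("orientations outside [0, 180) normalized modulo 180",
                      stacklevel=2)
        ori = np.mod(ori, 180.0)
    data["orientation_deg"] = ori
    dup = data.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        raise ValueError(
            f"duplicate (participant, voxel, run, orientation, contrast, repeat)"
            f" keys at rows {data.index[dup].tolist()[:10]}")
    labels = sorted(data["contrast"].unique())
    if baseline_label is not None:
        if baseline_label not in labels:
            raise ValueError(f"baseline label {baseline_label!r} not present "
                             f"in contrast column (found {labels})")
        order = [baseline_label] + [c for c in labels if c != baseline_label]
        data["contrast"] = pd.Categorical(data["contrast"], categories=order,
                                          ordered=True)
    return data


def write_dataset_csv(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Serializable run configuration; every stochastic stage has a seed."""

    seed: int = 0
    family: str = "multiplicative"
    design: dict = field(default_factory=dict)
    priors: Optional[dict] = None
    sampler: dict = field(default_factory=lambda: dict(
        chains=4, warmup=1000, draws=2000, thin=1))
    baseline_label: Optional[str] = None

    def to_dict(self) -> dict:
        return {"seed": self.seed, "family": self.family,
                "design": self.design, "priors": self.priors,
                "sampler": self.sampler,
                "baseline_label": self.baseline_label}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config: Optional[RunConfig] = None, seed=None,
               extra: Optional[dict] = None) -> dict:
    """Provenance record written next to every CLI artifact."""
    from . import __version__

    rec = {
        "voxtune_version": __version__,
        "python": platform.python_version(),
        "seed": seed if seed is not None else (config.seed if config else None),
        "config_hash": config.hash if config else None,
        "config": config.to_dict() if config else None,
    }
    if extra:
        rec.update(extra)
    return rec
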
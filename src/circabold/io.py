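"""File formats, run configuration and manifest plumbing.

Artifacts use open formats throughout: NIfTI-1 for volumes (nibabel),
tab-separated tables with BIDS-like column names for events, ratings,
hypnograms and result tables, YAML for the run configuration and JSON for
the run manifest.  The manifest records the resolved configuration hash and
the seed, and every stage appends the artifacts it wrote, so a stage can
verify that its upstream stage has run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bold import BOLDDataset, NoiseConfig, make_affine
from .cohort import CohortConfig
from .pvt import RTCoeffs
from .sleep import EEGConfig, HypnoCoeffs


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 1
    smooth_fwhm: float = 8.0      # mm
    n_perm: int = 1000
    alpha: float = 0.05
    contrast_sign: float = 1.0    # sign of the S-minus-C subtraction
    out_root: str = "circabold_out"

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        c = dict(d.pop("cohort", {}))
        sub = {}
        for key, typ in (("noise", NoiseConfig), ("rt_coeffs", RTCoeffs),
                         ("hypno_coeffs", HypnoCoeffs), ("eeg", EEGConfig)):
            if key in c:
                sub[key] = typ(**_tuplify(typ, c.pop(key)))
        c = {k: tuple(v) if isinstance(v, list) else v for k, v in c.items()}
        return cls(cohort=CohortConfig(**c, **sub), **d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_root", None)      # artifact location is not configuration
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_asdict(x) for x in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _tuplify(typ, d):
    out = {}
    for f in dataclasses.fields(typ):
        if f.name in d:
            v = d[f.name]
            out[f.name] = tuple(v) if isinstance(v, list) else v
    return out


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# --------------------------------------------------------------------------
# NIfTI

def write_nifti(volume: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.to_filename(str(path))


def write_atlas(atlas: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(atlas, dtype=np.int16),
                          make_affine(atlas.shape))
    img.to_filename(str(path))


def read_nifti(path) -> tuple:
    """Return (data, affine); raises a clear error on malformed files."""
    try:
        img = nib.load(str(path))
        return np.asarray(img.get_fdata()), img.affine
    except Exception as e:
        raise IOError(f"not a readable NIfTI-1 file: {path} ({e})") from e


def read_bold_dataset(path, atlas: np.ndarray, tr: float) -> BOLDDataset:
    data, affine = read_nifti(path)
    if data.shape[:3] != atlas.shape:
        raise ValueError(
            f"volume {path} has shape {data.shape[:3]}, atlas {atlas.shape}")
    return BOLDDataset(data=data, affine=affine, atlas=atlas, tr=tr)


# --------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def events_frame(pvt) -> pd.DataFrame:
    """BIDS-like events table (onset s, trial_type, response_time ms)."""
    return pvt.trials.rename(columns={"onset_s": "onset",
                                      "response_time_ms": "response_time"})


def hypnogram_frame(hypnograms: dict) -> pd.DataFrame:
    rows = []
    for sid, hyps in hypnograms.items():
        for h in hyps:
            for e, stage in enumerate(h.stages):
                rows.append({"subject_id": sid, "nap_index": h.nap_index,
                             "epoch": e, "stage": stage})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# manifest

class Manifest:
    """Append-only record of a run's stages and artifacts."""

    def __init__(self, root, config_hash: str = "", seed: int = 0):
        self.root = Path(root)
        self.path = self.root / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {"config_hash": config_hash, "seed": seed,
                         "stages": {}}

    def record(self, stage: str, artifacts: list) -> None:
        self.data["stages"][stage] = {"artifacts": [str(a) for a in artifacts]}
        self.path.write_text(json.dumps(self.data, indent=2))

    def require(self, stage: str) -> None:
        if stage not in self.data["stages"]:
            raise RuntimeError(
                f"stage {stage!r} has not been run in {self.root}; "
                f"run `circabold {stage}` first")

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def config_hash(self) -> str:
        return self.data["config_hash"]
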
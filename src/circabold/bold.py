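"""Forward model for event-related BOLD volumes over a labelled toy brain.

The toy brain is a small axis-aligned block atlas (default 20 x 24 x 20
voxels at 3-mm isotropic resolution with an MNI-like centred affine), with
regions named after the areas whose activation time courses the analysis is
designed to resolve.  A session's voxel time series is

    baseline * (1 + sum_e amp(region, e)/100 * x_e(t))
    + drift (random combination of the analysis DCT basis)
    + motion-coupled nuisance + AR(1) Gaussian noise,

where x_e is the unit-peak HRF-convolved onset train of event class e, built
with exactly the same code as the analysis design matrix, so a noise-free
simulation analysed by the first-level GLM returns the planted percent
amplitudes to numerical precision (the baseline is 100, so beta units are
percent signal change).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .behavior import partition_rts
from .glm import DEFAULT_TR_S, DesignMatrix, build_design, _dct_basis
from .pvt import PVTSession

DEFAULT_SHAPE = (20, 24, 20)
VOXEL_MM = 3.0
BASELINE = 100.0

REGION_LABELS = {
    "background": 0,
    "thalamus": 1,
    "putamen": 2,
    "postcentral": 3,
    "parietal": 4,
    "lingual": 5,
    "frontal": 6,
}

# fractional (lo, hi) extents per axis; blocks are mutually disjoint
_REGION_BLOCKS = {
    "thalamus":    ((0.35, 0.65), (0.42, 0.62), (0.35, 0.60)),
    "putamen":     ((0.68, 0.88), (0.45, 0.65), (0.35, 0.55)),
    "postcentral": ((0.15, 0.85), (0.30, 0.45), (0.70, 0.92)),
    "parietal":    ((0.15, 0.85), (0.10, 0.28), (0.55, 0.80)),
    "lingual":     ((0.30, 0.70), (0.02, 0.20), (0.15, 0.40)),
    "frontal":     ((0.15, 0.85), (0.70, 0.95), (0.35, 0.75)),
}


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth session-amplitude profile for one region and event class.

    ``amplitudes`` is a 5-vector of percent signal change, one value per scan
    session.  ``covariate`` optionally names a subject-level latent
    ("delta_rebound" or "circ_strength") whose standardised value scales the
    profile as (1 + covariate_gain * z), coupling individual effect size to
    the physiological marker.
    """

    region: str
    speed: str
    condition: str
    amplitudes: tuple
    covariate: str | None = None
    covariate_gain: float = 0.0

    def __post_init__(self):
        if self.region not in _REGION_BLOCKS:
            raise ValueError(f"unknown region label {self.region!r}")
        if len(self.amplitudes) != 5:
            raise ValueError("amplitude profile must have 5 sessions")


@dataclass
class NoiseConfig:
    """Nuisance and noise levels of the BOLD forward model."""

    sigma: float = 2.5          # marginal SD of the AR(1) noise, % of baseline
    ar_rho: float = 0.3         # lag-1 autocorrelation
    drift_scale: float = 1.0    # SD of random DCT drift coefficients
    motion_coupling: float = 0.5  # SD of voxelwise motion couplings

    @classmethod
    def noiseless(cls):
        return cls(sigma=0.0, drift_scale=0.0, motion_coupling=0.0)


@dataclass
class BOLDDataset:
    """One session's 4D volume with its geometry and atlas."""

    data: np.ndarray            # (x, y, z, scan)
    affine: np.ndarray
    atlas: np.ndarray           # integer label volume
    tr: float = DEFAULT_TR_S


def make_affine(shape=DEFAULT_SHAPE, voxel_mm: float = VOXEL_MM) -> np.ndarray:
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_mm
    return aff


def make_atlas(shape=DEFAULT_SHAPE) -> np.ndarray:
    """Integer label volume of the toy brain at the requested grid size."""
    atlas = np.zeros(shape, dtype=np.int16)
    for name, bounds in _REGION_BLOCKS.items():
        sl = []
        for ax, (lo, hi) in enumerate(bounds):
            a = int(round(lo * shape[ax]))
            b = max(int(round(hi * shape[ax])), a + 1)
            sl.append(slice(a, b))
        block = atlas[tuple(sl)]
        if np.any(block != 0):
            raise RuntimeError("atlas blocks overlap; check region definitions")
        atlas[tuple(sl)] = REGION_LABELS[name]
    return atlas


def region_mask(atlas: np.ndarray, region: str) -> np.ndarray:
    if region not in REGION_LABELS:
        raise ValueError(f"unknown region label {region!r}")
    return atlas == REGION_LABELS[region]


def simulate_motion(n_scans: int, rng: np.random.Generator,
                    step_sd: float = 0.02) -> np.ndarray:
    """Six slow random-walk realignment parameter series (mm / deg)."""
    return np.cumsum(rng.normal(0.0, step_sd, size=(n_scans, 6)), axis=0)


def simulate_bold(pvt: PVTSession, atlas: np.ndarray,
                  planted: list, noise: NoiseConfig,
                  seed, motion: np.ndarray | None = None,
                  tr: float = DEFAULT_TR_S) -> tuple:
    """Simulate one session's 4D BOLD dataset.

    Returns ``(BOLDDataset, DesignMatrix, motion)``; the design matrix is
    the one used to build the signal (and is what the analysis would also
    construct from the events and motion series).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_scans = int(np.ceil(pvt.duration_s / tr))
    if motion is None:
        motion = simulate_motion(n_scans, rng)

    partition = partition_rts(pvt.rts)
    design = build_design(pvt, partition, motion, tr=tr, n_scans=n_scans)
    X = design.matrix
    shape = atlas.shape
    n_vox = int(np.prod(shape))

    # --- task signal ----------------------------------------------------
    amp = np.zeros((n_vox, len(design.columns)))
    flat_atlas = atlas.reshape(-1)
    for eff in planted:
        if eff.condition != pvt.condition:
            continue
        if eff.speed not in design.columns:
            continue      # event class absent in this session
        col = design.columns.index(eff.speed)
        mask = flat_atlas == REGION_LABELS[eff.region]
        amp[mask, col] += eff.amplitudes[pvt.session_index] * BASELINE / 100.0

    signal = BASELINE + amp @ X.T               # voxels x scans

    # --- nuisance: random DCT drift and motion coupling -----------------
    dct = _dct_basis(n_scans, tr)
    if noise.drift_scale > 0 and dct.shape[1]:
        coef = rng.normal(0.0, noise.drift_scale, size=(n_vox, dct.shape[1]))
        signal += coef @ dct.T
    if noise.motion_coupling > 0:
        gamma = rng.normal(0.0, noise.motion_coupling, size=(n_vox, 6))
        signal += gamma @ motion.T

    # --- AR(1) noise -----------------------------------------------------
    if noise.sigma > 0:
        innov_sd = noise.sigma * np.sqrt(1.0 - noise.ar_rho ** 2)
        eps = rng.normal(0.0, innov_sd, size=(n_vox, n_scans))
        x0 = rng.normal(0.0, noise.sigma, size=n_vox)
        zi = (noise.ar_rho * x0)[:, None]
        ar, _ = lfilter([1.0], [1.0, -noise.ar_rho], eps, axis=1, zi=zi)
        signal = signal + ar

    data = signal.reshape(shape + (n_scans,))
    ds = BOLDDataset(data=data, affine=make_affine(shape), atlas=atlas, tr=tr)
    return ds, design, motion
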
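"""Event-related first-level general linear model.

One model per subject, arm and scan session.  Event onsets of the four
speed classes (fast / intermediate / slow / lapse) are convolved with the
canonical double-gamma haemodynamic response function; each class also gets
a first-order time-modulation regressor (the same onset train weighted by
the mean-centred trial index, capturing time-on-task drift of the response).
Six motion parameters, a discrete-cosine high-pass set (128-s cutoff) and an
intercept complete the design.  Estimation is ordinary least squares; the
synthetic noise is AR(1) with modest autocorrelation, for which OLS is
unbiased, and group-level inference is permutation-based, so no prewhitening
is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.ndimage import gaussian_filter

from .behavior import SPEED_LABELS, RTPartition
from .pvt import PVTSession

log = logging.getLogger(__name__)

HRF_LENGTH_S = 32.0
HRF_OVERSAMPLE_DT = 0.1
DCT_CUTOFF_S = 128.0
DEFAULT_TR_S = 2.2


@dataclass
class DesignMatrix:
    matrix: np.ndarray               # scans x regressors
    columns: list                    # column labels
    tr: float
    frame_times: np.ndarray
    dropped: list = field(default_factory=list)   # absent event types

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FirstLevelResult:
    betas: dict                      # column label -> volume (x, y, z)
    residual_variance: np.ndarray    # volume
    dof: int
    design: DesignMatrix


def canonical_hrf(dt: float, tr: float = DEFAULT_TR_S) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds over 32 s.

    Response gamma peaks at 6 s delay, undershoot at 16 s, unit dispersions,
    undershoot ratio 1/6; the kernel is normalised to unit peak so a planted
    amplitude is expressed in units of peak response.
    """
    if not (0 < dt <= tr):
        raise ValueError("dt must be in (0, TR]")
    t = np.arange(0, HRF_LENGTH_S + dt / 2, dt)

    def gpdf(x, shape):
        # gamma pdf with unit scale
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                x > 0,
                np.exp((shape - 1) * np.log(np.maximum(x, 1e-300)) - x
                       - special.gammaln(shape)),
                0.0,
            )
        return out

    h = gpdf(t, 6.0) - gpdf(t, 16.0) / 6.0
    return h / h.max()


def _dct_basis(n_scans: int, tr: float, cutoff_s: float = DCT_CUTOFF_S) -> np.ndarray:
    """Discrete cosine high-pass set (excluding the constant term)."""
    order = int(np.floor(2 * n_scans * tr / cutoff_s))
    n = np.arange(n_scans)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def _convolve_train(onsets, weights, hrf, frame_times, duration_s):
    """Convolve a weighted onset stick train with the HRF, sampled at scans."""
    dt = HRF_OVERSAMPLE_DT
    n_hi = int(np.ceil((duration_s + HRF_LENGTH_S) / dt)) + 1
    train = np.zeros(n_hi)
    idx = np.round(np.asarray(onsets) / dt).astype(int)
    np.add.at(train, idx, weights)
    sig = np.convolve(train, hrf)[:n_hi]
    return np.interp(frame_times, np.arange(n_hi) * dt, sig)


def build_design(pvt: PVTSession, partition: RTPartition, motion: np.ndarray,
                 tr: float = DEFAULT_TR_S, n_scans: int | None = None) -> DesignMatrix:
    """Assemble the session design matrix.

    ``motion`` is a (n_scans, 6) array of realignment parameters.  Event
    types with no occurrences are dropped (with a log message); events whose
    onset falls after the last scan are dropped with a warning.
    """
    if n_scans is None:
        n_scans = int(np.ceil(pvt.duration_s / tr))
    frame_times = np.arange(n_scans) * tr
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (n_scans, 6):
        raise ValueError(f"motion must be (n_scans, 6), got {motion.shape}")

    clock = pvt.trials["trial_type"].eq("clock").to_numpy()
    onsets_all = pvt.trials["onset_s"].to_numpy(dtype=float)[clock]
    if partition.labels.shape[0] != onsets_all.shape[0]:
        raise ValueError("partition labels must match the clock trials")

    t_max = frame_times[-1]
    keep = onsets_all <= t_max
    if not np.all(keep):
        log.warning("dropping %d events after the last scan", int(np.sum(~keep)))
    onsets_all = onsets_all[keep]
    labels = partition.labels[keep]

    hrf = canonical_hrf(HRF_OVERSAMPLE_DT, tr)
    cols, names, dropped = [], [], []
    for lab in SPEED_LABELS:
        sel = labels == lab
        if not np.any(sel):
            dropped.append(lab)
            log.info("event type %r absent; columns dropped", lab)
            continue
        onsets = onsets_all[sel]
        cols.append(_convolve_train(onsets, np.ones_like(onsets), hrf,
                                    frame_times, pvt.duration_s))
        names.append(lab)
        if onsets.size >= 2:        # a single event has no time-on-task slope
            idx = np.arange(onsets.size, dtype=float)
            idx -= idx.mean()       # mean-centred trial index
            cols.append(_convolve_train(onsets, idx, hrf, frame_times,
                                        pvt.duration_s))
            names.append(f"{lab}_tmod")
        else:
            log.info("event type %r has one event; tmod column omitted", lab)

    for j in range(6):
        cols.append(motion[:, j])
        names.append(f"motion_{j}")
    dct = _dct_basis(n_scans, tr)
    for j in range(dct.shape[1]):
        cols.append(dct[:, j])
        names.append(f"drift_{j}")
    cols.append(np.ones(n_scans))
    names.append("intercept")

    return DesignMatrix(matrix=np.column_stack(cols), columns=names, tr=tr,
                        frame_times=frame_times, dropped=dropped)


def fit_glm(bold: np.ndarray, design: DesignMatrix) -> FirstLevelResult:
    """Ordinary-least-squares fit of the design at every voxel.

    ``bold`` is a 4D array (x, y, z, scan).  Raises on rank deficiency,
    naming the collinear columns.
    """
    X = design.matrix
    n_scans, n_reg = X.shape
    if bold.shape[-1] != n_scans:
        raise ValueError("scan count of data and design differ")

    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < max(X.shape) * np.finfo(float).eps * diag.max()
    if np.any(bad):
        names = [design.columns[i] for i in np.nonzero(bad)[0]]
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {names}")

    shape = bold.shape[:3]
    Y = bold.reshape(-1, n_scans).T          # scans x voxels
    beta = np.linalg.solve(r, q.T @ Y)       # regressors x voxels
    resid = Y - X @ beta
    dof = n_scans - n_reg
    resvar = (resid ** 2).sum(axis=0) / dof

    betas = {name: beta[i].reshape(shape) for i, name in enumerate(design.columns)}
    return FirstLevelResult(betas=betas, residual_variance=resvar.reshape(shape),
                            dof=dof, design=design)


def session_contrast(result: FirstLevelResult, speed: str) -> np.ndarray:
    """Main-effect beta volume of the requested speed regressor."""
    if speed not in SPEED_LABELS:
        raise ValueError(f"unknown speed range {speed!r}")
    if speed not in result.betas:
        raise ValueError(f"regressor {speed!r} was dropped from this session")
    return result.betas[speed]


def smooth_volume(volume: np.ndarray, fwhm_mm: float,
                  voxel_size_mm: float | tuple = 3.0) -> np.ndarray:
    """Isotropic Gaussian smoothing with the FWHM given in millimetres."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma_mm = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma_vox = sigma_mm / vox
    return gaussian_filter(np.asarray(volume, dtype=float), sigma=tuple(sigma_vox))
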
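"""Second-level (group) inference with permutation family-wise error control.

One-sample t-tests on subject anchored-contrast volumes and simple
covariate (ANCOVA-style) slope tests, with voxel-level FWE p-values from
the permutation distribution of the maximum statistic (maxT): sign flipping
of subject maps for one-sample tests, permutation of the covariate for
slope tests.  Small-volume correction recomputes the maxT null within a
region-of-interest mask; exclusive masking removes from a primary map all
voxels that exceed an uncorrected threshold in another map, isolating
speed-range-specific effects.  Peaks are reported with Z-equivalent scores
and millimetre coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .bold import REGION_LABELS

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 1000
ALPHA = 0.05


@dataclass
class StatMap:
    """Voxelwise group statistic with optional permutation FWE p-values."""

    t: np.ndarray                  # statistic volume (NaN outside mask)
    dof: int
    mask: np.ndarray               # boolean volume
    fwe_p: np.ndarray | None = None
    n_subjects: int = 0
    info: dict = field(default_factory=dict)   # provenance: spec/speed/...
    two_sided: bool = True


@dataclass
class PeakTable:
    rows: pd.DataFrame             # region, side, z, p_fwe, x, y, z coordinates


def _stack(maps) -> np.ndarray:
    arr = np.stack([np.asarray(m, dtype=float) for m in maps], axis=0)
    return arr.reshape(arr.shape[0], -1)


def _one_sample_t_flat(data: np.ndarray) -> np.ndarray:
    """t = mean / (sd / sqrt(n)) along axis 0; zero-variance -> NaN."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def one_sample_t(maps, mask: np.ndarray | None = None, info: dict | None = None) -> StatMap:
    """Voxelwise one-sample t-test across subject volumes (df = n - 1)."""
    flat = _stack(maps)
    n = flat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    shape = np.asarray(maps[0]).shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    t = _one_sample_t_flat(flat).reshape(shape)
    n_bad = int(np.sum(np.isnan(t[mask])))
    if n_bad:
        log.info("%d zero-variance voxels set to NaN", n_bad)
    t = np.where(mask, t, np.nan)
    return StatMap(t=t, dof=n - 1, mask=mask, n_subjects=n, info=info or {})


def covariate_slope_t(maps, covariate, mask: np.ndarray | None = None,
                      info: dict | None = None) -> StatMap:
    """Voxelwise simple regression of map values on a mean-centred covariate.

    Returns the t statistic of the slope with df = n - 2; exact linear fits
    (zero residual) are capped at a large finite value and flagged in
    ``info['perfect_fit_voxels']``.
    """
    flat = _stack(maps)
    n = flat.shape[0]
    cov = np.asarray(covariate, dtype=float)
    if cov.shape != (n,):
        raise ValueError("covariate length must match the number of maps")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant")
    shape = np.asarray(maps[0]).shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)

    xc = cov - cov.mean()
    sxx = float(np.sum(xc ** 2))
    slope = xc @ flat / sxx
    fitted = np.outer(xc, slope) + flat.mean(axis=0)
    ss_res = ((flat - fitted) ** 2).sum(axis=0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(ss_res / dof / sxx)
        t = slope / se
    perfect = (ss_res <= 1e-12 * np.maximum((flat ** 2).sum(axis=0), 1e-300))
    t[perfect] = np.sign(slope[perfect]) * 1e6
    t = t.reshape(shape)
    t = np.where(mask, t, np.nan)
    info = dict(info or {})
    info["perfect_fit_voxels"] = int(perfect.sum())
    return StatMap(t=t, dof=dof, mask=mask, n_subjects=n, info=info)


def _max_stat(t_flat: np.ndarray, two_sided: bool) -> np.ndarray:
    s = np.abs(t_flat) if two_sided else t_flat
    return np.nanmax(s, axis=-1)


def permutation_fwe(maps, statmap: StatMap, n_perm: int = DEFAULT_N_PERM,
                    seed=0, mask: np.ndarray | None = None,
                    covariate=None, two_sided: bool = True) -> StatMap:
    """Attach voxelwise FWE p-values from the permutation maxT distribution.

    One-sample mode (``covariate is None``) flips the signs of subject maps;
    covariate mode permutes the covariate across subjects.  When fewer than
    ``n_perm`` distinct sign patterns exist the full set is enumerated (with
    a warning) and p-values become #{maxT >= t} / n_patterns, the identity
    pattern included; otherwise p = (1 + #{maxT >= t}) / (n_perm + 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = _stack(maps)
    n = flat.shape[0]
    shape = statmap.t.shape
    if mask is None:
        mask = statmap.mask
    mflat = mask.reshape(-1)
    data = flat[:, mflat]

    if covariate is None:
        t_obs = _one_sample_t_flat(data)
        if 2 ** n <= n_perm:
            warnings.warn(
                f"only {2 ** n} distinct sign patterns for n={n}; "
                "enumerating exhaustively")
            signs = np.array(
                [[1.0 if (i >> j) & 1 else -1.0 for j in range(n)]
                 for i in range(2 ** n)])
            exhaustive = True
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            exhaustive = False
        # vectorised t for every sign pattern: per-voxel second moment is
        # flip-invariant, so only the mean changes.
        m2 = (data ** 2).mean(axis=0)
        null_max = np.empty(signs.shape[0])
        chunk = max(1, int(2e7 // max(data.shape[1], 1)))
        for i in range(0, signs.shape[0], chunk):
            s = signs[i:i + chunk]
            mean = s @ data / n
            var = (m2[None, :] - mean ** 2) * n / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tt = mean / np.sqrt(var / n)
            null_max[i:i + chunk] = _max_stat(tt, two_sided)
    else:
        cov = np.asarray(covariate, dtype=float)
        xc = cov - cov.mean()
        t_obs = _covariate_t_flat(data, xc)
        exhaustive = False
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            null_max[i] = _max_stat(_covariate_t_flat(data, xc[perm]), two_sided)

    stat_obs = np.abs(t_obs) if two_sided else t_obs
    # broadcast comparison: p(v) over the null maxima
    cmp = null_max[:, None] >= stat_obs[None, :] - 1e-12
    counts = cmp.sum(axis=0)
    if exhaustive:
        p = counts / null_max.shape[0]
    else:
        p = (1.0 + counts) / (null_max.shape[0] + 1.0)
    p = np.where(np.isnan(stat_obs), np.nan, p)

    fwe = np.full(int(np.prod(shape)), np.nan)
    fwe[mflat] = p
    t_full = np.full(int(np.prod(shape)), np.nan)
    t_full[mflat] = t_obs
    return StatMap(t=t_full.reshape(shape), dof=statmap.dof, mask=mask,
                   fwe_p=fwe.reshape(shape), n_subjects=n,
                   info=dict(statmap.info), two_sided=two_sided)


def _covariate_t_flat(data: np.ndarray, xc: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    sxx = float(np.sum(xc ** 2))
    slope = xc @ data / sxx
    fitted = np.outer(xc, slope) + data.mean(axis=0)
    ss_res = ((data - fitted) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(ss_res / (n - 2) / sxx)
    return t


def roi_small_volume(maps, statmap: StatMap, roi_mask: np.ndarray,
                     n_perm: int = DEFAULT_N_PERM, seed=0,
                     covariate=None, two_sided: bool = True) -> StatMap:
    """Recompute maxT FWE p-values within a region-of-interest mask."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != statmap.t.shape:
        raise ValueError("ROI mask geometry mismatch")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    return permutation_fwe(maps, statmap, n_perm=n_perm, seed=seed,
                           mask=roi_mask & statmap.mask, covariate=covariate,
                           two_sided=two_sided)


def uncorrected_p(statmap: StatMap, two_sided: bool = True) -> np.ndarray:
    """Parametric per-voxel p-values from the t distribution."""
    sf = stats.t.sf(np.abs(statmap.t) if two_sided else statmap.t, statmap.dof)
    return 2 * sf if two_sided else sf


def exclusive_mask(primary: StatMap, other: StatMap,
                   p_thresh: float = ALPHA) -> StatMap:
    """Remove from ``primary`` every voxel exceeding ``p_thresh``
    (uncorrected) in ``other``; FWE-significant survivors are speed-specific.
    """
    if primary.t.shape != other.t.shape:
        raise ValueError("stat maps have mismatching geometry")
    p_other = uncorrected_p(other)
    remove = np.nan_to_num(p_other, nan=1.0) < p_thresh
    mask = primary.mask & ~remove
    t = np.where(mask, primary.t, np.nan)
    fwe = np.where(mask, primary.fwe_p, np.nan) if primary.fwe_p is not None else None
    info = dict(primary.info)
    info["exclusively_masked_against"] = other.info.get("speed", "other")
    return StatMap(t=t, dof=primary.dof, mask=mask, fwe_p=fwe,
                   n_subjects=primary.n_subjects, info=info,
                   two_sided=primary.two_sided)


def peak_table(statmap: StatMap, atlas: np.ndarray, affine: np.ndarray,
               alpha: float = ALPHA) -> PeakTable:
    """Local maxima of |t| with FWE p <= alpha, labelled by atlas region.

    Hemisphere comes from the sign of the x coordinate in mm (ties at
    x = 0 are 'B' for bilateral); rows are sorted by p then descending |t|.
    """
    if statmap.fwe_p is None:
        raise ValueError("stat map has no FWE p-values; run permutation_fwe first")
    label_of = {v: k for k, v in REGION_LABELS.items()}
    score = np.nan_to_num(np.abs(statmap.t), nan=-np.inf)
    local_max = (score == ndimage.maximum_filter(score, size=3))
    sig = np.nan_to_num(statmap.fwe_p, nan=1.0) <= alpha
    cand = local_max & sig & statmap.mask

    rows = []
    for idx in np.argwhere(cand):
        tval = statmap.t[tuple(idx)]
        mm = affine @ np.append(idx, 1.0)
        side = "B" if mm[0] == 0 else ("L" if mm[0] < 0 else "R")
        pf = float(statmap.fwe_p[tuple(idx)])
        # Z equivalent: standard-normal quantile matching the t tail
        z = float(stats.norm.isf(stats.t.sf(abs(tval), statmap.dof)))
        rows.append({
            "region": label_of.get(int(atlas[tuple(idx)]), "unknown"),
            "side": side,
            "z_score": np.sign(tval) * z,
            "p_fwe": pf,
            "x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2],
            "t": float(tval),
        })
    df = pd.DataFrame(rows, columns=["region", "side", "z_score", "p_fwe",
                                     "x_mm", "y_mm", "z_mm", "t"])
    if not df.empty:
        df = df.sort_values(["p_fwe", "t"], key=lambda c: c if c.name == "p_fwe"
                            else -c.abs()).reset_index(drop=True)
    return PeakTable(rows=df)
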
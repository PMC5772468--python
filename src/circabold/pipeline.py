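"""End-to-end analysis pipeline over a simulated cohort.

Runs the first-level GLM for every subject/arm/session, collects session
contrast volumes per speed range (optionally smoothed), combines them with
the sleepiness-anchored contrast weights, and performs group inference
(one-sample maxT permutation tests, covariate slope tests, exclusive
masking between speed ranges and peak tables).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import behavior
from .behavior import partition_rts
from .bold import VOXEL_MM, NoiseConfig
from .cohort import Cohort
from .contrasts import ContrastSpec, apply_anchored_contrast, make_contrast_specs
from .glm import build_design, fit_glm, session_contrast, smooth_volume
from .inference import (StatMap, exclusive_mask, one_sample_t, peak_table,
                        permutation_fwe)
from .markers import build_marker_table, circadian_strength, delta_rebound, \
    nrem_delta_power

log = logging.getLogger(__name__)

SPEEDS = ("fast", "slow")


@dataclass
class FirstLevelMaps:
    """Session contrast volumes per subject and speed range."""

    maps: dict          # (subject_id, condition, session, speed) -> 3D array
    smooth_fwhm: float


@dataclass
class GroupResult:
    spec: ContrastSpec
    statmap: StatMap
    peaks: object                    # PeakTable
    masked: StatMap | None = None    # after exclusive masking
    masked_peaks: object | None = None


def run_first_level(cohort: Cohort, conditions=("SD", "NP"),
                    smooth_fwhm: float = 8.0,
                    noise: NoiseConfig | None = None) -> FirstLevelMaps:
    """Fit every session GLM and return (smoothed) speed contrast volumes."""
    out = {}
    for i, params in enumerate(cohort.subjects):
        for cond in conditions:
            for sess in range(5):
                ds, design, _ = cohort.simulate_session_bold(i, cond, sess,
                                                             noise=noise)
                res = fit_glm(ds.data, design)
                for speed in SPEEDS:
                    if speed not in res.betas:
                        log.info("%s %s s%d: no %s events", params.subject_id,
                                 cond, sess, speed)
                        continue
                    vol = session_contrast(res, speed)
                    if smooth_fwhm > 0:
                        vol = smooth_volume(vol, smooth_fwhm, VOXEL_MM)
                    out[(params.subject_id, cond, sess, speed)] = vol
    return FirstLevelMaps(maps=out, smooth_fwhm=smooth_fwhm)


def subject_anchored_maps(cohort: Cohort, fl: FirstLevelMaps,
                          spec: ContrastSpec) -> list:
    """One anchored-contrast volume per subject for the spec's arm/speed."""
    maps = []
    for params in cohort.subjects:
        sess_maps = [fl.maps.get((params.subject_id, spec.condition, s,
                                  spec.speed)) for s in range(5)]
        maps.append(apply_anchored_contrast(sess_maps, spec))
    return maps


def group_anchored_analysis(cohort: Cohort, fl: FirstLevelMaps,
                            n_perm: int = 1000, seed: int = 0,
                            alpha: float = 0.05) -> dict:
    """One-sample maxT group tests of the four anchored contrasts.

    Statistics are two-sided (maxT of |t|); signed peaks distinguish T+
    from T-.  For the fast-range interaction contrast the result after
    exclusive masking against the slow-range map is attached.

    Returns {(name, speed): GroupResult}.
    """
    sd_prof = cohort.sleepiness_profile("SD")
    np_prof = cohort.sleepiness_profile("NP")
    results = {}
    subject_maps = {}
    for speed in SPEEDS:
        specs = make_contrast_specs(sd_prof, np_prof, speed=speed)
        for name, spec in specs.items():
            maps = subject_anchored_maps(cohort, fl, spec)
            subject_maps[(name, speed)] = maps
            base = one_sample_t(maps, info={"spec": name, "speed": speed,
                                            "n": len(maps)})
            sm = permutation_fwe(maps, base, n_perm=n_perm,
                                 seed=seed, two_sided=True)
            results[(name, speed)] = GroupResult(
                spec=spec, statmap=sm,
                peaks=peak_table(sm, cohort.atlas, _affine(cohort), alpha))

    # speed specificity of the interaction contrast via exclusive masking
    for speed, other in (("fast", "slow"), ("slow", "fast")):
        res = results[("CxS_SD", speed)]
        other_maps = subject_maps[("CxS_SD", other)]
        other_t = one_sample_t(other_maps, info={"spec": "CxS_SD",
                                                 "speed": other})
        masked = exclusive_mask(res.statmap, other_t)
        res.masked = masked
        res.masked_peaks = peak_table(masked, cohort.atlas, _affine(cohort),
                                      alpha)
    return results


def joint_speed_fwe(cohort: Cohort, fl: FirstLevelMaps, name: str,
                    n_perm: int = 1000, seed: int = 0) -> StatMap:
    """Single maxT family for one anchored contrast across both speed ranges.

    Subject fast- and slow-range anchored volumes are concatenated so the
    permutation maximum is taken over the joint voxel set, giving one
    family-wise error rate for the question "does this contrast detect
    anything in either speed range".
    """
    sd_prof = cohort.sleepiness_profile("SD")
    np_prof = cohort.sleepiness_profile("NP")
    joint = None
    for speed in SPEEDS:
        spec = make_contrast_specs(sd_prof, np_prof, speed=speed)[name]
        maps = [m.ravel() for m in subject_anchored_maps(cohort, fl, spec)]
        arr = np.stack(maps)
        joint = arr if joint is None else np.concatenate([joint, arr], axis=1)
    base = one_sample_t(list(joint), info={"spec": name, "speed": "joint"})
    return permutation_fwe(list(joint), base, n_perm=n_perm, seed=seed,
                           two_sided=True)


def group_covariate_analysis(cohort: Cohort, fl: FirstLevelMaps,
                             covariate_name: str, spec: ContrastSpec,
                             n_perm: int = 1000, seed: int = 0,
                             alpha: float = 0.05) -> GroupResult:
    """Slope test of subject anchored maps on a marker covariate.

    Marker values come from the measured marker table (delta rebound from
    the sleep EEG, circadian strength from the hypnograms); excluded
    subjects are removed.
    """
    mt = compute_marker_table(cohort)
    inc = mt.included().set_index("subject_id")
    maps, cov = [], []
    for params in cohort.subjects:
        if params.subject_id not in inc.index:
            continue
        sess_maps = [fl.maps.get((params.subject_id, spec.condition, s,
                                  spec.speed)) for s in range(5)]
        maps.append(apply_anchored_contrast(sess_maps, spec))
        cov.append(float(inc.loc[params.subject_id, covariate_name]))
    from .inference import covariate_slope_t
    base = covariate_slope_t(maps, cov, info={"spec": spec.name,
                                              "speed": spec.speed,
                                              "covariate": covariate_name})
    sm = permutation_fwe(maps, base, n_perm=n_perm, seed=seed,
                         covariate=cov, two_sided=True)
    return GroupResult(spec=spec, statmap=sm,
                       peaks=peak_table(sm, cohort.atlas, _affine(cohort),
                                        alpha))


def compute_marker_table(cohort: Cohort):
    """Measured per-subject markers (not the planted truths)."""
    sids, rebs, circs = [], [], []
    for params in cohort.subjects:
        key_b = (params.subject_id, "baseline")
        key_r = (params.subject_id, "recovery")
        if key_b not in cohort.eeg or params.subject_id not in cohort.hypnograms:
            continue
        reb = delta_rebound(nrem_delta_power(cohort.eeg[key_b]),
                            nrem_delta_power(cohort.eeg[key_r]))
        cs = circadian_strength(cohort.hypnograms[params.subject_id],
                                cohort.schedules["NP"])
        sids.append(params.subject_id)
        rebs.append(reb)
        circs.append(cs)
    return build_marker_table(sids, rebs, circs)


def behavioral_tables(cohort: Cohort, n_perm: int = 2000, seed: int = 0):
    """Summary table plus the two sleepiness profiles."""
    summary = behavior.behavioral_summary(cohort.kss_table, cohort.rt_table(),
                                          n_perm=n_perm, seed=seed)
    return summary, cohort.sleepiness_profile("SD"), cohort.sleepiness_profile("NP")


def _affine(cohort: Cohort) -> np.ndarray:
    from .bold import make_affine
    return make_affine(cohort.atlas.shape)
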
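"""Calibration and validation studies run on the generative model.

Each function simulates groups of subjects under a controlled regime and
pushes them through the real analysis code, returning summary statistics:

* :func:`null_calibration` — no sequence signal at all; checks that the three
  decoders' group t-tests reject at the nominal rate and that mean z is zero.
* :func:`feature_specificity` — signal in exactly one component (order,
  timing, or their interaction); checks that only the matched decoder picks
  it up, the computational content of factorized cross-decoding.
* :func:`crossnobis_null` — identical condition patterns; checks the
  cross-validated distance estimator is unbiased.
* :func:`switch_recovery` — the cross-phase geometry contrast: groups whose
  production patterns are redrawn (switch) versus reused (no switch), each
  tested against a matched simulated no-switch baseline.
* :func:`searchlight_localization` — a localized order signal inside a
  volume; checks that the peak of the searchlight decoding map falls in the
  signal region.

Problem sizes default to deliberately scaled-down regimes (documented in the
package methods note) so the full battery runs in minutes on one CPU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datasets import PREPARATION, VolumeMask
from .decoding import (
    crossvalidated_accuracy,
    make_factorized_folds,
    make_integrated_folds,
    remove_marginal_means,
)
from .datasets import complete_design_labels
from .geometry import (
    crossnobis_rdm,
    cross_phase_statistic,
    simulate_cross_phase_baseline,
    test_against_baseline,
)
from .searchlight import define_searchlights, run_searchlight
from .simulate import (
    SimulationConfig,
    embed_in_volume,
    simulate_subject_patterns,
)
from .stats import one_sample_t

DECODERS = ("order", "timing", "integrated")


def _decoder_folds(n_runs: int, phase: str = PREPARATION) -> dict:
    labels = complete_design_labels(n_runs)
    return {
        "order": make_factorized_folds(labels, "order", phase),
        "timing": make_factorized_folds(labels, "timing", phase),
        "integrated": make_integrated_folds(labels, phase),
    }


def _decode_all(ds, folds, shrinkage="auto") -> dict[str, float]:
    """z score of each decoder on the preparation phase of one subject."""
    z = {}
    for name in ("order", "timing"):
        z[name] = crossvalidated_accuracy(ds, folds[name], shrinkage).z_score
    residual = remove_marginal_means(ds)
    z["integrated"] = crossvalidated_accuracy(
        residual, folds["integrated"], shrinkage
    ).z_score
    return z


@dataclass
class DecoderSummary:
    mean_z: float
    rejection_rate: float
    n_reps: int


def _group_decoding_study(
    cfg: SimulationConfig,
    n_reps: int,
    n_subjects: int,
    alpha: float,
    seed: int,
    shrinkage: float | str = "auto",
) -> dict[str, DecoderSummary]:
    folds = _decoder_folds(cfg.n_runs)
    rejections = {d: 0 for d in DECODERS}
    z_sums = {d: 0.0 for d in DECODERS}
    children = np.random.SeedSequence(seed).spawn(n_reps)
    for child in children:
        subject_rngs = child.spawn(n_subjects)
        zs = {d: np.empty(n_subjects) for d in DECODERS}
        for s, srng in enumerate(subject_rngs):
            ds = simulate_subject_patterns(cfg, rng=np.random.default_rng(srng))
            for d, z in _decode_all(ds, folds, shrinkage).items():
                zs[d][s] = z
        for d in DECODERS:
            res = one_sample_t(zs[d], mu=0.0, tails="one")
            rejections[d] += int(res.p_uncorrected < alpha)
            z_sums[d] += float(zs[d].mean())
    return {
        d: DecoderSummary(
            mean_z=z_sums[d] / n_reps,
            rejection_rate=rejections[d] / n_reps,
            n_reps=n_reps,
        )
        for d in DECODERS
    }


def null_calibration(
    n_reps: int = 1000,
    n_subjects: int = 12,
    n_voxels: int = 40,
    n_runs: int = 6,
    var_e: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, DecoderSummary]:
    """Decoding under a signal-free model: nominal type-I rate and zero z."""
    cfg = SimulationConfig(
        n_voxels=n_voxels,
        n_runs=n_runs,
        var_s=0.0,
        var_t=0.0,
        var_i=0.0,
        var_r=1.0,
        var_e_prep=var_e,
        var_e_prod=var_e,
        phase_offset=0.0,
    )
    return _group_decoding_study(cfg, n_reps, n_subjects, alpha, seed)


def feature_specificity(
    signal: str,
    snr: float = 0.5,
    n_reps: int = 100,
    n_subjects: int = 24,
    n_voxels: int = 40,
    n_runs: int = 6,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, DecoderSummary]:
    """Decoding with signal confined to one component of the model.

    ``signal`` is 'order' (s only), 'timing' (t only) or 'integrated'
    (interaction i only); the noise variance is set so the component-to-
    residual SNR equals ``snr`` (run-effect variance 0 to keep the ratio
    exact).
    """
    if signal not in DECODERS:
        raise ValueError(f"signal must be one of {DECODERS}")
    variances = {"var_s": 0.0, "var_t": 0.0, "var_i": 0.0}
    variances[{"order": "var_s", "timing": "var_t", "integrated": "var_i"}[signal]] = 1.0
    cfg = SimulationConfig(
        n_voxels=n_voxels,
        n_runs=n_runs,
        var_r=0.0,
        var_e_prep=1.0 / snr,
        var_e_prod=1.0 / snr,
        phase_offset=0.0,
        **variances,
    )
    return _group_decoding_study(cfg, n_reps, n_subjects, alpha, seed)


@dataclass
class CrossnobisNullSummary:
    mean: float
    se: float
    n_sims: int

    @property
    def mean_over_se(self) -> float:
        return abs(self.mean) / self.se


def crossnobis_null(
    n_sims: int = 500,
    n_voxels: int = 40,
    n_runs: int = 6,
    var_e: float = 1.0,
    seed: int = 0,
) -> CrossnobisNullSummary:
    """Mean crossnobis distance between conditions with identical patterns."""
    cfg = SimulationConfig(
        n_voxels=n_voxels,
        n_runs=n_runs,
        var_s=0.0,
        var_t=0.0,
        var_i=0.0,
        var_r=1.0,
        var_e_prep=var_e,
        var_e_prod=var_e,
        phase_offset=0.0,
    )
    children = np.random.SeedSequence(seed).spawn(n_sims)
    vals = np.empty(n_sims)
    iu = None
    for s, child in enumerate(children):
        ds = simulate_subject_patterns(cfg, rng=np.random.default_rng(child))
        rdm = crossnobis_rdm(ds, shrinkage=0.4)
        if iu is None:
            iu = np.triu_indices(len(rdm.conditions), k=1)
        vals[s] = rdm.distances[iu].mean()
    return CrossnobisNullSummary(
        mean=float(vals.mean()),
        se=float(vals.std(ddof=1) / math.sqrt(n_sims)),
        n_sims=n_sims,
    )


@dataclass
class SwitchRecoverySummary:
    baseline_mean: float
    switch_mean: float
    noswitch_mean: float
    rejection_rate_switch: float
    rejection_rate_noswitch: float
    n_group_reps: int


def switch_recovery(
    n_group_reps: int = 200,
    n_subjects: int = 24,
    n_voxels: int = 160,
    n_runs: int = 6,
    snr_prep: float = 0.5,
    snr_prod: float = 1.0,
    n_baseline_sims: int = 200,
    alpha: float = 0.05 / 7,
    shrinkage: float | str = "auto",
    seed: int = 0,
) -> SwitchRecoverySummary:
    """Cross-phase statistic of switch vs no-switch groups against baseline.

    Each group repetition simulates ``n_subjects`` subjects, computes the
    normalized cross-phase distance per subject and tests the group one-sided
    against the matched simulated no-switch baseline mean at ``alpha``
    (default 0.05 Bonferroni-corrected for seven regions).
    """
    root = np.random.SeedSequence(seed)
    s_base, s_groups = root.spawn(2)
    baseline = simulate_cross_phase_baseline(
        n_voxels,
        n_runs,
        snr_prep,
        snr_prod,
        switch=False,
        n_sims=n_baseline_sims,
        shrinkage=shrinkage,
        seed=s_base.generate_state(1)[0] % (2**31),
    )
    cfgs = {
        sw: SimulationConfig.from_snr(
            snr_prep, snr_prod, n_voxels=n_voxels, n_runs=n_runs, switch=sw
        )
        for sw in (False, True)
    }
    rej = {False: 0, True: 0}
    means = {False: 0.0, True: 0.0}
    for group_seed in s_groups.spawn(n_group_reps):
        for sw in (False, True):
            vals = np.empty(n_subjects)
            for s, srng in enumerate(group_seed.spawn(n_subjects)):
                ds = simulate_subject_patterns(
                    cfgs[sw], rng=np.random.default_rng(srng)
                )
                vals[s] = cross_phase_statistic(
                    ds, shrinkage=shrinkage
                ).normalized_distance
            res = test_against_baseline(vals, baseline.mean, bonferroni_m=1)
            rej[sw] += int(res.p_uncorrected < alpha)
            means[sw] += float(vals.mean())
    return SwitchRecoverySummary(
        baseline_mean=baseline.mean,
        switch_mean=means[True] / n_group_reps,
        noswitch_mean=means[False] / n_group_reps,
        rejection_rate_switch=rej[True] / n_group_reps,
        rejection_rate_noswitch=rej[False] / n_group_reps,
        n_group_reps=n_group_reps,
    )


@dataclass
class LocalizationSummary:
    hit_rate: float
    n_sims: int
    mask_voxels: int
    signal_voxels: int


def _signal_cube_mask(mask_shape, cube_shape, voxel_size) -> tuple[VolumeMask, VolumeMask]:
    grid = np.ones(mask_shape, dtype=bool)
    sig = np.zeros(mask_shape, dtype=bool)
    starts = [(m - c) // 2 for m, c in zip(mask_shape, cube_shape)]
    sl = tuple(slice(s, s + c) for s, c in zip(starts, cube_shape))
    sig[sl] = True
    return (
        VolumeMask(grid, voxel_size),
        VolumeMask(sig, voxel_size),
    )


def searchlight_localization(
    n_sims: int = 50,
    mask_shape: tuple[int, int, int] = (10, 10, 10),
    signal_shape: tuple[int, int, int] = (4, 4, 4),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    max_radius_mm: float = 4.0,
    target_size: int = 160,
    n_runs: int = 6,
    var_e: float = 1.0,
    seed: int = 0,
    shrinkage: float | str = "auto",
) -> LocalizationSummary:
    """Does the peak of the order-decoding searchlight map land on the signal?

    The volume is noise everywhere except a central cube carrying a full
    order/timing signal.  Per simulation the order decoder is mapped over all
    searchlights; a hit is scored when the center of mass of the top half of
    the z map (z >= 0.5 * max) falls inside the signal cube's bounding box.
    """
    mask, signal_region = _signal_cube_mask(mask_shape, signal_shape, voxel_size)
    n_signal = signal_region.n_voxels
    cfg = SimulationConfig(
        n_voxels=n_signal,
        n_runs=n_runs,
        var_s=1.0,
        var_t=1.0,
        var_i=0.0,
        var_r=0.5,
        var_e_prep=var_e,
        var_e_prod=var_e,
        phase_offset=0.0,
    )
    searchlights = define_searchlights(mask, target_size, max_radius_mm)
    folds = make_factorized_folds(
        complete_design_labels(n_runs), "order", PREPARATION
    )

    def order_z(sub):
        return crossvalidated_accuracy(sub, folds, shrinkage).z_score

    sig_coords = signal_region.coordinates()
    lo, hi = sig_coords.min(axis=0), sig_coords.max(axis=0)
    hits = 0
    for child in np.random.SeedSequence(seed).spawn(n_sims):
        rng = np.random.default_rng(child)
        ds = simulate_subject_patterns(cfg, rng=rng)
        vol = embed_in_volume(ds, mask, signal_region, rng=rng)
        zmap = run_searchlight(vol, mask, searchlights, order_z)
        finite = np.nan_to_num(zmap, nan=-np.inf)
        top = np.clip(zmap, 0.0, None)
        top[~np.isfinite(zmap)] = 0.0
        top[finite < 0.5 * finite.max()] = 0.0
        if top.sum() <= 0:
            continue
        com = np.asarray(ndimage.center_of_mass(top))
        if np.all(com >= lo - 0.5) and np.all(com <= hi + 0.5):
            hits += 1
    return LocalizationSummary(
        hit_rate=hits / n_sims,
        n_sims=n_sims,
        mask_voxels=mask.n_voxels,
        signal_voxels=n_signal,
    )
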
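"""Generative model of condition-by-run voxel patterns.

The simulated activation of the sequence with order ``i`` and timing ``j`` in
run ``k`` is the additive pattern

    y_ijk = s_i + t_j + i_ij + r_k + e_ijk

where every component is an independent zero-mean normal random vector over
the voxels: ``s`` codes the spatial (finger order) feature, ``t`` the temporal
(timing) feature, ``i`` their non-additive integration, ``r`` a run-wide
offset shared by all conditions of the run (both phases; the two phases are
estimated from the same imaging run), and ``e`` fresh measurement noise per
pattern row.  Production-phase patterns either reuse the preparation draws of
``s``/``t``/``i`` (no switch; optionally rescaled by ``prod_scale``) or use
independent draws (switch), and receive a uniform activity offset that mimics
the large phase-related activity change seen in real data.

Signal-to-noise ratio (SNR) is defined against the condition-mean patterns:
the cross-run covariance of a condition's patterns estimates the signal
variance var_s + var_t + var_i, while the within-condition across-run residual
variance estimates var_r + var_e; the SNR is their ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import (
    PatternDataset,
    PREPARATION,
    PRODUCTION,
    VolumeMask,
    canonical_phase,
    complete_design_labels,
)


class InvalidConfigError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative pattern model.

    Variances are per voxel.  ``phase_offset`` is a uniform mean shift added
    to every production-phase voxel; the default (5 signal SDs) dominates the
    sequence-level structure so that the leading principal component of the
    simulated geometry reflects phase, as in real data.
    """

    n_voxels: int = 160
    n_runs: int = 6
    var_s: float = 1.0
    var_t: float = 1.0
    var_i: float = 1.0
    var_r: float = 1.0
    var_e_prep: float = 5.0
    var_e_prod: float = 5.0
    phase_offset: float = 5.0
    switch: bool = False
    prod_scale: float = 1.0
    seed: int = 0
    n_subjects: int = 24

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise InvalidConfigError("n_voxels must be a positive integer")
        if self.n_runs < 1:
            raise InvalidConfigError("n_runs must be a positive integer")
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be a positive integer")
        for name in ("var_s", "var_t", "var_i", "var_r", "var_e_prep", "var_e_prod"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if self.prod_scale <= 0:
            raise InvalidConfigError("prod_scale must be strictly positive")

    @property
    def signal_variance(self) -> float:
        return self.var_s + self.var_t + self.var_i

    @classmethod
    def from_snr(
        cls,
        snr_prep: float,
        snr_prod: float | None = None,
        **kwargs,
    ) -> "SimulationConfig":
        """Build a config whose noise level hits a target preparation SNR.

        ``var_e`` is set so that signal / (var_r + var_e) equals ``snr_prep``;
        the production signal is scaled by sqrt(snr_prod / snr_prep) so the
        measured production SNR equals ``snr_prod`` (noise variance is kept
        equal across phases).
        """
        if snr_prep <= 0:
            raise InvalidConfigError("snr_prep must be strictly positive")
        snr_prod = snr_prep if snr_prod is None else snr_prod
        if snr_prod <= 0:
            raise InvalidConfigError("snr_prod must be strictly positive")
        probe = cls(**{**kwargs, "var_e_prep": 0.0, "var_e_prod": 0.0})
        var_e = probe.signal_variance / snr_prep - probe.var_r
        if var_e < 0:
            raise InvalidConfigError(
                f"target SNR {snr_prep} unreachable with var_r={probe.var_r}; "
                "lower var_r or the target"
            )
        return replace(
            probe,
            var_e_prep=var_e,
            var_e_prod=var_e,
            prod_scale=math.sqrt(snr_prod / snr_prep),
        )


def _component_draws(rng: np.random.Generator, cfg: SimulationConfig) -> dict:
    """Draw one phase's worth of s, t and i component vectors."""
    P = cfg.n_voxels
    return {
        "s": rng.normal(0.0, math.sqrt(cfg.var_s), size=(2, P)),
        "t": rng.normal(0.0, math.sqrt(cfg.var_t), size=(2, P)),
        "i": rng.normal(0.0, math.sqrt(cfg.var_i), size=(2, 2, P)),
    }


def simulate_subject_patterns(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> PatternDataset:
    """Simulate one subject's complete design (n_runs x 8 rows)."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    P = cfg.n_voxels
    prep = _component_draws(rng, cfg)
    if cfg.switch:
        prod = _component_draws(rng, cfg)
    else:
        prod = prep
    run_effects = rng.normal(0.0, math.sqrt(cfg.var_r), size=(cfg.n_runs, P))

    labels = complete_design_labels(cfg.n_runs)
    patterns = np.empty((len(labels), P))
    noise_sd = {
        PREPARATION: math.sqrt(cfg.var_e_prep),
        PRODUCTION: math.sqrt(cfg.var_e_prod),
    }
    for row, lab in enumerate(labels.itertuples(index=False)):
        o, t = int(lab.order) - 1, int(lab.timing) - 1
        comp = prep if lab.phase == PREPARATION else prod
        signal = comp["s"][o] + comp["t"][t] + comp["i"][o, t]
        if lab.phase == PRODUCTION:
            signal = cfg.prod_scale * signal + cfg.phase_offset
        patterns[row] = (
            signal
            + run_effects[int(lab.run) - 1]
            + rng.normal(0.0, noise_sd[lab.phase], size=P)
        )
    return PatternDataset(patterns, labels)


def simulate_group(cfg: SimulationConfig) -> list[PatternDataset]:
    """Simulate ``cfg.n_subjects`` independent subjects, seeded from cfg.seed."""
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)
    return [
        simulate_subject_patterns(cfg, rng=np.random.default_rng(child))
        for child in children
    ]


def _condition_stacks(ds: PatternDataset, phase: str) -> np.ndarray:
    """Patterns of one phase stacked as (condition, run, voxel)."""
    sub = ds.select(phase=phase)
    runs = sub.runs
    if len(runs) < 2:
        raise InsufficientDataError("SNR estimation needs at least two runs")
    stacks = []
    for o in (1, 2):
        for t in (1, 2):
            rows = []
            for k in runs:
                sel = (
                    (sub.labels["order"] == o)
                    & (sub.labels["timing"] == t)
                    & (sub.labels["run"] == k)
                ).to_numpy()
                if sel.sum() != 1:
                    raise InsufficientDataError(
                        f"condition (order={o}, timing={t}) missing in run {k}"
                    )
                rows.append(sub.patterns[sel][0])
            stacks.append(np.stack(rows))
    return np.stack(stacks)


def estimate_snr(ds: PatternDataset, phase: str) -> float:
    """Signal-to-noise ratio of one phase's condition patterns.

    Signal variance is estimated as the covariance (over voxels) between the
    same condition's patterns in different runs, averaged over conditions and
    run pairs; residual variance as the per-voxel variance across runs within
    condition.  The ratio is clipped at zero; a noiseless dataset returns inf.
    """
    stacks = _condition_stacks(ds, canonical_phase(phase))
    n_cond, n_runs, P = stacks.shape
    covs = []
    for c in range(n_cond):
        centered = stacks[c] - stacks[c].mean(axis=1, keepdims=True)
        gram = centered @ centered.T / (P - 1)
        iu = np.triu_indices(n_runs, k=1)
        covs.append(gram[iu].mean())
    signal = float(np.mean(covs))
    resid = float(np.mean(np.var(stacks, axis=1, ddof=1)))
    # round-off from the run-mean subtraction can leave ~1e-32 residuals in
    # genuinely noiseless data
    if resid <= 1e-12 * max(abs(signal), 1.0):
        return math.inf
    return max(signal, 0.0) / resid


def residual_variance(ds: PatternDataset, phase: str) -> float:
    """Within-condition across-run residual variance of one phase."""
    stacks = _condition_stacks(ds, canonical_phase(phase))
    return float(np.mean(np.var(stacks, axis=1, ddof=1)))


def embed_in_volume(
    ds: PatternDataset,
    mask: VolumeMask,
    signal_region: VolumeMask | None,
    rng: np.random.Generator | int | None = None,
) -> PatternDataset:
    """Place a dataset's voxels inside a 3-D mask for searchlight analyses.

    The first ``signal_region.n_voxels`` columns of ``ds`` are assigned to the
    signal-region voxels (lexicographic order); the remaining in-mask voxels
    receive pure noise whose variance matches the dataset's within-condition
    across-run residual variance per phase.  ``signal_region=None`` yields a
    noise-only volume.
    """
    if signal_region is not None and not mask.contains(signal_region):
        raise ValueError("signal_region must be contained in the mask")
    n_signal = signal_region.n_voxels if signal_region is not None else 0
    if n_signal > ds.n_voxels:
        raise ValueError(
            f"signal_region has {n_signal} voxels but the dataset only "
            f"provides {ds.n_voxels}"
        )
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    coords = mask.coordinates()
    n_total = len(coords)
    sig_set = (
        {tuple(c) for c in signal_region.coordinates()}
        if signal_region is not None
        else set()
    )
    is_signal = np.array([tuple(c) in sig_set for c in coords])

    patterns = np.empty((ds.n_obs, n_total))
    if is_signal.any():
        patterns[:, is_signal] = ds.patterns[:, : int(is_signal.sum())]
    noise_cols = ~is_signal
    if noise_cols.any():
        sd = np.empty(ds.n_obs)
        for phase in ds.labels["phase"].unique():
            rows = (ds.labels["phase"] == phase).to_numpy()
            try:
                var = residual_variance(ds, phase)
            except InsufficientDataError:
                var = float(np.var(ds.patterns[rows]))
            sd[rows] = math.sqrt(var)
        patterns[:, noise_cols] = rng.normal(
            0.0, 1.0, size=(ds.n_obs, int(noise_cols.sum()))
        ) * sd[:, None]
    return PatternDataset(patterns, ds.labels.copy(), voxel_coordinates=coords)
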
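"""Prewhitened representational geometry of sequence patterns.

The route mirrors standard representational similarity analysis practice:

1. estimate a regularized voxel noise covariance from within-condition,
   across-run residuals and prewhiten patterns with its inverse principal
   square root;
2. compute cross-validated Mahalanobis (crossnobis) distances between the
   eight (sequence x phase) conditions — unbiased, so distances between
   identical conditions scatter around zero and may be negative;
3. embed run-averaged whitened condition means by classical (Torgerson) MDS;
4. summarize the planning-to-execution geometry change as the mean Euclidean
   distance between each sequence's preparation and production coordinates on
   components 2-3 (component 1 absorbs the large phase activity offset),
   normalized by the grand mean of the k(k-1)/2 within-phase pairwise
   distances in the same subspace.

Because noise alone biases the cross-phase distance upward, the statistic is
referred to a *no-switch* baseline: the identical pipeline applied to
simulated data whose production patterns reuse the preparation distributions,
with voxel count, run count and per-phase SNR matched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datasets import PatternDataset, PHASES, PREPARATION, PRODUCTION
from .decoding import analytic_shrinkage
from .simulate import (
    InsufficientDataError,
    SimulationConfig,
    simulate_subject_patterns,
)
from .stats import GroupStatResult, one_sample_t

#: canonical ordering of the eight (order, timing, phase) conditions
CONDITION_ORDER = [
    (o, t, p) for p in (PREPARATION, PRODUCTION) for o in (1, 2) for t in (1, 2)
]


@dataclass
class NoiseCovariance:
    """Regularized voxel noise covariance and its whitening transform."""

    covariance: np.ndarray
    shrinkage_intensity: float
    whitener: np.ndarray  # inverse principal square root of covariance


@dataclass
class RDM:
    """Condition-by-condition cross-validated dissimilarities."""

    conditions: list[tuple]
    distances: np.ndarray

    def value(self, cond_a: tuple, cond_b: tuple) -> float:
        ia, ib = self.conditions.index(cond_a), self.conditions.index(cond_b)
        return float(self.distances[ia, ib])


@dataclass
class MDSEmbedding:
    """Classical MDS coordinates of condition patterns."""

    coordinates: np.ndarray  # (n_conditions, n_components)
    eigenvalues: np.ndarray  # nonincreasing, clipped at zero
    variance_explained: np.ndarray
    conditions: list[tuple] = field(default_factory=list)

    def phase_coords(self, order: int, timing: int, phase: str) -> np.ndarray:
        idx = self.conditions.index((order, timing, phase))
        return self.coordinates[idx]


@dataclass
class CrossPhaseResult:
    """Normalized planning-to-execution distance for one dataset."""

    per_sequence_distance: np.ndarray  # (4,)
    within_phase_grand_mean: float
    normalized_distance: float


@dataclass
class BaselineSummary:
    """Distribution of the normalized statistic over simulated subjects."""

    mean: float
    sd: float
    values: np.ndarray
    switch: bool
    n_sims: int


def estimate_noise_covariance(
    ds: PatternDataset, shrinkage: float | str = "auto"
) -> NoiseCovariance:
    """Noise covariance from within-condition, across-run residuals.

    The pooled residual covariance is shrunk toward its diagonal with
    intensity ``shrinkage`` ('auto' = analytic estimate).  The whitener is the
    inverse principal square root, so whitened residuals have approximately
    identity covariance.
    """
    lab = ds.labels
    runs_per_cond = lab.groupby(["order", "timing", "phase"])["run"].nunique()
    if (runs_per_cond < 2).all():
        raise InsufficientDataError(
            "noise covariance needs at least two runs per condition"
        )
    resid_rows = []
    n_conditions = 0
    for _, idx in lab.groupby(["order", "timing", "phase"]).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        block = ds.patterns[idx]
        resid_rows.append(block - block.mean(axis=0))
        n_conditions += 1
    R = np.vstack(resid_rows)
    df = max(R.shape[0] - n_conditions, 1)
    S = R.T @ R / df
    P = S.shape[0]
    diag = np.diag(S).copy()
    if np.any(diag <= 0):
        floor = max(float(diag.max()), 1.0) * 1e-8
        warnings.warn(
            "zero residual variance in some voxels; flooring the diagonal",
            RuntimeWarning,
        )
        diag = np.maximum(diag, floor)
    lam = analytic_shrinkage(R) if shrinkage == "auto" else float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")
    cov = (1.0 - lam) * S
    np.fill_diagonal(cov, diag)
    w, V = np.linalg.eigh(cov)
    w = np.maximum(w, max(float(w.max()), 1e-12) * 1e-10)
    whitener = (V / np.sqrt(w)) @ V.T
    return NoiseCovariance(cov, lam, whitener)


def whiten(ds: PatternDataset, noise: NoiseCovariance) -> PatternDataset:
    """Apply the whitening transform to every pattern row."""
    return PatternDataset(
        ds.patterns @ noise.whitener.T, ds.labels.copy(), ds.voxel_coordinates
    )


def _condition_run_stack(ds: PatternDataset) -> tuple[np.ndarray, np.ndarray]:
    """Whitened-or-raw patterns as (condition, run, voxel), canonical order."""
    runs = ds.runs
    stacks = np.empty((len(CONDITION_ORDER), len(runs), ds.n_voxels))
    lab = ds.labels
    for c, (o, t, p) in enumerate(CONDITION_ORDER):
        for r, k in enumerate(runs):
            sel = (
                (lab["order"] == o)
                & (lab["timing"] == t)
                & (lab["phase"] == p)
                & (lab["run"] == k)
            ).to_numpy()
            if sel.sum() != 1:
                raise InsufficientDataError(
                    f"condition {(o, t, p)} missing in run {k}"
                )
            stacks[c, r] = ds.patterns[sel][0]
    return stacks, runs


def crossnobis_rdm(
    ds: PatternDataset,
    noise: NoiseCovariance | None = None,
    shrinkage: float | str = "auto",
) -> RDM:
    """Cross-validated Mahalanobis distances between the 8 conditions.

    For conditions a, b the distance is the mean over ordered run pairs
    (m != n) of ``(x_a^m - x_b^m)' Sigma^-1 (x_a^n - x_b^n) / P`` — computed
    on whitened patterns as a plain cross-run inner product.

    With ``noise=None`` (the default) the whitener itself is cross-validated:
    for every run pair it is re-estimated from the *remaining* runs only, so
    each cross-run product involves two pattern differences that are mutually
    independent and independent of the whitener, making the estimator exactly
    unbiased (expectation zero for conditions with identical true patterns).
    Passing a fixed :class:`NoiseCovariance` skips that fold structure; note
    that a whitener estimated from the same runs couples with the pattern
    noise and biases the distances upward.
    """
    stacks, runs = _condition_run_stack(ds)
    K = len(runs)
    if K < 2:
        raise InsufficientDataError("crossnobis needs at least two runs")
    P = ds.n_voxels
    n_cond = len(CONDITION_ORDER)
    D = np.zeros((n_cond, n_cond))
    n_pairs = 0
    use_loro = noise is None and K >= 4
    if noise is None and K < 4:
        warnings.warn(
            "fewer than 4 runs: whitener estimated from all runs, "
            "crossnobis distances may be positively biased",
            RuntimeWarning,
        )
    fixed = noise if noise is not None else (
        None if use_loro else estimate_noise_covariance(ds, shrinkage)
    )
    iu = np.triu_indices(n_cond, k=1)
    for m in range(K):
        for n in range(m + 1, K):
            if use_loro:
                keep = [runs[k] for k in range(K) if k not in (m, n)]
                pair_noise = estimate_noise_covariance(
                    ds.select(run=keep), shrinkage
                )
            else:
                pair_noise = fixed
            Wm = stacks[:, m] @ pair_noise.whitener.T  # (8, P)
            Wn = stacks[:, n] @ pair_noise.whitener.T
            dm = Wm[iu[0]] - Wm[iu[1]]
            dn = Wn[iu[0]] - Wn[iu[1]]
            D[iu] += np.einsum("cp,cp->c", dm, dn)
            n_pairs += 1
    D[iu] /= n_pairs * P
    D = D + D.T
    return RDM(list(CONDITION_ORDER), D)


def classical_mds(points: np.ndarray) -> MDSEmbedding:
    """Torgerson MDS of a point configuration given as (n_points, dim).

    The points are row-centered, the Gram matrix eigendecomposed, and
    coordinates formed as eigenvectors scaled by sqrt(eigenvalue); negative
    eigenvalues (possible when the input derives from cross-validated
    dissimilarities) are clipped to zero with a warning.
    """
    X = np.asarray(points, dtype=float)
    centered = X - X.mean(axis=0)
    gram = centered @ centered.T
    w, V = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(abs(float(w[0])), 1.0) * 1e-9
    if np.any(w < -tol):
        warnings.warn("negative MDS eigenvalues clipped to zero", RuntimeWarning)
    w = np.clip(w, 0.0, None)
    coords = V * np.sqrt(w)
    # numerically-null components carry pure round-off; zero them out
    coords[:, w <= max(float(w[0]), 1.0) * 1e-12] = 0.0
    total = float(w.sum())
    var_exp = w / total if total > 0 else np.zeros_like(w)
    return MDSEmbedding(coords, w, var_exp)


def mds_from_dataset(
    ds: PatternDataset, noise: NoiseCovariance | None = None,
    shrinkage: float | str = "auto",
) -> MDSEmbedding:
    """Whiten, run-average the 8 condition means, and embed them by MDS."""
    if noise is None:
        noise = estimate_noise_covariance(ds, shrinkage)
    wds = whiten(ds, noise)
    stacks, _ = _condition_run_stack(wds)
    means = stacks.mean(axis=1)  # (8, P)
    emb = classical_mds(means)
    emb.conditions = list(CONDITION_ORDER)
    return emb


def cross_phase_distance(emb: MDSEmbedding) -> np.ndarray:
    """Per-sequence prep-to-production Euclidean distance on components 2-3."""
    if emb.coordinates.shape[1] < 3:
        raise ValueError("embedding needs at least three components")
    if not emb.conditions:
        raise ValueError("embedding carries no condition labels")
    dists = []
    for o in (1, 2):
        for t in (1, 2):
            try:
                a = emb.phase_coords(o, t, PREPARATION)[1:3]
                b = emb.phase_coords(o, t, PRODUCTION)[1:3]
            except ValueError as exc:
                raise ValueError(
                    f"sequence (order={o}, timing={t}) lacks a phase"
                ) from exc
            dists.append(float(np.linalg.norm(a - b)))
    return np.asarray(dists)


def normalize_cross_phase(emb: MDSEmbedding) -> CrossPhaseResult:
    """Cross-phase distance scaled by within-phase representational spread.

    The denominator is the grand mean of the 4*(4-1)/2 pairwise distances
    between sequences within preparation plus the 6 within production, all
    restricted to components 2-3 like the numerator.
    """
    cross = cross_phase_distance(emb)
    within = []
    for phase in PHASES:
        coords = np.stack(
            [emb.phase_coords(o, t, phase)[1:3] for o in (1, 2) for t in (1, 2)]
        )
        for a in range(4):
            for b in range(a + 1, 4):
                within.append(float(np.linalg.norm(coords[a] - coords[b])))
    grand = float(np.mean(within))
    if grand == 0.0:
        raise ZeroDivisionError(
            "within-phase grand mean distance is zero; normalization undefined"
        )
    return CrossPhaseResult(cross, grand, float(cross.mean()) / grand)


def cross_phase_statistic(
    ds: PatternDataset, shrinkage: float | str = "auto"
) -> CrossPhaseResult:
    """Full per-subject pipeline: whiten, MDS, normalized cross-phase distance."""
    return normalize_cross_phase(mds_from_dataset(ds, shrinkage=shrinkage))


def simulate_cross_phase_baseline(
    n_voxels: int,
    n_runs: int,
    snr_prep: float,
    snr_prod: float,
    switch: bool,
    n_sims: int = 200,
    phase_offset: float = 5.0,
    var_r: float = 1.0,
    shrinkage: float | str = "auto",
    seed: int = 0,
) -> BaselineSummary:
    """Distribution of the normalized statistic under a simulated regime.

    Runs the generative model with matched voxel count, run count and
    per-phase SNR (production signal scaled by the prep-to-production SNR
    ratio) through the full whiten/MDS/normalize pipeline for ``n_sims``
    independent simulated subjects.  ``switch=False`` gives the noise-driven
    positive baseline the empirical statistic is tested against.
    """
    cfg = SimulationConfig.from_snr(
        snr_prep,
        snr_prod,
        n_voxels=n_voxels,
        n_runs=n_runs,
        switch=switch,
        phase_offset=phase_offset,
        var_r=var_r,
        seed=seed,
    )
    children = np.random.SeedSequence(seed).spawn(n_sims)
    values = np.empty(n_sims)
    for s, child in enumerate(children):
        ds = simulate_subject_patterns(cfg, rng=np.random.default_rng(child))
        values[s] = cross_phase_statistic(ds, shrinkage=shrinkage).normalized_distance
    return BaselineSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        values=values,
        switch=switch,
        n_sims=n_sims,
    )


def test_against_baseline(
    values: np.ndarray,
    baseline_mean: float,
    bonferroni_m: int = 7,
) -> GroupStatResult:
    """One-sided group t-test of subject statistics against a baseline mean."""
    return one_sample_t(values, mu=baseline_mean, tails="one", bonferroni_m=bonferroni_m)
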
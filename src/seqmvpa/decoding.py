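"""Factorized and integrated cross-validated LDA decoding of sequence features.

Three decoders operate on one trial phase of a complete 2x2 (order x timing)
design over runs:

* **order** — trained to separate the two finger orders under one timing
  level on all-but-one run, tested on the two orders under the *other* timing
  level in the held-out run.  Enumerating held-out runs and training timing
  levels gives 2 * n_runs folds (12 for the 6-run design).  Above-chance
  transfer therefore indicates an order representation that generalizes
  across the timing it was paired with.
* **timing** — the mirror-image scheme with the roles of order and timing
  exchanged.
* **integrated** — a 4-class leave-one-run-out decoder applied to the per-run
  two-way interaction residuals (order- and timing-marginal means removed),
  sensitive to sequence-unique, non-additive pattern structure.

Accuracies are pooled across folds and normalized to a z score under a
binomial model of the number of correct guesses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import DesignError, PatternDataset, canonical_phase

FEATURES = ("order", "timing")
CHANCE = {"order": 0.5, "timing": 0.5, "integrated": 0.25}


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class FoldSpec:
    """One train/test split with class labels per row."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_classes: np.ndarray
    test_classes: np.ndarray
    n_classes: int
    held_out_run: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("a fold needs at least two classes")
        if len(set(self.train_idx) & set(self.test_idx)):
            raise ValueError("train and test rows overlap")


@dataclass(frozen=True)
class DecodingResult:
    """Pooled cross-validated decoding outcome for one subject/decoder."""

    per_fold_correct: tuple[int, ...]
    n_total_guesses: int
    accuracy: float
    z_score: float
    chance: float


def _require_complete(labels: pd.DataFrame, phase: str) -> pd.DataFrame:
    phase = canonical_phase(phase)
    sub = labels[labels["phase"] == phase]
    if sub.empty:
        raise DesignError(f"no rows for phase {phase!r}")
    for run, grp in sub.groupby("run"):
        cells = set(zip(grp["order"], grp["timing"]))
        if cells != {(o, t) for o in (1, 2) for t in (1, 2)} or len(grp) != 4:
            raise DesignError(f"run {run} is not a complete 2x2 design in {phase}")
    if sub["run"].nunique() < 2:
        raise DesignError("cross-validation needs at least two runs")
    return sub


def make_factorized_folds(
    labels: pd.DataFrame, feature: str, phase: str
) -> list[FoldSpec]:
    """Cross-decoding folds for the order or timing classifier.

    Training uses one level of the *other* factor across all but one run; the
    test set is the held-out run at the other level of that factor, so correct
    transfer requires a representation invariant to the paired feature.
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    other = "timing" if feature == "order" else "order"
    sub = _require_complete(labels, phase)
    runs = sorted(sub["run"].unique())
    folds = []
    for held in runs:
        for train_level in (1, 2):
            test_level = 3 - train_level
            train_mask = (sub[other] == train_level) & (sub["run"] != held)
            test_mask = (sub[other] == test_level) & (sub["run"] == held)
            folds.append(
                FoldSpec(
                    train_idx=sub.index[train_mask].to_numpy(),
                    test_idx=sub.index[test_mask].to_numpy(),
                    train_classes=sub.loc[train_mask, feature].to_numpy(),
                    test_classes=sub.loc[test_mask, feature].to_numpy(),
                    n_classes=2,
                    held_out_run=int(held),
                    description=(
                        f"{feature}: train {other}={train_level} w/o run {held}, "
                        f"test {other}={test_level} run {held}"
                    ),
                )
            )
    return folds


def make_integrated_folds(labels: pd.DataFrame, phase: str) -> list[FoldSpec]:
    """Leave-one-run-out 4-class folds over all sequences of one phase."""
    sub = _require_complete(labels, phase)
    classes = ((sub["order"] - 1) * 2 + (sub["timing"] - 1)).to_numpy()
    runs = sorted(sub["run"].unique())
    folds = []
    for held in runs:
        train_mask = (sub["run"] != held).to_numpy()
        folds.append(
            FoldSpec(
                train_idx=sub.index[train_mask].to_numpy(),
                test_idx=sub.index[~train_mask].to_numpy(),
                train_classes=classes[train_mask],
                test_classes=classes[~train_mask],
                n_classes=4,
                held_out_run=int(held),
                description=f"integrated: test run {held}",
            )
        )
    return folds


def remove_marginal_means(
    ds: PatternDataset, phase: str | None = None
) -> PatternDataset:
    """Two-way interaction residuals per run (and phase), voxelwise.

    Within every (run, phase) cell the order-marginal and timing-marginal
    means are subtracted and the grand mean added back:
    ``y_ij - mean_i. - mean_.j + mean_..`` — the classical 2x2 ANOVA
    interaction residual.  Residuals have zero order- and timing-marginal
    means and purely additive inputs map to zero.
    """
    if phase is not None:
        ds = ds.select(phase=phase)
    ds.validate_complete_design()
    out = ds.patterns.copy()
    lab = ds.labels
    for (_, _), idx in lab.groupby(["run", "phase"]).groups.items():
        idx = np.asarray(idx)
        block = ds.patterns[idx]  # 4 rows
        orders = lab.loc[idx, "order"].to_numpy()
        timings = lab.loc[idx, "timing"].to_numpy()
        grand = block.mean(axis=0)
        for row, (o, t) in zip(range(len(idx)), zip(orders, timings)):
            order_mean = block[orders == o].mean(axis=0)
            timing_mean = block[timings == t].mean(axis=0)
            out[idx[row]] = block[row] - order_mean - timing_mean + grand
    return PatternDataset(out, lab.copy(), ds.voxel_coordinates)


# ---------------------------------------------------------------------------
# Gaussian LDA with diagonal-target shrinkage
# ---------------------------------------------------------------------------

def analytic_shrinkage(residuals: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the diagonal covariance target.

    Schaefer–Strimmer style estimate: the ratio of the summed sampling
    variances of the off-diagonal covariance entries to their summed squares,
    clipped to [0, 1].
    """
    R = np.asarray(residuals, dtype=float)
    n, p = R.shape
    if n < 2 or p < 2:
        return 1.0
    S = R.T @ R / (n - 1)
    # sum of Var_hat(s_ij) over all entries, then over the diagonal, using
    # sum_ij w_kij^2 = |r_k|^4 and sum_ij wbar_ij^2 = ((n-1)/n)^2 ||S||_F^2
    sq_norms = np.einsum("ki,ki->k", R, R)
    frob2_all = float(np.sum(S * S))
    scale = n**2 / (n - 1) ** 3
    var_all = scale * (
        float(sq_norms @ sq_norms) / n - ((n - 1) / n) ** 2 * frob2_all
    )
    diag = np.diag(S)
    frob2_diag = float(np.sum(diag**2))
    var_diag = scale * (
        float(np.sum(R**4)) / n - ((n - 1) / n) ** 2 * frob2_diag
    )
    denom = frob2_all - frob2_diag
    if denom <= 0:
        return 1.0
    return float(np.clip((var_all - var_diag) / denom, 0.0, 1.0))


@dataclass
class LDAModel:
    """Fitted Gaussian linear discriminant with pooled shrunk covariance."""

    classes: np.ndarray
    means: np.ndarray  # (n_classes, P)
    covariance: np.ndarray  # (P, P), after shrinkage
    shrinkage: float
    _weights: np.ndarray  # (P, n_classes) = Sigma^-1 mu_c
    _bias: np.ndarray  # (n_classes,)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self._weights + self._bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        # deterministic tie-break: argmax returns the lowest class index
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def train_lda(
    train_patterns: np.ndarray,
    train_classes: np.ndarray,
    shrinkage: float | str = "auto",
) -> LDAModel:
    """Fit equal-prior Gaussian LDA with a pooled, shrinkage-regularized
    voxel covariance.

    The covariance pooled over classes is shrunk toward its diagonal:
    ``(1 - lam) * S + lam * diag(S)``; ``shrinkage='auto'`` picks ``lam`` by
    the analytic estimator.  With 10 training rows over 160 voxels the raw
    pooled covariance is singular, so some shrinkage is required in practice.
    """
    X = np.asarray(train_patterns, dtype=float)
    y = np.asarray(train_classes)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise TrainingError("need at least two classes")
    counts = np.bincount(y_idx)
    if counts.min() < 1:
        raise TrainingError("every class needs at least one training row")
    means = np.empty((len(classes), X.shape[1]))
    for c in range(len(classes)):
        means[c] = X[y_idx == c].mean(axis=0)
    resid = X - means[y_idx]
    if shrinkage == "auto":
        # floor keeps the shrunk covariance invertible even when the
        # analytic estimate degenerates (e.g. two mirror-image residual rows
        # per class make the off-diagonal sampling variance vanish)
        lam = max(analytic_shrinkage(resid), 0.01)
    else:
        lam = float(shrinkage)
    if not 0.0 <= lam <= 1.0:
        raise TrainingError("shrinkage must lie in [0, 1]")
    df = max(X.shape[0] - len(classes), 1)
    S = resid.T @ resid / df
    diag = np.diag(S).copy()
    if np.any(diag <= 0):
        diag = np.maximum(diag, max(diag.max(), 1.0) * 1e-12)
    cov = (1.0 - lam) * S
    np.fill_diagonal(cov, diag)
    try:
        weights = np.linalg.solve(cov, means.T)
    except np.linalg.LinAlgError as exc:
        raise TrainingError(
            "singular pooled covariance; raise the shrinkage intensity"
        ) from exc
    bias = -0.5 * np.sum(means.T * weights, axis=0)
    return LDAModel(classes, means, cov, lam, weights, bias)


def crossvalidated_accuracy(
    ds: PatternDataset,
    folds: list[FoldSpec],
    shrinkage: float | str = "auto",
) -> DecodingResult:
    """Train/test over folds and pool correct counts into one accuracy/z."""
    if not folds:
        raise ValueError("no folds supplied")
    n_classes = folds[0].n_classes
    if any(f.n_classes != n_classes for f in folds):
        raise ValueError("folds disagree on the number of classes")
    per_fold = []
    n_total = 0
    for fold in folds:
        model = train_lda(ds.patterns[fold.train_idx], fold.train_classes, shrinkage)
        pred = model.predict(ds.patterns[fold.test_idx])
        per_fold.append(int(np.sum(pred == fold.test_classes)))
        n_total += len(fold.test_idx)
    chance = 1.0 / n_classes
    n_correct = int(sum(per_fold))
    return DecodingResult(
        per_fold_correct=tuple(per_fold),
        n_total_guesses=n_total,
        accuracy=n_correct / n_total,
        z_score=accuracy_to_z(n_correct, n_total, chance),
        chance=chance,
    )


def accuracy_to_z(n_correct: int, n_total: int, chance: float) -> float:
    """Binomial z score of a pooled correct count against chance."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_correct <= n_total:
        raise ValueError("n_correct must lie in [0, n_total]")
    if not 0.0 < chance < 1.0:
        raise ValueError("chance must lie strictly between 0 and 1")
    return (n_correct - n_total * chance) / math.sqrt(
        n_total * chance * (1.0 - chance)
    )


def decode_subject(
    ds: PatternDataset,
    phase: str,
    shrinkage: float | str = "auto",
    folds_cache: dict | None = None,
) -> dict[str, DecodingResult]:
    """Run the order, timing and integrated decoders on one phase.

    ``folds_cache`` may carry precomputed folds keyed by decoder name to
    avoid re-deriving identical fold structures across subjects.
    """
    phase = canonical_phase(phase)
    cache = folds_cache if folds_cache is not None else {}
    results: dict[str, DecodingResult] = {}
    for feature in FEATURES:
        key = (feature, phase)
        if key not in cache:
            cache[key] = make_factorized_folds(ds.labels, feature, phase)
        results[feature] = crossvalidated_accuracy(ds, cache[key], shrinkage)
    key = ("integrated", phase)
    if key not in cache:
        cache[key] = make_integrated_folds(ds.labels, phase)
    residual = remove_marginal_means(ds)
    results["integrated"] = crossvalidated_accuracy(residual, cache[key], shrinkage)
    return results
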
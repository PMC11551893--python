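"""Core containers for condition-by-run voxel pattern data.

The unit of analysis throughout the package is a *pattern dataset*: one
beta-weight-like activation estimate per (sequence, phase, run) cell, over a
fixed set of voxels.  Sequences form a 2x2 factorial design of finger order
(1 or 2) and press timing (1 or 2); each imaging run contributes one pattern
per sequence per trial phase (preparation vs production), i.e. eight patterns
per run in a complete design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

PREPARATION = "preparation"
PRODUCTION = "production"
PHASES = (PREPARATION, PRODUCTION)

#: canonical column order of the label table
LABEL_COLUMNS = ("order", "timing", "phase", "run")

_PHASE_ALIASES = {
    "prep": PREPARATION,
    "preparation": PREPARATION,
    "prod": PRODUCTION,
    "production": PRODUCTION,
}


def canonical_phase(phase: str) -> str:
    """Map a phase name or its short alias to the canonical label."""
    try:
        return _PHASE_ALIASES[str(phase).lower()]
    except KeyError:
        raise ValueError(
            f"unknown phase {phase!r}; expected one of {sorted(_PHASE_ALIASES)}"
        ) from None


class ConditionLabel(NamedTuple):
    """Label of one pattern row: sequence factors, trial phase and run."""

    order: int
    timing: int
    phase: str
    run: int


class DesignError(ValueError):
    """Raised when a label table is not a complete 2x2-by-run design."""


@dataclass
class PatternDataset:
    """Condition-by-run voxel patterns with aligned labels.

    Parameters
    ----------
    patterns:
        ``(n_obs, n_voxels)`` array of activation estimates.
    labels:
        Data frame with columns ``order``, ``timing``, ``phase``, ``run``,
        one row per pattern row.
    voxel_coordinates:
        Optional ``(n_voxels, 3)`` integer grid coordinates, present for
        volumetric datasets consumed by the searchlight machinery.
    """

    patterns: np.ndarray
    labels: pd.DataFrame
    voxel_coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be a 2-D (n_obs, n_voxels) array")
        if self.patterns.shape[1] < 1:
            raise ValueError("dataset needs at least one voxel")
        missing = set(LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"label table is missing columns {sorted(missing)}")
        if len(self.labels) != self.patterns.shape[0]:
            raise ValueError("labels and patterns must have the same length")
        self.labels = self.labels.reset_index(drop=True)
        if self.voxel_coordinates is not None:
            self.voxel_coordinates = np.asarray(self.voxel_coordinates, dtype=int)
            if self.voxel_coordinates.shape != (self.patterns.shape[1], 3):
                raise ValueError("voxel_coordinates must be (n_voxels, 3)")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[1]

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.labels["run"].to_numpy())

    @property
    def condition_labels(self) -> list[ConditionLabel]:
        return [
            ConditionLabel(int(r.order), int(r.timing), str(r.phase), int(r.run))
            for r in self.labels.itertuples(index=False)
        ]

    # -- selection ---------------------------------------------------------
    def select(
        self,
        phase: str | None = None,
        run: int | Iterable[int] | None = None,
    ) -> "PatternDataset":
        """Return the row subset matching ``phase`` and/or ``run``."""
        keep = np.ones(self.n_obs, dtype=bool)
        if phase is not None:
            keep &= (self.labels["phase"] == canonical_phase(phase)).to_numpy()
        if run is not None:
            runs = {run} if np.isscalar(run) else set(run)
            keep &= self.labels["run"].isin(runs).to_numpy()
        return PatternDataset(
            self.patterns[keep],
            self.labels.loc[keep].reset_index(drop=True),
            self.voxel_coordinates,
        )

    def restrict_voxels(self, columns: np.ndarray) -> "PatternDataset":
        """Return a dataset containing only the given voxel columns."""
        columns = np.asarray(columns, dtype=int)
        coords = (
            self.voxel_coordinates[columns]
            if self.voxel_coordinates is not None
            else None
        )
        return PatternDataset(self.patterns[:, columns], self.labels.copy(), coords)

    def validate_complete_design(self, phases: Sequence[str] | None = None) -> None:
        """Check one row per (order, timing) cell per run for each phase."""
        phases = tuple(phases) if phases is not None else tuple(
            self.labels["phase"].unique()
        )
        for phase in phases:
            sub = self.labels[self.labels["phase"] == canonical_phase(phase)]
            if sub.empty:
                raise DesignError(f"no rows for phase {phase!r}")
            for run, grp in sub.groupby("run"):
                cells = set(zip(grp["order"], grp["timing"]))
                expected = {(o, t) for o in (1, 2) for t in (1, 2)}
                if cells != expected or len(grp) != 4:
                    raise DesignError(
                        f"run {run} phase {phase!r} is not a complete 2x2 design"
                    )


def complete_design_labels(n_runs: int, phases: Sequence[str] = PHASES) -> pd.DataFrame:
    """Label table of the full factorial design: 4 sequences x phases x runs."""
    rows = [
        {"order": o, "timing": t, "phase": canonical_phase(p), "run": k}
        for k in range(1, n_runs + 1)
        for p in phases
        for o in (1, 2)
        for t in (1, 2)
    ]
    return pd.DataFrame(rows, columns=list(LABEL_COLUMNS))


@dataclass
class VolumeMask:
    """Binary 3-D voxel mask with physical voxel size in mm."""

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise ValueError("mask grid must be 3-D")
        if not self.grid.any():
            raise ValueError("mask must contain at least one voxel")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or min(self.voxel_size_mm) <= 0:
            raise ValueError("voxel size must be three strictly positive values")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def coordinates(self) -> np.ndarray:
        """In-mask voxel coordinates in lexicographic order, shape (n, 3)."""
        return np.argwhere(self.grid)

    def contains(self, other: "VolumeMask") -> bool:
        if other.grid.shape != self.grid.shape:
            return False
        return bool(np.all(self.grid[other.grid]))
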
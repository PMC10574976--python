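"""Performance evaluation: balanced subsets, LOOCV threshold search, uncertainty.

The study dataset is a list of scored ROI pairs — each a t-test p-value,
a flag for the warm-direction condition, and a clinician label (1 adequate,
0 inadequate).  Because adequate cases outnumber inadequate ones, the
evaluation first builds balanced subsets: every subset contains *all*
inadequate instances plus an equal-sized random draw of adequate ones.

Each subset is evaluated by leave-one-out cross-validation.  On each fold
the decision threshold is trained by grid search — the smallest of 1000
candidate thresholds in [0.005, 0.500] maximizing the classification
accuracy on the remaining instances — and the held-out instance is
classified with it (predict 1 iff p-value < threshold and the pressure
region was the warmer one).

Per-subset accuracy gets a type-A standard uncertainty (standard deviation
of the mean of the binary fold outcomes).  Subset accuracies are averaged;
their uncertainties are combined through the first-order law of propagation
of uncertainty for a mean of uncorrelated quantities, and a coverage factor
(default k = 2, ~95% confidence) yields the expanded uncertainty.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScoreRecord", "ThresholdGrid", "SubsetResult", "EvalReport",
           "make_balanced_subsets", "loocv_accuracy", "type_a_uncertainty",
           "propagate_mean_uncertainty", "expanded_uncertainty",
           "evaluate_system", "read_scores", "write_scores"]


@dataclass(frozen=True)
class ScoreRecord:
    """One scored ROI pair: the decision-stage score plus its clinical label."""

    p_value: float
    direction_ok: bool
    label: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass(frozen=True)
class ThresholdGrid:
    """Linearly spaced candidate thresholds, endpoints included."""

    lo: float = 0.005
    hi: float = 0.500
    n_points: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi < 1.0):
            raise ValueError("need 0 < lo < hi < 1")
        if self.n_points < 2:
            raise ValueError("need at least 2 grid points")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.lo, self.hi, self.n_points)


@dataclass(frozen=True)
class SubsetResult:
    """LOOCV outcome for one balanced subset."""

    indices: tuple[int, ...]
    accuracy_pct: float
    u_pct: float
    fold_outcomes: tuple[int, ...]


@dataclass(frozen=True)
class EvalReport:
    """Aggregated system performance: the content of the summary table."""

    per_subset: tuple[SubsetResult, ...]
    mean_accuracy_pct: float
    u_mean_pct: float
    coverage_k: float
    expanded_u_pct: float

    def to_dict(self) -> dict:
        return {
            "per_subset": [
                {"subset": i + 1, "accuracy_pct": s.accuracy_pct,
                 "u_pct": s.u_pct, "fold_outcomes": list(s.fold_outcomes),
                 "indices": list(s.indices)}
                for i, s in enumerate(self.per_subset)
            ],
            "mean_accuracy_pct": self.mean_accuracy_pct,
            "u_mean_pct": self.u_mean_pct,
            "coverage_k": self.coverage_k,
            "expanded_u_pct": self.expanded_u_pct,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def summary_table(self) -> str:
        """Human-readable per-subset summary, values rounded to 1 decimal."""
        header = ["subset"] + [str(i + 1) for i in range(len(self.per_subset))] + ["mean"]
        a_row = (["A (%)"] + [f"{s.accuracy_pct:.1f}" for s in self.per_subset]
                 + [f"{self.mean_accuracy_pct:.1f}"])
        u_row = (["u (%)"] + [f"{s.u_pct:.1f}" for s in self.per_subset]
                 + [f"{self.u_mean_pct:.1f}"])
        lines = ["\t".join(r) for r in (header, a_row, u_row)]
        lines.append(f"expanded U (k={self.coverage_k:g}): "
                     f"{self.expanded_u_pct:.1f} %")
        return "\n".join(lines)


def make_balanced_subsets(labels: Sequence[int], n_subsets: int = 10,
                          per_class: int = 10, seed: int = 0) -> list[list[int]]:
    """Build balanced index subsets from an imbalanced 0/1-labeled dataset.

    Every subset contains all ``label == 0`` (inadequate, minority) indices
    plus *per_class* indices sampled without replacement from the
    ``label == 1`` pool.  Subset ``i`` draws with its own seed ``seed + i``
    (a fresh seed for each subset), so the whole construction is
    reproducible and the subsets are independent draws.
    """
    y = np.asarray(labels, dtype=int)
    zeros = np.flatnonzero(y == 0)
    ones = np.flatnonzero(y == 1)
    if len(zeros) < per_class:
        raise ValueError(
            f"need at least {per_class} label-0 instances, got {len(zeros)}"
        )
    if len(ones) < per_class:
        raise ValueError(
            f"need at least {per_class} label-1 instances, got {len(ones)}"
        )
    subsets = []
    for i in range(n_subsets):
        rng = np.random.default_rng(seed + i)
        picked = rng.choice(ones, size=per_class, replace=False)
        subset = np.concatenate([zeros, np.sort(picked)])
        subsets.append([int(j) for j in subset])
    return subsets


def _predictions(records: Sequence[ScoreRecord], grid_values: np.ndarray) -> np.ndarray:
    """(n_records, n_grid) boolean matrix: predict adequate at each threshold."""
    p = np.array([r.p_value for r in records])[:, None]
    d = np.array([r.direction_ok for r in records], dtype=bool)[:, None]
    return (p < grid_values[None, :]) & d


def loocv_accuracy(records: Sequence[ScoreRecord],
                   grid: ThresholdGrid | None = None) -> tuple[float, list[int]]:
    """Leave-one-out accuracy with per-fold threshold grid search.

    For each held-out record the training threshold is the *smallest* grid
    value maximizing accuracy on the other ``k - 1`` records (deterministic
    and conservative tie-break); the held-out record is then classified
    with it.  Returns the accuracy in percent and the per-fold 0/1 outcome
    vector.
    """
    if len(records) < 2:
        raise ValueError("LOOCV needs at least 2 records")
    if grid is None:
        grid = ThresholdGrid()
    # accept a raw ascending array of candidate thresholds as well
    gv = grid.values if isinstance(grid, ThresholdGrid) else np.asarray(grid, dtype=float)
    labels = np.array([r.label for r in records], dtype=int)
    pred = _predictions(records, gv)                 # (k, n_grid)
    correct = pred == labels[:, None].astype(bool)
    totals = correct.sum(axis=0)                     # training+test correctness per th
    outcomes = []
    for i in range(len(records)):
        train_acc = totals - correct[i]
        best = int(np.argmax(train_acc))             # first max = smallest threshold
        outcomes.append(int(correct[i, best]))
    accuracy = 100.0 * sum(outcomes) / len(outcomes)
    return accuracy, outcomes


def type_a_uncertainty(fold_outcomes: Iterable[int]) -> float:
    """Type-A standard uncertainty (in %) of a LOOCV accuracy.

    Sample standard deviation (``n - 1`` denominator) of the binary fold
    outcomes divided by ``sqrt(n)``; equivalently
    ``100 * sqrt(phat * (1 - phat) / (n - 1))`` for success fraction phat.
    """
    x = np.asarray(list(fold_outcomes), dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 fold outcomes")
    return 100.0 * float(np.std(x, ddof=1)) / math.sqrt(n)


def propagate_mean_uncertainty(us: Iterable[float]) -> float:
    """First-order propagated uncertainty of the mean of n uncorrelated values.

    For ``A_m = (1/n) * sum(A_i)`` with standard uncertainties ``u_i``,
    ``u_m = sqrt(sum(u_i**2)) / n``.
    """
    u = np.asarray(list(us), dtype=float)
    if len(u) < 1:
        raise ValueError("need at least one uncertainty")
    return float(np.sqrt(np.sum(u ** 2)) / len(u))


def expanded_uncertainty(u_mean: float, coverage_k: float = 2.0) -> float:
    """Expanded uncertainty ``U = k * u_m`` (k = 2 for ~95% coverage)."""
    if u_mean < 0:
        raise ValueError("standard uncertainty must be non-negative")
    return coverage_k * u_mean


def evaluate_system(records: Sequence[ScoreRecord],
                    grid: ThresholdGrid | None = None,
                    n_subsets: int = 10, per_class: int = 10,
                    seed: int = 0, coverage_k: float = 2.0) -> EvalReport:
    """Full evaluation: balanced subsets -> per-subset LOOCV -> aggregation.

    Fully reproducible given *seed*.
    """
    grid = grid or ThresholdGrid()
    labels = [r.label for r in records]
    subsets = make_balanced_subsets(labels, n_subsets, per_class, seed)
    per_subset = []
    for idx in subsets:
        sub = [records[j] for j in idx]
        acc, outcomes = loocv_accuracy(sub, grid)
        per_subset.append(SubsetResult(
            indices=tuple(idx), accuracy_pct=acc,
            u_pct=type_a_uncertainty(outcomes),
            fold_outcomes=tuple(outcomes),
        ))
    mean_acc = float(np.mean([s.accuracy_pct for s in per_subset]))
    u_mean = propagate_mean_uncertainty([s.u_pct for s in per_subset])
    return EvalReport(
        per_subset=tuple(per_subset),
        mean_accuracy_pct=mean_acc,
        u_mean_pct=u_mean,
        coverage_k=coverage_k,
        expanded_u_pct=expanded_uncertainty(u_mean, coverage_k),
    )


# ---------------------------------------------------------------------------
# score dataset I/O


def read_scores(path: str) -> list[ScoreRecord]:
    """Read a score dataset from delimited text with header
    ``p_value,direction_ok,label``."""
    df = pd.read_csv(path)
    required = {"p_value", "direction_ok", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ScoreRecord(p_value=float(r.p_value),
                    direction_ok=bool(r.direction_ok),
                    label=int(r.label))
        for r in df.itertuples(index=False)
    ]


def write_scores(records: Sequence[ScoreRecord], path: str) -> None:
    pd.DataFrame(
        {"p_value": [r.p_value for r in records],
         "direction_ok": [int(r.direction_ok) for r in records],
         "label": [r.label for r in records]}
    ).to_csv(path, index=False)
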
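"""Non-parametric cut-off selection on dichotomized diagnostic data.

A cut-off c turns a ratio-scaled test value x into a binary result
(positive if x >= c), which together with the true disease label yields a
2x2 contingency table. Two selection criteria are implemented: the Youden
index J = Se + Sp - 1 and the mutual information (in bits) between disease
status and the dichotomized result. Both are maximized by a grid search that
steps the candidate cut-off from the sample minimum upwards in increments
of 1.0 until the first candidate above the sample maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "Method",
    "DiagnosticDataset",
    "ContingencyTable",
    "CutoffEstimate",
    "build_table",
    "se_sp",
    "youden_index",
    "mutual_information",
    "optimize_cutoff",
    "read_dataset",
]

#: Grid step of the systematic cut-off search, in test-value units.
GRID_STEP = 1.0


class Method(str, Enum):
    MUTUAL_INFORMATION = "mutual_information"
    YOUDEN = "youden"
    LIKELIHOOD_RATIO = "likelihood_ratio"


@dataclass
class DiagnosticDataset:
    """Aligned test values and binary disease labels (1 = disease).

    ``p_d`` records the nominal pre-test probability of disease used when the
    dataset was generated; for user-supplied data it defaults to the empirical
    disease fraction.
    """

    values: np.ndarray
    labels: np.ndarray
    p_d: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 1 or self.labels.ndim != 1:
            raise ValueError("values and labels must be one-dimensional")
        if len(self.values) != len(self.labels):
            raise ValueError(
                f"values ({len(self.values)}) and labels ({len(self.labels)}) "
                "must have equal length"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (no disease) or 1 (disease)")
        self.labels = self.labels.astype(np.int8)
        if not np.isfinite(self.values).all():
            raise ValueError("test values must be finite")
        if self.p_d is None and len(self.labels):
            self.p_d = float(self.labels.mean())

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_diseased(self) -> int:
        return int(self.labels.sum())

    @property
    def n_healthy(self) -> int:
        return len(self.labels) - self.n_diseased

    @property
    def both_classes_present(self) -> bool:
        return self.n_diseased > 0 and self.n_healthy > 0


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts induced by a cut-off; positive test means x >= cut-off."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            count = getattr(self, name)
            if count < 0 or count != int(count):
                raise ValueError(f"{name} must be a non-negative integer, got {count}")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.fp + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class CutoffEstimate:
    """An optimal cut-off plus the accuracy it achieves on the fitting data.

    ``criterion_value`` is the maximized criterion (MI in bits or Youden J);
    it is None for the likelihood-ratio method, whose cut-off is a root, not
    an argmax.
    """

    method: Method
    cutoff: float
    sensitivity: float
    specificity: float
    criterion_value: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity out of [0, 1]: {self.sensitivity}")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError(f"specificity out of [0, 1]: {self.specificity}")

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def build_table(data: DiagnosticDataset, cutoff: float) -> ContingencyTable:
    """Dichotomize a dataset at ``cutoff`` (positive means x >= cutoff)."""
    if len(data) == 0:
        raise ValueError("dataset is empty")
    positive = data.values >= cutoff
    diseased = data.labels == 1
    tp = int(np.count_nonzero(positive & diseased))
    fp = int(np.count_nonzero(positive & ~diseased))
    fn = int(data.n_diseased - tp)
    tn = int(data.n_healthy - fp)
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def se_sp(table: ContingencyTable) -> tuple[float, float]:
    """Sensitivity tp/(tp+fn) and specificity tn/(fp+tn)."""
    if table.n_diseased == 0 or table.n_healthy == 0:
        raise ValueError("sensitivity/specificity undefined: one class is empty")
    return table.tp / table.n_diseased, table.tn / table.n_healthy


def youden_index(table: ContingencyTable) -> float:
    """Youden index J = Se + Sp - 1, in [-1, 1]."""
    se, sp = se_sp(table)
    return se + sp - 1.0


def _mi_bits(tp, fp, fn, tn) -> np.ndarray:
    """Vectorized mutual information (bits) of 2x2 tables given as arrays.

    Uses relative frequencies; cells with zero probability contribute zero
    (the 0*log 0 := 0 convention), so degenerate margins give MI = 0.
    """
    tp, fp, fn, tn = (np.asarray(a, dtype=float) for a in (tp, fp, fn, tn))
    n = tp + fp + fn + tn
    out = np.zeros(np.broadcast(tp, fp, fn, tn).shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for cell, row, col in (
            (tp, tp + fn, tp + fp),
            (fn, tp + fn, fn + tn),
            (fp, fp + tn, tp + fp),
            (tn, fp + tn, fn + tn),
        ):
            term = cell / n * np.log2(cell * n / (row * col))
            out += np.where(cell > 0, term, 0.0)
    # clip tiny negative round-off
    return np.maximum(out, 0.0)


def mutual_information(table: ContingencyTable) -> float:
    """Mutual information between disease status and test result, in bits."""
    if table.total == 0:
        raise ValueError("mutual information undefined for an empty table")
    return float(_mi_bits(table.tp, table.fp, table.fn, table.tn))


def candidate_cutoffs(values: np.ndarray, step: float = GRID_STEP) -> np.ndarray:
    """The systematic search grid: min(values), min+step, ... up to the first
    candidate strictly above max(values)."""
    lo = float(np.min(values))
    hi = float(np.max(values))
    n_steps = int(np.floor((hi - lo) / step)) + 2
    return lo + step * np.arange(n_steps)


def _counts_at(data: DiagnosticDataset, cutoffs: np.ndarray):
    """tp/fp/fn/tn arrays for many cut-offs at once, via sorted search."""
    diseased = np.sort(data.values[data.labels == 1])
    healthy = np.sort(data.values[data.labels == 0])
    n_d, n_h = len(diseased), len(healthy)
    # number of values < c == searchsorted(..., side="left")
    tp = n_d - np.searchsorted(diseased, cutoffs, side="left")
    fp = n_h - np.searchsorted(healthy, cutoffs, side="left")
    return tp, fp, n_d - tp, n_h - fp


def optimize_cutoff(
    data: DiagnosticDataset,
    criterion: Method | str,
    *,
    step: float = GRID_STEP,
    log_base: float = 2.0,
) -> CutoffEstimate:
    """Grid-search the cut-off maximizing the Youden index or the MI.

    Candidates run from the sample minimum upwards in increments of ``step``
    until the first candidate above the sample maximum. Ties in the criterion
    are broken toward the smallest cut-off (deterministic; favors
    sensitivity). ``log_base`` only rescales the reported MI value; the argmax
    is base-invariant.
    """
    criterion = Method(criterion)
    if criterion is Method.LIKELIHOOD_RATIO:
        raise ValueError("the likelihood-ratio cut-off is not a grid criterion")
    if not data.both_classes_present:
        raise ValueError("both diagnostic classes must be present")

    cutoffs = candidate_cutoffs(data.values, step=step)
    tp, fp, fn, tn = _counts_at(data, cutoffs)
    n_d, n_h = data.n_diseased, data.n_healthy
    if criterion is Method.YOUDEN:
        # maximizing Se + Sp is equivalent to maximizing the integer score
        # tp*n_h + tn*n_d, which makes ties exact (no float round-off)
        exact = tp.astype(np.int64) * n_h + tn.astype(np.int64) * n_d
        best = int(np.argmax(exact))  # first max == smallest cut-off on a tie
        scores = tp / n_d + tn / n_h - 1.0
    else:
        scores = _mi_bits(tp, fp, fn, tn)
        if log_base != 2.0:
            scores = scores * (np.log(2.0) / np.log(log_base))
        # mathematically tied tables can differ in the last ulp; prefer the
        # smallest cut-off among scores within round-off of the maximum
        best = int(np.argmax(scores >= scores.max() - 1e-12))
    return CutoffEstimate(
        method=criterion,
        cutoff=float(cutoffs[best]),
        sensitivity=tp[best] / n_d,
        specificity=tn[best] / n_h,
        criterion_value=float(scores[best]),
    )


def read_dataset(
    path: str | Path,
    *,
    delimiter: str | None = None,
    invert: bool = False,
    p_d: float | None = None,
) -> DiagnosticDataset:
    """Read a two-column delimited text file of (test value, 0/1 label).

    The header row is optional and detected by a non-numeric first field.
    ``delimiter=None`` autodetects comma, semicolon, tab or whitespace.
    ``invert=True`` swaps the two class labels for tests whose low values
    indicate disease, so that the "positive if x >= cut-off" rule stays
    oriented toward the relabelled disease class.
    """
    path = Path(path)
    values: list[float] = []
    labels: list[int] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if delimiter is None:
                for cand in (",", ";", "\t"):
                    if cand in line:
                        fields = [f.strip() for f in line.split(cand)]
                        break
                else:
                    fields = line.split()
            else:
                fields = [f.strip() for f in line.split(delimiter)]
            fields = [f for f in fields if f]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns (value, label), "
                    f"got {len(fields)}"
                )
            try:
                value = float(fields[0])
            except ValueError:
                if lineno == 1 and not values:
                    continue  # header row
                raise ValueError(
                    f"{path}:{lineno}: non-numeric test value {fields[0]!r}"
                ) from None
            if fields[1] not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: label must be 0 or 1, got {fields[1]!r}"
                )
            values.append(value)
            labels.append(int(fields[1]))
    if not values:
        raise ValueError(f"{path}: no data rows")
    label_arr = np.asarray(labels, dtype=np.int8)
    if invert:
        label_arr = 1 - label_arr
    return DiagnosticDataset(np.asarray(values), label_arr, p_d=p_d)
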
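"""Classification metrics and reports.

Performance is summarized the way aerobiological classifier studies report
it: a confusion matrix (rows = truth, columns = prediction), per-taxon
accuracy — the diagonal over the row sum, i.e. recall, matching the
row-normalized heat-map convention — and the macro-averaged F1 score, the
unweighted mean over classes of the harmonic mean of precision and recall.
Species-level matrices can be aggregated to genus level (or to the pooled
Rapid-E+ classes) by summing rows and columns within groups; aggregation
acts on counts, never by re-running predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .taxonomy import species_to_genus

__all__ = [
    "ConfusionMatrix",
    "ClassificationReport",
    "confusion",
    "macro_f1",
    "per_class_accuracy",
    "overall_accuracy",
    "aggregate_by_genus",
    "report",
    "plot_heatmap",
]


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray  # square, rows = truth, columns = prediction

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts must be {k}x{k} for {k} classes, got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized_pct(self) -> np.ndarray:
        """Row percentages as drawn in the heat maps (NaN for empty rows)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / sums


@dataclass
class ClassificationReport:
    level: str
    matrix: ConfusionMatrix
    per_class_accuracy: dict[str, float | None]
    macro_f1: float
    overall_accuracy: float
    heatmap_path: str | None = field(default=None)


def confusion(
    truth: Sequence[str], pred: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #{truth==classes[i] & pred==classes[j]}``."""
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(pred)} predictions")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(truth, pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(list(classes), counts)


def macro_f1(matrix: ConfusionMatrix) -> float:
    """Unweighted mean over classes of the harmonic mean of precision and
    recall; a class with precision + recall = 0 contributes 0."""
    counts = matrix.counts.astype(float)
    diag = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    return float(f1.mean())


def per_class_accuracy(matrix: ConfusionMatrix) -> dict[str, float | None]:
    """Diagonal over row sum per class (recall); classes absent from the
    truth get ``None`` rather than 0."""
    counts = matrix.counts.astype(float)
    row = counts.sum(axis=1)
    out: dict[str, float | None] = {}
    for i, c in enumerate(matrix.classes):
        out[c] = float(counts[i, i] / row[i]) if row[i] > 0 else None
    return out


def overall_accuracy(matrix: ConfusionMatrix) -> float:
    """Correctly classified events over all evaluated events."""
    if matrix.total == 0:
        return float("nan")
    return float(np.trace(matrix.counts) / matrix.total)


def aggregate_by_genus(
    matrix: ConfusionMatrix,
    mapping: Callable[[str], str] | Mapping[str, str] = species_to_genus,
) -> ConfusionMatrix:
    """Sum rows and columns of a counts matrix within label groups.

    ``mapping`` takes each class label to its group (genus by default); the
    total event count is conserved. Aggregation operates on counts — the
    classifier is not re-run at the coarser level.
    """
    if callable(mapping):
        mapped = [mapping(c) for c in matrix.classes]
    else:
        try:
            mapped = [mapping[c] for c in matrix.classes]
        except KeyError as exc:
            raise KeyError(f"class {exc.args[0]!r} missing from the group mapping") from None
    groups = list(dict.fromkeys(mapped))
    gi = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=np.int64)
    for i, gi_row in enumerate(mapped):
        for j, gj_col in enumerate(mapped):
            counts[gi[gi_row], gi[gj_col]] += matrix.counts[i, j]
    return ConfusionMatrix(groups, counts)


def report(
    truth: Sequence[str],
    pred: Sequence[str],
    classes: Sequence[str],
    level: str = "species",
    heatmap_path: str | None = None,
) -> ClassificationReport:
    """Full report (matrix, per-class accuracy, macro F1, overall accuracy)
    with an optional row-normalized heat-map figure."""
    matrix = confusion(truth, pred, classes)
    rep = ClassificationReport(
        level=level,
        matrix=matrix,
        per_class_accuracy=per_class_accuracy(matrix),
        macro_f1=macro_f1(matrix),
        overall_accuracy=overall_accuracy(matrix),
    )
    if heatmap_path is not None:
        plot_heatmap(matrix, heatmap_path, title=f"{level}-level recognition")
        rep.heatmap_path = heatmap_path
    return rep


def plot_heatmap(matrix: ConfusionMatrix, path: str, title: str = "") -> str:
    """Render the matrix as a row-normalized percentage heat map."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    pct = matrix.row_normalized_pct()
    k = len(matrix.classes)
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * k + 2),) * 2)
    im = ax.imshow(np.nan_to_num(pct), vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(k), matrix.classes, rotation=90, fontsize=7)
    ax.set_yticks(range(k), matrix.classes, fontsize=7)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    if title:
        ax.set_title(title)
    for i in range(k):
        for j in range(k):
            if np.isfinite(pct[i, j]) and pct[i, j] >= 1:
                ax.text(j, i, f"{pct[i, j]:.0f}", ha="center", va="center",
                        color="w" if pct[i, j] < 60 else "k", fontsize=6)
    fig.colorbar(im, ax=ax, label="% of row")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
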
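"""Scoring new samples against a fitted control tree.

A cell's probability under the tree model is the root marginal times one
conditional Q(child | parent) per tree edge. A factor is zero when the
corresponding training count is zero (or the parent bin was never observed, or
the value fell outside the training range under the ``zero`` out-of-bounds
policy). The sample-level statistic is NoZ: the percentage of cells with
probability exactly zero. Zero-ness is always decided on integer counts, never
on a floating-point product, so underflow can never fake a zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chowliu import TreeModel
from .io_preprocess import OUT_OF_RANGE, CellTable, normalize_and_bin

logger = logging.getLogger(__name__)

#: Factor identifier: ("root", marker) or ("edge", child, parent)
Factor = tuple


@dataclass(frozen=True)
class CellEvaluation:
    """Probability of one cell under the tree model, with zero attribution.

    ``probability`` is exp of the log-domain sum and can underflow for very
    deep models; ``is_zero`` and ``zero_factors`` are decided from integer
    counts and are always exact.
    """

    probability: float
    log_probability: float  # natural log; -inf when is_zero
    is_zero: bool
    zero_factors: tuple[Factor, ...]


@dataclass(frozen=True)
class SampleScore:
    """NoZ score of one sample: percent of cells with zero tree probability."""

    sample_id: str
    label: Optional[str]
    n_cells: int
    n_zero: int
    marker_names: tuple[str, ...]
    marker_zero_counts: np.ndarray  # per model marker, int64

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        object.__setattr__(
            self,
            "marker_zero_counts",
            np.asarray(self.marker_zero_counts, dtype=np.int64),
        )
        if not (0 <= self.n_zero <= self.n_cells):
            raise ValueError("n_zero outside [0, n_cells]")

    @property
    def noz_percent(self) -> float:
        return 100.0 * self.n_zero / self.n_cells


def _factor_table(model: TreeModel) -> list[Factor]:
    """The model's probability factors: the root marginal plus one per edge."""
    parent = model.tree.parent_map()
    factors: list[Factor] = [("root", model.tree.root)]
    for child in sorted(parent):
        factors.append(("edge", child, parent[child]))
    return factors


def _factor_zero_masks(
    model: TreeModel, bins: np.ndarray
) -> tuple[list[Factor], np.ndarray]:
    """Per-factor boolean zero masks over the cells in ``bins`` (n x J)."""
    factors = _factor_table(model)
    n = bins.shape[0]
    masks = np.zeros((len(factors), n), dtype=bool)
    for fi, f in enumerate(factors):
        if f[0] == "root":
            b = bins[:, f[1]]
            sent = b == OUT_OF_RANGE
            counts = model.root_marginal[np.where(sent, 0, b)]
            masks[fi] = sent | (counts == 0)
        else:
            _, child, parent = f
            grid = model.edge_grid(child, parent)
            parent_marg = grid.sum(axis=0)
            bc, bp = bins[:, child], bins[:, parent]
            sent = (bc == OUT_OF_RANGE) | (bp == OUT_OF_RANGE)
            bc0 = np.where(sent, 0, bc)
            bp0 = np.where(sent, 0, bp)
            masks[fi] = sent | (parent_marg[bp0] == 0) | (grid[bc0, bp0] == 0)
    return factors, masks


def _log_probabilities(model: TreeModel, bins: np.ndarray) -> np.ndarray:
    """Natural-log probability per cell; -inf where any factor count is zero."""
    factors, masks = _factor_zero_masks(model, bins)
    n = bins.shape[0]
    logp = np.zeros(n)
    N = model.n_training_cells
    for fi, f in enumerate(factors):
        zero = masks[fi]
        if f[0] == "root":
            b = np.where(zero, 0, bins[:, f[1]])
            term = np.log(np.maximum(model.root_marginal[b], 1)) - np.log(N)
        else:
            _, child, parent = f
            grid = model.edge_grid(child, parent)
            parent_marg = grid.sum(axis=0)
            bc = np.where(zero, 0, bins[:, child])
            bp = np.where(zero, 0, bins[:, parent])
            term = np.log(np.maximum(grid[bc, bp], 1)) - np.log(
                np.maximum(parent_marg[bp], 1)
            )
        logp += np.where(zero, -np.inf, term)
    return logp


def evaluate_cell(model: TreeModel, binned_cell: Sequence[int]) -> CellEvaluation:
    """Evaluate one already-binned cell (one bin index or sentinel per marker).

    All zero factors are recorded, not only the first encountered.
    """
    cell = np.asarray(binned_cell, dtype=np.int64)
    if cell.shape != (model.n_markers,):
        raise ValueError(
            f"cell has {cell.shape} entries; model expects {model.n_markers}"
        )
    bins = cell[None, :]
    factors, masks = _factor_zero_masks(model, bins)
    zero_factors = tuple(f for fi, f in enumerate(factors) if masks[fi, 0])
    logp = float(_log_probabilities(model, bins)[0])
    is_zero = bool(zero_factors)
    return CellEvaluation(
        probability=0.0 if is_zero else float(np.exp(logp)),
        log_probability=logp,
        is_zero=is_zero,
        zero_factors=zero_factors,
    )


def score_sample(
    model: TreeModel, table: CellTable, label: Optional[str] = None
) -> SampleScore:
    """Normalize, bin and evaluate every cell of ``table``; aggregate NoZ.

    The table may contain extra markers (ignored with a log note) but must
    contain every model marker. Marker attribution counts every zero factor of
    every zero cell: a zero edge factor increments both endpoint markers, a
    zero root factor increments the root marker.
    """
    extra = [m for m in table.marker_names if m not in model.marker_names]
    missing = [m for m in model.marker_names if m not in table.marker_names]
    if missing:
        raise KeyError(f"sample {table.sample_id!r} lacks model markers: {missing}")
    if extra:
        logger.info("ignoring %d extra markers in %r", len(extra), table.sample_id)
    table = table.select_markers(list(model.marker_names))
    if model.normalization == "from_training":
        binned, _ = normalize_and_bin(table, model.binning_spec, model.normalizer)
    else:
        binned, _ = normalize_and_bin(table, model.binning_spec)
    factors, masks = _factor_zero_masks(model, binned.bin_indices)
    zero_cells = masks.any(axis=0)
    marker_counts = np.zeros(model.n_markers, dtype=np.int64)
    for fi, f in enumerate(factors):
        c = int(masks[fi].sum())
        if f[0] == "root":
            marker_counts[f[1]] += c
        else:
            marker_counts[f[1]] += c
            marker_counts[f[2]] += c
    return SampleScore(
        sample_id=table.sample_id,
        label=label,
        n_cells=table.n_cells,
        n_zero=int(zero_cells.sum()),
        marker_names=model.marker_names,
        marker_zero_counts=marker_counts,
    )


def aggregate_marker_attribution(
    scores: Sequence[SampleScore],
) -> tuple[np.ndarray, bool]:
    """Pool marker zero-factor counts across samples into relative frequencies.

    Returns ``(frequencies, any_zeros)``: frequencies sum to 1 when at least
    one zero factor occurred anywhere, otherwise they are all zero and the
    flag is False. All scores must come from the same model.
    """
    if not scores:
        raise ValueError("no scores to aggregate")
    names = scores[0].marker_names
    for s in scores[1:]:
        if s.marker_names != names:
            raise ValueError("scores come from different models (marker mismatch)")
    total = np.sum([s.marker_zero_counts for s in scores], axis=0)
    grand = int(total.sum())
    if grand == 0:
        return np.zeros(len(names)), False
    return total / grand, True


def scores_to_frame(scores: Sequence[SampleScore]) -> pd.DataFrame:
    """Tabulate scores: id, label, cell counts, NoZ percent, per-marker counts."""
    rows = []
    for s in scores:
        row = {
            "sample_id": s.sample_id,
            "label": s.label,
            "n_cells": s.n_cells,
            "n_zero": s.n_zero,
            "noz_percent": s.noz_percent,
        }
        row.update({m: int(c) for m, c in zip(s.marker_names, s.marker_zero_counts)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_scores(scores: Sequence[SampleScore], path: str | Path) -> None:
    scores_to_frame(scores).to_csv(path, index=False)
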
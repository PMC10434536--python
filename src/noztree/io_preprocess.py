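"""Reading, normalizing, binning, pooling and subsampling per-cell marker tables.

The input format is the CSV dialect that cytometry platforms export from FCS
files: one header row of marker/channel names, then one row per cell with the
measured intensity for each channel. No compensation, transformation or gating
is applied here — the downstream model deliberately consumes raw intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel bin index for values outside the training range under the
#: ``from_training`` normalization policy with ``oob_policy="zero"``.
OUT_OF_RANGE: int = -1


@dataclass(frozen=True)
class CellTable:
    """A per-cell x per-marker intensity matrix for one sample (or a pool).

    Attributes
    ----------
    sample_id
        Identifier of the sample (file stem by default).
    marker_names
        Channel names, one per column of ``values``.
    values
        Float matrix with one row per cell and one column per marker, in
        arbitrary fluorescence/scatter units.
    """

    sample_id: str
    marker_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (cells x markers)")
        if len(self.marker_names) != values.shape[1]:
            raise ValueError(
                f"{len(self.marker_names)} marker names for {values.shape[1]} columns"
            )
        if len(self.marker_names) < 1:
            raise ValueError("a cell table needs at least one marker")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("duplicated marker names")
        if values.shape[0] < 1:
            raise ValueError("a cell table needs at least one cell")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at cell {i}, marker {self.marker_names[j]!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def select_markers(self, markers: Sequence[str]) -> "CellTable":
        """Return a view of this table restricted to ``markers``, in that order."""
        missing = [m for m in markers if m not in self.marker_names]
        if missing:
            raise KeyError(f"markers not present in table: {missing}")
        cols = [self.marker_names.index(m) for m in markers]
        return CellTable(self.sample_id, tuple(markers), self.values[:, cols])


@dataclass(frozen=True)
class Normalizer:
    """Per-marker min/max used for column-wise min-max scaling to [0, 1]."""

    marker_names: tuple[str, ...]
    minima: np.ndarray
    maxima: np.ndarray
    policy: str = "per_file"  # {per_file, from_training}

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        object.__setattr__(self, "minima", np.asarray(self.minima, dtype=np.float64))
        object.__setattr__(self, "maxima", np.asarray(self.maxima, dtype=np.float64))
        if self.policy not in ("per_file", "from_training"):
            raise ValueError(f"unknown normalization policy {self.policy!r}")
        if np.any(self.maxima <= self.minima):
            j = int(np.flatnonzero(self.maxima <= self.minima)[0])
            raise ValueError(
                f"constant column: marker {self.marker_names[j]!r} has max <= min"
            )


@dataclass(frozen=True)
class BinningSpec:
    """Equal-width binning of normalized values into ``n_bins`` bins on [0, 1].

    ``oob_policy`` controls what happens to values outside the [min, max] range
    of a *training* normalizer: ``"clip"`` clamps them into the edge bins,
    ``"zero"`` marks them :data:`OUT_OF_RANGE` so every probability factor
    touching the marker becomes zero. It is irrelevant for per-file
    normalization, where every value is inside its own range by construction.
    """

    n_bins: int
    oob_policy: str = "clip"  # {clip, zero}

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.oob_policy not in ("clip", "zero"):
            raise ValueError(f"unknown oob_policy {self.oob_policy!r}")


@dataclass(frozen=True)
class BinnedTable:
    """Integer bin indices per cell and marker; OUT_OF_RANGE marks excluded values."""

    sample_id: str
    marker_names: tuple[str, ...]
    bin_indices: np.ndarray  # int64, entries in [0, n_bins-1] or OUT_OF_RANGE
    binning_spec: BinningSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        idx = np.asarray(self.bin_indices, dtype=np.int64)
        object.__setattr__(self, "bin_indices", idx)
        valid = (idx == OUT_OF_RANGE) | ((idx >= 0) & (idx < self.binning_spec.n_bins))
        if not valid.all():
            raise ValueError("bin index outside [0, n_bins-1] and not OUT_OF_RANGE")

    @property
    def n_cells(self) -> int:
        return self.bin_indices.shape[0]

    @property
    def n_markers(self) -> int:
        return self.bin_indices.shape[1]


def read_cell_table(
    path: str | Path, marker_subset: Optional[Sequence[str]] = None
) -> CellTable:
    """Read a per-cell CSV (header of marker names, one row per cell).

    Parameters
    ----------
    path
        CSV file, UTF-8, comma separated, decimal point.
    marker_subset
        If given, the returned table contains exactly these columns in this
        order; every name must appear in the header.

    Raises
    ------
    FileNotFoundError, ValueError, KeyError
        For a missing file, duplicated header names or non-numeric /
        non-finite entries (with row and column in the message).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    # check the raw header first: pandas silently mangles duplicates to "a.1"
    names = pd.read_csv(path, header=None, nrows=1).iloc[0].astype(str).tolist()
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicated marker name(s) in {path.name}: {dups}")
    df = pd.read_csv(path, header=0)
    df.columns = names
    try:
        values = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = np.nonzero(coerced.isna().to_numpy() & df[col].notna().to_numpy())[0]
            if bad.size:
                raise ValueError(
                    f"non-numeric value at row {int(bad[0])}, marker {names[j]!r}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing/non-numeric value at row {int(i)}, marker {names[j]!r}")
    table = CellTable(path.stem, tuple(names), values)
    if marker_subset is not None:
        table = table.select_markers(list(marker_subset))
    return table


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a CellTable in the same CSV dialect :func:`read_cell_table` reads."""
    pd.DataFrame(table.values, columns=list(table.marker_names)).to_csv(
        path, index=False
    )


def fit_normalizer(table: CellTable, policy: str = "per_file") -> Normalizer:
    """Column-wise min/max of ``table`` (errors on constant columns)."""
    return Normalizer(
        table.marker_names,
        table.values.min(axis=0),
        table.values.max(axis=0),
        policy=policy,
    )


def normalize_and_bin(
    table: CellTable,
    spec: BinningSpec,
    normalizer: Optional[Normalizer] = None,
) -> tuple[BinnedTable, Normalizer]:
    """Min-max normalize each column to [0, 1] and discretize into equal-width bins.

    A value v becomes u = (v - min) / (max - min), then bin floor(u * n_bins),
    with u = 1 assigned to the last bin. When ``normalizer`` is None the
    column minima/maxima of ``table`` itself are used (per-file policy). With a
    supplied training normalizer, out-of-range values are clamped
    (``oob_policy="clip"``) or marked :data:`OUT_OF_RANGE` (``"zero"``).

    Returns the binned table and the normalizer actually used.
    """
    if normalizer is None:
        normalizer = fit_normalizer(table, policy="per_file")
    else:
        if tuple(normalizer.marker_names) != tuple(table.marker_names):
            raise ValueError(
                "normalizer marker names do not match the table "
                f"({normalizer.marker_names} vs {table.marker_names})"
            )
    span = normalizer.maxima - normalizer.minima
    u = (table.values - normalizer.minima) / span
    nb = spec.n_bins
    if normalizer.policy == "from_training":
        oob = (u < 0.0) | (u > 1.0)
        u = np.clip(u, 0.0, 1.0)
    else:
        oob = None
    idx = np.floor(u * nb).astype(np.int64)
    np.clip(idx, 0, nb - 1, out=idx)  # u == 1 lands in the last bin
    if oob is not None and spec.oob_policy == "zero":
        idx[oob] = OUT_OF_RANGE
    binned = BinnedTable(table.sample_id, table.marker_names, idx, spec)
    return binned, normalizer


def pool_controls(
    tables: Sequence[CellTable], n_patients: int, seed: int
) -> tuple[CellTable, list[str]]:
    """Randomly select ``n_patients`` distinct tables and concatenate their cells.

    The selection is uniform without replacement and reproducible for a fixed
    seed; the pooled table keeps the shared marker order. Returns the pool and
    the selected sample ids (in selection order).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be positive")
    if n_patients > len(tables):
        raise ValueError(
            f"n_patients={n_patients} exceeds available tables ({len(tables)})"
        )
    names = tables[0].marker_names
    for t in tables[1:]:
        if t.marker_names != names:
            raise ValueError(
                f"inconsistent marker names: {t.sample_id!r} differs from "
                f"{tables[0].sample_id!r}"
            )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(tables), size=n_patients, replace=False)
    selected = [tables[int(i)] for i in chosen]
    pooled = np.concatenate([t.values for t in selected], axis=0)
    ids = [t.sample_id for t in selected]
    return CellTable("pooled:" + "+".join(ids), names, pooled), ids


def subsample_cells(table: CellTable, n_cells: int, seed: int) -> CellTable:
    """Uniform sample of ``n_cells`` cells without replacement, seeded.

    If ``n_cells`` is not smaller than the table, the table is returned
    unchanged (with a log note).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    if n_cells >= table.n_cells:
        if n_cells > table.n_cells:
            logger.info(
                "subsample_cells: requested %d cells but %r has only %d; keeping all",
                n_cells,
                table.sample_id,
                table.n_cells,
            )
        return table
    rng = np.random.default_rng(seed)
    rows = rng.choice(table.n_cells, size=n_cells, replace=False)
    return CellTable(table.sample_id, table.marker_names, table.values[rows])
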
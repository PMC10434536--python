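"""Two-group evaluation of NoZ scores: ROC/AUC, Mann-Whitney U, thresholds, sweeps.

Direction convention throughout: higher NoZ means more dissimilar to the
control pool, so the diseased group is expected to score higher. AUC is the
probability that a diseased sample's NoZ exceeds a control's (ties count 1/2),
which equals U / (n1 * n2) for the Mann-Whitney U of the diseased group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm

from .inference import SampleScore, score_sample
from .io_preprocess import BinningSpec, CellTable, pool_controls, subsample_cells
from .chowliu import fit_tree_model


@dataclass(frozen=True)
class EvaluationResult:
    """Classification performance of NoZ scores for one model configuration."""

    auc: float
    roc_points: tuple[tuple[float, float], ...]  # (fpr, tpr), (0,0) .. (1,1)
    u_statistic: float
    p_value: float
    threshold: float  # NoZ percent; call diseased iff NoZ > threshold
    confusion: tuple[int, int, int, int]  # (tp, fp, tn, fn)

    def __post_init__(self) -> None:
        pts = tuple((float(a), float(b)) for a, b in self.roc_points)
        object.__setattr__(self, "roc_points", pts)
        if pts[0] != (0.0, 0.0) or pts[-1] != (1.0, 1.0):
            raise ValueError("ROC must start at (0,0) and end at (1,1)")
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        if any(np.diff(fpr) < -1e-12) or any(np.diff(tpr) < -1e-12):
            raise ValueError("ROC coordinates must be non-decreasing")


def _split_scores(
    scores: Sequence[SampleScore], positive_label: str
) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([s.noz_percent for s in scores if s.label == positive_label])
    neg = np.array([s.noz_percent for s in scores if s.label != positive_label])
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must contain at least one sample")
    return pos, neg


def rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Rank-based AUC: P(pos > neg) + P(pos = neg)/2 via midranks."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


def roc_curve_points(
    pos: np.ndarray, neg: np.ndarray
) -> tuple[tuple[float, float], ...]:
    """Empirical ROC points from (0,0) to (1,1), no intermediate dropping."""
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = _skm.roc_curve(y, s, drop_intermediate=False)
    return tuple(zip(fpr.tolist(), tpr.tolist()))


def mann_whitney_u(
    pos: Sequence[float], neg: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is the statistic of the first group.

    For combined n <= 12 the p-value is computed by exact enumeration of all
    C(n, n1) group assignments of the pooled values (correct under ties);
    otherwise the tie-corrected normal approximation with continuity
    correction is used.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = pos.size, neg.size
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if n1 + n2 <= 12:
        mu = n1 * n2 / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def roc_auc(
    scores: Sequence[SampleScore], positive_label: str = "disease"
) -> tuple[float, tuple[tuple[float, float], ...]]:
    """Rank-based AUC and the empirical ROC curve of labelled sample scores."""
    pos, neg = _split_scores(scores, positive_label)
    return rank_auc(pos, neg), roc_curve_points(pos, neg)


def youden_threshold(pos: np.ndarray, neg: np.ndarray) -> float:
    """Threshold maximizing TPR - FPR for the rule NoZ > t; ties -> lowest t."""
    candidates = np.unique(np.concatenate([[0.0], pos, neg]))
    best_t, best_j = 0.0, -np.inf
    for t in candidates:  # ascending, so strict improvement keeps the lowest tie
        tpr = float(np.mean(pos > t))
        fpr = float(np.mean(neg > t))
        if tpr - fpr > best_j + 1e-12:
            best_j, best_t = tpr - fpr, float(t)
    return best_t


def classify_by_threshold(
    scores: Sequence[SampleScore],
    threshold: Optional[float] = None,
    positive_label: str = "disease",
) -> tuple[tuple[int, int, int, int], dict[str, bool], float]:
    """Call each sample diseased iff NoZ > threshold.

    With ``threshold=None`` the Youden-optimal point on the empirical ROC is
    used (maximum TPR - FPR, ties resolved toward the lower threshold).
    Returns ``(confusion, calls, threshold)`` with confusion =
    (tp, fp, tn, fn) and calls mapping sample_id -> called-diseased.
    """
    pos, neg = _split_scores(scores, positive_label)
    if threshold is None:
        threshold = youden_threshold(pos, neg)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    tp = fp = tn = fn = 0
    calls: dict[str, bool] = {}
    for s in scores:
        call = s.noz_percent > threshold
        calls[s.sample_id] = bool(call)
        if s.label == positive_label:
            tp += call
            fn += not call
        else:
            fp += call
            tn += not call
    return (int(tp), int(fp), int(tn), int(fn)), calls, float(threshold)


def evaluate_scores(
    scores: Sequence[SampleScore],
    positive_label: str = "disease",
    threshold: Optional[float] = None,
) -> EvaluationResult:
    """Full two-group evaluation: AUC, ROC, Mann-Whitney and confusion counts."""
    pos, neg = _split_scores(scores, positive_label)
    auc = rank_auc(pos, neg)
    points = roc_curve_points(pos, neg)
    u, p = mann_whitney_u(pos, neg)
    confusion, _, thr = classify_by_threshold(scores, threshold, positive_label)
    return EvaluationResult(auc, points, u, p, thr, confusion)


# --------------------------------------------------------------- sweeps ----


@dataclass(frozen=True)
class SweepRecord:
    """One evaluated configuration of the parameter sweep."""

    markers: tuple[str, ...]
    n_bins: int
    n_pooled_patients: int
    n_cells: Optional[int]
    seed: int
    auc: float
    p_value: float
    n_scored: int


def random_marker_combinations(
    marker_names: Sequence[str], k: int, n_combinations: int, seed: int
) -> list[tuple[str, ...]]:
    """Seeded random size-k marker subsets (distinct names within each subset)."""
    if k < 2:
        raise ValueError("a marker combination needs at least two markers")
    if k > len(marker_names):
        raise ValueError("k exceeds the number of available markers")
    rng = np.random.default_rng(seed)
    combos = []
    for _ in range(n_combinations):
        idx = rng.choice(len(marker_names), size=k, replace=False)
        combos.append(tuple(marker_names[int(i)] for i in idx))
    return combos


def _child_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([seed, *keys]).generate_state(1)[0] % (2**31))


def parameter_sweep(
    control_tables: Sequence[CellTable],
    disease_tables: Sequence[CellTable],
    marker_combinations: Sequence[Sequence[str]],
    n_bins_grid: Sequence[int] = (200,),
    n_pooled_grid: Sequence[int] = (20,),
    n_cells_grid: Sequence[Optional[int]] = (None,),
    seeds: Sequence[int] = (0,),
    include_pooled_controls: bool = False,
) -> list[SweepRecord]:
    """Evaluate every grid point: pool controls, fit, score held-out samples.

    For each (marker combination, n_bins, n_pooled, n_cells, seed): the cell
    tables are optionally subsampled to n_cells per sample, n_pooled control
    tables are pooled (seeded) to fit the tree, and all disease samples plus
    the non-pooled controls (all controls if ``include_pooled_controls``) are
    scored and compared. Fully deterministic for a fixed grid and seed set.
    """
    if not marker_combinations:
        raise ValueError("empty sweep grid")
    for combo in marker_combinations:
        if len(combo) < 2:
            raise ValueError("a marker combination needs at least two markers")
    records: list[SweepRecord] = []
    for combo, n_bins, n_pooled, n_cells, seed in itertools.product(
        [tuple(c) for c in marker_combinations],
        n_bins_grid,
        n_pooled_grid,
        n_cells_grid,
        seeds,
    ):
        ctrl = list(control_tables)
        dis = list(disease_tables)
        if n_cells is not None:
            ctrl = [
                subsample_cells(t, n_cells, _child_seed(seed, 1, i))
                for i, t in enumerate(ctrl)
            ]
            dis = [
                subsample_cells(t, n_cells, _child_seed(seed, 2, i))
                for i, t in enumerate(dis)
            ]
        pool, pooled_ids = pool_controls(ctrl, n_pooled, seed)
        model = fit_tree_model(
            pool,
            BinningSpec(n_bins),
            marker_subset=combo,
            provenance={"pooled_ids": pooled_ids, "seed": seed},
        )
        scores = [
            score_sample(model, t, label="control")
            for t in ctrl
            if include_pooled_controls or t.sample_id not in pooled_ids
        ]
        scores += [score_sample(model, t, label="disease") for t in dis]
        pos, neg = _split_scores(scores, "disease")
        auc = rank_auc(pos, neg)
        _, p = mann_whitney_u(pos, neg)
        records.append(
            SweepRecord(combo, n_bins, n_pooled, n_cells, seed, auc, p, len(scores))
        )
    return records


def sweep_to_frame(records: Sequence[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "markers": ["|".join(r.markers) for r in records],
            "n_bins": [r.n_bins for r in records],
            "n_pooled_patients": [r.n_pooled_patients for r in records],
            "n_cells": [r.n_cells for r in records],
            "seed": [r.seed for r in records],
            "auc": [r.auc for r in records],
            "p_value": [r.p_value for r in records],
            "n_scored": [r.n_scored for r in records],
        }
    )


def write_sweep(records: Sequence[SweepRecord], path: str | Path) -> None:
    sweep_to_frame(records).to_csv(path, index=False)
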
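"""Seeded synthetic cytometry cohorts and discrete tree-structured test data.

Two generators:

* :func:`simulate_cohorts` — continuous marker intensities: a Gaussian mixture
  per cell population with tree-structured correlation between markers and a
  per-sample mean jitter emulating inter-individual variation. Disease samples
  are identical draws except that a fraction of cells is displaced by a fixed
  number of standard deviations in a chosen set of markers, mimicking an
  aberrant low-abundance subpopulation.
* :func:`sample_from_tree_model` — exact ancestral sampling from an explicit
  discrete tree-structured distribution, used as ground truth for structure
  recovery experiments.

Everything is reproducible bit-for-bit from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_preprocess import BinnedTable, BinningSpec, CellTable


@dataclass(frozen=True)
class Population:
    """One cell population: mixture weight, per-marker location/scale, and a
    dependence tree of pairwise correlations (empty list = independent)."""

    weight: float
    mean: tuple[float, ...]
    scale: tuple[float, ...]
    dependence: tuple[tuple[int, int, float], ...] = ()  # (parent, child, rho)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", tuple(float(x) for x in self.mean))
        object.__setattr__(self, "scale", tuple(float(x) for x in self.scale))
        object.__setattr__(
            self, "dependence", tuple(tuple(e) for e in self.dependence)
        )
        if len(self.mean) != len(self.scale):
            raise ValueError("mean and scale must have the same length")
        if any(s <= 0 for s in self.scale):
            raise ValueError("scales must be positive")
        if not 0 <= self.weight <= 1:
            raise ValueError("weight must be in [0, 1]")
        for p, c, rho in self.dependence:
            if not -1 < rho < 1:
                raise ValueError("correlations must be in (-1, 1)")


@dataclass(frozen=True)
class DiseaseEffect:
    """Displacement of a cell subpopulation in disease samples."""

    affected_fraction: float
    affected_markers: tuple[int, ...]
    shift_sd: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "affected_markers", tuple(int(m) for m in self.affected_markers)
        )
        if not 0 <= self.affected_fraction <= 1:
            raise ValueError("affected_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative specification of a two-group cohort."""

    marker_names: tuple[str, ...]
    populations: tuple[Population, ...]
    n_samples_per_group: int
    n_cells: int | tuple[int, int]  # fixed, or log-uniform range (lo, hi)
    effect: DiseaseEffect
    sample_jitter_sd: float = 0.05  # per-sample mean jitter, in marker SD units
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_names", tuple(self.marker_names))
        object.__setattr__(self, "populations", tuple(self.populations))
        J = len(self.marker_names)
        if abs(sum(p.weight for p in self.populations) - 1.0) > 1e-9:
            raise ValueError("population weights must sum to 1")
        for p in self.populations:
            if len(p.mean) != J:
                raise ValueError("population dimensions must match marker count")
        if any(m >= J or m < 0 for m in self.effect.affected_markers):
            raise ValueError("affected markers outside marker range")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")


def chain_dependence(J: int, rho: float) -> tuple[tuple[int, int, float], ...]:
    """A correlation chain 0-1-2-...-(J-1) with uniform link strength rho."""
    return tuple((j, j + 1, rho) for j in range(J - 1))


def default_config(
    seed: int = 0,
    J: int = 7,
    n_samples_per_group: int = 20,
    n_cells: int | tuple[int, int] = 20_000,
    affected_fraction: float = 0.10,
    affected_markers: Sequence[int] = (2, 5),
    shift_sd: float = 4.0,
    rho: float = 0.6,
    sample_jitter_sd: float = 0.05,
) -> SyntheticConfig:
    """Reference cohort: one dominant correlated population per cell.

    Defaults describe the standard study conditions used throughout the test
    suite: 7 markers in a correlation chain (rho = 0.6), 20 samples per group
    of 20 000 cells, and a disease effect displacing 10% of cells by 4 SD in
    two markers.
    """
    names = tuple(f"M{j}" for j in range(J))
    pop = Population(
        weight=1.0,
        mean=(0.0,) * J,
        scale=(1.0,) * J,
        dependence=chain_dependence(J, rho),
    )
    return SyntheticConfig(
        marker_names=names,
        populations=(pop,),
        n_samples_per_group=n_samples_per_group,
        n_cells=n_cells,
        effect=DiseaseEffect(affected_fraction, tuple(affected_markers), shift_sd),
        sample_jitter_sd=sample_jitter_sd,
        seed=seed,
    )


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for downstream recovery checks."""

    labels: tuple[tuple[str, str], ...]  # (sample_id, group)
    dependence: tuple[tuple[int, int, float], ...]
    affected_markers: tuple[int, ...]
    seed: int

    def to_dict(self) -> dict:
        return {
            "labels": [list(x) for x in self.labels],
            "dependence": [list(x) for x in self.dependence],
            "affected_markers": list(self.affected_markers),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            tuple((a, b) for a, b in d["labels"]),
            tuple((int(p), int(c), float(r)) for p, c, r in d["dependence"]),
            tuple(int(m) for m in d["affected_markers"]),
            int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _draw_population(
    pop: Population, n: int, rng: np.random.Generator, jitter: np.ndarray
) -> np.ndarray:
    """Gaussian draw with tree-structured correlation, root-to-leaves."""
    J = len(pop.mean)
    mean = np.asarray(pop.mean) + jitter
    scale = np.asarray(pop.scale)
    x = np.empty((n, J))
    filled = np.zeros(J, dtype=bool)
    # roots: markers that never appear as a child
    children = {c for _, c, _ in pop.dependence}
    for j in range(J):
        if j not in children:
            x[:, j] = mean[j] + scale[j] * rng.standard_normal(n)
            filled[j] = True
    # iterate edges until all children are generated (tree => terminates)
    pending = list(pop.dependence)
    while pending:
        progressed = False
        for e in list(pending):
            p, c, rho = e
            if filled[p]:
                eps = rng.standard_normal(n)
                x[:, c] = (
                    mean[c]
                    + rho * (scale[c] / scale[p]) * (x[:, p] - mean[p])
                    + scale[c] * np.sqrt(1 - rho**2) * eps
                )
                filled[c] = True
                pending.remove(e)
                progressed = True
        if not progressed:
            raise ValueError("dependence edges do not form a rooted forest")
    return x


def _draw_sample(
    config: SyntheticConfig, rng: np.random.Generator, diseased: bool
) -> np.ndarray:
    if isinstance(config.n_cells, tuple):
        lo, hi = config.n_cells
        n = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        n = int(config.n_cells)
    J = len(config.marker_names)
    scales = np.asarray(config.populations[0].scale)
    jitter = config.sample_jitter_sd * scales * rng.standard_normal(J)
    weights = np.array([p.weight for p in config.populations])
    assignment = rng.choice(len(weights), size=n, p=weights)
    x = np.empty((n, J))
    for pi, pop in enumerate(config.populations):
        mask = assignment == pi
        if mask.any():
            x[mask] = _draw_population(pop, int(mask.sum()), rng, jitter)
    if diseased and config.effect.affected_fraction > 0 and config.effect.affected_markers:
        n_aff = int(round(config.effect.affected_fraction * n))
        aff = rng.choice(n, size=n_aff, replace=False)
        for m in config.effect.affected_markers:
            x[aff, m] += config.effect.shift_sd * scales[m]
    return x


def simulate_cohorts(
    config: SyntheticConfig,
) -> tuple[list[CellTable], list[CellTable], GroundTruth]:
    """Generate control and disease sample tables plus the ground truth record."""
    ss = np.random.SeedSequence(config.seed)
    n_total = 2 * config.n_samples_per_group
    children = ss.spawn(n_total)
    controls: list[CellTable] = []
    diseases: list[CellTable] = []
    labels: list[tuple[str, str]] = []
    for i in range(config.n_samples_per_group):
        rng = np.random.default_rng(children[i])
        sid = f"control_{i:03d}"
        controls.append(
            CellTable(sid, config.marker_names, _draw_sample(config, rng, False))
        )
        labels.append((sid, "control"))
    for i in range(config.n_samples_per_group):
        rng = np.random.default_rng(children[config.n_samples_per_group + i])
        sid = f"disease_{i:03d}"
        diseases.append(
            CellTable(sid, config.marker_names, _draw_sample(config, rng, True))
        )
        labels.append((sid, "disease"))
    truth = GroundTruth(
        tuple(labels),
        config.populations[0].dependence,
        config.effect.affected_markers,
        config.seed,
    )
    return controls, diseases, truth


# ------------------------------------------------ discrete tree sampler ----


@dataclass(frozen=True)
class TreeSamplerSpec:
    """Explicit discrete tree distribution for ancestral sampling.

    ``root_probs`` is the root marker's distribution over bins;
    ``conditionals`` maps each non-root marker to (parent, table) with
    ``table[child_bin, parent_bin]`` columns summing to 1.
    """

    n_bins: int
    n_markers: int
    root: int
    root_probs: np.ndarray
    conditionals: dict[int, tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        rp = np.asarray(self.root_probs, dtype=float)
        object.__setattr__(self, "root_probs", rp)
        conds = {
            int(c): (int(p), np.asarray(t, dtype=float))
            for c, (p, t) in self.conditionals.items()
        }
        object.__setattr__(self, "conditionals", conds)
        if rp.shape != (self.n_bins,) or abs(rp.sum() - 1) > 1e-9 or (rp < 0).any():
            raise ValueError("root_probs is not a distribution over the bins")
        if set(conds) | {self.root} != set(range(self.n_markers)):
            raise ValueError("every non-root marker needs exactly one conditional")
        for c, (p, t) in conds.items():
            if t.shape != (self.n_bins, self.n_bins) or (t < 0).any():
                raise ValueError(f"conditional table of marker {c} malformed")
            if np.abs(t.sum(axis=0) - 1).max() > 1e-9:
                raise ValueError(
                    f"conditional table of marker {c}: columns must sum to 1"
                )

    @property
    def edges(self) -> set[tuple[int, int]]:
        """Undirected edge set {(min, max)} of the dependence tree."""
        return {
            (min(c, p), max(c, p)) for c, (p, _) in self.conditionals.items()
        }


def chain_tree_spec(
    J: int, n_bins: int, stay_prob: float = 0.6
) -> TreeSamplerSpec:
    """Chain 0-1-...-(J-1): uniform root; each child copies its parent's bin
    with probability ``stay_prob``, otherwise is uniform over the other bins."""
    if not 0 < stay_prob < 1:
        raise ValueError("stay_prob must be in (0, 1)")
    root_probs = np.full(n_bins, 1.0 / n_bins)
    off = (1.0 - stay_prob) / (n_bins - 1)
    table = np.full((n_bins, n_bins), off)
    np.fill_diagonal(table, stay_prob)
    conds = {j: (j - 1, table) for j in range(1, J)}
    return TreeSamplerSpec(n_bins, J, 0, root_probs, conds)


def sample_from_tree_model(
    spec: TreeSamplerSpec, n_cells: int, seed: int
) -> BinnedTable:
    """Ancestral sampling root-to-leaves from an explicit discrete tree."""
    rng = np.random.default_rng(seed)
    bins = np.empty((n_cells, spec.n_markers), dtype=np.int64)
    bins[:, spec.root] = rng.choice(spec.n_bins, size=n_cells, p=spec.root_probs)
    filled = {spec.root}
    pending = dict(spec.conditionals)
    while pending:
        ready = [c for c, (p, _) in pending.items() if p in filled]
        if not ready:
            raise ValueError("conditionals do not form a tree rooted at root")
        for c in ready:
            p, table = pending.pop(c)
            cum = np.cumsum(table, axis=0)  # (child_bin, parent_bin)
            u = rng.random(n_cells)
            sel = cum[:, bins[:, p]]  # (n_bins, n_cells)
            bins[:, c] = (u[None, :] < sel).argmax(axis=0)
            filled.add(c)
    names = tuple(f"M{j}" for j in range(spec.n_markers))
    return BinnedTable(f"treesample_seed{seed}", names, bins, BinningSpec(spec.n_bins))
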
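"""Proportional (density / wiring-cost) thresholding.

A weighted connectome is thresholded by keeping exactly the k strongest
edges, k = round(density * n(n-1)/2), with a deterministic tie rule:
edges are ordered by weight descending, then by (row, column) index
ascending.  Because the rule is a fixed total order on edges, the kept
edge set at a lower density is always a subset of the set at a higher
density (nested supports).

The integration range over densities can either be fixed (the default
grid is 0.10..0.55 in steps of 0.05) or selected from the data: the
lower bound is the most conservative density at which no subject has a
fragmented (strength-0) node, the upper bound the most liberal density
at which every subject's network is still small-world (sigma > 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort, ConnectivityMatrix


class ThresholdError(ValueError):
    pass


class RangeSelectionError(RuntimeError):
    """No candidate density satisfies both range-selection criteria."""

    def __init__(self, message: str, diagnostics: pd.DataFrame):
        super().__init__(message + "\n" + diagnostics.to_string(index=False))
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class ThresholdRange:
    """Uniform, strictly increasing grid of connection densities in (0, 1]."""

    densities: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if len(d) < 2:
            raise ThresholdError("threshold range needs at least 2 densities")
        if not (np.all(d > 0) and np.all(d <= 1)):
            raise ThresholdError("densities must lie in (0, 1]")
        steps = np.diff(d)
        if np.any(steps <= 0):
            raise ThresholdError("densities must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-12:
            raise ThresholdError("densities must be uniformly spaced")
        object.__setattr__(self, "densities", tuple(float(x) for x in d))

    @property
    def step(self) -> float:
        return self.densities[1] - self.densities[0]

    def __len__(self) -> int:
        return len(self.densities)


def default_range() -> ThresholdRange:
    """The study-configuration grid: 0.10 to 0.55 in steps of 0.05 (10 values)."""
    return ThresholdRange(tuple(np.round(np.arange(10, 56, 5) / 100.0, 10)))


def default_candidates() -> tuple[float, ...]:
    """Candidate densities for range selection: 0.01..0.10 step 0.01, then to 0.90 step 0.05."""
    fine = np.arange(1, 10) / 100.0
    coarse = np.arange(10, 91, 5) / 100.0
    return tuple(np.round(np.concatenate([fine, coarse]), 10))


def edge_order(m: ConnectivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge indices in the deterministic threshold order.

    Sorted by weight descending, ties broken by row then column index
    ascending (a stable total order, the source of nested supports).
    """
    n = m.n
    iu, ju = np.triu_indices(n, 1)
    w = m.weights[iu, ju]
    # np.lexsort: last key is primary
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def edge_count_for_density(n: int, density: float) -> int:
    """k = round(density * n(n-1)/2), rounding half away from zero."""
    x = density * n * (n - 1) / 2.0
    return int(math.floor(x + 0.5))


def apply_density_threshold(m: ConnectivityMatrix, density: float) -> ConnectivityMatrix:
    """Keep exactly the k strongest edges; all other weights set to zero."""
    if not 0 < density <= 1:
        raise ThresholdError(f"density must be in (0, 1], got {density}")
    k = edge_count_for_density(m.n, density)
    if k == 0:
        raise ThresholdError(f"density {density} too low for n={m.n} (k=0 edges)")
    ii, jj = edge_order(m)
    w = np.zeros_like(m.weights)
    keep_i, keep_j = ii[:k], jj[:k]
    w[keep_i, keep_j] = m.weights[keep_i, keep_j]
    w[keep_j, keep_i] = m.weights[keep_j, keep_i]
    return ConnectivityMatrix(w, m.parcellation)


def network_density(m: ConnectivityMatrix) -> float:
    n = m.n
    iu, ju = np.triu_indices(n, 1)
    return float(np.count_nonzero(m.weights[iu, ju]) / (n * (n - 1) / 2))


def fragmented_node_count(m: ConnectivityMatrix) -> int:
    """Number of nodes with strength exactly 0."""
    return int(np.sum(m.weights.sum(axis=1) == 0))


@dataclass
class RangeSelection:
    range: ThresholdRange
    diagnostics: pd.DataFrame  # density, pct_fragmented_subjects, pct_sigma_gt1


def select_threshold_range(
    cohort: Cohort,
    candidate_densities: tuple[float, ...] | None = None,
    *,
    step: float = 0.05,
    sigma_fraction: float = 1.0,
    n_nulls: int = 20,
    swaps_per_edge: int = 10,
    seed: int = 0,
) -> RangeSelection:
    """Data-driven selection of the density integration range.

    Lower bound: the smallest candidate density at which no subject's
    thresholded matrix has a fragmented node.  Upper bound: the largest
    candidate density at which at least ``sigma_fraction`` of subjects
    have small-worldness sigma > 1 (default: all of them).  The returned
    grid runs from the lower bound upward in steps of ``step`` while it
    stays at or below the upper bound.  A per-density diagnostic table
    is attached for audit.
    """
    from .metrics import small_world_sigma
    from .nulls import NullEnsembleConfig

    candidates = tuple(candidate_densities or default_candidates())
    n_subj = cohort.n_subjects
    rows = []
    for di, density in enumerate(candidates):
        n_frag = 0
        n_sigma_gt1 = 0
        for si, subj in enumerate(cohort.subjects):
            t = apply_density_threshold(subj.matrix, density)
            if fragmented_node_count(t) > 0:
                n_frag += 1
                continue  # sigma undefined on fragmented networks
            cfg = NullEnsembleConfig(
                n_nulls=n_nulls,
                swaps_per_edge=swaps_per_edge,
                seed=int(np.random.SeedSequence([seed, si, di]).generate_state(1)[0] % 2**31),
            )
            try:
                sigma = small_world_sigma(t, config=cfg)
            except ValueError:
                continue
            if sigma > 1:
                n_sigma_gt1 += 1
        rows.append(
            {
                "density": density,
                "pct_fragmented_subjects": 100.0 * n_frag / n_subj,
                "pct_sigma_gt1": 100.0 * n_sigma_gt1 / n_subj,
            }
        )
    diag = pd.DataFrame(rows)

    ok_frag = diag["pct_fragmented_subjects"] == 0.0
    ok_sigma = diag["pct_sigma_gt1"] >= 100.0 * sigma_fraction
    if not ok_frag.any() or not ok_sigma.any():
        raise RangeSelectionError("no candidate density satisfies both criteria", diag)
    lower = float(diag.loc[ok_frag, "density"].min())
    upper = float(diag.loc[ok_sigma, "density"].max())
    if lower > upper:
        raise RangeSelectionError(
            f"fragmentation-free lower bound {lower} exceeds small-world upper bound {upper}",
            diag,
        )
    grid = []
    d = lower
    while d <= upper + 1e-12:
        grid.append(round(d, 10))
        d += step
    if len(grid) < 2:
        raise RangeSelectionError(
            f"bounds ({lower}, {upper}) leave fewer than 2 grid points at step {step}", diag
        )
    return RangeSelection(ThresholdRange(tuple(grid)), diag)
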
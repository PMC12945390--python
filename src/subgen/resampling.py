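"""Resampling inference for subspace generalization.

Four procedures:

* identity-shuffle permutation test — is the within-minus-across AUC gap of a
  population smaller than expected if cell assemblies were not preserved?
  The null permutes the unit identities of the second environment's matrix.
* matched subsampling — compare one population's gap statistics against a
  null distribution built by repeatedly subsampling a reference population
  (place cells) to matched cell counts per animal.
* low-resolution bootstrap — emulate supra-cellular resolution by sampling
  small groups of cells with replacement, averaging them into pseudo-units,
  concatenating across animals, and collecting the AUC gap for both
  projection directions (400 draws → 800 values by default).
* two-sample Kolmogorov–Smirnov comparison of two gap distributions, with a
  smoothed-histogram summary for plotting (50 bins, window 9).

All permutation/bootstrap p-values use the +1 smoothing,
p = (1 + #{null ≤ observed}) / (1 + n_draws), and are one-sided toward
"gap smaller than chance" (generalization) unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence
import warnings

import numpy as np
from scipy import stats

from ._util import as_rng
from .core import (
    ActivityMatrix,
    ScalingMode,
    generalization_gap,
    auc_from_variance,
    compute_pcs,
    variance_along,
)

__all__ = [
    "AUCDifferenceDistribution",
    "PermutationTestResult",
    "permutation_test_identity",
    "matched_subsample_test",
    "lowres_bootstrap",
    "compare_distributions",
    "KSComparison",
]


@dataclass
class AUCDifferenceDistribution:
    """Within-minus-across AUC values from a resampling procedure."""

    values: np.ndarray
    provenance: Literal["permutation", "bootstrap", "subsample"]
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("distribution values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distribution contains non-finite values")

    @property
    def n_draws(self) -> int:
        return self.values.size


@dataclass
class PermutationTestResult:
    observed: float
    null: AUCDifferenceDistribution
    pvalue: float
    alternative: str


def _smoothed_pvalue(null: np.ndarray, observed: float, alternative: str) -> float:
    if alternative == "smaller":
        hits = int(np.sum(null <= observed))
    elif alternative == "larger":
        hits = int(np.sum(null >= observed))
    elif alternative == "two-sided":
        hits = int(
            np.sum(np.abs(null - null.mean()) >= abs(observed - null.mean()))
        )
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + hits) / (1 + null.size)


def permutation_test_identity(
    A1: ActivityMatrix,
    A2: ActivityMatrix,
    n_perms: int = 1000,
    seed: int | np.random.Generator | None = None,
    scaling_mode: ScalingMode = "zscored",
    alternative: str = "smaller",
) -> PermutationTestResult:
    """Identity-shuffle test of coactivation preservation.

    Statistic: AUC_within − AUC_across (symmetrized, self-projection
    baseline).  Null draws permute the unit identities of ``A2`` only — if
    cell assemblies were arbitrary, relabeling the cells should not matter.
    Small observed gap relative to the null ⇒ the assemblies are preserved.
    """
    if A1.n_units < 3:
        raise ValueError("need at least 3 units for nontrivial permutations")
    if A1.n_units != A2.n_units:
        raise ValueError("unit counts differ")
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    rng = as_rng(seed)
    _, _, observed = generalization_gap(A1, A2, scaling_mode)
    null = np.empty(n_perms)
    for i in range(n_perms):
        perm = rng.permutation(A2.n_units)
        A2p = ActivityMatrix(
            A2.values[perm], list(A2.unit_labels), list(A2.state_labels)
        )
        _, _, null[i] = generalization_gap(A1, A2p, scaling_mode)
    dist = AUCDifferenceDistribution(null, "permutation")
    return PermutationTestResult(
        float(observed), dist, _smoothed_pvalue(null, observed, alternative),
        alternative,
    )


def _gap_both_directions(
    A1: ActivityMatrix, A2: ActivityMatrix, scaling_mode: ScalingMode
) -> tuple[float, float]:
    """(gap projecting on env-1 PCs, gap projecting on env-2 PCs)."""

    def one_direction(src: ActivityMatrix, other: ActivityMatrix) -> float:
        basis = compute_pcs(src, scaling_mode)
        within = auc_from_variance(variance_along(basis, src)).auc
        across = auc_from_variance(variance_along(basis, other)).auc
        return within - across

    return one_direction(A1, A2), one_direction(A2, A1)


def matched_subsample_test(
    grid_stats: Sequence[float],
    place_pops: Sequence[tuple[ActivityMatrix, ActivityMatrix]],
    n_cells: Sequence[int],
    n_draws: int = 500,
    seed: int | np.random.Generator | None = None,
    scaling_mode: ScalingMode = "zscored",
) -> tuple[AUCDifferenceDistribution, np.ndarray]:
    """Count-matched subsampling null (between cell types).

    Each draw subsamples every reference (place) population, without
    replacement, to its matched cell count, computes the AUC gap for both
    projection directions, and pools across animals.  Returns the pooled null
    and one +1-smoothed one-sided p-value per entry of ``grid_stats`` (is the
    statistic smaller than the reference null predicts?).
    """
    if len(place_pops) != len(n_cells):
        raise ValueError("one matched count per reference population required")
    for (a1, _), n in zip(place_pops, n_cells):
        if a1.n_units < n:
            raise ValueError(
                f"population of {a1.n_units} cells cannot be subsampled to {n}"
            )
    rng = as_rng(seed)
    null = []
    for _ in range(n_draws):
        for (a1, a2), n in zip(place_pops, n_cells):
            idx = rng.choice(a1.n_units, size=n, replace=False)
            s1 = ActivityMatrix(a1.values[idx], state_labels=list(a1.state_labels))
            s2 = ActivityMatrix(a2.values[idx], state_labels=list(a2.state_labels))
            null.extend(_gap_both_directions(s1, s2, scaling_mode))
    null = np.asarray(null)
    pvals = np.array(
        [_smoothed_pvalue(null, g, "smaller") for g in np.asarray(grid_stats, float)]
    )
    return AUCDifferenceDistribution(null, "subsample"), pvals


def lowres_bootstrap(
    animal_pairs: Sequence[tuple[ActivityMatrix, ActivityMatrix]],
    cells_per_group: int = 7,
    n_groups: int = 2,
    n_boot: int = 400,
    seed: int | np.random.Generator | None = None,
    scaling_mode: ScalingMode = "zscored",
) -> AUCDifferenceDistribution:
    """Bootstrap a low-resolution (pseudo-unit) gap distribution.

    Per draw and per animal: ``n_groups`` groups of ``cells_per_group`` cells
    are sampled with replacement (groups drawn independently; the same cells
    are used in both environments) and averaged into one pseudo-unit each.
    Pseudo-units are concatenated across animals; the AUC gap is computed for
    both projection directions, so ``n_boot`` draws yield 2·n_boot values.

    Input maps should already be normalized (see
    :func:`subgen.ratemaps.normalize_maps`).
    """
    if not animal_pairs:
        raise ValueError("need at least one animal")
    for a1, a2 in animal_pairs:
        if a1.n_units != a2.n_units:
            raise ValueError("environments of one animal differ in cell count")
    rng = as_rng(seed)
    values = np.empty(2 * n_boot)
    for b in range(n_boot):
        rows1, rows2 = [], []
        for a1, a2 in animal_pairs:
            for _ in range(n_groups):
                idx = rng.integers(0, a1.n_units, size=cells_per_group)
                rows1.append(a1.values[idx].mean(axis=0))
                rows2.append(a2.values[idx].mean(axis=0))
        s1 = ActivityMatrix(np.vstack(rows1))
        s2 = ActivityMatrix(np.vstack(rows2))
        values[2 * b], values[2 * b + 1] = _gap_both_directions(s1, s2, scaling_mode)
    return AUCDifferenceDistribution(values, "bootstrap")


@dataclass
class KSComparison:
    statistic: float
    pvalue: float
    bin_centers: np.ndarray
    density1: np.ndarray
    density2: np.ndarray


def compare_distributions(
    d1: AUCDifferenceDistribution | np.ndarray,
    d2: AUCDifferenceDistribution | np.ndarray,
    n_bins: int = 50,
    smooth_window: int = 9,
) -> KSComparison:
    """Two-sample KS test plus a smoothed-histogram display summary.

    The histogram (shared 50-bin grid, 9-sample moving average) is a plotting
    aid only; the test itself runs on the raw samples.
    """
    x1 = np.asarray(getattr(d1, "values", d1), dtype=float)
    x2 = np.asarray(getattr(d2, "values", d2), dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("both samples must be non-empty")
    if min(x1.size, x2.size) < 5:
        warnings.warn("fewer than 5 samples; KS p-value is unreliable")
    ks = stats.ks_2samp(x1, x2)
    lo = min(x1.min(), x2.min())
    hi = max(x1.max(), x2.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth_window) / smooth_window

    def smoothed_density(x: np.ndarray) -> np.ndarray:
        h, _ = np.histogram(x, bins=edges, density=True)
        return np.convolve(h, kernel, mode="same")

    return KSComparison(
        float(ks.statistic), float(ks.pvalue),
        centers, smoothed_density(x1), smoothed_density(x2),
    )
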
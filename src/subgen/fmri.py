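"""Cross-validated searchlight subspace generalization on run × graph betas.

The input is a :class:`BetaSet`: for each scanner run r ∈ {1..4} and task
graph g ∈ {Hl, Hs, Cl, Cs} (hexagonal/community structure × large/small
stimulus set), a voxels × conditions activation matrix.  For an ordered graph
pair (a, b) and held-out run j, the PCs are computed from the mean of graph
a's matrices over the runs ≠ j and graph b's run-j matrix is projected onto
them; the normalized cumulative variance-explained AUC, averaged over the
four folds, fills entry (a, b) of a 4 × 4 alignment matrix.  PCs and data
thus never come from the same run — including on the diagonal, which uses
cross-run data of the same graph, never a self-projection of identical data.

Contrasts over the alignment matrix isolate effects: the *visual* contrast
compares same-graph to same-structure/different-stimuli entries, the
*structural* contrast compares hexagonal data on hexagonal versus community
PCs.  Group-level inference uses a one-sample t per voxel with a max-statistic
sign-flip permutation null for familywise-error control (cluster-free
enhancement is deliberately not implemented; the max-t procedure keeps the
same sign-flip scaffold and null-max logic with no extra parameters).

A source matrix of 100 voxels × 10 conditions has rank ≤ 10, so eigenvectors
beyond the rank are an arbitrary completion.  The pipeline therefore takes
the informative directions from an SVD of the source and spreads the
projected variance of the orthogonal complement uniformly over the remaining
basis directions — exactly the expected AUC over a Haar-random completion,
and deterministic.  For full-rank sources this coincides with the generic
eigendecomposition path in :mod:`subgen.core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._util import DimensionMismatchError, as_rng
from .core import ActivityMatrix, ScalingMode, prepare_matrix

__all__ = [
    "DEFAULT_GRAPHS",
    "BetaSet",
    "AUCMatrix",
    "ContrastSpec",
    "builtin_contrast",
    "crossval_auc_matrix",
    "apply_contrast",
    "searchlight_run",
    "group_signflip",
    "SignFlipResult",
]

DEFAULT_GRAPHS = ("Hl", "Hs", "Cl", "Cs")


@dataclass
class BetaSet:
    """(run, graph) → voxels × conditions activity matrices, plus optional
    volume geometry (boolean mask + affine) for searchlight mode.

    All entries must share the same voxel set and ordering; in searchlight
    mode rows correspond to ``np.argwhere(mask)`` order.
    """

    betas: Mapping[tuple[int, str], ActivityMatrix]
    mask: np.ndarray | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = dict(self.betas)
        if not self.betas:
            raise ValueError("empty beta set")
        first = next(iter(self.betas.values()))
        for key, mat in self.betas.items():
            if mat.unit_labels != first.unit_labels:
                raise DimensionMismatchError(
                    f"voxel set of {key} differs from the other entries"
                )
            if mat.n_states < 2:
                raise ValueError(f"{key} has fewer than 2 conditions")
        runs = sorted({r for r, _ in self.betas})
        graphs = sorted({g for _, g in self.betas})
        for r in runs:
            for g in graphs:
                if (r, g) not in self.betas:
                    raise ValueError(f"missing (run={r}, graph={g})")
        self._runs = runs
        # keep canonical graph order when the standard four are present
        if set(graphs) == set(DEFAULT_GRAPHS):
            graphs = list(DEFAULT_GRAPHS)
        self._graphs = graphs
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if int(self.mask.sum()) != first.n_units:
                raise DimensionMismatchError(
                    f"mask has {int(self.mask.sum())} voxels, "
                    f"matrices have {first.n_units}"
                )

    @property
    def runs(self) -> list[int]:
        return list(self._runs)

    @property
    def graphs(self) -> list[str]:
        return list(self._graphs)

    @property
    def n_voxels(self) -> int:
        return next(iter(self.betas.values())).n_units


@dataclass
class AUCMatrix:
    """Graphs × graphs alignment matrix; entry (a, b) is the run-averaged AUC
    of graph b's data projected on graph a's cross-validated PCs."""

    values: np.ndarray
    graphs: list[str] = field(default_factory=lambda: list(DEFAULT_GRAPHS))
    run_averaged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = len(self.graphs)
        if self.values.shape != (g, g):
            raise DimensionMismatchError("alignment matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("alignment matrix contains non-finite values")

    def entry(self, data_graph: str, pc_graph: str) -> float:
        """Entry in data-on-PCs notation, e.g. ('Hs', 'Cs') = HsCs."""
        return float(
            self.values[self.graphs.index(pc_graph), self.graphs.index(data_graph)]
        )

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.values, **kwargs)
        ax.set_xticks(range(len(self.graphs)), self.graphs)
        ax.set_yticks(range(len(self.graphs)), self.graphs)
        ax.set_xlabel("data graph")
        ax.set_ylabel("PC-source graph")
        ax.figure.colorbar(im, ax=ax, label="AUC")
        return ax


@dataclass
class ContrastSpec:
    """Weights over the alignment matrix (rows = PC source, cols = data)."""

    weights: np.ndarray
    name: str = "custom"
    graphs: list[str] = field(default_factory=lambda: list(DEFAULT_GRAPHS))

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        g = len(self.graphs)
        if self.weights.shape != (g, g):
            raise DimensionMismatchError("contrast weight shape mismatch")

    @classmethod
    def from_pairs(
        cls,
        name: str,
        positive: Sequence[tuple[str, str]],
        negative: Sequence[tuple[str, str]] = (),
        graphs: Sequence[str] = DEFAULT_GRAPHS,
    ) -> "ContrastSpec":
        """Build from (data_graph, pc_graph) pairs in the XY notation where
        'HsCs' means data Hs projected on PCs of Cs."""
        graphs = list(graphs)
        w = np.zeros((len(graphs), len(graphs)))
        for data, pcs in positive:
            w[graphs.index(pcs), graphs.index(data)] += 1.0
        for data, pcs in negative:
            w[graphs.index(pcs), graphs.index(data)] -= 1.0
        return cls(w, name, graphs)


def builtin_contrast(name: str, graphs: Sequence[str] = DEFAULT_GRAPHS) -> ContrastSpec:
    """The two named contrasts of the pipeline, in data-on-PCs notation.

    ``visual``:    [HlHl + ClCl + HsHs + CsCs] − [HlHs + HsHl + ClCs + CsCl]
    ``structural``: [HlHl + HlHs + HsHl + HsHs] − [HlCl + HlCs + HsCl + HsCs]
    """
    if name == "visual":
        return ContrastSpec.from_pairs(
            "visual",
            positive=[("Hl", "Hl"), ("Cl", "Cl"), ("Hs", "Hs"), ("Cs", "Cs")],
            negative=[("Hl", "Hs"), ("Hs", "Hl"), ("Cl", "Cs"), ("Cs", "Cl")],
            graphs=graphs,
        )
    if name == "structural":
        return ContrastSpec.from_pairs(
            "structural",
            positive=[("Hl", "Hl"), ("Hl", "Hs"), ("Hs", "Hl"), ("Hs", "Hs")],
            negative=[("Hl", "Cl"), ("Hl", "Cs"), ("Hs", "Cl"), ("Hs", "Cs")],
            graphs=graphs,
        )
    raise ValueError(f"unknown contrast {name!r}")


def apply_contrast(m: AUCMatrix, c: ContrastSpec) -> float:
    if m.values.shape != c.weights.shape or m.graphs != c.graphs:
        raise DimensionMismatchError("contrast does not match alignment matrix")
    return float(np.sum(c.weights * m.values))


# ---------------------------------------------------------------------------
# rank-aware AUC

def _auc_weights(rank: int, k_total: int) -> tuple[np.ndarray, float]:
    """Trapezoidal AUC as a linear functional of normalized per-direction
    variances: AUC = Σ_i m_i (1 − (i−½)/K).  Returns the weights of the first
    ``rank`` directions and the mean weight of the remaining K − rank
    (the uniform-spread value for the orthogonal complement)."""
    idx = np.arange(1, rank + 1)
    w = 1.0 - (idx - 0.5) / k_total
    tail = 1.0 - (rank + k_total) / (2.0 * k_total) if k_total > rank else 0.0
    return w, tail


def _crossval_fold_auc(
    source_mean: np.ndarray, data: np.ndarray, k_total: int
) -> float:
    """AUC of ``data`` on the full PC basis of ``source_mean`` (both already
    prepared), with the complement variance spread uniformly."""
    u, s, _ = np.linalg.svd(source_mean, full_matrices=False)
    proj = u.T @ data
    v = np.einsum("ij,ij->i", proj, proj)
    total = float(np.sum(data * data))
    if total <= 0:
        raise ValueError("projected matrix has zero total variance")
    resid = max(total - float(v.sum()), 0.0)
    w, tail = _auc_weights(v.size, k_total)
    return float(np.dot(v / total, w) + (resid / total) * tail)


def crossval_auc_matrix(
    bs: BetaSet, scaling_mode: ScalingMode = "raw"
) -> AUCMatrix:
    """Leave-one-run-out alignment matrix over all ordered graph pairs."""
    runs, graphs = bs.runs, bs.graphs
    if len(runs) < 2:
        raise ValueError("cross-validation requires at least 2 runs")
    n_vox = bs.n_voxels
    acc = np.zeros((len(graphs), len(graphs)))
    for j in runs:
        others = [r for r in runs if r != j]
        for ai, a in enumerate(graphs):
            mean_raw = np.mean([bs.betas[(r, a)].values for r in others], axis=0)
            source = prepare_matrix(
                ActivityMatrix(mean_raw), scaling_mode
            ).values
            for bi, b in enumerate(graphs):
                data = prepare_matrix(bs.betas[(j, b)], scaling_mode).values
                acc[ai, bi] += _crossval_fold_auc(source, data, n_vox)
    return AUCMatrix(acc / len(runs), graphs)


# ---------------------------------------------------------------------------
# searchlight

def _neighborhoods(coords: np.ndarray, k: int, chunk: int = 256) -> np.ndarray:
    """k nearest in-mask voxels per center (Euclidean on integer grid
    coordinates, center included, ties broken by linear index — coords are in
    argwhere order, i.e. ascending linear index, and the sort is stable)."""
    n = coords.shape[0]
    if k > n:
        raise ValueError(f"searchlight k={k} exceeds mask size {n}")
    c = coords.astype(np.int64)
    out = np.empty((n, k), dtype=np.intp)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d2 = ((c[lo:hi, None, :] - c[None, :, :]) ** 2).sum(-1)
        out[lo:hi] = np.argsort(d2, axis=1, kind="stable")[:, :k]
    return out


def searchlight_run(
    bs: BetaSet,
    contrast: ContrastSpec | str,
    k_neighbors: int = 100,
    scaling_mode: ScalingMode = "raw",
    chunk: int = 64,
    return_matrices: bool = False,
):
    """Per-voxel contrast map of the cross-validated alignment matrix.

    For every in-mask center voxel, the alignment matrix is computed on the
    submatrix of its ``k_neighbors`` nearest in-mask voxels and the contrast
    applied.  Returns a volume aligned to the mask geometry (NaN outside the
    mask); with ``return_matrices`` also the (n_mask, G, G) AUC matrices.
    """
    if bs.mask is None:
        raise ValueError("searchlight mode requires a mask")
    if isinstance(contrast, str):
        contrast = builtin_contrast(contrast, bs.graphs)
    coords = np.argwhere(bs.mask)
    neigh = _neighborhoods(coords, k_neighbors)
    runs, graphs = bs.runs, bs.graphs
    n_mask, ng = coords.shape[0], len(graphs)

    prepared = {
        key: prepare_matrix(mat, scaling_mode).values
        for key, mat in bs.betas.items()
    }
    means = {}
    for j in runs:
        others = [r for r in runs if r != j]
        for g in graphs:
            raw_mean = np.mean([bs.betas[(r, g)].values for r in others], axis=0)
            means[(j, g)] = prepare_matrix(
                ActivityMatrix(raw_mean), scaling_mode
            ).values

    n_cond = next(iter(prepared.values())).shape[1]
    rank = min(k_neighbors, n_cond)
    w_top, w_tail = _auc_weights(rank, k_neighbors)

    aucs = np.zeros((n_mask, ng, ng))
    for lo in range(0, n_mask, chunk):
        idx = neigh[lo : lo + chunk]  # (c, k)
        for j in runs:
            data_nb = {
                b: prepared[(j, b)][idx] for b in graphs
            }  # each (c, k, C)
            totals = {
                b: np.einsum("cki,cki->c", d, d) for b, d in data_nb.items()
            }
            for ai, a in enumerate(graphs):
                u = np.linalg.svd(means[(j, a)][idx], full_matrices=False)[0]
                for bi, b in enumerate(graphs):
                    p = np.einsum("cki,ckj->cij", u, data_nb[b])
                    v = np.einsum("cij,cij->ci", p, p)
                    tot = totals[b]
                    resid = np.clip(tot - v.sum(1), 0.0, None)
                    aucs[lo : lo + chunk, ai, bi] += (
                        v @ w_top + resid * w_tail
                    ) / tot
    aucs /= len(runs)

    cvals = np.einsum("cab,ab->c", aucs, contrast.weights)
    cmap = np.full(bs.mask.shape, np.nan)
    cmap[bs.mask] = cvals
    if return_matrices:
        return cmap, aucs
    return cmap


# ---------------------------------------------------------------------------
# group-level sign-flip inference

@dataclass
class SignFlipResult:
    tmap: np.ndarray
    p_fwe: np.ndarray
    null_max: np.ndarray
    n_flips: int
    exhaustive: bool


def _t_from_signs(x: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t per voxel for each sign assignment.

    ``x`` is (n_subjects, n_voxels), ``signs`` (n_draws, n_subjects).  Sign
    flips leave each subject's squared value unchanged, so only the mean
    moves; sd = 0 with a nonzero mean gives ±inf, an all-zero voxel gives 0.
    """
    n = x.shape[0]
    mean = signs @ x / n
    ss = np.sum(x * x, axis=0)
    var = (ss - n * mean**2) / (n - 1)
    var = np.clip(var, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def group_signflip(
    contrast_maps: Sequence[np.ndarray],
    n_flips: int = 10000,
    seed: int | np.random.Generator | None = None,
    mask: np.ndarray | None = None,
    exhaustive: bool = False,
) -> SignFlipResult:
    """Voxelwise FWE-corrected one-sided (positive) inference.

    The observed statistic is the one-sample t per voxel; each null draw
    randomly flips every subject's map sign and records the maximum t over
    the mask.  FWE p per voxel = (1 + #{null max ≥ t}) / (1 + n_flips); with
    ``exhaustive`` all 2^n sign patterns are enumerated instead and
    p = #{null max ≥ t} / 2^n (the identity pattern is one of them).
    """
    maps = [np.asarray(m, dtype=float) for m in contrast_maps]
    n = len(maps)
    if n < 2:
        raise ValueError("group inference needs at least 2 subjects")
    shape = maps[0].shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    x = np.stack([m[mask] for m in maps])  # (n, V)

    tobs = _t_from_signs(x, np.ones((1, n)))[0]
    if exhaustive:
        if n > 20:
            raise ValueError("exhaustive enumeration limited to 20 subjects")
        codes = np.arange(2**n)[:, None] >> np.arange(n)
        signs = ((codes & 1) * 2 - 1).astype(float)
        null_max = _t_from_signs(x, signs).max(axis=1)
        p = np.sum(null_max[:, None] >= tobs[None, :], axis=0) / signs.shape[0]
        n_used = signs.shape[0]
    else:
        rng = as_rng(seed)
        null_max = np.empty(n_flips)
        batch = max(1, min(n_flips, 2_000_000 // max(x.shape[1], 1)))
        done = 0
        while done < n_flips:
            m = min(batch, n_flips - done)
            signs = rng.choice([-1.0, 1.0], size=(m, n))
            null_max[done : done + m] = _t_from_signs(x, signs).max(axis=1)
            done += m
        p = (1 + np.sum(null_max[:, None] >= tobs[None, :], axis=0)) / (
            1 + n_flips
        )
        n_used = n_flips

    tmap = np.full(shape, np.nan)
    pmap = np.full(shape, np.nan)
    tmap[mask] = tobs
    pmap[mask] = p
    return SignFlipResult(tmap, pmap, null_max, n_used, exhaustive)
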
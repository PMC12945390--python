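"""Subspace generalization: PC bases, cross-projection variance, AUC.

The central quantity of the package.  A population's unit × state activity
matrix ``A`` (cells × spatial bins, or voxels × task conditions) is summarized
by the eigenvectors of its unit × unit second-moment matrix ``A·Aᵀ`` — the
principal components, which are activity patterns across units ("cell
assemblies").  To ask how well the subspace occupied by task 1 explains task
2, task 2's matrix is projected onto task 1's PCs:

    V12 = diag(PC1ᵀ · A2 · A2ᵀ · PC1)

i.e. the task-2 variance captured along each task-1 direction, with the PCs
ordered by their task-1 eigenvalues.  The running sum of ``V12``, normalized
by task 2's total variance, is a concave curve over the PC index; its area
under the curve (trapezoidal, with an origin point, index axis rescaled to
[0, 1]) is the subspace-generalization score.  A shared low-dimensional
subspace pushes the curve toward the top-left corner (AUC → 1); projecting
onto directions unrelated to the data gives a linear curve and AUC = 0.5 in
expectation (the chance level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._util import DegenerateInputError, DimensionMismatchError, as_rng

__all__ = [
    "ActivityMatrix",
    "PCBasis",
    "GeneralizationCurve",
    "ScalingMode",
    "prepare_matrix",
    "compute_pcs",
    "variance_along",
    "auc_from_variance",
    "generalization_curve",
    "subspace_generalization",
    "self_projection_auc",
    "generalization_gap",
    "random_orthonormal_basis",
    "chance_auc",
]

ScalingMode = Literal["raw", "centered", "zscored"]
_SCALING_MODES = ("raw", "centered", "zscored")

#: eigenvalues below EIGENVALUE_CLIP × (largest eigenvalue) are treated as 0
EIGENVALUE_CLIP = 1e-12


def _as_labels(labels: Sequence[str] | None, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise DimensionMismatchError(
            f"{len(labels)} {prefix} labels for {n} {prefix}s"
        )
    return labels


@dataclass
class ActivityMatrix:
    """A units × states real matrix with axis labels.

    The universal input of the package: rows are recording units (cells or
    voxels), columns are task states (spatial bins or conditions).
    """

    values: np.ndarray
    unit_labels: list[str] = field(default=None)  # type: ignore[assignment]
    state_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activity matrix must be 2-D (units × states)")
        n_units, n_states = self.values.shape
        if n_units < 2 or n_states < 2:
            raise ValueError(
                f"need at least 2 units and 2 states, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activity matrix contains non-finite values")
        self.unit_labels = _as_labels(self.unit_labels, n_units, "unit")
        self.state_labels = _as_labels(self.state_labels, n_states, "state")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ActivityMatrix":
        return ActivityMatrix(
            self.values.copy(), list(self.unit_labels), list(self.state_labels)
        )

    @classmethod
    def from_dataframe(cls, df) -> "ActivityMatrix":
        """Build from a pandas DataFrame (index = units, columns = states)."""
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.unit_labels, columns=self.state_labels
        )


@dataclass
class PCBasis:
    """Orthonormal directions (columns) with non-increasing eigenvalues."""

    directions: np.ndarray  # (n_units, K)
    eigenvalues: np.ndarray  # (K,)
    scaling_mode: ScalingMode = "raw"

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.directions.ndim != 2:
            raise ValueError("directions must be 2-D (units × K)")
        n, k = self.directions.shape
        if self.eigenvalues.shape != (k,):
            raise DimensionMismatchError(
                f"{self.eigenvalues.shape[0]} eigenvalues for {k} directions"
            )
        gram = self.directions.T @ self.directions
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("directions are not orthonormal (1e-8)")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be sorted non-increasing")
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("eigenvalues must be non-negative")
        self.eigenvalues = np.clip(self.eigenvalues, 0.0, None)

    @property
    def n_units(self) -> int:
        return self.directions.shape[0]

    @property
    def n_components(self) -> int:
        return self.directions.shape[1]

    def truncate(self, k: int) -> "PCBasis":
        """Keep the top ``k`` directions (exploration helper)."""
        if not 1 <= k <= self.n_components:
            raise ValueError(f"cannot truncate to k={k}")
        return PCBasis(
            self.directions[:, :k], self.eigenvalues[:k], self.scaling_mode
        )


@dataclass
class GeneralizationCurve:
    """Per-PC variance, normalized cumulative curve and trapezoidal AUC.

    ``cumulative_fraction`` has length K+1 and starts at 0 so the trapezoid
    includes the origin; the index axis is rescaled to [0, 1], which makes a
    uniform spread of variance (the chance curve) integrate to exactly 0.5.
    Built in two stages: :func:`variance_along` fills the per-direction
    variances and the total, :func:`auc_from_variance` completes the curve.
    """

    per_pc_variance: np.ndarray
    total_variance: float
    cumulative_fraction: np.ndarray | None = None
    auc: float | None = None

    def __post_init__(self) -> None:
        self.per_pc_variance = np.asarray(self.per_pc_variance, dtype=float)
        if self.per_pc_variance.ndim != 1:
            raise ValueError("per_pc_variance must be 1-D")
        if np.any(self.per_pc_variance < -1e-10 * max(self.total_variance, 1.0)):
            raise ValueError("per_pc_variance must be non-negative")
        self.per_pc_variance = np.clip(self.per_pc_variance, 0.0, None)

    @property
    def n_components(self) -> int:
        return self.per_pc_variance.shape[0]

    def plot(self, ax=None, **kwargs):
        """Plot the normalized cumulative curve (completing it if needed)."""
        curve = self if self.auc is not None else auc_from_variance(self)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        k = curve.n_components
        x = np.linspace(0.0, 1.0, k + 1)
        ax.plot(x, curve.cumulative_fraction, **kwargs)
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
        ax.set_xlabel("PC index (fraction of basis)")
        ax.set_ylabel("cumulative variance explained")
        return ax


def prepare_matrix(raw: ActivityMatrix, scaling_mode: ScalingMode) -> ActivityMatrix:
    """Return a per-unit rescaled copy of ``raw``.

    raw      — unchanged copy (the printed beta-matrix equations use B·Bᵀ);
    centered — each unit's across-state mean removed (covariance convention);
    zscored  — centered and divided by the unit's across-state sample sd
               (ddof=1), under which X·Xᵀ is (n_states−1)× the unit × unit
               correlation matrix used for rate-map pipelines.
    """
    if scaling_mode not in _SCALING_MODES:
        raise ValueError(f"unknown scaling_mode {scaling_mode!r}")
    x = raw.values.copy()
    if scaling_mode in ("centered", "zscored"):
        x -= x.mean(axis=1, keepdims=True)
    if scaling_mode == "zscored":
        sd = raw.values.std(axis=1, ddof=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            names = ", ".join(raw.unit_labels[i] for i in bad[:5])
            raise DegenerateInputError(
                f"zero variance across states for unit(s) {names}; "
                "cannot z-score"
            )
        x /= sd[:, None]
    return ActivityMatrix(x, list(raw.unit_labels), list(raw.state_labels))


def compute_pcs(A: ActivityMatrix, scaling_mode: ScalingMode = "raw") -> PCBasis:
    """Full PC basis of the unit × unit second-moment matrix of prepared A.

    Eigenvalues sum to the total sum of squares of the prepared matrix;
    values below ``EIGENVALUE_CLIP`` × max are clipped to zero.  The basis is
    complete (K = n_units); ordering among exactly tied eigenvalues is
    solver-dependent but does not affect any downstream variance partial sum.
    """
    x = prepare_matrix(A, scaling_mode).values
    second_moment = x @ x.T
    evals, evecs = np.linalg.eigh(second_moment)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    if evals[0] > 0:
        evals[evals < EIGENVALUE_CLIP * evals[0]] = 0.0
    return PCBasis(evecs, evals, scaling_mode)


def variance_along(
    basis: PCBasis, A: ActivityMatrix, scaling_mode: ScalingMode | None = None
) -> GeneralizationCurve:
    """Variance of (prepared) ``A`` along each basis direction.

    Entry k is the sum over states of squared projections onto direction k;
    ``total_variance`` is the total sum of squares of the prepared matrix, so
    with a complete basis the entries sum to the total.  The returned curve
    is not yet cumulated — pass it to :func:`auc_from_variance`.
    """
    if scaling_mode is None:
        scaling_mode = basis.scaling_mode
    if basis.n_units != A.n_units:
        raise DimensionMismatchError(
            f"basis has {basis.n_units} units, matrix has {A.n_units}"
        )
    x = prepare_matrix(A, scaling_mode).values
    proj = basis.directions.T @ x  # (K, n_states)
    per_pc = np.einsum("ks,ks->k", proj, proj)
    total = float(np.sum(x * x))
    return GeneralizationCurve(per_pc, total)


def generalization_curve(
    per_pc_variance: np.ndarray, total_variance: float
) -> GeneralizationCurve:
    """Complete a curve directly from per-direction variances and a total."""
    return auc_from_variance(GeneralizationCurve(per_pc_variance, total_variance))


def auc_from_variance(curve: GeneralizationCurve) -> GeneralizationCurve:
    """Fill in the normalized cumulative curve and its trapezoidal AUC."""
    if not curve.total_variance > 0:
        raise DegenerateInputError(
            f"total variance must be positive, got {curve.total_variance}"
        )
    k = curve.n_components
    cum = np.concatenate(
        ([0.0], np.cumsum(curve.per_pc_variance) / curve.total_variance)
    )
    auc = float(np.trapezoid(cum, dx=1.0 / k))
    return replace(curve, cumulative_fraction=cum, auc=auc)


def _check_matched_units(A1: ActivityMatrix, A2: ActivityMatrix) -> None:
    if A1.unit_labels != A2.unit_labels:
        raise DimensionMismatchError(
            "unit labels of the two matrices do not match"
        )


def subspace_generalization(
    A1: ActivityMatrix,
    A2: ActivityMatrix,
    scaling_mode: ScalingMode = "zscored",
    symmetrize: bool = False,
) -> float:
    """AUC of ``A2`` projected on the PCs of ``A1``.

    With ``symmetrize`` the two projection directions (A2 on PCs of A1, and
    A1 on PCs of A2) are averaged, as when reporting a single
    across-environment score.
    """
    _check_matched_units(A1, A2)
    auc_12 = auc_from_variance(
        variance_along(compute_pcs(A1, scaling_mode), A2)
    ).auc
    if not symmetrize:
        return float(auc_12)
    auc_21 = auc_from_variance(
        variance_along(compute_pcs(A2, scaling_mode), A1)
    ).auc
    return float(0.5 * (auc_12 + auc_21))


def self_projection_auc(A: ActivityMatrix, scaling_mode: ScalingMode = "zscored") -> float:
    """AUC of a matrix on its own PCs — the within-task ceiling."""
    return subspace_generalization(A, A, scaling_mode)


def _splithalf_auc(A: ActivityMatrix, scaling_mode: ScalingMode) -> float:
    """Within-task AUC estimated across disjoint state halves (even/odd
    states), averaged over both directions — a less optimistic baseline than
    self-projection when states are noisy."""
    even = ActivityMatrix(A.values[:, 0::2], list(A.unit_labels))
    odd = ActivityMatrix(A.values[:, 1::2], list(A.unit_labels))
    return subspace_generalization(even, odd, scaling_mode, symmetrize=True)


def generalization_gap(
    A1: ActivityMatrix,
    A2: ActivityMatrix,
    scaling_mode: ScalingMode = "zscored",
    baseline: Literal["self", "splithalf"] = "self",
) -> tuple[float, float, float]:
    """(AUC_within, AUC_across, gap = within − across), symmetrized.

    ``within`` averages the two within-task baselines — self-projection
    ceilings by default, or cross-projections between even/odd state halves
    with ``baseline="splithalf"`` — and ``across`` the two cross-task
    projections.  A gap near zero means the two tasks occupy the same
    subspace (generalization); a large gap means remapping.
    """
    if baseline == "self":
        within = 0.5 * (
            self_projection_auc(A1, scaling_mode)
            + self_projection_auc(A2, scaling_mode)
        )
    elif baseline == "splithalf":
        within = 0.5 * (
            _splithalf_auc(A1, scaling_mode) + _splithalf_auc(A2, scaling_mode)
        )
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    across = subspace_generalization(A1, A2, scaling_mode, symmetrize=True)
    return float(within), float(across), float(within - across)


def random_orthonormal_basis(
    n_units: int, seed: int | np.random.Generator | None = None
) -> PCBasis:
    """A Haar-uniform random orthonormal basis (QR of a Gaussian matrix,
    sign-fixed by the R diagonal so the distribution is exactly uniform)."""
    rng = as_rng(seed)
    g = rng.standard_normal((n_units, n_units))
    q, r = np.linalg.qr(g)
    q *= np.sign(np.diag(r))
    return PCBasis(q, np.zeros(n_units), "raw")


def chance_auc(
    A: ActivityMatrix,
    n_draws: int = 2000,
    seed: int | np.random.Generator | None = None,
    scaling_mode: ScalingMode = "raw",
) -> float:
    """Empirical chance level: mean AUC over Haar-random orthonormal bases.

    By linearity of expectation this equals 0.5 for any data matrix; the
    function exists to verify that numerically.
    """
    rng = as_rng(seed)
    x = prepare_matrix(A, scaling_mode)
    aucs = np.empty(n_draws)
    for i in range(n_draws):
        basis = random_orthonormal_basis(A.n_units, rng)
        aucs[i] = auc_from_variance(variance_along(basis, x, "raw")).auc
    return float(aucs.mean())
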
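"""Model/Results interface over the library, statsmodels-style.

Three model classes cover the three analysis levels:

* :class:`SubspaceGeneralization` — two unit × state matrices (two
  environments or tasks recorded from the same units); ``fit`` computes the
  within/across AUCs, the generalization gap, and optionally an
  identity-shuffle permutation p-value.
* :class:`CrossvalSubspace` — a run × graph BetaSet; ``fit`` computes the
  leave-one-run-out 4 × 4 alignment matrix and evaluates contrasts.
* :class:`GroupSignFlip` — per-subject contrast maps; ``fit`` runs the
  max-statistic sign-flip FWE procedure.

Each ``fit`` returns a Results object carrying the estimates, resampling
uncertainty where applicable, and a ``summary()`` table; plotting hangs off
the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ActivityMatrix,
    ScalingMode,
    auc_from_variance,
    compute_pcs,
    variance_along,
)
from .fmri import (
    AUCMatrix,
    BetaSet,
    ContrastSpec,
    SignFlipResult,
    apply_contrast,
    builtin_contrast,
    crossval_auc_matrix,
    group_signflip,
)
from .ratemaps import RateMapStack, flatten
from .resampling import PermutationTestResult, permutation_test_identity

__all__ = [
    "SubspaceGeneralization",
    "SubspaceGeneralizationResults",
    "CrossvalSubspace",
    "CrossvalSubspaceResults",
    "GroupSignFlip",
    "GroupSignFlipResults",
]


def _fmt(x: float) -> str:
    return f"{x: .4f}"


class SubspaceGeneralization:
    """Subspace generalization between two tasks recorded from one unit set."""

    def __init__(
        self,
        task_a: ActivityMatrix,
        task_b: ActivityMatrix,
        scaling_mode: ScalingMode = "zscored",
    ):
        if task_a.unit_labels != task_b.unit_labels:
            raise ValueError("the two tasks must share the same unit set")
        self.task_a = task_a
        self.task_b = task_b
        self.scaling_mode = scaling_mode

    @classmethod
    def from_dataframes(cls, df_a, df_b, scaling_mode: ScalingMode = "zscored"):
        return cls(
            ActivityMatrix.from_dataframe(df_a),
            ActivityMatrix.from_dataframe(df_b),
            scaling_mode,
        )

    @classmethod
    def from_ratemaps(
        cls,
        stack_a: RateMapStack,
        stack_b: RateMapStack,
        scaling_mode: ScalingMode = "zscored",
    ):
        return cls(flatten(stack_a), flatten(stack_b), scaling_mode)

    def fit(
        self,
        n_perms: int = 0,
        seed: int | np.random.Generator | None = None,
    ) -> "SubspaceGeneralizationResults":
        basis_a = compute_pcs(self.task_a, self.scaling_mode)
        basis_b = compute_pcs(self.task_b, self.scaling_mode)
        curves = {
            "a_on_a": auc_from_variance(variance_along(basis_a, self.task_a)),
            "b_on_a": auc_from_variance(variance_along(basis_a, self.task_b)),
            "b_on_b": auc_from_variance(variance_along(basis_b, self.task_b)),
            "a_on_b": auc_from_variance(variance_along(basis_b, self.task_a)),
        }
        within = 0.5 * (curves["a_on_a"].auc + curves["b_on_b"].auc)
        across = 0.5 * (curves["b_on_a"].auc + curves["a_on_b"].auc)
        perm = None
        if n_perms:
            perm = permutation_test_identity(
                self.task_a,
                self.task_b,
                n_perms=n_perms,
                seed=seed,
                scaling_mode=self.scaling_mode,
            )
        return SubspaceGeneralizationResults(
            self, curves, float(within), float(across), perm
        )


@dataclass
class SubspaceGeneralizationResults:
    model: SubspaceGeneralization
    curves: dict
    auc_within: float
    auc_across: float
    permutation: PermutationTestResult | None = None

    @property
    def gap(self) -> float:
        """Within − across AUC; near 0 ⇒ the tasks share their subspace."""
        return self.auc_within - self.auc_across

    def summary(self) -> str:
        m = self.model
        lines = [
            "Subspace generalization",
            "=" * 47,
            f"units: {m.task_a.n_units}   states: "
            f"{m.task_a.n_states} / {m.task_b.n_states}   "
            f"scaling: {m.scaling_mode}",
            "-" * 47,
            f"AUC within  (self-projection)  {_fmt(self.auc_within)}",
            f"AUC across  (symmetrized)      {_fmt(self.auc_across)}",
            f"gap (within - across)          {_fmt(self.gap)}",
        ]
        if self.permutation is not None:
            p = self.permutation
            lines += [
                "-" * 47,
                f"identity-shuffle null ({p.null.n_draws} perms, "
                f"alternative: {p.alternative})",
                f"null gap mean {_fmt(float(p.null.values.mean()))}   "
                f"p = {p.pvalue:.4g}",
            ]
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Within (solid) and across (dotted) cumulative curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        self.curves["a_on_a"].plot(ax=ax, color="k", label="within (a|a)")
        self.curves["b_on_b"].plot(ax=ax, color="k", ls="--", label="within (b|b)")
        self.curves["b_on_a"].plot(ax=ax, color="tab:green", ls=":", label="across (b|a)")
        self.curves["a_on_b"].plot(ax=ax, color="tab:green", ls="-.", label="across (a|b)")
        ax.legend()
        return ax


class CrossvalSubspace:
    """Leave-one-run-out alignment analysis of a run × graph BetaSet."""

    def __init__(self, betas: BetaSet, scaling_mode: ScalingMode = "raw"):
        self.betas = betas
        self.scaling_mode = scaling_mode

    def fit(self) -> "CrossvalSubspaceResults":
        return CrossvalSubspaceResults(
            self, crossval_auc_matrix(self.betas, self.scaling_mode)
        )


@dataclass
class CrossvalSubspaceResults:
    model: CrossvalSubspace
    auc_matrix: AUCMatrix

    def contrast(self, spec: ContrastSpec | str) -> float:
        if isinstance(spec, str):
            spec = builtin_contrast(spec, self.auc_matrix.graphs)
        return apply_contrast(self.auc_matrix, spec)

    def summary(self) -> str:
        g = self.auc_matrix.graphs
        head = "Cross-validated subspace alignment (rows: PC graph, cols: data graph)"
        lines = [head, "=" * len(head), "        " + "".join(f"{x:>8}" for x in g)]
        for i, gi in enumerate(g):
            lines.append(
                f"{gi:>8}" + "".join(f"{v:8.4f}" for v in self.auc_matrix.values[i])
            )
        lines.append("-" * len(head))
        for name in ("visual", "structural"):
            try:
                lines.append(f"{name:>10} contrast  {_fmt(self.contrast(name))}")
            except ValueError:
                pass
        lines.append("=" * len(head))
        return "\n".join(lines)

    def plot(self, ax=None, **kwargs):
        return self.auc_matrix.plot(ax=ax, **kwargs)


class GroupSignFlip:
    """Max-statistic sign-flip FWE inference over subjects' contrast maps."""

    def __init__(self, contrast_maps, mask: np.ndarray | None = None):
        self.contrast_maps = list(contrast_maps)
        self.mask = mask

    def fit(
        self,
        n_flips: int = 10000,
        seed: int | np.random.Generator | None = None,
        exhaustive: bool = False,
    ) -> "GroupSignFlipResults":
        return GroupSignFlipResults(
            self,
            group_signflip(
                self.contrast_maps,
                n_flips=n_flips,
                seed=seed,
                mask=self.mask,
                exhaustive=exhaustive,
            ),
        )


@dataclass
class GroupSignFlipResults:
    model: GroupSignFlip
    result: SignFlipResult

    @property
    def tmap(self) -> np.ndarray:
        return self.result.tmap

    @property
    def p_fwe(self) -> np.ndarray:
        return self.result.p_fwe

    def n_significant(self, alpha: float = 0.05) -> int:
        return int(np.nansum(self.result.p_fwe < alpha))

    def summary(self, alpha: float = 0.05) -> str:
        r = self.result
        finite_t = r.tmap[np.isfinite(r.tmap)]
        kind = "exhaustive" if r.exhaustive else "random"
        lines = [
            "Group sign-flip inference (max-statistic FWE)",
            "=" * 46,
            f"subjects: {len(self.model.contrast_maps)}   "
            f"flips: {r.n_flips} ({kind})",
            f"peak t = {np.max(finite_t) if finite_t.size else float('nan'):.3f}   "
            f"min FWE p = {np.nanmin(r.p_fwe):.4g}",
            f"voxels with FWE p < {alpha}: {self.n_significant(alpha)}",
            "=" * 46,
        ]
        return "\n".join(lines)
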
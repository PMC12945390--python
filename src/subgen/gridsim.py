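"""Grid-cell modules, environment realignment, and pseudo-voxel aggregation.

A grid cell's rate map is the thresholded (rectified) sum of three 2-D
cosines whose wave vectors are 60° apart with magnitude 4π/(√3·spacing), so
the firing fields sit on a hexagonal lattice with the given spacing and
orientation.  A *module* is a population of such cells tiling the unit
rhombus of phase offsets (default 116 × 116 = 13,456 cells), so the average
map across the module is near-constant over the box.

Across environments a module realigns coherently: every cell's fields shift
by the same module-level phase offset (optionally rotate), so pairwise
coactivation is preserved — the defining generalization property of grid
cells, and the property the subspace-generalization measure is built to
detect.  Realignment shifts are snapped to the module's phase lattice, under
which the realigned population is exactly a permutation of the original one
(see :func:`realignment_permutation`).

Pseudo-voxels emulate the supra-cellular resolution of BOLD: each module is
split into groups of cells (either randomly, or contiguously by grid phase,
or a mixture controlled by ``ratio_random``), and a voxel's map is the mean
of its member cells' peak-normalized maps, optionally plus spatial white
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._util import DegenerateInputError, as_rng
from .core import ActivityMatrix
from .ratemaps import RateMapStack

__all__ = [
    "GridModuleSpec",
    "EnvironmentRealignment",
    "VoxelGrouping",
    "GridModule",
    "default_module_specs",
    "grid_cell_map",
    "build_module",
    "realign",
    "realignment_permutation",
    "group_into_voxels",
    "add_voxel_noise",
    "simulate_place_cells",
    "pseudo_voxel_pair",
    "power_sweep",
]


@dataclass(frozen=True)
class GridModuleSpec:
    """Geometry of one grid module and of the simulated box.

    ``spacing`` and ``box_size`` share the same (arbitrary) environment unit;
    ``phase_lattice`` is the number of phase offsets along each rhombus axis;
    ``threshold`` is subtracted from the three-cosine sum before
    rectification (0 = plain zero-clipping).
    """

    spacing: float
    orientation: float = 0.0  # radians
    phase_lattice: tuple[int, int] = (116, 116)
    threshold: float = 0.0
    box_size: float = 10.0
    resolution: int = 50

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if min(self.phase_lattice) < 1:
            raise ValueError("phase_lattice entries must be >= 1")
        if self.resolution < 8:
            raise ValueError("resolution must be >= 8")

    @property
    def n_cells(self) -> int:
        return self.phase_lattice[0] * self.phase_lattice[1]

    def lattice_vectors(self, rotation: float = 0.0) -> np.ndarray:
        """Rows: the two primitive lattice vectors a1, a2 (60° apart)."""
        th = self.orientation + rotation
        return self.spacing * np.array(
            [
                [np.cos(th), np.sin(th)],
                [np.cos(th + np.pi / 3), np.sin(th + np.pi / 3)],
            ]
        )

    def wave_vectors(self, rotation: float = 0.0) -> np.ndarray:
        """Rows: the three wave vectors, 60° apart, |k| = 4π/(√3·spacing)."""
        th = self.orientation + rotation
        mag = 4 * np.pi / (np.sqrt(3) * self.spacing)
        angles = th + np.pi / 6 + np.array([0.0, np.pi / 3, 2 * np.pi / 3])
        return mag * np.column_stack([np.cos(angles), np.sin(angles)])

    def bin_centers(self) -> np.ndarray:
        """(resolution², 2) box coordinates of bin centers, row-major."""
        step = self.box_size / self.resolution
        c = (np.arange(self.resolution) + 0.5) * step
        gx, gy = np.meshgrid(c, c, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass(frozen=True)
class EnvironmentRealignment:
    """Module-level realignment between environments.

    ``phase_shift`` is a 2-vector in rhombus coordinates (fractions of the
    two lattice vectors), wrapped into [0, 1) and snapped to the module's
    phase lattice when maps are rendered; ``rotation`` rotates the whole
    grid pattern (default 0: shift only).
    """

    phase_shift: tuple[float, float] = (0.0, 0.0)
    rotation: float = 0.0

    def __post_init__(self) -> None:
        u, v = self.phase_shift
        object.__setattr__(self, "phase_shift", (float(u) % 1.0, float(v) % 1.0))

    def lattice_steps(self, phase_lattice: tuple[int, int]) -> tuple[int, int]:
        """Nearest lattice point: (round(u·P1) mod P1, round(v·P2) mod P2)."""
        p1, p2 = phase_lattice
        return (
            int(round(self.phase_shift[0] * p1)) % p1,
            int(round(self.phase_shift[1] * p2)) % p2,
        )


@dataclass(frozen=True)
class VoxelGrouping:
    """How cells are aggregated into pseudo-voxels within each module.

    ``ratio_random`` = 0 groups purely by grid phase (contiguous blocks of
    the lex-sorted rhombus coordinates); 1 groups purely at random; values
    in between remove a random fraction first and phase-block the rest.
    Group sizes are equal within ±1 cell.
    """

    n_groups_per_module: int = 4
    ratio_random: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_random <= 1.0:
            raise ValueError("ratio_random must be in [0, 1]")
        if self.n_groups_per_module < 1:
            raise ValueError("need at least one group per module")


def default_module_specs(
    phase_lattice: tuple[int, int] = (116, 116),
    box_size: float = 10.0,
    resolution: int = 50,
) -> list[GridModuleSpec]:
    """Four modules with ≈√2 spacing progression and staggered orientations,
    the standard rodent module geometry.

    Spacings are in box units and chosen so every module fits several grid
    periods into the box (2.4–6.7 periods at the default box of 10): with
    fewer than ~2 periods, box-boundary effects dominate the voxel maps and
    the coherent-realignment subspace is no longer preserved across
    environments, destroying the very property grid modules are simulated to
    exhibit.  The ratio of arena size to module spacing here matches typical
    rodent recordings (30–100 cm spacing in a 1–2 m arena).
    """
    spacings = (1.5, 2.1, 2.95, 4.15)
    orientations = np.deg2rad((0.0, 7.5, 15.0, 22.5))
    return [
        GridModuleSpec(s, o, phase_lattice, 0.0, box_size, resolution)
        for s, o in zip(spacings, orientations)
    ]


def _render_maps(
    spec: GridModuleSpec,
    phases_frac: np.ndarray,
    env: EnvironmentRealignment,
    dtype=np.float32,
) -> np.ndarray:
    """Rate maps for phases given as rhombus fractions, shape (n, res, res).

    r(x) = max(0, Σ_m cos(k_m·(x − φ − Δ)) − threshold) evaluated on the box
    grid, computed as a single matmul via the angle-addition identity.
    """
    lat = spec.lattice_vectors(env.rotation)
    kvecs = spec.wave_vectors(env.rotation)
    steps = env.lattice_steps(spec.phase_lattice)
    shift = (steps[0] / spec.phase_lattice[0]) * lat[0] + (
        steps[1] / spec.phase_lattice[1]
    ) * lat[1]
    offsets = phases_frac @ lat + shift  # (n, 2) box coordinates
    theta = spec.bin_centers() @ kvecs.T  # (S, 3)
    psi = offsets @ kvecs.T  # (n, 3)
    raw = np.cos(psi, dtype=dtype) @ np.cos(theta, dtype=dtype).T
    raw += np.sin(psi, dtype=dtype) @ np.sin(theta, dtype=dtype).T
    raw -= dtype(spec.threshold)
    np.maximum(raw, 0.0, out=raw)
    n = phases_frac.shape[0]
    return raw.reshape(n, spec.resolution, spec.resolution)


@dataclass
class GridModule:
    """A grid-cell population: spec + environment + per-cell phases.

    ``phases`` are rhombus-fraction coordinates, one row per cell.  Maps are
    rendered on demand (a full default module is ~130 MB, so they are not
    cached).
    """

    spec: GridModuleSpec
    env: EnvironmentRealignment = field(default_factory=EnvironmentRealignment)
    phases: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.phases is None:
            p1, p2 = self.spec.phase_lattice
            gi, gj = np.meshgrid(np.arange(p1), np.arange(p2), indexing="ij")
            self.phases = np.column_stack([gi.ravel() / p1, gj.ravel() / p2])
        self.phases = np.asarray(self.phases, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.phases.shape[0]

    def maps(self, dtype=np.float32) -> np.ndarray:
        return _render_maps(self.spec, self.phases, self.env, dtype)

    def stack(self) -> RateMapStack:
        return RateMapStack(
            self.maps(np.float64),
            [f"cell{i}" for i in range(self.n_cells)],
        )


def grid_cell_map(
    spec: GridModuleSpec,
    phase: tuple[float, float],
    env: EnvironmentRealignment | None = None,
) -> np.ndarray:
    """Single-cell rate map (resolution × resolution) for one phase."""
    env = env or EnvironmentRealignment()
    return _render_maps(spec, np.atleast_2d(np.asarray(phase, float)), env, np.float64)[0]


def build_module(
    spec: GridModuleSpec, env: EnvironmentRealignment | None = None
) -> GridModule:
    """One cell per phase-lattice offset covering the unit rhombus."""
    return GridModule(spec, env or EnvironmentRealignment())


def realign(module: GridModule, env2: EnvironmentRealignment) -> GridModule:
    """The same cells in a second environment (common module-level offset)."""
    return GridModule(module.spec, env2, module.phases.copy())


def realignment_permutation(
    module: GridModule, env2: EnvironmentRealignment
) -> np.ndarray:
    """Index array π with maps(env2)[c] == maps(env1)[π(c)] for a full-lattice
    module with a pure (rotation-free) shift: shifting every phase by the same
    lattice step relabels the population."""
    p1, p2 = module.spec.phase_lattice
    if module.n_cells != p1 * p2:
        raise ValueError("permutation only defined for a full-lattice module")
    d1 = env2.lattice_steps((p1, p2))
    d0 = module.env.lattice_steps((p1, p2))
    di, dj = (d1[0] - d0[0]) % p1, (d1[1] - d0[1]) % p2
    gi, gj = np.meshgrid(np.arange(p1), np.arange(p2), indexing="ij")
    return (((gi + di) % p1) * p2 + (gj + dj) % p2).ravel()


def _group_membership(
    n_cells: int,
    phases: np.ndarray,
    grouping: VoxelGrouping,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Cell index sets per group: random fraction first, remainder
    phase-blocked; combined sizes equal within ±1."""
    g = grouping.n_groups_per_module
    if g > n_cells:
        raise ValueError(f"{g} groups exceed {n_cells} cells")
    base, extra = divmod(n_cells, g)
    targets = np.array([base + (i < extra) for i in range(g)])

    n_random = int(round(grouping.ratio_random * n_cells))
    random_idx = rng.choice(n_cells, size=n_random, replace=False)
    rng.shuffle(random_idx)
    rand_sizes = np.minimum(
        targets, [n_random // g + (i < n_random % g) for i in range(g)]
    )
    # phase-sorted remainder, cut into contiguous blocks sized to equalize
    rest = np.setdiff1d(np.arange(n_cells), random_idx)
    order = np.lexsort((phases[rest, 1], phases[rest, 0]))
    rest = rest[order]
    rest_sizes = targets - rand_sizes

    members = []
    r0 = p0 = 0
    for gi in range(g):
        r1, p1 = r0 + rand_sizes[gi], p0 + rest_sizes[gi]
        members.append(np.concatenate([random_idx[r0:r1], rest[p0:p1]]))
        r0, p0 = r1, p1
    return members


def group_into_voxels(
    modules: Sequence[GridModule],
    grouping: VoxelGrouping,
    normalize: str = "peak",
) -> ActivityMatrix:
    """Aggregate cells into pseudo-voxels: voxel map = mean of member cells.

    Membership depends only on (grouping, module order, phases), never on the
    environment, so calling this on realigned modules with the same grouping
    keeps each voxel's cell membership fixed — grouping and realignment
    commute.  Per-cell maps are peak-normalized before averaging by default
    (``normalize="none"`` disables), which is what makes the phase-grouped vs
    random-grouped amplitude contrast visible.
    """
    if not modules:
        raise ValueError("need at least one module")
    res = modules[0].spec.resolution
    box = modules[0].spec.box_size
    for m in modules[1:]:
        if m.spec.resolution != res or m.spec.box_size != box:
            raise ValueError("modules must share box size and resolution")
    children = np.random.SeedSequence(grouping.seed).spawn(len(modules))
    rows, labels = [], []
    for mi, (module, ss) in enumerate(zip(modules, children)):
        rng = np.random.default_rng(ss)
        members = _group_membership(module.n_cells, module.phases, grouping, rng)
        maps = module.maps().reshape(module.n_cells, -1)
        if normalize == "peak":
            peaks = maps.max(axis=1)
            if np.any(peaks <= 0):
                raise DegenerateInputError("cell with an all-zero map")
            maps = maps / peaks[:, None]
        elif normalize != "none":
            raise ValueError(f"unknown normalize {normalize!r}")
        for gi, idx in enumerate(members):
            rows.append(maps[idx].mean(axis=0, dtype=np.float64))
            labels.append(f"m{mi}_g{gi}")
        del maps
    states = [f"bin_{i}_{j}" for i in range(res) for j in range(res)]
    return ActivityMatrix(np.vstack(rows), labels, states)


def add_voxel_noise(
    A: ActivityMatrix, sigma: float, seed: int | np.random.Generator | None = None
) -> ActivityMatrix:
    """Independent zero-mean Gaussian noise, sd = sigma, per voxel per bin."""
    if sigma < 0:
        raise ValueError("noise sd must be non-negative")
    out = A.copy()
    if sigma > 0:
        out.values += as_rng(seed).normal(0.0, sigma, size=out.values.shape)
    return out


def simulate_place_cells(
    n_cells: int,
    field_width: float = 1.2,
    box_size: float = 10.0,
    resolution: int = 50,
    seed: int | np.random.Generator | None = None,
    remap: bool = True,
) -> tuple[RateMapStack, RateMapStack]:
    """Gaussian-bump place cells in two environments.

    Centers are uniform in the box; with ``remap`` (the place-cell
    phenomenology) environment 2 redraws every center independently, breaking
    the coactivation structure while leaving each within-environment map
    statistically identical.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = as_rng(seed)
    step = box_size / resolution
    c = (np.arange(resolution) + 0.5) * step
    gx, gy = np.meshgrid(c, c, indexing="ij")

    def stack_from_centers(centers: np.ndarray) -> RateMapStack:
        d2 = (gx[None] - centers[:, 0, None, None]) ** 2 + (
            gy[None] - centers[:, 1, None, None]
        ) ** 2
        return RateMapStack(np.exp(-0.5 * d2 / field_width**2))

    centers1 = rng.uniform(0, box_size, size=(n_cells, 2))
    centers2 = rng.uniform(0, box_size, size=(n_cells, 2)) if remap else centers1
    return stack_from_centers(centers1), stack_from_centers(centers2)


def pseudo_voxel_pair(
    grouping: VoxelGrouping,
    specs: Sequence[GridModuleSpec] | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[ActivityMatrix, ActivityMatrix]:
    """Noise-free pseudo-voxel matrices for two environments.

    Environment 1 uses zero realignment; environment 2 draws an independent
    uniform phase shift per module (snapped to the phase lattice).  The same
    grouping is applied to both, so voxel membership is identical.
    """
    rng = as_rng(seed)
    specs = list(specs) if specs is not None else default_module_specs()
    env1 = EnvironmentRealignment()
    mods1 = [build_module(s, env1) for s in specs]
    mods2 = [
        realign(m, EnvironmentRealignment(tuple(rng.uniform(0, 1, 2))))
        for m in mods1
    ]
    return (
        group_into_voxels(mods1, grouping),
        group_into_voxels(mods2, grouping),
    )


def power_sweep(
    ratio_grid: Sequence[float],
    sigma_grid: Sequence[float],
    n_reps: int = 1,
    seed: int | np.random.Generator | None = None,
    specs: Sequence[GridModuleSpec] | None = None,
    n_groups: int = 4,
    n_perms: int = 0,
    scaling_mode: str = "zscored",
):
    """Sweep grouping randomness × noise level; one row per grid cell × rep.

    Columns: ratio_random, sigma, rep, auc_within, auc_between, gap, and a
    one-sided identity-permutation p-value when ``n_perms`` > 0.  Reproducible
    under a fixed seed; a 1×1 grid with one rep reduces to a single
    subspace-generalization evaluation.
    """
    import pandas as pd

    from .core import generalization_gap
    from .resampling import permutation_test_identity

    if len(ratio_grid) == 0 or len(sigma_grid) == 0:
        raise ValueError("sweep grids must be non-empty")
    root = np.random.SeedSequence(
        seed if isinstance(seed, (int, np.integer)) or seed is None else None
    )
    rows = []
    for rep in range(n_reps):
        rep_ss = root.spawn(1)[0]
        env_rng = np.random.default_rng(rep_ss)
        group_seed = int(env_rng.integers(2**31))
        for ratio in ratio_grid:
            grouping = VoxelGrouping(n_groups, float(ratio), group_seed)
            a1, a2 = pseudo_voxel_pair(grouping, specs, env_rng)
            for sigma in sigma_grid:
                n1 = add_voxel_noise(a1, float(sigma), env_rng)
                n2 = add_voxel_noise(a2, float(sigma), env_rng)
                within, across, gap = generalization_gap(n1, n2, scaling_mode)
                row = {
                    "ratio_random": float(ratio),
                    "sigma": float(sigma),
                    "rep": rep,
                    "auc_within": within,
                    "auc_between": across,
                    "gap": gap,
                }
                if n_perms > 0:
                    row["p_perm"] = permutation_test_identity(
                        n1, n2, n_perms=n_perms, seed=env_rng,
                        scaling_mode=scaling_mode,
                    ).pvalue
                rows.append(row)
    return pd.DataFrame(rows)
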
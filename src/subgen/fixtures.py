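"""Seeded generators for every input the pipeline needs — no downloads.

The planted beta generator emulates the statistical structure the
entorhinal-style analysis assumes: inside an *effect region*, graphs of the
same structural family share a low-dimensional subspace of voxel loadings
that is stable across runs; everywhere else (and for the non-shared part of
the signal) the loadings are redrawn per run, so nothing generalizes across
runs and the structural contrast is null by construction.  Condition codes
are fresh random draws for every run and graph — there is deliberately no
condition correspondence across graphs, which is the regime the
subspace-generalization method exists for.

For graph g of family f(g), run r:

    B_{g,r} = ( W_f(g) · Z_{g,r}  +  W_{g,r} · Z'_{g,r} ) / √d  +  ε

where ``W_f`` (voxels × round(overlap·d)) is drawn once per subject per
family and supported on the effect region only, ``W_{g,r}`` carries the
remaining d − round(overlap·d) run-specific columns over all voxels, the Z
are i.i.d. N(0,1) condition codes and ε is N(0, noise_sd²).  ``overlap`` = 0
removes every run-stable component (all 16 alignment entries at chance);
``overlap`` = 1 makes all four within-family entries elevated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._util import as_rng
from .core import ActivityMatrix
from .fmri import DEFAULT_GRAPHS, BetaSet
from .gridsim import (
    EnvironmentRealignment,
    GridModule,
    GridModuleSpec,
    default_module_specs,
    simulate_place_cells,
)
from .ratemaps import EventTable, RateMapStack

__all__ = [
    "PlantedBetaSpec",
    "generate_beta_set",
    "generate_session",
    "preset",
    "PRESET_NAMES",
]

_FAMILY = {"Hl": "H", "Hs": "H", "Cl": "C", "Cs": "C"}


@dataclass(frozen=True)
class PlantedBetaSpec:
    """Planted-subspace run × graph beta volumes for a cohort of subjects."""

    n_subjects: int = 12
    shape: tuple[int, int, int] = (10, 10, 10)
    n_conditions: int = 10
    n_runs: int = 4
    shared_dim: int = 6
    overlap: float = 1.0
    noise_sd: float = 0.5
    effect_center: tuple[float, float, float] = (2.0, 2.0, 2.0)
    effect_radius: float = 2.6
    seed: int = 0
    graphs: tuple[str, ...] = DEFAULT_GRAPHS

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must be in [0, 1]")
        if self.shared_dim >= int(np.prod(self.shape)):
            raise ValueError("shared_dim must be smaller than the voxel count")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def effect_mask(self) -> np.ndarray:
        """Ball of ``effect_radius`` voxels around ``effect_center``.

        The region sits toward one corner of the volume so the opposite
        corner has voxels whose searchlights never touch it.
        """
        grid = np.indices(self.shape).reshape(3, -1).T
        d = np.linalg.norm(grid - np.asarray(self.effect_center), axis=1)
        return (d <= self.effect_radius).reshape(self.shape)

    def null_mask(self, k_neighbors: int = 100) -> np.ndarray:
        """Voxels whose ``k_neighbors``-voxel searchlight contains no effect
        voxel, computed with the pipeline's own neighborhood definition (near
        box corners a searchlight reaches much farther than in the bulk, so a
        fixed distance margin would be wrong)."""
        from .fmri import _neighborhoods

        coords = np.argwhere(np.ones(self.shape, dtype=bool))
        neigh = _neighborhoods(coords, k_neighbors)
        effect_flat = self.effect_mask().ravel()
        clean = ~effect_flat[neigh].any(axis=1)
        return clean.reshape(self.shape)


def generate_beta_set(
    spec: PlantedBetaSpec, subject: int = 0
) -> BetaSet:
    """One subject's BetaSet; bit-reproducible from (spec, subject)."""
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject,))
    rng = np.random.default_rng(ss)
    n_vox, d = spec.n_voxels, spec.shared_dim
    d_sh = int(round(spec.overlap * d))
    d_fresh = d - d_sh
    effect = spec.effect_mask().ravel()
    mask = np.ones(spec.shape, dtype=bool)

    w_family = {}
    for fam in ("H", "C"):
        w = np.zeros((n_vox, d_sh))
        w[effect] = rng.standard_normal((int(effect.sum()), d_sh))
        w_family[fam] = w

    betas = {}
    for r in range(1, spec.n_runs + 1):
        for g in spec.graphs:
            z_sh = rng.standard_normal((d_sh, spec.n_conditions))
            w_fresh = rng.standard_normal((n_vox, d_fresh))
            z_fresh = rng.standard_normal((d_fresh, spec.n_conditions))
            b = (w_family[_FAMILY.get(g, g[0])] @ z_sh + w_fresh @ z_fresh) / np.sqrt(d)
            b += spec.noise_sd * rng.standard_normal((n_vox, spec.n_conditions))
            betas[(r, g)] = ActivityMatrix(
                b,
                [f"v{i}" for i in range(n_vox)],
                [f"cond{c}" for c in range(spec.n_conditions)],
            )
    return BetaSet(betas, mask=mask, affine=np.eye(4))


def generate_session(
    rate_surfaces: RateMapStack | np.ndarray,
    duration: float = 600.0,
    dt: float = 0.02,
    seed: int | np.random.Generator | None = None,
    box_size: float = 10.0,
    speed_sd: float = 2.0,
    tau: float = 1.0,
) -> EventTable:
    """A random-walk foraging session with inhomogeneous Poisson spiking.

    The trajectory is an Ornstein–Uhlenbeck velocity process (relaxation time
    ``tau`` s, stationary speed scale ``speed_sd`` units/s) reflected at the
    box walls.  Each cell spikes as a Poisson process whose rate (Hz) is its
    surface value at the current position's bin; spike times are jittered
    uniformly within their time step.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = as_rng(seed)
    maps = rate_surfaces.maps if isinstance(rate_surfaces, RateMapStack) else np.asarray(rate_surfaces)
    if maps.ndim == 2:
        maps = maps[None]
    n_cells, res_x, res_y = maps.shape

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps) * dt
    pos = np.empty((n_steps, 2))
    pos[0] = rng.uniform(0, box_size, 2)
    vel = rng.normal(0, speed_sd, 2)
    alpha = np.exp(-dt / tau)
    kick = speed_sd * np.sqrt(1 - alpha**2)
    for i in range(1, n_steps):
        vel = alpha * vel + kick * rng.standard_normal(2)
        p = pos[i - 1] + vel * dt
        for ax in range(2):  # reflect at walls
            if p[ax] < 0:
                p[ax] = -p[ax]
                vel[ax] = -vel[ax]
            elif p[ax] > box_size:
                p[ax] = 2 * box_size - p[ax]
                vel[ax] = -vel[ax]
        pos[i] = np.clip(p, 0, box_size)

    ix = np.clip((pos[:, 0] / box_size * res_x).astype(int), 0, res_x - 1)
    iy = np.clip((pos[:, 1] / box_size * res_y).astype(int), 0, res_y - 1)
    spikes = {}
    for c in range(n_cells):
        lam = maps[c, ix, iy] * dt
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(n_steps), counts)
        st = times[idx] + rng.uniform(0, dt, idx.size)
        st = np.sort(np.clip(st, times[0], times[-1]))
        spikes[f"cell{c}"] = st
    return EventTable(
        times, pos, spikes, bounds=((0.0, box_size), (0.0, box_size))
    )


@dataclass
class GridPlaceBundle:
    """Per-animal (env1, env2) map stacks for one cell type."""

    animals: list[tuple[RateMapStack, RateMapStack]]
    kind: str


def _grid_animal(
    n_cells: int,
    spec: GridModuleSpec,
    rng: np.random.Generator,
) -> tuple[RateMapStack, RateMapStack]:
    """Random-phase grid cells from one module; env2 applies one common,
    lattice-snapped shift (coherent realignment)."""
    phases = rng.uniform(0, 1, size=(n_cells, 2))
    env1 = EnvironmentRealignment()
    env2 = EnvironmentRealignment(tuple(rng.uniform(0, 1, 2)))
    m1 = GridModule(spec, env1, phases)
    m2 = GridModule(spec, env2, phases.copy())
    return m1.stack(), m2.stack()


PRESET_NAMES = ("grid_pair", "place_pair", "mixed_animals", "fmri_small")


def preset(name: str, seed: int = 2024):
    """Named, versioned fixture bundles used by the tests and docs.

    grid_pair / place_pair — 3 pseudo-animals × 20 cells each, two
    environments (grid: coherent realignment; place: full remapping),
    25 × 25 maps in a 10 × 10 box.
    mixed_animals — dict with both bundles from a shared seed stream.
    fmri_small — PlantedBetaSpec for a 12-subject, 10×10×10 cohort with a
    central planted effect region, plus the generated subjects.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    rng = np.random.default_rng(seed)
    if name in ("grid_pair", "place_pair", "mixed_animals"):
        specs = default_module_specs(phase_lattice=(24, 24), resolution=25)
        grids = GridPlaceBundle(
            [_grid_animal(20, specs[i % len(specs)], rng) for i in range(3)],
            "grid",
        )
        places = GridPlaceBundle(
            [simulate_place_cells(20, 1.2, 10.0, 25, rng) for _ in range(3)],
            "place",
        )
        if name == "grid_pair":
            return grids
        if name == "place_pair":
            return places
        return {"grid": grids, "place": places}
    spec = PlantedBetaSpec(seed=seed)
    subjects = [generate_beta_set(spec, s) for s in range(spec.n_subjects)]
    return spec, subjects
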
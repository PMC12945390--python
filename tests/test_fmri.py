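"""Cross-validated alignment matrices, contrasts, searchlight, sign-flip FWE."""

import numpy as np
import pytest

from subgen import (
    ActivityMatrix,
    AUCMatrix,
    BetaSet,
    ContrastSpec,
    apply_contrast,
    builtin_contrast,
    crossval_auc_matrix,
    group_signflip,
    searchlight_run,
)
from subgen.fmri import _auc_weights, _neighborhoods
from subgen.core import generalization_curve

GRAPHS = ("Hl", "Hs", "Cl", "Cs")


def constant_betaset(rng, n_vox=12, n_cond=6):
    m = ActivityMatrix(rng.standard_normal((n_vox, n_cond)))
    return BetaSet({(r, g): m for r in range(1, 5) for g in GRAPHS})


class TestAUCWeights:
    def test_linear_functional_matches_trapezoid(self, rng):
        """AUC = Σ m_i·(1 − (i−½)/K), and uniform spreading of the residual
        equals the explicit padded-variance trapezoid."""
        k_total, r = 20, 6
        v = rng.random(r)
        resid = 2.0
        total = v.sum() + resid
        w, tail = _auc_weights(r, k_total)
        fast = v / total @ w + (resid / total) * tail
        padded = np.concatenate([v, np.full(k_total - r, resid / (k_total - r))])
        assert fast == pytest.approx(generalization_curve(padded, total).auc, abs=1e-12)


class TestCrossvalAUCMatrix:
    def test_identical_matrices_equal_entries(self, rng):
        m = crossval_auc_matrix(constant_betaset(rng))
        assert np.allclose(m.values, m.values[0, 0])
        assert np.all((m.values > 0) & (m.values <= 1))

    def test_missing_cell_rejected(self, rng):
        m = ActivityMatrix(rng.standard_normal((8, 5)))
        betas = {(r, g): m for r in range(1, 5) for g in GRAPHS}
        del betas[(2, "Cl")]
        with pytest.raises(ValueError, match="Cl"):
            BetaSet(betas)

    def test_no_leakage_of_held_out_run(self, rng):
        """Each run's matrix is rank-1 along a run-specific orthogonal
        direction, so the held-out run is orthogonal to the PC source; if the
        held-out run leaked into the PCs the AUC would be near its maximum."""
        q, _ = np.linalg.qr(rng.standard_normal((8, 4)))
        betas = {
            (r, g): ActivityMatrix(np.outer(q[:, r - 1], rng.standard_normal(4)))
            for r in range(1, 5)
            for g in GRAPHS
        }
        m = crossval_auc_matrix(BetaSet(betas))
        # orthogonal-complement spread only: AUC stays near the tail value
        assert np.all(m.values < 0.6)

    def test_planted_family_structure_recovered(self):
        """Graphs sharing voxel loadings align better: HH entries exceed HC
        entries for every seed."""
        from subgen.fixtures import PlantedBetaSpec, generate_beta_set

        for seed in range(5):
            spec = PlantedBetaSpec(
                n_subjects=1, shape=(4, 4, 4), shared_dim=3, overlap=1.0,
                noise_sd=0.5, effect_radius=99.0, effect_center=(1.5, 1.5, 1.5),
                seed=seed,
            )
            m = crossval_auc_matrix(generate_beta_set(spec, 0))
            hh = np.mean([m.entry(d, p) for d in ("Hl", "Hs") for p in ("Hl", "Hs")])
            hc = np.mean([m.entry(d, p) for d in ("Hl", "Hs") for p in ("Cl", "Cs")])
            assert hh > hc + 0.05

    def test_graph_relabeling_permutes_matrix(self, rng):
        """Permuting graph labels of the input permutes rows and columns of
        the alignment matrix consistently."""
        mats = {g: ActivityMatrix(rng.standard_normal((8, 5))) for g in GRAPHS}
        noise = {
            (r, g): ActivityMatrix(
                mats[g].values + 0.1 * rng.standard_normal((8, 5))
            )
            for r in range(1, 5)
            for g in GRAPHS
        }
        m = crossval_auc_matrix(BetaSet(noise))
        for da in GRAPHS:
            for pa in GRAPHS:
                assert m.entry(da, pa) == pytest.approx(
                    m.values[GRAPHS.index(pa), GRAPHS.index(da)]
                )


class TestContrasts:
    def test_zero_matrix_zero_contrast(self):
        m = AUCMatrix(np.zeros((4, 4)) + 1e-9)
        assert apply_contrast(m, builtin_contrast("structural")) == pytest.approx(0)

    def test_constant_matrix_zero_sum_weights(self):
        m = AUCMatrix(np.full((4, 4), 0.7))
        for name in ("structural", "visual"):
            c = builtin_contrast(name)
            assert c.weights.sum() == 0
            assert apply_contrast(m, c) == pytest.approx(0)

    def test_block_arithmetic(self):
        """HH block 0.9 and HC block 0.7 give structural contrast 0.8."""
        vals = np.full((4, 4), 0.5)
        for pa in (0, 1):  # PC source H rows
            for da in (0, 1):
                vals[pa, da] = 0.9
        for pa in (2, 3):  # PC source C rows, data H columns
            for da in (0, 1):
                vals[pa, da] = 0.7
        m = AUCMatrix(vals)
        assert apply_contrast(m, builtin_contrast("structural")) == pytest.approx(0.8)

    def test_quoted_weight_patterns(self):
        """The built-ins reproduce the two published weight patterns exactly
        (XY notation: data graph X projected on PCs of graph Y)."""
        struct = builtin_contrast("structural")
        expect = np.zeros((4, 4))
        for data, pcs in [("Hl", "Hl"), ("Hl", "Hs"), ("Hs", "Hl"), ("Hs", "Hs")]:
            expect[GRAPHS.index(pcs), GRAPHS.index(data)] += 1
        for data, pcs in [("Hl", "Cl"), ("Hl", "Cs"), ("Hs", "Cl"), ("Hs", "Cs")]:
            expect[GRAPHS.index(pcs), GRAPHS.index(data)] -= 1
        assert np.array_equal(struct.weights, expect)

        vis = builtin_contrast("visual")
        expect = np.zeros((4, 4))
        for data, pcs in [("Hl", "Hl"), ("Cl", "Cl"), ("Hs", "Hs"), ("Cs", "Cs")]:
            expect[GRAPHS.index(pcs), GRAPHS.index(data)] += 1
        for data, pcs in [("Hl", "Hs"), ("Hs", "Hl"), ("Cl", "Cs"), ("Cs", "Cl")]:
            expect[GRAPHS.index(pcs), GRAPHS.index(data)] -= 1
        assert np.array_equal(vis.weights, expect)

    def test_shape_mismatch_rejected(self):
        m = AUCMatrix(np.full((4, 4), 0.5))
        bad = ContrastSpec(np.zeros((3, 3)), graphs=["a", "b", "c"])
        with pytest.raises(ValueError):
            apply_contrast(m, bad)


class TestNeighborhoods:
    def test_center_is_own_first_neighbor(self):
        mask = np.ones((5, 5, 4), dtype=bool)
        coords = np.argwhere(mask)
        neigh = _neighborhoods(coords, 10)
        assert np.array_equal(neigh[:, 0], np.arange(coords.shape[0]))

    def test_ties_broken_by_linear_index(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        coords = np.argwhere(mask)
        neigh = _neighborhoods(coords, 7)
        center = 13  # (1,1,1): six distance-1 neighbors, ties by argwhere order
        assert list(neigh[center]) == [13, 4, 10, 12, 14, 16, 22]

    def test_k_larger_than_mask_rejected(self):
        coords = np.argwhere(np.ones((2, 2, 2), dtype=bool))
        with pytest.raises(ValueError):
            _neighborhoods(coords, 9)


class TestSearchlight:
    def test_whole_mask_searchlight_is_constant(self, rng):
        bs = constant_betaset(rng, n_vox=27, n_cond=5)
        bs.mask = np.ones((3, 3, 3), dtype=bool)
        cmap, mats = searchlight_run(
            bs, "structural", k_neighbors=27, return_matrices=True
        )
        assert np.allclose(cmap, cmap.ravel()[0], atol=1e-12)
        assert np.allclose(mats, mats[0], atol=1e-12)

    def test_planted_region_recovery(self):
        """Contrast map elevated only where the shared subspace is planted."""
        from subgen.fixtures import PlantedBetaSpec, generate_beta_set

        spec = PlantedBetaSpec(
            n_subjects=1, shape=(8, 8, 8), effect_center=(1.5, 1.5, 1.5),
            effect_radius=2.2, noise_sd=0.5, seed=3,
        )
        bs = generate_beta_set(spec, 0)
        cmap = searchlight_run(bs, "structural", k_neighbors=30)
        eff = spec.effect_mask()
        nul = spec.null_mask(30)
        assert nul.sum() > 20
        assert np.nanmean(cmap[eff]) > np.nanmean(cmap[nul]) + 0.2
        assert abs(np.nanmean(cmap[nul])) < 0.1

    def test_mask_required(self, rng):
        with pytest.raises(ValueError, match="mask"):
            searchlight_run(constant_betaset(rng), "structural", k_neighbors=5)


class TestGroupSignFlip:
    def test_exhaustive_single_voxel_oracle(self):
        """Ten equal-valued subjects, one voxel: only the identity pattern
        reaches the observed (infinite) t, so p = 1/1024 exactly."""
        maps = [np.array([3.0]) for _ in range(10)]
        res = group_signflip(maps, exhaustive=True)
        assert res.p_fwe[0] == pytest.approx(1 / 1024, abs=0)

    def test_global_sign_flip_negates_t(self, rng):
        maps = [rng.standard_normal(6) for _ in range(8)]
        r1 = group_signflip(maps, n_flips=50, seed=0)
        r2 = group_signflip([-m for m in maps], n_flips=50, seed=0)
        assert np.allclose(r1.tmap, -r2.tmap)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            group_signflip([np.zeros(3)], n_flips=10)

    def test_false_positive_rate_controlled(self):
        """Sign-symmetric null maps: the familywise error rate stays at or
        below the nominal level (exact binomial acceptance at n=200)."""
        rng = np.random.default_rng(99)
        fp = 0
        for _ in range(200):
            maps = [rng.standard_normal(60) for _ in range(8)]
            res = group_signflip(maps, n_flips=200, seed=rng)
            fp += np.nanmin(res.p_fwe) <= 0.05
        # binom(200, 0.05): central 95% acceptance region is [4, 17]
        assert fp <= 17

    def test_fwe_p_in_unit_interval(self, rng):
        maps = [rng.standard_normal(20) for _ in range(6)]
        res = group_signflip(maps, n_flips=100, seed=1)
        assert np.all((res.p_fwe > 0) & (res.p_fwe <= 1))
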
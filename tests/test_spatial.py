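"""Moran's I, its inference, sector classification, and co-expression ranking.

The index and the correlation matrix are checked against independent
brute-force oracles (explicit double sums over voxel pairs) on small random
masks; inference is checked by permutation/analytic agreement and null
calibration.
"""

import math

import numpy as np
import pytest
from scipy import stats

from tomo3d import (
    ConstantFieldError,
    VolumeMask,
    build_weights,
    coexpression_ranking,
    model_from_truth,
    morans_i,
    morans_test,
    pairwise_correlation,
    screen_regionalized,
    sector_classify,
)
from tomo3d.spatial import moran_screen_table
from tomo3d.synthetic import SimulationConfig, TerritorySpec, make_gene_field, make_phantom

from conftest import random_mask


def brute_force_moran(field, mask):
    """O(N^2) Moran's I straight from the double-sum definition."""
    coords = np.argwhere(mask.in_mask)
    x = field[mask.in_mask].astype(float)
    n = len(x)
    z = x - x.mean()
    num = 0.0
    w_sum = 0.0
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            if np.abs(coords[a] - coords[b]).max() <= 1:
                num += z[a] * z[b]
                w_sum += 1.0
    return (n / w_sum) * num / (z @ z)


class TestWeights:
    def test_interior_voxel_has_26_neighbors(self, cuboid_mask):
        weights = build_weights(cuboid_mask)
        grid_index = np.full(cuboid_mask.shape, -1)
        grid_index[cuboid_mask.in_mask] = np.arange(cuboid_mask.n_voxels)
        interior = grid_index[2, 3, 3]
        assert weights.neighbor_counts[interior] == 26

    def test_corner_voxel_has_7_neighbors(self, cuboid_mask):
        weights = build_weights(cuboid_mask)
        grid_index = np.full(cuboid_mask.shape, -1)
        grid_index[cuboid_mask.in_mask] = np.arange(cuboid_mask.n_voxels)
        corner = grid_index[0, 0, 0]
        assert weights.neighbor_counts[corner] == 7

    def test_out_of_mask_voxels_never_neighbors(self):
        grid = np.ones((3, 3, 3), dtype=bool)
        grid[1, 1, 1] = False  # hollow center
        weights = build_weights(VolumeMask(grid))
        # center removed: each face-center voxel loses exactly the center
        assert weights.neighbor_counts.max() <= 16
        assert weights.matrix.diagonal().sum() == 0

    def test_symmetry_binary(self, cuboid_mask):
        w = build_weights(cuboid_mask).matrix
        assert (w != w.T).nnz == 0

    def test_row_standardized_rows_sum_to_one(self, cuboid_mask):
        w = build_weights(cuboid_mask, style="row_standardized").matrix
        np.testing.assert_allclose(np.asarray(w.sum(axis=1)).ravel(), 1.0)


class TestMoransI:
    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(20):
            mask = random_mask(rng)
            field = np.where(mask.in_mask, rng.normal(size=mask.shape), 0.0)
            weights = build_weights(mask)
            assert morans_i(field, weights) == pytest.approx(
                brute_force_moran(field, mask), abs=1e-12
            )

    def test_constant_field_is_an_explicit_error(self, cuboid_mask):
        weights = build_weights(cuboid_mask)
        with pytest.raises(ConstantFieldError):
            morans_i(np.ones(cuboid_mask.shape), weights)

    def test_checkerboard_along_one_axis_is_negative(self, cuboid_mask):
        weights = build_weights(cuboid_mask)
        field = np.zeros(cuboid_mask.shape)
        field[::2, :, :] = 1.0
        assert morans_i(field, weights) < 0

    def test_expected_value_closed_form(self, cuboid_mask, rng):
        weights = build_weights(cuboid_mask)
        field = np.where(cuboid_mask.in_mask, rng.normal(size=cuboid_mask.shape), 0)
        result = morans_test(field, weights)
        assert result.expected == pytest.approx(-1 / (weights.n - 1))


class TestMoranInference:
    def test_permutation_p_uniform_under_null(self, rng):
        """p-values of fields that are themselves random permutations are
        uniform on the permutation grid (KS at alpha=0.01)."""
        grid = np.ones((6, 6, 6), dtype=bool)
        mask = VolumeMask(grid)
        weights = build_weights(mask)
        n_perm = 199
        pvals = []
        for _ in range(200):
            field = np.where(grid, rng.normal(size=grid.shape), 0.0)
            res = morans_test(field, weights, method="permutation",
                              n_perm=n_perm, seed=rng)
            pvals.append(res.p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_analytic_close_to_permutation_on_smooth_fields(self, rng):
        from scipy import ndimage

        mask = VolumeMask(np.ones((6, 6, 6), dtype=bool))
        weights = build_weights(mask)
        n_perm = 2000
        for _ in range(10):
            field = ndimage.gaussian_filter(rng.normal(size=(6, 6, 6)), sigma=1.0)
            analytic = morans_test(field, weights, method="analytic")
            perm = morans_test(field, weights, method="permutation",
                               n_perm=n_perm, seed=rng)
            se = math.sqrt(max(perm.p_value * (1 - perm.p_value), 1e-9) / n_perm)
            assert abs(analytic.p_value - perm.p_value) < 3 * se + 1 / (n_perm + 1)

    def test_too_few_permutations_rejected(self, cuboid_mask, rng):
        weights = build_weights(cuboid_mask)
        field = np.where(cuboid_mask.in_mask, rng.normal(size=cuboid_mask.shape), 0)
        with pytest.raises(ValueError, match="n_perm"):
            morans_test(field, weights, method="permutation", n_perm=10)

    def test_index_decreases_as_field_is_shuffled(self, rng):
        """Partial random permutation of a regionalized field strictly lowers
        the index in expectation (monotone over shuffle fractions)."""
        mask = VolumeMask(np.ones((8, 8, 8), dtype=bool))
        weights = build_weights(mask)
        spec = TerritorySpec("blob", fraction=0.2)
        base = make_gene_field(mask, spec, seed=5)
        fractions = np.linspace(0.0, 1.0, 6)
        means = []
        for frac in fractions:
            vals = []
            for _ in range(30):
                field = base.copy()
                flat = field[mask.in_mask]
                k = int(frac * flat.size)
                if k >= 2:
                    pick = rng.choice(flat.size, size=k, replace=False)
                    flat[pick] = rng.permutation(flat[pick])
                field[mask.in_mask] = flat
                vals.append(morans_i(field, weights))
            means.append(np.mean(vals))
        assert (np.diff(means) < 0).all()


class TestSectorClassification:
    @pytest.mark.parametrize(
        "I,neg_log_p,sector",
        [
            (0.015, 5.0, 1),
            (0.065, 5.0, 2),
            (0.095, 5.0, 3),
            (0.15, math.inf, 4),
            (0.65, math.inf, 5),
            (0.15, 50.0, None),   # band 4 needs p underflow
            (0.5, math.inf, None),  # between bands
            (-0.065, 5.0, None),  # negative indexes are outside every band
        ],
    )
    def test_sector_bands(self, I, neg_log_p, sector):
        assert sector_classify(I, neg_log_p) == sector


class TestScreen:
    def test_blob_and_salt_and_pepper_fully_separated(self):
        config = SimulationConfig(shape=(20, 22, 24), noise_model="none", seed=13)
        truth = make_phantom(config, {"blob": 8, "salt_and_pepper": 8})
        model = model_from_truth(truth)
        weights = build_weights(truth.mask)
        passing = {r.gene_id for r in screen_regionalized(model, weights)}
        blobs = {g for g in truth.fields if g.startswith("blob")}
        peppers = {g for g in truth.fields if g.startswith("salt")}
        assert passing >= blobs
        assert passing & peppers == set()

    def test_infinite_threshold_empties_screen(self, small_model):
        _, model = small_model
        weights = build_weights(model.mask)
        assert screen_regionalized(model, weights, i_min=math.inf) == []

    def test_uniform_gene_reported_unscreenable(self):
        config = SimulationConfig(shape=(10, 11, 12), noise_model="none", seed=14)
        truth = make_phantom(config, {"uniform": 1, "blob": 1})
        model = model_from_truth(truth)
        weights = build_weights(truth.mask)
        table = moran_screen_table(model, weights)
        assert bool(table.loc["uniform_001", "unscreenable"])
        assert not bool(table.loc["blob_001", "unscreenable"])

    def test_bh_adjustment_is_optional_and_monotone(self):
        config = SimulationConfig(shape=(10, 11, 12), noise_model="none", seed=16)
        truth = make_phantom(config, {"blob": 2, "salt_and_pepper": 3})
        model = model_from_truth(truth)
        weights = build_weights(truth.mask)
        raw = moran_screen_table(model, weights)
        adj = moran_screen_table(model, weights, p_adjust="bh")
        assert "p_adjusted" not in raw.columns
        assert (adj["p_adjusted"] >= adj["p_value"] - 1e-15).all()
        # underflowed p-values stay zero, so the default screen is unchanged
        assert (adj["passes"] == raw["passes"]).all()

    def test_low_expression_flag_below_100_counts(self):
        config = SimulationConfig(shape=(10, 11, 12), noise_model="none", seed=15)
        truth = make_phantom(config, {"blob": 1})
        gene = "blob_001"
        truth.fields[gene] *= 50.0 / truth.fields[gene].sum()
        model = model_from_truth(truth)
        table = moran_screen_table(model, build_weights(truth.mask))
        assert bool(table.loc[gene, "low_expression"])


class TestPairwiseCorrelation:
    def test_matches_textbook_formula_oracle(self, rng):
        mask = random_mask(rng, max_side=5)
        truth_fields = {
            f"g{i}": np.where(mask.in_mask, rng.normal(size=mask.shape), 0.0)
            for i in range(10)
        }
        from tomo3d import DigitalExpressionModel
        import pandas as pd

        model = DigitalExpressionModel(mask=mask, volumes=truth_fields,
                                       convergence=pd.DataFrame())
        cor = pairwise_correlation(model)
        for a in truth_fields:
            for b in truth_fields:
                expected = stats.pearsonr(
                    truth_fields[a][mask.in_mask], truth_fields[b][mask.in_mask]
                ).statistic
                assert cor.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_self_correlation_and_exact_anticorrelation(self, rng):
        import pandas as pd
        from tomo3d import DigitalExpressionModel

        mask = VolumeMask(np.ones((4, 4, 4), dtype=bool))
        g = np.where(mask.in_mask, rng.normal(size=mask.shape), 0.0)
        model = DigitalExpressionModel(
            mask=mask, volumes={"g": g, "anti": np.where(mask.in_mask, 3.0 - g, 0.0)},
            convergence=pd.DataFrame(),
        )
        cor = pairwise_correlation(model)
        assert cor.loc["g", "g"] == 1.0
        assert cor.loc["g", "anti"] == pytest.approx(-1.0)

    def test_constant_gene_reported_missing(self, rng):
        import pandas as pd
        from tomo3d import DigitalExpressionModel

        mask = VolumeMask(np.ones((4, 4, 4), dtype=bool))
        model = DigitalExpressionModel(
            mask=mask,
            volumes={
                "g": np.where(mask.in_mask, rng.normal(size=mask.shape), 0.0),
                "flat": mask.in_mask.astype(float),
            },
            convergence=pd.DataFrame(),
        )
        cor = pairwise_correlation(model)
        assert np.isnan(cor.loc["g", "flat"])
        assert np.isnan(cor.loc["flat", "flat"])

    def test_fewer_than_two_genes_rejected(self, small_model):
        _, model = small_model
        with pytest.raises(ValueError, match="at least 2"):
            pairwise_correlation(model, genes=[model.genes[0]])


class TestCoexpressionRanking:
    def _planted_model(self, seed):
        config = SimulationConfig(shape=(14, 15, 16), noise_model="none", seed=seed)
        truth = make_phantom(config, {"midline_stripe": 1, "blob": 4, "gradient": 2,
                                      "salt_and_pepper": 2})
        rng = np.random.default_rng(seed + 1000)
        ref = truth.fields["midline_stripe_001"]
        lam = 5.0
        duplicate = rng.poisson(ref * lam) / lam
        duplicate[~truth.mask.in_mask] = 0.0
        truth.fields["planted_duplicate"] = duplicate.astype(float)
        return model_from_truth(truth)

    def test_planted_duplicate_ranks_first(self):
        model = self._planted_model(seed=31)
        ranking = coexpression_ranking(model, "midline_stripe_001", cor_min=0.0)
        assert ranking.entries[0][0] == "planted_duplicate"
        assert ranking.entries[0][1] > 0.4

    def test_reference_excluded_and_threshold_applied(self):
        model = self._planted_model(seed=32)
        ranking = coexpression_ranking(model, "midline_stripe_001", cor_min=0.4)
        genes = [g for g, _ in ranking.entries]
        assert "midline_stripe_001" not in genes
        assert all(c >= 0.4 for _, c in ranking.entries)

    def test_vacuous_threshold_gives_empty_list(self):
        model = self._planted_model(seed=33)
        ranking = coexpression_ranking(model, "midline_stripe_001", cor_min=1.0 + 1e-9)
        assert ranking.entries == []

    def test_ranking_invariant_under_positive_affine_rescale(self):
        model = self._planted_model(seed=34)
        before = coexpression_ranking(model, "midline_stripe_001", cor_min=-1.0)
        for gene in model.genes:
            if gene != "midline_stripe_001":
                model.volumes[gene] = 2.5 * model.volumes[gene]
        after = coexpression_ranking(model, "midline_stripe_001", cor_min=-1.0)
        assert before.entries[0][0] == after.entries[0][0]
        a = dict(before.entries)
        b = dict(after.entries)
        assert set(a) == set(b)
        for gene in a:
            assert a[gene] == pytest.approx(b[gene], abs=1e-12)

    def test_constant_reference_rejected(self):
        config = SimulationConfig(shape=(10, 11, 12), noise_model="none", seed=35)
        truth = make_phantom(config, {"uniform": 1, "blob": 1})
        model = model_from_truth(truth)
        with pytest.raises(ConstantFieldError):
            coexpression_ranking(model, "uniform_001")
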
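"""Latent sampling, SNR realization, outcome links, grids, fixtures."""

import numpy as np
import pytest

import simguided as sg
from simguided.simulate import random_loadings


def _spec(layout, **kw):
    defaults = dict(variant="cluster", snr_db=0.0, seed=0)
    defaults.update(kw)
    return sg.LatentCohortSpec(layout=layout, **defaults)


class TestSampleLatent:
    def test_cluster_is_two_point_and_balanced(self):
        layout = sg.small_layout(10_000, 1, 1)
        z = sg.sample_latent(_spec(layout, mixing_proportion=0.5))
        assert set(np.unique(np.abs(z))) == {1.0}
        assert abs(z.mean()) < 0.05  # binomial concentration at n=1e4

    def test_spectrum_is_standard_normal(self):
        layout = sg.small_layout(10_000, 1, 1)
        z = sg.sample_latent(_spec(layout, variant="spectrum"))
        # within 3 standard errors of N(0, 1) moments
        assert abs(z.mean()) < 3 / np.sqrt(len(z))
        assert abs(z.var() - 1) < 3 * np.sqrt(2 / len(z))

    def test_deterministic_given_seed(self, tiny_layout):
        a = sg.sample_latent(_spec(tiny_layout, seed=5))
        b = sg.sample_latent(_spec(tiny_layout, seed=5))
        np.testing.assert_array_equal(a, b)

    def test_mixing_proportion_respected(self):
        layout = sg.small_layout(20_000, 1, 1)
        z = sg.sample_latent(_spec(layout, mixing_proportion=0.8))
        assert (z > 0).mean() == pytest.approx(0.8, abs=0.02)


class TestGenerateCohort:
    @pytest.mark.parametrize("snr_db,lo,hi", [(0.0, 0.99, 1.01),
                                              (20.0, 99.0, 101.0),
                                              (-10.0, 0.099, 0.101)])
    def test_realized_snr_within_one_percent(self, snr_db, lo, hi):
        layout = sg.small_layout(300, 3, 4)
        spec = _spec(layout, snr_db=snr_db, seed=2)
        ds = sg.generate_cohort(spec)
        z = np.array(ds.meta["latent"])
        loadings = random_loadings(layout, spec.seed)
        signal = np.column_stack([np.outer(z, loadings.loadings[s])
                                  for s in layout.submodality_names])
        noise = ds.full_matrix().to_numpy() - signal
        assert lo <= signal.var() / noise.var() <= hi

    def test_low_snr_features_nearly_uncorrelated_with_latent(self):
        # at -20 dB the typical feature is indistinguishable from the
        # permutation null (dataset-level convention: mean per-feature
        # variance ratio 0.01, so r ~ 0.1 at most for average loadings)
        layout = sg.small_layout(300, 2, 3)
        ds = sg.generate_cohort(_spec(layout, snr_db=-20.0, seed=4))
        z = np.array(ds.meta["latent"])
        X = ds.full_matrix().to_numpy()
        rng = np.random.default_rng(0)
        null = np.array([
            np.abs(np.corrcoef(rng.permutation(z), X[:, j])[0, 1])
            for _ in range(200) for j in range(X.shape[1])
        ])
        bound = np.quantile(null, 0.999)
        r = np.array([abs(np.corrcoef(z, X[:, j])[0, 1])
                      for j in range(X.shape[1])])
        assert np.median(r) <= bound      # typical feature is null-like
        assert r.max() <= 0.3             # even the best-loaded feature weak
        # contrast: at +20 dB features are strongly latent-driven
        ds_hi = sg.generate_cohort(_spec(layout, snr_db=20.0, seed=4))
        X_hi = ds_hi.full_matrix().to_numpy()
        z_hi = np.array(ds_hi.meta["latent"])
        r_hi = np.array([abs(np.corrcoef(z_hi, X_hi[:, j])[0, 1])
                         for j in range(X_hi.shape[1])])
        assert np.median(r_hi) > 0.8

    def test_all_zero_loadings_rejected(self, tiny_layout):
        with pytest.raises(ValueError, match="all-zero"):
            lo = random_loadings(tiny_layout, 0)
            bad = {k: (np.zeros_like(v) if k == "volumes" else v)
                   for k, v in lo.loadings.items()}
            sg.LoadingModel(loadings=bad, noise_scale=lo.noise_scale)

    def test_meta_records_provenance(self, tiny_cohort):
        assert tiny_cohort.meta["variant"] == "cluster"
        assert tiny_cohort.meta["snr_db"] == 10.0
        assert tiny_cohort.meta["seed"] == 7


class TestDeriveOutcomes:
    def test_cluster_label_is_sign_indicator(self):
        out = sg.derive_outcomes(np.array([-1.0, -1.0, 1.0]), "cluster_label", 0)
        assert list(out["label"]) == [0, 0, 1]

    def test_binary_threshold_median_split(self):
        z = np.random.default_rng(1).standard_normal(100)
        out = sg.derive_outcomes(z, "binary_threshold", 0)
        assert out["label"].sum() == 50

    def test_linear_response_r2_matches_snr(self):
        # analytic R^2 = SNR/(SNR+1); at +20 dB that is 100/101
        z = np.random.default_rng(2).standard_normal(10_000)
        out = sg.derive_outcomes(z, "linear_response", 3, snr_db=20.0)
        r2 = np.corrcoef(out["response"], z)[0, 1] ** 2
        assert r2 == pytest.approx(100 / 101, abs=0.005)

    def test_unknown_link_rejected(self):
        with pytest.raises(ValueError, match="unknown outcome link"):
            sg.derive_outcomes(np.ones(3), "nope", 0)


class TestMissingPattern:
    def test_all_false_mask_leaves_dataset_unchanged(self, tiny_cohort):
        mask = sg.extract_missing_mask(tiny_cohort)
        ds = sg.apply_missing_pattern(tiny_cohort, mask)
        for name in ds.blocks:
            np.testing.assert_array_equal(ds.blocks[name].to_numpy(),
                                          tiny_cohort.blocks[name].to_numpy())

    def test_blockwise_rows_punched_exactly(self, tiny_cohort):
        mask = sg.extract_missing_mask(tiny_cohort)
        m = mask.blocks["volumes"].copy()
        m.iloc[[2, 5], :] = True
        mask.blocks["volumes"] = m
        ds = sg.apply_missing_pattern(tiny_cohort, mask)
        vol = ds.blocks["volumes"]
        assert vol.iloc[[2, 5]].isna().all().all()
        assert not vol.drop(vol.index[[2, 5]]).isna().any().any()
        assert not ds.blocks["reaction_time"].isna().any().any()

    def test_fractions_conserved(self):
        layout, mask, loadings = sg.reference_fixture(seed=1, n_subjects=10)
        spec = sg.LatentCohortSpec(layout=layout, variant="cluster",
                                   snr_db=0.0, seed=1)
        ds = sg.apply_missing_pattern(sg.generate_cohort(spec, loadings), mask)
        out = sg.extract_missing_mask(ds)
        assert out.fractions == pytest.approx(mask.fractions)

    def test_size_mismatch_resamples_rows(self, tiny_cohort):
        # mask has 50 rows, data 10: rows are resampled with replacement
        import pandas as pd
        rng = np.random.default_rng(5)
        mask50 = sg.MissingMask(blocks={
            name: pd.DataFrame(rng.random((50, 3)) < 0.2,
                               columns=block.columns)
            for name, block in tiny_cohort.blocks.items()
        })
        ds = sg.apply_missing_pattern(tiny_cohort, mask50, seed=3)
        assert ds.n_subjects == 10
        assert sg.extract_missing_mask(ds).blocks[
            "reaction_time"].to_numpy().any()


class TestGrid:
    def test_default_grid_is_180_datasets(self, tiny_layout):
        grid = sg.GridSpec(base=_spec(tiny_layout))
        assert grid.size == 180
        assert len(list(grid.cells())) == 180

    def test_single_cell_grid(self, tiny_layout):
        grid = sg.GridSpec(base=_spec(tiny_layout), snr_values=(0.0,),
                           variants=("cluster",), seeds=(1,))
        assert len(sg.build_grid(grid)) == 1

    def test_product_count(self, tiny_layout):
        grid = sg.GridSpec(base=_spec(tiny_layout), snr_values=(0.0, 5.0),
                           variants=("cluster", "spectrum"), seeds=(1, 2, 3))
        datasets = sg.build_grid(grid)
        assert len(datasets) == 12
        cells = {(d.meta["snr_db"], d.meta["variant"], d.meta["seed"])
                 for d in datasets}
        assert len(cells) == 12  # every dataset tagged with its own cell


class TestReferenceFixture:
    def test_five_modalities_289_subjects(self):
        layout, mask, loadings = sg.reference_fixture(seed=0)
        assert len(layout.modality_names) == 5
        assert layout.n_subjects == 289
        assert set(layout.modality_names) == {
            "cognition", "MRI", "electrophysiology", "psychopathology",
            "perinatal_register"}

    def test_mask_has_blockwise_and_random_holes(self):
        layout, mask, _ = sg.reference_fixture(seed=0)
        assert any(mask.block_rows_missing(s).any()
                   for s in layout.submodality_names)
        fracs = mask.fractions
        assert all(0.0 < f < 0.6 for f in fracs.values())

    def test_same_seed_identical(self):
        a = sg.reference_fixture(seed=4)
        b = sg.reference_fixture(seed=4)
        assert a[0] == b[0]
        assert a[1] == b[1]
        for s in a[0].submodality_names:
            np.testing.assert_array_equal(a[2].loadings[s], b[2].loadings[s])
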
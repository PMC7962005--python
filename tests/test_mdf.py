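import numpy as np
import pytest

from trpscope import mdf
from trpscope import synthetic as syn

from conftest import build_eem_cube


class TestTsfsToTeem:
    def test_coordinate_identity(self, trp_bank):
        cube = syn.simulate_tsfs(trp_bank, [[1.0, 0.5]])
        teem = mdf.tsfs_to_teem(cube)
        j = int(np.flatnonzero(cube.exc_grid == 280.0)[0])
        o = int(np.flatnonzero(cube.offset_grid == 60.0)[0])
        m = int(np.flatnonzero(teem.em_grid == 340.0)[0])
        assert teem.values[0, j, m] == pytest.approx(cube.values[0, j, o], rel=1e-12)
        assert not teem.missing_mask[0, j, m]

    def test_unmasked_support_matches_offsets(self, trp_bank):
        cube = syn.simulate_tsfs(trp_bank, [[1.0, 1.0]])
        teem = mdf.tsfs_to_teem(cube)
        j = int(np.flatnonzero(cube.exc_grid == 260.0)[0])
        supported = teem.em_grid[~teem.missing_mask[0, j]]
        assert supported[0] == 280.0 and supported[-1] == 420.0

    def test_round_trip_on_support(self, trp_bank):
        cube = syn.simulate_tsfs(trp_bank, [[1.3, 0.4]])
        teem = mdf.tsfs_to_teem(cube)
        # invert: lambda_em back to offsets on the same grid step
        for j, exc in enumerate(cube.exc_grid[::7]):
            jj = j * 7
            em_src = exc + cube.offset_grid
            back = np.interp(em_src, teem.em_grid, teem.values[0, jj])
            assert np.allclose(back, cube.values[0, jj], atol=1e-9)

    def test_insufficient_em_grid_rejected(self, trp_bank):
        cube = syn.simulate_tsfs(trp_bank, [[1.0, 1.0]])
        with pytest.raises(ValueError):
            mdf.tsfs_to_teem(cube, em_grid=np.arange(300.0, 350.0, 2.0))


class TestPreprocess:
    def test_blank_subtraction_exact(self, trp_bank):
        cube = syn.simulate_tsfs(trp_bank, [[1.0, 1.0]])
        teem = mdf.tsfs_to_teem(cube)
        out = mdf.preprocess_teem(teem, blank=teem, sg_window=5, sg_order=2)
        assert np.allclose(out.values[out.observed], 0.0, atol=1e-12)

    def test_polynomial_invariant_under_smoothing(self, trp_bank):
        em = np.arange(300.0, 441.0, 2.0)
        exc = np.arange(260.0, 321.0, 2.0)
        # quadratic along emission: exactly reproduced by SG of order >= 2
        values = np.tile(0.01 * (em - 350.0) ** 2 + 3.0, (1, exc.size, 1))
        cube = mdf.EEMCube(["s0"], exc, em, values, np.zeros(values.shape, bool))
        out = mdf.preprocess_teem(cube, scatter_window=0.0, sg_window=7, sg_order=2)
        assert np.allclose(out.values, values, rtol=1e-10)

    def test_scatter_ridge_removed(self):
        # place the band so the second-order line 2*exc crosses the em range
        bank = [syn.FluorophoreComponent("uv", 210.0, 8.0, 430.0, 25.0)]
        exc = np.arange(200.0, 241.0, 2.0)
        em = np.arange(360.0, 481.0, 2.0)
        clean = build_eem_cube(bank, [[1.0]], exc_grid=exc, em_grid=em)
        ridge = 0.5 * np.exp(
            -0.5 * ((em[None, :] - 2.0 * exc[:, None]) / 4.0) ** 2
        )
        dirty = mdf.EEMCube(
            ["s0"], exc, em, clean.values + ridge[None], np.zeros(clean.values.shape, bool)
        )
        out = mdf.preprocess_teem(dirty, scatter_window=12.0, sg_window=5, sg_order=2)
        ref = mdf.preprocess_teem(clean, scatter_window=12.0, sg_window=5, sg_order=2)
        band = np.abs(em[None, :] - 2.0 * exc[:, None]) <= 12.0
        scale = clean.values.max()
        err = np.abs(out.values[0] - ref.values[0])[band] / scale
        assert err.max() < 0.05

    def test_bad_sg_params_rejected(self, rank2_cube):
        with pytest.raises(ValueError):
            mdf.preprocess_teem(rank2_cube, sg_window=6, sg_order=2)
        with pytest.raises(ValueError):
            mdf.preprocess_teem(rank2_cube, sg_window=3, sg_order=3)


class TestParafac:
    def test_exact_rank1_recovery(self, trp_bank):
        cube = build_eem_cube(trp_bank[:1], [[1.0], [0.7], [1.3]])
        m = mdf.parafac_fit(cube, 1, n_starts=2, seed=0)
        assert m.fit_residual_fraction < 1e-8
        # loadings match the generator profiles up to scale (unit peak both)
        assert np.allclose(
            m.em_loadings[:, 0], trp_bank[0].emission(cube.em_grid), atol=1e-5
        )
        assert np.allclose(
            m.exc_loadings[:, 0], trp_bank[0].excitation(cube.exc_grid), atol=1e-5
        )

    def test_rank2_argmax_recovery(self, rank2_cube):
        m = mdf.parafac_fit(rank2_cube, 2, n_starts=3, seed=0)
        s = mdf.summarize_components(m)
        assert list(s["em_max"]) == [330.0, 362.0]
        assert list(s["exc_max"]) == [282.0, 284.0]

    def test_masked_entries_never_influence_fit(self, trp_bank):
        cube = syn.simulate_tsfs(trp_bank, [[1.0, 0.5], [0.5, 1.2], [1.1, 0.9]])
        teem = mdf.tsfs_to_teem(cube)
        m1 = mdf.parafac_fit(teem, 2, n_starts=2, seed=1, max_iter=300)
        poisoned = mdf.EEMCube(
            teem.sample_ids,
            teem.exc_grid,
            teem.em_grid,
            np.where(teem.missing_mask, 1e6, teem.values),
            teem.missing_mask,
        )
        m2 = mdf.parafac_fit(poisoned, 2, n_starts=2, seed=1, max_iter=300)
        assert np.array_equal(m1.sample_scores, m2.sample_scores)
        assert np.array_equal(m1.em_loadings, m2.em_loadings)

    def test_nonnegativity_and_unit_peak(self, rank2_cube):
        m = mdf.parafac_fit(rank2_cube, 2, n_starts=2, seed=0)
        assert (m.sample_scores >= 0).all()
        assert (m.em_loadings >= 0).all() and (m.exc_loadings >= 0).all()
        assert np.allclose(m.em_loadings.max(axis=0), 1.0)
        assert np.allclose(m.exc_loadings.max(axis=0), 1.0)

    def test_insufficient_data_rejected(self, trp_bank):
        cube = build_eem_cube(trp_bank, [[1.0, 1.0]])
        mask = np.ones(cube.values.shape, bool)
        mask[0, :2, :2] = False
        starved = mdf.EEMCube(cube.sample_ids, cube.exc_grid, cube.em_grid,
                              cube.values, mask)
        with pytest.raises(ValueError):
            mdf.parafac_fit(starved, 2)


class TestCoreConsistency:
    def test_exact_rank2_near_100(self, rank2_cube):
        m = mdf.parafac_fit(rank2_cube, 2, n_starts=3, seed=0)
        assert mdf.core_consistency(m, rank2_cube) > 99.0

    def test_overfactored_model_strictly_lower(self, rank2_cube):
        m2 = mdf.parafac_fit(rank2_cube, 2, n_starts=3, seed=0)
        m3 = mdf.parafac_fit(rank2_cube, 3, n_starts=3, seed=0, max_iter=500)
        assert mdf.core_consistency(m3, rank2_cube) < mdf.core_consistency(
            m2, rank2_cube
        )

    def test_single_component_always_100(self, trp_bank):
        # K=1: the LS core of a converged one-component model is exactly 1
        cube = syn.simulate_tsfs(trp_bank, [[1.0, 0.8], [0.6, 1.1]], noise_sd=0.05, seed=2)
        teem = mdf.tsfs_to_teem(cube)
        m = mdf.parafac_fit(teem, 1, n_starts=2, seed=0)
        assert mdf.core_consistency(m, teem) == pytest.approx(100.0, abs=0.1)


class TestSelectComponents:
    def test_rank2_selected(self, rank2_cube):
        sel = mdf.select_n_components(rank2_cube, k_max=3, n_starts=3, seed=0,
                                      max_iter=500)
        assert sel["K"] == 2
        assert sel["warning"] is None

    def test_rank1_selected(self, trp_bank):
        cube = build_eem_cube(trp_bank[:1], [[1.0], [0.5], [2.0]])
        sel = mdf.select_n_components(cube, k_max=2, n_starts=2, seed=0,
                                      max_iter=500)
        assert sel["K"] == 1

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(5)
        exc = np.arange(260.0, 321.0, 4.0)
        em = np.arange(300.0, 441.0, 4.0)
        # zero-mean, as after blank subtraction: no structure to factor
        values = rng.normal(0, 1, (6, exc.size, em.size))
        cube = mdf.EEMCube([f"s{i}" for i in range(6)], exc, em, values,
                           np.zeros(values.shape, bool))
        sel = mdf.select_n_components(cube, k_max=2, n_starts=2, seed=0,
                                      max_iter=300)
        assert sel["K"] == 1
        assert sel["warning"] == "no_structure"


class TestSummaries:
    def test_score_shares_sum_to_one(self, rank2_cube):
        m = mdf.parafac_fit(rank2_cube, 2, n_starts=2, seed=0)
        s = mdf.summarize_components(m)
        assert s["score_share"].sum() == pytest.approx(1.0)
        assert s["em_max"].is_monotonic_increasing

    def test_tsfs_long_io_round_trip(self, trp_bank, tmp_path):
        cube = syn.simulate_tsfs(trp_bank, [[1.0, 0.5], [0.2, 2.0]], noise_sd=0.01, seed=8)
        path = tmp_path / "cube.tsv"
        mdf.write_tsfs_long(cube, path)
        back = mdf.read_tsfs_long(path)
        assert back.sample_ids == cube.sample_ids
        assert np.allclose(back.values, cube.values, rtol=1e-9)
        assert np.array_equal(back.exc_grid, cube.exc_grid)
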
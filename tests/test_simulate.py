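import json

import numpy as np
import pytest

from nircal.pretreat import MSC, SNV
from nircal.simulate import (
    REGION_STATS,
    SimulatedDataset,
    SyntheticConfig,
    baseline_spectrum,
    band_amplitudes,
    clean_spectra,
    complete_correlation_matrix,
    generate_spectra,
    implant_outliers,
    make_dataset,
    nearest_correlation_matrix,
    sample_concentrations,
)


def _noise_free(**kwargs) -> SyntheticConfig:
    return SyntheticConfig(
        mult_log_sd=0.0, add_sd=0.0, tilt_sd=0.0, rep_mult_log_sd=0.0,
        rep_add_sd=0.0, noise_sd=0.0, association_sd={}, n_replicates=1,
        **kwargs)


class TestConcentrations:
    def test_region_counts_are_52_16_23(self):
        regions = SyntheticConfig().region_of()
        counts = {r: int((regions == r).sum()) for r in set(regions)}
        assert counts == {"Chile": 52, "Galicia": 16, "Castilla-Leon": 23}

    def test_same_seed_reproduces_table(self):
        a = sample_concentrations(SyntheticConfig(seed=7))
        b = sample_concentrations(SyntheticConfig(seed=7))
        assert a.values.equals(b.values)
        assert a.below_loq.equals(b.below_loq)

    def test_values_respect_region_ranges(self):
        cfg = SyntheticConfig(seed=4)
        table, truth = sample_concentrations(cfg, return_truth=True)
        regions = np.array([truth["regions"][s] for s in table.sample_ids])
        tv = truth["true_values"]
        for region in cfg.region_counts:
            mean, lo, hi = REGION_STATS[region]["K"]
            vals = tv["K"].to_numpy()[regions == region]
            assert vals.min() >= lo and vals.max() <= hi

    def test_large_draw_recovers_target_pearson(self):
        # single-region draw isolates the copula from between-region effects
        cfg = SyntheticConfig(n_samples=5000, region_counts={"Chile": 52},
                              n_calibration=4000, n_validation=1000, seed=2)
        _, truth = sample_concentrations(cfg, return_truth=True)
        tv = truth["true_values"]
        assert np.corrcoef(tv["Ca"], tv["Mg"])[0, 1] == pytest.approx(0.97, abs=0.02)
        assert np.corrcoef(tv["Cr"], tv["Ni"])[0, 1] == pytest.approx(0.90, abs=0.02)
        assert np.corrcoef(tv["K"], tv["Fe"])[0, 1] == pytest.approx(-0.32, abs=0.03)

    def test_nd_censoring_fraction_applied(self):
        table = sample_concentrations(SyntheticConfig(seed=5))
        nd = table.below_loq.sum()
        assert nd["Cu"] == int(np.ceil(0.06 * 91)) or nd["Cu"] == int(0.06 * 91)
        assert nd["Pb"] >= 1 and nd["Ni"] >= 1
        assert nd["K"] == 0

    def test_infeasible_range_rejected(self):
        from nircal.simulate import _solve_marginal

        with pytest.raises(ValueError):
            _solve_marginal(5.0, 10.0, 8.0, 0.01)


class TestCorrelationMatrixMachinery:
    def test_completion_keeps_fixed_entries_exact(self):
        k = 6
        C = np.eye(k)
        fixed = np.zeros((k, k), dtype=bool)
        pairs = [(0, 1, 0.97), (2, 3, 0.9), (0, 4, -0.3)]
        for i, j, r in pairs:
            C[i, j] = C[j, i] = r
            fixed[i, j] = fixed[j, i] = True
        A, _ = complete_correlation_matrix(C, fixed)
        for i, j, r in pairs:
            assert A[i, j] == pytest.approx(r, abs=1e-6)
        assert np.linalg.eigvalsh(A).min() > 0

    def test_nearest_pd_projection_fixes_indefinite_matrix(self):
        C = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        A, dist = nearest_correlation_matrix(C)
        assert np.linalg.eigvalsh(A).min() >= 0
        assert dist > 0
        np.testing.assert_allclose(np.diag(A), 1.0)


class TestSpectra:
    def test_zero_concentrations_give_baseline_exactly(self):
        cfg = _noise_free(n_samples=3, n_calibration=2, n_validation=1, seed=0)
        table = sample_concentrations(cfg)
        zeros = (table.values * 0.0).fillna(0.0)
        spectra = generate_spectra(table, cfg, true_values=zeros)
        np.testing.assert_allclose(
            spectra.absorbance, np.tile(baseline_spectrum(cfg.grid()), (3, 1)))

    def test_band_contribution_linear_in_concentration(self):
        cfg = _noise_free(n_samples=2, n_calibration=1, n_validation=1, seed=0)
        table = sample_concentrations(cfg)
        base = table.values * 0.0
        single = base.copy()
        double = base.copy()
        single["K"] = 100.0
        double["K"] = 200.0
        b = clean_spectra(base, cfg)
        s = clean_spectra(single, cfg)
        d = clean_spectra(double, cfg)
        np.testing.assert_allclose(d - b, 2.0 * (s - b), rtol=1e-12)

    def test_amplitudes_recoverable_from_noiseless_spectra(self):
        cfg = _noise_free(seed=6)
        ds = make_dataset(cfg)
        tv = ds.truth["true_values"]
        wl = cfg.grid()
        residual = ds.spectra.absorbance - baseline_spectrum(wl)
        # per-element responses: shape_e scaled by concentration
        from nircal.simulate import _gaussian

        shapes = []
        for e in cfg.elements:
            shape = np.zeros_like(wl)
            for center, width, weight in cfg.bands[e].bands:
                shape += weight * _gaussian(wl, center, width)
            shapes.append(shape)
        # residual = sum_e amp_e * c_e * shape_e; solve for amp by lstsq
        design = np.stack([np.outer(tv[e], shapes[i]).ravel()
                           for i, e in enumerate(cfg.elements)], axis=1)
        est, *_ = np.linalg.lstsq(design, residual.ravel(), rcond=None)
        truth_amp = np.array([ds.truth["band_amplitudes"][e] for e in cfg.elements])
        np.testing.assert_allclose(est, truth_amp, rtol=1e-8)

    def test_triplicate_structure(self, dataset1):
        sp = dataset1.spectra
        assert sp.n_samples == 3 * 91
        assert set(sp.replicate) == {"r1", "r2", "r3"}

    def test_seed_stability_of_written_csvs(self, tmp_path):
        cfg = SyntheticConfig(seed=9, n_samples=12, region_counts={"Chile": 1},
                              n_calibration=9, n_validation=3)
        make_dataset(cfg, outdir=tmp_path / "a")
        make_dataset(cfg, outdir=tmp_path / "b")
        for name in ("spectra.csv", "reference.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_truth_json_is_loadable(self, tmp_path):
        cfg = SyntheticConfig(seed=9, n_samples=10, region_counts={"Galicia": 1},
                              n_calibration=7, n_validation=3)
        make_dataset(cfg, outdir=tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert len(truth["calibration_ids"]) == 7
        assert "band_amplitudes" in truth


class TestScatterRemoval:
    @pytest.mark.parametrize("corrector", [SNV(), MSC()])
    def test_scatter_correction_removes_replicate_variance(self, corrector):
        cfg = SyntheticConfig(seed=8, noise_sd=1e-5)
        ds = make_dataset(cfg)
        sp = ds.spectra

        def between_replicate_ss(X):
            total = 0.0
            for sid in set(sp.sample_ids):
                rows = X[sp.sample_ids == sid]
                total += ((rows - rows.mean(axis=0)) ** 2).sum()
            return total

        raw = between_replicate_ss(sp.absorbance)
        corrected = between_replicate_ss(corrector.fit(sp.absorbance)
                                         .transform(sp.absorbance))
        assert corrected <= 0.05 * raw


class TestNoiseLadder:
    def test_rmsecv_non_decreasing_in_instrument_noise(self):
        from nircal.io import align
        from nircal.mpls import cross_validate
        from nircal.pretreat import parse_treatment

        values = []
        for noise in (0.002, 0.02, 0.1):
            ds = make_dataset(SyntheticConfig(seed=3, noise_sd=noise))
            cal = set(ds.calibration_ids)
            a = align(ds.spectra, ds.reference, "K")
            mask = np.isin(a.ids, list(cal))
            cv = cross_validate(
                a.X[mask], a.y[mask],
                parse_treatment("SNV only 0,0,1,1", wavelengths=a.wavelengths),
                rng=np.random.default_rng(5))
            values.append(cv.rmsecv)
        assert values[0] <= values[1] <= values[2]


class TestImplantedOutliers:
    def test_marked_samples_are_modified(self, dataset1):
        sp2, ref2, info = implant_outliers(dataset1, element="K",
                                           rng=np.random.default_rng(51))
        assert len(info["spectral"]) == 3 and len(info["chemical"]) == 2
        sid = info["spectral"][0]
        orig = dataset1.spectra.absorbance[dataset1.spectra.sample_ids == sid]
        new = sp2.absorbance[sp2.sample_ids == sid]
        assert np.abs(new).max() > 5 * np.abs(orig).max()
        cid = info["chemical"][0]
        assert ref2.values.loc[cid, "K"] != dataset1.reference.values.loc[cid, "K"]
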
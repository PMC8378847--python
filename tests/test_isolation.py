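import numpy as np
import pytest

from physiofc import isolation as iso
from physiofc import nuisance_model as nm
from physiofc.io import ROITimeseries

TR = 0.72


def _design(rng, n=400):
    blocks = (
        rng.normal(size=n),
        rng.normal(size=(n, 6)),
        rng.normal(size=(n, 6)),
        rng.normal(size=(n, 12)),
    )
    design, _ = nm.assemble_design(*blocks, tr=TR)
    return design


def _roi_ts(values):
    return ROITimeseries(
        values=values, tr=TR, roi_labels=[f"r{i}" for i in range(values.shape[1])]
    )


class TestGLM:
    def test_noiseless_single_regressor_recovered_exactly(self, rng):
        design = _design(rng)
        y = 2.0 * design.values[:, [0]] + 5.0
        fit = iso.fit_glm(_roi_ts(y), design)
        assert fit.betas[0, 0] == pytest.approx(2.0, abs=1e-10)
        assert np.abs(fit.betas[1:, 0]).max() < 1e-10
        assert fit.beta0[0] == pytest.approx(5.0, abs=1e-10)

    def test_residual_orthogonal_to_design(self, rng):
        design = _design(rng)
        y = rng.normal(size=(design.n_frames, 5))
        fit = iso.fit_glm(_roi_ts(y), design)
        dots = design.values.T @ fit.residual
        norms = np.linalg.norm(design.values, axis=0)[:, None] * np.linalg.norm(
            fit.residual, axis=0
        )[None, :]
        assert np.abs(dots / norms).max() < 1e-8

    def test_beta_recovery_on_simulated_cohort(self, default_snr_cohort):
        """Forward/inverse consistency: GLM on 20 simulated scans at default
        SNR recovers the mixing coefficients within 15% relative RMSE."""
        errs = []
        for _, bundle in default_snr_cohort:
            fit = iso.fit_glm(bundle.roi_ts, bundle.design)
            err = np.linalg.norm(fit.betas.T - bundle.truth.beta_true) / np.linalg.norm(
                bundle.truth.beta_true
            )
            errs.append(err)
        assert max(errs) < 0.15

    def test_rank_deficient_design_rejected(self, rng):
        design = _design(rng)
        design.values[:, 3] = design.values[:, 2]
        with pytest.raises(ValueError, match="rank deficient"):
            iso.fit_glm(_roi_ts(rng.normal(size=(design.n_frames, 2))), design)


class TestComponents:
    def test_additive_decomposition_is_exact(self, one_scan):
        b = one_scan
        fit = iso.fit_glm(b.roi_ts, b.design)
        total = fit.beta0[None, :] + fit.residual
        for process in nm.PROCESS_TAGS:
            total = total + iso.extract_components(fit, b.design, b.roi_ts, process).y_npi
        assert np.abs(total - b.roi_ts.values).max() < 1e-9

    def test_slfo_component_is_rank_one(self, one_scan):
        b = one_scan
        fit = iso.fit_glm(b.roi_ts, b.design)
        comps = iso.extract_components(fit, b.design, b.roi_ts, "SLFO")
        s = np.linalg.svd(comps.y_npi, compute_uv=False)
        assert s[1] < 1e-8 * s[0]

    def test_unknown_tag_rejected(self, one_scan):
        fit = iso.fit_glm(one_scan.roi_ts, one_scan.design)
        with pytest.raises(ValueError, match="unknown process"):
            iso.extract_components(fit, one_scan.design, one_scan.roi_ts, "FOO")


class TestContributions:
    def test_pythagorean_construction(self, rng):
        n = 10000
        u = rng.normal(size=n)
        v = rng.normal(size=n)
        v -= u * (u @ v) / (u @ u)  # orthogonalize
        u = (u - u.mean()) / u.std()
        v = (v - v.mean()) / v.std()
        comps = iso.ProcessComponents(
            process="SLFO",
            y_npi=(0.6 * u)[:, None],
            y_npi_plus_neur=(0.6 * u + 0.8 * v)[:, None],
        )
        res = iso.compute_contributions(comps)
        assert res.r_nuis[0] == pytest.approx(0.6, abs=0.02)
        assert res.r_neur[0] == pytest.approx(0.8, abs=0.02)

    def test_pure_nuisance_gives_unit_r_nuis(self, rng):
        x = rng.normal(size=(200, 3))
        comps = iso.ProcessComponents(process="CP", y_npi=x, y_npi_plus_neur=x)
        res = iso.compute_contributions(comps)
        assert np.allclose(res.r_nuis, 1.0)
        assert np.allclose(res.r_neur, 0.0)

    def test_unit_circle_identity_on_ols_components(self, mini_cohort):
        for _, b in mini_cohort[:4]:
            fit = iso.fit_glm(b.roi_ts, b.design)
            for process in nm.PROCESS_TAGS:
                comps = iso.extract_components(fit, b.design, b.roi_ts, process)
                res = iso.compute_contributions(comps)
                assert np.abs(res.r_nuis**2 + res.r_neur**2 - 1).max() < 1e-8

    def test_degenerate_process_flagged(self, rng):
        comps = iso.ProcessComponents(
            process="CP",
            y_npi=np.zeros((100, 2)),
            y_npi_plus_neur=rng.normal(size=(100, 2)),
        )
        res = iso.compute_contributions(comps)
        assert np.all(res.degenerate)
        assert np.allclose(res.r_nuis, 0.0)


class TestAR1Pool:
    def test_white_noise_pool_centered_at_zero(self, rng):
        pool = iso.fit_ar1_pool([rng.normal(size=1200) for _ in range(1000)])
        assert abs(pool.a1_pool.mean()) < 0.02

    def test_ar1_pool_recovers_coefficient(self, rng):
        from scipy.signal import lfilter

        series = [lfilter([1.0], [1.0, -0.5], rng.normal(size=1200)) for _ in range(300)]
        pool = iso.fit_ar1_pool(series)
        assert pool.a1_pool.mean() == pytest.approx(0.5, abs=0.03)

    def test_constant_series_excluded(self, rng):
        pool = iso.fit_ar1_pool([np.ones(100), rng.normal(size=100)])
        assert pool.excluded == 1
        assert pool.a1_pool.size == 1


class TestSynthesis:
    def _setup(self, rng, r_nuis, n=1200, R=2):
        u = rng.normal(size=(n, R))
        r_neur = np.sqrt(1 - r_nuis**2)
        comps = iso.ProcessComponents(process="SLFO", y_npi=u, y_npi_plus_neur=u)
        contrib = iso.ContributionResult(
            r_nuis=np.full(R, r_nuis),
            r_neur=np.full(R, r_neur),
            degenerate=np.zeros(R, dtype=bool),
        )
        roi_ts = _roi_ts(u)
        ar1 = iso.AR1Params(a1_pool=np.array([0.3, 0.4, 0.5]))
        return comps, contrib, roi_ts, ar1

    def test_pure_nuisance_reproduces_zscored_component(self, rng):
        comps, contrib, roi_ts, ar1 = self._setup(rng, r_nuis=1.0)
        out, prov = iso.synthesize_nuisance_dataset(comps, contrib, ar1, roi_ts, seed=0)
        z = (comps.y_npi - comps.y_npi.mean(axis=0)) / comps.y_npi.std(axis=0, ddof=1)
        assert np.allclose(out.values, z)
        assert prov["process"] == "SLFO"

    def test_zero_nuisance_gives_uncorrelated_ar1(self, rng):
        comps, contrib, roi_ts, ar1 = self._setup(rng, r_nuis=0.0)
        out, _ = iso.synthesize_nuisance_dataset(comps, contrib, ar1, roi_ts, seed=1)
        for j in range(out.values.shape[1]):
            r = np.corrcoef(out.values[:, j], comps.y_npi[:, j])[0, 1]
            assert abs(r) < 0.1

    def test_seed_determinism(self, rng):
        comps, contrib, roi_ts, ar1 = self._setup(rng, r_nuis=0.5)
        a, _ = iso.synthesize_nuisance_dataset(comps, contrib, ar1, roi_ts, seed=7)
        b, _ = iso.synthesize_nuisance_dataset(comps, contrib, ar1, roi_ts, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_mean_corr_with_component_approaches_r_nuis(self, rng):
        comps, contrib, roi_ts, ar1 = self._setup(rng, r_nuis=0.6, R=1)
        z = (comps.y_npi[:, 0] - comps.y_npi[:, 0].mean()) / comps.y_npi[:, 0].std(ddof=1)
        corrs = []
        for seed in range(100):
            out, _ = iso.synthesize_nuisance_dataset(comps, contrib, ar1, roi_ts, seed=seed)
            corrs.append(np.corrcoef(out.values[:, 0], z)[0, 1])
        n = comps.y_npi.shape[0]
        assert np.mean(corrs) == pytest.approx(0.6, abs=2 / np.sqrt(n))

    def test_weakly_driven_rois_do_not_correlate_perfectly(self, rng):
        """Two ROIs with r_nuis = 0.1 sharing one SLFO component: without the
        AR(1) term their synthetic series would correlate at +/-1; with it the
        correlation must stay modest."""
        n = 1200
        shared = rng.normal(size=n)
        comps = iso.ProcessComponents(
            process="SLFO",
            y_npi=np.column_stack([shared, -shared]),
            y_npi_plus_neur=np.column_stack([shared, -shared]),
        )
        contrib = iso.ContributionResult(
            r_nuis=np.array([0.1, 0.1]),
            r_neur=np.array([np.sqrt(1 - 0.01)] * 2),
            degenerate=np.zeros(2, dtype=bool),
        )
        ar1 = iso.AR1Params(a1_pool=np.array([0.3]))
        roi_ts = _roi_ts(comps.y_npi)
        corrs = [
            np.corrcoef(
                *iso.synthesize_nuisance_dataset(comps, contrib, ar1, roi_ts, seed=s)[0].values.T
            )[0, 1]
            for s in range(20)
        ]
        assert np.max(np.abs(corrs)) < 0.5
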
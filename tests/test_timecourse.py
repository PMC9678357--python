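"""Trajectory bases, BH-FDR, mixed-model fits, maps, and VOI extraction."""
import math

import numpy as np
import pytest
from scipy import ndimage, optimize

from plastimap.model_selection import aicc
from plastimap.timecourse import (
    SESSION_DAYS,
    InsufficientDataError,
    SubjectRecord,
    TrajectoryLME,
    VolumeSeries,
    cluster_volume,
    extract_voi,
    fdr_bh,
    fit_voxel_lme,
    preferred_model_map,
    smooth_volume,
    subject_trajectory_aicc,
    tpm_mask,
    trajectory_basis,
    voxelwise_maps,
)


# ---------------------------------------------------------------------------
# trajectory bases
# ---------------------------------------------------------------------------

class TestTrajectoryBasis:
    @pytest.mark.parametrize("shape", ["linear", "asymptotic", "quadratic"])
    def test_anchored_at_baseline(self, shape):
        assert trajectory_basis(shape, 0.0) == 0.0

    def test_endpoints(self):
        assert trajectory_basis("asymptotic", 14.0) == 1.0
        assert trajectory_basis("quadratic", 14.0) == 0.0
        assert trajectory_basis("linear", 14.0) == 1.0

    def test_quadratic_peaks_mid_course(self):
        assert trajectory_basis("quadratic", 7.0) == 1.0

    @pytest.mark.parametrize("shape", ["linear", "asymptotic", "quadratic"])
    def test_bounded_by_one(self, shape):
        t = np.linspace(0, 14, 141)
        f = trajectory_basis(shape, t)
        assert np.all(np.abs(f) <= 1.0 + 1e-12)

    def test_opposite_function(self):
        t = np.linspace(0, 14, 15)
        np.testing.assert_allclose(
            trajectory_basis("asymptotic", t, sign=-1),
            -trajectory_basis("asymptotic", t),
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            trajectory_basis("linear", -0.1)
        with pytest.raises(ValueError):
            trajectory_basis("linear", 15.0, horizon=14.0)
        with pytest.raises(ValueError):
            trajectory_basis("cubic", 1.0)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def bh_oracle(p, q):
    """Hand-rolled step-up: largest i with p(i) <= i*q/m, reject below."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    thresh = 0.0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            thresh = p[idx]
    return p <= thresh if thresh > 0 else np.zeros(m, bool)


class TestFdrBh:
    def test_hand_step_up_all_rejected(self):
        mask, thr = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert mask.all()
        assert thr == 0.04

    def test_none_rejected(self):
        mask, thr = fdr_bh(np.array([0.9, 0.95]), q=0.05)
        assert not mask.any()
        assert thr == 0.0

    def test_single_p_is_uncorrected(self):
        mask, _ = fdr_bh(np.array([0.049]), q=0.05)
        assert mask.all()
        mask, _ = fdr_bh(np.array([0.051]), q=0.05)
        assert not mask.any()

    def test_empty_input(self):
        mask, thr = fdr_bh(np.array([]), q=0.05)
        assert mask.size == 0 and thr == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([rng.uniform(size=60), rng.uniform(0, 1e-3, 10)])
        mask, _ = fdr_bh(p, q=0.05)
        np.testing.assert_array_equal(mask, bh_oracle(p, 0.05))

    def test_nan_entries_never_rejected(self):
        p = np.array([0.001, np.nan, 0.002])
        mask, _ = fdr_bh(p, q=0.05)
        assert mask[0] and mask[2] and not mask[1]

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5]), q=1.5)


# ---------------------------------------------------------------------------
# cluster volume / preferred model / masks / smoothing
# ---------------------------------------------------------------------------

class TestClusterVolume:
    def test_published_conversions(self):
        assert cluster_volume(78442, 0.08) == 40.16
        assert cluster_volume(109811, 0.08) == 56.22
        assert cluster_volume(33817, 0.08) == 17.31

    def test_zero_and_closed_form(self):
        assert cluster_volume(0) == 0.0
        assert cluster_volume(1000, 0.1) == 1.00

    def test_linear_in_count_cubic_in_size(self):
        assert cluster_volume(2000, 0.1) == pytest.approx(2 * cluster_volume(1000, 0.1))
        assert cluster_volume(1000, 0.2) == pytest.approx(8 * cluster_volume(1000, 0.1))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cluster_volume(-1)


class TestPreferredModelMap:
    def test_clear_winner(self):
        maps = {
            "linear": np.array([[[100.0]]]),
            "asymptotic": np.array([[[85.0]]]),
            "quadratic": np.array([[[100.0]]]),
        }
        labels, shapes = preferred_model_map(maps, delta=10)
        assert shapes[labels[0, 0, 0] - 1] == "asymptotic"

    def test_insufficient_margin_unlabeled(self):
        maps = {
            "linear": np.array([[[100.0]]]),
            "asymptotic": np.array([[[95.0]]]),
            "quadratic": np.array([[[100.0]]]),
        }
        labels, _ = preferred_model_map(maps, delta=10)
        assert labels[0, 0, 0] == 0

    def test_nan_counts_as_infinitely_bad(self):
        maps = {"a": np.array([[[np.nan]]]), "b": np.array([[[5.0]]])}
        labels, shapes = preferred_model_map(maps, delta=1)
        assert shapes[labels[0, 0, 0] - 1] == "b"

    def test_mismatched_geometry_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            preferred_model_map({"a": np.zeros((2, 2, 2)), "b": np.zeros((3, 2, 2))})


class TestMaskAndSmoothing:
    def test_tpm_threshold_inclusive(self):
        np.testing.assert_array_equal(
            tpm_mask(np.array([0.1, 0.2, 0.3])), [False, True, True]
        )

    def test_tpm_degenerate_maps(self):
        assert not tpm_mask(np.zeros((3, 3))).any()
        assert tpm_mask(np.full((3, 3), 0.5)).all()

    def test_tpm_range_validated(self):
        with pytest.raises(ValueError):
            tpm_mask(np.array([1.2]))

    def test_sigma_conversion(self):
        # fwhm 0.4 mm at 0.08 mm voxels -> sigma 2.1233 voxels
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        out = smooth_volume(vol, fwhm=0.4, voxel_size=0.08)
        sigma = 0.4 / (2 * math.sqrt(2 * math.log(2))) / 0.08
        assert sigma == pytest.approx(2.1233, abs=1e-4)
        expected = ndimage.gaussian_filter(vol, sigma=sigma, mode="reflect")
        np.testing.assert_allclose(out, expected)

    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.random((8, 8, 8))
        np.testing.assert_array_equal(smooth_volume(vol, 0.0), vol)

    def test_mass_conservation_on_impulse(self):
        vol = np.zeros((15, 15, 15))
        vol[7, 9, 6] = 1.0
        out = smooth_volume(vol, fwhm=0.4, voxel_size=0.08)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(out.argmax(), out.shape) == (7, 9, 6)


# ---------------------------------------------------------------------------
# mixed-model fits
# ---------------------------------------------------------------------------

def toy_panel(rng, n_subj=4, days=(0.0, 6.0, 14.0)):
    subs = [
        SubjectRecord(
            f"s{i}",
            "trained" if i < n_subj // 2 else "control",
            float(rng.normal(450, 20)),
            days_present=days,
        )
        for i in range(n_subj)
    ]
    f = trajectory_basis("asymptotic", np.array(days), 14.0)
    y = np.empty((n_subj, len(days)))
    for i, s in enumerate(subs):
        g = 1.0 if s.is_trained else 0.0
        y[i] = (
            0.5
            + rng.normal(0, 0.02)
            + rng.normal(0, 0.01) * f
            + 0.05 * g * f
            + rng.normal(0, 0.01, len(days))
        )
    return subs, y, f


def brute_force_lme_neg2ll(y, subs, f):
    """Direct numerical maximization of the full marginal Gaussian
    likelihood over all 9 parameters. Independent oracle."""
    n_subj, ni = y.shape
    tivc = np.array([s.tiv for s in subs]) - np.mean([s.tiv for s in subs])
    Z = np.column_stack([np.ones(ni), f])
    Xs = []
    for i, s in enumerate(subs):
        g = 1.0 if s.is_trained else 0.0
        Xs.append(
            np.column_stack(
                [np.ones(ni), np.full(ni, tivc[i]), np.full(ni, g), f, g * f]
            )
        )

    def neg2ll(params):
        beta = params[:5]
        log_sigma, l0, l1, l2 = params[5:]
        sigma2 = math.exp(2 * log_sigma)
        L = np.array([[math.exp(l0), 0.0], [l1, math.exp(l2)]])
        G = sigma2 * (L @ L.T)
        total = 0.0
        for i in range(n_subj):
            V = Z @ G @ Z.T + sigma2 * np.eye(ni)
            r = y[i] - Xs[i] @ beta
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                return np.inf
            total += logdet + r @ np.linalg.solve(V, r) + ni * math.log(2 * math.pi)
        return total

    best = np.inf
    for s0 in ([0.5, 0, 0, 0, 0, math.log(0.01), -2, 0, -2],
               [0.5, 0, 0, 0, 0.05, math.log(0.02), -1, 0.2, -1],
               [0.4, 0, 0.01, 0.01, 0, math.log(0.05), -3, -0.1, -3]):
        res = optimize.minimize(neg2ll, s0, method="Nelder-Mead",
                                options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-10})
        res = optimize.minimize(neg2ll, res.x, method="Nelder-Mead",
                                options={"maxiter": 8000, "xatol": 1e-8, "fatol": 1e-10})
        best = min(best, res.fun)
    return best


class TestFitVoxelLme:
    def test_loglik_matches_brute_force_on_toy_panel(self, rng):
        subs, y, f = toy_panel(rng)
        fit = fit_voxel_lme(y, subs, "asymptotic", session_days=subs[0].days_present)
        oracle = brute_force_lme_neg2ll(y, subs, f)
        assert -2 * fit.log_likelihood == pytest.approx(oracle, abs=1e-4)

    def test_loglik_matches_statsmodels(self, rng):
        import pandas as pd
        import statsmodels.formula.api as smf

        subs, y, f = toy_panel(rng, n_subj=12, days=SESSION_DAYS)
        fit = fit_voxel_lme(y, subs, "asymptotic")
        rows = []
        tiv_mean = np.mean([s.tiv for s in subs])
        for i, s in enumerate(subs):
            for j in range(len(SESSION_DAYS)):
                rows.append(
                    dict(y=y[i, j], tiv=s.tiv - tiv_mean,
                         g=1.0 * s.is_trained, f=f[j], subj=s.id)
                )
        sm_fit = smf.mixedlm(
            "y ~ tiv + g + f + g:f", pd.DataFrame(rows), groups="subj", re_formula="~f"
        ).fit(reml=False)
        # both maximize the same likelihood; ours must not fall below the
        # reference optimum, and the two should agree closely (statsmodels
        # occasionally under-converges near a variance boundary)
        assert fit.log_likelihood >= sm_fit.llf - 1e-4
        assert fit.log_likelihood == pytest.approx(sm_fit.llf, abs=0.01)
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params.values, atol=1e-3)

    def test_no_group_difference_by_construction(self):
        subs = [
            SubjectRecord(f"s{i}", "trained" if i < 3 else "control", 450.0)
            for i in range(6)
        ]
        f = trajectory_basis("asymptotic", np.array(SESSION_DAYS))
        y = np.tile(0.3 + 0.1 * f, (6, 1))
        fit = fit_voxel_lme(y, subs, "asymptotic")
        assert abs(fit.beta3) < 1e-6

    def test_interaction_coverage(self):
        """95% Wald CI covers the true interaction in >= 93/100 replicates."""
        rng = np.random.default_rng(7)
        subs = [
            SubjectRecord(f"s{i}", "trained" if i < 20 else "control",
                          float(rng.normal(450, 20)))
            for i in range(40)
        ]
        f = trajectory_basis("asymptotic", np.array(SESSION_DAYS))
        lme = TrajectoryLME(subs, "asymptotic")
        covered = 0
        theta = None
        for _ in range(100):
            y = np.empty((40, 6))
            for i, s in enumerate(subs):
                g = 1.0 if s.is_trained else 0.0
                y[i] = (0.5 + rng.normal(0, 0.02) + rng.normal(0, 0.01) * f
                        + 0.05 * g * f + rng.normal(0, 0.01, 6))
            fit = lme.fit(y, theta0=theta)
            theta = getattr(fit, "theta", None)
            lo, hi = fit.ci95_interaction
            covered += lo <= 0.05 <= hi
        assert covered >= 93

    def test_subject_order_invariance(self, rng):
        subs, y, _ = toy_panel(rng, n_subj=8, days=SESSION_DAYS)
        fit = fit_voxel_lme(y, subs, "asymptotic")
        perm = rng.permutation(len(subs))
        fit_p = fit_voxel_lme(y[perm], [subs[i] for i in perm], "asymptotic")
        assert fit_p.log_likelihood == pytest.approx(fit.log_likelihood, abs=1e-6)
        assert fit_p.beta3 == pytest.approx(fit.beta3, abs=1e-8)

    def test_tiv_rescale_leaves_interaction_unchanged(self, rng):
        subs, y, _ = toy_panel(rng, n_subj=8, days=SESSION_DAYS)
        scaled = [
            SubjectRecord(s.id, s.group, s.tiv * 10.0, s.days_present) for s in subs
        ]
        fit = fit_voxel_lme(y, subs, "asymptotic")
        fit_s = fit_voxel_lme(y, scaled, "asymptotic")
        assert fit_s.beta3 == pytest.approx(fit.beta3, abs=1e-7)
        assert fit_s.beta[1] == pytest.approx(fit.beta[1] / 10.0, rel=1e-4)

    def test_degenerate_voxel_flagged(self):
        subs = [
            SubjectRecord(f"s{i}", "trained" if i < 2 else "control", 450.0)
            for i in range(4)
        ]
        y = np.zeros((4, 6))
        fit = fit_voxel_lme(y, subs, "linear")
        assert fit.degenerate
        assert fit.p_interaction == 1.0

    def test_unbalanced_panel(self, rng):
        days_a = SESSION_DAYS
        days_b = SESSION_DAYS[:4]
        subs = [
            SubjectRecord("s0", "trained", 440.0, days_a),
            SubjectRecord("s1", "trained", 455.0, days_b),
            SubjectRecord("s2", "control", 450.0, days_a),
            SubjectRecord("s3", "control", 445.0, days_b),
        ]
        y = 0.5 + rng.normal(0, 0.01, (4, 6))
        y[1, 4:] = np.nan
        y[3, 4:] = np.nan
        fit = fit_voxel_lme(y, subs, "linear")
        assert fit.n == 2 * 6 + 2 * 4
        assert np.isfinite(fit.log_likelihood)


# ---------------------------------------------------------------------------
# voxelwise maps
# ---------------------------------------------------------------------------

class TestVoxelwiseMaps:
    def test_single_voxel_mask_fdr_identity(self, rng):
        from plastimap.synthetic import LongitudinalConfig, gen_longitudinal_volumes

        cfg = LongitudinalConfig(seed=3, n_per_group=6, grid=(2, 1, 1),
                                 effect_amplitude=0.0)
        series, subjects, _ = gen_longitudinal_volumes(cfg)
        mask = np.zeros((2, 1, 1), dtype=bool)
        mask[0, 0, 0] = True
        maps = voxelwise_maps(series, subjects, mask, shapes=("linear",), q=0.05)
        p = maps.pvalue["linear"][0, 0, 0]
        rejected = maps.significant[("linear", "increase")] | maps.significant[("linear", "decrease")]
        assert rejected.any() == bool(p <= 0.05)

    def test_empty_mask_rejected(self, rng):
        from plastimap.synthetic import LongitudinalConfig, gen_longitudinal_volumes

        cfg = LongitudinalConfig(seed=3, n_per_group=6, grid=(2, 1, 1))
        series, subjects, _ = gen_longitudinal_volumes(cfg)
        with pytest.raises(ValueError, match="empty"):
            voxelwise_maps(series, subjects, np.zeros((2, 1, 1), bool))

    def test_null_simulation_controls_fdr(self):
        """Mean false-discovery proportion <= q over 50 null replicates."""
        from plastimap.synthetic import LongitudinalConfig, gen_longitudinal_volumes

        q = 0.05
        fdps = []
        for rep in range(50):
            cfg = LongitudinalConfig(
                seed=1000 + rep, n_per_group=10, grid=(4, 4, 4),
                effect_amplitude=0.0, baseline_spatial_sd=0.0,
            )
            series, subjects, _ = gen_longitudinal_volumes(cfg)
            mask = np.ones((4, 4, 4), dtype=bool)
            maps = voxelwise_maps(series, subjects, mask, shapes=("asymptotic",), q=q)
            n_disc = int(
                maps.significant[("asymptotic", "increase")].sum()
                + maps.significant[("asymptotic", "decrease")].sum()
            )
            fdps.append(1.0 if n_disc > 0 else 0.0)  # all discoveries false under null
        # E[FDP] <= q; allow 2 binomial standard errors of Monte-Carlo slack
        se = math.sqrt(q * (1 - q) / 50)
        assert np.mean(fdps) <= q + 2 * se


# ---------------------------------------------------------------------------
# VOI extraction and per-subject fits
# ---------------------------------------------------------------------------

def small_series(rng, n=6, grid=(3, 3, 3)):
    data = 0.5 + 0.01 * rng.random((n, 6) + grid)
    subs = [
        SubjectRecord(f"s{i}", "trained" if i < n // 2 else "control", 450.0)
        for i in range(n)
    ]
    return VolumeSeries(data), subs


class TestExtractVoi:
    def test_constructed_ratio(self, rng):
        series, subs = small_series(rng)
        controls = [i for i, s in enumerate(subs) if not s.is_trained]
        ctrl_mean = series.data[controls].mean(axis=0)
        for i, s in enumerate(subs):
            series.data[i] = 0.95 * ctrl_mean if s.is_trained else ctrl_mean
        voi = np.ones((3, 3, 3), bool)
        out = extract_voi(series, voi, subs)
        trained_rows = out.loc[[s.id for s in subs if s.is_trained]]
        np.testing.assert_allclose(trained_rows.to_numpy(), 0.95, atol=1e-12)

    def test_identity_when_equal(self, rng):
        series, subs = small_series(rng)
        base = series.data[0].copy()
        for i in range(len(subs)):
            series.data[i] = base
        out = extract_voi(series, np.ones((3, 3, 3), bool), subs)
        np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-12)

    def test_zero_control_mean_rejected(self, rng):
        series, subs = small_series(rng)
        series.data[:] = 0.0
        with pytest.raises(ValueError, match="zero|undefined"):
            extract_voi(series, np.ones((3, 3, 3), bool), subs)

    def test_empty_voi_rejected(self, rng):
        series, subs = small_series(rng)
        with pytest.raises(ValueError, match="empty"):
            extract_voi(series, np.zeros((3, 3, 3), bool), subs)

    def test_asymptotic_effect_recovered_in_normalized_trajectory(self):
        """A +4% plateau effect shows in the normalized trajectory and its
        group-mean fit prefers asymptotic over linear."""
        from plastimap.model_selection import compare_trajectories
        from plastimap.synthetic import LongitudinalConfig, gen_longitudinal_volumes
        from plastimap.timecourse import ols_trajectory_fit

        cfg = LongitudinalConfig(
            seed=11, n_per_group=16, grid=(6, 6, 6),
            effect_shape="asymptotic", effect_amplitude=0.04,
            effect_region=(slice(0, 6), slice(0, 6), slice(0, 6)),
            noise_sd=0.004, random_intercept_sd=0.004, random_slope_sd=0.002,
        )
        series, subjects, _ = gen_longitudinal_volumes(cfg)
        out = extract_voi(series, np.ones((6, 6, 6), bool), subjects)
        trained = out.loc[[s.id for s in subjects if s.is_trained]]
        mean_traj = trained.mean(axis=0).to_numpy()
        assert mean_traj[-1] == pytest.approx(1.04, abs=0.01)
        days = np.array(SESSION_DAYS)
        comp = compare_trajectories(
            [ols_trajectory_fit(days, mean_traj, s) for s in ("linear", "asymptotic")]
        )
        assert comp.preferred == "asymptotic"


class TestSubjectTrajectoryAicc:
    def test_noise_free_asymptotic_prefers_asymptotic(self):
        days = np.array(SESSION_DAYS)
        y = 1.0 + 0.04 * trajectory_basis("asymptotic", days)
        out = subject_trajectory_aicc(days, y)
        assert out["asymptotic"] < out["linear"]

    def test_flat_trajectory_ties_within_correction(self, rng):
        days = np.array(SESSION_DAYS)
        y = 1.0 + rng.normal(0, 0.01, len(days))  # no time signal, only noise
        out = subject_trajectory_aicc(days, y)
        # zero-signal OLS: both shapes share k=3, so the AICc gap is the
        # (small) difference in how much noise each basis soaks up
        assert abs(out["asymptotic"] - out["linear"]) < 2 * 3

    def test_insufficient_sessions_rejected(self):
        with pytest.raises((InsufficientDataError, ValueError)):
            subject_trajectory_aicc([0, 2, 6], [1, 1, 1])

    def test_learning_rate_correlation_sign(self):
        """Animals whose plateau amplitude scales with learning rate show a
        negative correlation between rate and asymptotic AICc."""
        from scipy import stats

        rng = np.random.default_rng(5)
        days = np.array(SESSION_DAYS)
        f = trajectory_basis("asymptotic", days)
        rates, aiccs = [], []
        for _ in range(40):
            rate = rng.uniform(0.5, 8.0)
            amp = 0.01 * rate  # amplitude proportional to learning rate
            y = 1.0 + amp * f + rng.normal(0, 0.004, len(days))
            rates.append(rate)
            aiccs.append(subject_trajectory_aicc(days, y)["asymptotic"])
        r, _ = stats.pearsonr(rates, aiccs)
        assert r < 0
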
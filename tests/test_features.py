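"""Torque matrix, k=1 CCA, reconstruction, angular impulse and slope test."""

import warnings

import numpy as np
import pytest
from scipy import stats

from tetherpitch import features as feat
from tetherpitch.wingstrokes import Wingstroke

FS = 10_000.0


def strokes_and_tau(rows_fn, n=4, period=0.05):
    """Synthesize a tau_x series realizing given per-stroke waveforms."""
    per = int(period * FS)
    strokes, tau = [], np.zeros(n * per)
    for i in range(n):
        strokes.append(Wingstroke(index=i, t0=i * period, t1=(i + 1) * period))
        tau[i * per : (i + 1) * per] = rows_fn(i, np.arange(per) / per)
    return strokes, tau


class TestTorqueMatrix:
    def test_constant_trace_row(self):
        strokes, tau = strokes_and_tau(lambda i, p: 3.0 + i)
        tm = feat.build_torque_matrix(strokes, tau, FS)
        assert tm.T.shape == (4, 300)
        for i in range(4):
            np.testing.assert_allclose(tm.T[i], 3.0 + i)

    def test_linear_ramp_row(self):
        strokes, tau = strokes_and_tau(lambda i, p: 2.0 + 5.0 * p)
        tm = feat.build_torque_matrix(strokes, tau, FS)
        expected = 2.0 + 5.0 * np.arange(300) / 300
        np.testing.assert_allclose(tm.T[0], expected, atol=5.0 / 500)

    def test_roundtrip_band_limited(self):
        strokes, tau = strokes_and_tau(
            lambda i, p: np.sin(2 * np.pi * 4 * p) + 0.5 * np.cos(2 * np.pi * 2 * p)
        )
        tm = feat.build_torque_matrix(strokes, tau, FS)
        back = feat.resample_to_original(tm, tm.T)
        for i, s in enumerate(tm.strokes):
            grid_end = s.t0 + (s.t1 - s.t0) * (tm.m - 1) / tm.m
            inside = tm.orig_times[i] <= grid_end  # beyond is edge extrapolation
            dev = np.abs(back[i][inside] - tm.orig_values[i][inside]).max()
            assert dev < 0.01 * np.ptp(tm.orig_values[i])

    def test_too_few_strokes_rejected(self):
        strokes, tau = strokes_and_tau(lambda i, p: p, n=1)
        with pytest.raises(ValueError, match="at least 2"):
            feat.build_torque_matrix(strokes[:1], tau, FS)


def zscore(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


class TestCCA:
    def test_perfect_predictor_column(self):
        rng = np.random.default_rng(0)
        n = 50
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 6))
        X[:, 2] = y
        model = feat.CCATimingFeatures(ridge=1e-10).fit(zscore(X), zscore(y.reshape(-1, 1))[:, 0])
        assert model.canonical_correlation_ > 0.999
        w = np.abs(model.x_weights_)
        assert w[2] > 5 * np.delete(w, 2).max()

    def test_permuted_timing_not_significant(self):
        """Independent y: canonical correlation sits inside the permutation null."""
        rng = np.random.default_rng(1)
        X, y = zscore(rng.normal(size=(80, 10))), zscore(rng.normal(size=(80, 1)))[:, 0]
        r_obs = feat.CCATimingFeatures(ridge=1e-10).fit(X, y).canonical_correlation_
        null = []
        for _ in range(100):
            null.append(
                feat.CCATimingFeatures(ridge=1e-10)
                .fit(X, y[rng.permutation(80)])
                .canonical_correlation_
            )
        assert r_obs < np.quantile(null, 0.99)

    def test_brute_force_oracle_n6_m2(self):
        """1-degree grid search over unit-norm weights agrees with the solver."""
        rng = np.random.default_rng(2)
        X, y = zscore(rng.normal(size=(6, 2))), zscore(rng.normal(size=(6, 1)))[:, 0]
        model = feat.CCATimingFeatures(ridge=1e-10).fit(X, y)
        best_w, best_r = None, -1.0
        for deg in np.arange(0.0, 180.0, 1.0):
            w = np.array([np.cos(np.radians(deg)), np.sin(np.radians(deg))])
            r = abs(np.corrcoef(X @ w, y)[0, 1])
            if r > best_r:
                best_w, best_r = w, r
        angle = np.degrees(np.arccos(np.clip(abs(best_w @ model.x_weights_), 0, 1)))
        assert angle <= 1.0
        assert model.canonical_correlation_ == pytest.approx(best_r, abs=1e-4)

    def test_matches_sklearn_cca_on_full_rank_instance(self):
        """Independent library route: scikit-learn's CCA finds the same
        canonical direction and correlation for univariate y."""
        from sklearn.cross_decomposition import CCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        y = X @ rng.normal(size=5) + 0.5 * rng.normal(size=60)
        Xz, yz = zscore(X), zscore(y.reshape(-1, 1))[:, 0]
        mine = feat.CCATimingFeatures(ridge=1e-10).fit(Xz, yz)
        sk = CCA(n_components=1).fit(Xz, yz.reshape(-1, 1))
        w_sk = sk.x_weights_[:, 0] / np.linalg.norm(sk.x_weights_[:, 0])
        assert abs(w_sk @ mine.x_weights_) > 0.9999
        r_sk = abs(np.corrcoef(Xz @ w_sk, yz)[0, 1])
        assert mine.canonical_correlation_ == pytest.approx(r_sk, abs=1e-6)

    def test_constant_timing_rejected(self):
        X = zscore(np.random.default_rng(4).normal(size=(10, 3)))
        with pytest.raises(ValueError, match="constant"):
            feat.CCATimingFeatures().fit(X, np.ones(10))

    def test_rank_deficiency_warns(self):
        rng = np.random.default_rng(5)
        X, y = zscore(rng.normal(size=(10, 20))), zscore(rng.normal(size=(10, 1)))[:, 0]
        with pytest.warns(UserWarning, match="rank deficient"):
            feat.CCATimingFeatures().fit(X, y)


class TestReconstruction:
    def make_rank1(self, seed=0, n=20, m=30):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=n), rng.normal(size=m)
        T = np.outer(a, b) + 5.0
        strokes = [Wingstroke(index=i, t0=i * 0.05, t1=(i + 1) * 0.05) for i in range(n)]
        tm = feat.TorqueMatrix(
            T, T.mean(0), T.std(0, ddof=1), strokes,
            [np.linspace(i * 0.05, (i + 1) * 0.05, 500, endpoint=False) for i in range(n)],
            [np.interp(np.arange(500) / 500, np.arange(m) / m, T[i]) for i in range(n)],
            np.zeros(m, dtype=bool),
        )
        return tm, a

    def test_rank1_matrix_reconstructed_exactly(self):
        tm, a = self.make_rank1()
        model = feat.fit_cca(tm, a, ridge=1e-12)
        recon = feat.reconstruct(model, tm)
        np.testing.assert_allclose(recon, tm.T, atol=1e-8)
        assert feat.variance_explained(tm, recon) == pytest.approx(1.0, abs=1e-9)

    def test_zero_scores_give_column_means(self):
        tm, a = self.make_rank1(seed=1)
        model = feat.fit_cca(tm, a, ridge=1e-12)
        recon_z = model.inverse_transform(np.zeros(tm.n))
        recon = tm.unzscore_rows(recon_z)
        np.testing.assert_allclose(recon, np.tile(tm.col_mean, (tm.n, 1)))
        assert feat.variance_explained(tm, recon) == pytest.approx(0.0, abs=1e-12)

    def test_residual_orthogonal_to_scores(self, stim_small):
        import tetherpitch.features as f

        tm, phases = self._fit_stim(stim_small)
        model = self.model
        resid = tm.zscored - model.inverse_transform(model.scores_)
        inner = np.abs(model.scores_ @ resid) / len(model.scores_)
        assert inner.max() < 1e-8

    def _fit_stim(self, stim_small):
        tm = feat.build_torque_matrix(
            stim_small["valid_strokes"], stim_small["ft"].tau_x, FS
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model = feat.fit_cca(tm, stim_small["phases"])
        return tm, stim_small["phases"]

    def test_oscillation_phase_advances_with_earlier_spikes(self, stim_small):
        """Reconstructions shift the within-stroke torque oscillation
        monotonically with evoked DLM phase (rank correlation)."""
        tm, phases = self._fit_stim(stim_small)
        recon = feat.reconstruct(self.model, tm)
        phi = np.arange(tm.m) / tm.m
        k = stim_small["cfg"].torque_osc_cycles
        s_, c_ = np.sin(2 * np.pi * k * phi), np.cos(2 * np.pi * k * phi)
        order = np.argsort(phases)
        osc = np.array([np.arctan2((r - r.mean()) @ c_, (r - r.mean()) @ s_) for r in recon])
        rho = stats.spearmanr(phases[order], np.unwrap(osc[order])).statistic
        assert abs(rho) > 0.9
        assert rho < 0  # earlier spike -> phase advance

    def test_explained_beats_permuted_scores(self, stim_small):
        tm, _ = self._fit_stim(stim_small)
        model = self.model
        recon = feat.reconstruct(model, tm)
        v_fit = feat.variance_explained(tm, recon)
        rng = np.random.default_rng(6)
        X = tm.zscored
        for _ in range(100):
            s = model.scores_[rng.permutation(tm.n)]
            loadings = (s @ X) / (s @ s)
            v_perm = feat.variance_explained(tm, tm.unzscore_rows(np.outer(s, loadings)))
            assert v_fit >= v_perm

    def test_calibrated_variance_fraction_recovered(self, stim_small):
        """Generator calibrated at a coupled fraction of 0.355: the CCA
        explained fraction lands within +/-0.067 of it."""
        tm, _ = self._fit_stim(stim_small)
        recon = feat.reconstruct(self.model, tm)
        v = feat.variance_explained(tm, recon)
        target = stim_small["cfg"].coupled_variance_fraction_target
        assert v == pytest.approx(target, abs=0.067)


class TestMechanics:
    def test_constant_torque_rectangle(self):
        J = feat.angular_impulse(np.ones(500), t0=0.0, t1=0.05)
        assert J == pytest.approx(5e-5, rel=1e-12)

    def test_full_period_sinusoid_integrates_to_zero(self):
        t = np.linspace(0.0, 0.05, 501)
        J = feat.angular_impulse(np.sin(2 * np.pi * 20 * t), times=t)
        assert abs(J) < 1e-9

    def test_piecewise_linear_exact(self):
        t = np.array([0.0, 0.01, 0.03, 0.05])
        v = np.array([0.0, 2.0, -1.0, 1.0])  # mN m
        J = feat.angular_impulse(v, times=t)
        # trapezoid is exact on piecewise-linear traces
        exact = 1e-3 * (0.01 * 1.0 + 0.02 * 0.5 + 0.02 * 0.0)
        assert J == pytest.approx(exact, rel=1e-12)

    def test_delta_omega_definitions(self):
        assert feat.delta_omega(0.0) == 0.0
        J = feat.I_YY_KG_M2 * np.radians(400.0)
        assert feat.delta_omega(J) == pytest.approx(400.0, rel=1e-12)

    def test_delta_omega_worked_example(self):
        """Constant 3.73e-5 N m over 50 ms -> J = 1.865e-6 N m s -> ~400.7 deg/s."""
        J = feat.angular_impulse(np.full(500, 3.73e-2), t0=0.0, t1=0.05)
        assert J == pytest.approx(1.865e-6, rel=1e-9)
        assert feat.delta_omega(J) == pytest.approx(400.7, abs=0.05)

    def test_impulse_linearity(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 0.05, 40))
        a, b = rng.normal(size=40), rng.normal(size=40)
        lhs = feat.angular_impulse(a + b, times=t)
        rhs = feat.angular_impulse(a, times=t) + feat.angular_impulse(b, times=t)
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestSlopeTest:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 60)
        groups = np.repeat(["a", "b", "c"], 20)
        offsets = {"a": 0.0, "b": 1.0, "c": -1.0}
        y = 2.0 * x + np.array([offsets[g] for g in groups]) + rng.normal(0, 1e-6, 60)
        res = feat.slope_test(x, y, groups)
        assert res["slope"] == pytest.approx(2.0, abs=1e-3)
        assert res["pvalue"] < 1e-6

    def test_null_rejection_rate(self):
        """y independent of x: ~5% rejections at alpha=0.05 (200 replicates)."""
        rng = np.random.default_rng(9)
        rej = 0
        for _ in range(200):
            x = rng.uniform(0, 1, 40)
            groups = np.repeat(["a", "b", "c", "d"], 10)
            y = rng.normal(size=40)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if feat.slope_test(x, y, groups)["pvalue"] < 0.05:
                    rej += 1
        assert 0.02 <= rej / 200 <= 0.08

    def test_group_requirements(self):
        with pytest.raises(ValueError, match="2 groups"):
            feat.slope_test([1, 2, 3], [1, 2, 3], ["a"] * 3)
        with pytest.raises(ValueError, match="3 points"):
            feat.slope_test([1, 2, 3, 4], [1, 2, 3, 4], ["a", "a", "a", "b"])


class TestCouplingSweep:
    def test_gain_sweep_monotone_span(self):
        """Stronger DLM-torque coupling gives monotonically larger evoked
        delta-omega span and canonical correlation."""
        import tetherpitch.spikes as spk
        from tetherpitch.config import SynthConfig
        from tetherpitch.pipeline import _process_recording, _validate_trials
        from tetherpitch.synth import generate_stimulation_session

        spans, corrs = [], []
        for mult in (0.25, 1.0, 4.0):
            cfg = SynthConfig.stim_session(
                seed=17,
                stim_min_separation=1.0,
                coupling_gain=1.5 * mult,
                transient_gain=15.0 * mult,
                coupled_variance_fraction_target=None,
            )
            rec, gt = generate_stimulation_session(cfg, 150)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ft, strokes, trains, _ = _process_recording(
                    rec, "stimulation_10_40", 1000.0, 5.0
                )
                dlm = {m: spk.label_evoked(trains[m], rec.stim_marks) for m in ("LDLM", "RDLM")}
                vs, phases, _ = _validate_trials(rec.stim_marks, dlm, strokes)
                tm = feat.build_torque_matrix(vs, ft.tau_x, rec.fs)
                model = feat.fit_cca(tm, np.asarray(phases))
            recon = feat.reconstruct(model, tm)
            mech = feat.stroke_mechanics(tm, recon, np.asarray(phases))
            order = np.argsort(mech["evoked_phase"].to_numpy())
            k = max(len(order) // 10, 3)
            span = (
                mech["delta_omega_feature"].to_numpy()[order[-k:]].mean()
                - mech["delta_omega_feature"].to_numpy()[order[:k]].mean()
            )
            spans.append(span)
            corrs.append(model.canonical_correlation_)
        assert spans[0] < spans[1] < spans[2]
        assert corrs[0] <= corrs[1] + 1e-6 and corrs[1] <= corrs[2] + 1e-6
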
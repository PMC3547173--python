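"""Variational-Laplace inversion: packing, free energy, fitting, comparison."""

import numpy as np
import pytest
from dataclasses import replace

from cmcfield import inversion, synthetic
from cmcfield.params import default_parameters, to_flat_dict


class TestPackParameters:
    def test_zero_scalings_identity(self, priors):
        p, f, o = priors
        p2, f2, o2 = inversion.pack_parameters(p, f, o, {n: 0.0 for n in
                                                         inversion.DEFAULT_FREE})
        assert to_flat_dict(p2, f2, o2) == to_flat_dict(p, f, o)

    def test_single_parameter_doubles(self, priors):
        p, f, o = priors
        p2, f2, o2 = inversion.pack_parameters(p, f, o, {"m_e": np.log(2.0)})
        flat, flat2 = to_flat_dict(p, f, o), to_flat_dict(p2, f2, o2)
        assert flat2["m_e"] == pytest.approx(2.0 * flat["m_e"])
        changed = [k for k in flat
                   if isinstance(flat[k], float)
                   and not np.isclose(flat2[k], flat[k])]
        assert changed == ["m_e"]

    def test_log_ratio_round_trip(self, priors):
        p, f, o = priors
        rng = np.random.default_rng(0)
        names = [n for n in inversion.DEFAULT_FREE if n != "eta"]  # eta mean is 0
        theta = {n: rng.uniform(-1, 1) for n in names}
        p2, f2, o2 = inversion.pack_parameters(p, f, o, theta)
        flat, flat2 = to_flat_dict(p, f, o), to_flat_dict(p2, f2, o2)
        for n, v in theta.items():
            assert np.log(flat2[n] / flat[n]) == pytest.approx(v, abs=1e-12)

    def test_unknown_name_rejected(self, priors):
        p, f, o = priors
        with pytest.raises(KeyError):
            inversion.pack_parameters(p, f, o, {"bogus": 0.1})


class TestFreeEnergy:
    def test_identical_posterior_and_zero_residuals(self):
        model = inversion.ModelSpec(variant="field")
        prior_var = model.prior.variance_vector()
        mu = np.zeros(prior_var.size)
        C = np.diag(prior_var)
        data_power = model.predict(np.arange(30.0, 81.0), mu)
        from cmcfield.spectra import SpectralData
        data = SpectralData(np.arange(30.0, 81.0), data_power)
        lam = 2.7
        fe = inversion.free_energy(data, model, mu, C, lam,
                                   lambda_var=model.prior.hyper_variance)
        assert fe.complexity_params == pytest.approx(0.0, abs=1e-10)
        n = data_power.size
        # hyper posterior differs from its prior only through the mean
        expected_kl_h = 0.5 * (lam - model.prior.hyper_mean) ** 2 / model.prior.hyper_variance
        assert fe.complexity_hyper == pytest.approx(expected_kl_h)
        assert fe.accuracy == pytest.approx(-0.5 * n * np.log(2 * np.pi) + 0.5 * n * lam)

    def test_shrinking_covariance_costs_entropy(self):
        model = inversion.ModelSpec(variant="field")
        prior_var = model.prior.variance_vector()
        mu = np.zeros(prior_var.size)
        from cmcfield.spectra import SpectralData
        freqs = np.arange(30.0, 81.0)
        data = SpectralData(freqs, model.predict(freqs, mu))
        f_wide = inversion.free_energy(data, model, mu, np.diag(prior_var), 0.0)
        f_narrow = inversion.free_energy(data, model, mu,
                                         np.diag(prior_var) * 1e-3, 0.0)
        assert f_narrow.total < f_wide.total

    def test_truth_beats_prior_mean_and_margin_grows_with_snr(self):
        scalings = {"c_diag": 0.4}
        model = inversion.ModelSpec(variant="field")
        prior_var = model.prior.variance_vector()
        C = np.diag(prior_var)
        names = list(model.prior.free)
        mu_truth = np.zeros(len(names))
        for i, n in enumerate(names):
            if n.startswith("c_") and n[2] == n[3]:
                mu_truth[i] = 0.4
        margins = []
        for noise in (0.05, 0.01):
            data = synthetic.simulate_spectrum(
                synthetic.GroundTruth(scalings=scalings, noise_fraction=noise,
                                      seed=3))
            lam = float(-np.log((noise * data.power.mean()) ** 2))
            f_truth = inversion.free_energy(data, model, mu_truth, C, lam).total
            f_prior = inversion.free_energy(data, model,
                                            np.zeros(len(names)), C, lam).total
            margins.append(f_truth - f_prior)
        assert margins[0] > 0
        assert margins[1] > margins[0]


class TestFit:
    def test_self_consistency_at_prior_means(self):
        data = synthetic.simulate_spectrum(
            synthetic.GroundTruth(noise_fraction=0.001, seed=42))
        res = inversion.fit(data, inversion.ModelSpec(variant="field"))
        assert res.converged
        sd = np.sqrt(np.diag(res.C))
        assert np.all(np.abs(res.mu) <= 2.0 * sd)

    def test_trajectory_non_decreasing(self):
        data = synthetic.simulate_spectrum(
            synthetic.GroundTruth(scalings={"c_diag": 0.4}, seed=0))
        res = inversion.fit(data, inversion.ModelSpec(variant="field"))
        assert np.all(np.diff(res.trajectory) >= 0.0)

    def test_posterior_covariance_is_symmetric_psd(self):
        data = synthetic.simulate_spectrum(synthetic.GroundTruth(seed=17))
        res = inversion.fit(data, inversion.ModelSpec(variant="field"))
        assert np.allclose(res.C, res.C.T)
        assert np.min(np.linalg.eigvalsh(res.C)) > 0

    def test_sign_recovery_small_replicate_set(self):
        # strong direction only; the full 20-replicate joint experiment is
        # exercised by the acceptance suite
        hits = 0
        for seed in range(3):
            data = synthetic.simulate_spectrum(
                synthetic.GroundTruth(scalings={"c_diag": 0.4, "a_23": -0.4},
                                      seed=seed))
            res = inversion.fit(data, inversion.ModelSpec(variant="field"))
            c_diag = np.mean([res.scaling(n) for n in
                              ("c_11", "c_22", "c_33", "c_44")])
            hits += c_diag > 0
        assert hits >= 2

    def test_fit_serialization_round_trip(self, tmp_path):
        data = synthetic.simulate_spectrum(synthetic.GroundTruth(seed=2))
        res = inversion.fit(data, inversion.ModelSpec(variant="mass"))
        res.to_json(tmp_path / "fit.json")
        back = inversion.PosteriorFit.from_json(tmp_path / "fit.json")
        assert back.names == res.names
        assert np.allclose(back.mu, res.mu)
        assert back.F == pytest.approx(res.F)


class TestPosteriorCorrelations:
    def test_diagonal_covariance_gives_identity(self):
        fit = _dummy_fit(C=np.diag([0.1, 0.2, 0.3]))
        _, R = inversion.posterior_correlations(fit)
        assert np.allclose(R, np.eye(3))

    def test_matches_direct_normalization(self, rng):
        A = rng.standard_normal((4, 4))
        C = A @ A.T + 0.1 * np.eye(4)
        fit = _dummy_fit(C=C)
        _, R = inversion.posterior_correlations(fit)
        d = np.sqrt(np.diag(C))
        assert np.allclose(R, C / np.outer(d, d), atol=1e-12)
        assert np.allclose(R, R.T)
        assert np.allclose(np.diag(R), 1.0)


def _dummy_fit(C):
    p = C.shape[0]
    return inversion.PosteriorFit(
        names=tuple(f"p{i}" for i in range(p)), mu=np.zeros(p), C=C,
        lambda_mean=0.0, lambda_var=1.0, F=0.0,
        free_energy=inversion.FreeEnergy(0.0, 0.0, 0.0, 0.0),
        trajectory=np.zeros(1), converged=True, n_iter=0,
        data_checksum="x", settings_hash="y")


class TestCompareModels:
    def test_self_comparison_is_zero(self):
        data = synthetic.simulate_spectrum(synthetic.GroundTruth(seed=1))
        res = inversion.fit(data, inversion.ModelSpec(variant="mass"))
        cmp_result = inversion.compare_models([(res, res)])
        assert cmp_result.delta_f[0] == 0.0
        assert not cmp_result.strong_evidence[0]

    def test_threshold_is_inclusive(self):
        a = _dummy_fit(np.eye(2))
        b = _dummy_fit(np.eye(2))
        b.F = -3.0
        cmp_result = inversion.compare_models([(a, b)])
        assert cmp_result.delta_f[0] == 3.0
        assert cmp_result.strong_evidence[0]

    def test_mismatched_data_rejected(self):
        a = _dummy_fit(np.eye(2))
        b = _dummy_fit(np.eye(2))
        b.data_checksum = "other"
        with pytest.raises(ValueError, match="different data"):
            inversion.compare_models([(a, b)])

    def test_field_data_favours_field_model(self):
        deltas = []
        for seed in range(10):
            data = synthetic.simulate_spectrum(synthetic.GroundTruth(
                noise_fraction=synthetic.NOISE_HIGH_SNR, seed=100 + seed))
            ff = inversion.fit(data, inversion.ModelSpec(variant="field"))
            fm = inversion.fit(data, inversion.ModelSpec(variant="mass"))
            deltas.append((ff, fm))
        cmp_result = inversion.compare_models(deltas)
        assert cmp_result.mean > 0


class TestMassFieldEquivalence:
    def test_mass_fit_equals_clamped_field_fit(self):
        data = synthetic.simulate_spectrum(
            synthetic.GroundTruth(noise_fraction=0.01, seed=7))
        mass = inversion.fit(data, inversion.ModelSpec(variant="mass"))
        pr = inversion.PriorSpec.default()
        pr0 = replace(pr, field=replace(pr.field, upsilon=0.0),
                      obs=replace(pr.obs, k_order=0),
                      free=tuple(n for n in pr.free if n != "upsilon"))
        clamped = inversion.fit(data, inversion.ModelSpec(variant="field",
                                                          prior=pr0))
        assert abs(mass.F - clamped.F) < 1e-6


class TestOccam:
    def test_irrelevant_free_parameter_never_helps_on_average(self):
        # data generated at prior means; m_i is irrelevant extra freedom
        base_free = inversion.DEFAULT_FREE
        extra_free = (*base_free, "m_i")
        diffs = []
        for seed in (0, 1, 2):
            data = synthetic.simulate_spectrum(synthetic.GroundTruth(seed=seed))
            f_base = inversion.fit(
                data, inversion.ModelSpec(
                    variant="field",
                    prior=inversion.PriorSpec.default(free=base_free))).F
            f_extra = inversion.fit(
                data, inversion.ModelSpec(
                    variant="field",
                    prior=inversion.PriorSpec.default(free=extra_free))).F
            diffs.append(f_extra - f_base)
        assert np.mean(diffs) <= 0.0
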
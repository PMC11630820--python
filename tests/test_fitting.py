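"""Chi-squared objective, single and global fits, profiles, recovery."""

import numpy as np
import pytest

import tmfret as tm
from tmfret.fitting import chi_squared, profile_parameter


@pytest.fixture(scope="module")
def pairs():
    return {a: tm.get_pair(a) for a in ("Fe(phenM)3", "Ru(bpy)2phenM")}


@pytest.fixture(scope="module")
def noisefree_study():
    design = tm.StudyDesign(noise_phase=0.0, noise_mod=0.0, seed=3)
    return tm.generate_fd_study(design)


def test_chi_squared_zero_for_exact_predictions():
    ds = tm.generate_donor_only(seed=0)
    assert chi_squared([ds], [(ds.phase_deg, ds.mod_ratio)]) == 0.0


def test_chi_squared_unit_contribution_per_sigma():
    ds = tm.generate_donor_only(noise_phase=0.0, noise_mod=0.0, seed=0)
    phase = ds.phase_deg.copy()
    phase[3] += 0.2  # exactly one default phase sigma
    assert chi_squared([ds], [(phase, ds.mod_ratio)]) == pytest.approx(1.0)


def test_chi_squared_matches_brute_force_resummation():
    rng = np.random.default_rng(7)
    ds = tm.generate_donor_only(seed=5)
    pred_phase = ds.phase_deg + rng.normal(0, 0.5, len(ds))
    pred_mod = np.clip(ds.mod_ratio + rng.normal(0, 0.01, len(ds)), 0.01, 1.0)
    total = chi_squared([ds], [(pred_phase, pred_mod)], sigma_phase=0.3, sigma_mod=0.005)
    brute = 0.0
    for i in range(len(ds)):
        sp = ds.phase_sd[i] if ds.phase_sd is not None else 0.3
        sm = ds.mod_sd[i] if ds.mod_sd is not None else 0.005
        brute += ((ds.phase_deg[i] - pred_phase[i]) / sp) ** 2
        brute += ((ds.mod_ratio[i] - pred_mod[i]) / sm) ** 2
    assert total == pytest.approx(brute, rel=1e-12)


def test_chi_squared_shape_mismatch():
    ds = tm.generate_donor_only(seed=0)
    with pytest.raises(ValueError):
        chi_squared([ds], [(ds.phase_deg[:-1], ds.mod_ratio)])


def test_donor_only_fit_recovers_tau():
    ds = tm.generate_donor_only(tau_d=17.2, noise_phase=0.0, noise_mod=0.0, seed=0)
    res = tm.fit_donor_only(ds)
    assert res.converged
    assert res.parameters["tau"] == pytest.approx(17.2, abs=1e-6)
    noisy = tm.generate_donor_only(tau_d=17.2, seed=11)
    res = tm.fit_donor_only(noisy)
    assert res.parameters["tau"] == pytest.approx(17.2, abs=0.15)


def test_single_gaussian_noise_free_self_consistency(fe_pair):
    dist = tm.make_single(39.6, 4.0)
    nuis = tm.NuisanceParams(f_donor_only=0.1, f_background=0.02, t0=0.2)
    ds = tm.predict_dataset(dist, fe_pair, nuis, condition="apo")
    res = tm.fit_single_gaussian(ds, fe_pair, seed=0)
    assert res.converged
    assert res.parameters["rbar"] == pytest.approx(39.6, abs=1e-3)
    assert res.parameters["sigma"] == pytest.approx(4.0, abs=1e-3)


def test_single_gaussian_noisy_replicate_average_recovery(fe_pair):
    """Averaging n=4 noisy replicates recovers the mean distance within 0.5 Å."""
    dist = tm.make_single(39.6, 4.0)
    nuis = tm.NuisanceParams(f_donor_only=0.1, f_background=0.02, t0=0.1)
    clean = tm.predict_dataset(dist, fe_pair, nuis)
    rng = np.random.default_rng(17)
    phases = np.mean(
        [clean.phase_deg + rng.normal(0, 0.2, len(clean)) for _ in range(4)], axis=0
    )
    mods = np.mean(
        [clean.mod_ratio + rng.normal(0, 0.004, len(clean)) for _ in range(4)], axis=0
    )
    avg = tm.FDDataset(frequencies=clean.frequencies, phase_deg=phases, mod_ratio=mods)
    res = tm.fit_single_gaussian(avg, fe_pair, seed=0)
    assert res.converged
    assert res.parameters["rbar"] == pytest.approx(39.6, abs=0.5)


def test_single_gaussian_flags_donor_only_data_as_unidentifiable(fe_pair):
    """Acceptor-free data carries no distance information: the fitted mean
    runs to a bound (or transfer is negligible) and the result says so."""
    ds = tm.generate_donor_only(noise_phase=0.05, noise_mod=0.001, seed=2)
    res = tm.fit_single_gaussian(ds, fe_pair, seed=0)
    assert "distance_unidentifiable" in res.flags


def test_global_fit_noise_free_self_consistency(pairs, noisefree_study):
    """Six noise-free datasets at the two-state truth are recovered to 1e-2."""
    datasets, truth = noisefree_study
    res = tm.fit_global_two_gaussian(datasets, pairs, n_starts=1, seed=0)
    assert res.converged
    assert res.parameters["rbar1"] == pytest.approx(40.9, abs=1e-2)
    assert res.parameters["sigma1"] == pytest.approx(4.3, abs=1e-2)
    assert res.parameters["rbar2"] == pytest.approx(29.5, abs=1e-2)
    assert res.parameters["sigma2"] == pytest.approx(0.84, abs=1e-2)
    assert res.parameters["A2_apo"] == pytest.approx(0.12, abs=1e-2)
    assert res.parameters["A2_cAMP"] == pytest.approx(1.0, abs=1e-2)
    assert res.parameters["A2_cGMP"] == pytest.approx(0.34, abs=1e-2)
    # nuisance recovery: shared donor-only fractions per sample
    for rep_id, nuis in truth["nuisance"].items():
        sample = rep_id.rsplit("_", 1)[0]
        key = f"f_do_{sample}".replace("(", "_").replace(")", "_")
        assert res.parameters[key] == pytest.approx(nuis["f_donor_only"], abs=1e-2)


def test_global_fit_nested_models(pairs, noisefree_study):
    """Forcing A2 = 0 everywhere on two-state truth must cost chi-squared."""
    datasets, _ = noisefree_study
    free = tm.fit_global_two_gaussian(datasets, pairs, n_starts=1, seed=0)
    forced = tm.fit_global_two_gaussian(
        datasets,
        pairs,
        n_starts=1,
        seed=0,
        _extra_fixed={"A2_apo": 0.0, "A2_cAMP": 0.0, "A2_cGMP": 0.0},
    )
    assert forced.chi2 > free.chi2 + 100.0


def test_global_fit_requires_registered_acceptor(pairs):
    datasets, _ = tm.generate_fd_study(tm.StudyDesign(seed=0))
    datasets[0].acceptor = "mystery-metal"
    with pytest.raises(KeyError, match="mystery-metal"):
        tm.fit_global_two_gaussian(datasets, {"Fe(phenM)3": pairs["Fe(phenM)3"]})


def test_global_fit_order_invariance(pairs):
    datasets, _ = tm.generate_fd_study(tm.StudyDesign(seed=4))
    res_fwd = tm.fit_global_two_gaussian(datasets, pairs, n_starts=1, seed=0)
    res_rev = tm.fit_global_two_gaussian(datasets[::-1], pairs, n_starts=1, seed=0)
    for k in ("rbar1", "sigma1", "rbar2", "sigma2", "A2_apo", "A2_cAMP", "A2_cGMP"):
        assert res_fwd.parameters[k] == pytest.approx(res_rev.parameters[k], abs=1e-8)


def test_global_fit_reports_a2_bound_hit(pairs, noisefree_study):
    """A2 = 1 (saturating agonist) must be reported as a bound, not an
    interior estimate."""
    datasets, _ = noisefree_study
    res = tm.fit_global_two_gaussian(datasets, pairs, n_starts=1, seed=0)
    assert "A2_cAMP" in res.bound_hits


def test_recovery_study_bias(recovery_study):
    """Across seeded noisy studies, median biases stay small: the estimator
    is calibrated at the study's own noise level."""
    assert np.median(np.abs(recovery_study["rbar1"] - 40.9)) < 0.2
    assert np.median(np.abs(recovery_study["rbar2"] - 29.5)) < 0.2
    assert np.median(np.abs(recovery_study["A2_apo"] - 0.12)) < 0.02
    assert np.median(np.abs(recovery_study["A2_cGMP"] - 0.34)) < 0.02
    assert recovery_study["converged"].all()


def test_profile_minimum_at_truth(pairs, noisefree_study):
    """The chi-squared profile of rbar2 on noise-free truth dips at 29.5 Å."""
    datasets, _ = noisefree_study
    grid = np.array([28.0, 28.75, 29.5, 30.25, 31.0])
    scan = profile_parameter(datasets, pairs, "rbar2", grid, seed=0)
    assert scan.ok.all()
    assert int(np.argmin(scan.chi2)) == 2
    assert scan.chi2[0] > scan.chi2[2] and scan.chi2[-1] > scan.chi2[2]


def test_profile_of_unknown_parameter_errors(pairs, noisefree_study):
    datasets, _ = noisefree_study
    with pytest.raises(KeyError):
        profile_parameter(datasets, pairs, "not_a_param", np.array([1.0, 2.0]))
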
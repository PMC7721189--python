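import numpy as np
import pytest

from conftest import make_random_system
from spatialscaling import (
    CitySystem,
    DistanceMatrix,
    GeneratorConfig,
    Kernel,
    attractiveness,
    bootstrap_sigma_beta,
    build_distance_matrix,
    fit_beta,
    map_fit,
    profile_alpha,
    simulate,
)


def test_counts_proportional_to_population_give_beta_one(rng):
    system = make_random_system(rng, n=30, with_counts=False)
    system = system.with_counts(3.0 * system.x)
    bf = fit_beta(system.x, system.y, system.x)
    assert bf.beta == pytest.approx(1.0, abs=1e-3)
    assert not bf.boundary


def test_all_tokens_in_largest_unit_hit_upper_boundary(rng):
    system = make_random_system(rng, n=10, with_counts=False)
    y = np.zeros(10)
    y[np.argmax(system.x)] = 1000.0
    bf = fit_beta(system.x, y, system.x)
    assert bf.beta == 2.0
    assert bf.boundary


def test_flat_likelihood_flagged_unidentified(rng):
    system = make_random_system(rng, n=10)
    A = np.full(10, system.total_population)  # constant A: beta drops out
    bf = fit_beta(system.x, system.y, A)
    assert bf.unidentified and bf.beta == 1.0


def test_single_unit_rejected():
    with pytest.raises(ValueError, match="unidentif"):
        fit_beta([10.0], [5.0], [10.0])


def test_fit_invariant_to_permutation_and_attractiveness_scaling(rng):
    system = make_random_system(rng, n=20)
    A = system.x * rng.uniform(1, 4, 20)
    bf = fit_beta(system.x, system.y, A)
    perm = rng.permutation(20)
    bf_perm = fit_beta(system.x[perm], system.y[perm], A[perm])
    bf_scaled = fit_beta(system.x, system.y, 137.0 * A)
    assert bf_perm.beta == pytest.approx(bf.beta, abs=1e-6)
    assert bf_scaled.beta == pytest.approx(bf.beta, abs=1e-6)
    assert bf_scaled.loglik == pytest.approx(bf.loglik, abs=1e-6)


def test_city_simulated_beta_recovery():
    cfg = GeneratorConfig(n_units=100, total_tokens=10**6, family="C",
                          alpha=0.0, beta=1.3, seed=42)
    system, dist = simulate(cfg)
    fit = map_fit(system, dist, "C")
    assert fit.beta == pytest.approx(1.3, abs=0.02)


def test_profile_alpha_zero_row_equals_city_fit(rng):
    system = make_random_system(rng, n=25)
    dist = build_distance_matrix(system)
    prof = profile_alpha(system, dist, "G", [0.0, 10.0, 100.0])
    cfit = map_fit(system, dist, "C")
    row = prof.iloc[0]
    assert row["alpha_km"] == 0.0
    assert row["beta_hat"] == pytest.approx(cfit.beta, abs=1e-6)
    assert row["loglik"] == pytest.approx(cfit.loglik, abs=1e-9)


def test_profile_huge_alpha_approaches_per_capita(rng):
    system = make_random_system(rng, n=25)
    dist = build_distance_matrix(system)
    prof = profile_alpha(system, dist, "G", [1e12])
    pfit = map_fit(system, dist, "P")
    assert prof.iloc[0]["loglik"] == pytest.approx(pfit.loglik, abs=1e-6)
    assert prof.iloc[0]["beta_unidentified"]


def test_profile_rejects_empty_grid_and_wrong_family(rng):
    system = make_random_system(rng, n=5)
    dist = build_distance_matrix(system)
    with pytest.raises(ValueError, match="empty"):
        profile_alpha(system, dist, "G", [])
    with pytest.raises(ValueError, match="famil"):
        profile_alpha(system, dist, "C", [1.0])


def test_per_capita_fit_has_no_free_parameters(random_system):
    from spatialscaling import log_likelihood

    fit = map_fit(random_system, None, "P")
    assert fit.beta == 1.0 and fit.alpha is None
    expected = log_likelihood(random_system.y, random_system.x,
                              random_system.x, 1.0)
    assert fit.loglik == pytest.approx(expected, abs=1e-9)


def test_city_simulated_data_drives_spatial_fit_to_small_alpha():
    cfg = GeneratorConfig(n_units=80, total_tokens=10**6, family="C",
                          alpha=0.0, beta=1.3, seed=11)
    system, dist = simulate(cfg)
    gfit = map_fit(system, dist, "G")
    cfit = map_fit(system, dist, "C")
    # with no spatial signal the fitted scale falls below the smallest
    # inter-city distance, where the kernel reaches nobody
    off_diag = dist.values[dist.values > 0]
    assert gfit.alpha < off_diag.min()
    assert gfit.beta == pytest.approx(cfit.beta, abs=0.01)
    assert gfit.loglik == pytest.approx(cfit.loglik, abs=0.5)


def test_nested_families_ordered_by_loglik(rng):
    system = make_random_system(rng, n=30, total_tokens=50_000)
    dist = build_distance_matrix(system)
    llG = map_fit(system, dist, "G").loglik
    llC = map_fit(system, dist, "C").loglik
    llP = map_fit(system, dist, "P").loglik
    assert llG >= llC - 1e-6
    assert llG >= llP - 1e-6


def test_bootstrap_is_deterministic_given_seed():
    cfg = GeneratorConfig(n_units=40, total_tokens=10**5, family="C",
                          alpha=0.0, beta=1.2, seed=5)
    system, dist = simulate(cfg)
    fit = map_fit(system, dist, "C")
    s1 = bootstrap_sigma_beta(system, dist, fit, n_boot=25, seed=99)
    s2 = bootstrap_sigma_beta(system, dist, fit, n_boot=25, seed=99)
    assert s1 == s2
    assert s1 > 0


def test_bootstrap_rejects_per_capita_and_tiny_replicate_counts(random_system):
    pfit = map_fit(random_system, None, "P")
    with pytest.raises(ValueError, match="per-capita"):
        bootstrap_sigma_beta(random_system, None, pfit, n_boot=10, seed=0)
    cfit = map_fit(random_system, None, "C")
    with pytest.raises(ValueError, match="replicates"):
        bootstrap_sigma_beta(random_system, None, cfit, n_boot=1, seed=0)


def test_noninteger_totals_warn_on_resampling():
    system = CitySystem(unit_id=["a", "b", "c"], x=[100.0, 300.0, 50.0],
                        y=[10.5, 20.25, 1.0])
    fit = map_fit(system, None, "C")
    with pytest.warns(UserWarning, match="not an integer"):
        bootstrap_sigma_beta(system, None, fit, n_boot=5, seed=0)


def test_downstream_results_permutation_invariant():
    cfg = GeneratorConfig(n_units=30, total_tokens=10**5, seed=21)
    system, dist = simulate(cfg)
    fit = map_fit(system, dist, "E")
    perm = np.random.default_rng(3).permutation(30)
    fit_p = map_fit(system.subset(perm), dist.subset(perm), "E")
    assert fit_p.beta == pytest.approx(fit.beta, abs=1e-4)
    assert fit_p.loglik == pytest.approx(fit.loglik, abs=1e-6)
    if fit.alpha and fit_p.alpha:
        assert fit_p.alpha == pytest.approx(fit.alpha, rel=0.02)
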
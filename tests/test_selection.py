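import numpy as np
import pytest
from scipy.special import logsumexp

from conftest import make_random_system
from spatialscaling import (
    CitySystem,
    DistanceMatrix,
    GeneratorConfig,
    PriorSpec,
    compare_models,
    description_length,
    laplace_log_evidence,
    log_evidence,
    map_fit,
    simulate,
)
from spatialscaling.likelihood import (
    allocation_log_likelihood_grid,
    log_multinomial_coefficient,
)

_8LN2 = 8 * np.log(2)


def test_prior_densities_normalise_on_their_support():
    priors = PriorSpec()
    # density * support volume = 1 for each family
    assert priors.log_theta_density("P") == 0.0
    assert priors.log_theta_density("C") + np.log(2.0) == pytest.approx(0.0)
    for fam in ("G", "E"):
        vol = 2.0 * priors.alpha_max
        assert priors.log_theta_density(fam) + np.log(vol) == pytest.approx(0.0)
    assert 4 * np.exp(priors.log_model_prior) == pytest.approx(1.0)


def test_description_length_unit_conversion_and_monotonicity():
    assert description_length(-8 * np.log(2)) == pytest.approx(1.0)
    assert description_length(-20.0) > description_length(-10.0)


def test_per_capita_description_length_two_unit_worked_value(two_unit_system):
    system, dist = two_unit_system
    ev = log_evidence(system, dist, "P")
    expected = (-np.log(0.375) + np.log(4.0)) / _8LN2
    assert ev.dl_bytes == pytest.approx(expected, abs=1e-9)
    assert ev.log_evidence == pytest.approx(np.log(0.375) - np.log(4.0))


def test_city_evidence_matches_fine_riemann_oracle(rng):
    # broad likelihood (small Y) so that a brute-force uniform grid resolves it
    system = make_random_system(rng, n=5, total_tokens=50)
    betas = np.linspace(0.0, 2.0, 20001)
    vals = allocation_log_likelihood_grid(system.y, system.x, system.x, betas)
    riemann = (log_multinomial_coefficient(system.y)
               + logsumexp(vals) + np.log(betas[1] - betas[0])
               + np.log(0.5) + np.log(0.25))
    ev = log_evidence(system, None, "C")
    assert abs(description_length(ev.log_evidence)
               - description_length(riemann)) < 0.05


def test_evidence_never_exceeds_map_likelihood_bound(rng):
    system = make_random_system(rng, n=12, total_tokens=5000)
    dist = None
    from spatialscaling import build_distance_matrix

    dist = build_distance_matrix(system)
    for fam in ("P", "C", "G", "E"):
        fit = map_fit(system, dist, fam)
        ev = log_evidence(system, dist, fam, fit=fit)
        assert ev.log_evidence <= fit.loglik + np.log(0.25) + 1e-6


def test_posterior_model_probabilities_form_a_simplex(rng):
    system = make_random_system(rng, n=10, total_tokens=2000)
    from spatialscaling import build_distance_matrix

    dist = build_distance_matrix(system)
    log_evs = [log_evidence(system, dist, f).log_evidence
               for f in ("P", "C", "G", "E")]
    post = np.exp(log_evs - logsumexp(log_evs))
    assert post.sum() == pytest.approx(1.0, abs=1e-12)


def test_occam_penalty_on_per_capita_data():
    deltas = []
    for seed in range(3):
        cfg = GeneratorConfig(n_units=60, total_tokens=10**5, family="P",
                              seed=seed)
        system, dist = simulate(cfg)
        dC = log_evidence(system, dist, "C").dl_bytes
        dP = log_evidence(system, dist, "P").dl_bytes
        deltas.append(dC - dP)
    assert np.mean(deltas) > 0  # extra parameter penalised


def test_comparison_table_structure_and_winner_on_city_data():
    cfg = GeneratorConfig(n_units=60, total_tokens=10**6, family="C",
                          alpha=0.0, beta=1.3, seed=2)
    system, dist = simulate(cfg)
    cmp_ = compare_models(system, dist, n_boot=20, seed=0)
    table = cmp_.table
    assert table.loc["P", "delta_D_bytes"] == 0.0
    assert (table["delta_D_bytes"] == 0).sum() == 1
    assert cmp_.winner != "P"
    assert table.loc[cmp_.winner, "delta_D_bytes"] < 0
    assert cmp_.winner == table["D_bytes"].idxmin()
    fitted = table.drop(index="P")
    assert np.isfinite(fitted["sigma_beta"]).all()


def test_comparison_requires_two_families(random_system):
    with pytest.raises(ValueError, match="2 families"):
        compare_models(random_system, families=["P"])


def test_laplace_agrees_with_quadrature_at_interior_map():
    cfg = GeneratorConfig(n_units=60, total_tokens=10**6, family="G",
                          alpha=30.0, beta=1.25, seed=8)
    system, dist = simulate(cfg)
    fit = map_fit(system, dist, "G")
    assert fit.alpha > 0 and not fit.beta_boundary
    quad = log_evidence(system, dist, "G", fit=fit).log_evidence
    lap = laplace_log_evidence(system, dist, "G", fit=fit)
    assert abs(description_length(lap) - description_length(quad)) < 1.0
    # the C family too (1-D Gaussian)
    cfit = map_fit(system, dist, "C")
    quad_c = log_evidence(system, dist, "C", fit=cfit).log_evidence
    lap_c = laplace_log_evidence(system, dist, "C", fit=cfit)
    assert abs(description_length(lap_c) - description_length(quad_c)) < 1.0


def test_laplace_refused_at_boundary_map(rng):
    system = make_random_system(rng, n=10, with_counts=False)
    y = np.zeros(10)
    y[np.argmax(system.x)] = 500.0
    system = system.with_counts(y)
    fit = map_fit(system, None, "C")
    assert fit.beta_boundary
    with pytest.raises(ValueError, match="boundary"):
        laplace_log_evidence(system, None, "C", fit=fit)


def test_laplace_refused_at_alpha_zero():
    # the parameter prior is discontinuous at alpha = 0: the Gaussian
    # expansion is invalid there and must be refused outright
    from spatialscaling import ModelFit, build_distance_matrix

    cfg = GeneratorConfig(n_units=50, total_tokens=10**6, family="C",
                          alpha=0.0, beta=1.3, seed=11)
    system, dist = simulate(cfg)
    boundary_fit = ModelFit(family="G", alpha=0.0, beta=1.3, loglik=-1.0)
    with pytest.raises(ValueError, match="alpha"):
        laplace_log_evidence(system, dist, "G", fit=boundary_fit)
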
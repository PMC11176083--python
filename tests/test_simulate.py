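"""Clone-growth model, read sampler and cohort generator."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from clonalselect import (
    DriverSite,
    SimParams,
    clone_density,
    expected_detectable,
    forward_birth_death,
    generate_cohort,
    phi,
    sample_clone_vafs,
    simulate_reads,
)
from clonalselect.simulate import simulate_site_observations


class TestPhi:
    def test_neutral_drift_limit(self):
        assert phi(0.0, 60, 140_000) == pytest.approx(60 / 280_000)

    def test_selected_value(self):
        # direct high-precision evaluation of (e^{st}-1)/(2*Ntau*s)
        expected = np.expm1(0.159 * 60) / (2 * 140_000 * 0.159)
        assert phi(0.159, 60, 140_000) == pytest.approx(expected, rel=1e-12)
        assert phi(0.159, 60, 140_000) == pytest.approx(0.312, rel=2e-3)

    def test_monotone_in_s_and_t(self):
        ss = np.linspace(0.0, 0.3, 20)
        ts = np.linspace(1.0, 80.0, 20)
        vals_s = [phi(s, 50, 1e5) for s in ss]
        vals_t = [phi(0.1, t, 1e5) for t in ts]
        assert np.all(np.diff(vals_s) > 0)
        assert np.all(np.diff(vals_t) > 0)

    def test_negative_s_rejected(self):
        with pytest.raises(ValueError):
            phi(-0.1, 50, 1e5)


class TestCloneDensity:
    def test_zero_mu_zero_density(self):
        f = np.linspace(0.01, 0.5, 10)
        assert np.all(clone_density(f, 0.1, 0.0, 50, 1e5) == 0)

    def test_value_example(self):
        assert clone_density(0.1, 0.159, 1e-6, 60, 140_000) == pytest.approx(1.016, rel=2e-3)

    def test_f_times_density_monotone_decreasing(self):
        f = np.linspace(0.01, 0.5, 50)
        vals = f * clone_density(f, 0.12, 1e-6, 55, 1e5)
        assert np.all(np.diff(vals) < 0)

    def test_invalid_f(self):
        with pytest.raises(ValueError):
            clone_density(0.0, 0.1, 1e-6, 50, 1e5)


class TestExpectedDetectable:
    def test_closed_form_matches_quadrature(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = rng.uniform(0.02, 0.3)
            mu = 10 ** rng.uniform(-8, -5)
            t = rng.uniform(40, 70)
            ntau = 10 ** rng.uniform(4, 6)
            f_min = rng.uniform(0.01, 0.2)
            lam = expected_detectable(s, mu, t, ntau, f_min)
            quad, _ = integrate.quad(lambda f: clone_density(f, s, mu, t, ntau), f_min, 0.5)
            assert lam == pytest.approx(quad, rel=1e-8)

    def test_monotone_in_s_mu_t(self):
        base = dict(s=0.1, mu=1e-6, t=55.0, ntau=1e5, f_min=0.05)
        lam0 = expected_detectable(**base)
        assert expected_detectable(**{**base, "s": 0.15}) > lam0
        assert expected_detectable(**{**base, "mu": 2e-6}) > lam0
        assert expected_detectable(**{**base, "t": 65.0}) > lam0

    def test_zero_mu_and_domain_error(self):
        assert expected_detectable(0.1, 0.0, 50, 1e5, 0.05) == 0
        with pytest.raises(ValueError):
            expected_detectable(0.1, 1e-6, 50, 1e5, 0.0)


class TestSampler:
    def test_zero_mu_always_empty(self):
        rng = np.random.default_rng(0)
        assert sample_clone_vafs(0.1, 0.0, 50, 1e5, 0.05, rng).size == 0

    def test_mean_count_matches_lambda(self):
        s, mu, t, ntau, f_min = 0.15, 2e-6, 60.0, 1e5, 0.03
        lam = expected_detectable(s, mu, t, ntau, f_min)
        rng = np.random.default_rng(1)
        counts = [sample_clone_vafs(s, mu, t, ntau, f_min, rng).size for _ in range(10_000)]
        se = np.sqrt(lam / 10_000)
        assert np.mean(counts) == pytest.approx(lam, abs=3 * se)

    def test_matches_forward_birth_death(self):
        """Inverse-CDF sampler and the forward oracle agree in distribution."""
        N, s, tau, t, mu, f_min = 1000, 0.15, 1.0, 40.0, 2e-4, 0.02
        rng = np.random.default_rng(2)
        bd = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(250):
                sizes = forward_birth_death(N, s, tau, t, mu, rng)
                bd.extend(f for f in sizes / (2 * N) if f_min < f <= 0.5)
        samp = []
        for _ in range(2000):
            samp.extend(sample_clone_vafs(s, mu, t, N * tau, f_min, rng).tolist())
        assert len(bd) > 100 and len(samp) > 500
        assert stats.ks_2samp(bd, samp).pvalue > 0.01


class TestForwardBirthDeath:
    def test_neutral_surviving_mean_scales_with_t_over_tau(self):
        # critical birth-death, clone age a: E[size|survive] = 1 + a/tau and
        # P(survive) = 1/(1 + a/tau); averaging over uniform founding times in
        # (0, t) gives mean surviving size t / (tau * ln(1 + t/tau))
        rng = np.random.default_rng(3)
        for t in (10.0, 20.0):
            sizes = []
            for _ in range(3000):
                out = forward_birth_death(200, 0.0, 1.0, t, 5e-5, rng)
                sizes.extend(out.tolist())
            pred = t / np.log1p(t)
            assert np.mean(sizes) == pytest.approx(pred, rel=0.2)

    def test_supercritical_conditioned_mean(self):
        # single founder aged Delta: E[size | survival] ~ (e^{s*Delta}-1)/(s*tau)
        s, tau, delta = 0.1, 1.0, 15.0
        rng = np.random.default_rng(4)

        def founder():
            dt = tau / 10
            n = 1
            for _ in range(int(round(delta / dt))):
                if n == 0:
                    return 0
                n += rng.binomial(n, dt / tau) - rng.binomial(n, (1 - s * tau) * dt / tau)
            return n

        sizes = [founder() for _ in range(20_000)]
        surv = [x for x in sizes if x > 0]
        pred = np.expm1(s * delta) / (s * tau)
        assert np.mean(surv) == pytest.approx(pred, rel=0.15)

    def test_determinism_and_guards(self):
        a = forward_birth_death(500, 0.1, 1.0, 20.0, 1e-4, np.random.default_rng(5))
        b = forward_birth_death(500, 0.1, 1.0, 20.0, 1e-4, np.random.default_rng(5))
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            forward_birth_death(20_000, 0.1, 1.0, 10.0, 1e-6, np.random.default_rng(0))


class TestSimulateReads:
    def test_no_signal_no_error_no_alt(self):
        rng = np.random.default_rng(0)
        _, alt, *_ = simulate_reads(np.zeros(500), 45, 0.0, rng)
        assert np.all(alt == 0)

    def test_het_mean_alt_fraction(self):
        rng = np.random.default_rng(1)
        depth, alt, *_ = simulate_reads(np.full(1000, 0.5), 45, 0.0, rng)
        frac = alt.sum() / depth.sum()
        se = 0.5 / np.sqrt(depth.sum())
        assert frac == pytest.approx(0.5, abs=3 * se)

    def test_depth_median(self):
        rng = np.random.default_rng(2)
        depth, *_ = simulate_reads(np.zeros(20_000), 45, 0.001, rng)
        assert np.median(depth) == 45

    def test_error_tail_matches_exact_binomial(self):
        # error-only sites at fixed depth 45: P(alt >= 5) from the exact tail
        rng = np.random.default_rng(3)
        n_sites, p_err = 200_000, 0.001 / 3
        alt = rng.binomial(45, p_err, size=n_sites)  # depth pinned for the oracle
        exact = stats.binom.sf(4, 45, p_err)
        observed = np.mean(alt >= 5)
        assert observed == pytest.approx(exact, abs=5e-6)
        # and the read simulator's alt draw follows the same binomial law
        _, alt2, *_ = simulate_reads(np.zeros(50_000), 45, 0.001, rng)
        p1 = stats.binom.sf(0, 45, p_err)  # P(>=1 alt) at depth 45
        assert np.mean(alt2[np.newaxis, :] >= 1) == pytest.approx(p1, rel=0.15)

    def test_artifact_strand_and_quality(self):
        rng = np.random.default_rng(4)
        _, alt, fa, ra, _, _, bqa, bqr = simulate_reads(
            np.full(200, 0.3), 45, 0.001, rng, artifact=True
        )
        nonzero = alt > 0
        assert np.all((fa[nonzero] == 0) | (ra[nonzero] == 0))
        assert np.all(bqr - bqa == 8)


class TestGenerateCohort:
    def test_empty_params_empty_table(self, gene_set):
        params = SimParams(
            n_individuals=50, driver_sites=(), passenger_rate=0.0,
            germline_sites_per_indiv=0, error_rate=0.0, artifact_rate=0.0, seed=1,
        )
        records, truth, individuals = generate_cohort(params, gene_set)
        assert records.empty
        assert truth.clones.empty
        assert len(individuals) == 50

    def test_determinism(self, gene_set):
        params = SimParams(n_individuals=60, germline_sites_per_indiv=1,
                           error_sites_per_indiv=5, seed=9)
        r1, _, _ = generate_cohort(params, gene_set)
        r2, _, _ = generate_cohort(params, gene_set)
        pd.testing.assert_frame_equal(r1, r2)
        r3, _, _ = generate_cohort(SimParams(n_individuals=60, germline_sites_per_indiv=1,
                                             error_sites_per_indiv=5, seed=10), gene_set)
        assert not r1.equals(r3)

    def test_truth_conservation(self, small_cohort):
        _, _, records, truth, _ = small_cohort
        assert set(records["truth_origin"]) <= {"driver", "passenger", "germline", "seq_error", "artifact"}
        drivers = records[records["truth_origin"] == "driver"]
        clone_keys = set(zip(truth.clones["individual_id"], truth.clones["gene_id"], truth.clones["cds_pos"]))
        for row in drivers.itertuples(index=False):
            assert (row.individual_id, row.gene_id, row.cds_pos) in clone_keys
        assert (records.loc[records["truth_origin"] != "driver", "truth_s"] == 0).sum() == (
            (records["truth_origin"].isin(["germline", "seq_error", "artifact"])).sum()
        )

    def test_read_count_consistency(self, small_cohort):
        _, _, records, _, _ = small_cohort
        assert (records["alt_reads"] <= records["depth"]).all()
        assert (records["fwd_alt"] + records["rev_alt"] == records["alt_reads"]).all()
        assert np.allclose(records["vaf"], records["alt_reads"] / records["depth"])

    def test_carrier_fraction_matches_poisson_prediction(self):
        """P(carry site) ~ 1 - E_age[e^{-lambda(age)}] at moderate cohort size."""
        gene = None
        rng = np.random.default_rng(0)
        from clonalselect import annotate_impact, random_gene_set

        genes = random_gene_set(2, rng, length_codons=(60, 80))
        g = genes[0]
        pos, ref, alt = 5, g.cds_seq[4], "ACGT".replace(g.cds_seq[4], "")[0]
        site = DriverSite(g.gene_id, pos, ref, alt, s=0.2, mu=5e-6)
        params = SimParams(
            n_individuals=4000, driver_sites=(site,), passenger_rate=0.0,
            germline_sites_per_indiv=0, error_rate=0.0, artifact_rate=0.0,
            f_min=0.02, seed=3,
        )
        records, truth, individuals = generate_cohort(params, genes)
        carriers = truth.clones["individual_id"].nunique()
        ages = np.linspace(40, 70, 301)
        lam = expected_detectable(site.s, site.mu, ages, params.ntau, params.f_min)
        p_carry = float(np.mean(1 - np.exp(-lam)))
        se = np.sqrt(p_carry * (1 - p_carry) / params.n_individuals)
        assert carriers / params.n_individuals == pytest.approx(p_carry, abs=3.5 * se)


def test_site_observation_shortcut_matches_model_rates():
    rng = np.random.default_rng(11)
    ages, carrier, vaf = simulate_site_observations(0.15, 1e-6, 1.4e5, 5000, 0.02, rng)
    assert carrier.sum() == np.isfinite(vaf).sum()
    lam_bar = float(np.mean(expected_detectable(0.15, 1e-6, ages, 1.4e5, 0.02)))
    p = 1 - np.exp(-lam_bar)
    assert carrier.mean() == pytest.approx(p, abs=3.5 * np.sqrt(p * (1 - p) / 5000))
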
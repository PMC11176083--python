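"""Global and per-gene dN/dS under the context-aware Poisson model."""

import numpy as np
import pandas as pd
import pytest

from clonalselect import (
    excess_metrics,
    fit_global_dnds,
    gene_dnds_test,
    random_gene_set,
    restricted_gene_test,
    sum_opportunities,
    tally_counts,
)
from clonalselect.dnds import _alternating_mle, _poisson_ll, driver_fraction_identified
from clonalselect.genes import IMPACT_INDEX, ImpactClass, build_opportunities
from clonalselect.simulate import sample_neutral_mutations

SYN = IMPACT_INDEX[ImpactClass.SYNONYMOUS]
MIS = IMPACT_INDEX[ImpactClass.MISSENSE]
NON = IMPACT_INDEX[ImpactClass.NONSENSE]


def _toy_matrices(n_syn, e_syn, n_mis, e_mis, ctx=0):
    counts = np.zeros((96, 5))
    opps = np.zeros((96, 5))
    counts[ctx, SYN], opps[ctx, SYN] = n_syn, e_syn
    counts[ctx, MIS], opps[ctx, MIS] = n_mis, e_mis
    opps[ctx, NON] = 1.0  # keep the class identifiable
    return counts, opps


class TestGlobalFit:
    def test_counts_proportional_to_opportunities_gives_omega_one(self):
        rng = np.random.default_rng(0)
        opps = rng.integers(50, 500, size=(96, 5)).astype(float)
        counts = 0.37 * opps  # exact proportionality across every class
        fit, _ = fit_global_dnds(counts, opps)
        for cls in ("missense", "nonsense", "essential_splice", "all_nonsynonymous"):
            assert fit.omega[cls] == pytest.approx(1.0, abs=1e-8)

    def test_single_context_closed_form(self):
        # E_syn=1000 with 100 hits, E_mis=2000 with 400 hits -> omega = 2.0
        counts, opps = _toy_matrices(100, 1000, 400, 2000)
        fit, rates = fit_global_dnds(counts, opps)
        assert fit.omega["missense"] == pytest.approx(2.0, abs=1e-8)
        assert fit.ci["missense"][0] < 2.0 < fit.ci["missense"][1]

    def test_zero_count_boundary(self):
        counts, opps = _toy_matrices(100, 1000, 0, 2000)
        fit, _ = fit_global_dnds(counts, opps)
        assert fit.omega["missense"] == pytest.approx(0.0, abs=1e-10)
        assert np.isfinite(fit.ci["missense"][1])
        assert fit.ci["missense"][0] == 0.0

    def test_unidentifiable_without_synonymous_opportunities(self):
        counts = np.zeros((96, 5))
        opps = np.zeros((96, 5))
        opps[:, MIS] = 10
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_global_dnds(counts, opps)

    def test_scale_property_doubling_shrinks_ci(self):
        counts, opps = _toy_matrices(100, 1000, 300, 2000)
        fit1, _ = fit_global_dnds(counts, opps)
        fit2, _ = fit_global_dnds(2 * counts, 2 * opps)
        assert fit2.omega["missense"] == pytest.approx(fit1.omega["missense"], rel=1e-8)
        w1 = fit1.ci["missense"][1] - fit1.ci["missense"][0]
        w2 = fit2.ci["missense"][1] - fit2.ci["missense"][0]
        assert w2 < w1

    def test_alternating_mle_matches_grid_search_oracle(self):
        """Brute-force maximisation of the same Poisson likelihood on a
        two-context, two-class toy finds the alternating-update optimum."""
        counts = np.zeros((96, 2))
        L = np.zeros((96, 2))
        counts[0] = [40, 90]
        counts[1] = [25, 30]
        L[0] = [300, 800]
        L[1] = [200, 350]
        r_hat, om_hat = _alternating_mle(counts[:2], L[:2])
        ll_hat = _poisson_ll(counts[:2], r_hat[:2, None] * L[:2] * om_hat[None, :])
        best = (-np.inf, None)
        for om in np.linspace(0.5, 3.0, 601):
            # profile r in closed form for fixed omega
            r = counts[:2].sum(axis=1) / (L[:2] @ np.array([1.0, om]))
            ll = _poisson_ll(counts[:2], r[:, None] * L[:2] * np.array([1.0, om]))
            if ll > best[0]:
                best = (ll, om)
        assert om_hat[1] == pytest.approx(best[1], abs=0.005)
        assert ll_hat >= best[0] - 1e-6


class TestNeutralCalibration:
    def test_neutral_cohort_omega_near_one(self):
        rng = np.random.default_rng(123)
        genes = random_gene_set(40, rng, length_codons=(100, 200))
        weights = np.exp(rng.normal(0, 0.8, size=96))  # heterogeneous context rates
        table = sample_neutral_mutations(genes, 8000, rng, context_weights=weights, indel_per_sub=0.05)
        counts = tally_counts(table, {g.gene_id: g for g in genes})
        fit, _ = fit_global_dnds(counts, sum_opportunities(genes))
        assert fit.omega["missense"] == pytest.approx(1.0, abs=0.08)
        assert fit.omega["truncating"] == pytest.approx(1.0, abs=0.12)
        assert fit.ci["missense"][0] < 1.0 < fit.ci["missense"][1]


@pytest.fixture(scope="module")
def neutral_plus_injected():
    rng = np.random.default_rng(2024)
    genes = random_gene_set(60, rng, length_codons=(100, 200))
    table = sample_neutral_mutations(genes, 6000, rng)
    hot = [g.gene_id for g in genes[:3]]
    extra = []
    for gid in hot:
        g = next(x for x in genes if x.gene_id == gid)
        # inject missense at ~5x the neutral expectation for that gene
        base = 6000 * 3 * g.length / sum(3 * x.length for x in genes)
        n_extra = int(round(4 * base * 0.7))  # 0.7 ~ missense share
        extra.append(sample_neutral_mutations([g], n_extra, rng, impact="missense"))
    table = pd.concat([table] + extra, ignore_index=True)
    return genes, table, hot


class TestGeneTests:
    def test_injected_genes_flagged_neutral_mostly_not(self, neutral_plus_injected):
        genes, table, hot = neutral_plus_injected
        gmap = {g.gene_id: g for g in genes}
        counts_all = tally_counts(table, gmap)
        fit, rates = fit_global_dnds(counts_all, sum_opportunities(genes))
        gene_counts = {gid: tally_counts(sub, gmap) for gid, sub in table.groupby("gene_id")}
        gene_opps = {gid: build_opportunities(gmap[gid]).L for gid in gene_counts}
        res = gene_dnds_test(gene_counts, gene_opps, rates)
        flagged = set(res.loc[res["positive_selection"], "gene_id"])
        assert set(hot) <= flagged
        assert len(flagged - set(hot)) <= 2
        # neutral genes sit near omega 1
        neutral = res[~res["gene_id"].isin(hot)]
        assert abs(neutral["omega_missense"].median() - 1.0) < 0.15

    def test_exactly_neutral_gene_p_one(self):
        rates_r = np.full(96, 0.1)
        from clonalselect.dnds import NeutralRateModel

        L = np.zeros((96, 5))
        L[:, SYN] = 10
        L[:, MIS] = 30
        counts = np.zeros((96, 5))
        counts[:, MIS] = rates_r * L[:, MIS]  # exactly the neutral expectation
        res = gene_dnds_test({"g": counts}, {"g": L}, NeutralRateModel(r=rates_r))
        row = res.iloc[0]
        assert row["omega_missense"] == pytest.approx(1.0)
        assert row["p_missense"] == pytest.approx(1.0)
        assert not row["positive_selection"]

    def test_restricted_testing_properties(self, neutral_plus_injected):
        genes, table, hot = neutral_plus_injected
        gmap = {g.gene_id: g for g in genes}
        counts_all = tally_counts(table, gmap)
        _, rates = fit_global_dnds(counts_all, sum_opportunities(genes))
        gene_counts = {gid: tally_counts(sub, gmap) for gid, sub in table.groupby("gene_id")}
        gene_opps = {gid: build_opportunities(gmap[gid]).L for gid in gene_counts}
        full = gene_dnds_test(gene_counts, gene_opps, rates).set_index("gene_id")
        one = restricted_gene_test([hot[0]], gene_counts, gene_opps, rates)
        assert one["q_missense"].iloc[0] == pytest.approx(one["p_missense"].iloc[0])
        sub = restricted_gene_test(hot, gene_counts, gene_opps, rates).set_index("gene_id")
        for gid in hot:
            assert sub.loc[gid, "q_missense"] <= full.loc[gid, "q_missense"] + 1e-12
        with pytest.raises(ValueError):
            restricted_gene_test([], gene_counts, gene_opps, rates)


class TestExcessMetrics:
    def test_omega_two(self):
        frac, n = excess_metrics(2.0)
        assert frac == pytest.approx(0.5)
        assert n == 2

    @pytest.mark.parametrize("omega,expected", [(1.13, 8), (1.11, 10), (1.16, 7)])
    def test_cohort_values(self, omega, expected):
        assert excess_metrics(omega)[1] == expected

    def test_monotone_nonincreasing(self):
        oms = np.linspace(1.05, 3.0, 100)
        ns = [excess_metrics(o)[1] for o in oms]
        assert np.all(np.diff(ns) <= 0)

    def test_omega_below_one_rejected(self):
        with pytest.raises(ValueError):
            excess_metrics(0.9)


class TestDriverFraction:
    def test_split_excess_recovered(self):
        """Half the injected excess placed in unflaggable singleton genes
        drives the flagged-gene share toward one half."""
        rng = np.random.default_rng(31)
        genes = random_gene_set(40, rng, length_codons=(100, 180))
        table = sample_neutral_mutations(genes, 4000, rng)
        n_extra = 400
        concentrated = sample_neutral_mutations(genes[:2], n_extra, rng, impact="missense")
        diffuse = sample_neutral_mutations(genes[2:], n_extra, rng, impact="missense")
        table = pd.concat([table, concentrated, diffuse], ignore_index=True)
        gmap = {g.gene_id: g for g in genes}
        point, (lo, hi) = driver_fraction_identified(
            table, gmap, [g.gene_id for g in genes[:2]], n_boot=200, rng=rng
        )
        assert lo <= 0.5 <= hi or abs(point - 0.5) < 0.15

    def test_no_flagged_genes_zero(self):
        rng = np.random.default_rng(32)
        genes = random_gene_set(10, rng, length_codons=(80, 120))
        table = sample_neutral_mutations(genes, 1500, rng)
        extra = sample_neutral_mutations(genes[:1], 300, rng, impact="missense")
        table = pd.concat([table, extra], ignore_index=True)
        point, _ = driver_fraction_identified(table, {g.gene_id: g for g in genes}, [], n_boot=0)
        assert point == 0.0
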
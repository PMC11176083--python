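"""Shared fixtures: toy genes, the filter-cascade fixture table, small cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clonalselect import DriverSite, GeneModel, SimParams, generate_cohort, random_gene_set
from clonalselect.simulate import RECORD_COLUMNS


@pytest.fixture(scope="session")
def tiny_gene() -> GeneModel:
    return GeneModel("TINY", "chr1", "+", 100, "ATGGGATAA", flank5="C", flank3="G")


@pytest.fixture(scope="session")
def gene_set() -> list[GeneModel]:
    rng = np.random.default_rng(42)
    return random_gene_set(8, rng, length_codons=(60, 120))


def _base_row(**over) -> dict:
    """A record that passes every filter (depth 45, VAF 6/45 ~ 0.133)."""
    row = {
        "individual_id": "I0",
        "age": 55.0,
        "sex": "F",
        "gene_id": "G1",
        "contig": "chr1",
        "pos": 1000,
        "cds_pos": 10,
        "ref": "A",
        "alt": "G",
        "impact": "missense",
        "depth": 45,
        "alt_reads": 6,
        "vaf": 6 / 45,
        "fwd_alt": 3,
        "rev_alt": 3,
        "fwd_ref": 20,
        "rev_ref": 19,
        "bq_alt_median": 37,
        "bq_ref_median": 37,
        "pop_af": 0.0,
        "homopolymer_len": 1,
        "chrx_male": False,
        "truth_origin": "driver",
        "truth_s": 0.1,
    }
    row.update(over)
    return row


@pytest.fixture()
def cascade_fixture() -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Constructed table exercising every reason code exactly as designed.

    Nine singleton rows each violate one record-local filter; the two
    relational filters get a dedicated pair each (a recurrent high-VAF site
    and two proximal calls in one individual).  Expected: nothing kept,
    every designed row failing for exactly its designed reason.
    """
    rows = [
        _base_row(individual_id="I1", pos=1_000, bq_alt_median=30),                 # bq_diff
        _base_row(individual_id="I2", pos=2_000, depth=100, alt_reads=12,
                  vaf=0.12, fwd_alt=12, rev_alt=0, fwd_ref=44, rev_ref=44),         # strand_bias
        _base_row(individual_id="I3", pos=3_000, gene_id="G_BLACK"),                # gene_blacklist
        _base_row(individual_id="I4", pos=4_000, ref="A", alt="AT", impact="indel"),  # indel_support
        _base_row(individual_id="I5", pos=5_000, alt_reads=4, vaf=4 / 45,
                  fwd_alt=2, rev_alt=2),                                            # low_vaf_support
        _base_row(individual_id="I6", pos=6_000, alt_reads=22, vaf=22 / 45,
                  fwd_alt=11, rev_alt=11, fwd_ref=12, rev_ref=11),                  # germline_vaf
        _base_row(individual_id="I7", pos=7_000, pop_af=1e-3),                      # common_snp
        _base_row(individual_id="I8", pos=8_000, homopolymer_len=5),                # homopolymer
        _base_row(individual_id="I9", pos=9_000, depth=200, alt_reads=24,
                  vaf=0.12, fwd_alt=12, rev_alt=12, fwd_ref=88, rev_ref=88),        # high_depth
        # recurrent site: two occurrences, both VAF > 0.15
        _base_row(individual_id="I10", pos=10_000, cds_pos=77, alt_reads=9, vaf=0.2,
                  fwd_alt=5, rev_alt=4, fwd_ref=18, rev_ref=18),                    # recurrence
        _base_row(individual_id="I11", pos=10_000, cds_pos=77, alt_reads=9, vaf=0.2,
                  fwd_alt=4, rev_alt=5, fwd_ref=18, rev_ref=18),                    # recurrence
        # proximal pair in one individual, 30 bp apart
        _base_row(individual_id="I12", pos=20_000, cds_pos=20),                     # proximity
        _base_row(individual_id="I12", pos=20_030, cds_pos=50, alt="T"),            # proximity
    ]
    expected = {
        "bq_diff": [0], "strand_bias": [1], "gene_blacklist": [2],
        "indel_support": [3], "low_vaf_support": [4], "germline_vaf": [5],
        "common_snp": [6], "homopolymer": [7], "high_depth": [8],
        "recurrence": [9, 10], "proximity": [11, 12],
    }
    return pd.DataFrame(rows)[RECORD_COLUMNS], expected


@pytest.fixture(scope="session")
def small_cohort():
    """Cohort of 400 individuals, 8 genes, 2 driver sites, with ground truth."""
    rng = np.random.default_rng(7)
    genes = random_gene_set(8, rng, length_codons=(60, 120))
    drivers = []
    for g, (s, mu) in zip(genes[:2], [(0.18, 2e-6), (0.12, 5e-6)]):
        for pos in range(4, g.length):
            ref = g.cds_seq[pos - 1]
            alt = "ACGT".replace(ref, "")[0]
            from clonalselect import annotate_impact

            if annotate_impact(g, pos, ref, alt).value == "missense":
                drivers.append(DriverSite(g.gene_id, pos, ref, alt, s, mu))
                break
    params = SimParams(
        n_individuals=400, driver_sites=tuple(drivers), passenger_rate=1.0,
        germline_sites_per_indiv=2, error_sites_per_indiv=10, artifact_rate=0.3, seed=11,
    )
    records, truth, individuals = generate_cohort(params, genes)
    return params, genes, records, truth, individuals
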
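"""Post-calling quality filters for cohort somatic variant tables.

The cascade mirrors standard practice for calling somatic clones in bulk blood
sequencing: read-level artifact filters (base-quality differential, strand
bias), support thresholds (the VAF/alt-read floor derived from a cohort-wide
false-positive budget), germline removal (exact binomial test against VAF 0.5
plus a population allele-frequency cutoff), and cohort-level sanity filters
(site recurrence, homopolymers, depth, proximity).

``fp_expected`` implements the false-positive budget that motivates the VAF
floor: with B bases tested across the cohort, per-base error rate e and depth
d, a call at VAF v requires d*v error reads, so the expected number of
cohort-wide false positives is B * e^(d*v), evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterConfig",
    "FilterReason",
    "fp_expected",
    "vaf_threshold_for_budget",
    "strand_bias_test",
    "germline_binomial_test",
    "apply_filter_cascade",
]


class FilterReason(str, Enum):
    """Reason codes, in cascade order."""

    BQ_DIFF = "bq_diff"                # median base-quality difference alt vs ref > 5
    STRAND_BIAS = "strand_bias"        # chi-square P < 0.01
    GENE_BLACKLIST = "gene_blacklist"
    INDEL_SUPPORT = "indel_support"    # indel with <= 10 alt reads
    LOW_VAF_SUPPORT = "low_vaf_support"  # VAF < 0.11 or < 3 alt reads
    GERMLINE_VAF = "germline_vaf"      # binomial test does not reject VAF 0.5
    COMMON_SNP = "common_snp"          # -log10 population MAF < 3.35
    RECURRENCE = "recurrence"          # site too recurrent / high-VAF heavy
    HOMOPOLYMER = "homopolymer"        # run length >= 4 overlapping the site
    HIGH_DEPTH = "high_depth"          # depth > 150
    PROXIMITY = "proximity"            # within 50 bp of another call, same individual


@dataclass
class FilterConfig:
    """Thresholds of the cascade; defaults are the whole-blood exome settings."""

    bq_diff_max: float = 5.0
    strand_p: float = 0.01
    min_vaf: float = 0.11
    min_alt_reads: int = 3
    indel_min_alt_reads: int = 11   # indels with <= 10 alt reads removed
    germline_p: float = 1e-4
    neglog10_maf_min: float = 3.35
    recurrence_cap: int | None = None  # None: cap at the most recurrent site (no removal)
    high_vaf_fraction: float = 0.5
    vaf_cut: float = 0.15
    homopolymer_len: int = 4
    depth_max: int = 150
    proximity_bp: int = 50
    gene_blacklist: frozenset[str] = frozenset()


def fp_expected(n_individuals: float, region_bp: float, error_rate: float, depth: float, vaf: float) -> float:
    """Expected cohort-wide false-positive count (n * B) * e^(depth * vaf).

    Computed in log10 space so tiny probabilities do not underflow.
    """
    if min(n_individuals, region_bp, error_rate, depth) <= 0:
        raise ValueError("all inputs must be positive")
    log10 = np.log10(n_individuals) + np.log10(region_bp) + depth * vaf * np.log10(error_rate)
    return float(10.0 ** log10)


def vaf_threshold_for_budget(
    n_individuals: float, region_bp: float, error_rate: float, depth: float,
    budget: float = 1.0, grid_step: float = 0.01,
) -> float:
    """Smallest grid VAF in [0, 0.5] whose expected FP count falls below ``budget``."""
    if budget <= 0 or grid_step <= 0:
        raise ValueError("budget and grid_step must be positive")
    for k in range(int(np.floor(0.5 / grid_step)) + 1):
        v = k * grid_step
        if fp_expected(n_individuals, region_bp, error_rate, depth, v) < budget:
            return round(v, 10)
    raise ValueError("no VAF threshold in (0, 0.5] meets the false-positive budget")


def strand_bias_test(fwd_alt, rev_alt, fwd_ref, rev_ref):
    """Pearson chi-square (no continuity correction) on the 2x2 allele-by-strand table.

    Degenerate tables (a zero row or column margin) are untestable and return
    p = 1 so the record is kept.  Vectorised over arrays.
    """
    fa, ra, fr, rr = (np.asarray(x, dtype=float) for x in (fwd_alt, rev_alt, fwd_ref, rev_ref))
    total = fa + ra + fr + rr
    if np.any(total <= 0):
        raise ValueError("strand-bias test needs at least one read")
    alt_m, ref_m = fa + ra, fr + rr
    fwd_m, rev_m = fa + fr, ra + rr
    degenerate = (alt_m == 0) | (ref_m == 0) | (fwd_m == 0) | (rev_m == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack([alt_m * fwd_m, alt_m * rev_m, ref_m * fwd_m, ref_m * rev_m]) / total
        obs = np.stack([fa, ra, fr, rr])
        chi2 = np.where(degenerate, 0.0, np.nansum((obs - exp) ** 2 / exp, axis=0))
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(degenerate, 1.0, p)
    return p if p.ndim else float(p)


def germline_binomial_test(alt_reads, depth, p_null: float = 0.5, threshold: float = 1e-4):
    """Exact two-sided binomial test of alt_reads against VAF ``p_null``.

    Returns ``(p, germline_like)``; a record counts as somatic only when the
    test *rejects* VAF 0.5 (p < threshold).  For the symmetric null the exact
    two-sided p-value is min(1, 2*P(X <= min(k, n-k))).  Vectorised.
    """
    k = np.asarray(alt_reads, dtype=np.int64)
    n = np.asarray(depth, dtype=np.int64)
    if np.any((k < 0) | (k > n)) or np.any(n <= 0):
        raise ValueError("need 0 <= alt_reads <= depth and depth > 0")
    m = np.minimum(k, n - k)
    p = np.minimum(1.0, 2.0 * stats.binom.cdf(m, n, p_null))
    germ = p >= threshold
    if p.ndim:
        return p, germ
    return float(p), bool(germ)


def _is_indel(records: pd.DataFrame) -> np.ndarray:
    return (records["ref"].str.len() != records["alt"].str.len()).to_numpy()


def _site_key(records: pd.DataFrame) -> pd.Series:
    return (
        records["gene_id"].astype(str)
        + ":" + records["cds_pos"].astype(str)
        + ":" + records["ref"].astype(str)
        + ">" + records["alt"].astype(str)
    )


_REQUIRED = [
    "individual_id", "gene_id", "contig", "pos", "cds_pos", "ref", "alt",
    "depth", "alt_reads", "vaf", "fwd_alt", "rev_alt", "fwd_ref", "rev_ref",
    "bq_alt_median", "bq_ref_median", "pop_af", "homopolymer_len",
]


def _local_failures(records: pd.DataFrame, cfg: FilterConfig) -> dict[FilterReason, np.ndarray]:
    """Record-local predicates (everything except recurrence and proximity)."""
    fails: dict[FilterReason, np.ndarray] = {}
    fails[FilterReason.BQ_DIFF] = (
        (records["bq_ref_median"] - records["bq_alt_median"]) > cfg.bq_diff_max
    ).to_numpy()
    p_strand = strand_bias_test(
        records["fwd_alt"], records["rev_alt"], records["fwd_ref"], records["rev_ref"]
    )
    fails[FilterReason.STRAND_BIAS] = np.atleast_1d(p_strand) < cfg.strand_p
    fails[FilterReason.GENE_BLACKLIST] = records["gene_id"].isin(cfg.gene_blacklist).to_numpy()
    indel = _is_indel(records)
    fails[FilterReason.INDEL_SUPPORT] = indel & (records["alt_reads"] < cfg.indel_min_alt_reads).to_numpy()
    fails[FilterReason.LOW_VAF_SUPPORT] = (
        (records["vaf"] < cfg.min_vaf) | (records["alt_reads"] < cfg.min_alt_reads)
    ).to_numpy()
    p_germ, germ_like = germline_binomial_test(
        records["alt_reads"], records["depth"], threshold=cfg.germline_p
    )
    fails[FilterReason.GERMLINE_VAF] = np.atleast_1d(germ_like)
    pop_af = records["pop_af"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neglog = np.where(pop_af > 0, -np.log10(np.where(pop_af > 0, pop_af, 1.0)), np.inf)
    fails[FilterReason.COMMON_SNP] = neglog < cfg.neglog10_maf_min
    fails[FilterReason.HOMOPOLYMER] = (records["homopolymer_len"] >= cfg.homopolymer_len).to_numpy()
    fails[FilterReason.HIGH_DEPTH] = (records["depth"] > cfg.depth_max).to_numpy()
    return fails


def _recurrence_failures(records: pd.DataFrame, alive: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Sites (among surviving records) that are too recurrent or high-VAF heavy."""
    sub = records.loc[alive]
    if sub.empty:
        return np.zeros(len(records), dtype=bool)
    key = _site_key(sub)
    counts = key.map(key.value_counts())
    cap = cfg.recurrence_cap if cfg.recurrence_cap is not None else int(counts.max())
    high = (sub["vaf"] > cfg.vaf_cut).groupby(key).transform("mean")
    # the high-VAF-share rule targets recurrent artifact sites; a singleton
    # carries no recurrence evidence, so it needs >= 2 occurrences to fire
    bad_key = set(key[(counts > cap) | ((high > cfg.high_vaf_fraction) & (counts >= 2))])
    out = np.zeros(len(records), dtype=bool)
    if bad_key:
        out[alive] = key.isin(bad_key).to_numpy()
    return out


def _proximity_failures(records: pd.DataFrame, alive: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Both members of any same-individual pair within ``proximity_bp`` are removed."""
    sub = records.loc[alive, ["individual_id", "contig", "pos"]]
    out = np.zeros(len(records), dtype=bool)
    for _, grp in sub[sub["pos"] >= 0].groupby(["individual_id", "contig"], sort=False):
        if len(grp) < 2:
            continue
        order = grp.sort_values("pos")
        pos = order["pos"].to_numpy()
        close = np.diff(pos) <= cfg.proximity_bp
        bad = np.zeros(len(pos), dtype=bool)
        bad[:-1] |= close
        bad[1:] |= close
        out[order.index[bad]] = True
    return out


def apply_filter_cascade(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cascade; returns ``(kept, outcome_log)``.

    The outcome log has one row per input record with ``kept`` and the ordered
    comma-joined ``reasons`` (cascade order) for every failed filter.
    Record-local filters are pure predicates; the two cohort-level filters
    (recurrence, proximity) are evaluated on the surviving set and iterated to
    a fixpoint, which makes the cascade idempotent.
    """
    config = config or FilterConfig()
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise KeyError(f"records table is missing required columns: {missing}")
    n = len(records)
    if n == 0:
        log = records.loc[:, ["individual_id"]].copy() if "individual_id" in records else pd.DataFrame()
        log["kept"] = pd.Series(dtype=bool)
        log["reasons"] = pd.Series(dtype=str)
        return records.copy(), log

    records = records.reset_index(drop=True)
    fails = _local_failures(records, config)
    alive = ~np.logical_or.reduce(list(fails.values()))
    fails[FilterReason.RECURRENCE] = np.zeros(n, dtype=bool)
    fails[FilterReason.PROXIMITY] = np.zeros(n, dtype=bool)
    while True:
        rec = _recurrence_failures(records, alive, config)
        new_alive = alive & ~rec
        prox = _proximity_failures(records, new_alive, config)
        new_alive &= ~prox
        fails[FilterReason.RECURRENCE] |= rec
        fails[FilterReason.PROXIMITY] |= prox
        if new_alive.sum() == alive.sum():
            break
        alive = new_alive
    alive = new_alive

    reason_lists = []
    ordered = list(FilterReason)
    fail_matrix = np.stack([fails[r] for r in ordered], axis=1)
    for row in fail_matrix:
        reason_lists.append(",".join(r.value for r, f in zip(ordered, row) if f))
    log = pd.DataFrame(
        {
            "individual_id": records["individual_id"],
            "site": _site_key(records),
            "kept": alive,
            "reasons": reason_lists,
        }
    )
    return records.loc[alive].reset_index(drop=True), log
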
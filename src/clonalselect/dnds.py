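"""Trinucleotide-context dN/dS: global and per-gene selection inference.

Observed mutation counts n[j, c] (96 context classes j, impact classes c) are
modelled as independent Poissons,

    n[j, c] ~ Poisson( r_j * L[j, c] * omega_c ),      omega_syn = 1,

where L is the summed opportunity matrix, r_j the context-specific neutral
rate (expected mutations per available site across the cohort) and omega_c the
selection ratio per impact class.  The joint MLE has closed-form alternating
updates; profile likelihood gives 95% CIs.  Per-gene tests condition on the
cohort-wide rates and use likelihood-ratio statistics with Benjamini-Hochberg
correction across genes; a positive-selection flag requires omega > 1 at
q < 0.1.

Indels carry no trinucleotide class: their background is a single per-bp rate
estimated from non-flagged genes, with omega_ind = observed / expected.  The
"truncating" class pools nonsense substitutions with frameshift indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genes import (
    GeneModel,
    IMPACT_INDEX,
    IMPACT_ORDER,
    ImpactClass,
    N_CONTEXT_CLASSES,
    build_opportunities,
    context_class,
)

__all__ = [
    "NeutralRateModel",
    "GlobalDnds",
    "fit_global_dnds",
    "gene_dnds_test",
    "restricted_gene_test",
    "excess_metrics",
    "driver_fraction_identified",
    "tally_counts",
    "sum_opportunities",
]

# substitution classes entering the context model, in L-column order
_SUB_CLASSES = (ImpactClass.SYNONYMOUS, ImpactClass.MISSENSE, ImpactClass.NONSENSE, ImpactClass.ESSENTIAL_SPLICE)
_CHI2_95 = float(stats.chi2.ppf(0.95, df=1))


@dataclass
class NeutralRateModel:
    """Context-specific neutral rates fitted from (mostly) synonymous counts."""

    r: np.ndarray                    # shape (96,)
    indel_rate_per_bp: float = 0.0   # global background indel rate
    fitted_from_synonymous: bool = True


@dataclass
class GlobalDnds:
    """Global omega estimates with 95% profile CIs, keyed by class name."""

    omega: dict[str, float]
    ci: dict[str, tuple[float, float]]
    counts: dict[str, float]
    expected: dict[str, float]


def tally_counts(records: pd.DataFrame, genes: dict[str, GeneModel]) -> np.ndarray:
    """Tally a variant table into the (96, 5) context-by-impact count matrix.

    Substitution contexts are recomputed from the gene sequences; indels go to
    row 0 of the indel column (mirroring the opportunity-matrix convention).
    """
    counts = np.zeros((N_CONTEXT_CLASSES, len(IMPACT_ORDER)), dtype=float)
    for row in records.itertuples(index=False):
        imp = ImpactClass(row.impact)
        if imp is ImpactClass.INDEL or len(row.ref) != len(row.alt):
            counts[0, IMPACT_INDEX[ImpactClass.INDEL]] += 1
            continue
        gene = genes[row.gene_id]
        if imp is ImpactClass.ESSENTIAL_SPLICE and (row.cds_pos is None or pd.isna(row.cds_pos)):
            try:
                k = list(gene.splice_positions).index(row.pos)
            except ValueError as exc:
                raise KeyError(f"splice position {row.pos} not in gene {row.gene_id}") from exc
            from .genes import context_class_of_triplet

            ctx = context_class_of_triplet(gene.splice_contexts[k], row.alt)
        else:
            ctx = context_class(gene, int(row.cds_pos), row.alt)
        counts[ctx, IMPACT_INDEX[imp]] += 1
    return counts


def sum_opportunities(genes: list[GeneModel]) -> np.ndarray:
    """Summed (96, 5) opportunity matrix for a gene set."""
    return np.sum([build_opportunities(g).L for g in genes], axis=0)


def _alternating_mle(
    n: np.ndarray, L: np.ndarray, fixed: dict[int, float] | None = None, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray]:
    """Joint MLE of (r, omega) by closed-form alternating updates.

    ``n`` and ``L`` are (96, C) with column 0 synonymous (omega fixed at 1).
    ``fixed`` pins additional omegas (for profile likelihood).
    """
    C = n.shape[1]
    if L[:, 0].sum() == 0:
        raise ValueError("zero synonymous opportunities: model unidentifiable")
    omega = np.ones(C)
    fixed = dict(fixed or {})
    fixed[0] = 1.0
    r = np.zeros(n.shape[0])
    for _ in range(max_iter):
        denom = L @ omega
        with np.errstate(invalid="ignore", divide="ignore"):
            r_new = np.where(denom > 0, n.sum(axis=1) / denom, 0.0)
        e = r_new[:, None] * L
        esum = e.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            om_new = np.where(esum > 0, n.sum(axis=0) / esum, 0.0)
        for c, v in fixed.items():
            om_new[c] = v
        delta = np.max(np.abs(om_new - omega)) + np.max(np.abs(r_new - r))
        r, omega = r_new, om_new
        if delta < tol * (1.0 + np.max(omega)):
            break
    return r, omega


def _poisson_ll(n: np.ndarray, mean: np.ndarray) -> float:
    """Poisson log-likelihood up to the n-only constant."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(np.where(mean > 0, mean, 1.0)), 0.0)
    if np.any((mean == 0) & (n > 0)):
        return -np.inf
    return float(term.sum() - mean.sum())


def _profile_ll(n: np.ndarray, L: np.ndarray, c: int, value: float) -> float:
    r, omega = _alternating_mle(n, L, fixed={c: value})
    return _poisson_ll(n, r[:, None] * L * omega[None, :])


def _profile_ci(n: np.ndarray, L: np.ndarray, c: int, mle: float, ll_max: float) -> tuple[float, float]:
    """95% profile-likelihood CI for omega_c by bisection on the deviance."""

    def dev(v: float) -> float:
        return 2.0 * (ll_max - _profile_ll(n, L, c, v)) - _CHI2_95

    # lower bound
    if mle <= 0 or n[:, c].sum() == 0:
        lo = 0.0
    else:
        v = mle
        while v > 1e-12 and dev(v / 4) < 0:
            v /= 4
        lo = 0.0 if v <= 1e-12 else _bisect(dev, v / 4, mle)
    # upper bound
    v = max(mle, 1e-6)
    while dev(v * 4) < 0:
        v *= 4
        if v > 1e12:
            return lo, np.inf
    hi = _bisect(dev, max(mle, 1e-6), v * 4)
    return lo, hi


def _bisect(fun, lo: float, hi: float, iters: int = 60) -> float:
    flo = fun(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (fun(mid) < 0) == (flo < 0):
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6 * (1 + hi):
            break
    return 0.5 * (lo + hi)


def _garwood_ci(k: float, expected: float) -> tuple[float, float]:
    """Exact Poisson 95% CI for a count/expected ratio."""
    lo = 0.0 if k == 0 else stats.chi2.ppf(0.025, 2 * k) / 2 / expected
    hi = stats.chi2.ppf(0.975, 2 * (k + 1)) / 2 / expected
    return float(lo), float(hi)


def fit_global_dnds(
    counts: np.ndarray,
    opportunities: np.ndarray,
    indel_bp: float | None = None,
    indel_rate_per_bp: float | None = None,
) -> tuple[GlobalDnds, NeutralRateModel]:
    """Fit the global context model; returns estimates and the rate model.

    ``counts`` and ``opportunities`` are (96, 5) matrices in
    :data:`clonalselect.genes.IMPACT_ORDER` column order.  Classes reported:
    missense, nonsense, essential_splice (joint fit), all_nonsynonymous
    (missense+nonsense+splice pooled against synonymous), indel (observed over
    a per-bp background) and truncating (nonsense + frameshift-indel pool).
    ``indel_rate_per_bp`` supplies a background fitted on non-flagged genes;
    when omitted it is estimated from the table itself (global omega_ind = 1).
    """
    counts = np.asarray(counts, dtype=float)
    L = np.asarray(opportunities, dtype=float)
    sub_cols = [IMPACT_INDEX[c] for c in _SUB_CLASSES]
    n_sub, L_sub = counts[:, sub_cols], L[:, sub_cols]
    r, omega = _alternating_mle(n_sub, L_sub)
    ll_max = _poisson_ll(n_sub, r[:, None] * L_sub * omega[None, :])

    out_omega: dict[str, float] = {}
    out_ci: dict[str, tuple[float, float]] = {}
    out_counts: dict[str, float] = {}
    out_expected: dict[str, float] = {}
    for k, cls in enumerate(_SUB_CLASSES[1:], start=1):
        out_omega[cls.value] = float(omega[k])
        out_ci[cls.value] = _profile_ci(n_sub, L_sub, k, float(omega[k]), ll_max)
        out_counts[cls.value] = float(n_sub[:, k].sum())
        out_expected[cls.value] = float((r * L_sub[:, k]).sum())

    # pooled nonsynonymous wall: one omega for missense+nonsense+splice
    n_pool = np.stack([n_sub[:, 0], n_sub[:, 1:].sum(axis=1)], axis=1)
    L_pool = np.stack([L_sub[:, 0], L_sub[:, 1:].sum(axis=1)], axis=1)
    r_p, om_p = _alternating_mle(n_pool, L_pool)
    ll_p = _poisson_ll(n_pool, r_p[:, None] * L_pool * om_p[None, :])
    out_omega["all_nonsynonymous"] = float(om_p[1])
    out_ci["all_nonsynonymous"] = _profile_ci(n_pool, L_pool, 1, float(om_p[1]), ll_p)
    out_counts["all_nonsynonymous"] = float(n_pool[:, 1].sum())
    out_expected["all_nonsynonymous"] = float((r_p * L_pool[:, 1]).sum())

    ind_col = IMPACT_INDEX[ImpactClass.INDEL]
    n_ind = float(counts[:, ind_col].sum())
    bp = float(indel_bp if indel_bp is not None else L[0, ind_col])
    if indel_rate_per_bp is None:
        indel_rate_per_bp = n_ind / bp if bp > 0 else 0.0
    e_ind = indel_rate_per_bp * bp
    out_omega["indel"] = n_ind / e_ind if e_ind > 0 else np.nan
    out_ci["indel"] = _garwood_ci(n_ind, e_ind) if e_ind > 0 else (np.nan, np.nan)
    out_counts["indel"], out_expected["indel"] = n_ind, e_ind

    # truncating: nonsense + frameshift indels (indel calls assumed frameshift-
    # classified upstream; callers may pass a frameshift-only count matrix)
    n_tr = out_counts["nonsense"] + n_ind
    e_tr = out_expected["nonsense"] + e_ind
    out_omega["truncating"] = n_tr / e_tr if e_tr > 0 else np.nan
    out_ci["truncating"] = _garwood_ci(n_tr, e_tr) if e_tr > 0 else (np.nan, np.nan)
    out_counts["truncating"], out_expected["truncating"] = n_tr, e_tr

    fit = GlobalDnds(out_omega, out_ci, out_counts, out_expected)
    model = NeutralRateModel(r=r, indel_rate_per_bp=float(indel_rate_per_bp))
    return fit, model


def _gene_class_stats(n: float, e: float) -> tuple[float, float, float]:
    """(omega, deviance vs omega=1, two-sided p) for one gene-class Poisson cell."""
    if e <= 0:
        return np.nan, 0.0, 1.0
    om = n / e
    if n == 0:
        dev = 2.0 * e
    else:
        dev = 2.0 * (n * np.log(n / e) - (n - e))
    return om, dev, float(stats.chi2.sf(dev, df=1))


def gene_dnds_test(
    gene_counts: dict[str, np.ndarray],
    gene_opportunities: dict[str, np.ndarray],
    rates: NeutralRateModel,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-gene selection tests conditioned on cohort-wide context rates.

    ``gene_counts``/``gene_opportunities`` map gene_id to (96, 5) matrices.
    Returns one row per gene with per-class omega/p/q, a combined test (sum of
    class deviances, df = number of tested classes) and the positive-selection
    flag (any omega > 1 with q below ``q_threshold``).
    """
    if not gene_counts:
        raise ValueError("no genes supplied")
    classes = ["missense", "nonsense", "essential_splice", "indel"]
    cols = {
        "missense": IMPACT_INDEX[ImpactClass.MISSENSE],
        "nonsense": IMPACT_INDEX[ImpactClass.NONSENSE],
        "essential_splice": IMPACT_INDEX[ImpactClass.ESSENTIAL_SPLICE],
    }
    rows = []
    for gid, n in gene_counts.items():
        if gid not in gene_opportunities:
            raise KeyError(f"gene {gid} missing from the opportunity set")
        L = np.asarray(gene_opportunities[gid], dtype=float)
        n = np.asarray(n, dtype=float)
        if L[:, : IMPACT_INDEX[ImpactClass.ESSENTIAL_SPLICE] + 1].sum() == 0:
            raise ValueError(f"gene {gid} has no substitution opportunities")
        row: dict = {"gene_id": gid}
        dev_sum, n_classes = 0.0, 0
        any_pos = {}
        for cls in classes:
            if cls == "indel":
                bp = float(L[0, IMPACT_INDEX[ImpactClass.INDEL]])
                e = rates.indel_rate_per_bp * bp
                obs = float(n[:, IMPACT_INDEX[ImpactClass.INDEL]].sum())
            else:
                c = cols[cls]
                e = float((rates.r * L[:, c]).sum())
                obs = float(n[:, c].sum())
            om, dev, p = _gene_class_stats(obs, e)
            row[f"n_{cls}"], row[f"omega_{cls}"], row[f"p_{cls}"] = obs, om, p
            if e > 0:
                dev_sum += dev
                n_classes += 1
                any_pos[cls] = om > 1
        row["p_combined"] = float(stats.chi2.sf(dev_sum, df=max(n_classes, 1)))
        row["_any_positive"] = any_pos
        rows.append(row)
    df = pd.DataFrame(rows)
    for cls in classes:
        p = df[f"p_{cls}"].fillna(1.0)
        df[f"q_{cls}"] = multipletests(p, method="fdr_bh")[1]
    df["q_combined"] = multipletests(df["p_combined"], method="fdr_bh")[1]
    flags = []
    for _, row in df.iterrows():
        pos = row["_any_positive"]
        flag = any(
            pos.get(cls, False) and row[f"q_{cls}"] < q_threshold for cls in classes
        )
        flags.append(flag)
    df["positive_selection"] = flags
    return df.drop(columns="_any_positive")


def restricted_gene_test(
    gene_list: list[str],
    gene_counts: dict[str, np.ndarray],
    gene_opportunities: dict[str, np.ndarray],
    rates: NeutralRateModel,
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Identical statistics with BH correction over ``gene_list`` only."""
    if not gene_list:
        raise ValueError("gene_list must not be empty")
    missing = [g for g in gene_list if g not in gene_counts]
    if missing:
        raise KeyError(f"genes absent from the count set: {missing}")
    sub_counts = {g: gene_counts[g] for g in gene_list}
    sub_opps = {g: gene_opportunities[g] for g in gene_list}
    return gene_dnds_test(sub_counts, sub_opps, rates, q_threshold)


def excess_metrics(omega: float) -> tuple[float, int]:
    """Convert an omega into (excess fraction, one-in-n driver statement).

    excess fraction = (omega-1)/omega is the share of observed nonsynonymous
    mutations in excess of the neutral expectation; one_in_n =
    floor(omega/(omega-1)) says one in every n observed mutations is a driver.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    frac = (omega - 1.0) / omega
    if omega <= 1.0:
        raise ValueError("one_in_n undefined for omega <= 1")
    return frac, int(np.floor(omega / (omega - 1.0)))


def excess_fraction(omega: float) -> float:
    """(omega-1)/omega, defined (possibly <= 0) for any positive omega."""
    if omega <= 0:
        raise ValueError("omega must be positive")
    return (omega - 1.0) / omega


def driver_fraction_identified(
    records: pd.DataFrame,
    genes: dict[str, GeneModel],
    flagged_genes: list[str],
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Share of the exome-wide excess attributable to flagged genes.

    numerator = sum over flagged genes and nonsynonymous classes of
    n_gc*(omega_gc-1)/omega_gc; denominator = n_ns*(omega_all-1)/omega_all
    from the pooled global fit.  CI by bootstrap over individuals.
    """
    rng = rng or np.random.default_rng(0)
    gene_models = list(genes.values())
    opp_total = sum_opportunities(gene_models)
    gene_opps = {g.gene_id: build_opportunities(g).L for g in gene_models}
    flagged = [g for g in flagged_genes if g in gene_opps]

    subs = records[records["ref"].str.len() == records["alt"].str.len()].reset_index(drop=True)
    # per-record classification, computed once
    ctx = np.empty(len(subs), dtype=np.int64)
    col = np.empty(len(subs), dtype=np.int64)
    for idx, row in enumerate(subs.itertuples(index=False)):
        col[idx] = IMPACT_INDEX[ImpactClass(row.impact)]
        ctx[idx] = context_class(genes[row.gene_id], int(row.cds_pos), row.alt)
    indiv_codes, individuals = pd.factorize(subs["individual_id"])
    gene_ids = subs["gene_id"].to_numpy()
    n_indiv = len(individuals)

    nonsyn_cols = [IMPACT_INDEX[c] for c in (ImpactClass.MISSENSE, ImpactClass.NONSENSE, ImpactClass.ESSENTIAL_SPLICE)]
    syn_col = IMPACT_INDEX[ImpactClass.SYNONYMOUS]
    L_pool = np.stack([opp_total[:, syn_col], opp_total[:, nonsyn_cols].sum(axis=1)], axis=1).astype(float)
    L_gene_ns = {g: float(gene_opps[g][:, nonsyn_cols].sum()) for g in flagged}
    L_gene_ns_ctx = {g: gene_opps[g][:, nonsyn_cols].sum(axis=1).astype(float) for g in flagged}

    def proportion(weights: np.ndarray) -> float:
        w = weights[indiv_codes]
        n_pool = np.zeros((N_CONTEXT_CLASSES, 2))
        np.add.at(n_pool[:, 0], ctx[col == syn_col], w[col == syn_col])
        ns_mask = np.isin(col, nonsyn_cols)
        np.add.at(n_pool[:, 1], ctx[ns_mask], w[ns_mask])
        r_p, om_p = _alternating_mle(n_pool, L_pool)
        om_all = om_p[1]
        total_excess = n_pool[:, 1].sum() * (om_all - 1.0) / om_all if om_all > 0 else 0.0
        if total_excess <= 0:
            raise ValueError("exome-wide excess is not positive; proportion undefined")
        num = 0.0
        for gid in flagged:
            sel = ns_mask & (gene_ids == gid)
            n_g = float(w[sel].sum())
            e_g = float((r_p * L_gene_ns_ctx[gid]).sum())
            if e_g > 0 and n_g > e_g:
                num += n_g * (n_g - e_g) / n_g  # = n_g*(om-1)/om with om = n_g/e_g
        return num / total_excess

    point = proportion(np.ones(n_indiv))
    if n_boot <= 0:
        return point, (point, point)
    boots = []
    for _ in range(n_boot):
        w = rng.multinomial(n_indiv, np.full(n_indiv, 1.0 / n_indiv)).astype(float)
        try:
            boots.append(proportion(w))
        except ValueError:
            continue
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan)
    return point, (float(lo), float(hi))
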
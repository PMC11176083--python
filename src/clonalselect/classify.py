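"""Per-individual clonal-hematopoiesis (CH) status and age-trend statistics.

Genes that can confer CH status fall in three disjoint categories:
classical fitness-inferred (canonical CH genes confirmed under positive
selection), classical non-fitness-inferred (canonical but not under selection
in this cohort) and new fitness-inferred (under selection but outside the
canonical set).  A qualifying variant must pass the clone-size rule
(VAF > 0.1), survive the VAF > 0.5 germline removal (with the chrX-in-males
exception) and match the gene's allowed impact classes.

"Driverless" CH marks individuals whose somatic mutation burden is at or above
the cohort's 95th percentile while carrying no driver variant above VAF 0.02
and no autosomal mosaic CNV: a clonal expansion inferred purely from
hitch-hiking passengers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .genes import ImpactClass

__all__ = [
    "GeneCategoryConfig",
    "assign_ch_status",
    "driverless_status",
    "age_trend",
    "incidence_by_age",
]

_ALL_IMPACTS = frozenset(i.value for i in ImpactClass if i is not ImpactClass.SYNONYMOUS)


@dataclass
class GeneCategoryConfig:
    """Gene categories for CH status.

    ``qualifying_impacts`` restricts, per gene, which impact classes confer
    status (e.g. a gene under selection only for missense variation); genes
    not listed accept any nonsynonymous class.
    """

    canonical_genes: frozenset[str]
    fitness_inferred: frozenset[str]
    qualifying_impacts: dict[str, frozenset[str]] = field(default_factory=dict)
    vaf_qualifying: float = 0.1
    vaf_germline_cut: float = 0.5

    @property
    def classical_fi(self) -> frozenset[str]:
        return self.canonical_genes & self.fitness_inferred

    @property
    def classical_nonfi(self) -> frozenset[str]:
        return self.canonical_genes - self.fitness_inferred

    @property
    def new_fi(self) -> frozenset[str]:
        return self.fitness_inferred - self.canonical_genes

    def allowed(self, gene_id: str) -> frozenset[str]:
        return self.qualifying_impacts.get(gene_id, _ALL_IMPACTS)


def assign_ch_status(
    records: pd.DataFrame, individuals: pd.DataFrame, config: GeneCategoryConfig
) -> pd.DataFrame:
    """Per-individual CH category flags, max driver VAF and mutation count.

    Applies, in order: the VAF > 0.5 removal (kept when ``chrx_male``), the
    qualifying clone-size threshold (VAF > 0.1) and per-gene impact
    restrictions.  Genes absent from every category are counted in an
    ``unclassified`` bucket with a warning.
    """
    known = config.canonical_genes | config.fitness_inferred
    unknown = set(records["gene_id"]) - known
    if unknown:
        warnings.warn(f"{len(unknown)} gene(s) not in any CH category: left unclassified", stacklevel=2)

    recs = records[(records["vaf"] <= config.vaf_germline_cut) | records["chrx_male"].astype(bool)]
    qualifying = recs[recs["vaf"] > config.vaf_qualifying]

    def flag_for(genes: frozenset[str]) -> pd.Series:
        sub = qualifying[qualifying["gene_id"].isin(genes)]
        ok = [
            row.impact in config.allowed(row.gene_id)
            for row in sub.itertuples(index=False)
        ]
        return sub[ok] if len(sub) else sub

    out = individuals[["individual_id", "age"]].copy()
    for name, genes in (
        ("classical_fi", config.classical_fi),
        ("classical_nonfi", config.classical_nonfi),
        ("new_fi", config.new_fi),
    ):
        hits = flag_for(genes)
        out[name] = out["individual_id"].isin(set(hits["individual_id"])).to_numpy()
    driver_recs = recs[recs["gene_id"].isin(known)]
    max_vaf = driver_recs.groupby("individual_id")["vaf"].max()
    out["max_driver_vaf"] = out["individual_id"].map(max_vaf).fillna(0.0)
    burden = recs.groupby("individual_id").size()
    out["somatic_mutation_count"] = out["individual_id"].map(burden).fillna(0).astype(int)
    out["unclassified"] = out["individual_id"].isin(
        set(qualifying[qualifying["gene_id"].isin(unknown)]["individual_id"])
    )
    return out


def driverless_status(
    status: pd.DataFrame,
    cnv_flags: pd.Series | np.ndarray,
    percentile: float = 95.0,
    driver_vaf_cut: float = 0.02,
    pinned_count: int | None = None,
) -> pd.Series:
    """Driverless-CH flag per individual.

    True when the somatic mutation count reaches the cohort ``percentile``
    count (or ``pinned_count`` when given), there is no driver variant above
    ``driver_vaf_cut`` and no autosomal CNV flag.
    """
    counts = status["somatic_mutation_count"].to_numpy()
    if pinned_count is not None:
        threshold = pinned_count
    else:
        # discrete quantile: the smallest observed count at or above the
        # percentile rank, so the threshold is always an attained burden
        threshold = int(np.percentile(counts, percentile, method="higher"))
    threshold = max(threshold, 1)
    cnv = np.asarray(cnv_flags, dtype=bool)
    flag = (counts >= threshold) & (status["max_driver_vaf"].to_numpy() <= driver_vaf_cut) & ~cnv
    return pd.Series(flag, index=status.index, name="driverless")


def age_trend(y, ages) -> tuple[float, float, float]:
    """OLS of an indicator or log(VAF) series on age: (slope, intercept, p).

    ``y`` may be boolean incidence indicators or continuous values; requires
    at least three distinct ages.
    """
    y = np.asarray(y, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if y.shape != ages.shape or y.size < 3:
        raise ValueError("need matched y/ages with at least 3 points")
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages for a trend")
    X = sm.add_constant(ages)
    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.params[0]), float(res.pvalues[1])


def incidence_by_age(status: pd.DataFrame, column: str, bin_years: float = 5.0) -> pd.DataFrame:
    """Binned incidence of a CH category versus age (for reporting/plotting)."""
    bins = np.arange(status["age"].min(), status["age"].max() + bin_years, bin_years)
    grp = status.groupby(pd.cut(status["age"], bins, include_lowest=True), observed=True)[column]
    out = grp.agg(["mean", "size"]).reset_index()
    out.columns = ["age_bin", "incidence", "n"]
    return out
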
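"""Synthetic cohort generator under the exponential clone-growth model.

The generative model: haematopoietic stem cells (HSCs) acquire driver mutations
at per-site rate mu per cell per year; a driver clone with selection
coefficient s (excess symmetric self-renewal per year) grows so that the
population of detectable clones at age t has VAF density

    rho(f) = (Ntau * mu / f) * exp(-f / phi(t)),    phi(t) = (e^{st} - 1) / (2 Ntau s)

where N is the HSC count, tau the years between symmetric divisions and
f = cells / 2N the variant allele frequency (diploid denominator).  The s -> 0
limit of phi is the neutral drift scale t / (2 Ntau).

The simulator draws clone counts Poisson(lambda) with
lambda = integral of rho over (f_min, 0.5], clone VAFs by inverse CDF, then
pushes every record (drivers, hitch-hiking passengers, germline SNPs,
sequencing errors, strand-biased artifacts) through a read-level sampler with
negative-binomial depth and per-base error.  A small forward birth--death
simulation is provided as an independent oracle for the clone-size density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from .genes import (
    GeneModel,
    ImpactClass,
    annotate_impact,
    enumerate_substitutions,
    homopolymer_length,
)

__all__ = [
    "DriverSite",
    "SimParams",
    "CohortTruth",
    "phi",
    "clone_density",
    "expected_detectable",
    "sample_clone_vafs",
    "forward_birth_death",
    "simulate_reads",
    "generate_cohort",
    "simulate_site_observations",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "individual_id", "age", "sex", "gene_id", "contig", "pos", "cds_pos",
    "ref", "alt", "impact", "depth", "alt_reads", "vaf",
    "fwd_alt", "rev_alt", "fwd_ref", "rev_ref",
    "bq_alt_median", "bq_ref_median", "pop_af", "homopolymer_len",
    "chrx_male", "truth_origin", "truth_s",
]


@dataclass(frozen=True)
class DriverSite:
    """A recurrently mutated driver site with its fitness parameters."""

    gene_id: str
    cds_pos: int
    ref: str
    alt: str
    s: float       # selection coefficient, per year
    mu: float      # site mutation rate, per cell per year

    def key(self) -> tuple:
        return (self.gene_id, self.cds_pos, self.ref, self.alt)


@dataclass
class SimParams:
    """Study conditions for the synthetic cohort.

    Defaults follow the whole-blood exome setting the analysis assumes:
    individuals aged 40-70, Ntau = 140,000 cell-years, sequencing at median
    depth 45 with error rate 1/1,000, germline SNPs near VAF 0.5 and
    strand-biased artifacts injected at a low per-individual rate.
    """

    n_individuals: int = 1000
    age_low: float = 40.0
    age_high: float = 70.0
    ntau: float = 140_000.0
    driver_sites: tuple[DriverSite, ...] = ()
    passenger_rate: float = 1.0          # expected passengers hitch-hiking per clone
    passenger_indel_fraction: float = 0.1
    passenger_subclonality: float = 1.0  # passenger VAF = clone VAF * this factor
    germline_sites_per_indiv: int = 2
    depth_median: int = 45
    depth_dispersion: float = 20.0       # negative-binomial size parameter
    error_rate: float = 0.001
    error_sites_per_indiv: int = 20      # candidate error loci examined per individual
    f_min: float = 0.02                  # detection limit for simulated clones
    artifact_rate: float = 0.3           # strand-biased artifact calls per individual
    cnv_rate: float = 0.01               # fraction of individuals with a mosaic CNV flag
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ntau <= 0:
            raise ValueError("ntau must be positive")
        if not 0 < self.f_min < 0.5:
            raise ValueError("f_min must lie in (0, 0.5)")
        for d in self.driver_sites:
            if d.s <= 0 or d.mu <= 0:
                raise ValueError(f"driver {d.key()}: s and mu must be positive")


@dataclass
class CohortTruth:
    """Ground truth: per-individual clone list and per-site parameters."""

    clones: pd.DataFrame       # individual_id, gene_id, cds_pos, ref, alt, true_vaf, founding_age
    site_params: pd.DataFrame  # gene_id, cds_pos, ref, alt, s, mu


def phi(s: float, t, ntau: float):
    """Characteristic VAF scale of the clone-size distribution at age ``t``.

    phi = (e^{st} - 1) / (2 Ntau s) for s > 0, continuous limit t / (2 Ntau)
    at s = 0.  Strictly increasing in both s and t.
    """
    if s < 0:
        raise ValueError("selection coefficient must be nonnegative")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("age must be positive")
    if s == 0:
        out = t / (2.0 * ntau)
    else:
        out = np.expm1(s * t) / (2.0 * ntau * s)
    return out if out.ndim else float(out)


def clone_density(f, s: float, mu: float, t: float, ntau: float):
    """Density per unit VAF of detectable clones: (Ntau mu / f) exp(-f/phi)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("VAF must be positive")
    out = ntau * mu / f * np.exp(-f / phi(s, t, ntau))
    return out if out.ndim else float(out)


def expected_detectable(s: float, mu: float, t, ntau: float, f_min: float) -> float:
    """Expected clone count lambda = integral of rho over (f_min, 0.5].

    Closed form Ntau*mu*(E1(f_min/phi) - E1(0.5/phi)) with E1 the exponential
    integral; diverges logarithmically as f_min -> 0.
    """
    if np.any(np.asarray(f_min) <= 0):
        raise ValueError("f_min must be positive (integral diverges at 0)")
    if f_min >= 0.5:
        return 0.0 * np.asarray(t, dtype=float) if np.ndim(t) else 0.0
    ph = phi(s, t, ntau)
    out = ntau * mu * (special.exp1(f_min / ph) - special.exp1(0.5 / ph))
    return out if np.ndim(out) else float(out)


def _inverse_cdf_grid(s: float, t: float, ntau: float, f_min: float, n_grid: int = 4096):
    """Log-f grid and normalised CDF of the truncated clone-VAF density."""
    ph = phi(s, t, ntau)
    f = np.geomspace(f_min, 0.5, n_grid)
    e1 = special.exp1(f / ph)
    cdf = (e1[0] - e1) / (e1[0] - e1[-1])
    return f, cdf


def sample_clone_vafs(
    s: float, mu: float, t: float, ntau: float, f_min: float, rng: np.random.Generator
) -> np.ndarray:
    """Clone VAFs for one individual at one site: Poisson count, inverse-CDF draws."""
    lam = expected_detectable(s, mu, t, ntau, f_min)
    if not np.isfinite(lam) or lam > 1e6:
        raise ValueError(f"unphysical expected clone count {lam}")
    n = rng.poisson(lam)
    if n == 0:
        return np.empty(0)
    f, cdf = _inverse_cdf_grid(s, t, ntau, f_min)
    return np.interp(rng.random(n), cdf, f)


def forward_birth_death(
    N: int, s: float, tau: float, t: float, mu: float, rng: np.random.Generator,
    steps_per_division: int = 10,
) -> np.ndarray:
    """Forward birth--death oracle: mutant clone cell counts at age ``t``.

    Each mutant cell divides symmetrically (two mutant daughters) at rate
    1/tau per year and is lost (symmetric differentiation) at rate
    (1 - s*tau)/tau, i.e. the birth--death asymmetry per division is s*tau;
    wild-type turnover is balanced.  New mutant cells arise at rate N*mu per
    year.  Time is discretised in sub-steps of tau/steps_per_division.
    Desk-scale oracle only (N <= 10,000).
    """
    if N > 10_000:
        raise ValueError("forward oracle is desk-scale only (N <= 10,000)")
    if s * tau >= 1:
        raise ValueError("s*tau >= 1: death rate would be negative")
    dt = tau / steps_per_division
    p_birth = dt / tau
    p_death = (1.0 - s * tau) * dt / tau
    clones: list[int] = []
    n_steps = int(round(t / dt))
    warned = False
    for _ in range(n_steps):
        if clones:
            sizes = np.array(clones)
            births = rng.binomial(sizes, p_birth)
            deaths = rng.binomial(sizes, p_death)
            sizes = sizes + births - deaths
            clones = [int(n) for n in sizes if n > 0]
            if not warned and any(n > N for n in clones):
                import warnings

                warnings.warn("a mutant clone exceeded N cells (fixation regime)", stacklevel=2)
                warned = True
        new = rng.binomial(N, min(mu * dt, 1.0))
        clones.extend([1] * new)
    return np.array(sorted(clones, reverse=True), dtype=np.int64)


def _solve_depth_params(depth_median: int, dispersion: float) -> tuple[float, float]:
    """Negative-binomial (n, p) whose 1-shifted draw has the requested median."""
    r = dispersion
    # search the mean so that median(1 + NB) == depth_median
    lo, hi = max(depth_median - 15, 1.0), depth_median + 15.0
    for _ in range(60):
        mean = 0.5 * (lo + hi)
        p = r / (r + mean)
        med = 1 + stats.nbinom.ppf(0.5, r, p)
        if med < depth_median:
            lo = mean
        else:
            hi = mean
    mean = 0.5 * (lo + hi)
    return r, r / (r + mean)


def simulate_reads(
    vaf, depth_median: int, error_rate: float, rng: np.random.Generator,
    dispersion: float = 20.0, artifact=False,
):
    """Read-level summaries for an array of sites.

    depth ~ 1 + NB tuned so the distribution's median equals ``depth_median``;
    alt_reads ~ Binomial(depth, vaf(1-e) + (1-vaf)e/3); strand split
    Binomial(alt_reads, 1/2) except artifacts, which put every alt read on one
    strand; alt base qualities sit 8 Phred below reference for artifacts and
    match it otherwise.
    """
    vaf = np.atleast_1d(np.asarray(vaf, dtype=float))
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("vaf outside [0, 1]")
    n = vaf.size
    r, p = _solve_depth_params(depth_median, dispersion)
    depth = 1 + rng.negative_binomial(r, p, size=n)
    p_alt = vaf * (1 - error_rate) + (1 - vaf) * error_rate / 3.0
    alt = rng.binomial(depth, p_alt)
    artifact = np.broadcast_to(np.asarray(artifact, dtype=bool), (n,))
    fwd_alt = np.where(
        artifact,
        np.where(rng.random(n) < 0.5, alt, 0),
        rng.binomial(alt, 0.5),
    )
    rev_alt = alt - fwd_alt
    ref_reads = depth - alt
    fwd_ref = rng.binomial(ref_reads, 0.5)
    rev_ref = ref_reads - fwd_ref
    bq_ref = np.clip(np.rint(rng.normal(37.0, 1.0, size=n)), 2, 41).astype(int)
    bq_alt = np.where(artifact, bq_ref - 8, bq_ref + rng.integers(-1, 2, size=n))
    return depth, alt, fwd_alt, rev_alt, fwd_ref, rev_ref, bq_alt, bq_ref


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in RECORD_COLUMNS})


def generate_cohort(params: SimParams, genes: list[GeneModel]) -> tuple[pd.DataFrame, CohortTruth, pd.DataFrame]:
    """Simulate a cohort variant-call table with ground truth.

    Returns ``(records, truth, individuals)``: one call row per detected
    variant, the :class:`CohortTruth`, and a per-individual frame
    (individual_id, age, sex, cnv_flag).  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    gene_by_id = {g.gene_id: g for g in genes}
    for d in params.driver_sites:
        if d.gene_id not in gene_by_id:
            raise KeyError(f"driver gene {d.gene_id} not in the gene set")
        g = gene_by_id[d.gene_id]
        if g.cds_seq[d.cds_pos - 1] != d.ref:
            raise ValueError(f"driver {d.key()}: ref does not match the gene sequence")

    n = params.n_individuals
    ages = rng.uniform(params.age_low, params.age_high, size=n)
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    cnv = rng.random(n) < params.cnv_rate
    individuals = pd.DataFrame(
        {"individual_id": [f"I{i:06d}" for i in range(n)], "age": ages, "sex": sexes, "cnv_flag": cnv}
    )

    # flat site pool for passengers / errors / germline / artifacts
    all_subs = (
        pd.concat(
            [enumerate_substitutions(g).assign(gene_id=g.gene_id, contig=g.contig) for g in genes],
            ignore_index=True,
        )
        .dropna(subset=["cds_pos"])
        .reset_index(drop=True)
    )
    driver_keys = {d.key() for d in params.driver_sites}

    rows: list[dict] = []
    clone_rows: list[dict] = []

    def add_record(i: int, gene: GeneModel, cds_pos, ref, alt, impact, true_vaf, origin, truth_s, pop_af=0.0):
        hp = homopolymer_length(gene, int(cds_pos)) if cds_pos is not None else 1
        rows.append(
            {
                "individual_id": individuals.individual_id[i],
                "age": ages[i],
                "sex": sexes[i],
                "gene_id": gene.gene_id,
                "contig": gene.contig,
                "pos": gene.genomic_pos(int(cds_pos)) if cds_pos is not None else -1,
                "cds_pos": cds_pos,
                "ref": ref,
                "alt": alt,
                "impact": impact,
                "_true_vaf": true_vaf,
                "pop_af": pop_af,
                "homopolymer_len": hp,
                "chrx_male": gene.contig == "chrX" and sexes[i] == "M",
                "truth_origin": origin,
                "truth_s": truth_s,
            }
        )

    for i in range(n):
        t = ages[i]
        # driver clones + hitch-hiking passengers
        for d in params.driver_sites:
            vafs = sample_clone_vafs(d.s, d.mu, t, params.ntau, params.f_min, rng)
            if vafs.size == 0:
                continue
            gene = gene_by_id[d.gene_id]
            for v in vafs:
                clone_rows.append(
                    {
                        "individual_id": individuals.individual_id[i],
                        "gene_id": d.gene_id,
                        "cds_pos": d.cds_pos,
                        "ref": d.ref,
                        "alt": d.alt,
                        "true_vaf": v,
                        "founding_age": t - np.log1p(2 * params.ntau * d.s * v) / d.s,
                    }
                )
            vmax = float(vafs.max())  # bulk calling reports one VAF per site
            impact = annotate_impact(gene, d.cds_pos, d.ref, d.alt).value
            add_record(i, gene, d.cds_pos, d.ref, d.alt, impact, vmax, "driver", d.s)
            n_pass = rng.poisson(params.passenger_rate * vafs.size)
            for _ in range(n_pass):
                pv = vmax * params.passenger_subclonality
                if rng.random() < params.passenger_indel_fraction:
                    g2 = genes[rng.integers(len(genes))]
                    cp = int(rng.integers(1, g2.length + 1))
                    ref2 = g2.cds_seq[cp - 1]
                    dlen = int(rng.integers(1, 4))
                    add_record(i, g2, cp, ref2, ref2 + "A" * dlen, ImpactClass.INDEL.value, pv, "passenger", d.s)
                else:
                    row = all_subs.iloc[int(rng.integers(len(all_subs)))]
                    g2 = gene_by_id[row.gene_id]
                    if (row.gene_id, int(row.cds_pos), row.ref, row.alt) in driver_keys:
                        continue
                    add_record(i, g2, int(row.cds_pos), row.ref, row.alt, row.impact, pv, "passenger", d.s)
        # germline heterozygous SNPs near VAF 0.5
        for _ in range(params.germline_sites_per_indiv):
            row = all_subs.iloc[int(rng.integers(len(all_subs)))]
            g2 = gene_by_id[row.gene_id]
            true_vaf = 1.0 if (g2.contig == "chrX" and sexes[i] == "M") else rng.beta(200, 200)
            pop_af = 10 ** rng.uniform(-3.3, -0.4)  # common SNP, above the MAF cutoff
            add_record(i, g2, int(row.cds_pos), row.ref, row.alt, row.impact, true_vaf, "germline", 0.0, pop_af)
        # sequencing-error candidates
        if params.error_rate > 0 and params.error_sites_per_indiv > 0:
            idx = rng.integers(len(all_subs), size=params.error_sites_per_indiv)
            for j in idx:
                row = all_subs.iloc[int(j)]
                add_record(i, gene_by_id[row.gene_id], int(row.cds_pos), row.ref, row.alt, row.impact, 0.0, "seq_error", 0.0)
        # strand-biased artifacts
        for _ in range(rng.poisson(params.artifact_rate)):
            row = all_subs.iloc[int(rng.integers(len(all_subs)))]
            add_record(i, gene_by_id[row.gene_id], int(row.cds_pos), row.ref, row.alt, row.impact,
                       rng.uniform(0.05, 0.3), "artifact", 0.0)

    truth = CohortTruth(
        clones=pd.DataFrame(clone_rows, columns=["individual_id", "gene_id", "cds_pos", "ref", "alt", "true_vaf", "founding_age"]),
        site_params=pd.DataFrame(
            [{"gene_id": d.gene_id, "cds_pos": d.cds_pos, "ref": d.ref, "alt": d.alt, "s": d.s, "mu": d.mu} for d in params.driver_sites]
        ),
    )
    if not rows:
        return _empty_records(), truth, individuals

    records = pd.DataFrame(rows)
    artifact_mask = (records["truth_origin"] == "artifact").to_numpy()
    depth, alt, fa, ra, fr, rr, bqa, bqr = simulate_reads(
        records["_true_vaf"].to_numpy(), params.depth_median, params.error_rate, rng,
        dispersion=params.depth_dispersion, artifact=artifact_mask,
    )
    records["depth"] = depth
    records["alt_reads"] = alt
    records["vaf"] = alt / depth
    records["fwd_alt"], records["rev_alt"] = fa, ra
    records["fwd_ref"], records["rev_ref"] = fr, rr
    records["bq_alt_median"], records["bq_ref_median"] = bqa, bqr
    records = records[records["alt_reads"] > 0].drop(columns="_true_vaf").reset_index(drop=True)
    return records[RECORD_COLUMNS], truth, individuals


def sample_neutral_mutations(
    genes: list[GeneModel],
    n_mutations: int,
    rng: np.random.Generator,
    context_weights: np.ndarray | None = None,
    indel_per_sub: float = 0.0,
    impact: str | None = None,
) -> pd.DataFrame:
    """Draw coding mutations with no selection: substitution probability is
    proportional to the trinucleotide-context weight of each possible change,
    identically across impact classes (the null of the dN/dS model).

    ``context_weights`` is a 96-vector of relative rates (default: all equal).
    ``indel_per_sub`` appends Poisson(n*rate) frameshift-style indels placed
    uniformly per bp.  ``impact`` optionally restricts the sampled class (used
    to inject selection by oversampling one class).
    """
    pool = pd.concat(
        [enumerate_substitutions(g).assign(gene_id=g.gene_id, contig=g.contig) for g in genes],
        ignore_index=True,
    )
    pool = pool.dropna(subset=["cds_pos"]).reset_index(drop=True)
    if impact is not None:
        pool = pool[pool["impact"] == impact].reset_index(drop=True)
    w = np.ones(96) if context_weights is None else np.asarray(context_weights, dtype=float)
    probs = w[pool["context"].to_numpy()]
    probs = probs / probs.sum()
    idx = rng.choice(len(pool), size=n_mutations, p=probs)
    out = pool.iloc[idx].reset_index(drop=True).copy()
    out["individual_id"] = [f"I{j:06d}" for j in rng.integers(0, max(n_mutations // 2, 1), size=n_mutations)]
    out["cds_pos"] = out["cds_pos"].astype(int)
    if indel_per_sub > 0:
        n_ind = rng.poisson(indel_per_sub * n_mutations)
        lengths = np.array([g.length for g in genes], dtype=float)
        gpick = rng.choice(len(genes), size=n_ind, p=lengths / lengths.sum())
        rows = []
        for gi in gpick:
            g = genes[gi]
            cp = int(rng.integers(1, g.length + 1))
            ref = g.cds_seq[cp - 1]
            rows.append(
                {"cds_pos": cp, "pos": g.genomic_pos(cp), "ref": ref, "alt": ref + "A",
                 "impact": ImpactClass.INDEL.value, "context": 0, "gene_id": g.gene_id,
                 "contig": g.contig, "individual_id": f"I{int(rng.integers(0, max(n_mutations // 2, 1))):06d}"}
            )
        if rows:
            out = pd.concat([out, pd.DataFrame(rows)], ignore_index=True)
    return out


def simulate_site_observations(
    s: float, mu: float, ntau: float, n_individuals: int, f_min: float,
    rng: np.random.Generator, age_low: float = 40.0, age_high: float = 70.0,
):
    """Direct per-site observations (ages, carrier flags, max-clone VAFs).

    A lightweight path to :mod:`clonalselect.fitness` that skips read-level
    noise: exactly the clone-growth model the likelihood assumes.
    """
    ages = rng.uniform(age_low, age_high, size=n_individuals)
    vafs = np.full(n_individuals, np.nan)
    lam = expected_detectable(s, mu, ages, ntau, f_min)
    counts = rng.poisson(lam)
    for i in np.nonzero(counts)[0]:
        draws = np.interp(
            rng.random(counts[i]), *_inverse_cdf_grid(s, float(ages[i]), ntau, f_min)[::-1]
        )
        vafs[i] = draws.max()
    return ages, ~np.isnan(vafs), vafs
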
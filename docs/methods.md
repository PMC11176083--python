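# Methods

## Scope and model overview

`clonalselect` implements the computational core of a population-scale
clonal-hematopoiesis (CH) analysis over synthetic data with known truth:
a cohort simulator under an exponential clone-growth model, a variant-filter
cascade, trinucleotide-context dN/dS selection inference, per-site fitness
estimation, and CH classification.  It deliberately excludes read-level
(BAM) calling, caller concordance, clinical outcome regressions, mosaic-CNV
detection and single-cell phylogenetics: the simulator emits call-level
summaries, so everything downstream of raw reads is in scope and everything
upstream is not.

## Clone-growth model

Haematopoietic stem cells (HSCs) number N and divide symmetrically every τ
years; only the product Nτ (cell·years) is identifiable and it sets the
drift/VAF scale.  A driver mutation with selection coefficient s (excess
symmetric self-renewal per year) arises at per-site rate μ per cell per
year.  Conditioned on survival, a clone founded Δ years ago has mean size
(e^{sΔ} − 1)/(sτ) cells, and the population of clones at age t has VAF
density

    ρ(f) = (Nτ μ / f) · exp(−f / φ(t)),    φ(t) = (e^{st} − 1) / (2 Nτ s),

with f = cells/2N (diploid denominator; any factor-2 convention difference
is absorbed into μ̂ and documented here so fitted μ is interpreted
consistently).  The (e^{st} − 1) numerator is chosen over e^{st} so the
s → 0 limit reproduces the neutral drift scale t/(2Nτ) — a testable
continuity property.  The expected number of clones detectable above f_min
is the closed form λ = Nτμ·[E₁(f_min/φ) − E₁(0.5/φ)] (E₁ the exponential
integral), which the suite verifies against adaptive quadrature at 1e−8
relative tolerance.  λ diverges logarithmically as f_min → 0, so a positive
detection limit is structural, not an implementation nicety.

### Forward birth–death oracle

As an independent check, `forward_birth_death` simulates mutant clones
directly: each mutant cell divides (two mutant daughters) at rate 1/τ per
year and is lost at rate (1 − sτ)/τ — a per-division birth–death asymmetry
of sτ — with new mutants arising at rate Nμ per year and time discretised
at τ/10.  This parameterisation is the one whose conditioned-on-survival
mean (e^{sΔ} − 1)/(sτ) and stationary clone-size density match ρ(f) above;
a per-generation {0, 2}-offspring scheme would halve the size scale and
disagree with the density the inference assumes.  The inverse-CDF VAF
sampler is required to agree with this oracle in distribution
(Kolmogorov–Smirnov p > 0.01 on truncation to (f_min, 0.5]).

## Cohort simulator

Per individual: age ~ Uniform(40, 70) years; per driver site, clone count ~
Poisson(λ(age)) and VAFs i.i.d. from the normalised truncated density via
inverse CDF on a 4096-point log-f grid; the largest clone per site is
reported, mirroring bulk calling (multiple clones per site are simulated but
not separately observable).  Passengers hitch-hike at the clone's VAF times
a configurable subclonality factor (default 1.0), placed uniformly over the
gene set's possible substitutions, with a 10% indel fraction.  Germline
heterozygous SNPs sit at true VAF ~ Beta(200, 200) centred on 0.5 (VAF 1.0
for chrX sites in males) with population allele frequencies drawn above the
common-SNP threshold.  Sequencing-error candidates are drawn at a
configurable number of loci per individual (default 20) with true VAF 0;
strand-biased artifacts arrive at a Poisson rate per individual (default
0.3).

Reads: depth = 1 + negative binomial with dispersion 20, with the mean tuned
numerically so the distribution's *median* equals the configured 45 (only
the median is specified by the study conditions); alt reads ~
Binomial(depth, f(1−e) + (1−f)e/3) at error rate e = 0.001; strands split
Binomial(alt, 1/2) except artifacts, which put all alt reads on one strand;
alt base qualities match reference for genuine calls and sit 8 Phred below
it for artifacts — just enough structure for the two read-level filters to
have true and false positives.

What this emulates and what it does not: the generator reproduces the
age-structured carrier statistics, clone-size distribution, depth/error
characteristics, and the artifact/germline failure modes the filters target.
It does not model real exome capture unevenness, sample contamination,
mapping artifacts, clonal phylogenies, multiple drivers per clone, or the
empirical (non-uniform) cohort age histogram.  Passing tests therefore
demonstrate correctness of the inference machinery under its stated model,
not robustness to every failure mode of real exome data.

## Filter cascade

Record-local filters, in reporting order: (1) median base-quality
differential > 5 Phred; (2) strand-bias Pearson chi-square p < 0.01 on the
2×2 allele-by-strand table, without Yates correction, with zero-margin
tables defined untestable (p = 1, keep); (3) gene blacklist; (4) indels with
≤ 10 alt reads; (5) VAF < 0.11 or < 3 alt reads; (6) germline: exact
two-sided binomial test against VAF 0.5 — for the symmetric null this equals
min(1, 2·P(X ≤ min(k, n−k))), cross-checked against `scipy.stats.binomtest`
— where a record is retained as somatic only when the test *rejects*
(p < 1e−4); the opposite reading would delete every clone near the VAF floor
at depth 45; (7) −log10 population MAF < 3.35 removes common SNPs, with
pop_af = 0 treated as −log10 = ∞ (novel variants are never SNP-filtered).
Cohort-level filters: (8) recurrence — sites occurring more often than a
configurable cap (default: the most recurrent site's count, making the rule
vacuous until pinned) or with > 50% of occurrences at VAF > 0.15; the
high-VAF share rule requires ≥ 2 occurrences, since a singleton carries no
recurrence evidence and the literal rule would delete every genuine large
clone seen once; (9) homopolymer runs ≥ 4 overlapping the site (≥ is the
conservative reading of "length 4"); (10) depth > 150; (11) proximity —
both members of any same-individual pair within 50 bp are removed
(symmetric removal avoids order dependence).

The VAF floor is justified by the false-positive budget
B·e^(depth·VAF) (B bases tested cohort-wide), evaluated in log10 space;
`vaf_threshold_for_budget` scans a VAF grid for the smallest value meeting a
budget.  With the cohort constants the smallest 0.01-grid value under one
expected false positive is 0.10; the adopted 0.11 adds a safety margin, and
both values are surfaced.

Order and idempotence: each local filter is a pure predicate, so order
affects only reason attribution.  The two cohort-level filters depend on the
surviving set; they are evaluated on survivors and iterated to a fixpoint,
which makes the cascade exactly idempotent (asserted by test).  Every
removal is logged with all applicable reason codes in cascade order.

## dN/dS model

Counts by context and impact follow n_{jc} ~ Poisson(r_j·L_{jc}·ω_c) with
ω_syn ≡ 1 over 96 strand-collapsed trinucleotide classes (32
pyrimidine-centred contexts × 3 alts; bulk blood calling is strand-agnostic,
and the class code is isolated so a 192-class strand-specific model could be
swapped in).  The canonical class ordering is lexicographic over (5′ base,
pyrimidine centre, 3′ base, alt).  Opportunities L are exhaustive per-gene
tallies of all 3L substitutions (edge codons use explicit flanking bases so
no opportunity is dropped; essential-splice positions contribute 3
opportunities each in a dedicated class).  The joint MLE uses the
closed-form alternating updates r_j = Σ_c n_{jc}/Σ_c L_{jc}ω_c and
ω_c = Σ_j n_{jc}/Σ_j r_j L_{jc}, iterated to 1e−10 relative change; 95% CIs
are profile-likelihood (χ², df 1) with bisection on the deviance.  The model
is plain Poisson without a negative-binomial covariate regression: the
synthetic genome has no covariate structure; an overdispersion hook is the
documented extension point.

Indels carry no trinucleotide class; their background is a single per-bp
rate (estimated from non-flagged genes when a flag list is supplied,
otherwise from all genes) with ω_ind = observed/expected and exact Poisson
(Garwood) CIs.  "Truncating" pools nonsense substitutions with frameshift
indels.  The pooled "all nonsynonymous" wall (missense + nonsense + splice
against synonymous) is fitted separately, since a point estimate like the
global ratio may refer either to that wall or to missense+nonsense only;
both are computed and labelled.

Per-gene tests condition on cohort-wide rates: per class, ω̂ = n/E with
Poisson deviance against ω = 1 (two-sided p from χ²₁); a combined statistic
sums class deviances (df = classes tested); Benjamini–Hochberg correction
runs across genes, per class and combined; the positive-selection flag
requires ω > 1 with q < 0.1.  Restricted testing applies the same statistics
with BH over a pre-specified gene list only, reducing the multiple-testing
burden.  `excess_metrics` converts ω into the excess fraction (ω−1)/ω and
one_in_n = ⌊ω/(ω−1)⌋ — floor is the only rounding consistent with the
reference triple (8, 7, 10) at ω = 1.13, 1.16, 1.11.  The
driver-fraction-identified statistic divides the flagged genes' summed
excess counts by the exome-wide excess from the pooled wall, with a
1,000-resample bootstrap over individuals (multinomial weights; the fit is
re-run per resample).

## Fitness inference

For one site, observations are per-individual (age, carrier flag, largest
VAF).  Clones form a Poisson process with intensity ρ, so a non-carrier
contributes −λ(t) to the log-likelihood and a carrier with largest clone at
f contributes log ρ(f) − Λ(f, 0.5), where Λ(f, 0.5) = Nτμ[E₁(f/φ) −
E₁(0.5/φ)] is the exact thinning term for "no clone larger than f".  This
makes the per-individual density integrate to one; the cruder carrier term
log ρ(f) − λ is its first-order approximation and leaves the MLE visibly
biased at λ ≈ 0.2–0.4 (μ low by ~18%, s high by ~1.5% — enough to break
nominal CI coverage at n = 20,000).

Numerics: optimisation is over (log s, log μ) — a 9×9 coarse grid scan
(s ∈ [0.02, 0.5], μ ∈ [1e−8, 1e−4]) followed by Nelder–Mead polish; the s CI
is profile likelihood with the inner μ optimisation done by bounded Brent;
the μ CI is a log-scale quadratic (Wald) approximation.  Non-carrier ages
are aggregated on a 0.1-year grid before evaluation — λ is smooth in age, so
this changes the likelihood negligibly while making each evaluation
O(bins + carriers) instead of O(cohort).  Sites whose 95% CI for s is wider
than 0.2 (or with a boundary/degenerate fit, e.g. zero carriers) are flagged
excluded.  Ages are used as observed; no cohort-age dispersion parameter is
re-estimated.

Nτ is weakly identified — amplitude Nτμ and the VAF scale absorb most of a
rescaling, a near-ridge the suite asserts directly (doubling Nτ with (s, μ)
re-optimised costs < 0.05 log-likelihood per carrier).  `calibrate_ntau`
therefore maximises over a 13-point log grid (10⁴–10⁷) on the cohort's most
recurrently mutated site, recovers the truth within a factor of ~2 at
n = 30,000, and fixes Nτ for all other sites; a flat profile raises a
calibration-failure error with guidance rather than returning an arbitrary
grid point.

Detection limits: when fed from the filter stage f_min defaults to the 0.11
VAF floor; fitness simulations and examples use f_min = 0.02 (or 0.003 for
the hotspot-versus-driver contrast), the sensitive-calling regime in which
recurrent-site fitness estimation is typically run — a weakly selected clone
(s ≈ 0.05) never reaches VAF 0.11 within a human lifespan, so the contrast
between high-μ/low-s and low-μ/high-s sites only exists below the discovery
threshold.

## CH classification

Gene categories are derived set-theoretically from a canonical list and the
fitness-inferred flags: classical-FI = canonical ∩ fitness-inferred,
classical-non-FI = canonical \ fitness-inferred, new-FI = fitness-inferred \
canonical — disjoint by construction.  Qualifying variants must survive the
VAF > 0.5 germline removal (kept when on chrX in males), exceed VAF 0.1, and
match the gene's allowed impact classes (e.g. a missense-only gene ignores
truncating variants).  Driverless CH requires somatic burden at or above the
cohort's 95th-percentile count — computed as a discrete (attained) quantile,
recomputed per cohort and pinnable to a fixed count — with no driver variant
above VAF 0.02 and no autosomal CNV flag (CNV flags are consumed as an input
column; no CNV detection is implemented).  Burden is counted on the kept
(post-filter) table.  Age trends are ordinary least squares of
per-individual binary indicators (incidence) or log(VAF) on age; binned
incidence tables are provided for reporting, with any curve smoothing left
to plotting.

## Determinism and problem sizes

All randomness flows through `numpy.random.Generator` seeded explicitly;
the pipeline fans a single top-level seed into per-stage child seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`, so each stage is
independently reproducible and identical config + seed gives byte-identical
TSVs.  Test and acceptance problem sizes were chosen as the smallest at
which each statistical property is comfortably resolved: 22,000 mutations
over 100 genes for neutral dN/dS calibration (±0.05 at ~3 standard errors),
200 genes with 5 injected at ω ≈ 5 for detection power/FDR, 50 replicates of
n = 20,000 individuals for CI coverage of s, n = 20,000 for age-trend
significance, and N = 1,000 cells for the forward birth–death oracle.

## Known limitations

The Poisson dN/dS has no overdispersion or covariate regression, so on real
exomes with gene-level rate covariates it would be anticonservative; indel
and splice backgrounds are simplified (one global indel rate, two designated
splice positions per boundary, single-transcript genes); the fitness
likelihood assumes one observable clone per site per individual (largest
VAF) and a detection limit known exactly; Nτ calibration assumes the top
site obeys the same clone-growth model; and the simulator's artifact model
is intentionally minimal.  These are the points to revisit before applying
the pipeline to real cohort tables.
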
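"""CH status, driverless CH and age trends on a simulated cohort.

Simulates 6,000 individuals with one expanding driver gene, classifies them
into CH categories (treating the gene as a newly fitness-inferred driver),
marks driverless CH from passenger burden, and regresses incidence and
log(VAF) on age.
"""

import warnings

import numpy as np

from clonalselect import (
    DriverSite,
    GeneCategoryConfig,
    SimParams,
    age_trend,
    annotate_impact,
    assign_ch_status,
    driverless_status,
    generate_cohort,
    random_gene_set,
)

rng = np.random.default_rng(17)
genes = random_gene_set(6, rng, length_codons=(60, 120))
g = genes[0]
pos, ref, alt = next(
    (p, g.cds_seq[p - 1], a)
    for p in range(4, g.length)
    for a in "ACGT"
    if a != g.cds_seq[p - 1] and annotate_impact(g, p, g.cds_seq[p - 1], a).value == "missense"
)
params = SimParams(
    n_individuals=6000, driver_sites=(DriverSite(g.gene_id, pos, ref, alt, 0.2, 8e-6),),
    passenger_rate=2.0, germline_sites_per_indiv=0, error_rate=0.0,
    artifact_rate=0.0, f_min=0.02, seed=23,
)
records, truth, individuals = generate_cohort(params, genes)

config = GeneCategoryConfig(canonical_genes=frozenset(), fitness_inferred=frozenset({g.gene_id}))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # passenger genes are deliberately uncategorised
    status = assign_ch_status(records, individuals, config)
status["driverless"] = driverless_status(status, individuals["cnv_flag"], pinned_count=3)

n_fi = int(status["new_fi"].sum())
print(f"{n_fi} of {len(status)} individuals carry a qualifying clone (VAF > 0.1)"
      f" in the fitness-inferred gene")
print(f"{int(status['driverless'].sum())} individuals are driverless-CH"
      f" (>=3 somatic mutations, no known driver > VAF 0.02, no CNV)")

slope, _, p = age_trend(status["new_fi"], status["age"])
print(f"incidence vs age: slope = {slope:.2e}/yr, p = {p:.2g}")
drv = records[records["truth_origin"] == "driver"]
slope_v, _, p_v = age_trend(np.log(drv["vaf"]), drv["age"])
print(f"log(VAF) vs age:  slope = {slope_v:.3f}/yr, p = {p_v:.2g}")
# Both clone frequency and clone size grow with age under positive selection
# -- the twin signatures the classifier's trend statistics quantify.
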
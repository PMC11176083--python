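"""Impact annotation and the mutational-opportunity matrix of one gene.

Builds a toy coding gene, classifies a few substitutions with the standard
codon table, and tallies all possible substitutions into the 96-context by
impact-class opportunity matrix that normalises the dN/dS model.
"""

from clonalselect import GeneModel, annotate_impact, build_opportunities, context_class

gene = GeneModel("DEMO", "chr1", "+", 1000, "ATGGGATCACGGTAA", flank5="C", flank3="G")

print("gene:", gene.gene_id, f"({gene.length} bp coding)")
for cds_pos, alt in [(6, "G"), (5, "A"), (4, "T")]:
    ref = gene.cds_seq[cds_pos - 1]
    impact = annotate_impact(gene, cds_pos, ref, alt)
    ctx = context_class(gene, cds_pos, alt)
    print(f"  {ref}>{alt} at cds position {cds_pos}: {impact.value:10s} (context class {ctx})")

om = build_opportunities(gene)
totals = om.class_totals()
print("opportunity totals by impact class:")
for impact, n in totals.items():
    print(f"  {impact.value:16s} {n}")
print(f"sum over substitution classes = {om.L[:, :4].sum()} (= 3 x {gene.length} coding bases)")
# Each coding base can mutate to 3 alternatives, so a gene offers exactly 3L
# substitution opportunities, split here into synonymous/missense/nonsense.
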
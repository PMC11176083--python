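"""Synthetic coding genes, impact annotation and mutational-opportunity counting.

A :class:`GeneModel` is a single-transcript, single-CDS coding gene: an in-frame
nucleotide sequence plus one explicit flanking base on each side (so edge codons
have a resolvable trinucleotide context) and an optional set of essential-splice
positions lying outside the coding sequence.

Every single-base substitution in a coding region is classified into exactly one
impact class by translating the mutated codon with the standard codon table, and
into one of 96 strand-collapsed trinucleotide substitution classes
(32 pyrimidine-centred contexts x 3 alternate bases).  Tallying the two
classifications over all 3L possible substitutions of a gene yields its
opportunity matrix ``L[context, impact]`` -- the per-site normalisation of the
dN/dS model.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "BASES",
    "GeneModel",
    "ImpactClass",
    "N_CONTEXT_CLASSES",
    "IMPACT_ORDER",
    "OpportunityMatrix",
    "annotate_impact",
    "context_class",
    "context_class_of_triplet",
    "build_opportunities",
    "enumerate_substitutions",
    "reverse_complement",
    "random_gene_set",
    "homopolymer_length",
]

BASES = "ACGT"
_PYRIMIDINES = "CT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

N_CONTEXT_CLASSES = 96  # 4 (5' base) x 2 (pyrimidine centre) x 4 (3' base) x 3 (alt)

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for the three stop codons
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})


class ImpactClass(str, Enum):
    """Functional impact of a variant on the coding sequence."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    ESSENTIAL_SPLICE = "essential_splice"
    INDEL = "indel"


#: fixed column order of the opportunity matrix / count matrices
IMPACT_ORDER = (
    ImpactClass.SYNONYMOUS,
    ImpactClass.MISSENSE,
    ImpactClass.NONSENSE,
    ImpactClass.ESSENTIAL_SPLICE,
    ImpactClass.INDEL,
)
IMPACT_INDEX = {imp: i for i, imp in enumerate(IMPACT_ORDER)}


class ReferenceMismatchError(ValueError):
    """The supplied reference base disagrees with the gene sequence."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A synthetic coding gene.

    Parameters
    ----------
    gene_id, contig, strand
        Identifiers; ``strand`` is ``+`` or ``-`` and affects genomic
        bookkeeping only (all classifications are strand-collapsed).
    cds_start
        1-based genomic coordinate of the first coding base.  Coding base
        ``cds_pos`` (1-based) sits at genomic position ``cds_start+cds_pos-1``.
    cds_seq
        In-frame coding sequence over ACGT, length a multiple of 3, with no
        internal stop codon.
    flank5, flank3
        Single reference bases immediately 5' and 3' of the CDS, used for the
        trinucleotide context of edge positions.
    splice_positions
        Genomic positions (disjoint from the CDS) designated essential-splice;
        each contributes 3 substitution opportunities to the splice class.
    splice_contexts
        Reference trinucleotide at each splice position (same order as
        ``splice_positions``); defaults to the donor-like ``"AGT"``.
    """

    gene_id: str
    contig: str
    strand: str
    cds_start: int
    cds_seq: str
    flank5: str = "A"
    flank3: str = "A"
    splice_positions: tuple[int, ...] = ()
    splice_contexts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        seq = self.cds_seq
        if len(seq) < 3 or len(seq) % 3:
            raise ValueError(f"{self.gene_id}: CDS length {len(seq)} is not a positive multiple of 3")
        if set(seq) - set(BASES) or self.flank5 not in BASES or self.flank3 not in BASES:
            raise ValueError(f"{self.gene_id}: non-ACGT base in sequence or flanks")
        aas = [CODON_TO_AA[seq[i : i + 3]] for i in range(0, len(seq), 3)]
        if "*" in aas[:-1]:
            raise ValueError(f"{self.gene_id}: internal stop codon")
        coding = set(range(self.cds_start, self.cds_start + len(seq)))
        if coding & set(self.splice_positions):
            raise ValueError(f"{self.gene_id}: splice positions overlap the CDS")
        if not self.splice_contexts:
            object.__setattr__(self, "splice_contexts", tuple("AGT" for _ in self.splice_positions))
        if len(self.splice_contexts) != len(self.splice_positions):
            raise ValueError(f"{self.gene_id}: splice_contexts length mismatch")

    @property
    def length(self) -> int:
        return len(self.cds_seq)

    def genomic_pos(self, cds_pos: int) -> int:
        return self.cds_start + cds_pos - 1

    def padded(self) -> str:
        """CDS with the two explicit flanking bases attached."""
        return self.flank5 + self.cds_seq + self.flank3


@dataclass
class OpportunityMatrix:
    """Counts of possible substitutions per gene by context x impact class.

    ``L`` has shape (96, 5) in :data:`IMPACT_ORDER` column order.  Indels carry
    no trinucleotide class; the per-bp indel opportunity (the CDS length) is
    stored in row 0 of the indel column.
    """

    gene_id: str
    L: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=np.int64)
        if self.L.shape != (N_CONTEXT_CLASSES, len(IMPACT_ORDER)):
            raise ValueError(f"L must be (96, 5), got {self.L.shape}")
        if (self.L < 0).any():
            raise ValueError("negative opportunity count")

    def class_totals(self) -> dict[ImpactClass, int]:
        return {imp: int(self.L[:, i].sum()) for i, imp in enumerate(IMPACT_INDEX)}


def context_class_of_triplet(tri: str, alt: str) -> int:
    """Strand-collapsed class id of substituting the centre of ``tri`` by ``alt``.

    Canonical ordering is lexicographic over (5' base, pyrimidine centre,
    3' base, alt): ``id = ((i5*2 + ic)*4 + i3)*3 + ia`` with ``i5, i3`` indexing
    ACGT, ``ic`` indexing CT and ``ia`` indexing the three non-reference bases
    in alphabetical order.  A substitution and its reverse complement share one id.
    """
    if len(tri) != 3 or set(tri) - set(BASES) or alt not in BASES:
        raise ValueError(f"non-ACGT base in context {tri!r} alt {alt!r}")
    if alt == tri[1]:
        raise ValueError("alt equals the reference base")
    if tri[1] not in _PYRIMIDINES:  # collapse purine-centred onto the other strand
        tri = reverse_complement(tri)
        alt = alt.translate(_COMPLEMENT)
    five, centre, three = tri
    alts = [b for b in BASES if b != centre]
    return ((BASES.index(five) * 2 + _PYRIMIDINES.index(centre)) * 4 + BASES.index(three)) * 3 + alts.index(alt)


def _check_cds_pos(gene: GeneModel, cds_pos: int) -> None:
    if not 1 <= cds_pos <= gene.length:
        raise IndexError(f"cds_pos {cds_pos} outside 1..{gene.length} for {gene.gene_id}")


def annotate_impact(gene: GeneModel, cds_pos: int, ref: str, alt: str) -> ImpactClass:
    """Impact of the single-base substitution ``ref>alt`` at 1-based ``cds_pos``.

    Classified by standard-codon-table translation of the mutated codon:
    same amino acid -> synonymous; amino acid to stop -> nonsense; stop lost or
    amino acid changed -> missense.
    """
    _check_cds_pos(gene, cds_pos)
    i = cds_pos - 1
    if gene.cds_seq[i] != ref:
        raise ReferenceMismatchError(
            f"{gene.gene_id}:{cds_pos} reference is {gene.cds_seq[i]}, call says {ref}"
        )
    if alt == ref or alt not in BASES:
        raise ValueError(f"invalid alt {alt!r} for ref {ref!r}")
    codon_start = 3 * (i // 3)
    codon = gene.cds_seq[codon_start : codon_start + 3]
    mutated = codon[: i % 3] + alt + codon[i % 3 + 1 :]
    aa_ref, aa_alt = CODON_TO_AA[codon], CODON_TO_AA[mutated]
    if aa_alt == aa_ref:
        return ImpactClass.SYNONYMOUS
    if aa_alt == "*":
        return ImpactClass.NONSENSE
    return ImpactClass.MISSENSE


def context_class(gene: GeneModel, cds_pos: int, alt: str) -> int:
    """Strand-collapsed trinucleotide class of a coding substitution."""
    _check_cds_pos(gene, cds_pos)
    padded = gene.padded()
    return context_class_of_triplet(padded[cds_pos - 1 : cds_pos + 2], alt)


@functools.lru_cache(maxsize=512)
def enumerate_substitutions(gene: GeneModel) -> pd.DataFrame:
    """All 3L coding substitutions (plus splice opportunities) of a gene.

    Returns a frame with columns ``cds_pos`` (pandas NA for splice rows),
    ``pos`` (genomic), ``ref``, ``alt``, ``impact``, ``context``.
    """
    padded = gene.padded()
    rows: list[tuple] = []
    for cds_pos in range(1, gene.length + 1):
        ref = gene.cds_seq[cds_pos - 1]
        tri = padded[cds_pos - 1 : cds_pos + 2]
        for alt in BASES:
            if alt == ref:
                continue
            rows.append(
                (
                    cds_pos,
                    gene.genomic_pos(cds_pos),
                    ref,
                    alt,
                    annotate_impact(gene, cds_pos, ref, alt).value,
                    context_class_of_triplet(tri, alt),
                )
            )
    for pos, tri in zip(gene.splice_positions, gene.splice_contexts):
        ref = tri[1]
        for alt in BASES:
            if alt == ref:
                continue
            rows.append((None, pos, ref, alt, ImpactClass.ESSENTIAL_SPLICE.value, context_class_of_triplet(tri, alt)))
    df = pd.DataFrame(rows, columns=["cds_pos", "pos", "ref", "alt", "impact", "context"])
    df["cds_pos"] = df["cds_pos"].astype("Int64")
    return df


def build_opportunities(gene: GeneModel) -> OpportunityMatrix:
    """Tally :func:`enumerate_substitutions` into the 96 x 5 opportunity matrix."""
    subs = enumerate_substitutions(gene)
    L = np.zeros((N_CONTEXT_CLASSES, len(IMPACT_ORDER)), dtype=np.int64)
    imp_idx = subs["impact"].map({imp.value: i for imp, i in IMPACT_INDEX.items()}).to_numpy()
    np.add.at(L, (subs["context"].to_numpy(), imp_idx), 1)
    L[0, IMPACT_INDEX[ImpactClass.INDEL]] = gene.length  # one indel opportunity per bp
    return OpportunityMatrix(gene.gene_id, L)


def homopolymer_length(gene: GeneModel, cds_pos: int) -> int:
    """Length of the longest reference homopolymer run containing ``cds_pos``."""
    _check_cds_pos(gene, cds_pos)
    padded = gene.padded()
    i = cds_pos  # index into padded
    base = padded[i]
    lo = i
    while lo > 0 and padded[lo - 1] == base:
        lo -= 1
    hi = i
    while hi < len(padded) - 1 and padded[hi + 1] == base:
        hi += 1
    return hi - lo + 1


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame CDS: ATG start, non-stop internals, stop end."""
    internals = [c for c in CODON_TO_AA if CODON_TO_AA[c] != "*" and c != "ATG"]
    stops = sorted(_STANDARD_TABLE.stop_codons)
    body = rng.choice(internals, size=max(n_codons - 2, 1))
    return "ATG" + "".join(body) + stops[rng.integers(len(stops))]


def random_gene_set(
    n_genes: int,
    rng: np.random.Generator,
    length_codons: tuple[int, int] = (120, 500),
    splice_sites_per_gene: int = 0,
    contig: str = "chr1",
    spacing: int = 10_000,
) -> list[GeneModel]:
    """Generate a synthetic gene set laid out along one contig.

    Genes are spaced ``spacing`` bp apart; optional essential-splice positions
    are placed in the 3' flank region just past the CDS with random contexts.
    """
    genes = []
    start = 1_000
    for g in range(n_genes):
        n_codons = int(rng.integers(length_codons[0], length_codons[1] + 1))
        cds = _random_cds(n_codons, rng)
        flank5, flank3 = (BASES[i] for i in rng.integers(4, size=2))
        n_spl = splice_sites_per_gene
        spl_pos = tuple(start + len(cds) + 10 + 3 * k for k in range(n_spl))
        spl_ctx = tuple("".join(BASES[i] for i in rng.integers(4, size=3)) for _ in range(n_spl))
        genes.append(
            GeneModel(
                gene_id=f"G{g:04d}",
                contig=contig,
                strand="+" if rng.random() < 0.5 else "-",
                cds_start=start,
                cds_seq=cds,
                flank5=flank5,
                flank3=flank3,
                splice_positions=spl_pos,
                splice_contexts=spl_ctx,
            )
        )
        start += len(cds) + spacing
    return genes
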
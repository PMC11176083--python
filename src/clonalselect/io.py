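"""Standard-format I/O: gene sets (FASTA + TSV sidecar), cohort TSV, VCF export.

TSV is the canonical interchange format; all coordinates are 1-based
inclusive.  The optional VCF export writes one minimal VCF v4.2 file per
individual via pysam (INFO SB_FWD/SB_REV, BQA/BQR, PAF, HPL; FORMAT GT:AD:DP).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import GeneModel
from .simulate import RECORD_COLUMNS

__all__ = [
    "save_gene_set",
    "load_gene_set",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_vcf_per_individual",
]


def save_gene_set(genes: list[GeneModel], fasta_path, table_path) -> None:
    """Write CDS sequences as FASTA and gene metadata (incl. flanks) as TSV."""
    SeqIO.write(
        (SeqRecord(Seq(g.cds_seq), id=g.gene_id, description="") for g in genes),
        str(fasta_path),
        "fasta",
    )
    rows = [
        {
            "gene_id": g.gene_id,
            "contig": g.contig,
            "strand": g.strand,
            "cds_start": g.cds_start,
            "flank5": g.flank5,
            "flank3": g.flank3,
            "splice_positions": ",".join(map(str, g.splice_positions)),
            "splice_contexts": ",".join(g.splice_contexts),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)


def load_gene_set(fasta_path, table_path) -> list[GeneModel]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(table_path, sep="\t", dtype={"splice_positions": str, "splice_contexts": str})
    genes = []
    for row in table.itertuples(index=False):
        if row.gene_id not in seqs:
            raise KeyError(f"gene {row.gene_id} missing from FASTA")
        spl_pos = tuple(int(x) for x in str(row.splice_positions).split(",") if x and x != "nan")
        spl_ctx = tuple(x for x in str(row.splice_contexts).split(",") if x and x != "nan")
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                contig=row.contig,
                strand=row.strand,
                cds_start=int(row.cds_start),
                cds_seq=seqs[row.gene_id],
                flank5=row.flank5,
                flank3=row.flank3,
                splice_positions=spl_pos,
                splice_contexts=spl_ctx,
            )
        )
    return genes


def write_cohort_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RECORD_COLUMNS if c not in df.columns and c not in ("truth_origin", "truth_s")]
    if missing:
        raise KeyError(f"cohort table at {path} lacks columns: {missing}")
    return df


def write_vcf_per_individual(records: pd.DataFrame, out_dir, contigs: list[str] | None = None) -> list[Path]:
    """Minimal per-individual VCF v4.2 export of a cohort call table."""
    import pysam

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if contigs is None:
        contigs = sorted(set(records["contig"]))
    paths = []
    for indiv, sub in records.groupby("individual_id"):
        header = pysam.VariantHeader()
        header.add_line('##fileformat=VCFv4.2')
        for c in contigs:
            header.contigs.add(c)
        header.info.add("SB_FWD", 1, "Integer", "Alt reads on forward strand")
        header.info.add("SB_REV", 1, "Integer", "Alt reads on reverse strand")
        header.info.add("BQA", 1, "Integer", "Median alt base quality")
        header.info.add("BQR", 1, "Integer", "Median ref base quality")
        header.info.add("PAF", 1, "Float", "Population minor allele frequency")
        header.info.add("HPL", 1, "Integer", "Reference homopolymer length at site")
        header.formats.add("GT", 1, "String", "Genotype")
        header.formats.add("AD", "R", "Integer", "Allelic depths")
        header.formats.add("DP", 1, "Integer", "Read depth")
        header.add_sample(str(indiv))
        path = out_dir / f"{indiv}.vcf"
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for row in sub.sort_values(["contig", "pos"]).itertuples(index=False):
                if row.pos < 0:
                    continue
                rec = vcf.new_record(
                    contig=row.contig, start=int(row.pos) - 1, stop=int(row.pos) - 1 + len(row.ref),
                    alleles=(row.ref, row.alt),
                )
                rec.info["SB_FWD"] = int(row.fwd_alt)
                rec.info["SB_REV"] = int(row.rev_alt)
                rec.info["BQA"] = int(row.bq_alt_median)
                rec.info["BQR"] = int(row.bq_ref_median)
                rec.info["PAF"] = float(row.pop_af)
                rec.info["HPL"] = int(row.homopolymer_len)
                rec.samples[str(indiv)]["GT"] = (0, 1)
                rec.samples[str(indiv)]["AD"] = (int(row.depth - row.alt_reads), int(row.alt_reads))
                rec.samples[str(indiv)]["DP"] = int(row.depth)
                vcf.write(rec)
        paths.append(path)
    return paths
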
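"""Coding-effect classification of variants against gene models.

Variants inside a gene's analysis region are classified as upstream_2kb
(strand-aware upstream flank), cds_synonymous / cds_nonsynonymous (coding SNP,
via standard-codon-table translation of the affected codon on the coding
strand), cds_frameshift_or_indel (indel touching coding sequence) or
other_genic (introns, UTRs, downstream gene body).  Coding variants are also
flagged for overlap with user-supplied protein-domain intervals given in
protein residue coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio.Seq import Seq

from sweepscan.errors import DataError, ParseError
from sweepscan.genotype_io import GeneRegion

CATEGORIES = (
    "upstream_2kb",
    "cds_synonymous",
    "cds_nonsynonymous",
    "cds_frameshift_or_indel",
    "other_genic",
)


@dataclass
class GeneModel:
    """A gene's coding structure: ordered CDS exons plus optional domains.

    ``cds_exons`` are 1-based inclusive genomic intervals stored in ascending
    genomic order; the coding order is strand-aware.  ``domains`` are
    (start_res, end_res, name) intervals in 1-based protein coordinates.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]
    domains: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"{self.gene_id}: strand must be '+' or '-'")
        exons = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if e1 >= s2:
                raise DataError(f"{self.gene_id}: overlapping CDS exons")
        self.cds_exons = exons
        if self.cds_length % 3 != 0:
            raise DataError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    def cds_index_of(self, pos: int) -> int | None:
        """0-based index of a genomic position within the coding sequence.

        Counts along the coding strand: from the leftmost exon start on '+',
        from the rightmost exon end on '-'.  None if pos is not in any exon.
        """
        offset = 0
        exons = self.cds_exons if self.strand == "+" else self.cds_exons[::-1]
        for s, e in exons:
            if s <= pos <= e:
                return offset + (pos - s if self.strand == "+" else e - pos)
            offset += e - s + 1
        return None

    def cds_sequence(self, genome) -> str:
        """Spliced coding-strand sequence extracted from the genome."""
        parts = [_fetch(genome, self.chrom, s, e) for s, e in self.cds_exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq.upper()


@dataclass
class VariantEffect:
    """Classification of one variant against one gene model."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    category: str
    ref_aa: str | None = None
    alt_aa: str | None = None
    aa_pos: int | None = None  # 1-based residue index of the affected codon
    domain_overlap: bool = False


def _fetch(genome, chrom: str, start1: int, end1: int) -> str:
    """1-based inclusive substring from a dict of strings or a pyfaidx Fasta."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start1 - 1 : end1]
    return str(seq[start1 - 1 : end1])  # pyfaidx FastaRecord slice (0-based)


def classify_effect(
    variant: tuple[str, int, str, str],
    model: GeneModel,
    region: GeneRegion,
    genome,
) -> VariantEffect:
    """Classify a variant's genic context and, for coding SNPs, its codon change.

    The variant must lie inside the gene's analysis region.  The upstream
    flank is the strand-defined side: before gene_start on '+', after
    gene_end on '-'.  Coding SNP codons are translated on the coding strand
    (reverse complement for '-' genes) with the standard codon table.
    """
    chrom, pos, ref, alt = variant
    if chrom != region.chrom or not (region.analysis_start <= pos <= region.analysis_end):
        raise DataError(
            f"variant {chrom}:{pos} outside analysis region of {region.gene_id}"
        )
    is_snp = len(ref) == 1 and len(alt) == 1

    upstream = (
        pos < region.gene_start if region.strand == "+" else pos > region.gene_end
    )
    if upstream:
        return VariantEffect(chrom, pos, ref, alt, model.gene_id, "upstream_2kb")

    if is_snp:
        cds_idx = model.cds_index_of(pos)
        if cds_idx is None:
            return VariantEffect(chrom, pos, ref, alt, model.gene_id, "other_genic")
        cds = model.cds_sequence(genome)
        ref_base = ref.upper() if model.strand == "+" else str(Seq(ref).reverse_complement())
        alt_base = alt.upper() if model.strand == "+" else str(Seq(alt).reverse_complement())
        if cds[cds_idx] != ref_base:
            raise DataError(
                f"{model.gene_id}: reference allele {ref!r} at {chrom}:{pos} does not "
                f"match the genome CDS base {cds[cds_idx]!r}"
            )
        codon_i = cds_idx // 3
        ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt_codon = list(ref_codon)
        alt_codon[cds_idx % 3] = alt_base
        alt_codon = "".join(alt_codon)
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        category = "cds_synonymous" if ref_aa == alt_aa else "cds_nonsynonymous"
        effect = VariantEffect(
            chrom, pos, ref, alt, model.gene_id, category,
            ref_aa=ref_aa, alt_aa=alt_aa, aa_pos=codon_i + 1,
        )
        effect.domain_overlap = domain_overlap(effect, model)
        return effect

    # indel: coding if the affected reference span touches any CDS exon
    span_end = pos + max(len(ref) - 1, 0)
    touches_cds = any(s <= span_end and pos <= e for s, e in model.cds_exons)
    if touches_cds:
        return VariantEffect(chrom, pos, ref, alt, model.gene_id, "cds_frameshift_or_indel")
    return VariantEffect(chrom, pos, ref, alt, model.gene_id, "other_genic")


def domain_overlap(effect: VariantEffect, model: GeneModel) -> bool:
    """True iff the affected residue of a coding SNP falls in a domain interval.

    Non-coding variants (no affected residue) report False.
    """
    if effect.aa_pos is None:
        return False
    return any(s <= effect.aa_pos <= e for s, e, _ in model.domains)


def load_gene_models(path: str | os.PathLike) -> dict[str, GeneModel]:
    """Read gene models from GFF3: strand from ``gene`` rows, exons from ``CDS`` rows.

    CDS rows are attached to their gene via the ``Parent`` (or ``gene_id``)
    attribute.
    """
    genes: dict[str, dict] = {}
    path = os.fspath(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            if parts[2] == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature lacks ID")
                genes.setdefault(gid, {"chrom": parts[0], "strand": parts[6], "cds": []})
            elif parts[2] == "CDS":
                gid = attrs.get("Parent") or attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: CDS feature lacks Parent")
                entry = genes.setdefault(
                    gid, {"chrom": parts[0], "strand": parts[6], "cds": []}
                )
                entry["cds"].append((int(parts[3]), int(parts[4])))
    return {
        gid: GeneModel(gid, d["chrom"], d["strand"], d["cds"])
        for gid, d in genes.items()
        if d["cds"]
    }


def load_domains(path: str | os.PathLike) -> dict[str, list[tuple[int, int, str]]]:
    """Read protein-domain intervals: TSV of gene_id, start_res, end_res, name."""
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            out.setdefault(parts[0], []).append((int(parts[1]), int(parts[2]), parts[3]))
    return out
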
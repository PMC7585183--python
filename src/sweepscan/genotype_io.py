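"""Variant, manifest and gene-region input/output plus allele-frequency primitives.

The central container is :class:`VariantMatrix`: biallelic sites x samples with
genotypes coded 0 (reference allele), 1 (alternate allele) and -1 (missing
allele slot).  Multi-allelic VCF records are split into one biallelic record
per alternate allele.  Coordinates are 1-based inclusive at every interface
(VCF/GFF convention); windowing code converts to 0-based half-open internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from sweepscan.errors import ConfigError, DataError, ParseError

MISSING = -1

POPULATION_LABELS = ("wild", "local", "improved")


def _variant_class(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"


@dataclass
class VariantMatrix:
    """Biallelic sites x samples genotype table.

    Attributes
    ----------
    chrom, pos, ref, alt, vclass
        Per-site arrays; ``pos`` is the 1-based position of the first base of
        the reference allele and ``vclass`` is ``"SNP"`` or ``"indel"``.
    genotypes
        int8 array of shape (n_sites, n_samples, ploidy) over {0, 1, -1};
        the allele pair per sample is unordered.
    sample_ids
        Ordered sample names matching the genotype columns.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    vclass: np.ndarray
    genotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.vclass = np.asarray(self.vclass, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 3 or self.genotypes.shape[0] != len(self.pos):
            raise DataError("genotypes must have shape (n_sites, n_samples, ploidy)")
        if self.genotypes.shape[1] != len(self.sample_ids):
            raise DataError("genotype columns do not match sample_ids")
        for r, a in zip(self.ref, self.alt):
            if r == a:
                raise DataError(f"ref equals alt ({r!r}) at a site")
        # keep sites sorted by (chrom, pos); stable so split records stay adjacent
        order = np.lexsort((self.pos, _chrom_sort_key(self.chrom)))
        if not np.array_equal(order, np.arange(len(order))):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.vclass = self.vclass[order]
            self.genotypes = self.genotypes[order]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def ploidy(self) -> int:
        return self.genotypes.shape[2]

    def site_missingness(self) -> np.ndarray:
        """Fraction of missing allele slots per site, pooled over all samples."""
        if self.n_sites == 0:
            return np.zeros(0)
        return (self.genotypes == MISSING).sum(axis=(1, 2)) / (self.n_samples * self.ploidy)

    def take_sites(self, index: np.ndarray) -> "VariantMatrix":
        return VariantMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            vclass=self.vclass[index],
            genotypes=self.genotypes[index],
            sample_ids=list(self.sample_ids),
        )

    def sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise ConfigError(f"sample {exc.args[0]!r} not present in variant matrix") from None


def _chrom_sort_key(chroms: np.ndarray) -> np.ndarray:
    uniq = sorted(set(chroms.tolist()))
    rank = {c: i for i, c in enumerate(uniq)}
    return np.array([rank[c] for c in chroms], dtype=np.int64)


@dataclass
class PopulationManifest:
    """Mapping sample_id -> population label (wild / local / improved)."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for sample, label in self.assignments.items():
            if label not in POPULATION_LABELS:
                raise ConfigError(
                    f"sample {sample!r} has label {label!r}; expected one of {POPULATION_LABELS}"
                )
            counts[label] = counts.get(label, 0) + 1
        for label, n in counts.items():
            if n < 2:
                raise ConfigError(f"population {label!r} has {n} sample(s); need >= 2")

    def samples(self, pop: str) -> list[str]:
        if pop not in POPULATION_LABELS:
            raise ConfigError(f"unknown population label {pop!r}")
        return [s for s, lab in self.assignments.items() if lab == pop]

    @property
    def populations(self) -> list[str]:
        return [p for p in POPULATION_LABELS if any(v == p for v in self.assignments.values())]

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "PopulationManifest":
        assignments: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
                if parts[0] == "sample_id":  # optional header
                    continue
                assignments[parts[0]] = parts[1]
        return cls(assignments)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpopulation\n")
            for s, lab in self.assignments.items():
                fh.write(f"{s}\t{lab}\n")


@dataclass(frozen=True)
class GeneRegion:
    """A gene span extended by the strand-defined upstream flank (default 2 kb).

    All coordinates are 1-based inclusive.  ``analysis_start..analysis_end``
    is the scanned interval: gene body plus the upstream extension, clamped at
    the chromosome start.
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    analysis_start: int = field(default=0)
    analysis_end: int = field(default=0)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.gene_start > self.gene_end:
            raise DataError(f"{self.gene_id}: gene_start > gene_end")
        if not (self.analysis_start <= self.gene_start and self.gene_end <= self.analysis_end):
            raise DataError(f"{self.gene_id}: analysis span must contain the gene span")

    @classmethod
    def from_gene(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        gene_start: int,
        gene_end: int,
        upstream_bp: int = 2000,
    ) -> "GeneRegion":
        if strand == "+":
            a_start = max(1, gene_start - upstream_bp)
            a_end = gene_end
        else:
            a_start = gene_start
            a_end = gene_end + upstream_bp
        return cls(gene_id, chrom, strand, gene_start, gene_end, a_start, a_end)

    @property
    def length(self) -> int:
        return self.analysis_end - self.analysis_start + 1


def load_regions(
    path: str | os.PathLike, fmt: str = "auto", upstream_bp: int = 2000
) -> list[GeneRegion]:
    """Read gene regions from GFF3 (``gene`` features) or a 5-column TSV.

    The TSV layout is ``gene_id  chrom  start  end  strand`` (1-based
    inclusive), with an optional header row.
    """
    path = os.fspath(path)
    if fmt == "auto":
        fmt = "gff3" if path.endswith((".gff", ".gff3")) else "tsv"
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(parts) != 9:
                        raise ValueError("expected 9 GFF3 columns")
                    if parts[2] != "gene":
                        continue
                    attrs = dict(
                        kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                    )
                    gene_id = attrs.get("ID") or attrs.get("gene_id")
                    if gene_id is None:
                        raise ValueError("gene feature lacks ID attribute")
                    regions.append(
                        GeneRegion.from_gene(
                            gene_id, parts[0], parts[6], int(parts[3]), int(parts[4]), upstream_bp
                        )
                    )
                else:
                    if parts[0] == "gene_id":
                        continue
                    if len(parts) != 5:
                        raise ValueError("expected 5 TSV columns")
                    regions.append(
                        GeneRegion.from_gene(
                            parts[0], parts[1], parts[4], int(parts[2]), int(parts[3]), upstream_bp
                        )
                    )
            except (ValueError, DataError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return regions


# ---------------------------------------------------------------------------
# variant loading


def load_variants(path: str | os.PathLike, dialect: str = "vcf") -> VariantMatrix:
    """Read variant calls into a :class:`VariantMatrix`.

    ``dialect="vcf"`` reads VCF 4.x through pysam (only the GT field is used;
    multi-allelic records are split into biallelic records sharing a position).
    ``dialect="table"`` reads the package's tabular genotype dialect: columns
    ``chrom  pos  ref  alt`` then one ``a/b`` genotype column per sample, with
    a header row naming the samples.
    """
    if dialect == "vcf":
        return _load_vcf(path)
    if dialect == "table":
        return _load_table(path)
    raise ConfigError(f"unknown dialect {dialect!r}")


def _load_vcf(path: str | os.PathLike) -> VariantMatrix:
    path = os.fspath(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: cannot open VCF: {exc}") from exc
    sample_ids = list(vcf.header.samples)
    if not sample_ids:
        raise ParseError(f"{path}: VCF header declares no samples")
    chroms, poss, refs, alts, classes, gts = [], [], [], [], [], []
    for rec in vcf:
        if rec.alts is None:
            continue
        ref = rec.ref
        for alt_index, alt in enumerate(rec.alts, start=1):
            if alt is None or alt in (".", "*") or alt == ref:
                continue
            row = np.full((len(sample_ids), 2), MISSING, dtype=np.int8)
            for j, sample in enumerate(sample_ids):
                gt = rec.samples[sample].get("GT")
                if gt is None:
                    continue
                if len(gt) > 2:
                    raise ParseError(
                        f"{path}: {rec.chrom}:{rec.pos}: ploidy > 2 unsupported"
                    )
                for k, allele in enumerate(gt):
                    if allele is None:
                        row[j, k] = MISSING
                    elif allele == 0:
                        row[j, k] = 0
                    elif allele == alt_index:
                        row[j, k] = 1
                    else:
                        # an allele belonging to a different split record
                        row[j, k] = MISSING
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            refs.append(ref)
            alts.append(alt)
            classes.append(_variant_class(ref, alt))
            gts.append(row)
    genotypes = (
        np.stack(gts) if gts else np.zeros((0, len(sample_ids), 2), dtype=np.int8)
    )
    return VariantMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        vclass=np.array(classes, dtype=object),
        genotypes=genotypes,
        sample_ids=sample_ids,
    )


_GT_CODE = {"0": 0, "1": 1, ".": MISSING}


def _load_table(path: str | os.PathLike) -> VariantMatrix:
    path = os.fspath(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(f"{path}:1: header must start with chrom, pos, ref, alt")
        sample_ids = header[4:]
        if not sample_ids:
            raise ParseError(f"{path}:1: no sample columns")
        chroms, poss, refs, alts, classes, gts = [], [], [], [], [], []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4 + len(sample_ids):
                raise ParseError(f"{path}:{lineno}: expected {4 + len(sample_ids)} columns")
            row = np.empty((len(sample_ids), 2), dtype=np.int8)
            for j, cell in enumerate(parts[4:]):
                halves = cell.split("/")
                if len(halves) != 2 or any(h not in _GT_CODE for h in halves):
                    raise ParseError(f"{path}:{lineno}: bad genotype {cell!r}")
                row[j, 0] = _GT_CODE[halves[0]]
                row[j, 1] = _GT_CODE[halves[1]]
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            refs.append(parts[2])
            alts.append(parts[3])
            classes.append(_variant_class(parts[2], parts[3]))
            gts.append(row)
    genotypes = (
        np.stack(gts) if gts else np.zeros((0, len(sample_ids), 2), dtype=np.int8)
    )
    return VariantMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        vclass=np.array(classes, dtype=object),
        genotypes=genotypes,
        sample_ids=sample_ids,
    )


_CODE_GT = {0: "0", 1: "1", MISSING: "."}


def write_table(vm: VariantMatrix, path: str | os.PathLike) -> None:
    """Write the tabular genotype dialect (round-trips through ``load_variants``)."""
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", *vm.sample_ids]) + "\n")
        for i in range(vm.n_sites):
            cells = [
                "/".join(_CODE_GT[int(a)] for a in vm.genotypes[i, j])
                for j in range(vm.n_samples)
            ]
            fh.write(
                "\t".join([str(vm.chrom[i]), str(vm.pos[i]), str(vm.ref[i]), str(vm.alt[i]), *cells])
                + "\n"
            )


# ---------------------------------------------------------------------------
# filtering and allele frequencies


def filter_by_missingness(vm: VariantMatrix, max_miss: float = 0.20) -> VariantMatrix:
    """Drop sites whose pooled missing-slot fraction strictly exceeds ``max_miss``.

    Missingness is computed over all samples pooled (all populations), and the
    removal rule is strict: a site at exactly ``max_miss`` is kept.
    """
    if not 0 <= max_miss <= 1:
        raise ConfigError("max_miss must lie in [0, 1]")
    if vm.n_sites == 0:
        return vm
    keep = vm.site_missingness() <= max_miss
    return vm.take_sites(np.flatnonzero(keep))


def allele_counts(
    vm: VariantMatrix, manifest: PopulationManifest, pop: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, called allele count) within one population."""
    idx = vm.sample_indices(manifest.samples(pop))
    g = vm.genotypes[:, idx, :]
    alt = (g == 1).sum(axis=(1, 2))
    called = (g != MISSING).sum(axis=(1, 2))
    return alt.astype(np.int64), called.astype(np.int64)


def allele_frequencies(
    vm: VariantMatrix, manifest: PopulationManifest, site: int, pop: str
) -> tuple[float, float, int]:
    """Reference/alternate allele frequencies at one site in one population.

    Missing allele slots are excluded from both numerator and denominator.
    With zero called alleles the frequencies are undefined and returned as
    NaN (never 0/0 silently).
    """
    alt, called = allele_counts(vm, manifest, pop)
    n = int(called[site])
    if n == 0:
        return (float("nan"), float("nan"), 0)
    af = int(alt[site]) / n
    return (1.0 - af, af, n)
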
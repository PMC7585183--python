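"""Synthetic fixtures with the statistical structure the sweep scan assumes.

Three generators, all deterministic given a seed:

* :func:`simulate_genotypes` — a three-population diploid genotype panel
  (wild, local, improved) over a panel of gene regions.  Wild allele
  frequencies are drawn from a Beta distribution; the local population is the
  wild one plus bounded zero-mean drift; the improved population drifts again
  from local with a smaller scale, so E[pi_wild] > E[pi_local] >= E[pi_improved]
  by construction.  In designated sweep genes each derived-population
  frequency is pushed to its nearest boundary {0, 1} with probability ``s``,
  emulating near-fixation after strong artificial selection.  Genotype-level
  missingness and a configurable indel fraction complete the panel.
* :func:`simulate_expression` — a gene x tissue abundance matrix where each
  gene mixes a shared tissue profile with independent noise; the shared-profile
  weight controls the mean pairwise Pearson r monotonically.
* :func:`simulate_tfbs_fixture` — a small genome, one high-information motif,
  and variants that destroy, create, or shift a planted binding site, with a
  constructional truth table of expected lost/gained motifs.

The frequency-perturbation model is deliberately not a coalescent: it is
sufficient to induce the F_ST / pi / ROD structure the scan consumes, with no
linkage or demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sweepscan.errors import ConfigError
from sweepscan.expression_quant import ExpressionMatrix
from sweepscan.genotype_io import (
    GeneRegion,
    PopulationManifest,
    VariantMatrix,
    MISSING,
)
from sweepscan.tfbs_delta import PFM

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study panel.

    Defaults mirror the analysed study design where one exists (44 gene
    regions, three populations, 20% missingness downstream); free parameters
    are documented in the methods note.
    """

    seed: int = 1
    n_wild: int = 20
    n_local: int = 20
    n_improved: int = 10
    n_genes: int = 44
    region_length: int = 6000
    variant_density: float = 0.07  # variants per bp, matching dense resequencing panels
    wild_beta: tuple[float, float] = (0.8, 0.8)
    sigma_local: float = 0.08  # drift scale wild -> local
    sigma_improved: float = 0.04  # drift scale local -> improved
    sweep_genes: tuple[int, ...] = (4, 23)  # 0-based gene indices
    sweep_stage: str = "domestication"
    s: float = 0.95  # per-site fixation push probability inside the sweep core
    sweep_core_bp: int = 2500  # length of the swept subregion (sweeps are local)
    missingness: float = 0.05
    indel_fraction: float = 0.10
    upstream_bp: int = 2000
    # expression block
    n_tissues: int = 15
    shared_weight: float = 0.79  # calibrated: mean pairwise r ~ 0.85 at defaults
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_wild", "n_local", "n_improved", "n_genes"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be >= 2")
        for name in ("s", "missingness", "indel_fraction", "shared_weight"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.sweep_stage not in ("domestication", "breeding"):
            raise ConfigError("sweep_stage must be 'domestication' or 'breeding'")
        if self.sweep_genes and self.variant_density <= 0:
            raise ConfigError("cannot plant sweeps with variant_density = 0")
        if any(not 0 <= g < self.n_genes for g in self.sweep_genes):
            raise ConfigError("sweep gene index out of range")
        if self.n_tissues < 3:
            raise ConfigError("n_tissues must be >= 3")


def _gene_id(i: int) -> str:
    return f"EME{i + 1:02d}"


def simulate_genotypes(
    cfg: SimulationConfig,
) -> tuple[VariantMatrix, PopulationManifest, list[GeneRegion], list[str]]:
    """Simulate the three-population panel; returns (variants, manifest, regions, truth).

    ``truth`` is the list of planted sweep gene ids.  Each gene occupies its
    own contig, spanning [upstream_bp + 1, region_length] with the upstream
    flank in [1, upstream_bp].
    """
    rng = np.random.default_rng(cfg.seed)
    sample_ids = (
        [f"W{i + 1:03d}" for i in range(cfg.n_wild)]
        + [f"L{i + 1:03d}" for i in range(cfg.n_local)]
        + [f"I{i + 1:03d}" for i in range(cfg.n_improved)]
    )
    manifest = PopulationManifest(
        {
            **{s: "wild" for s in sample_ids[: cfg.n_wild]},
            **{s: "local" for s in sample_ids[cfg.n_wild : cfg.n_wild + cfg.n_local]},
            **{s: "improved" for s in sample_ids[cfg.n_wild + cfg.n_local :]},
        }
    )

    regions = [
        GeneRegion.from_gene(
            _gene_id(i),
            f"chr{i + 1:02d}",
            "+",
            cfg.upstream_bp + 1,
            cfg.region_length,
            upstream_bp=cfg.upstream_bp,
        )
        for i in range(cfg.n_genes)
    ]
    truth = [_gene_id(i) for i in sorted(cfg.sweep_genes)]

    n_samples = len(sample_ids)
    chroms, poss, refs, alts, classes, gts = [], [], [], [], [], []
    n_var = int(round(cfg.variant_density * cfg.region_length))
    a, b = cfg.wild_beta
    for gi, region in enumerate(regions):
        positions = np.sort(
            rng.choice(np.arange(1, cfg.region_length + 1), size=n_var, replace=False)
        )
        p_wild = rng.beta(a, b, size=n_var)
        # a sweep affects a contiguous core subregion, not the whole gene region
        in_core = np.zeros(n_var, dtype=bool)
        if gi in cfg.sweep_genes:
            core_bp = min(cfg.sweep_core_bp, cfg.region_length)
            core_start = int(rng.integers(1, cfg.region_length - core_bp + 2))
            in_core = (positions >= core_start) & (positions < core_start + core_bp)
        p_local = np.clip(p_wild + rng.normal(0.0, cfg.sigma_local, size=n_var), 0, 1)
        if gi in cfg.sweep_genes and cfg.sweep_stage == "domestication":
            push = in_core & (rng.random(n_var) < cfg.s)
            p_local = np.where(push, np.round(p_local), p_local)
        p_impr = np.clip(p_local + rng.normal(0.0, cfg.sigma_improved, size=n_var), 0, 1)
        if gi in cfg.sweep_genes and cfg.sweep_stage == "breeding":
            push = in_core & (rng.random(n_var) < cfg.s)
            p_impr = np.where(push, np.round(p_impr), p_impr)

        freqs = np.concatenate(
            [
                np.repeat(p_wild[:, None], cfg.n_wild, axis=1),
                np.repeat(p_local[:, None], cfg.n_local, axis=1),
                np.repeat(p_impr[:, None], cfg.n_improved, axis=1),
            ],
            axis=1,
        )  # (n_var, n_samples)
        g = (rng.random((n_var, n_samples, 2)) < freqs[:, :, None]).astype(np.int8)
        miss = rng.random((n_var, n_samples)) < cfg.missingness
        g[miss] = MISSING

        is_indel = rng.random(n_var) < cfg.indel_fraction
        for k in range(n_var):
            ref_base = str(rng.choice(_BASES))
            if is_indel[k]:
                ins = str(rng.choice(_BASES)) + str(rng.choice(_BASES))
                if rng.random() < 0.5:  # insertion
                    ref, alt = ref_base, ref_base + ins
                else:  # deletion
                    ref, alt = ref_base + ins, ref_base
            else:
                alt_base = str(rng.choice(_BASES[_BASES != ref_base]))
                ref, alt = ref_base, alt_base
            chroms.append(region.chrom)
            poss.append(int(positions[k]))
            refs.append(ref)
            alts.append(alt)
            classes.append("SNP" if len(ref) == len(alt) == 1 else "indel")
        gts.append(g)

    vm = VariantMatrix(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        vclass=np.array(classes, dtype=object),
        genotypes=np.concatenate(gts, axis=0),
        sample_ids=sample_ids,
    )
    return vm, manifest, regions, truth


def simulate_expression(cfg: SimulationConfig) -> ExpressionMatrix:
    """Gene x tissue matrix: each gene = w * shared profile + (1 - w) * noise.

    The shared profile and the per-gene noise are lognormal with matched
    scale, so the expected pairwise Pearson r grows monotonically with the
    shared-profile weight w (w = 1 gives r = 1 exactly; w = 0 gives r near 0).
    A per-gene positive scale factor varies absolute abundance without
    affecting r.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed + 1_000_003)
    w = cfg.shared_weight
    common = rng.lognormal(mean=2.0, sigma=1.0, size=cfg.n_tissues)
    genes = []
    for _ in range(cfg.n_genes):
        noise = rng.lognormal(mean=2.0, sigma=1.0, size=cfg.n_tissues) * cfg.noise_scale
        scale = rng.lognormal(mean=0.0, sigma=0.5)
        genes.append(scale * (w * common + (1.0 - w) * noise))
    values = pd.DataFrame(
        np.vstack(genes),
        index=[_gene_id(i) for i in range(cfg.n_genes)],
        columns=[f"tissue{t + 1:02d}" for t in range(cfg.n_tissues)],
    )
    return ExpressionMatrix(values)


# ---------------------------------------------------------------------------
# TFBS fixture

_MOTIF_CONSENSUS = "GTACGTCA"
_MOTIF_ID = "SYN0001.1"
_MOTIF_TF = "synTF"


@dataclass
class TFBSFixture:
    """A small genome, one motif, and variants with known motif-change truth.

    ``truth`` maps each variant key to its expected (lost, gained) matrix-id
    sets at ``min_rel_score``; with the high-information 8-bp motif used here
    a hit requires an exact consensus (or reverse-complement) match at that
    threshold, so the truth is fixed by construction.
    """

    genome: dict[str, str]
    pfms: list[PFM]
    variants: list[tuple[str, int, str, str]]
    truth: dict[tuple[str, int, str, str], tuple[set[str], set[str]]]
    min_rel_score: float = 0.90
    consensus: str = _MOTIF_CONSENSUS


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _count_motif(seq: str, motif: str) -> int:
    """Occurrences of the motif on either strand (overlapping allowed)."""
    n = 0
    rc = _revcomp(motif)
    for i in range(len(seq) - len(motif) + 1):
        sub = seq[i : i + len(motif)]
        if sub == motif or sub == rc:
            n += 1
    return n


def _window(seq: str, pos: int, ref: str, alt: str) -> tuple[str, str]:
    """60-bp ref window and its alt counterpart (mirrors the scan geometry)."""
    p0 = pos - 1
    left = seq[max(0, p0 - 30) : p0]
    right = seq[p0 + len(ref) : p0 + len(ref) + max(60 - 30 - len(ref), 0)]
    return left + ref + right, left + alt + right


def simulate_tfbs_fixture(cfg: SimulationConfig) -> TFBSFixture:
    """Four single-variant contigs: motif destroyed, created, shifted, untouched.

    The motif is an 8-bp consensus with maximally informative columns; at the
    fixture's relative-score threshold (0.90) any single mismatch abolishes a
    hit, so a SNP inside the site destroys it and a SNP completing a planted
    1-mismatch site creates one.  Backgrounds are resampled until no
    accidental consensus occurs in any scanned window.
    """
    rng = np.random.default_rng(cfg.seed + 7_000_017)
    L = 120
    pos = 61  # 1-based variant position on every contig
    cons = _MOTIF_CONSENSUS
    counts = np.zeros((4, len(cons)))
    for j, base in enumerate(cons):
        counts["ACGT".index(base), j] = 20.0
    pfm = PFM(_MOTIF_ID, _MOTIF_TF, counts)

    def random_seq(n: int) -> str:
        return "".join(rng.choice(_BASES, size=n))

    def build(expected: dict[str, int], planter) -> tuple[str, tuple[str, str, str]]:
        """Resample background until the planted windows carry the expected counts."""
        for _ in range(200):
            seq = random_seq(L)
            seq, ref, alt = planter(seq)
            w_ref, w_alt = _window(seq, pos, ref, alt)
            if _count_motif(w_ref, cons) == expected["ref"] and _count_motif(
                w_alt, cons
            ) == expected["alt"]:
                return seq, (ref, alt, seq)
        raise RuntimeError("could not construct a clean TFBS fixture background")

    def plant(seq: str, start0: int, insert: str) -> str:
        return seq[:start0] + insert + seq[start0 + len(insert) :]

    mism_base = "C" if cons[2] != "C" else "T"  # differs from consensus position 3

    # destroy: variant is motif position 3 (0-based 2); motif occupies 0-based 58..65
    def plant_destroy(seq):
        seq = plant(seq, 58, cons)
        return seq, cons[2], mism_base

    # create: planted site has one mismatch at the variant position
    def plant_create(seq):
        near = cons[:2] + mism_base + cons[3:]
        seq = plant(seq, 58, near)
        return seq, mism_base, cons[2]

    # shift: 2-bp deletion 4 bp upstream of a planted motif (0-based 67..74)
    def plant_shift(seq):
        seq = plant(seq, 67, cons)
        ref = seq[60:63]
        if _count_motif(ref, cons):  # cannot happen (len 3 < 8) but keep symmetry
            raise RuntimeError
        return seq, ref, ref[0]

    def plant_null(seq):
        ref = seq[60]
        alt = str(rng.choice(_BASES[_BASES != ref]))
        return seq, ref, alt

    genome: dict[str, str] = {}
    variants: list[tuple[str, int, str, str]] = []
    truth: dict[tuple, tuple[set[str], set[str]]] = {}
    plan = [
        ("tfbs_destroy", plant_destroy, {"ref": 1, "alt": 0}, ({_MOTIF_ID}, set())),
        ("tfbs_create", plant_create, {"ref": 0, "alt": 1}, (set(), {_MOTIF_ID})),
        ("tfbs_shift", plant_shift, {"ref": 1, "alt": 1}, (set(), set())),
        ("tfbs_null", plant_null, {"ref": 0, "alt": 0}, (set(), set())),
    ]
    for contig, planter, expected, (lost, gained) in plan:
        seq, (ref, alt, seq_full) = build(expected, planter)
        genome[contig] = seq_full
        key = (contig, pos, ref, alt)
        variants.append(key)
        truth[key] = (lost, gained)
    return TFBSFixture(genome=genome, pfms=[pfm], variants=variants, truth=truth)


# ---------------------------------------------------------------------------
# fixture bundle writers (plain-text formats consumed by the CLI)


def write_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_jaspar(pfms: list[PFM], path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.matrix_id} {p.tf_name}\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{int(c):6d}" for c in p.counts[bi])
                fh.write(f"{base}  [ {row} ]\n")


def write_regions_tsv(regions: list[GeneRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for r in regions:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.gene_start}\t{r.gene_end}\t{r.strand}\n")


def write_fixture_bundle(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Write every fixture artifact under ``outdir``; returns the path map."""
    import os

    from sweepscan.genotype_io import write_table

    os.makedirs(outdir, exist_ok=True)
    vm, manifest, regions, truth = simulate_genotypes(cfg)
    em = simulate_expression(cfg)
    tf = simulate_tfbs_fixture(cfg)
    paths = {
        "genotypes": os.path.join(outdir, "genotypes.tsv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "regions": os.path.join(outdir, "regions.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "genome": os.path.join(outdir, "tfbs_genome.fa"),
        "pfms": os.path.join(outdir, "motifs.jaspar"),
        "tfbs_variants": os.path.join(outdir, "tfbs_variants.tsv"),
        "truth": os.path.join(outdir, "sweep_truth.txt"),
    }
    write_table(vm, paths["genotypes"])
    manifest.to_tsv(paths["manifest"])
    write_regions_tsv(regions, paths["regions"])
    em.to_tsv(paths["expression"])
    write_fasta(tf.genome, paths["genome"])
    write_jaspar(tf.pfms, paths["pfms"])
    with open(paths["tfbs_variants"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in tf.variants:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("\n".join(truth) + "\n")
    return paths
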
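"""End-to-end orchestration: load -> filter -> window stats -> thresholds ->
window/gene calls -> per-variant rescan, with optional effect annotation and
TFBS-change stages, a structured run report, and deterministic outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import yaml

from sweepscan import __version__
from sweepscan.errors import ConfigError
from sweepscan.effect_annotation import classify_effect, load_domains, load_gene_models
from sweepscan.genotype_io import (
    PopulationManifest,
    filter_by_missingness,
    load_regions,
    load_variants,
)
from sweepscan.popgen_windows import stats_to_frame, window_stats_table
from sweepscan.sweep_scan import (
    calls_to_frame,
    call_genes,
    call_windows,
    derive_thresholds,
    scan_variants,
)
from sweepscan.tfbs_delta import load_pfms, tfbs_change


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    Defaults are the scan's canonical parameters: 1-kb windows advanced by
    100 bp, 20% missingness cutoff, top-1% F_ST and ROD with bottom-5%
    derived-population pi, 2-kb upstream extension, 60-bp TFBS windows at a
    0.80 relative-score threshold.
    """

    variants: str = ""
    dialect: str = "vcf"
    manifest: str = ""
    regions: str = ""
    stage: str = "domestication"
    out_dir: str = "sweepscan_out"
    window_bp: int = 1000
    step_bp: int = 100
    max_missingness: float = 0.20
    fst_estimator: str = "hudson"
    fst_top: float = 0.01
    rod_top: float = 0.01
    pi_bottom: float = 0.05
    quantile_method: str = "linear"
    upstream_bp: int = 2000
    # optional stages
    gene_models: str | None = None
    domains: str | None = None
    genome: str | None = None
    pfms: str | None = None
    tfbs_min_rel_score: float = 0.80
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the scan and write tables plus a machine-readable run report.

    Outputs under ``cfg.out_dir``: window_stats.tsv, window_calls.tsv,
    selected_windows.bed, variant_calls.tsv, effects.tsv / tfbs_changes.tsv
    when the optional inputs are configured, and report.json.
    """
    for name in ("variants", "manifest", "regions"):
        path = getattr(cfg, name)
        if not path or not os.path.exists(path):
            raise ConfigError(f"{name} file not found: {path!r}")
    os.makedirs(cfg.out_dir, exist_ok=True)

    vm = load_variants(cfg.variants, cfg.dialect)
    manifest = PopulationManifest.from_tsv(cfg.manifest)
    regions = load_regions(cfg.regions, upstream_bp=cfg.upstream_bp)
    n_before = vm.n_sites
    vm = filter_by_missingness(vm, cfg.max_missingness)

    stats = window_stats_table(
        vm, manifest, regions, cfg.window_bp, cfg.step_bp, cfg.fst_estimator
    )
    thresholds = derive_thresholds(
        stats, cfg.stage, cfg.fst_top, cfg.rod_top, cfg.pi_bottom, cfg.quantile_method
    )
    wcalls = call_windows(stats, thresholds)
    genes = call_genes(wcalls)
    selected_regions = [r for r in regions if r.gene_id in genes]
    vscan = scan_variants(vm, manifest, selected_regions, thresholds, cfg.fst_estimator)
    selected_variants = [(st, c) for st, c in vscan if c.selected]

    stats_to_frame(stats).to_csv(
        os.path.join(cfg.out_dir, "window_stats.tsv"), sep="\t", index=False
    )
    calls_to_frame(wcalls).to_csv(
        os.path.join(cfg.out_dir, "window_calls.tsv"), sep="\t", index=False
    )
    with open(os.path.join(cfg.out_dir, "selected_windows.bed"), "w") as fh:
        for c in wcalls:
            if c.selected:
                w = c.target
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{c.gene_id}\n")
    calls_to_frame([c for _, c in vscan]).to_csv(
        os.path.join(cfg.out_dir, "variant_calls.tsv"), sep="\t", index=False
    )

    report = {
        "version": __version__,
        "config": asdict(cfg),
        "thresholds": {
            "stage": thresholds.stage,
            "fst_cutoff": thresholds.fst_cutoff,
            "rod_cutoff": thresholds.rod_cutoff,
            "pi_cutoff": thresholds.pi_cutoff,
            "quantile_method": thresholds.quantile_method,
        },
        "counts": {
            "sites_loaded": n_before,
            "sites_after_missingness_filter": vm.n_sites,
            "windows": len(stats),
            "selected_windows": sum(c.selected for c in wcalls),
            "selected_genes": len(genes),
            "variants_rescanned": len(vscan),
            "selected_variants": len(selected_variants),
        },
        "selected_genes": genes,
    }

    if cfg.gene_models:
        models = load_gene_models(cfg.gene_models)
        if cfg.domains:
            for gid, doms in load_domains(cfg.domains).items():
                if gid in models:
                    models[gid].domains = doms
        genome = _load_genome(cfg.genome) if cfg.genome else None
        region_by_gene = {r.gene_id: r for r in regions}
        rows = []
        for st, c in selected_variants:
            gid = c.gene_id
            if gid in models and genome is not None:
                eff = classify_effect(
                    (st.chrom, st.pos, st.ref, st.alt), models[gid], region_by_gene[gid], genome
                )
                rows.append(
                    {
                        "chrom": eff.chrom, "pos": eff.pos, "ref": eff.ref, "alt": eff.alt,
                        "gene_id": eff.gene_id, "category": eff.category,
                        "ref_aa": eff.ref_aa, "alt_aa": eff.alt_aa,
                        "domain_overlap": eff.domain_overlap,
                    }
                )
        if rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(
                os.path.join(cfg.out_dir, "effects.tsv"), sep="\t", index=False
            )
        report["counts"]["annotated_variants"] = len(rows)

    if cfg.pfms and cfg.genome:
        pfms = load_pfms(cfg.pfms)
        genome = _load_genome(cfg.genome)
        rows = []
        for st, c in selected_variants:
            delta = tfbs_change(
                (st.chrom, st.pos, st.ref, st.alt), pfms, genome, cfg.tfbs_min_rel_score
            )
            for mid in sorted(delta.lost):
                rows.append({"chrom": st.chrom, "pos": st.pos, "matrix_id": mid, "status": "lost"})
            for mid in sorted(delta.gained):
                rows.append({"chrom": st.chrom, "pos": st.pos, "matrix_id": mid, "status": "gained"})
        import pandas as pd

        pd.DataFrame(rows, columns=["chrom", "pos", "matrix_id", "status"]).to_csv(
            os.path.join(cfg.out_dir, "tfbs_changes.tsv"), sep="\t", index=False
        )
        report["counts"]["tfbs_change_rows"] = len(rows)

    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _load_genome(path: str):
    from pyfaidx import Fasta

    return Fasta(path)
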
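"""Empirical percentile thresholds and sweep calling for windows, genes, variants.

A window is called selected for a stage when it simultaneously lies in the top
1% of F_ST, the top 1% of ROD, and the bottom 5% of the derived population's
pi — all strict inequalities against empirical quantile cutoffs computed over
the pooled windows of all gene regions.  Genes with at least one selected
window are selected genes; variants inside selected genes' regions are then
rescreened individually with the same cutoffs applied to per-site statistics.

Stages: ``domestication`` contrasts wild vs local strains (derived = local);
``breeding`` contrasts local vs improved strains (derived = improved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from sweepscan.errors import ConfigError, DataError
from sweepscan.genotype_io import GeneRegion, PopulationManifest, VariantMatrix, allele_counts
from sweepscan.popgen_windows import (
    WindowStats,
    Window,
    hudson_components,
    rod,
    site_pi,
    wc_components,
)

STAGES = ("domestication", "breeding")

# stage -> (F_ST population pair key, ancestral pop, derived pop)
_STAGE_SPEC = {
    "domestication": ("wild_local", "wild", "local"),
    "breeding": ("local_improved", "local", "improved"),
}


def _stage_values(s: WindowStats, stage: str) -> tuple[float, float, float]:
    fst_key, _, derived = _STAGE_SPEC[stage]
    rod_val = s.rod_domesticated if stage == "domestication" else s.rod_breeding
    return s.fst[fst_key], rod_val, s.pi[derived]


@dataclass
class SweepThresholds:
    """Stage-specific empirical cutoffs: top-1% F_ST, top-1% ROD, bottom-5% pi."""

    stage: str
    fst_cutoff: float
    rod_cutoff: float
    pi_cutoff: float
    quantile_method: str = "linear"


@dataclass
class SweepCall:
    """Joint-criterion pass/fail record for one window or variant."""

    target: object  # Window or (chrom, pos, ref, alt)
    stage: str
    gene_id: str | None
    fst_pass: bool
    rod_pass: bool
    pi_pass: bool

    @property
    def selected(self) -> bool:
        return self.fst_pass and self.rod_pass and self.pi_pass


@dataclass
class SiteStats:
    """Per-variant selection signatures: pi per population, F_ST, ROD."""

    chrom: str
    pos: int
    ref: str
    alt: str
    pi: dict[str, float]
    fst: float
    rod: float
    stage: str


_QUANTILE_METHODS = {"linear": "linear", "nearest-rank": "inverted_cdf"}


def empirical_quantile(values, q: float, method: str = "linear") -> float:
    """Empirical quantile over defined (non-NaN) values.

    ``linear`` is the interpolated type-7 convention (the common default);
    ``nearest-rank`` is the inverted-CDF alternative.
    """
    if method not in _QUANTILE_METHODS:
        raise ConfigError(f"unknown quantile method {method!r}")
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise DataError("no defined values to take a quantile of")
    return float(np.quantile(vals, q, method=_QUANTILE_METHODS[method]))


def derive_thresholds(
    stats: list[WindowStats],
    stage: str,
    fst_top: float = 0.01,
    rod_top: float = 0.01,
    pi_bottom: float = 0.05,
    quantile_method: str = "linear",
    min_windows: int = 20,
) -> SweepThresholds:
    """Percentile cutoffs from the pooled distribution of defined window values.

    F_ST and ROD cutoffs are the empirical (1 - top) quantiles; the pi cutoff
    is the ``pi_bottom`` quantile of the derived population's window pi.
    Undefined (NaN) windows are excluded from each pool.
    """
    if stage not in STAGES:
        raise ConfigError(f"stage must be one of {STAGES}")
    trip = np.array([_stage_values(s, stage) for s in stats], dtype=float).reshape(-1, 3)
    cutoffs = []
    for col, q, name in (
        (trip[:, 0], 1 - fst_top, "F_ST"),
        (trip[:, 1], 1 - rod_top, "ROD"),
        (trip[:, 2], pi_bottom, "pi"),
    ):
        defined = col[~np.isnan(col)]
        if defined.size == 0:
            raise DataError(f"all window values of {name} are undefined")
        if defined.size < min_windows:
            raise DataError(
                f"only {defined.size} defined {name} windows; need >= {min_windows}"
            )
        cutoffs.append(empirical_quantile(defined, q, quantile_method))
    return SweepThresholds(stage, cutoffs[0], cutoffs[1], cutoffs[2], quantile_method)


def _passes(fst: float, rod_val: float, pi_derived: float, th: SweepThresholds):
    # strict inequalities; NaN (undefined) fails every test
    fst_pass = not math.isnan(fst) and fst > th.fst_cutoff
    rod_pass = not math.isnan(rod_val) and rod_val > th.rod_cutoff
    pi_pass = not math.isnan(pi_derived) and pi_derived < th.pi_cutoff
    return fst_pass, rod_pass, pi_pass


def call_windows(stats: list[WindowStats], thresholds: SweepThresholds) -> list[SweepCall]:
    """Evaluate the joint selection criterion for every window."""
    calls = []
    for s in stats:
        fst, rod_val, pi_d = _stage_values(s, thresholds.stage)
        f, r, p = _passes(fst, rod_val, pi_d, thresholds)
        calls.append(SweepCall(s.window, thresholds.stage, s.window.gene_id, f, r, p))
    return calls


def call_genes(calls: list[SweepCall]) -> list[str]:
    """Genes with at least one selected window, sorted and deduplicated."""
    return sorted({c.gene_id for c in calls if c.selected and c.gene_id is not None})


_SITE_FST = {"hudson": hudson_components, "wc": wc_components}


def scan_variants(
    vm: VariantMatrix,
    manifest: PopulationManifest,
    selected_regions: list[GeneRegion],
    thresholds: SweepThresholds,
    fst_estimator: str = "hudson",
) -> list[tuple[SiteStats, SweepCall]]:
    """Rescreen individual variants inside selected regions.

    Each variant gets per-site pi for every population, a per-site F_ST and a
    per-site ROD for the stage, evaluated against the SAME window-derived
    cutoffs (per-site pi is a heterozygosity, so the pi criterion at site
    level selects near-monomorphic derived sites).
    """
    if fst_estimator not in _SITE_FST:
        raise ConfigError(f"unknown F_ST estimator {fst_estimator!r}")
    _, ancestral, derived = _STAGE_SPEC[thresholds.stage]
    pops = ("wild", "local", "improved")
    counts = {p: allele_counts(vm, manifest, p) for p in pops}
    pis = {p: np.atleast_1d(site_pi(counts[p][0], counts[p][1])) for p in pops}
    a_anc, n_anc = counts[ancestral]
    a_der, n_der = counts[derived]
    num, den = _SITE_FST[fst_estimator](a_anc, n_anc, a_der, n_der)
    num, den = np.atleast_1d(num), np.atleast_1d(den)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst_site = np.where(den != 0, num / den, np.nan)

    pos0 = vm.pos - 1
    out: list[tuple[SiteStats, SweepCall]] = []
    for region in selected_regions:
        idx = np.flatnonzero(
            (vm.chrom == region.chrom)
            & (pos0 >= region.analysis_start - 1)
            & (pos0 < region.analysis_end)
        )
        for i in idx:
            pi_anc = float(pis[ancestral][i])
            pi_der = float(pis[derived][i])
            if math.isnan(pi_anc):
                rod_val = float("nan")
            else:
                rod_val = rod(pi_anc, pi_der) if not math.isnan(pi_der) else float("nan")
            stats = SiteStats(
                chrom=str(vm.chrom[i]),
                pos=int(vm.pos[i]),
                ref=str(vm.ref[i]),
                alt=str(vm.alt[i]),
                pi={p: float(pis[p][i]) for p in pops},
                fst=float(fst_site[i]),
                rod=rod_val,
                stage=thresholds.stage,
            )
            f, r, p = _passes(stats.fst, stats.rod, pi_der, thresholds)
            key = (stats.chrom, stats.pos, stats.ref, stats.alt)
            out.append((stats, SweepCall(key, thresholds.stage, region.gene_id, f, r, p)))
    return out


def calls_to_frame(calls: list[SweepCall]):
    """Flatten SweepCalls into a pandas DataFrame."""
    import pandas as pd

    rows = []
    for c in calls:
        t = c.target
        if isinstance(t, Window):
            target = f"{t.chrom}:{t.start}-{t.end}"
        else:
            target = f"{t[0]}:{t[1]}:{t[2]}>{t[3]}"
        rows.append(
            {
                "target": target,
                "gene_id": c.gene_id,
                "stage": c.stage,
                "fst_pass": c.fst_pass,
                "rod_pass": c.rod_pass,
                "pi_pass": c.pi_pass,
                "selected": c.selected,
            }
        )
    return pd.DataFrame(rows)
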
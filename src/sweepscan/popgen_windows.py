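"""Windowed nucleotide diversity, Hudson F_ST and reduction-of-diversity (ROD).

Statistics follow standard population-genetic definitions for biallelic sites:

* per-site diversity is the unbiased heterozygosity
  ``2 a (n - a) / (n (n - 1))`` for ``a`` alternate alleles among ``n`` called
  allele copies — the mean pairwise difference over allele-copy pairs;
* window pi sums per-site diversity over the variant sites inside a window and
  divides by the full window length in bp (invariant positions contribute 0);
* F_ST uses the sample-size-corrected Hudson estimator, combined across sites
  as a ratio of averages (sum of numerators over sum of denominators), which is
  robust for small, unequal panels.  A Weir-Cockerham-style estimator is
  available as an alternative;
* ROD = 1 - pi_derived / pi_ancestral contrasts a derived population against
  its ancestor; it approaches 1 when the derived population has lost diversity,
  as after a selective sweep.

Undefined values (zero denominators, populations with fewer than two called
alleles) propagate as NaN and are never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sweepscan.errors import ConfigError, DataError
from sweepscan.genotype_io import GeneRegion, PopulationManifest, VariantMatrix, allele_counts

POP_PAIRS = (("wild", "local"), ("local", "improved"))


@dataclass(frozen=True)
class Window:
    """A sliding window inside a gene's analysis region (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowStats:
    """Per-window summary: site count, pi per population, pairwise F_ST, ROD."""

    window: Window
    n_sites: int
    pi: dict[str, float]
    fst: dict[str, float]
    rod_domesticated: float
    rod_breeding: float


def make_windows(
    region: GeneRegion, window_bp: int = 1000, step_bp: int = 100
) -> list[Window]:
    """Tile a gene region with sliding windows (default 1 kb, 100 bp step).

    The first window starts at the region's analysis start; subsequent windows
    advance by ``step_bp``; the last window is truncated at the region end.  A
    region shorter than ``window_bp`` yields exactly one window covering it.
    """
    if not (window_bp >= step_bp >= 1):
        raise ConfigError("require window_bp >= step_bp >= 1")
    start0 = region.analysis_start - 1  # to 0-based half-open
    end0 = region.analysis_end
    if end0 <= start0:
        raise DataError(f"{region.gene_id}: empty region")
    windows = []
    start = start0
    while True:
        end = min(start + window_bp, end0)
        windows.append(Window(region.gene_id, region.chrom, start, end))
        if end >= end0:
            break
        start += step_bp
    return windows


def site_pi(alt_count, n_alleles):
    """Unbiased per-site heterozygosity; NaN where fewer than 2 alleles called.

    Accepts scalars or arrays.  Equals the mean pairwise difference over all
    pairs of sampled allele copies.
    """
    a = np.asarray(alt_count, dtype=float)
    n = np.asarray(n_alleles, dtype=float)
    if np.any(a < 0) or np.any(a > n):
        raise DataError("require 0 <= alt_count <= n_alleles")
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(n >= 2, 2.0 * a * (n - a) / (n * np.maximum(n - 1.0, 1.0)), np.nan)
    return float(pi) if pi.ndim == 0 else pi


def window_pi(
    vm: VariantMatrix,
    manifest: PopulationManifest,
    pop: str,
    window: Window,
) -> float:
    """Window pi per bp for one population: sum of site_pi / window length.

    Sites with no called alleles in the population are skipped; invariant
    positions contribute 0 implicitly.
    """
    alt, called = allele_counts(vm, manifest, pop)
    in_win = (
        (vm.chrom == window.chrom)
        & (vm.pos - 1 >= window.start)
        & (vm.pos - 1 < window.end)
    )
    pis = site_pi(alt[in_win], called[in_win])
    return float(np.nansum(pis)) / window.length


def hudson_fst(alt_a, n_a, alt_b, n_b) -> float:
    """Sample-size-corrected Hudson F_ST.

    With scalar inputs returns the per-site value N/D where

        N = (p_A - p_B)^2 - p_A (1-p_A)/(n_A - 1) - p_B (1-p_B)/(n_B - 1)
        D = p_A (1-p_B) + p_B (1-p_A)

    With array inputs returns the window value sum(N)/sum(D) over sites where
    both populations have >= 2 called alleles ("ratio of averages").  NaN when
    no site is usable or the summed denominator is 0.
    """
    N, D = hudson_components(alt_a, n_a, alt_b, n_b)
    N, D = np.atleast_1d(N), np.atleast_1d(D)
    ok = ~np.isnan(N)
    sum_d = float(D[ok].sum())
    if not ok.any() or sum_d == 0.0:
        return float("nan")
    return float(N[ok].sum()) / sum_d


def hudson_components(alt_a, n_a, alt_b, n_b):
    """Per-site Hudson numerator and denominator arrays (NaN where undefined)."""
    aa = np.asarray(alt_a, dtype=float)
    na = np.asarray(n_a, dtype=float)
    ab = np.asarray(alt_b, dtype=float)
    nb = np.asarray(n_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pa = aa / na
        pb = ab / nb
        num = (
            (pa - pb) ** 2
            - pa * (1 - pa) / (na - 1)
            - pb * (1 - pb) / (nb - 1)
        )
        den = pa * (1 - pb) + pb * (1 - pa)
    bad = (na < 2) | (nb < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def wc_fst(alt_a, n_a, alt_b, n_b) -> float:
    """Weir-Cockerham-style two-population F_ST on allele counts.

    Moment estimator on allele copies (r = 2 demes): between- and within-
    population mean squares combined as a ratio of averages across sites.
    Provided as the alternative estimator; Hudson is the default.
    """
    A, B = wc_components(alt_a, n_a, alt_b, n_b)
    A, B = np.atleast_1d(A), np.atleast_1d(B)
    ok = ~np.isnan(A)
    denom = float(B[ok].sum())
    if not ok.any() or denom == 0.0:
        return float("nan")
    return float(A[ok].sum()) / denom


def wc_components(alt_a, n_a, alt_b, n_b):
    """Per-site (numerator, denominator) arrays for the Weir-Cockerham ratio."""
    aa = np.asarray(alt_a, dtype=float)
    na = np.asarray(n_a, dtype=float)
    ab = np.asarray(alt_b, dtype=float)
    nb = np.asarray(n_b, dtype=float)
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        pa, pb = aa / na, ab / nb
        n_tot = na + nb
        n_bar = n_tot / r
        n_c = (n_tot - (na**2 + nb**2) / n_tot) / (r - 1)
        p_bar = (aa + ab) / n_tot
        msp = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / (r - 1)
        msg = (na * pa * (1 - pa) + nb * pb * (1 - pb)) / (n_tot - r)
        num = msp - msg
        den = msp + (n_c - 1) * msg
    bad = (na < 2) | (nb < 2)
    return np.where(bad, np.nan, num), np.where(bad, np.nan, den)


def rod(pi_ancestral: float, pi_derived: float) -> float:
    """Reduction of diversity: 1 - pi_derived / pi_ancestral.

    NaN (undefined) when the ancestral diversity is 0; negative inputs are an
    error.  A complete sweep in the derived population gives 1.
    """
    if pi_ancestral < 0 or pi_derived < 0:
        raise DataError("pi values must be nonnegative")
    if pi_ancestral == 0:
        return float("nan")
    return 1.0 - pi_derived / pi_ancestral


_FST_FUNCS = {"hudson": hudson_components, "wc": wc_components}


def window_stats_table(
    vm: VariantMatrix,
    manifest: PopulationManifest,
    regions: list[GeneRegion],
    window_bp: int = 1000,
    step_bp: int = 100,
    fst_estimator: str = "hudson",
) -> list[WindowStats]:
    """One :class:`WindowStats` per sliding window per gene region.

    Carries pi for the three populations, F_ST for the wild-local and
    local-improved contrasts, and both ROD statistics
    (ROD_domesticated = 1 - pi_local/pi_wild, ROD_breeding = 1 - pi_improved/pi_local).
    Regions without overlapping variants yield windows with n_sites = 0,
    pi = 0 and undefined (NaN) F_ST/ROD.
    """
    if fst_estimator not in _FST_FUNCS:
        raise ConfigError(f"unknown F_ST estimator {fst_estimator!r}")
    comp = _FST_FUNCS[fst_estimator]
    pops = ("wild", "local", "improved")
    counts = {p: allele_counts(vm, manifest, p) for p in pops}
    pis = {p: site_pi(counts[p][0], counts[p][1]) for p in pops}
    fst_nd = {
        f"{a}_{b}": comp(counts[a][0], counts[a][1], counts[b][0], counts[b][1])
        for a, b in POP_PAIRS
    }
    pos0 = vm.pos - 1
    out: list[WindowStats] = []
    for region in regions:
        on_chrom = np.flatnonzero(
            (vm.chrom == region.chrom)
            & (pos0 >= region.analysis_start - 1)
            & (pos0 < region.analysis_end)
        )
        rpos = pos0[on_chrom]  # sorted within a chromosome
        for w in make_windows(region, window_bp, step_bp):
            lo, hi = np.searchsorted(rpos, [w.start, w.end])
            idx = on_chrom[lo:hi]
            pi_w = {
                p: float(np.nansum(np.atleast_1d(pis[p])[idx])) / w.length for p in pops
            }
            fst_w = {}
            for key, (num, den) in fst_nd.items():
                n_i = np.atleast_1d(num)[idx]
                d_i = np.atleast_1d(den)[idx]
                ok = ~np.isnan(n_i)
                sd = float(d_i[ok].sum()) if ok.any() else 0.0
                fst_w[key] = float(n_i[ok].sum()) / sd if sd != 0.0 else float("nan")
            out.append(
                WindowStats(
                    window=w,
                    n_sites=len(idx),
                    pi=pi_w,
                    fst=fst_w,
                    rod_domesticated=rod(pi_w["wild"], pi_w["local"]),
                    rod_breeding=rod(pi_w["local"], pi_w["improved"]),
                )
            )
    return out


def stats_to_frame(stats: list[WindowStats]):
    """Flatten WindowStats into a pandas DataFrame (one row per window)."""
    import pandas as pd

    rows = []
    for s in stats:
        rows.append(
            {
                "gene_id": s.window.gene_id,
                "chrom": s.window.chrom,
                "start": s.window.start,
                "end": s.window.end,
                "n_sites": s.n_sites,
                "pi_wild": s.pi["wild"],
                "pi_local": s.pi["local"],
                "pi_improved": s.pi["improved"],
                "fst_wild_local": s.fst["wild_local"],
                "fst_local_improved": s.fst["local_improved"],
                "rod_domesticated": s.rod_domesticated,
                "rod_breeding": s.rod_breeding,
            }
        )
    return pd.DataFrame(rows)
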
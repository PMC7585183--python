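"""Allele-aware transcription-factor-binding-site gain/loss prediction.

Each candidate regulatory variant is represented by a 60-bp window centered on
the mutation site, once with the reference allele and once with the alternate
allele (indels change the alt window length accordingly).  Both windows are
scanned on both strands with JASPAR-format position weight matrices; a motif
counts as present when any offset reaches the relative-score threshold
(default 0.80, the common JASPAR-scan convention).  Presence/absence is per
matrix identity, so a motif that merely shifts position is neither lost nor
gained.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs

from sweepscan.errors import ConfigError, DataError, ParseError

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PFM:
    """Position frequency matrix: 4 x L base counts (rows A, C, G, T)."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise DataError(f"{self.matrix_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise DataError(f"{self.matrix_id}: empty motif")
        if (self.counts < 0).any():
            raise DataError(f"{self.matrix_id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise DataError(f"{self.matrix_id}: a column has zero total count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWM:
    """Log2-odds matrix derived from a PFM with pseudocount and background."""

    matrix_id: str
    tf_name: str
    matrix: np.ndarray  # 4 x L log2 odds
    max_score: float
    min_score: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        bases = "ACGT"
        return "".join(bases[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class TFBSHit:
    """One motif occurrence in a scanned window."""

    matrix_id: str
    strand: str  # '+' or '-'
    offset: int  # 0-based start in the window, on the + strand
    score: float
    rel_score: float


@dataclass
class TFBSDelta:
    """Motif presence difference between reference- and alternate-allele windows."""

    chrom: str
    pos: int
    ref: str
    alt: str
    hits_ref: set[str]
    hits_alt: set[str]
    best_rel: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def lost(self) -> set[str]:
        return self.hits_ref - self.hits_alt

    @property
    def gained(self) -> set[str]:
        return self.hits_alt - self.hits_ref


def load_pfms(path: str | os.PathLike, min_length: int = 4) -> list[PFM]:
    """Parse a JASPAR-format PFM text file (">ID NAME" header, 4 count rows).

    Database matrices shorter than ``min_length`` (default 4) are rejected as
    malformed; programmatically built PFMs have no such floor.
    """
    path = os.fspath(path)
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # Bio raises bare Exception on ragged rows
            raise ParseError(f"{path}: {exc}") from exc
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            try:
                pfm = PFM(m.matrix_id or m.name, m.name or "", counts)
            except DataError as exc:
                raise ParseError(f"{path}: {exc}") from exc
            if pfm.length < min_length:
                raise ParseError(
                    f"{path}: matrix {pfm.matrix_id} shorter than {min_length} bp"
                )
            out.append(pfm)
    return out


def pfm_to_pwm(
    pfm: PFM,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> PWM:
    """Log2-odds transform with a background-weighted pseudocount.

    entry(b, j) = log2( (count(b,j) + pseudocount * bg(b))
                        / (column_total(j) + pseudocount) / bg(b) ).
    max_score / min_score are the sums of column maxima / minima; the
    consensus sequence attains max_score.
    """
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be > 0")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError("background must be 4 positive probabilities summing to 1")
    totals = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    matrix = np.log2(probs / bg[:, None])
    return PWM(
        matrix_id=pfm.matrix_id,
        tf_name=pfm.tf_name,
        matrix=matrix,
        max_score=float(matrix.max(axis=0).sum()),
        min_score=float(matrix.min(axis=0).sum()),
    )


@dataclass(frozen=True)
class AlleleWindows:
    """The reference- and alternate-allele scan windows for one variant."""

    ref: str
    alt: str
    truncated: bool = False


def allele_window_sequences(
    variant: tuple[str, int, str, str], genome, window_bp: int = 60, flank5: int = 30
) -> AlleleWindows:
    """Variant-centered scan windows: 30 bp of 5' flank + allele + 3' fill to 60 bp.

    The reference window is exactly ``window_bp`` long (the genome substring
    around the site); the alternate window is the same flanks with the
    alternate allele substituted, so its length is 60 - len(ref) + len(alt)
    for indels.  Windows are truncated (and flagged) at contig ends.
    """
    chrom, pos, ref, alt = variant
    seq = genome[chrom]
    contig = seq if isinstance(seq, str) else str(seq[:])
    contig_len = len(contig)
    p0 = pos - 1
    if not (0 <= p0 < contig_len):
        raise DataError(f"position {chrom}:{pos} outside contig")
    genome_ref = contig[p0 : p0 + len(ref)].upper()
    if genome_ref != ref.upper():
        raise DataError(
            f"{chrom}:{pos}: reference allele {ref!r} does not match genome {genome_ref!r}"
        )
    left_start = max(0, p0 - flank5)
    left = contig[left_start:p0].upper()
    right_len = max(window_bp - flank5 - len(ref), 0)
    right_end = min(contig_len, p0 + len(ref) + right_len)
    right = contig[p0 + len(ref) : right_end].upper()
    truncated = len(left) < flank5 or len(right) < right_len
    return AlleleWindows(
        ref=left + ref.upper() + right,
        alt=left + alt.upper() + right,
        truncated=truncated,
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_ROW.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _scores_one_strand(rows: np.ndarray, pwm: PWM) -> np.ndarray:
    """Raw score at every offset; ambiguity (N) positions contribute 0."""
    L = pwm.length
    n = len(rows) - L + 1
    if n <= 0:
        return np.zeros(0)
    scores = np.zeros(n)
    for j in range(L):
        r = rows[j : j + n]
        col = np.where(r >= 0, pwm.matrix[np.clip(r, 0, 3), j], 0.0)
        scores += col
    return scores


def scan_pwm(window: str, pwm: PWM, min_rel_score: float = 0.80) -> list[TFBSHit]:
    """All motif occurrences with relative score >= threshold, both strands.

    Relative score = (score - min_score) / (max_score - min_score); reverse-
    strand scanning scores the reverse complement, with hit offsets reported
    in the coordinates of the forward window.
    """
    if not 0 < min_rel_score <= 1:
        raise ConfigError("min_rel_score must lie in (0, 1]")
    span = pwm.max_score - pwm.min_score
    if span <= 0:
        raise DataError(f"{pwm.matrix_id}: degenerate PWM (max == min)")
    hits: list[TFBSHit] = []
    n_fwd = len(window) - pwm.length + 1
    for strand, seq in (("+", window), ("-", window.translate(_COMPLEMENT)[::-1])):
        rows = _encode(seq)
        scores = _scores_one_strand(rows, pwm)
        for off, sc in enumerate(scores):
            rel = (sc - pwm.min_score) / span
            if rel >= min_rel_score:
                fwd_off = off if strand == "+" else n_fwd - 1 - off
                hits.append(TFBSHit(pwm.matrix_id, strand, fwd_off, float(sc), float(rel)))
    return hits


def tfbs_change(
    variant: tuple[str, int, str, str],
    pfms: list[PFM],
    genome,
    min_rel_score: float = 0.80,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> TFBSDelta:
    """Motifs lost/gained between the reference- and alternate-allele windows."""
    windows = allele_window_sequences(variant, genome)
    hits_ref: set[str] = set()
    hits_alt: set[str] = set()
    best: dict[str, tuple[float, float]] = {}
    for pfm in pfms:
        pwm = pfm_to_pwm(pfm, pseudocount, background)
        h_ref = scan_pwm(windows.ref, pwm, min_rel_score)
        h_alt = scan_pwm(windows.alt, pwm, min_rel_score)
        if h_ref:
            hits_ref.add(pfm.matrix_id)
        if h_alt:
            hits_alt.add(pfm.matrix_id)
        if h_ref or h_alt:
            best[pfm.matrix_id] = (
                max((h.rel_score for h in h_ref), default=0.0),
                max((h.rel_score for h in h_alt), default=0.0),
            )
    chrom, pos, ref, alt = variant
    return TFBSDelta(chrom, pos, ref, alt, hits_ref, hits_alt, best)
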
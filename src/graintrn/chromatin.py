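"""Promoter-proximal accessible chromatin: peak-to-gene assignment, PWM
scanning, footprint support, motif-count dynamics and background-matched
TF-activity deviation scores.

A pACR (promoter-proximal accessible chromatin region) is any peak
intersecting the strand-aware window [tss-3000, tss+1000) of a gene. Motif
scanning scores log2 odds against a uniform 0.25 background on both
strands; a hit is any window reaching ``threshold_frac`` of the matrix's
maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._utils import overlap_len, rng_for
from .dynamics import _promoter_window
from .io import PWM, GenomeAnnotation, IntervalSet

__all__ = [
    "MotifHit",
    "ActivityMatrix",
    "assign_promoter_peaks",
    "scan_pwm",
    "scan_promoter_peaks",
    "mark_footprint_support",
    "footprint_depletion_score",
    "motif_count_by_stage",
    "tf_activity_deviation",
]

_SEQ_CODE = {c: i for i, c in enumerate("ACGTN")}


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    peak: str
    gene_id: str
    chrom: str
    offset: int  # hit start, chromosome frame, 0-based
    strand: str
    score: float  # log-odds bits
    span: int = 0  # motif length in bp
    footprint_supported: bool = False

    @property
    def end(self) -> int:
        return self.offset + self.span


@dataclass
class ActivityMatrix:
    """Motif x sample deviation z-scores with their raw deviations."""

    z: pd.DataFrame
    raw: pd.DataFrame
    n_background: int
    seed: int


def assign_promoter_peaks(annotation: GenomeAnnotation, peaks: IntervalSet,
                          up: int = 3000, down: int = 1000) -> dict[str, list[str]]:
    """Map gene -> names of peaks intersecting its promoter window.

    The window is strand-aware: [tss-up, tss+down) for ``+`` genes and the
    mirror image for ``-`` genes; windows reaching past the chromosome
    start are clipped to 0. A peak may serve several genes.
    """
    trees: dict[str, IntervalTree] = {}
    for row in peaks:
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end), str(row.name))
    out: dict[str, list[str]] = {}
    for gene in annotation.genes:
        lo, hi = _promoter_window(gene, up, down)
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        names = [iv.data for iv in sorted(tree.overlap(lo, hi))]
        if names:
            out[gene.gene_id] = names
    return out


def _encode(sequence: str) -> np.ndarray:
    return np.fromiter((_SEQ_CODE.get(c, 4) for c in sequence.upper()),
                       dtype=np.int8, count=len(sequence))


def scan_pwm(sequence: str, pwm: PWM, threshold_frac: float = 0.8) -> list[MotifHit]:
    """Scan one DNA string on both strands.

    Window score = sum_j log2(p[base_j, j] / 0.25); a reverse-strand hit is
    the same window scored against the reverse complement, reported at the
    same forward-frame offset. Windows containing N are skipped. Offsets
    are relative to ``sequence``; peak/gene fields are left blank.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    L = pwm.length
    n = len(sequence)
    if n < L:
        return []
    lom = pwm.log_odds()  # 4 x L
    # reverse-complement matrix: complement rows (A<->T, C<->G), reverse cols
    lom_rc = lom[::-1, ::-1]
    codes = _encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    has_n = (windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    cols = np.arange(L)
    fwd = lom[safe, cols].sum(axis=1)
    rev = lom_rc[safe, cols].sum(axis=1)
    cutoff = threshold_frac * pwm.max_score()
    hits = []
    for off in np.nonzero(~has_n & ((fwd >= cutoff) | (rev >= cutoff)))[0]:
        if fwd[off] >= cutoff:
            hits.append(MotifHit(pwm.motif_id, "", "", "", int(off), "+",
                                 float(fwd[off]), span=L))
        if rev[off] >= cutoff:
            hits.append(MotifHit(pwm.motif_id, "", "", "", int(off), "-",
                                 float(rev[off]), span=L))
    return hits


def scan_promoter_peaks(genome: dict[str, str], peaks: IntervalSet,
                        pwms: list[PWM], promoter_map: dict[str, list[str]],
                        threshold_frac: float = 0.8) -> list[MotifHit]:
    """Scan every promoter-assigned peak with every PWM.

    Emits one hit per (motif occurrence, gene served by the peak), with
    offsets in the chromosome frame.
    """
    peak_rows = {str(r.name): r for r in peaks}
    genes_of_peak: dict[str, list[str]] = {}
    for gene, names in promoter_map.items():
        for name in names:
            genes_of_peak.setdefault(name, []).append(gene)
    hits: list[MotifHit] = []
    for name in sorted(genes_of_peak):
        row = peak_rows[name]
        seq = genome[str(row.chrom)][int(row.start): int(row.end)]
        for pwm in pwms:
            for h in scan_pwm(seq, pwm, threshold_frac):
                for gene in sorted(genes_of_peak[name]):
                    hits.append(replace(h, peak=name, gene_id=gene,
                                        chrom=str(row.chrom),
                                        offset=int(row.start) + h.offset))
    return hits


def mark_footprint_support(hits: list[MotifHit], footprints: IntervalSet,
                           min_overlap_frac: float = 1.0) -> list[MotifHit]:
    """Flag hits whose span lies (to at least ``min_overlap_frac`` of its
    length) within some single footprint interval."""
    trees: dict[str, IntervalTree] = {}
    for row in footprints:
        trees.setdefault(str(row.chrom), IntervalTree()).addi(
            int(row.start), int(row.end))
    out = []
    for h in hits:
        tree = trees.get(h.chrom)
        supported = False
        if tree is not None and h.span > 0:
            span = h.span
            best = max((overlap_len(h.offset, h.offset + span, iv.begin, iv.end)
                        for iv in tree.overlap(h.offset, h.offset + span)),
                       default=0)
            supported = best / span >= min_overlap_frac
        out.append(replace(h, footprint_supported=supported))
    return out


def footprint_depletion_score(cut_counts, core: tuple[int, int],
                              flank_width: int) -> float:
    """Simple protection score of a candidate footprint: mean flanking
    cut-site density over (mean core density + 1). Higher = more protected."""
    if flank_width <= 0:
        raise ValueError("flank_width must be > 0")
    x = np.asarray(cut_counts, dtype=float)
    s, e = core
    if s - flank_width < 0 or e + flank_width > x.size or s >= e:
        raise ValueError("core +/- flank out of bounds")
    flank = np.concatenate([x[s - flank_width: s], x[e: e + flank_width]])
    return float(flank.mean() / (x[s:e].mean() + 1.0))


def motif_count_by_stage(hits: list[MotifHit],
                         stage_peaks: dict[str, IntervalSet],
                         gene_subset: set[str],
                         stages: list[str] | None = None) -> pd.Series:
    """Count hits (of genes in ``gene_subset``) whose span lies fully inside
    a peak accessible at each stage."""
    stages = list(stage_peaks) if stages is None else stages
    unknown = [s for s in stages if s not in stage_peaks]
    if unknown:
        raise KeyError(f"unknown stage label(s): {unknown}")
    sub = [h for h in hits if h.gene_id in gene_subset]
    counts = {}
    for stage in stages:
        trees: dict[str, IntervalTree] = {}
        for row in stage_peaks[stage]:
            trees.setdefault(str(row.chrom), IntervalTree()).addi(
                int(row.start), int(row.end))
        n = 0
        for h in sub:
            tree = trees.get(h.chrom)
            if tree is None:
                continue
            if any(iv.begin <= h.offset and h.offset + h.span <= iv.end
                   for iv in tree.overlap(h.offset, h.offset + h.span)):
                n += 1
        counts[stage] = n
    return pd.Series(counts, name="motif_hits")


def tf_activity_deviation(peak_counts: pd.DataFrame,
                          motif_membership: dict[str, list[str]],
                          n_background: int = 50, n_bins: int = 10,
                          seed: int = 0) -> ActivityMatrix:
    """Background-matched accessibility deviation z-scores per motif and
    sample (a chromVAR-style statistic).

    For motif m with member peak set S, expected counts in sample s are
    (sum of mean-accessibility fractions over S) x total counts of s; the
    raw deviation is (observed - expected) / expected. Each member peak is
    then resampled ``n_background`` times from its mean-accessibility
    decile bin, and z = (raw - mean(raw_bg)) / sd(raw_bg). When the
    background spread is zero, z is 0 if raw equals the background mean
    and NaN (flagged undefined) otherwise.
    """
    X = peak_counts.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("peak counts must be non-negative")
    peak_index = {p: i for i, p in enumerate(peak_counts.index)}
    rowsum = X.sum(axis=1)
    colsum = X.sum(axis=0)
    grand = X.sum()
    frac = rowsum / grand

    bins = pd.qcut(frac, min(n_bins, len(set(frac))), labels=False,
                   duplicates="drop")
    bins = np.asarray(bins)
    bin_members = {b: np.nonzero(bins == b)[0] for b in np.unique(bins)}

    rng = rng_for(seed, "activity")

    def _raw(idx: np.ndarray) -> np.ndarray:
        expected = frac[idx].sum() * colsum
        if np.all(expected == 0):
            raise ValueError("motif with zero expected counts")
        observed = X[idx].sum(axis=0)
        return np.divide(observed - expected, expected,
                         out=np.zeros_like(expected), where=expected > 0)

    z_rows, raw_rows, index = [], [], []
    for motif in sorted(motif_membership):
        members = [peak_index[p] for p in motif_membership[motif]
                   if p in peak_index]
        if not members:
            continue
        idx = np.asarray(members)
        raw = _raw(idx)
        bg = np.empty((n_background, X.shape[1]))
        for b in range(n_background):
            sampled = np.array([
                bin_members[bins[i]][rng.integers(len(bin_members[bins[i]]))]
                for i in idx])
            bg[b] = _raw(sampled)
        mu, sd = bg.mean(axis=0), bg.std(axis=0, ddof=1)
        z = np.full_like(raw, np.nan)
        ok = sd > 1e-10  # spread below fp noise counts as degenerate
        z[ok] = (raw[ok] - mu[ok]) / sd[ok]
        z[~ok & np.isclose(raw, mu, atol=1e-10)] = 0.0
        z_rows.append(z)
        raw_rows.append(raw)
        index.append(motif)
    cols = list(peak_counts.columns)
    return ActivityMatrix(z=pd.DataFrame(z_rows, index=index, columns=cols),
                          raw=pd.DataFrame(raw_rows, index=index, columns=cols),
                          n_background=n_background, seed=seed)
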
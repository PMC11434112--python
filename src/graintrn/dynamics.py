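"""Expression dynamics: normalization, filtering, temporal clustering,
variability, homoeolog-triad balance, and expression-epigenome correlation.

Conventions follow common practice for polyploid developmental
transcriptomics: TPM within-sample normalization; a gene is "expressed" if
it reaches 0.5 TPM in at least one sample; temporal clustering runs on
z-scaled stage-mean profiles; triad balance is the nearest of seven fixed
centroids in the (A, B, D) relative-expression simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._utils import derive_seed, overlap_len, zscale
from .io import ExpressionMatrix, GenomeAnnotation, IntervalSet

__all__ = [
    "normalize_tpm",
    "filter_expressed",
    "cluster_temporal_profiles",
    "ClusterModel",
    "compute_cv",
    "triad_relative_expression",
    "classify_triad",
    "TRIAD_CENTROIDS",
    "expression_mark_correlation",
    "CorrelationRecord",
]

# Seven reference points of the triad-balance classification, in tie-break
# order: the balanced centre, single-homoeolog dominance, and
# single-homoeolog suppression (the remaining two share the signal).
TRIAD_CENTROIDS: list[tuple[str, tuple[float, float, float]]] = [
    ("balanced", (1 / 3, 1 / 3, 1 / 3)),
    ("A-dominant", (1.0, 0.0, 0.0)),
    ("B-dominant", (0.0, 1.0, 0.0)),
    ("D-dominant", (0.0, 0.0, 1.0)),
    ("A-suppressed", (0.0, 0.5, 0.5)),
    ("B-suppressed", (0.5, 0.0, 0.5)),
    ("D-suppressed", (0.5, 0.5, 0.0)),
]


def normalize_tpm(counts: ExpressionMatrix, lengths: dict[str, float]) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and gene lengths.

    TPM_gs = (count_gs / length_g) / sum_g'(count_g's / length_g') * 1e6,
    so every sample column sums to one million.
    """
    if counts.unit != "count":
        raise ValueError("normalize_tpm expects a count matrix")
    lens = pd.Series({g: float(lengths[g]) for g in counts.row_ids})
    if (lens <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.values.div(lens, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        raise ValueError("all-zero sample column")
    return ExpressionMatrix(rate.div(colsum, axis=1) * 1e6, unit="TPM",
                            sample_meta=counts.sample_meta)


def filter_expressed(expr: ExpressionMatrix, threshold: float = 0.5) -> list[str]:
    """Genes reaching ``threshold`` TPM in at least one sample (inclusive)."""
    if expr.unit != "TPM":
        raise ValueError("filter_expressed expects TPM")
    keep = expr.values.max(axis=1) >= threshold
    return list(expr.values.index[keep])


@dataclass
class ClusterModel:
    k: int
    assignments: dict[str, int]
    centroids: np.ndarray  # k x n_stages, z-profile space
    seed: int
    inertia: float


def cluster_temporal_profiles(expr: ExpressionMatrix, genes: list[str] | None,
                              k: int, seed: int = 0, n_init: int = 10) -> ClusterModel:
    """k-means over z-scaled stage-mean expression profiles.

    Replicates are averaged per stage first; genes with zero variance
    across stages are excluded with a warning (their z-profile is
    undefined).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    stage_mean = expr.stage_means()
    if genes is not None:
        stage_mean = stage_mean.loc[[g for g in genes if g in stage_mean.index]]
    sd = stage_mean.std(axis=1, ddof=0)
    flat = stage_mean.index[sd == 0]
    if len(flat):
        warnings.warn(f"{len(flat)} zero-variance genes excluded from clustering")
        stage_mean = stage_mean.drop(index=flat)
    profiles = zscale(stage_mean.to_numpy(), axis=1)
    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=derive_seed(seed, "kmeans")).fit(profiles)
    assignments = {g: int(c) for g, c in zip(stage_mean.index, km.labels_)}
    return ClusterModel(k=k, assignments=assignments,
                        centroids=km.cluster_centers_, seed=seed,
                        inertia=float(km.inertia_))


def compute_cv(values) -> float:
    """Coefficient of variation: sample standard deviation (n-1) over mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def triad_relative_expression(expr: ExpressionMatrix, annotation: GenomeAnnotation,
                              triad_id: str, samples: list[str] | None = None,
                              min_total: float = 0.5):
    """Relative (a, b, d) contribution of each homoeolog to its triad.

    Per-gene value is the mean TPM over the requested samples (all samples
    by default). Returns ``((a, b, d), expressed)`` where ``expressed`` is
    False when the triad total falls below ``min_total`` TPM.
    """
    members = annotation.triad_members(triad_id)
    for m in members:
        if m.gene_id not in expr.values.index:
            raise ValueError(f"triad member {m.gene_id} missing from matrix")
    cols = samples if samples is not None else expr.samples
    vals = np.array([expr.values.loc[m.gene_id, cols].mean() for m in members])
    total = vals.sum()
    if total < min_total:
        return (np.nan, np.nan, np.nan), False
    a, b, d = (vals / total).tolist()
    return (a, b, d), True


def classify_triad(rel) -> str:
    """Nearest-centroid balance category of an (a, b, d) simplex point.

    Ties go to the earlier centroid in the fixed order balanced,
    A/B/D-dominant, A/B/D-suppressed.
    """
    rel = np.asarray(rel, dtype=float)
    if rel.shape != (3,) or (rel < 0).any() or abs(rel.sum() - 1) > 1e-6:
        raise ValueError("rel must be 3 non-negative components summing to 1")
    best, best_d = None, np.inf
    for name, centroid in TRIAD_CENTROIDS:
        d = float(np.sum((rel - np.asarray(centroid)) ** 2))
        if d < best_d - 1e-15:
            best, best_d = name, d
    return best


@dataclass
class CorrelationRecord:
    gene_id: str
    r: float
    n: int
    p: float
    defined: bool = True


def _promoter_window(gene, up: int, down: int) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, clipped at 0."""
    if gene.strand == "+":
        lo, hi = gene.tss - up, gene.tss + down
    else:
        lo, hi = gene.tss - down + 1, gene.tss + up + 1
    return max(0, lo), hi


def expression_mark_correlation(expr: ExpressionMatrix, mark: ExpressionMatrix,
                                annotation: GenomeAnnotation, peaks: IntervalSet,
                                window: tuple[int, int] = (3000, 1000)
                                ) -> list[CorrelationRecord]:
    """Pearson correlation between each gene's stage-mean expression and the
    summed mark CPM over peaks intersecting its promoter window.

    Both series are z-scaled per gene before correlating (Pearson r is
    invariant to this; the z-scaling mirrors how the profiles are
    compared). Genes without any promoter peak are omitted; zero-variance
    series yield a flagged, undefined record.
    """
    up, down = window
    expr_stage = expr.stage_means()
    mark_stage = mark.stage_means()
    common = [s for s in expr_stage.columns if s in mark_stage.columns]
    if len(common) < 3:
        raise ValueError("need at least 3 shared stages")
    peaks_by_chrom = peaks.by_chrom()

    records = []
    for gene in annotation.genes:
        if gene.gene_id not in expr_stage.index:
            continue
        lo, hi = _promoter_window(gene, up, down)
        sub = peaks_by_chrom.get(gene.chrom)
        if sub is None:
            continue
        hit_names = [str(r.name) for r in sub.itertuples(index=False)
                     if overlap_len(lo, hi, r.start, r.end) > 0
                     and str(r.name) in mark_stage.index]
        if not hit_names:
            continue
        x = zscale(expr_stage.loc[gene.gene_id, common].to_numpy())
        y = zscale(mark_stage.loc[hit_names, common].sum(axis=0).to_numpy())
        if np.all(x == 0) or np.all(y == 0):
            records.append(CorrelationRecord(gene.gene_id, np.nan, len(common),
                                             np.nan, defined=False))
            continue
        r, p = stats.pearsonr(x, y)
        records.append(CorrelationRecord(gene.gene_id, float(r), len(common), float(p)))
    return records
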
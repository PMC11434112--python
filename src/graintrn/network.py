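"""Footprint-anchored TF->target network inference.

The network is assembled from three evidence layers:

1. *TF->motif*: each TF carries one binding motif (best similarity hit, or
   an explicit map; families may share motifs).
2. *Motif->target*: a gene is a candidate target of a motif when the motif
   has a footprint-supported occurrence inside one of the gene's
   promoter-proximal accessible regions.
3. *Co-expression weight*: per target, a random-forest ensemble predicts
   the target's z-scaled expression from all other TFs' profiles; a TF's
   importance (normalized variance reduction, summing to 1 per target) is
   the edge weight.

A TF's footprint evidence is declared informative by a one-sided
Mann-Whitney U test of its weights over footprint-positive vs
footprint-negative genes (BH-adjusted across TFs). The final network keeps
footprint-supported candidate edges of significant TFs whose weight clears
a per-TF quantile, signed by the Pearson correlation of the pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from ._utils import bh_adjust, derive_seed, zscale
from .chromatin import MotifHit
from .dynamics import ClusterModel
from .io import ExpressionMatrix

__all__ = [
    "TfMotifMap",
    "TRNEdge",
    "TRN",
    "map_tf_to_motif",
    "derive_motif_targets",
    "genie3_importance",
    "footprint_conditioned_significance",
    "assemble_trn",
    "cluster_regulation_enrichment",
    "ClusterRegulationMatrix",
]


@dataclass
class TfMotifMap:
    mapping: dict[str, str]
    provenance: str  # "supplied" | "best_hit"
    scores: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, tf_id: str) -> str:
        return self.mapping[tf_id]

    def __contains__(self, tf_id: str) -> bool:
        return tf_id in self.mapping


@dataclass(frozen=True)
class TRNEdge:
    tf_id: str
    target_id: str
    weight: float
    sign: int  # +1 / -1 / 0 (dead-zone)
    r: float
    footprint_supported: bool = True


@dataclass
class TRN:
    edges: list[TRNEdge]
    tf_significance: dict[str, tuple[float, float, float]]  # (U, p, q)
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def tfs(self) -> set[str]:
        return {e.tf_id for e in self.edges}

    @property
    def nodes(self) -> set[str]:
        return {e.tf_id for e in self.edges} | {e.target_id for e in self.edges}

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.tf_id, e.target_id) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.tf_id, e.target_id, e.weight, e.sign, e.r, e.footprint_supported)
             for e in self.edges],
            columns=["tf", "target", "weight", "sign", "r", "footprint_supported"])


def map_tf_to_motif(similarities: pd.DataFrame | dict[str, str]) -> TfMotifMap:
    """Assign one motif per TF.

    ``similarities`` is either an explicit {tf: motif} map (validated and
    passed through) or a long-form table with columns tf, motif, score, in
    which case each TF takes its argmax-similarity motif, ties broken by
    lexicographically smaller motif id.
    """
    if isinstance(similarities, dict):
        return TfMotifMap(dict(similarities), provenance="supplied")
    df = similarities
    required = {"tf", "motif", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"similarity table needs columns {sorted(required)}")
    mapping, scores = {}, {}
    for tf, sub in df.groupby("tf"):
        sub = sub.sort_values(["score", "motif"], ascending=[False, True])
        best = sub.iloc[0]
        mapping[str(tf)] = str(best["motif"])
        scores[str(tf)] = float(best["score"])
    return TfMotifMap(mapping, provenance="best_hit", scores=scores)


def derive_motif_targets(hits: list[MotifHit],
                         promoter_map: dict[str, list[str]],
                         require_footprint: bool = True) -> dict[str, set[str]]:
    """Motif -> set of genes with a qualifying hit in one of their pACRs."""
    peak_genes = {g: set(ps) for g, ps in promoter_map.items()}
    out: dict[str, set[str]] = {}
    for h in hits:
        if require_footprint and not h.footprint_supported:
            continue
        if h.gene_id and h.peak in peak_genes.get(h.gene_id, ()):  # consistency
            out.setdefault(h.motif_id, set()).add(h.gene_id)
    return out


def genie3_importance(expr: ExpressionMatrix, tf_ids: set[str],
                      n_trees: int = 1000, mtry_rule: str = "sqrt",
                      seed: int = 0) -> pd.DataFrame:
    """Tree-ensemble importance of each TF for each gene (tf x gene).

    For every target gene a random forest predicts its z-scaled expression
    from the z-scaled expression of all *other* TFs; importances are
    normalized per target to sum to 1 (self-edges fixed at 0).
    Zero-variance targets get an all-zero column.
    """
    if expr.shape[1] < 6:
        raise ValueError("need at least 6 samples")
    genes = list(expr.values.index)
    tfs = sorted(set(tf_ids))
    missing = [t for t in tfs if t not in expr.values.index]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing}")
    Z = pd.DataFrame(zscale(expr.values.to_numpy(), axis=1),
                     index=genes, columns=expr.samples)
    tf_mat = Z.loc[tfs].to_numpy().T  # samples x tfs
    max_features = ("sqrt" if mtry_rule == "sqrt"
                    else 1.0 if mtry_rule == "all" else mtry_rule)

    W = np.zeros((len(tfs), len(genes)))
    col_of = {g: i for i, g in enumerate(genes)}
    for gi, gene in enumerate(sorted(genes)):
        y = Z.loc[gene].to_numpy()
        if np.all(y == 0):
            continue  # zero-variance target, flagged by its all-zero column
        use = [j for j, tf in enumerate(tfs) if tf != gene]
        if not use:
            continue
        X = tf_mat[:, use]
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features=max_features,
            random_state=derive_seed(seed, "genie3", gi), n_jobs=1)
        rf.fit(X, y)
        imp = rf.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        W[use, col_of[gene]] = imp
    return pd.DataFrame(W, index=tfs, columns=genes)


def _mannwhitney_one_sided(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """One-sided (pos > neg) Mann-Whitney U; exact when both groups are
    small and tie-free, normal approximation with tie correction otherwise."""
    exact = len(pos) <= 20 and len(neg) <= 20 and \
        len(np.unique(np.concatenate([pos, neg]))) == len(pos) + len(neg)
    res = stats.mannwhitneyu(pos, neg, alternative="greater",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def footprint_conditioned_significance(weights: pd.DataFrame | None,
                                       motif_targets: dict[str, set[str]],
                                       tf_motif: TfMotifMap,
                                       alpha: float = 0.05,
                                       min_group: int = 5,
                                       stat: str = "pearson",
                                       expr: ExpressionMatrix | None = None
                                       ) -> dict[str, tuple[float, float, float]]:
    """Per-TF test of whether footprint evidence predicts transcriptional
    coupling.

    Splits the genes into footprint-positive (candidate targets of the
    TF's motif) and footprint-negative groups and applies a one-sided
    Mann-Whitney U (positive > negative) to the TF's per-gene statistic:
    ``stat="pearson"`` uses |Pearson r| between TF and gene expression
    (default; robust to collinearity among TF profiles over few stages),
    ``stat="weight"`` uses the tree-ensemble importance row. p-values are
    BH-adjusted across the tested TFs. TFs with fewer than ``min_group``
    genes on either side are skipped and reported as untested.
    """
    if stat == "pearson":
        if expr is None:
            raise ValueError("stat='pearson' requires expr")
        tf_list = sorted(t for t in tf_motif.mapping
                         if t in expr.values.index)
        genes = list(expr.values.index)
        Z = zscale(expr.values.to_numpy(), axis=1)
        n = Z.shape[1]
        tf_rows = {t: Z[genes.index(t)] for t in tf_list}
        score_of = {t: pd.Series(np.abs(Z @ tf_rows[t]) / n, index=genes)
                    for t in tf_list}
    elif stat == "weight":
        if weights is None:
            raise ValueError("stat='weight' requires a weight matrix")
        tf_list = [t for t in weights.index if t in tf_motif]
        score_of = {t: weights.loc[t] for t in tf_list}
    else:
        raise ValueError(f"unknown stat {stat!r}")

    tested, results = [], {}
    for tf in tf_list:
        targets = motif_targets.get(tf_motif[tf], set())
        row = score_of[tf]
        pos = row[[g for g in row.index if g in targets and g != tf]]
        neg = row[[g for g in row.index if g not in targets and g != tf]]
        if len(pos) < min_group or len(neg) < min_group:
            warnings.warn(f"TF {tf}: group too small, untested")
            continue
        U, p = _mannwhitney_one_sided(pos.to_numpy(), neg.to_numpy())
        tested.append(tf)
        results[tf] = (U, p)
    qs = bh_adjust(np.array([results[tf][1] for tf in tested]))
    return {tf: (results[tf][0], results[tf][1], float(q))
            for tf, q in zip(tested, qs)}


def assemble_trn(weights: pd.DataFrame, motif_targets: dict[str, set[str]],
                 tf_motif: TfMotifMap, expr: ExpressionMatrix,
                 tf_significance: dict[str, tuple[float, float, float]],
                 alpha: float = 0.05, weight_quantile: float = 0.75,
                 r_min: float = 0.1) -> TRN:
    """Final signed, footprint-flagged network.

    An edge (tf, target) is retained iff the target is a
    footprint-supported candidate of the TF's motif, the TF's footprint
    test passes q <= alpha, and the edge weight reaches the TF's
    ``weight_quantile`` over all genes. Signs come from the Pearson
    correlation of the pair across samples, with |r| < r_min mapping to 0.
    """
    Zexpr = expr.values
    edges = []
    for tf in sorted(weights.index):
        if tf not in tf_motif:
            continue
        sig = tf_significance.get(tf)
        if sig is None or sig[2] > alpha:
            continue
        cut = float(weights.loc[tf].quantile(weight_quantile))
        for target in sorted(motif_targets.get(tf_motif[tf], set())):
            if target == tf:
                continue
            if target not in weights.columns:
                raise ValueError(f"target {target} absent from weight matrix")
            w = float(weights.loc[tf, target])
            if w < cut:
                continue
            r = float(np.corrcoef(Zexpr.loc[tf], Zexpr.loc[target])[0, 1])
            sign = 0 if abs(r) < r_min else (1 if r > 0 else -1)
            edges.append(TRNEdge(tf, target, w, sign, r, True))
    return TRN(edges=edges, tf_significance=dict(tf_significance),
               thresholds={"alpha": alpha, "weight_quantile": weight_quantile,
                           "r_min": r_min})


@dataclass
class ClusterRegulationMatrix:
    counts: pd.DataFrame  # k x k edge counts, TF cluster -> target cluster
    p: pd.DataFrame
    q: pd.DataFrame


def cluster_regulation_enrichment(trn: TRN, clusters: ClusterModel
                                  ) -> ClusterRegulationMatrix:
    """Edge counts between temporal clusters with hypergeometric
    over-representation tests.

    Cell (i, j) counts edges from cluster-i TFs to cluster-j targets.
    Enrichment per cell: drawing the edges of cluster-i TFs from the pool
    of all clustered edges, is cluster j over-represented among their
    targets? Upper-tail hypergeometric p, BH-adjusted across the k^2 cells.
    """
    if clusters.k < 2:
        raise ValueError("need k >= 2 clusters")
    lab = clusters.assignments
    clustered = [(e.tf_id, e.target_id) for e in trn.edges
                 if e.tf_id in lab and e.target_id in lab]
    dropped = len(trn.edges) - len(clustered)
    if dropped:
        warnings.warn(f"{dropped} edges with unclustered endpoints dropped")
    k = clusters.k
    counts = np.zeros((k, k), dtype=int)
    for tf, tg in clustered:
        counts[lab[tf], lab[tg]] += 1
    N = counts.sum()
    pvals = np.ones((k, k))
    for i in range(k):
        n_i = counts[i].sum()  # edges out of cluster-i TFs
        for j in range(k):
            M_j = counts[:, j].sum()  # edges into cluster-j targets
            if N > 0 and n_i > 0 and M_j > 0:
                pvals[i, j] = stats.hypergeom.sf(counts[i, j] - 1, N, M_j, n_i)
    qvals = bh_adjust(pvals.ravel()).reshape(k, k)
    idx = pd.RangeIndex(k, name="tf_cluster")
    cols = pd.RangeIndex(k, name="target_cluster")
    return ClusterRegulationMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        p=pd.DataFrame(pvals, index=idx, columns=cols),
        q=pd.DataFrame(qvals, index=idx, columns=cols))
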
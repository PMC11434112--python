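"""Candidate-regulator triage and population statistics.

Core TFs are the union of *structure TFs* (hubs of the TF-TF subnetwork,
judged against a degree-preserving permutation null) and *direct
regulators* (TFs with at least one network edge into the starch- or
seed-storage-protein gene sets). Novel core TFs are then triaged by three
independent evidence layers: overlap with 3-Mb windows around GWAS
signals, expression-phenotype correlation groups in an accession panel at
two stages (grain-size and grain-quality trait classes), and
mutant-line phenotype flags. The high-confidence set is the conjunction.

The population layer also provides the haplotype workflow (variant
filtering, haplotype grouping, Welch trait tests, breeding-era frequency
trends) and SNP density inside promoter-proximal accessible chromatin.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust, rng_for
from .io import GenomeAnnotation, GenotypeTable, IntervalSet
from .network import TRN

__all__ = [
    "identify_structure_tfs",
    "identify_direct_regulators",
    "classify_regulators",
    "gwas_overlap",
    "expression_phenotype_groups",
    "build_triage_table",
    "select_high_confidence",
    "filter_variants",
    "HaplotypeGroups",
    "assign_haplotypes",
    "haplotype_trait_test",
    "haplotype_frequency_trend",
    "snp_density_in_peaks",
]

GROUP_LABELS = ("GS-DAP10", "GQ-DAP10", "GS-DAP20", "GQ-DAP20")


# ---------------------------------------------------------------------------
# core-TF identification

def identify_structure_tfs(trn: TRN, tf_ids: set[str] | None = None,
                           n_perm: int = 1000, alpha: float = 0.05,
                           seed: int = 0) -> set[str]:
    """TFs with significantly high out-degree in the TF-TF subnetwork.

    The null preserves each node's *total* degree: edge stubs are
    re-paired uniformly at random with random orientation (self-loops
    permitted), and the empirical p of a TF is the fraction of
    permutations reaching its observed out-degree, BH-adjusted.
    """
    tf_ids = trn.tfs if tf_ids is None else set(tf_ids)
    sub = [(e.tf_id, e.target_id) for e in trn.edges if e.target_id in tf_ids]
    if not sub:
        warnings.warn("TF-TF subnetwork is empty")
        return set()
    nodes = sorted({u for u, _ in sub} | {v for _, v in sub})
    node_idx = {n: i for i, n in enumerate(nodes)}
    out_deg = np.zeros(len(nodes), dtype=int)
    total_deg = np.zeros(len(nodes), dtype=int)
    for u, v in sub:
        out_deg[node_idx[u]] += 1
        total_deg[node_idx[u]] += 1
        total_deg[node_idx[v]] += 1
    stubs = np.repeat(np.arange(len(nodes)), total_deg)
    rng = rng_for(seed, "structure")
    exceed = np.zeros(len(nodes), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(stubs)
        heads = perm[0::2]
        perm_out = np.bincount(heads, minlength=len(nodes))
        assert np.array_equal(
            np.bincount(perm, minlength=len(nodes)), total_deg)
        exceed += perm_out >= out_deg
    pvals = (1 + exceed) / (n_perm + 1)
    qvals = bh_adjust(pvals)
    return {nodes[i] for i in range(len(nodes))
            if qvals[i] <= alpha and nodes[i] in {u for u, _ in sub}}


def identify_direct_regulators(trn: TRN, starch_genes: set[str],
                               ssp_genes: set[str]) -> set[str]:
    """TFs with at least one network edge into the storage-gene sets."""
    storage = set(starch_genes) | set(ssp_genes)
    if not storage:
        raise ValueError("storage gene sets are empty")
    return {e.tf_id for e in trn.edges if e.target_id in storage}


def classify_regulators(trn: TRN, starch_genes: set[str],
                        ssp_genes: set[str]) -> pd.DataFrame:
    """Per-TF storage-target counts, enrichment class and sign mode.

    A TF is starch-/SSP-enriched when its target count strictly exceeds
    the median over TFs with any storage edge; "dual" needs both. The mode
    summarizes edge signs into the storage sets: uniformly positive,
    uniformly negative, strictly opposite between the two sets, or mixed.
    """
    starch_genes, ssp_genes = set(starch_genes), set(ssp_genes)
    rows = {}
    for e in trn.edges:
        rec = rows.setdefault(e.tf_id, {"starch_signs": [], "ssp_signs": []})
        if e.target_id in starch_genes:
            rec["starch_signs"].append(e.sign)
        if e.target_id in ssp_genes:
            rec["ssp_signs"].append(e.sign)
    tfs = [tf for tf, rec in rows.items()
           if rec["starch_signs"] or rec["ssp_signs"]]
    n_starch = {tf: len(rows[tf]["starch_signs"]) for tf in tfs}
    n_ssp = {tf: len(rows[tf]["ssp_signs"]) for tf in tfs}
    med_starch = float(np.median(list(n_starch.values()))) if tfs else 0.0
    med_ssp = float(np.median(list(n_ssp.values()))) if tfs else 0.0

    out = []
    for tf in sorted(tfs):
        s_enr = n_starch[tf] > med_starch
        p_enr = n_ssp[tf] > med_ssp
        cls = ("dual" if s_enr and p_enr else "starch-enriched" if s_enr
               else "SSP-enriched" if p_enr else "neither")
        signs = rows[tf]["starch_signs"] + rows[tf]["ssp_signs"]
        s_signs, p_signs = set(rows[tf]["starch_signs"]), set(rows[tf]["ssp_signs"])
        if signs and all(s == 1 for s in signs):
            mode = "positive"
        elif signs and all(s == -1 for s in signs):
            mode = "negative"
        elif (len(s_signs) == 1 and len(p_signs) == 1
              and 0 not in s_signs | p_signs
              and next(iter(s_signs)) == -next(iter(p_signs))):
            mode = "opposite"
        else:
            mode = "mixed"
        out.append((tf, n_starch[tf], n_ssp[tf], cls, mode))
    return pd.DataFrame(out, columns=["tf_id", "n_starch_targets",
                                      "n_ssp_targets", "class", "mode"]
                        ).set_index("tf_id")


# ---------------------------------------------------------------------------
# triage evidence layers

def gwas_overlap(annotation: GenomeAnnotation, tfs: set[str],
                 signals: pd.DataFrame,
                 window_total: int = 3_000_000) -> pd.DataFrame:
    """Flag TFs whose gene interval intersects a ``window_total`` window
    centered on any GWAS signal.

    Returns a boolean frame indexed by TF with an ``any`` column plus one
    column per trait class when signals carry a ``trait_class`` label.
    """
    half = window_total // 2
    classes = (sorted(signals["trait_class"].unique())
               if "trait_class" in signals.columns else [])
    flags = pd.DataFrame(False, index=sorted(tfs), columns=["any", *classes])
    for sig in signals.itertuples(index=False):
        if sig.chrom not in annotation.chrom_sizes:
            warnings.warn(f"signal on unknown chromosome {sig.chrom}, skipped")
            continue
        lo, hi = sig.pos - half, sig.pos + half
        for tf in flags.index:
            g = annotation.by_id.get(tf)
            if g is None or g.chrom != sig.chrom:
                continue
            if g.start < hi and lo < g.end:
                flags.loc[tf, "any"] = True
                if classes:
                    flags.loc[tf, getattr(sig, "trait_class")] = True
    return flags


def expression_phenotype_groups(panels, traits: pd.DataFrame,
                                trait_classes: dict[str, str],
                                tfs: set[str], alpha: float = 0.05
                                ) -> dict[str, set[str]]:
    """Membership of each TF in the four stage x trait-class groups.

    A TF joins group ``{class}-{stage}`` when its panel expression at that
    stage has a two-sided Pearson p <= alpha with at least one trait of
    the class; accessions with missing trait values are excluded pairwise.
    """
    groups: dict[str, set[str]] = {tf: set() for tf in tfs}
    for stage, panel in panels.items():
        shared = [a for a in panel.samples if a in traits.index]
        if len(shared) < 10:
            raise ValueError(f"stage {stage}: fewer than 10 shared accessions")
        for tf in sorted(tfs):
            if tf not in panel.values.index:
                continue
            x_all = panel.values.loc[tf, shared].to_numpy(dtype=float)
            if np.std(x_all) == 0:
                continue  # zero-variance expression, untestable this stage
            for trait, cls in trait_classes.items():
                y_all = traits.loc[shared, trait].to_numpy(dtype=float)
                ok = ~np.isnan(y_all)
                if ok.sum() < 3 or np.std(x_all[ok]) == 0 or np.std(y_all[ok]) == 0:
                    continue
                _, p = stats.pearsonr(x_all[ok], y_all[ok])
                if p <= alpha:
                    groups[tf].add(f"{cls}-{stage}")
    return groups


def build_triage_table(tfs: list[str], structure: set[str], direct: set[str],
                       known_tfs: set[str], gwas_flags: pd.DataFrame,
                       groups: dict[str, set[str]],
                       mutant_status: dict[str, str],
                       group_min: int = 2) -> pd.DataFrame:
    """Assemble per-TF evidence flags and the high-confidence call."""
    rows = []
    for tf in sorted(tfs):
        is_core = tf in structure or tf in direct
        is_novel = is_core and tf not in known_tfs
        gwas_hit = bool(gwas_flags.loc[tf, "any"]) if tf in gwas_flags.index else False
        tf_groups = sorted(groups.get(tf, set()))
        status = mutant_status.get(tf, "no_line")
        high = (is_novel and gwas_hit and len(tf_groups) >= group_min
                and status == "altered")
        rows.append((tf, is_core, is_novel, gwas_hit, ",".join(tf_groups),
                     len(tf_groups), status, high))
    return pd.DataFrame(rows, columns=[
        "tf_id", "is_core", "is_novel", "gwas_hit", "groups", "n_groups",
        "mutant_status", "high_confidence"]).set_index("tf_id")


def select_high_confidence(triage: pd.DataFrame, group_min: int = 2) -> set[str]:
    """Novel TFs supported by all three evidence layers."""
    mask = (triage["is_novel"] & triage["gwas_hit"]
            & (triage["n_groups"] >= group_min)
            & (triage["mutant_status"] == "altered"))
    return set(triage.index[mask])


# ---------------------------------------------------------------------------
# population genetics

def filter_variants(genotypes: GenotypeTable, max_missing: float = 0.5,
                    min_maf: float = 0.05, max_het: float = 0.5) -> GenotypeTable:
    """Retain variants with missing rate < max_missing, minor-allele
    frequency > min_maf and heterozygote fraction < max_het (all strict,
    frequencies computed over non-missing calls)."""
    calls = genotypes.calls
    n = calls.shape[1]
    missing = np.isnan(calls)
    miss_rate = missing.mean(axis=1)
    n_called = n - missing.sum(axis=1)
    with np.errstate(invalid="ignore"):
        p_alt = np.nansum(calls, axis=1) / (2 * np.maximum(n_called, 1))
        maf = np.minimum(p_alt, 1 - p_alt)
        het = np.nansum(calls == 1, axis=1) / np.maximum(n_called, 1)
    keep = (miss_rate < max_missing) & (n_called > 0) & (maf > min_maf) & (het < max_het)
    return GenotypeTable(genotypes.variants[keep].reset_index(drop=True),
                         calls[keep], genotypes.accessions)


@dataclass
class HaplotypeGroups:
    assignment: dict[str, str]  # accession -> "Hap1", ...
    sites: list[int]  # variant row indices used
    n_haplotypes: int
    members: dict[str, list[str]] = field(default_factory=dict)
    tuples: dict[str, tuple] = field(default_factory=dict)


def assign_haplotypes(genotypes: GenotypeTable,
                      region: tuple[str, int, int]) -> HaplotypeGroups:
    """Group accessions by their dosage tuple over the region's variants.

    Accessions with any missing or heterozygous call in the region are
    excluded (inbred-line assumption). Haplotypes are labelled Hap1,
    Hap2, ... by descending carrier count, ties by lexicographic tuple.
    """
    chrom, start, end = region
    pos = genotypes.variants["pos"].to_numpy()
    in_region = ((genotypes.variants["chrom"] == chrom).to_numpy()
                 & (pos >= start) & (pos < end))
    sites = np.nonzero(in_region)[0]
    if sites.size == 0:
        raise ValueError(f"no variants in region {chrom}:{start}-{end}")
    sub = genotypes.calls[sites]
    usable = ~(np.isnan(sub) | (sub == 1)).any(axis=0)
    n_dropped = (~usable).sum()
    if n_dropped:
        warnings.warn(f"{n_dropped} accessions with missing/het calls excluded")
    tuples: dict[tuple, list[str]] = {}
    for ai, acc in enumerate(genotypes.accessions):
        if usable[ai]:
            tuples.setdefault(tuple(int(d) for d in sub[:, ai]), []).append(acc)
    ordered = sorted(tuples, key=lambda t: (-len(tuples[t]), t))
    assignment, members, tup_of = {}, {}, {}
    for i, t in enumerate(ordered, start=1):
        label = f"Hap{i}"
        members[label] = tuples[t]
        tup_of[label] = t
        for acc in tuples[t]:
            assignment[acc] = label
    return HaplotypeGroups(assignment, [int(s) for s in sites], len(ordered),
                           members, tup_of)


def haplotype_trait_test(groups: HaplotypeGroups, trait: pd.Series,
                         min_n: int = 3) -> pd.DataFrame:
    """Welch two-sample t-test of the trait for every haplotype pair."""
    rows = []
    for ha, hb in itertools.combinations(sorted(groups.members), 2):
        a = trait.reindex(groups.members[ha]).dropna().to_numpy(dtype=float)
        b = trait.reindex(groups.members[hb]).dropna().to_numpy(dtype=float)
        if len(a) < min_n or len(b) < min_n:
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                continue  # degenerate, no finite statistic
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((ha, hb, float(a.mean() - b.mean()), float(t), float(p),
                     len(a), len(b)))
    return pd.DataFrame(rows, columns=["hap_a", "hap_b", "delta_mean",
                                       "t", "p", "n_a", "n_b"])


def haplotype_frequency_trend(groups: HaplotypeGroups,
                              era_labels: pd.Series) -> pd.DataFrame:
    """Haplotype carrier frequencies per era; rows sum to 1, empty eras
    omitted."""
    labels = sorted(groups.members)
    rows = {}
    for era, accs in era_labels.groupby(era_labels):
        assigned = [a for a in accs.index if a in groups.assignment]
        if not assigned:
            continue
        counts = pd.Series([groups.assignment[a] for a in assigned]
                           ).value_counts()
        rows[era] = [counts.get(h, 0) / len(assigned) for h in labels]
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def snp_density_in_peaks(genotypes: GenotypeTable, peaks: IntervalSet,
                         gene_peak_map: dict[str, list[str]]) -> pd.Series:
    """Variants per kb of promoter-proximal accessible chromatin, per gene.

    Each variant is counted once even when overlapping pACRs repeat it;
    genes without pACRs (or with zero total pACR length) are omitted.
    """
    peak_iv = {str(r.name): (str(r.chrom), int(r.start), int(r.end))
               for r in peaks}
    chrom_arr = genotypes.variants["chrom"].to_numpy()
    pos_arr = genotypes.variants["pos"].to_numpy()
    out = {}
    for gene, names in gene_peak_map.items():
        total_bp = 0
        hit = np.zeros(len(pos_arr), dtype=bool)
        for name in names:
            if name not in peak_iv:
                continue
            chrom, s, e = peak_iv[name]
            total_bp += e - s
            hit |= (chrom_arr == chrom) & (pos_arr >= s) & (pos_arr < e)
        if total_bp == 0:
            warnings.warn(f"gene {gene}: zero pACR length, omitted")
            continue
        out[gene] = hit.sum() / (total_bp / 1000.0)
    return pd.Series(out, name="snps_per_kb")
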
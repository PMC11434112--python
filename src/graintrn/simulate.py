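"""Synthetic miniature study generator with known ground truth.

Emulates the data layout of a developing-endosperm multi-omics study in
hexaploid wheat: three homoeologous chromosomes (A/B/D subgenomes) carrying
gene triads and a set of transcription factors; promoter-proximal accessible
chromatin with TF footprints; a planted signed TF->target network driving an
8-stage x 3-replicate expression time course; activating/repressive
chromatin-mark signal coupled to expression; and a ~100-accession panel with
cis-variant-driven expression variation, trait values, GWAS signal
positions, and a mutant-line flag table.

Everything is deterministic under a root seed; each sub-generator draws
from an independently derived stream so one stage can be regenerated
without perturbing another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from ._utils import rng_for, zscale

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimDataset",
    "simulate_genome",
    "simulate_timeseries_expression",
    "simulate_marks",
    "simulate_population",
    "simulate_all",
    "write_dataset",
]

# canonical sampling days of the time course
_DAP_DAYS = [0, 2, 4, 6, 8, 12, 16, 22]
_CHROMS = {"A": "chr1A", "B": "chr1B", "D": "chr1D"}
_GS_TRAITS = ["grain_length", "grain_width"]
_GQ_TRAITS = ["gluten_content", "sedimentation_volume"]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults describe the reference condition used throughout the test
    suite: 200 triads (600 homoeologs) plus 20 TFs, 8 stages x 3
    replicates, regulatory effect size ``effect_beta`` = 0.8 (log2 units
    per TF standard deviation) against replicate noise ``noise_sd`` = 0.3,
    and a 100-accession population panel.
    """

    n_triads: int = 200
    n_tfs: int = 20
    targets_per_tf: int = 8
    n_stages: int = 8
    n_reps: int = 3
    n_accessions: int = 100
    noise_sd: float = 0.3
    effect_beta: float = 0.8
    decoy_motif_rate: float = 0.1
    mark_expr_corr: float = 0.7
    seed: int = 0
    # genome layout
    gene_span: int = 2000
    gene_spacing: int = 20000
    peak_len: int = 400
    motif_len: int = 8
    chrom_size: int | None = None  # override; error if too short
    # network topology
    tf_tf_edge_prob: float = 0.3
    max_regulators: int = 3
    # intrinsic (non-regulatory) temporal amplitude of non-TF genes
    target_bump_amp: tuple[float, float] = (0.2, 2.0)
    # population layer
    n_causal_tfs: int = 5
    n_neutral_variants: int = 200
    causal_variant_effect: float = 1.5
    trait_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_triads", "n_tfs", "targets_per_tf", "n_stages",
                     "n_reps", "n_accessions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if abs(self.mark_expr_corr) > 1:
            raise ValueError("|mark_expr_corr| must be <= 1")
        if self.n_causal_tfs > self.n_tfs:
            raise ValueError("n_causal_tfs cannot exceed n_tfs")

    @property
    def stage_labels(self) -> list[str]:
        days = list(_DAP_DAYS)
        while len(days) < self.n_stages:
            days.append(days[-1] + 6)
        return [f"DAP{d}" for d in days[: self.n_stages]]


@dataclass
class TruthSet:
    """Planted ground truth for every downstream recovery test."""

    network: list[tuple[str, str, int, float]]  # (tf, target, sign, beta)
    tf_motif: dict[str, str]
    causal_tfs: list[str] = field(default_factory=list)
    starch_genes: list[str] = field(default_factory=list)
    ssp_genes: list[str] = field(default_factory=list)
    tf_order: list[str] = field(default_factory=list)  # topological order
    causal_trait_genes: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    causal_variants: list[tuple[int, str, float]] = field(default_factory=list)

    def targets_of(self, tf_id: str) -> set[str]:
        return {t for f, t, _, _ in self.network if f == tf_id}

    def edge_set(self) -> set[tuple[str, str]]:
        return {(f, t) for f, t, _, _ in self.network}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        d["network"] = [tuple(e) for e in d["network"]]
        d["causal_variants"] = [tuple(v) for v in d["causal_variants"]]
        d["causal_trait_genes"] = {k: [tuple(g) for g in v]
                                   for k, v in d["causal_trait_genes"].items()}
        return cls(**d)


@dataclass
class SimDataset:
    """One complete simulated study."""

    config: SimConfig
    annotation: gio.GenomeAnnotation
    peaks: gio.IntervalSet
    footprints: gio.IntervalSet
    pwms: list[gio.PWM]
    genome: dict[str, str]
    truth: TruthSet
    expr: gio.ExpressionMatrix
    ac: gio.ExpressionMatrix
    me: gio.ExpressionMatrix
    panels: dict[str, gio.ExpressionMatrix]
    traits: pd.DataFrame
    genotypes: gio.GenotypeTable
    gwas_signals: pd.DataFrame
    mutant_flags: pd.DataFrame

    @property
    def peak_gene(self) -> dict[str, str]:
        return {row.name: row.name.removeprefix("peak_") for row in self.peaks}


def _promoter_peak_interval(gene: gio.Gene, cfg: SimConfig) -> tuple[int, int]:
    """A peak ~1.1-1.5 kb upstream of the TSS, strand-aware."""
    if gene.strand == "+":
        start = gene.tss - 1500
    else:
        start = gene.tss + 1500 - cfg.peak_len + 1
    start = max(0, start)
    return start, start + cfg.peak_len


def _random_consensus(rng: np.random.Generator, length: int, taken: set[str]) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    while True:
        s = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        rc = s.translate(comp)[::-1]
        if s not in taken and rc not in taken:
            taken.add(s)
            taken.add(rc)
            return s


def simulate_genome(config: SimConfig):
    """Generate annotation, peaks, footprints, PWMs, genome sequence and the
    planted regulatory truth.

    Every gene receives one promoter-proximal peak inside its
    [tss-3000, tss+1000) window. For each planted (tf, target) edge the TF
    motif consensus is embedded inside the target's peak and covered by a
    footprint interval; decoy consensi are embedded in non-target peaks
    without footprint cover at rate ``decoy_motif_rate``.
    """
    cfg = config
    rng = rng_for(cfg.seed, "genome")

    # --- gene catalogue -----------------------------------------------------
    genes_by_sub: dict[str, list[dict]] = {"A": [], "B": [], "D": []}
    for t in range(cfg.n_triads):
        for sub in "ABD":
            genes_by_sub[sub].append({
                "gene_id": f"g{t:04d}{sub}", "triad_id": f"tri{t:04d}",
                "is_tf": False, "subgenome": sub})
    tf_ids = [f"tf{k:02d}" for k in range(cfg.n_tfs)]
    for k, tf in enumerate(tf_ids):
        sub = "ABD"[k % 3]
        genes_by_sub[sub].append({"gene_id": tf, "triad_id": None,
                                  "is_tf": True, "subgenome": sub})

    genes: list[gio.Gene] = []
    chrom_sizes: dict[str, int] = {}
    margin = 5000
    for sub in "ABD":
        chrom = _CHROMS[sub]
        items = genes_by_sub[sub]
        order = rng.permutation(len(items))
        need = margin + len(items) * cfg.gene_spacing + margin
        size = cfg.chrom_size if cfg.chrom_size is not None else need
        if size < need:
            raise ValueError(
                f"chromosome size {size} too short for {len(items)} genes "
                f"(need {need})")
        chrom_sizes[chrom] = size
        for slot, idx in enumerate(order):
            info = items[idx]
            start = margin + slot * cfg.gene_spacing
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(gio.Gene(info["gene_id"], chrom, start,
                                  start + cfg.gene_span, strand,
                                  subgenome=sub, triad_id=info["triad_id"],
                                  is_tf=info["is_tf"]))
    genes.sort(key=lambda g: (g.chrom, g.start))
    annotation = gio.GenomeAnnotation(genes, chrom_sizes)

    # --- motifs -------------------------------------------------------------
    taken: set[str] = set()
    pwms, tf_motif, consensus = [], {}, {}
    for k, tf in enumerate(tf_ids):
        cons = _random_consensus(rng, cfg.motif_len, taken)
        counts = np.ones((4, cfg.motif_len))
        for j, base in enumerate(cons):
            counts["ACGT".index(base), j] = 12.0
        motif_id = f"M{k:02d}"
        pwms.append(gio.PWM.from_counts(motif_id, counts, tf_family=tf))
        tf_motif[tf] = motif_id
        consensus[tf] = cons

    # --- planted network ----------------------------------------------------
    tf_order = [tf_ids[i] for i in rng.permutation(cfg.n_tfs)]
    network: list[tuple[str, str, int, float]] = []
    n_regulators: dict[str, int] = {}
    for j, tf in enumerate(tf_order[1:], start=1):
        if rng.random() < cfg.tf_tf_edge_prob:
            reg = tf_order[int(rng.integers(0, j))]
            sign = 1 if rng.random() < 0.7 else -1
            network.append((reg, tf, sign, cfg.effect_beta))
            n_regulators[tf] = n_regulators.get(tf, 0) + 1
    non_tf = sorted(g.gene_id for g in genes if not g.is_tf)
    targets_by_tf: dict[str, set[str]] = {tf: set() for tf in tf_ids}
    for f, t_, _, _ in network:
        targets_by_tf[f].add(t_)
    for tf in tf_order:
        pool = [g for g in non_tf
                if n_regulators.get(g, 0) < cfg.max_regulators
                and g not in targets_by_tf[tf]]
        chosen = rng.choice(len(pool), size=min(cfg.targets_per_tf, len(pool)),
                            replace=False)
        for i in sorted(chosen):
            target = pool[int(i)]
            sign = 1 if rng.random() < 0.6 else -1
            network.append((tf, target, sign, cfg.effect_beta))
            targets_by_tf[tf].add(target)
            n_regulators[target] = n_regulators.get(target, 0) + 1

    causal_tfs = tf_ids[: cfg.n_causal_tfs]
    starch, ssp = [], []
    for i, tf in enumerate(causal_tfs):
        for j, tgt in enumerate(sorted({t for f, t, _, _ in network
                                        if f == tf and not t.startswith("tf")})):
            (starch if (i + j) % 2 == 0 else ssp).append(tgt)

    # --- genome sequence with embedded sites --------------------------------
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    seqs = {c: base_arr[rng.integers(0, 4, size=n)].copy()
            for c, n in sorted(chrom_sizes.items())}

    peak_records, fp_records = [], []
    peak_pos: dict[str, tuple[str, int, int]] = {}
    for g in genes:
        s, e = _promoter_peak_interval(g, cfg)
        e = min(e, chrom_sizes[g.chrom])
        peak_records.append((g.chrom, s, e, f"peak_{g.gene_id}", np.nan, "."))
        peak_pos[g.gene_id] = (g.chrom, s, e)

    cursor: dict[str, int] = {}

    def _embed(gene_id: str, motif_consensus: str, with_footprint: bool) -> None:
        chrom, ps, pe = peak_pos[gene_id]
        off = cursor.get(gene_id, 10)
        pos = ps + off
        if pos + cfg.motif_len + 4 > pe:
            return  # peak saturated; enough sites exist already
        cursor[gene_id] = off + cfg.motif_len + 8
        seqs[chrom][pos: pos + cfg.motif_len] = np.frombuffer(
            motif_consensus.encode(), dtype="S1")
        if with_footprint:
            fp_records.append((chrom, pos - 2, pos + cfg.motif_len + 2,
                               f"fp_{gene_id}_{pos}", np.nan, "."))

    for tf, target, _sign, _beta in network:
        _embed(target, consensus[tf], with_footprint=True)
    for g in genes:
        if rng.random() < cfg.decoy_motif_rate:
            others = [tf for tf in tf_ids if g.gene_id not in targets_by_tf[tf]]
            if others:
                decoy_tf = others[int(rng.integers(0, len(others)))]
                _embed(g.gene_id, consensus[decoy_tf], with_footprint=False)

    genome = {c: s.tobytes().decode() for c, s in seqs.items()}
    peaks = gio.IntervalSet(pd.DataFrame(peak_records, columns=gio.IntervalSet.COLUMNS))
    footprints = (gio.IntervalSet(pd.DataFrame(fp_records, columns=gio.IntervalSet.COLUMNS))
                  if fp_records else gio.IntervalSet.empty())
    truth = TruthSet(network=network, tf_motif=tf_motif, causal_tfs=causal_tfs,
                     starch_genes=sorted(set(starch)), ssp_genes=sorted(set(ssp)),
                     tf_order=tf_order)
    return annotation, peaks, footprints, pwms, genome, truth


def _bump(stage_idx: np.ndarray, mu: float, width: float) -> np.ndarray:
    return np.exp(-((stage_idx - mu) ** 2) / (2 * width**2))


def simulate_timeseries_expression(truth: TruthSet, annotation: gio.GenomeAnnotation,
                                   config: SimConfig) -> gio.ExpressionMatrix:
    """Planted-network time course: TFs follow smooth stage-shifted bumps;
    each target's log2 expression adds ``sign * beta * z(TF)`` per regulator
    plus Normal(0, noise_sd) replicate noise. Values are exponentiated and
    column-rescaled to TPM (each sample sums to 1e6)."""
    cfg = config
    rng = rng_for(cfg.seed, "timeseries")
    stages = cfg.stage_labels
    samples = [f"{st}_r{r + 1}" for st in stages for r in range(cfg.n_reps)]
    t = np.repeat(np.arange(cfg.n_stages, dtype=float), cfg.n_reps)

    gene_ids = [g.gene_id for g in annotation.genes]
    log2 = pd.DataFrame(0.0, index=gene_ids, columns=samples)

    regulators: dict[str, list[tuple[str, int, float]]] = {}
    for tf, target, sign, beta in truth.network:
        regulators.setdefault(target, []).append((tf, sign, beta))

    tf_set = set(annotation.tf_ids)
    order = [tf for tf in truth.tf_order if tf in tf_set] + \
            sorted(g for g in gene_ids if g not in tf_set)
    lo_amp, hi_amp = cfg.target_bump_amp
    for gid in order:
        if gid in tf_set:
            mu = rng.uniform(0, cfg.n_stages - 1)
            width = rng.uniform(1.0, 2.0)
            amp = rng.uniform(2.0, 4.0)
            base = rng.uniform(2.0, 5.0)
            prof = base + amp * _bump(t, mu, width)
            prof = prof + rng.normal(0, cfg.noise_sd / 2, size=len(samples))
        else:
            mu = rng.uniform(0, cfg.n_stages - 1)
            width = rng.uniform(1.0, 2.0)
            amp = rng.uniform(lo_amp, hi_amp)
            base = rng.uniform(2.0, 6.0)
            prof = base + amp * _bump(t, mu, width)
            prof = prof + rng.normal(0, cfg.noise_sd, size=len(samples))
        for tf, sign, beta in regulators.get(gid, []):
            prof = prof + sign * beta * zscale(log2.loc[tf].to_numpy())
        log2.loc[gid] = prof

    values = np.power(2.0, log2)
    values = values / values.sum(axis=0) * 1e6
    meta = pd.DataFrame({"stage": [s.rsplit("_", 1)[0] for s in samples],
                         "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples]})
    return gio.ExpressionMatrix(values, unit="TPM", sample_meta=meta)


def simulate_marks(expr: gio.ExpressionMatrix, peaks: gio.IntervalSet,
                   config: SimConfig):
    """Per-peak chromatin-mark CPM over stages: the activating mark tracks
    the host gene's stage-mean expression with correlation
    ``+mark_expr_corr``; the repressive mark with ``-mark_expr_corr``.

    Peak names are expected to encode their gene as ``peak_<gene_id>``
    (the layout :func:`simulate_genome` writes); peaks of genes absent from
    ``expr`` are skipped with a warning.
    """
    import warnings

    cfg = config
    rng = rng_for(cfg.seed, "marks")
    rho = cfg.mark_expr_corr
    stage_mean = expr.stage_means()
    stages = list(stage_mean.columns)

    rows_ac, rows_me, names = [], [], []
    for row in peaks:
        gid = str(row.name).removeprefix("peak_")
        if gid not in stage_mean.index:
            warnings.warn(f"peak {row.name}: no expression for gene {gid}, skipped")
            continue
        z = zscale(stage_mean.loc[gid].to_numpy())
        mix = np.sqrt(max(0.0, 1 - rho**2))
        ac = rho * z + mix * rng.standard_normal(len(stages))
        me = -rho * z + mix * rng.standard_normal(len(stages))
        rows_ac.append(np.maximum(100 + 30 * ac, 0.1))
        rows_me.append(np.maximum(100 + 30 * me, 0.1))
        names.append(str(row.name))
    ac_df = pd.DataFrame(rows_ac, index=names, columns=stages)
    me_df = pd.DataFrame(rows_me, index=names, columns=stages)
    ac_df = ac_df / ac_df.sum(axis=0) * 1e6
    me_df = me_df / me_df.sum(axis=0) * 1e6
    return (gio.ExpressionMatrix(ac_df, unit="CPM"),
            gio.ExpressionMatrix(me_df, unit="CPM"))


def simulate_population(truth: TruthSet, annotation: gio.GenomeAnnotation,
                        peaks: gio.IntervalSet, config: SimConfig):
    """Accession panel: a cis variant inside each TF's promoter peak shifts
    that TF's expression additively; planted-network effects propagate to
    targets; traits load on the causal TFs' DAP20 expression; one GWAS
    signal lands within 1 Mb of each causal TF; mutant flags mark causal
    TFs altered with probability 0.9 (others 0.1).

    Returns (panels, traits, genotypes, gwas_signals, mutant_flags) and
    fills ``truth.causal_variants`` / ``truth.causal_trait_genes``.
    """
    cfg = config
    if cfg.n_accessions < 10:
        raise ValueError("n_accessions must be >= 10 for usable correlations")
    rng = rng_for(cfg.seed, "population")
    accessions = [f"acc{i + 1:03d}" for i in range(cfg.n_accessions)]

    peak_pos = {str(r.name).removeprefix("peak_"): (r.chrom, r.start, r.end)
                for r in peaks}
    bases = "ACGT"

    # --- variants -----------------------------------------------------------
    var_rows, effects = [], {}  # gene -> (variant_index, effect)
    causal_variants = []
    for tf in sorted(annotation.tf_ids):
        chrom, ps, pe = peak_pos[tf]
        pos = int(rng.integers(ps, pe))
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        idx = len(var_rows)
        var_rows.append((chrom, pos, ref, alt))
        effects[tf] = (idx, cfg.causal_variant_effect)
        causal_variants.append((idx, tf, cfg.causal_variant_effect))
    chroms = sorted(annotation.chrom_sizes)
    for _ in range(cfg.n_neutral_variants):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        if rng.random() < 0.5 and len(peaks):
            row = peaks.df.iloc[int(rng.integers(0, len(peaks)))]
            chrom = row["chrom"]
            pos = int(rng.integers(row["start"], row["end"]))
        else:
            pos = int(rng.integers(0, annotation.chrom_sizes[chrom]))
        ref = bases[int(rng.integers(0, 4))]
        alt = bases[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        var_rows.append((chrom, pos, ref, alt))
    variants = pd.DataFrame(var_rows, columns=["chrom", "pos", "ref", "alt"])

    n_var = len(var_rows)
    freqs = rng.uniform(0.15, 0.5, size=n_var)
    calls = (rng.random((n_var, cfg.n_accessions)) < freqs[:, None]).astype(float) * 2
    het = rng.random(calls.shape) < 0.03
    calls[het] = 1.0
    miss = rng.random(calls.shape) < 0.02
    calls[miss] = np.nan
    genotypes = gio.GenotypeTable(variants, calls, accessions)

    # --- panel expression (two stages) --------------------------------------
    regulators: dict[str, list[tuple[str, int, float]]] = {}
    for tf, target, sign, beta in truth.network:
        regulators.setdefault(target, []).append((tf, sign, beta))
    gene_ids = [g.gene_id for g in annotation.genes]
    tf_set = set(annotation.tf_ids)
    order = [tf for tf in truth.tf_order if tf in tf_set] + \
            sorted(g for g in gene_ids if g not in tf_set)
    base_level = {gid: rng.uniform(2.0, 6.0) for gid in sorted(gene_ids)}

    panels: dict[str, gio.ExpressionMatrix] = {}
    for stage in ("DAP10", "DAP20"):
        log2 = pd.DataFrame(0.0, index=gene_ids, columns=accessions)
        for gid in order:
            prof = np.full(cfg.n_accessions, base_level[gid])
            if gid in effects:
                idx, eff = effects[gid]
                dose = calls[idx].copy()
                dose[np.isnan(dose)] = 2 * freqs[idx]
                prof = prof + eff * dose / 2.0
            for tf, sign, beta in regulators.get(gid, []):
                prof = prof + sign * beta * zscale(log2.loc[tf].to_numpy())
            prof = prof + rng.normal(0, cfg.noise_sd, size=cfg.n_accessions)
            log2.loc[gid] = prof
        vals = np.power(2.0, log2)
        vals = vals / vals.sum(axis=0) * 1e6
        panels[stage] = gio.ExpressionMatrix(vals, unit="TPM")

    # --- traits -------------------------------------------------------------
    trait_names = _GS_TRAITS + _GQ_TRAITS
    loadings: dict[str, list[tuple[str, float]]] = {t: [] for t in trait_names}
    for i, tf in enumerate(truth.causal_tfs):
        loadings[_GS_TRAITS[i % 2]].append((tf, 0.7))
        loadings[_GQ_TRAITS[i % 2]].append((tf, 0.7))
    truth.causal_trait_genes = loadings
    truth.causal_variants = causal_variants

    expr20 = panels["DAP20"].values
    traits = pd.DataFrame(index=pd.Index(accessions, name="accession"))
    eras = ["landrace", "1950-1980", "1980-2000", "post-2000"]
    traits["era"] = [eras[int(i)] for i in rng.integers(0, len(eras),
                                                        size=cfg.n_accessions)]
    for trait in trait_names:
        val = rng.normal(0, cfg.trait_noise_sd, size=cfg.n_accessions)
        for gene, w in loadings[trait]:
            val = val + w * zscale(expr20.loc[gene].to_numpy())
        traits[trait] = val

    # --- GWAS signals and mutant flags --------------------------------------
    sig_rows = []
    for i, tf in enumerate(truth.causal_tfs):
        g = annotation.by_id[tf]
        pos = int(np.clip(g.tss + rng.integers(-1_000_000, 1_000_001),
                          0, annotation.chrom_sizes[g.chrom] - 1))
        cls = "GS" if i % 2 == 0 else "GQ"
        trait = (_GS_TRAITS if cls == "GS" else _GQ_TRAITS)[i % 2]
        sig_rows.append((g.chrom, pos, trait, cls))
    for _ in range(2):  # unlinked decoy signals
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, annotation.chrom_sizes[chrom]))
        sig_rows.append((chrom, pos, _GS_TRAITS[0], "GS"))
    gwas_signals = pd.DataFrame(sig_rows, columns=["chrom", "pos", "trait",
                                                   "trait_class"])

    causal = set(truth.causal_tfs)
    status = []
    for tf in sorted(annotation.tf_ids):
        u = rng.random()
        if tf in causal:
            status.append("altered" if u < 0.9 else "normal")
        elif u < 0.1:
            status.append("altered")
        elif u < 0.2:
            status.append("no_line")
        else:
            status.append("normal")
    mutant_flags = pd.DataFrame({"tf_id": sorted(annotation.tf_ids),
                                 "status": status})
    return panels, traits, genotypes, gwas_signals, mutant_flags


def simulate_all(config: SimConfig) -> SimDataset:
    """Run every generator stage and bundle the results."""
    annotation, peaks, footprints, pwms, genome, truth = simulate_genome(config)
    expr = simulate_timeseries_expression(truth, annotation, config)
    ac, me = simulate_marks(expr, peaks, config)
    panels, traits, genotypes, gwas, mutants = simulate_population(
        truth, annotation, peaks, config)
    return SimDataset(config, annotation, peaks, footprints, pwms, genome,
                      truth, expr, ac, me, panels, traits, genotypes, gwas,
                      mutants)


def write_dataset(ds: SimDataset, outdir) -> Path:
    """Write the simulated study as a self-contained plain-text directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_fasta(ds.genome, out / "genome.fa")
    gio.write_gene_models(ds.annotation, out / "genes.gff3")
    gio.write_bed(ds.peaks, out / "peaks.bed")
    gio.write_bed(ds.footprints, out / "footprints.bed")
    gio.write_jaspar_pwm(ds.pwms, out / "motifs.jaspar")
    gio.write_matrix_tsv(ds.expr, out / "expr_timeseries.tsv")
    gio.write_matrix_tsv(ds.ac, out / "ac.tsv")
    gio.write_matrix_tsv(ds.me, out / "me.tsv")
    for stage, panel in ds.panels.items():
        gio.write_matrix_tsv(panel, out / f"panel_{stage}.tsv")
    ds.traits.to_csv(out / "traits.tsv", sep="\t", float_format="%.10g")
    gio.write_vcf_lite(ds.genotypes, out / "variants.vcf")
    ds.gwas_signals.to_csv(out / "gwas_signals.tsv", sep="\t", index=False)
    ds.mutant_flags.to_csv(out / "mutants.tsv", sep="\t", index=False)
    ds.truth.to_json(out / "truth.json")
    storage = pd.DataFrame(
        [(g, "starch") for g in ds.truth.starch_genes]
        + [(g, "ssp") for g in ds.truth.ssp_genes],
        columns=["gene_id", "set"])
    storage.to_csv(out / "storage_genes.tsv", sep="\t", index=False)
    classes = pd.DataFrame(
        [(t, "GS") for t in _GS_TRAITS] + [(t, "GQ") for t in _GQ_TRAITS],
        columns=["trait", "trait_class"])
    classes.to_csv(out / "trait_classes.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w") as fh:
        cfg = dataclasses.asdict(ds.config)
        cfg["target_bump_amp"] = list(cfg["target_bump_amp"])
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out
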
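"""End-to-end orchestration of the analysis stages over one config.

Stages read their inputs from ``input_dir`` (by default the directory the
``simulate`` stage writes) and leave TSV/JSON artifacts plus a JSON run
manifest in ``outdir``. Every stage derives its randomness from the single
config seed, so a re-run with the same config reproduces identical
artifacts byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import chromatin as chrom
from . import dynamics as dyn
from . import io as gio
from . import network as net
from . import simulate as sim
from . import triage as tri

__all__ = ["PipelineConfig", "run"]

STAGES = ("simulate", "dynamics", "chromatin", "trn", "triage")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unknown keys are rejected on load."""

    outdir: str = "run"
    input_dir: str | None = None  # defaults to <outdir>/data
    seed: int = 0
    # dynamics
    tpm_threshold: float = 0.5
    k: int = 6
    min_total: float = 0.5
    # chromatin
    window_up: int = 3000
    window_down: int = 1000
    threshold_frac: float = 0.8
    min_overlap_frac: float = 1.0
    n_background: int = 50
    n_bins: int = 10
    # trn
    n_trees: int = 1000
    alpha: float = 0.05
    weight_quantile: float = 0.75
    r_min: float = 0.1
    min_group: int = 5
    # triage
    window_total: int = 3_000_000
    group_min: int = 2
    n_perm: int = 1000
    max_missing: float = 0.5
    min_maf: float = 0.05
    max_het: float = 0.5
    # simulate stage
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def data_dir(self) -> Path:
        return Path(self.input_dir) if self.input_dir else Path(self.outdir) / "data"


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Inputs:
    """Lazy view of the (simulated or user-supplied) input directory."""

    def __init__(self, cfg: PipelineConfig):
        self.dir = cfg.data_dir
        missing = [n for n in ("genes.gff3", "peaks.bed", "expr_timeseries.tsv")
                   if not (self.dir / n).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing input file(s) in {self.dir}: {missing}")
        self.annotation = gio.read_gene_models(self.dir / "genes.gff3")
        self.peaks = gio.read_bed(self.dir / "peaks.bed")
        self.expr = gio.read_matrix_tsv(self.dir / "expr_timeseries.tsv", unit="TPM")

    def footprints(self):
        return gio.read_bed(self.dir / "footprints.bed")

    def pwms(self):
        return gio.read_jaspar_pwm(self.dir / "motifs.jaspar")

    def genome(self):
        return gio.read_fasta(self.dir / "genome.fa")

    def marks(self):
        return (gio.read_matrix_tsv(self.dir / "ac.tsv", unit="CPM"),
                gio.read_matrix_tsv(self.dir / "me.tsv", unit="CPM"))

    def panels(self):
        return {st: gio.read_matrix_tsv(self.dir / f"panel_{st}.tsv", unit="TPM")
                for st in ("DAP10", "DAP20")}

    def traits(self):
        return pd.read_csv(self.dir / "traits.tsv", sep="\t", index_col=0)

    def trait_classes(self):
        df = pd.read_csv(self.dir / "trait_classes.tsv", sep="\t")
        return dict(zip(df["trait"], df["trait_class"]))

    def storage_genes(self):
        df = pd.read_csv(self.dir / "storage_genes.tsv", sep="\t")
        return (set(df.loc[df["set"] == "starch", "gene_id"]),
                set(df.loc[df["set"] == "ssp", "gene_id"]))

    def genotypes(self):
        return gio.read_vcf_lite(self.dir / "variants.vcf")

    def gwas_signals(self):
        return pd.read_csv(self.dir / "gwas_signals.tsv", sep="\t")

    def mutants(self):
        df = pd.read_csv(self.dir / "mutants.tsv", sep="\t")
        return dict(zip(df["tf_id"], df["status"]))


def _stage_simulate(cfg: PipelineConfig) -> list[Path]:
    sim_kwargs = dict(cfg.sim)
    sim_kwargs.setdefault("seed", cfg.seed)
    if "target_bump_amp" in sim_kwargs:
        sim_kwargs["target_bump_amp"] = tuple(sim_kwargs["target_bump_amp"])
    ds = sim.simulate_all(sim.SimConfig(**sim_kwargs))
    out = sim.write_dataset(ds, cfg.data_dir)
    return sorted(out.iterdir())


def _stage_dynamics(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    inp = _Inputs(cfg)
    expressed = dyn.filter_expressed(inp.expr, cfg.tpm_threshold)
    clusters = dyn.cluster_temporal_profiles(inp.expr, expressed, cfg.k,
                                             seed=cfg.seed)
    written = []

    def _write(df: pd.DataFrame, name: str, **kw):
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.10g", **kw)
        written.append(path)

    _write(pd.DataFrame({"gene_id": expressed}), "expressed_genes.tsv", index=False)
    _write(pd.DataFrame(sorted(clusters.assignments.items()),
                        columns=["gene_id", "cluster"]),
           "clusters.tsv", index=False)

    cv_rows = [(g, dyn.compute_cv(inp.expr.values.loc[g].to_numpy()))
               for g in expressed
               if inp.expr.values.loc[g].mean() > 0]
    _write(pd.DataFrame(cv_rows, columns=["gene_id", "cv"]), "cv.tsv", index=False)

    triad_rows = []
    for triad_id in sorted(inp.annotation.triads):
        (a, b, d), ok = dyn.triad_relative_expression(
            inp.expr, inp.annotation, triad_id, min_total=cfg.min_total)
        cat = dyn.classify_triad((a, b, d)) if ok else "unexpressed"
        triad_rows.append((triad_id, a, b, d, cat))
    _write(pd.DataFrame(triad_rows, columns=["triad_id", "a", "b", "d",
                                             "category"]),
           "triad_balance.tsv", index=False)

    ac, me = inp.marks()
    for label, mark in (("ac", ac), ("me", me)):
        recs = dyn.expression_mark_correlation(
            inp.expr, mark, inp.annotation, inp.peaks,
            window=(cfg.window_up, cfg.window_down))
        _write(pd.DataFrame([(r.gene_id, r.r, r.n, r.p, r.defined)
                             for r in recs],
                            columns=["gene_id", "r", "n", "p", "defined"]),
               f"expr_{label}_correlation.tsv", index=False)
    return written


def _stage_chromatin(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    inp = _Inputs(cfg)
    promoter_map = chrom.assign_promoter_peaks(
        inp.annotation, inp.peaks, up=cfg.window_up, down=cfg.window_down)
    hits = chrom.scan_promoter_peaks(inp.genome(), inp.peaks, inp.pwms(),
                                     promoter_map, cfg.threshold_frac)
    hits = chrom.mark_footprint_support(hits, inp.footprints(),
                                        cfg.min_overlap_frac)
    written = []
    hits_df = pd.DataFrame(
        [(h.chrom, h.offset, h.end, h.motif_id, round(h.score * 100),
          h.strand, h.gene_id, h.peak, int(h.footprint_supported))
         for h in hits],
        columns=["chrom", "start", "end", "motif_id", "score_x100", "strand",
                 "gene_id", "peak", "footprint_supported"])
    path = outdir / "motif_hits.tsv"
    hits_df.to_csv(path, sep="\t", index=False)
    written.append(path)

    pmap_df = pd.DataFrame([(g, ",".join(ps)) for g, ps in
                            sorted(promoter_map.items())],
                           columns=["gene_id", "peaks"])
    path = outdir / "promoter_map.tsv"
    pmap_df.to_csv(path, sep="\t", index=False)
    written.append(path)

    ac, _ = inp.marks()
    membership = {}
    for h in hits:
        if h.footprint_supported:
            membership.setdefault(h.motif_id, set()).add(h.peak)
    membership = {m: sorted(ps) for m, ps in membership.items()}
    if membership:
        act = chrom.tf_activity_deviation(ac.values, membership,
                                          n_background=cfg.n_background,
                                          n_bins=cfg.n_bins, seed=cfg.seed)
        path = outdir / "tf_activity.tsv"
        act.z.to_csv(path, sep="\t", float_format="%.10g", index_label="motif")
        written.append(path)
    return written


def _stage_trn(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    inp = _Inputs(cfg)
    hits_df = pd.read_csv(outdir / "motif_hits.tsv", sep="\t")
    hits = [chrom.MotifHit(r.motif_id, r.peak, r.gene_id, r.chrom, r.start,
                           r.strand, r.score_x100 / 100.0, r.end - r.start,
                           bool(r.footprint_supported))
            for r in hits_df.itertuples(index=False)]
    pmap_df = pd.read_csv(outdir / "promoter_map.tsv", sep="\t")
    promoter_map = {r.gene_id: r.peaks.split(",")
                    for r in pmap_df.itertuples(index=False)}

    tf_ids = set(inp.annotation.tf_ids)
    tf_motif = net.map_tf_to_motif(
        {p.tf_family: p.motif_id for p in inp.pwms() if p.tf_family in tf_ids})
    motif_targets = net.derive_motif_targets(hits, promoter_map,
                                             require_footprint=True)
    weights = net.genie3_importance(inp.expr, tf_ids, n_trees=cfg.n_trees,
                                    seed=cfg.seed)
    significance = net.footprint_conditioned_significance(
        weights, motif_targets, tf_motif, alpha=cfg.alpha,
        min_group=cfg.min_group, expr=inp.expr)
    trn = net.assemble_trn(weights, motif_targets, tf_motif, inp.expr,
                           significance, alpha=cfg.alpha,
                           weight_quantile=cfg.weight_quantile,
                           r_min=cfg.r_min)
    written = []
    path = outdir / "trn_edges.tsv"
    trn.to_frame().to_csv(path, sep="\t", float_format="%.10g", index=False)
    written.append(path)
    path = outdir / "tf_significance.json"
    with open(path, "w") as fh:
        json.dump({"tf_significance": {tf: list(v) for tf, v in
                                       sorted(significance.items())},
                   "thresholds": trn.thresholds}, fh, indent=1)
    written.append(path)

    clusters_df = pd.read_csv(outdir / "clusters.tsv", sep="\t")
    model = dyn.ClusterModel(k=cfg.k,
                             assignments=dict(zip(clusters_df["gene_id"],
                                                  clusters_df["cluster"])),
                             centroids=None, seed=cfg.seed, inertia=float("nan"))
    crm = net.cluster_regulation_enrichment(trn, model)
    path = outdir / "cluster_regulation.tsv"
    out = crm.counts.copy().astype(float)
    crm_long = crm.counts.stack().rename("edges").to_frame()
    crm_long["p"] = crm.p.stack()
    crm_long["q"] = crm.q.stack()
    crm_long.to_csv(path, sep="\t", float_format="%.10g")
    written.append(path)
    del out
    return written


def _stage_triage(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    inp = _Inputs(cfg)
    edges_df = pd.read_csv(outdir / "trn_edges.tsv", sep="\t")
    with open(outdir / "tf_significance.json") as fh:
        sig = {tf: tuple(v) for tf, v in
               json.load(fh)["tf_significance"].items()}
    trn = net.TRN(edges=[net.TRNEdge(r.tf, r.target, r.weight, int(r.sign),
                                     r.r, bool(r.footprint_supported))
                         for r in edges_df.itertuples(index=False)],
                  tf_significance=sig)
    tf_ids = set(inp.annotation.tf_ids)
    starch, ssp = inp.storage_genes()

    structure = tri.identify_structure_tfs(trn, tf_ids, n_perm=cfg.n_perm,
                                           alpha=cfg.alpha, seed=cfg.seed)
    direct = tri.identify_direct_regulators(trn, starch, ssp)
    reg_class = tri.classify_regulators(trn, starch, ssp)
    gwas_flags = tri.gwas_overlap(inp.annotation, tf_ids, inp.gwas_signals(),
                                  window_total=cfg.window_total)
    groups = tri.expression_phenotype_groups(inp.panels(), inp.traits(),
                                             inp.trait_classes(), tf_ids,
                                             alpha=cfg.alpha)
    known_path = cfg.data_dir / "known_tfs.tsv"
    known = (set(pd.read_csv(known_path, sep="\t")["tf_id"])
             if known_path.exists() else set())
    triage = tri.build_triage_table(sorted(tf_ids), structure, direct, known,
                                    gwas_flags, groups, inp.mutants(),
                                    group_min=cfg.group_min)
    written = []
    path = outdir / "triage.tsv"
    triage.to_csv(path, sep="\t")
    written.append(path)
    path = outdir / "regulator_classes.tsv"
    reg_class.to_csv(path, sep="\t")
    written.append(path)

    genotypes = tri.filter_variants(inp.genotypes(),
                                    max_missing=cfg.max_missing,
                                    min_maf=cfg.min_maf, max_het=cfg.max_het)
    promoter_map = {r.gene_id: r.peaks.split(",") for r in
                    pd.read_csv(outdir / "promoter_map.tsv", sep="\t"
                                ).itertuples(index=False)}
    density = tri.snp_density_in_peaks(genotypes, inp.peaks, promoter_map)
    path = outdir / "snp_density.tsv"
    density.to_csv(path, sep="\t", float_format="%.10g", index_label="gene_id")
    written.append(path)
    return written


def run(subcommand: str, config: PipelineConfig) -> dict:
    """Run one stage (or ``all``) and write a run manifest.

    Returns the manifest dict; raises on the first failing stage after
    recording it in the manifest.
    """
    if subcommand not in STAGES + ("all",):
        raise ValueError(f"unknown subcommand {subcommand!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if subcommand == "all" else [subcommand]
    manifest = {
        "config": {**dataclasses.asdict(config)},
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "input_checksums": {},
    }
    try:
        for stage in stages:
            t0 = time.time()
            if stage == "simulate":
                written = _stage_simulate(config)
            elif stage == "dynamics":
                written = _stage_dynamics(config, outdir)
            elif stage == "chromatin":
                written = _stage_chromatin(config, outdir)
            elif stage == "trn":
                written = _stage_trn(config, outdir)
            else:
                written = _stage_triage(config, outdir)
            manifest["stages"][stage] = {
                "seconds": round(time.time() - t0, 3),
                "artifacts": [str(p) for p in written],
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    if config.data_dir.exists():
        manifest["input_checksums"] = {
            p.name: _md5(p) for p in sorted(config.data_dir.iterdir())
            if p.is_file()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
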
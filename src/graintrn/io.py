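"""Readers, writers and core containers for the formats the pipeline touches.

All interval work inside the package uses a single convention: 0-based,
half-open ``[start, end)`` coordinates, the BED convention. GFF3 (1-based,
closed) is converted at the boundary in both directions. The transcription
start site of a ``-``-strand gene is ``end - 1`` — the last base of the
half-open interval.
"""

from __future__ import annotations

import textwrap
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from Bio import motifs as _bio_motifs

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "IntervalSet",
    "PWM",
    "ExpressionMatrix",
    "GenotypeTable",
    "read_gene_models",
    "write_gene_models",
    "read_bed",
    "write_bed",
    "read_jaspar_pwm",
    "write_jaspar_pwm",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_vcf_lite",
    "write_vcf_lite",
    "read_fasta",
    "write_fasta",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Gene:
    """A gene model in 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    subgenome: str = "unknown"
    triad_id: str | None = None
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: invalid interval")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: first base of the transcript."""
        return self.start if self.strand == "+" else self.end - 1


class GenomeAnnotation:
    """Gene models plus chromosome sizes; the coordinate frame for all
    interval arithmetic downstream."""

    def __init__(self, genes: list[Gene], chrom_sizes: dict[str, int]):
        self.genes = list(genes)
        self.chrom_sizes = dict(chrom_sizes)
        self.by_id: dict[str, Gene] = {}
        for g in self.genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            if g.chrom in self.chrom_sizes and g.end > self.chrom_sizes[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past {g.chrom}")
            self.by_id[g.gene_id] = g
        triads: dict[str, list[Gene]] = {}
        for g in self.genes:
            if g.triad_id is not None:
                triads.setdefault(g.triad_id, []).append(g)
        self.triads = triads

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def tf_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.is_tf]

    def triad_members(self, triad_id: str) -> list[Gene]:
        members = self.triads.get(triad_id, [])
        if len(members) != 3:
            raise ValueError(f"triad {triad_id!r} has {len(members)} members, expected 3")
        return sorted(members, key=lambda g: g.subgenome)


class IntervalSet:
    """A named set of genomic intervals (peaks, footprints), 0-based half-open.

    Backed by a DataFrame with columns chrom, start, end, name, score, strand.
    """

    COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col, default in (("name", "."), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[self.COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        df["score"] = pd.to_numeric(df["score"], errors="coerce").astype(float)
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval {bad}: start >= end")
        self.df = df

    @classmethod
    def from_records(cls, records) -> "IntervalSet":
        return cls(pd.DataFrame(records, columns=cls.COLUMNS[: len(records[0])] if records else cls.COLUMNS))

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(pd.DataFrame(columns=cls.COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.df.groupby("chrom", sort=True)}


@dataclass
class PWM:
    """Position weight matrix: 4 x L probabilities, rows A, C, G, T."""

    motif_id: str
    matrix: np.ndarray
    tf_family: str = ""
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x L with L >= 1")
        if (self.matrix < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, pseudocount: float = 0.001,
                    tf_family: str = "") -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if (counts < 0).any():
            raise ValueError(f"motif {motif_id}: negative counts")
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        return cls(motif_id, probs, tf_family=tf_family, pseudocount=pseudocount)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=0))

    def log_odds(self, background: float = 0.25) -> np.ndarray:
        """Per-position log2 odds against a uniform background; zero
        probabilities floored at 1e-9 to keep scores finite."""
        p = np.maximum(self.matrix, 1e-9)
        return np.log2(p / background)

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())


class ExpressionMatrix:
    """Genes (or peaks) x samples abundance matrix with per-sample metadata."""

    def __init__(self, values: pd.DataFrame, unit: str = "TPM",
                 sample_meta: pd.DataFrame | None = None):
        if unit not in ("TPM", "CPM", "count"):
            raise ValueError(f"unknown unit {unit!r}")
        values = values.astype(float)
        if (values.values < 0).any():
            raise ValueError(f"negative values in a {unit} matrix")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicated row id {dup!r}")
        if values.isna().any().any():
            raise ValueError("missing cells are not allowed")
        self.values = values
        self.unit = unit
        if sample_meta is not None and len(sample_meta) != values.shape[1]:
            raise ValueError("sample_meta length must equal the column count")
        self.sample_meta = sample_meta

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    def stage_of(self, sample: str) -> str:
        """Stage label of a sample; 'DAP8_r2' -> 'DAP8'."""
        if self.sample_meta is not None and "stage" in self.sample_meta.columns:
            return str(self.sample_meta.loc[self.sample_meta.index[self.samples.index(sample)], "stage"])
        return sample.rsplit("_", 1)[0]

    def stage_means(self) -> pd.DataFrame:
        """Average replicate columns per stage, preserving stage order of
        first appearance."""
        stages = [self.stage_of(s) for s in self.samples]
        order = list(dict.fromkeys(stages))
        grouped = self.values.T.groupby(pd.Categorical(stages, categories=order), observed=True).mean().T
        grouped.columns = order
        return grouped


@dataclass
class GenotypeTable:
    """Biallelic variants x accessions alt-allele dosages; NaN = missing."""

    variants: pd.DataFrame  # columns chrom, pos, ref, alt
    calls: np.ndarray  # float, entries 0/1/2/NaN
    accessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.variants), len(self.accessions)):
            raise ValueError("calls shape does not match variants x accessions")
        valid = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    def __len__(self) -> int:
        return len(self.variants)


# ---------------------------------------------------------------------------
# GFF3

_GFF_ATTRS = ("subgenome", "triad_id", "is_tf")


def read_gene_models(path) -> GenomeAnnotation:
    """Read gene features from a GFF3 file into a :class:`GenomeAnnotation`.

    GFF3's 1-based closed coordinates become 0-based half-open. Chromosome
    sizes come from ``##sequence-region`` pragmas when present, else from the
    right-most gene end per chromosome.
    """
    path = str(path)
    chrom_sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    chrom_sizes[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}")
    db = gffutils.create_db(path, ":memory:", force=True,
                            merge_strategy="error", keep_order=True)
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in "+-":
            raise ValueError(f"gene {feat.id}: missing strand")
        attrs = {k: feat.attributes[k][0] for k in _GFF_ATTRS if k in feat.attributes}
        genes.append(Gene(
            gene_id=feat.id,
            chrom=feat.seqid,
            start=feat.start - 1,  # 1-based closed -> 0-based half-open
            end=feat.end,
            strand=feat.strand,
            subgenome=attrs.get("subgenome", "unknown"),
            triad_id=attrs.get("triad_id") or None,
            is_tf=attrs.get("is_tf", "0") in ("1", "true", "True"),
        ))
    for g in genes:
        chrom_sizes.setdefault(g.chrom, 0)
        chrom_sizes[g.chrom] = max(chrom_sizes[g.chrom], g.end)
    return GenomeAnnotation(genes, chrom_sizes)


def write_gene_models(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            attrs = [f"ID={g.gene_id}", f"subgenome={g.subgenome}"]
            if g.triad_id is not None:
                attrs.append(f"triad_id={g.triad_id}")
            attrs.append(f"is_tf={int(g.is_tf)}")
            fh.write("\t".join([
                g.chrom, "graintrn", "gene",
                str(g.start + 1), str(g.end), ".", g.strand, ".",
                ";".join(attrs),
            ]) + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> IntervalSet:
    """Read BED3/BED6; coordinates kept as-is (BED is already half-open)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype={0: str}, na_values=[], keep_default_na=False)
    except pd.errors.EmptyDataError:
        return IntervalSet.empty()
    if df.shape[1] < 3:
        raise ValueError("BED requires at least 3 columns")
    df = df.iloc[:, :6]
    df.columns = IntervalSet.COLUMNS[: df.shape[1]]
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"non-integer {col} coordinate in BED file")
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce").astype(float)
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path) -> None:
    df = intervals.df.copy()
    df["score"] = df["score"].map(lambda s: "." if pd.isna(s) else f"{s:g}")
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JASPAR PWMs

def read_jaspar_pwm(path, pseudocount: float = 0.001) -> list[PWM]:
    """Parse a JASPAR-format text file of count matrices into PWMs.

    ``pseudocount`` is an additive count applied per matrix cell before
    column normalization.
    """
    with open(path) as fh:
        parsed = _bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in _BASES], dtype=float)
        if (counts < 0).any():
            raise ValueError(f"motif {m.matrix_id}: negative counts")
        pwms.append(PWM.from_counts(m.matrix_id, counts, pseudocount=pseudocount,
                                    tf_family=m.name or ""))
    return pwms


def write_jaspar_pwm(pwms: list[PWM], path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count blocks (probabilities x ``scale``)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.tf_family or pwm.motif_id}\n")
            counts = np.rint(pwm.matrix * scale).astype(int)
            for i, base in enumerate(_BASES):
                row = " ".join(f"{c:6d}" for c in counts[i])
                fh.write(f"{base}  [{row} ]\n")


# ---------------------------------------------------------------------------
# TSV matrices

def read_matrix_tsv(path, unit: str = "TPM",
                    sample_meta: pd.DataFrame | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing or ragged cells")
    return ExpressionMatrix(df, unit=unit, sample_meta=sample_meta)


def write_matrix_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.12g", index_label="id")


# ---------------------------------------------------------------------------
# VCF

def read_vcf_lite(path) -> GenotypeTable:
    """Read a minimal VCF (CHROM POS ID REF ALT + GT) with cyvcf2.

    GT dosage coding: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
    Multi-allelic records are skipped with a warning. POS is converted to the
    internal 0-based frame.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    rows, calls = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at {rec.CHROM}:{rec.POS}")
            continue
        dosages = []
        for gt in rec.genotypes:
            a, b = gt[0], gt[1]
            dosages.append(np.nan if a < 0 or b < 0 else float((a > 0) + (b > 0)))
        rows.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        calls.append(dosages)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    calls_arr = np.array(calls, dtype=float) if calls else np.empty((0, len(accessions)))
    return GenotypeTable(variants, calls_arr, accessions)


def write_vcf_lite(table: GenotypeTable, path) -> None:
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(table.variants["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.accessions) + "\n")
        for i, var in enumerate(table.variants.itertuples(index=False)):
            gts = ["./." if np.isnan(d) else gt_map[d] for d in table.calls[i]]
            fh.write(f"{var.chrom}\t{var.pos + 1}\tv{i}\t{var.ref}\t{var.alt}"
                     f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Load sequences into memory keyed by name (synthetic genomes are small)."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")
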
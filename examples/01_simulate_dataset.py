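"""Generate a miniature endosperm multi-omics study with known ground truth.

Builds three homoeologous chromosomes of gene triads plus 20 transcription
factors, a planted signed TF->target network with footprint-covered motif
sites, an 8-stage x 3-replicate expression time course, chromatin marks,
and a 100-accession population panel — then writes everything as plain-text
files (GFF3/BED/FASTA/JASPAR/TSV/VCF).
"""

from pathlib import Path

from graintrn.simulate import SimConfig, simulate_all, write_dataset

cfg = SimConfig(seed=42)
ds = simulate_all(cfg)
out = write_dataset(ds, Path("scratch/example_dataset"))

print(f"genes:            {len(ds.annotation)} "
      f"({len(ds.annotation.triads)} triads, {len(ds.annotation.tf_ids)} TFs)")
print(f"planted edges:    {len(ds.truth.network)}")
print(f"promoter peaks:   {len(ds.peaks)}; footprints: {len(ds.footprints)}")
print(f"expression:       {ds.expr.shape[0]} genes x {ds.expr.shape[1]} samples")
print(f"population panel: {ds.panels['DAP20'].shape[1]} accessions")
print(f"written to:       {out}")
# Each planted edge leaves a footprint-covered motif site in its target's
# promoter peak, so the network is recoverable from sequence + expression.
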
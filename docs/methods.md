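# Methods

## Scope and data model

`graintrn` implements the computational core of a footprint-anchored
regulatory study of developing cereal endosperm: build a signed TF→target
network from accessible-chromatin footprints plus a time-series
transcriptome, and triage candidate regulators with population evidence.
All coordinates are 0-based half-open (the BED convention); GFF3 is
converted at the boundary, and the TSS of a −strand gene is `end − 1`.
The model organism is hexaploid wheat: three subgenomes (A/B/D),
homoeologous gene triads, grain-filling stages labelled in days after
pollination (DAP0 … DAP22).

## Synthetic study generator

The generator (`graintrn.simulate`) produces a complete miniature study
from one seed; each stage (genome, time series, marks, population) draws
from an independently derived stream, so regenerating one layer never
perturbs another.

**Genome and regulatory truth.** Three chromosomes carry `n_triads` triads
(one homoeolog each) plus `n_tfs` TF genes at 20-kb spacing. Each TF gets
a distinct random 8-mer consensus wrapped into a sharp count matrix
(12 : 1 : 1 : 1 per column). The planted network is sampled from a random
topological order over TFs (no TF cycles, so signed effects are
unambiguous); each TF takes `targets_per_tf` = 8 targets, each target at
most 3 regulators, signs 60 : 40 positive : negative. Every gene has one
400-bp promoter peak ~1.1–1.5 kb upstream of its TSS (strand-aware); each
planted edge embeds the TF consensus in the target's peak under a
footprint interval, while decoy consensi (rate 0.1/gene) are embedded
*without* footprints. Background sequence is uniform random, so chance
consensus matches occur (≈ a few per motif genome-wide) but are
essentially never footprint-covered — decoys and chance hits are exactly
what the footprint filter is supposed to reject.

**Time series.** TF log₂ profiles are stage-shifted Gaussian bumps
(amplitude 2–4, width 1–2 stages) plus replicate noise σ/2; a target adds
`sign · β · z(TF)` per regulator plus noise σ, with β = 0.8 and σ = 0.3 by
default — chosen so a single-regulator pair has |r| ≈ 0.9 and a
three-regulator target still correlates detectably with each regulator.
Non-TF genes carry their own mild bump (amplitude 0.2–2.0) so clustering
and CV have structure. Values are exponentiated and column-scaled to TPM.

**Marks.** Per peak, the activating mark is generated with correlation
`+mark_expr_corr` (default 0.7) to the host gene's z-scaled stage-mean
expression, the repressive mark with the opposite sign, in linear space
(affine, so Pearson r is preserved) before CPM scaling.

**Population.** Each TF carries one cis variant inside its promoter peak
(allele frequencies 0.15–0.5, 3% heterozygous, 2% missing calls —
near-inbred lines) shifting its log₂ expression by 1.5 per homozygous
alternate; planted-network effects propagate to targets. Traits load
(weight 0.7) on the DAP20 z-expression of the five causal TFs, split
between grain-size and grain-quality classes; one GWAS signal lands within
1 Mb of each causal TF plus two unlinked decoys; mutant flags mark causal
TFs altered with probability 0.9, others 0.1. These rates are the study
conditions every recovery benchmark runs under.

**What the generator does not emulate:** linkage disequilibrium, GC/
dinucleotide sequence composition, read-level noise, distal enhancers,
and genome-scale gene counts. Passing tests therefore demonstrate that the
algorithms recover the structures they are defined on, not that they would
reach any particular accuracy on real wheat data.

## Analysis stages

**Expression dynamics.** TPM normalization follows the standard
rate-per-million form; a gene counts as expressed at ≥ 0.5 TPM in at least
one sample (boundary inclusive). Temporal clustering is k-means (k = 6 by
default, 10 restarts, seeded) on z-scaled stage means; zero-variance genes
are excluded with a warning. Triad balance takes each homoeolog's share of
the triad's mean TPM and assigns the nearest of seven fixed centroids —
balanced (⅓,⅓,⅓), single-homoeolog dominance (1,0,0)-type, and
single-homoeolog suppression (0,½,½)-type — with ties broken in that
order; triads under 0.5 TPM total are "unexpressed". Expression–mark
correlation sums peak CPM over the strand-aware promoter window
(aggregation by sum, i.e. total local signal; configurable) and correlates
z-scaled stage means. Stage means (not replicate samples) are used because
the comparison is between temporal trajectories.

**Chromatin.** PWM scanning uses log₂ odds against a uniform 0.25
background (probabilities floored at 1e-9), both strands, windows with N
skipped, and a hit threshold of 0.8 × the maximum attainable score — a
deterministic rule that an exhaustive scorer can reproduce exactly, in
preference to p-value calibration. Footprint support requires the hit
fully inside a single footprint (`min_overlap_frac` = 1.0, the strictest
reading of footprint evidence). TF-activity deviations follow the
background-matched scheme: expected counts from the peak's share of total
accessibility, raw deviation (obs − exp)/exp, and z-scores against 50
background sets resampled per member peak from its mean-accessibility
decile bin (no GC matching — the synthetic sequences have no GC
structure). When the background spread is numerically zero, z is 0 if the
observed deviation equals the background mean and undefined (NaN)
otherwise. Under random membership the z-scores are standardized by
construction, so their *signed* mean is the calibration quantity (≈ 0);
their absolute mean sits near E|N(0,1)| ≈ 0.8 as for any z-statistic.

**Network inference.** One motif per TF (argmax similarity, lexicographic
ties); motif targets are genes with a footprint-supported hit in their
pACRs. Importance weights follow the GENIE3 scheme with scikit-learn
random forests (√p feature sampling), per-target seeds derived from the
pipeline seed and the sorted target index so results are invariant to
input order. The footprint-conditioned significance test defaults to
|Pearson r| as the coupling statistic rather than the ensemble weight:
with 8 stages × 3 replicates, twenty smooth unimodal TF profiles are
strongly collinear and forest importance splits across correlated TFs,
which halves the test's power, while |r| is unaffected; the weight-based
variant remains available (`stat="weight"`). The Mann–Whitney U uses exact
enumeration for tie-free groups of ≤ 20 and the tie-corrected normal
approximation otherwise. The final edge filter (per-TF 75th weight
percentile) is a tunable default justified by recovery on planted truth;
no principled genome-scale threshold exists for it. Cluster-level
regulation is tested per (TF-cluster, target-cluster) cell with an
upper-tail hypergeometric draw — cluster-i TFs' edges drawn from all
clustered edges, successes = edges into cluster j — BH-adjusted over the
k² cells.

**Triage.** Structure TFs are out-degree hubs of the TF–TF subnetwork
against a null that re-pairs edge stubs uniformly (preserving each node's
*total* degree; preserving in/out degrees separately would fix every
out-degree and make the test vacuous), empirical p = (1 + #{perm ≥ obs})/
(n_perm + 1), BH-adjusted. Direct regulators have ≥ 1 edge into the
starch/SSP sets; core = structure ∪ direct; novel = core minus a supplied
known list. Enrichment classes use strict "over the median" counts; the
sign mode distinguishes uniformly activating, uniformly repressing, and
strictly opposite (starch vs SSP) regulators. GWAS overlap intersects the
whole gene interval with a 3-Mb window centered on each signal (inclusive
reading). Expression–phenotype groups use raw two-sided Pearson p ≤ 0.05
per trait (no multiple-testing correction, matching the per-trait
"significant correlation" convention; a BH flag exists), membership per
(stage, trait-class); `group_min` = 2 of the four groups. High confidence
is the full conjunction: novel ∧ GWAS ∧ groups ∧ mutant-altered.
Variant filtering applies the strict inequalities missing < 0.5,
MAF > 0.05, het < 0.5 on non-missing dosages; haplotypes are dosage tuples
over a region with heterozygous/missing accessions excluded (inbred-line
assumption), labelled Hap1, Hap2, … by descending frequency; trait
contrasts are Welch t-tests; SNP density counts variants per kb of pACR.

## Numerical and design choices

- Single root seed; sub-streams via `numpy.random.SeedSequence` with fixed
  stream ids; all derived seeds < 2³¹.
- Matrices are written with `%.12g`, making reader/writer round trips
  exact to 12 significant digits and pipeline re-runs byte-identical.
- JASPAR pseudocount is an additive per-cell count (default 0.001).
- Multi-allelic VCF records are skipped (the haplotype procedure is
  biallelic); missing genotypes are excluded pairwise.
- Triad relative expression defaults to stage-averaged TPM; per-stage
  values are available through the `samples` argument.
- Activity deviations default to all peaks; restricting to a gene set's
  pACRs is a caller-side filter on the membership map.

## Benchmark problem sizes

The evaluation harness (`graintrn.benchmarks`, driven by
`scripts/acceptance.py` and the acceptance tests) uses the reference study
(200 triads + 20 TFs, 8 × 3 samples) for recovery and calibration — 10
seeds for recovery, 200 null + 100 planted-effect studies for the
significance test — with 25-tree ensembles, where recovery is already
saturated at this size; the library default remains 1000 trees. The
activity benchmark uses 300 peaks × 6 samples with ~15% multiplicative
noise and a 2× planted gain, the operating regime the deviation score is
meant for (a large peak universe also keeps accessibility-matched
backgrounds from being dominated by the planted peaks themselves).

## Known limitations

- Footprint calling itself is out of scope; footprints are consumed as
  intervals, with only a simple flank/core depletion score provided.
- The promoter-proximal window is the only peak–gene link (no distal
  enhancer assignment).
- The per-TF weight-quantile edge cut has no external calibration; at
  reference conditions it trades recall (~0.55–0.6) for precision (~1.0).
- The footprint significance test loses ~5% of truly regulating TFs at
  reference conditions (targets diluted across 2–3 co-regulators), which
  bounds triage recovery slightly above 0.9 on average.
- Population simulation has no linkage structure, so the GWAS and
  haplotype layers exercise bookkeeping and statistics, not fine-mapping.
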
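"""Structure/direct regulators, triage evidence layers, haplotypes and
population variability statistics."""

import numpy as np
import pandas as pd
import pytest

from graintrn import io as gio
from graintrn import triage as tri
from graintrn.network import TRN, TRNEdge


def _trn(edges, signs=None):
    signs = signs or {}
    return TRN(edges=[TRNEdge(u, v, 1.0, signs.get((u, v), 1), 0.9)
                      for u, v in edges], tf_significance={})


# ---------------------------------------------------------------------------
# structure TFs

def test_star_hub_is_selected():
    tf_ids = {f"tf{i}" for i in range(11)}
    edges = [("tf0", f"tf{i}") for i in range(1, 11)]
    got = tri.identify_structure_tfs(_trn(edges), tf_ids, n_perm=500, seed=1)
    assert got == {"tf0"}


def test_random_tf_network_selection_is_calibrated():
    rng = np.random.default_rng(51)
    rates = []
    for seed in range(20):
        tf_ids = {f"tf{i}" for i in range(12)}
        edges = {(f"tf{int(a)}", f"tf{int(b)}")
                 for a, b in rng.integers(0, 12, size=(25, 2)) if a != b}
        got = tri.identify_structure_tfs(_trn(sorted(edges)), tf_ids,
                                         n_perm=300, seed=seed)
        regs = {u for u, _ in edges}
        rates.append(len(got) / len(regs))
    assert np.mean(rates) <= 0.10


def test_empty_tf_tf_subnetwork_warns():
    trn = _trn([("tf0", "g1")])
    with pytest.warns(UserWarning, match="empty"):
        assert tri.identify_structure_tfs(trn, {"tf0"}, n_perm=10) == set()


# ---------------------------------------------------------------------------
# direct regulators and classes

def test_direct_regulator_membership():
    trn = _trn([("tf0", "starch1"), ("tf1", "other")])
    got = tri.identify_direct_regulators(trn, {"starch1"}, {"ssp1"})
    assert got == {"tf0"}


def test_classify_regulators_strict_median_and_modes():
    edges = [("tfA", "s1"), ("tfA", "s2"), ("tfA", "p1"),
             ("tfB", "s3"), ("tfB", "p2"),
             ("tfC", "p3")]
    signs = {("tfA", "s1"): -1, ("tfA", "s2"): -1, ("tfA", "p1"): 1,
             ("tfB", "s3"): 1, ("tfB", "p2"): 1, ("tfC", "p3"): -1}
    trn = _trn(edges, signs)
    table = tri.classify_regulators(trn, {"s1", "s2", "s3"}, {"p1", "p2", "p3"})
    # medians: starch counts (2,1,0) -> 1; ssp counts (1,1,1) -> 1
    assert table.loc["tfA", "class"] == "starch-enriched"
    assert table.loc["tfB", "class"] == "neither"  # both exactly at median
    assert table.loc["tfA", "mode"] == "opposite"  # -1 on starch, +1 on SSP
    assert table.loc["tfB", "mode"] == "positive"
    assert table.loc["tfC", "mode"] == "negative"


def test_classify_matches_brute_force_on_random_tables():
    rng = np.random.default_rng(53)
    starch = {f"s{i}" for i in range(6)}
    ssp = {f"p{i}" for i in range(6)}
    for _ in range(20):
        edges, signs = [], {}
        for tf in range(5):
            for tgt in rng.choice(sorted(starch | ssp),
                                  size=int(rng.integers(1, 7)), replace=False):
                edges.append((f"tf{tf}", str(tgt)))
                signs[(f"tf{tf}", str(tgt))] = int(rng.choice([-1, 1]))
        table = tri.classify_regulators(_trn(edges, signs), starch, ssp)
        ns = {tf: sum(t in starch for f, t in edges if f == tf)
              for tf in {f for f, _ in edges}}
        np_ = {tf: sum(t in ssp for f, t in edges if f == tf)
               for tf in {f for f, _ in edges}}
        ms, mp = np.median(list(ns.values())), np.median(list(np_.values()))
        for tf in table.index:
            s_enr, p_enr = ns[tf] > ms, np_[tf] > mp
            expected = ("dual" if s_enr and p_enr else
                        "starch-enriched" if s_enr else
                        "SSP-enriched" if p_enr else "neither")
            assert table.loc[tf, "class"] == expected


# ---------------------------------------------------------------------------
# GWAS overlap

def _ann_with_gene(dist_bp):
    g = gio.Gene("tf1", "chr1A", 5_000_000 + dist_bp, 5_002_000 + dist_bp, "+")
    return gio.GenomeAnnotation([g], {"chr1A": 20_000_000})


def test_gene_within_half_window_flagged():
    ann = _ann_with_gene(1_400_000)
    sig = pd.DataFrame({"chrom": ["chr1A"], "pos": [5_000_000]})
    assert tri.gwas_overlap(ann, {"tf1"}, sig).loc["tf1", "any"]


def test_gene_beyond_half_window_not_flagged():
    ann = _ann_with_gene(1_600_000)
    sig = pd.DataFrame({"chrom": ["chr1A"], "pos": [5_000_000]})
    assert not tri.gwas_overlap(ann, {"tf1"}, sig).loc["tf1", "any"]


def test_gwas_overlap_matches_brute_force():
    rng = np.random.default_rng(59)
    genes = []
    for i in range(50):
        s = int(rng.integers(0, 50_000_000))
        genes.append(gio.Gene(f"tf{i}", f"chr{i % 2}", s, s + 2000, "+"))
    ann = gio.GenomeAnnotation(genes, {"chr0": 60_000_000, "chr1": 60_000_000})
    sig = pd.DataFrame({
        "chrom": [f"chr{int(i)}" for i in rng.integers(0, 2, 50)],
        "pos": rng.integers(0, 50_000_000, 50),
    })
    flags = tri.gwas_overlap(ann, {g.gene_id for g in genes}, sig)
    half = 1_500_000
    for g in genes:
        expected = any(r.chrom == g.chrom
                       and g.start < r.pos + half and r.pos - half < g.end
                       for r in sig.itertuples())
        assert flags.loc[g.gene_id, "any"] == expected


def test_unknown_chromosome_warned_and_skipped():
    ann = _ann_with_gene(0)
    sig = pd.DataFrame({"chrom": ["chrUn"], "pos": [5_000_000]})
    with pytest.warns(UserWarning, match="unknown chromosome"):
        flags = tri.gwas_overlap(ann, {"tf1"}, sig)
    assert not flags.loc["tf1", "any"]


# ---------------------------------------------------------------------------
# expression-phenotype groups

def _panel(values, accessions):
    df = pd.DataFrame(values, index=["tf1"], columns=accessions)
    return gio.ExpressionMatrix(df, unit="TPM")


def test_planted_trait_association_detected():
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        accs = [f"a{i}" for i in range(100)]
        x = rng.uniform(1, 100, 100)
        z = (x - x.mean()) / x.std()
        traits = pd.DataFrame({"gl": 0.9 * z + 0.1 * rng.standard_normal(100)},
                              index=accs)
        groups = tri.expression_phenotype_groups(
            {"DAP10": _panel([x], accs)}, traits, {"gl": "GS"}, {"tf1"})
        hits += "GS-DAP10" in groups["tf1"]
    assert hits >= 95


def test_null_membership_rate_matches_alpha():
    members = 0
    for seed in range(200):
        rng = np.random.default_rng(1000 + seed)
        accs = [f"a{i}" for i in range(100)]
        x = rng.uniform(1, 100, 100)
        traits = pd.DataFrame({"gl": rng.standard_normal(100)}, index=accs)
        groups = tri.expression_phenotype_groups(
            {"DAP10": _panel([x], accs)}, traits, {"gl": "GS"}, {"tf1"})
        members += "GS-DAP10" in groups["tf1"]
    assert members / 200 == pytest.approx(0.05, abs=0.03)


def test_group_bookkeeping_single_membership():
    rng = np.random.default_rng(61)
    accs = [f"a{i}" for i in range(50)]
    x = rng.uniform(1, 100, 50)
    z = (x - x.mean()) / x.std()
    traits = pd.DataFrame({"gl": z, "gluten": rng.standard_normal(50)},
                          index=accs)
    panels = {"DAP10": _panel([x], accs),
              "DAP20": _panel([rng.uniform(1, 100, 50)], accs)}
    groups = tri.expression_phenotype_groups(
        panels, traits, {"gl": "GS", "gluten": "GQ"}, {"tf1"})
    assert "GS-DAP10" in groups["tf1"]
    assert "GQ-DAP10" not in groups["tf1"]


def test_too_few_shared_accessions_rejected():
    accs = [f"a{i}" for i in range(5)]
    traits = pd.DataFrame({"gl": np.ones(5)}, index=accs)
    with pytest.raises(ValueError, match="10 shared"):
        tri.expression_phenotype_groups({"DAP10": _panel([np.ones(5)], accs)},
                                        traits, {"gl": "GS"}, {"tf1"})


# ---------------------------------------------------------------------------
# triage table

def _triage_frame(**overrides):
    base = dict(structure={"tf1"}, direct=set(), known_tfs=set(),
                groups={"tf1": {"GS-DAP10", "GQ-DAP20"}},
                mutant_status={"tf1": "altered"})
    base.update(overrides)
    gwas = pd.DataFrame({"any": [True]}, index=["tf1"])
    return tri.build_triage_table(["tf1"], base["structure"], base["direct"],
                                  base["known_tfs"], gwas, base["groups"],
                                  base["mutant_status"])


def test_all_evidence_selected():
    t = _triage_frame()
    assert tri.select_high_confidence(t) == {"tf1"}


def test_no_mutant_line_excluded():
    t = _triage_frame(mutant_status={"tf1": "no_line"})
    assert tri.select_high_confidence(t) == set()


def test_known_tf_not_novel():
    t = _triage_frame(known_tfs={"tf1"})
    assert not t.loc["tf1", "is_novel"]
    assert tri.select_high_confidence(t) == set()


def test_selection_monotone_in_group_min():
    t = _triage_frame()
    assert tri.select_high_confidence(t, group_min=3) <= \
        tri.select_high_confidence(t, group_min=2) <= \
        tri.select_high_confidence(t, group_min=1)


# ---------------------------------------------------------------------------
# variant filtering

def _table(calls, accessions=None):
    calls = np.asarray(calls, dtype=float)
    accs = accessions or [f"a{i}" for i in range(calls.shape[1])]
    variants = pd.DataFrame({
        "chrom": ["chr1A"] * len(calls),
        "pos": np.arange(100, 100 + len(calls)),
        "ref": ["A"] * len(calls), "alt": ["T"] * len(calls)})
    return gio.GenotypeTable(variants, calls, accs)


def test_maf_boundary_strict():
    # 10 accessions, one hom-alt carrier: p = 0.1 > 0.05 retained;
    # exactly 0.05 (one het in 10) removed.
    m = np.nan
    keep = _table([[2] + [0] * 9])
    drop = _table([[1] + [0] * 9])
    assert len(tri.filter_variants(keep)) == 1
    assert len(tri.filter_variants(drop)) == 0
    assert m is np.nan  # silence lint on unused sentinel


def test_missing_boundary_strict():
    half_missing = _table([[np.nan] * 5 + [0, 0, 2, 2, 2]])
    assert len(tri.filter_variants(half_missing)) == 0  # rate == 0.5, strict <


def test_filter_matches_hand_enumeration():
    calls = [
        [0, 0, 0, 0, 2, 2, 0, 0],        # MAF .25 keep
        [0, 0, 0, 0, 0, 0, 0, 0],        # MAF 0 drop
        [1, 1, 1, 1, 1, 0, 0, 2],        # het 5/8 drop
        [np.nan, np.nan, np.nan, np.nan, np.nan, 0, 2, 2],  # missing 5/8 drop
        [2, 2, 2, 2, 2, 2, 2, 0],        # MAF .125 keep
        [0, 2, 0, 2, 0, 2, 0, 2],        # keep
        [1, 0, 0, 0, 0, 0, 0, 0],        # MAF 1/16 = .0625 keep, het .125
        [2, 2, 2, 2, 2, 2, 2, 2],        # MAF 0 drop
    ]
    out = tri.filter_variants(_table(calls))
    assert out.variants["pos"].tolist() == [100, 104, 105, 106]


def test_filter_idempotent(small_ds):
    once = tri.filter_variants(small_ds.genotypes)
    twice = tri.filter_variants(once)
    assert np.array_equal(once.calls, twice.calls, equal_nan=True)


# ---------------------------------------------------------------------------
# haplotypes

def test_two_haplotypes_largest_first():
    calls = [[0, 0, 0, 2, 2, 2, 2, 0, 0, 0],
             [2, 2, 2, 0, 0, 0, 0, 2, 2, 2]]
    groups = tri.assign_haplotypes(_table(calls), ("chr1A", 0, 1000))
    assert groups.n_haplotypes == 2
    assert len(groups.members["Hap1"]) == 6
    assert groups.tuples["Hap1"] == (0, 2)


def test_identical_tuples_single_haplotype():
    groups = tri.assign_haplotypes(_table([[2] * 10]), ("chr1A", 0, 1000))
    assert groups.n_haplotypes == 1
    assert len(groups.members["Hap1"]) == 10


def test_het_and_missing_accessions_excluded():
    calls = [[0, 1, np.nan, 2, 0, 0, 0, 0, 0, 0]]
    with pytest.warns(UserWarning, match="excluded"):
        groups = tri.assign_haplotypes(_table(calls), ("chr1A", 0, 1000))
    assert len(groups.assignment) == 8


def test_haplotype_grouping_matches_brute_force():
    rng = np.random.default_rng(67)
    for _ in range(20):
        calls = rng.choice([0.0, 2.0], size=(4, 30))
        groups = tri.assign_haplotypes(_table(calls), ("chr1A", 0, 1000))
        expected = {}
        for ai in range(30):
            expected.setdefault(tuple(calls[:, ai].astype(int)), []).append(ai)
        assert groups.n_haplotypes == len(expected)
        for label, accs in groups.members.items():
            idx = [int(a[1:]) for a in accs]
            assert sorted(idx) == sorted(expected[groups.tuples[label]])


def test_empty_region_rejected():
    with pytest.raises(ValueError, match="no variants"):
        tri.assign_haplotypes(_table([[0] * 10]), ("chr1B", 0, 1000))


# ---------------------------------------------------------------------------
# trait tests and frequencies

def _groups_two(n=30):
    members = {"Hap1": [f"x{i}" for i in range(n)],
               "Hap2": [f"y{i}" for i in range(n)]}
    assignment = {a: h for h, accs in members.items() for a in accs}
    return tri.HaplotypeGroups(assignment, [0], 2, members,
                               {"Hap1": (0,), "Hap2": (2,)})


def test_identical_groups_t_zero_p_one():
    g = _groups_two(5)
    trait = pd.Series(1.0, index=[*g.members["Hap1"], *g.members["Hap2"]])
    row = tri.haplotype_trait_test(g, trait).iloc[0]
    assert (row["t"], row["p"]) == (0.0, 1.0)


def test_separated_groups_powerful():
    """d=2 at n=30/group: closed-form Welch power at p<1e-6 is 0.980
    (noncentral t, ncp 7.75, df 58); the detection count must sit inside
    the 99% binomial band of that power (>= 94 of 100)."""
    detections = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        g = _groups_two(30)
        trait = pd.Series(
            np.concatenate([rng.normal(0, 1, 30), rng.normal(2, 1, 30)]),
            index=[*g.members["Hap1"], *g.members["Hap2"]])
        detections += tri.haplotype_trait_test(g, trait).iloc[0]["p"] < 1e-6
    assert detections >= 94


def test_welch_matches_closed_form():
    a = np.array([3.1, 2.7, 4.5, 3.3, 2.9])
    b = np.array([5.0, 6.1, 5.5, 4.9, 6.4, 5.8])
    g = tri.HaplotypeGroups(
        {f"a{i}": "Hap1" for i in range(5)} | {f"b{i}": "Hap2" for i in range(6)},
        [0], 2,
        {"Hap1": [f"a{i}" for i in range(5)], "Hap2": [f"b{i}" for i in range(6)]},
        {})
    trait = pd.Series(np.concatenate([a, b]),
                      index=[f"a{i}" for i in range(5)] + [f"b{i}" for i in range(6)])
    row = tri.haplotype_trait_test(g, trait).iloc[0]
    va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 6
    t_expected = (a.mean() - b.mean()) / np.sqrt(va + vb)
    assert row["t"] == pytest.approx(t_expected, abs=1e-12)
    assert row["delta_mean"] == pytest.approx(a.mean() - b.mean(), abs=1e-12)


def test_frequency_trend_tally_and_normalization():
    g = _groups_two(10)
    eras = pd.Series(
        {**{f"x{i}": "old" for i in range(10)},
         **{f"y{i}": ("old" if i < 3 else "new") for i in range(10)}})
    freq = tri.haplotype_frequency_trend(g, eras)
    assert freq.loc["old", "Hap1"] == pytest.approx(10 / 13)
    assert freq.loc["new", "Hap2"] == pytest.approx(1.0)
    assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-12)


# ---------------------------------------------------------------------------
# SNP density

def test_snp_density_hand_computation():
    peaks = gio.IntervalSet(pd.DataFrame(
        [("chr1A", 0, 1000, "p1")], columns=["chrom", "start", "end", "name"]))
    gt = _table([[0] * 10, [2] * 10])  # positions 100, 101 both inside p1
    density = tri.snp_density_in_peaks(gt, peaks, {"g1": ["p1"]})
    assert density["g1"] == pytest.approx(2.0)


def test_snp_density_zero_and_brute_force():
    rng = np.random.default_rng(71)
    rows = []
    for i in range(20):
        s = int(rng.integers(0, 9000))
        rows.append(("chr1A", s, s + int(rng.integers(100, 600)), f"p{i}"))
    peaks = gio.IntervalSet(pd.DataFrame(rows, columns=["chrom", "start",
                                                        "end", "name"]))
    n_var = 200
    variants = pd.DataFrame({
        "chrom": ["chr1A"] * n_var,
        "pos": rng.integers(0, 10_000, n_var),
        "ref": ["A"] * n_var, "alt": ["T"] * n_var})
    gt = gio.GenotypeTable(variants, np.zeros((n_var, 4)),
                           [f"a{i}" for i in range(4)])
    gene_map = {f"g{i}": [f"p{i}", f"p{(i + 1) % 20}"] for i in range(20)}
    density = tri.snp_density_in_peaks(gt, peaks, gene_map)
    for gene, names in gene_map.items():
        ivs = [r for r in rows if r[3] in names]
        hits = sum(any(s <= p < e for _, s, e, _ in ivs)
                   for p in variants["pos"])
        total = sum(e - s for _, s, e, _ in ivs)
        assert density[gene] == pytest.approx(hits / (total / 1000))
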
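"""TF-motif mapping, motif targets, tree-ensemble weights, footprint
significance and network assembly."""

import itertools

import numpy as np
import pandas as pd
import pytest

from graintrn import chromatin as chrom
from graintrn import network as net
from graintrn.dynamics import ClusterModel
from graintrn.io import ExpressionMatrix


# ---------------------------------------------------------------------------
# TF -> motif

def test_best_hit_argmax():
    df = pd.DataFrame({"tf": ["tf1", "tf1"], "motif": ["m1", "m2"],
                       "score": [50.0, 90.0]})
    assert net.map_tf_to_motif(df).mapping == {"tf1": "m2"}


def test_tie_broken_lexicographically():
    df = pd.DataFrame({"tf": ["tf1", "tf1"], "motif": ["mB", "mA"],
                       "score": [70.0, 70.0]})
    assert net.map_tf_to_motif(df).mapping == {"tf1": "mA"}


def test_best_hit_matches_brute_force_argmax():
    rng = np.random.default_rng(31)
    for _ in range(30):
        n = int(rng.integers(2, 30))
        df = pd.DataFrame({
            "tf": [f"tf{int(i)}" for i in rng.integers(0, 5, n)],
            "motif": [f"m{int(i)}" for i in rng.integers(0, 8, n)],
            "score": rng.integers(0, 10, n).astype(float),
        }).drop_duplicates(["tf", "motif"])
        got = net.map_tf_to_motif(df).mapping
        for tf, sub in df.groupby("tf"):
            best = max(sub.itertuples(),
                       key=lambda r: (r.score, tuple(-ord(c) for c in r.motif)))
            assert got[tf] == best.motif


# ---------------------------------------------------------------------------
# motif -> targets

def _hit(motif, gene, peak, supported):
    return chrom.MotifHit(motif, peak, gene, "chr1A", 100, "+", 5.0, 8,
                          footprint_supported=supported)


def test_supported_hit_creates_target():
    pmap = {"g1": ["p1"]}
    targets = net.derive_motif_targets([_hit("m", "g1", "p1", True)], pmap)
    assert targets == {"m": {"g1"}}


def test_unsupported_hits_excluded_when_footprint_required():
    pmap = {"g1": ["p1"]}
    hits = [_hit("m", "g1", "p1", False)]
    assert net.derive_motif_targets(hits, pmap, require_footprint=True) == {}
    assert net.derive_motif_targets(hits, pmap, require_footprint=False) == {"m": {"g1"}}


def test_derived_targets_equal_truth_without_decoys(small_ds):
    ds = small_ds
    pmap = chrom.assign_promoter_peaks(ds.annotation, ds.peaks)
    hits = chrom.scan_promoter_peaks(ds.genome, ds.peaks, ds.pwms, pmap)
    hits = chrom.mark_footprint_support(hits, ds.footprints)
    targets = net.derive_motif_targets(hits, pmap, require_footprint=True)
    for tf in ds.annotation.tf_ids:
        assert targets.get(ds.truth.tf_motif[tf], set()) == ds.truth.targets_of(tf)


# ---------------------------------------------------------------------------
# tree-ensemble importance

def _planted_expr(seed, n=50, beta=2.0, noise=0.1):
    rng = np.random.default_rng(seed)
    tfs = {f"tf{i}": rng.standard_normal(n) for i in range(6)}
    y = beta * tfs["tf0"] + rng.normal(0, noise, n)
    df = pd.DataFrame({**tfs, "y": y}).T
    df.columns = [f"s{j}" for j in range(n)]
    return ExpressionMatrix(df - df.values.min() + 1.0, unit="TPM")


def test_planted_regulator_wins_importance():
    wins = 0
    for seed in range(100):
        expr = _planted_expr(seed)
        w = net.genie3_importance(expr, {f"tf{i}" for i in range(6)},
                                  n_trees=50, seed=seed)
        wins += w["y"].idxmax() == "tf0"
    assert wins >= 95


def test_independent_target_gets_diffuse_weights():
    maxima = []
    for seed in range(20):
        expr = _planted_expr(seed, beta=0.0, noise=1.0)
        w = net.genie3_importance(expr, {f"tf{i}" for i in range(6)},
                                  n_trees=50, seed=seed)
        maxima.append(w["y"].max())
    assert np.mean(maxima) < 3 / 6


def test_importance_columns_normalized():
    expr = _planted_expr(0)
    w = net.genie3_importance(expr, {f"tf{i}" for i in range(6)},
                              n_trees=30, seed=1)
    sums = w.sum(axis=0)
    for gene, s in sums.items():
        assert s == pytest.approx(1.0, abs=1e-9) or s == 0.0
    assert all(w.loc[tf, tf] == 0.0 for tf in w.index)


def test_importance_deterministic_and_order_invariant():
    expr = _planted_expr(2)
    tfs = {f"tf{i}" for i in range(6)}
    w1 = net.genie3_importance(expr, tfs, n_trees=30, seed=5)
    shuffled = ExpressionMatrix(expr.values.iloc[::-1], unit="TPM")
    w2 = net.genie3_importance(shuffled, tfs, n_trees=30, seed=5)
    assert np.allclose(w1.sort_index(axis=1).values,
                       w2.sort_index(axis=1).loc[w1.index].values)


# ---------------------------------------------------------------------------
# Mann-Whitney footprint significance

def _exact_mwu_p(pos, neg):
    """Full enumeration of all C(n1+n2, n1) labelings (one-sided, pos > neg)."""
    pooled = list(pos) + list(neg)
    n1 = len(pos)

    def ustat(idx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    observed = ustat(range(n1))
    total = 0
    at_least = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        at_least += ustat(idx) >= observed
    return at_least / total


def test_maximal_separation_five_vs_five():
    pos = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
    neg = np.array([0.4, 0.3, 0.2, 0.1, 0.05])
    U, p = net._mannwhitney_one_sided(pos, neg)
    assert U == 25
    assert p == pytest.approx(1 / 252, rel=1e-9)


def test_exact_path_matches_full_enumeration():
    rng = np.random.default_rng(37)
    for _ in range(10):
        n1, n2 = int(rng.integers(3, 8)), int(rng.integers(3, 8))
        vals = rng.permutation(np.arange(n1 + n2, dtype=float))  # tie-free
        pos, neg = vals[:n1], vals[n1:]
        _, p = net._mannwhitney_one_sided(pos, neg)
        assert p == pytest.approx(_exact_mwu_p(pos, neg), rel=1e-9)


def test_null_p_values_centred():
    rng = np.random.default_rng(41)
    ps = []
    for _ in range(200):
        vals = rng.standard_normal(16)
        _, p = net._mannwhitney_one_sided(vals[:8], vals[8:])
        ps.append(p)
    assert np.mean(ps) == pytest.approx(0.5, abs=0.08)


def test_reversed_effect_gives_large_p():
    _, p = net._mannwhitney_one_sided(np.arange(5.0), np.arange(5.0) + 10)
    assert p > 0.5


def test_small_groups_skipped_as_untested():
    weights = pd.DataFrame(np.random.default_rng(0).uniform(size=(1, 10)),
                           index=["tf1"], columns=[f"g{i}" for i in range(10)])
    tfmap = net.TfMotifMap({"tf1": "m"}, provenance="supplied")
    with pytest.warns(UserWarning, match="untested"):
        out = net.footprint_conditioned_significance(
            weights, {"m": {"g0", "g1"}}, tfmap, stat="weight")
    assert out == {}


# ---------------------------------------------------------------------------
# assembly

def _toy_state(seed=0, sign=+1):
    rng = np.random.default_rng(seed)
    n = 24
    tf = rng.standard_normal(n)
    target = sign * 2.0 * tf + rng.normal(0, 0.1, n)
    decoys = {f"g{i}": rng.standard_normal(n) for i in range(8)}
    df = pd.DataFrame({"tf1": tf, "gT": target, **decoys}).T
    expr = ExpressionMatrix(df - df.values.min() + 1.0, unit="TPM",
                            sample_meta=None)
    weights = net.genie3_importance(expr, {"tf1"}, n_trees=30, seed=seed)
    tfmap = net.TfMotifMap({"tf1": "m"}, provenance="supplied")
    motif_targets = {"m": {"gT", "g0", "g1", "g2", "g3", "g4"}}
    sig = net.footprint_conditioned_significance(weights, motif_targets, tfmap,
                                                 expr=expr)
    return weights, motif_targets, tfmap, expr, sig


def test_alpha_zero_empties_network():
    weights, mt, tfmap, expr, sig = _toy_state()
    trn = net.assemble_trn(weights, mt, tfmap, expr, sig, alpha=0.0)
    assert trn.edges == []


def test_flipping_simulated_sign_flips_reported_sign():
    for sign in (+1, -1):
        weights, mt, tfmap, expr, sig = _toy_state(seed=3, sign=sign)
        sig = {"tf1": (0.0, 0.0, 0.0)}  # force retention; sign is under test
        trn = net.assemble_trn(weights, mt, tfmap, expr, sig,
                               weight_quantile=0.5)
        edge = next(e for e in trn.edges if e.target_id == "gT")
        assert edge.sign == sign


def test_no_self_edges():
    weights, mt, tfmap, expr, sig = _toy_state(seed=4)
    mt["m"].add("tf1")
    trn = net.assemble_trn(weights, mt, tfmap, expr,
                           {"tf1": (0.0, 0.0, 0.0)}, weight_quantile=0.0)
    assert all(e.tf_id != e.target_id for e in trn.edges)


# ---------------------------------------------------------------------------
# cluster regulation

def _trn_from_edges(edges):
    return net.TRN(edges=[net.TRNEdge(u, v, 1.0, 1, 0.9) for u, v in edges],
                   tf_significance={})


def test_all_edges_one_direction_extreme_enrichment():
    edges = [(f"tf{i}", f"g{i}") for i in range(10)]
    clusters = ClusterModel(k=2, assignments={**{f"tf{i}": 0 for i in range(10)},
                                              **{f"g{i}": 1 for i in range(10)}},
                            centroids=None, seed=0, inertia=0.0)
    crm = net.cluster_regulation_enrichment(_trn_from_edges(edges), clusters)
    assert crm.counts.loc[0, 1] == 10
    assert crm.counts.values.sum() == 10
    assert crm.q.loc[0, 1] == crm.q.values.min()


def test_matrix_total_equals_clustered_edges():
    rng = np.random.default_rng(43)
    edges = [(f"tf{int(rng.integers(5))}", f"g{int(rng.integers(30))}")
             for _ in range(60)]
    nodes = {n for e in edges for n in e}
    clusters = ClusterModel(k=3, assignments={n: int(rng.integers(3))
                                              for n in nodes},
                            centroids=None, seed=0, inertia=0.0)
    crm = net.cluster_regulation_enrichment(_trn_from_edges(edges), clusters)
    assert crm.counts.values.sum() == len(edges)


def test_random_cluster_assignment_is_calibrated():
    rng = np.random.default_rng(47)
    flagged, total = 0, 0
    for _ in range(50):
        edges = [(f"tf{int(rng.integers(8))}", f"g{int(rng.integers(40))}")
                 for _ in range(80)]
        nodes = {n for e in edges for n in e}
        clusters = ClusterModel(k=3, assignments={n: int(rng.integers(3))
                                                  for n in nodes},
                                centroids=None, seed=0, inertia=0.0)
        crm = net.cluster_regulation_enrichment(_trn_from_edges(edges), clusters)
        flagged += int((crm.q.values <= 0.05).sum())
        total += crm.q.size
    assert flagged / total <= 0.10
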
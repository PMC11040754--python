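"""PAV calling, occupancy classes, rarefaction, frequency scan, clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pantropon.pav import (PavMatrix, call_presence, classify_occupancy,
                           cluster_dispensable, frequency_change_scan,
                           jaccard_distance_matrix, occupancy_thresholds,
                           pan_core_curve)


def make_matrix(presence: np.ndarray, groups=None) -> PavMatrix:
    genes = [f"g{i}" for i in range(presence.shape[0])]
    accs = [f"a{j}" for j in range(presence.shape[1])]
    g = pd.Series(groups if groups is not None else ["all"] * len(accs), index=accs)
    return PavMatrix(presence=pd.DataFrame(presence, index=genes, columns=accs),
                     groups=g)


# ---------------------------------------------------------------------------
# presence calling

def depth_row(acc, gene, exon, length, covered):
    return {"accession": acc, "gene": gene, "exon": exon,
            "exon_length": length, "covered_bases": covered}


@pytest.mark.parametrize("covered,expected", [(85, 1), (80, 0), (81, 1), (0, 0)])
def test_call_presence_threshold_is_strict(covered, expected):
    table = pd.DataFrame([depth_row("a1", "g1", "e1", 100, covered)])
    m = call_presence(table)
    assert m.presence.loc["g1", "a1"] == expected


def test_call_presence_sums_over_exons():
    table = pd.DataFrame([depth_row("a1", "g1", "e1", 100, 100),
                          depth_row("a1", "g1", "e2", 100, 70)])
    # 170/200 = 0.85 > 0.8 -> present
    assert call_presence(table).presence.loc["g1", "a1"] == 1


def test_call_presence_zero_exon_length_errors():
    table = pd.DataFrame([depth_row("a1", "g1", "e1", 0, 0)])
    with pytest.raises(ValueError, match="zero total exon length"):
        call_presence(table)


def test_call_presence_lost_cutoff_mode():
    table = pd.DataFrame([depth_row("a1", "g1", "e1", 100, 25),
                          depth_row("a1", "g2", "e1", 100, 15)])
    m = call_presence(table, mode="lost_cutoff")
    assert m.presence.loc["g1", "a1"] == 1  # 0.25 >= 0.2
    assert m.presence.loc["g2", "a1"] == 0


# ---------------------------------------------------------------------------
# occupancy

def test_occupancy_thresholds_reproduce_published_boundaries_at_n341():
    assert occupancy_thresholds(341) == (337, 324, 4)


@pytest.mark.parametrize("count,expected", [
    (341, "core"), (338, "core"), (337, "softcore"), (324, "softcore"),
    (323, "shell"), (4, "shell"), (3, "cloud"), (0, "cloud")])
def test_classify_occupancy_boundaries_at_n341(count, expected):
    presence = np.zeros((1, 341), dtype=np.int8)
    presence[0, :count] = 1
    occ = classify_occupancy(make_matrix(presence))
    assert occ.classes.iloc[0] == expected


def test_classify_occupancy_partitions_genes():
    rng = np.random.default_rng(0)
    presence = (rng.random((200, 341)) < rng.random((200, 1))).astype(np.int8)
    occ = classify_occupancy(make_matrix(presence))
    assert occ.counts().sum() == 200


def test_classify_occupancy_requires_four_accessions():
    with pytest.raises(ValueError):
        classify_occupancy(make_matrix(np.ones((2, 3), dtype=np.int8)))


# ---------------------------------------------------------------------------
# pan/core curves

def test_pan_core_curve_all_present_is_flat_with_zero_width_interval():
    m = make_matrix(np.ones((5, 8), dtype=np.int8))
    curve = pan_core_curve(m, n_samplings=50, seed=0)
    assert (curve["pan_mean"] == 5).all() and (curve["core_mean"] == 5).all()
    assert (curve["pan_lo"] == curve["pan_hi"]).all()


def test_pan_core_curve_full_panel_size_equals_panel_values():
    rng = np.random.default_rng(1)
    pres = (rng.random((20, 10)) < 0.7).astype(np.int8)
    m = make_matrix(pres)
    curve = pan_core_curve(m, n_samplings=20, sizes=[10], seed=0)
    assert curve["pan_mean"].iloc[0] == (pres.any(axis=1)).sum()
    assert curve["core_mean"].iloc[0] == (pres.all(axis=1)).sum()


def test_pan_core_curve_size2_matches_exhaustive_pair_enumeration():
    """Sampled mean at size 2 agrees with brute-force enumeration of all 45
    accession pairs on a 10-accession fixture."""
    rng = np.random.default_rng(2)
    pres = (rng.random((5, 10)) < 0.5).astype(np.int8)
    m = make_matrix(pres)
    pans, cores = [], []
    for i, j in itertools.combinations(range(10), 2):
        sub = pres[:, [i, j]]
        pans.append(sub.any(axis=1).sum())
        cores.append(sub.all(axis=1).sum())
    exact_pan, exact_core = np.mean(pans), np.mean(cores)
    curve = pan_core_curve(m, n_samplings=4000, sizes=[2], seed=0)
    assert abs(curve["pan_mean"].iloc[0] - exact_pan) < 0.05 * exact_pan
    assert abs(curve["core_mean"].iloc[0] - exact_core) < 0.05 * max(exact_core, 1)


def test_pan_core_curve_nested_mode_is_monotone():
    rng = np.random.default_rng(3)
    pres = (rng.random((30, 12)) < 0.6).astype(np.int8)
    m = make_matrix(pres)
    curve = pan_core_curve(m, n_samplings=30, seed=0, nested=True)
    assert (np.diff(curve["pan_mean"]) >= 0).all()
    assert (np.diff(curve["core_mean"]) <= 0).all()


# ---------------------------------------------------------------------------
# frequency scan

def hypergeom_fisher_p(a, b, c, d):
    """Independent two-sided Fisher p by full hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def pmf(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


def test_scan_identical_frequencies_are_ns():
    pres = np.tile([1, 1, 0, 1, 1, 0], (10, 1)).astype(np.int8)
    m = make_matrix(pres, groups=["g1"] * 3 + ["g2"] * 3)
    out = frequency_change_scan(m, "g1")
    assert (out["fold_change"] == 1).all()
    assert (out["verdict"] == "ns").all()


def test_scan_fisher_p_matches_hypergeometric_enumeration():
    """2x2 (90,10) vs (40,60): exact-test p equals full enumeration."""
    pres = np.concatenate([np.ones(90), np.zeros(10), np.ones(40), np.zeros(60)])
    m = make_matrix(pres[None, :].astype(np.int8),
                    groups=["focal"] * 100 + ["other"] * 100)
    out = frequency_change_scan(m, "focal")
    assert out["p"].iloc[0] == pytest.approx(hypergeom_fisher_p(90, 10, 40, 60),
                                             rel=1e-9)


def test_scan_planted_fold_change_flagged_and_null_clean():
    """50 planted fc=4 genes all flagged favorable; 450 null genes produce no
    flags at FDR 0.001 (expected false positives < 1)."""
    rng = np.random.default_rng(4)
    n_f, n_o = 120, 120
    groups = ["focal"] * n_f + ["other"] * n_o
    planted = (rng.random((50, n_f + n_o))
               < np.concatenate([np.full(n_f, 0.8), np.full(n_o, 0.2)])).astype(np.int8)
    null = (rng.random((450, n_f + n_o)) < 0.5).astype(np.int8)
    m = make_matrix(np.vstack([planted, null]), groups=groups)
    out = frequency_change_scan(m, "focal")
    planted_ids = [f"g{i}" for i in range(50)]
    null_ids = [f"g{i}" for i in range(50, 500)]
    assert (out.loc[planted_ids, "verdict"] == "favorable").all()
    assert (out.loc[out.index.intersection(null_ids), "verdict"] == "ns").all()


def test_scan_haldane_continuity_on_zero_cells():
    pres = np.concatenate([np.ones(50), np.zeros(50)])[None, :].astype(np.int8)
    m = make_matrix(pres, groups=["focal"] * 50 + ["other"] * 50)
    out = frequency_change_scan(m, "focal")
    assert np.isfinite(out["fold_change"].iloc[0])
    assert out["fold_change"].iloc[0] > 2


def test_scan_excludes_genes_absent_everywhere_and_checks_groups():
    pres = np.zeros((2, 6), dtype=np.int8)
    pres[0, :2] = 1
    m = make_matrix(pres, groups=["g1"] * 3 + ["g2"] * 3)
    out = frequency_change_scan(m, "g1")
    assert list(out.index) == ["g0"]
    with pytest.raises(ValueError):
        frequency_change_scan(m, "missing-group")


# ---------------------------------------------------------------------------
# clustering

def test_cluster_dispensable_recovers_planted_blocks():
    from sklearn.metrics import adjusted_rand_score
    rng = np.random.default_rng(5)
    blocks = []
    truth = []
    for b in range(4):
        pat = np.zeros(40, dtype=np.int8)
        pat[b * 10:(b + 1) * 10] = 1
        blocks.append(np.tile(pat, (25, 1)))
        truth += [b] * 25
    m = make_matrix(np.vstack(blocks))
    labels = cluster_dispensable(m, k=4, seed=0)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_cluster_dispensable_edge_cases():
    m = make_matrix((np.arange(20) % 2)[:, None].repeat(6, 1).astype(np.int8))
    one = cluster_dispensable(m, k=1, seed=0)
    assert one.nunique() == 1
    two = cluster_dispensable(m, k=2, seed=0)
    # identical rows land in the same cluster
    assert two[::2].nunique() == 1 and two[1::2].nunique() == 1
    with pytest.raises(ValueError):
        cluster_dispensable(m, k=100, seed=0)


def test_jaccard_distance_matrix_is_symmetric_zero_diagonal():
    rng = np.random.default_rng(6)
    m = make_matrix((rng.random((30, 8)) < 0.5).astype(np.int8))
    d = jaccard_distance_matrix(m)
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
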
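"""LTR dating, clustering, specificity, lifespan, retention, spatial stats."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pantropon.core import Interval, decode
from pantropon.ltr import (LtrElement, SaturationError, adjacent_homolog_spacings,
                           assign_specificity, cluster_elements, cluster_lifespan,
                           date_element, homolog_spacing_test, jukes_cantor,
                           ltr_gene_distance_stats, retention_rates)
from pantropon.simulate import mutate_jc


def rand_seq(rng, n):
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


# ---------------------------------------------------------------------------
# dating

def test_identical_repeats_date_to_zero():
    a = date_element("ACGT" * 100, "ACGT" * 100)
    assert a.p == 0 and a.K == 0 and a.T == 0


def test_dating_closed_form_at_p_0018():
    """p = 0.018 -> K = 0.0182195..., T = 2.0244e6 yr (frozen closed-form
    values computed independently at high precision)."""
    rng = np.random.default_rng(0)
    ltr5 = rand_seq(rng, 1000)
    # plant exactly 18 substitutions
    vals = list(ltr5)
    for i in rng.choice(1000, 18, replace=False):
        vals[i] = "ACGT"[("ACGT".index(vals[i]) + 1) % 4]
    ltr3 = "".join(vals)
    a = date_element(ltr5, ltr3)
    assert a.p == pytest.approx(0.018, abs=1e-12)
    assert a.K == pytest.approx(0.0182195194267834, rel=1e-12)
    assert a.T == pytest.approx(2024391.0474203805, rel=1e-12)


def test_dating_saturation_errors():
    with pytest.raises(SaturationError):
        jukes_cantor(0.75)
    rng = np.random.default_rng(1)
    with pytest.raises(ValueError):
        date_element(rand_seq(rng, 5), "", r=9e-9)


def test_dating_is_monotone_in_mismatch_proportion():
    rng = np.random.default_rng(2)
    base = rng.integers(0, 4, 2000, dtype=np.uint8)
    ts = []
    for lam in (0.001, 0.005, 0.02, 0.08):
        a = decode(mutate_jc(base, lam, rng))
        b = decode(mutate_jc(base, lam, rng))
        ts.append(date_element(a, b).T)
    assert all(x < y for x, y in zip(ts, ts[1:]))


def test_dating_tolerates_terminal_indels():
    """Free end gaps: ragged repeat termini do not inflate p."""
    rng = np.random.default_rng(3)
    core = rand_seq(rng, 1000)
    a = date_element(rand_seq(rng, 30) + core, core + rand_seq(rng, 25))
    assert a.p < 0.01


def test_ltr_element_validation():
    iv = Interval("c", 0, 100)
    with pytest.raises(ValueError):
        LtrElement("e", "A2", iv, "Gypsy", "f", "", "ACGT")
    with pytest.raises(ValueError):
        LtrElement("e", "A2", iv, "Gypsy", "f", "A" * 100, "A" * 50)


# ---------------------------------------------------------------------------
# clustering

def elements_df(seqs, genomes=None):
    return pd.DataFrame({
        "element_id": [f"e{i}" for i in range(len(seqs))],
        "genome": genomes or ["A2"] * len(seqs),
        "chrom": "c", "start": 0, "end": [len(s) for s in seqs],
        "family": "f", "superfamily": "Gypsy",
        "ltr5_seq": "A" * 100, "ltr3_seq": "A" * 100, "seq": seqs})


def test_cluster_identical_elements_form_one_cluster():
    rng = np.random.default_rng(4)
    s = rand_seq(rng, 3000)
    clusters = cluster_elements(elements_df([s] * 10))
    assert len(clusters) == 1 and len(clusters[0].member_ids) == 10


def test_cluster_two_planted_families_resolve_exactly():
    """2% within-family divergence, unrelated between families -> 2 clusters."""
    rng = np.random.default_rng(5)
    fams = [rng.integers(0, 4, 4000, dtype=np.uint8) for _ in range(2)]
    seqs, labels = [], []
    for fi, cons in enumerate(fams):
        for _ in range(10):
            seqs.append(decode(mutate_jc(cons, 0.02, rng)))
            labels.append(fi)
    clusters = cluster_elements(elements_df(seqs))
    assert len(clusters) == 2
    for cl in clusters:
        member_fams = {labels[int(m[1:])] for m in cl.member_ids}
        assert len(member_fams) == 1


def test_cluster_singleton_and_empty():
    rng = np.random.default_rng(6)
    clusters = cluster_elements(elements_df([rand_seq(rng, 2000)]))
    assert len(clusters) == 1 and len(clusters[0].member_ids) == 1
    with pytest.raises(ValueError):
        cluster_elements(elements_df([]))


# ---------------------------------------------------------------------------
# genome specificity

@pytest.mark.parametrize("comp,expected", [
    ({"A2": 95, "At": 3, "Dt": 2}, "A2"),
    ({"At": 50, "Dt": 48, "A2": 2}, "At_Dt"),
    ({"A2": 30, "At": 25, "Dt": 25, "D5": 20}, "common"),
    ({"A2": 40, "At": 40, "Dt": 19, "D5": 1}, "A2_At_Dt"),
])
def test_assign_specificity_examples(comp, expected):
    assert assign_specificity(comp) == expected


def test_assign_specificity_empty_cluster_errors():
    with pytest.raises(ValueError):
        assign_specificity({})


def oracle_specificity(comp):
    """Independent literal re-evaluation of the decision tree."""
    order = ("A2", "At", "D5", "Dt")
    total = sum(comp.get(g, 0) for g in order)
    fr = [comp.get(g, 0) / total for g in order]
    for g, f in zip(order, fr):
        if f > 0.9:
            return g
    pair_sums = {}
    for (i, g1), (j, g2) in itertools.combinations(enumerate(order), 2):
        pair_sums[(g1, g2)] = fr[i] + fr[j]
    best = max(pair_sums, key=lambda k: pair_sums[k])
    # ties: first pair in canonical enumeration order, as the implementation
    best = next(k for k in pair_sums if pair_sums[k] == pair_sums[best])
    if pair_sums[best] > 0.9:
        return "_".join(best)
    mins = min(fr)
    if mins < 0.1:
        g_min = order[fr.index(mins)]
        return "_".join(g for g in order if g != g_min)
    return "common"


def test_assign_specificity_matches_brute_force_oracle():
    """Exhaustive agreement over every composition vector with total <= 20."""
    order = ("A2", "At", "D5", "Dt")
    for total in range(1, 21):
        for a in range(total + 1):
            for b in range(total - a + 1):
                for c in range(total - a - b + 1):
                    d = total - a - b - c
                    comp = dict(zip(order, (a, b, c, d)))
                    assert assign_specificity(comp) == oracle_specificity(comp), comp


# ---------------------------------------------------------------------------
# lifespan

def test_lifespan_percentiles():
    assert cluster_lifespan(np.full(5, 7.0)) == (7.0, 7.0)
    ages = np.arange(1, 101) * 1e4
    t_start, t_end = cluster_lifespan(ages)
    assert t_start == pytest.approx(95.05e4)
    assert t_end == pytest.approx(5.95e4)
    assert cluster_lifespan(np.array([1.0])) == (pytest.approx(np.nan, nan_ok=True),) * 2


# ---------------------------------------------------------------------------
# retention rates

def test_retention_cv_hand_example():
    loci = pd.DataFrame([{"locus_id": "L1", "aln_length": 1000,
                          "retained_A2": 800, "retained_At": 800,
                          "retained_D5": 200, "retained_Dt": 200},
                         {"locus_id": "L2", "aln_length": 1000,
                          "retained_A2": 400, "retained_At": 400,
                          "retained_D5": 400, "retained_Dt": 400}])
    out = retention_rates(loci, cv_cutoffs=(0.5,))
    sub = out[out["genome"].isin(["A2", "At", "D5", "Dt"])]
    # only L1 passes CV >= 0.5 (sample sd/mean = 346.4/500 = 0.6928); L2 has CV 0
    assert (sub["n_loci"] == 1).all()
    got = dict(zip(sub["genome"], sub["mean_retention"]))
    assert got == {"A2": 0.8, "At": 0.8, "D5": 0.2, "Dt": 0.2}


def test_retention_planted_tetraploid_deletion_detected():
    from pantropon.simulate import SimulationConfig, simulate_retention_loci
    loci = simulate_retention_loci(SimulationConfig(seed=2))
    out = retention_rates(loci, cv_cutoffs=(0.0, 0.5))
    high = out[(out["cv_cutoff"] == 0.5) & out["genome"].isin(["A2", "At", "D5", "Dt"])]
    m = dict(zip(high["genome"], high["mean_retention"]))
    assert (m["At"] + m["Dt"]) / 2 < (m["A2"] + m["D5"]) / 2


def test_retention_zero_alignment_length_skipped():
    loci = pd.DataFrame([{"locus_id": "L1", "aln_length": 0,
                          "retained_A2": 0, "retained_At": 0,
                          "retained_D5": 0, "retained_Dt": 0}])
    out = retention_rates(loci, cv_cutoffs=(0.0,))
    assert (out["n_loci"] == 0).all()


# ---------------------------------------------------------------------------
# spatial statistics

def test_distance_stats_null_slope_and_planted_trend():
    rng = np.random.default_rng(7)
    genes = [Interval("c", int(s), int(s) + 1000)
             for s in np.arange(0, 2_000_000, 50_000)]
    # planted: old elements near genes, young far
    rows, ages = [], []
    for i in range(60):
        age = rng.uniform(1e5, 3e6)
        gene = genes[int(rng.integers(0, len(genes)))]
        offset = int(4 + (3e6 - age) / 3e6 * 20_000)
        start = gene.end + offset
        rows.append({"element_id": f"e{i}", "chrom": "c", "start": start,
                     "end": start + 2000, "superfamily": "Gypsy"})
        ages.append({"element_id": f"e{i}", "T": age})
    out = ltr_gene_distance_stats(pd.DataFrame(rows), pd.DataFrame(ages),
                                  genes, {"c": 2_100_000}, n_perm=200, seed=0)
    assert out["Gypsy"]["slope_kb_per_myr"] < 0
    assert out["Gypsy"]["slope_p"] < 0.05


def test_distance_stats_single_element_gives_na_slope():
    genes = [Interval("c", 0, 1000)]
    el = pd.DataFrame([{"element_id": "e0", "chrom": "c", "start": 5000,
                        "end": 6000, "superfamily": "Copia"}])
    ages = pd.DataFrame([{"element_id": "e0", "T": 1e6}])
    out = ltr_gene_distance_stats(el, ages, genes, {"c": 100_000}, n_perm=50,
                                  seed=0)
    assert np.isnan(out["Copia"]["slope_kb_per_myr"])
    with pytest.raises(ValueError):
        ltr_gene_distance_stats(el, ages, [], {"c": 100_000})


# ---------------------------------------------------------------------------
# homolog spacing

def test_spacing_identical_gives_zero_log_ratios():
    d = np.array([1000.0, 2000, 3000, 1500, 800])
    out = homolog_spacing_test(d, d, n_rand=100, seed=0)
    assert np.allclose(out["log_ratios"], 0)


def test_spacing_errors_and_single_pair_na():
    with pytest.raises(ValueError, match="paired"):
        homolog_spacing_test(np.array([1.0, 2.0]), np.array([1.0]))
    with pytest.raises(ValueError, match="positive"):
        homolog_spacing_test(np.array([0.0]), np.array([1.0]))
    out = homolog_spacing_test(np.array([1000.0]), np.array([1200.0]))
    assert np.isnan(out["p"])


def test_spacing_null_self_consistency_p_is_not_degenerate():
    """Spacings shuffled as their own null give non-extreme p over seeds."""
    rng = np.random.default_rng(8)
    ps = []
    for seed in range(20):
        d1 = rng.lognormal(8, 1, 60)
        d2 = np.random.default_rng(seed).permutation(
            rng.lognormal(8, 1, 60))
        ps.append(homolog_spacing_test(d1, d2, n_rand=300, seed=seed)["p"])
    ps = np.array(ps)
    assert (ps < 0.01).mean() <= 0.2
    assert ps.max() > 0.1


def test_adjacent_homolog_spacings_from_annotations(small_quartet):
    quartet, _ = small_quartet
    pairs = adjacent_homolog_spacings(quartet.genes, "A2", "At")
    assert len(pairs) > 10
    assert (pairs["d_diploid"] > 0).all() and (pairs["d_tetraploid"] > 0).all()
    # the quartet conserves gene order and most spacings -> log ratios peak at 0
    lr = np.log2(pairs["d_tetraploid"] / pairs["d_diploid"])
    assert np.median(np.abs(lr)) < 0.1
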
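"""Full-length LTR retrotransposon dynamics.

Insertion dating from terminal-repeat divergence under the Jukes-Cantor
correction (T = K / r with the nucleotide mutation rate r = 9e-9 per site
per year), 90/90 family clustering, genome-specificity of clusters,
amplification lifespans, retention/deletion rates in homologous regions,
and spatial statistics of elements relative to genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval, greedy_cluster, nearest_distances, rng_for
from .origin import distance_permutation_test

GENOME_ORDER = ("A2", "At", "D5", "Dt")


@dataclass
class LtrElement:
    """A full-length LTR retrotransposon with both terminal repeats."""

    element_id: str
    genome: str
    interval: Interval
    superfamily: str
    family: str
    ltr5_seq: str
    ltr3_seq: str
    seq: str = ""

    def __post_init__(self):
        if not self.ltr5_seq or not self.ltr3_seq:
            raise ValueError(f"{self.element_id}: terminal repeats must be non-empty")
        ratio = len(self.ltr5_seq) / len(self.ltr3_seq)
        if not (0.8 <= ratio <= 1.25):
            raise ValueError(f"{self.element_id}: terminal repeat lengths too dissimilar")


def elements_from_frame(df: pd.DataFrame) -> list[LtrElement]:
    out = []
    for row in df.itertuples():
        out.append(LtrElement(
            element_id=row.element_id, genome=row.genome,
            interval=Interval(chrom=row.chrom, start=int(row.start), end=int(row.end),
                              genome=row.genome),
            superfamily=row.superfamily, family=row.family,
            ltr5_seq=row.ltr5_seq, ltr3_seq=row.ltr3_seq,
            seq=getattr(row, "seq", "")))
    return out


# ---------------------------------------------------------------------------
# dating

@dataclass
class LtrAge:
    element_id: str
    p: float  # mismatch proportion between aligned terminal repeats
    K: float  # Jukes-Cantor distance
    T: float  # years


class SaturationError(ValueError):
    """Terminal repeats diverged beyond the Jukes-Cantor domain (p >= 0.75)."""


def jukes_cantor(p: float) -> float:
    """K = -(3/4) ln(1 - (4/3) p); undefined at p >= 0.75."""
    if p >= 0.75:
        raise SaturationError(f"mismatch proportion {p} is saturated (>= 0.75)")
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def _gap_penalized_aligner():
    from Bio import Align
    al = Align.PairwiseAligner(match_score=1, mismatch_score=-2,
                               open_gap_score=-7, extend_gap_score=-2)
    # free end gaps: the repeats may be annotated with ragged termini
    for attr in ("open_left_insertion_score", "extend_left_insertion_score",
                 "open_right_insertion_score", "extend_right_insertion_score",
                 "open_left_deletion_score", "extend_left_deletion_score",
                 "open_right_deletion_score", "extend_right_deletion_score"):
        setattr(al, attr, 0)
    return al


def date_element(ltr5: str, ltr3: str, r: float = 9e-9,
                 divergence_factor: float = 1.0,
                 element_id: str = "") -> LtrAge:
    """Insertion age from terminal-repeat divergence.

    The repeats are globally aligned with free end gaps and internal gaps
    penalised more than substitutions (so clustered substitutions are not
    re-explained as indel pairs); gap columns are excluded, p = mismatches /
    compared sites, K is Jukes-Cantor corrected, and
    T = K / (divergence_factor * r).  The default factor 1 is the printed
    T = K/r convention; pass 2 for the two-sided clock in which each repeat
    diverges at rate r, halving all ages.

    Equal-length repeat pairs whose edit distance equals their Hamming
    distance take a fast path: the substitution-only alignment is then
    provably optimal under any gap-penalised scoring, so p is the Hamming
    mismatch fraction.
    """
    if not ltr5 or not ltr3:
        raise ValueError("empty terminal repeat")
    if len(ltr5) == len(ltr3):
        ham = sum(a != b for a, b in zip(ltr5, ltr3))
        if edlib.align(ltr5, ltr3, mode="NW", task="distance")["editDistance"] == ham:
            p = ham / len(ltr5)
            K = jukes_cantor(p)
            return LtrAge(element_id=element_id, p=p, K=K,
                          T=K / (divergence_factor * r))
    aln = _gap_penalized_aligner().align(ltr5, ltr3)[0]
    matches = mismatches = 0
    for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1]):
        mismatches += sum(a != b for a, b in zip(ltr5[qs:qe], ltr3[ts:te]))
        matches += (qe - qs) - sum(a != b for a, b in zip(ltr5[qs:qe], ltr3[ts:te]))
    compared = matches + mismatches
    if compared == 0:
        raise ValueError("no aligned (gap-free) columns between the repeats")
    p = mismatches / compared
    K = jukes_cantor(p)
    return LtrAge(element_id=element_id, p=p, K=K, T=K / (divergence_factor * r))


def date_elements(df: pd.DataFrame, r: float = 9e-9,
                  divergence_factor: float = 1.0) -> pd.DataFrame:
    """Date every element of an element table; saturated or undatable
    elements get NA with a note."""
    rows = []
    for row in df.itertuples():
        try:
            a = date_element(row.ltr5_seq, row.ltr3_seq, r=r,
                             divergence_factor=divergence_factor,
                             element_id=row.element_id)
            rows.append((row.element_id, a.p, a.K, a.T, ""))
        except ValueError as exc:
            rows.append((row.element_id, np.nan, np.nan, np.nan, str(exc)))
    return pd.DataFrame(rows, columns=["element_id", "p", "K", "T", "note"])


# ---------------------------------------------------------------------------
# clustering and genome specificity

@dataclass
class LtrCluster:
    cluster_id: str
    member_ids: list
    composition: dict  # genome -> member count
    specificity: str = ""
    lifespan: tuple = (np.nan, np.nan)  # (t_start old, t_end young)


def cluster_elements(df: pd.DataFrame, identity: float = 0.90,
                     coverage: float = 0.90) -> list[LtrCluster]:
    """90/90-style clustering of full-length element sequences by greedy
    length-sorted centroid clustering (deterministic)."""
    if len(df) == 0:
        raise ValueError("no elements to cluster")
    items = [(row.element_id, row.seq) for row in df.itertuples()]
    genome_of = dict(zip(df["element_id"], df["genome"]))
    clusters = []
    for i, cl in enumerate(greedy_cluster(items, identity=identity, coverage=coverage)):
        comp: dict = {}
        for m in cl.members:
            comp[genome_of[m]] = comp.get(genome_of[m], 0) + 1
        clusters.append(LtrCluster(cluster_id=f"C{i:04d}", member_ids=list(cl.members),
                                   composition=comp))
    return clusters


def assign_specificity(composition: dict, single_frac: float = 0.90,
                       pair_frac: float = 0.90, minor_frac: float = 0.10) -> str:
    """Genome-specificity decision tree over a cluster's composition vector.

    Rules, applied in order: (1) one genome holds strictly more than
    ``single_frac`` of members -> that genome; (2) the best genome pair holds
    strictly more than ``pair_frac`` -> pair label; (3) the smallest
    contributor falls strictly below ``minor_frac`` -> label of the remaining
    three genomes (e.g. A2_At_Dt for an element family that crossed between
    the subgenomes but is absent from D5); (4) otherwise common.
    """
    total = sum(composition.get(g, 0) for g in GENOME_ORDER)
    if total == 0:
        raise ValueError("empty cluster")
    frac = {g: composition.get(g, 0) / total for g in GENOME_ORDER}
    for g in GENOME_ORDER:
        if frac[g] > single_frac:
            return g
    best_pair, best_sum = None, -1.0
    for i, g1 in enumerate(GENOME_ORDER):
        for g2 in GENOME_ORDER[i + 1:]:
            s = frac[g1] + frac[g2]
            if s > best_sum:
                best_pair, best_sum = (g1, g2), s
    if best_sum > pair_frac:
        return "_".join(best_pair)
    minor = min(GENOME_ORDER, key=lambda g: frac[g])
    if frac[minor] < minor_frac:
        return "_".join(g for g in GENOME_ORDER if g != minor)
    return "common"


def cluster_lifespan(ages: np.ndarray) -> tuple[float, float]:
    """Amplification lifespan (t_start, t_end) = (95th, 5th) percentile of
    member insertion ages (linear-interpolation percentiles); NA with fewer
    than 2 dated members."""
    ages = np.asarray(ages, dtype=float)
    ages = ages[np.isfinite(ages)]
    if len(ages) < 2:
        return (np.nan, np.nan)
    return (float(np.percentile(ages, 95)), float(np.percentile(ages, 5)))


def annotate_clusters(clusters: list[LtrCluster], ages: pd.DataFrame,
                      **spec_kw) -> list[LtrCluster]:
    """Fill specificity labels and lifespans in place (ages: element_id, T)."""
    age_of = ages.set_index("element_id")["T"]
    for cl in clusters:
        cl.specificity = assign_specificity(cl.composition, **spec_kw)
        cl.lifespan = cluster_lifespan(age_of.reindex(cl.member_ids).to_numpy())
    return clusters


# ---------------------------------------------------------------------------
# retention / deletion rates in homologous regions

def retention_rates(loci: pd.DataFrame, cv_cutoffs=(0.0, 0.3, 0.5, 0.7),
                    genomes=GENOME_ORDER) -> pd.DataFrame:
    """Mean LTR retention rate per genome at increasing variability cutoffs.

    ``loci`` columns: locus_id, aln_length, retained_<genome> for each
    genome.  Retention rate = retained length / alignment length; for each
    CV cutoff only loci whose retained lengths have a coefficient of
    variation (sample sd / mean) at or above the cutoff are kept.  Pairwise
    Welch t-tests between genomes accompany each cutoff.
    """
    loci = loci[loci["aln_length"] > 0].copy()
    ret = loci[[f"retained_{g}" for g in genomes]].to_numpy(dtype=float)
    rates = ret / loci["aln_length"].to_numpy()[:, None]
    mean = ret.mean(axis=1)
    sd = ret.std(axis=1, ddof=1)
    cv = np.where(mean > 0, sd / mean, 0.0)
    rows = []
    for cut in cv_cutoffs:
        keep = cv >= cut
        sub = rates[keep]
        for gi, g in enumerate(genomes):
            rows.append({"cv_cutoff": cut, "genome": g, "n_loci": int(keep.sum()),
                         "mean_retention": float(sub[:, gi].mean()) if keep.any() else np.nan})
        for gi, g1 in enumerate(genomes):
            for gj in range(gi + 1, len(genomes)):
                g2 = genomes[gj]
                if keep.sum() >= 2:
                    p = float(stats.ttest_ind(sub[:, gi], sub[:, gj], equal_var=False).pvalue)
                else:
                    p = np.nan
                rows.append({"cv_cutoff": cut, "genome": f"{g1}_vs_{g2}",
                             "n_loci": int(keep.sum()), "p_t_test": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial statistics

def ltr_gene_distance_stats(elements: pd.DataFrame, ages: pd.DataFrame,
                            genes: list[Interval], chrom_lengths: dict,
                            n_perm: int = 1000, seed: int = 0) -> dict:
    """Per-superfamily nearest-gene distances, permutation p-values, and the
    OLS regression of distance (kb) on insertion age (Myr).

    Returns superfamily -> dict with distances, p_closer/p_farther (null:
    length-matched uniform random placements), slope_kb_per_myr, slope_p.
    """
    if not genes:
        raise ValueError("no genes supplied")
    age_of = ages.set_index("element_id")["T"]
    out = {}
    for sf, sub in elements.groupby("superfamily", sort=True):
        ivs = [Interval(chrom=r.chrom, start=int(r.start), end=int(r.end))
               for r in sub.itertuples()]
        d = nearest_distances(ivs, genes)
        ok = np.isfinite(d)
        perm = distance_permutation_test(
            [iv for iv, o in zip(ivs, ok) if o], genes, chrom_lengths,
            n_perm=n_perm, seed=seed)
        t = age_of.reindex(sub["element_id"]).to_numpy()
        good = ok & np.isfinite(t)
        if good.sum() >= 2 and np.nanstd(t[good]) > 0:
            reg = stats.linregress(t[good] / 1e6, d[good] / 1e3)
            slope, slope_p = float(reg.slope), float(reg.pvalue)
        else:
            slope, slope_p = np.nan, np.nan
        out[sf] = {"distances": d[ok], "observed_mean": perm["observed_mean"],
                   "p_closer": perm["p_closer"], "p_farther": perm["p_farther"],
                   "slope_kb_per_myr": slope, "slope_p": slope_p,
                   "n_elements": int(ok.sum())}
    return out


def adjacent_homolog_spacings(genes: pd.DataFrame, diploid: str,
                              tetraploid_sub: str) -> pd.DataFrame:
    """Spacings between adjacent homologous gene pairs shared by a diploid
    and the corresponding tetraploid subgenome.

    A pair qualifies when two gene families are adjacent (same chromosome,
    same order) in both genomes with positive spacing in both.  Returns
    columns family_a, family_b, d_diploid, d_tetraploid.
    """
    def ordered(genome):
        sub = genes[genes["genome"] == genome].sort_values(["chrom", "start"])
        return sub

    dip = ordered(diploid)
    tet = ordered(tetraploid_sub)
    tet_pos = {r.family_id: (r.chrom, int(r.start), int(r.end))
               for r in tet.itertuples()}
    tet_next: dict = {}
    for chrom, sub in tet.groupby("chrom"):
        fams = sub["family_id"].tolist()
        for a, b in zip(fams, fams[1:]):
            tet_next[a] = b
    rows = []
    for chrom, sub in dip.groupby("chrom"):
        recs = list(sub.itertuples())
        for a, b in zip(recs, recs[1:]):
            if tet_next.get(a.family_id) != b.family_id:
                continue
            dd = int(b.start) - int(a.end)
            ta, tb = tet_pos[a.family_id], tet_pos[b.family_id]
            dt = tb[1] - ta[2]
            if dd > 0 and dt > 0:
                rows.append((a.family_id, b.family_id, dd, dt))
    return pd.DataFrame(rows, columns=["family_a", "family_b", "d_diploid", "d_tetraploid"])


def homolog_spacing_test(d_diploid: np.ndarray, d_tetraploid: np.ndarray,
                         n_rand: int = 1000, seed: int = 0,
                         n_bins: int = 10) -> dict:
    """Test whether adjacent-homolog spacings are conserved between a diploid
    and the tetraploid.

    The observable is log2(tetraploid spacing / diploid spacing) per pair
    (a conserved genome peaks at 0).  The null preserves gene order but
    shuffles the inter-gene distances within each genome, re-pairing them;
    observed and null histograms share quantile bins of the null and are
    compared by a chi-square test.
    """
    d_dip = np.asarray(d_diploid, dtype=float)
    d_tet = np.asarray(d_tetraploid, dtype=float)
    if len(d_dip) != len(d_tet):
        raise ValueError("spacing lists must be paired")
    if (d_dip <= 0).any() or (d_tet <= 0).any():
        raise ValueError("spacings must be positive")
    obs = np.log2(d_tet / d_dip)
    if len(obs) < 2:
        return {"log_ratios": obs, "chi2": np.nan, "p": np.nan}
    rng = rng_for(seed, "homolog-spacing")
    null = np.empty((n_rand, len(obs)))
    for i in range(n_rand):
        null[i] = np.log2(rng.permutation(d_tet) / rng.permutation(d_dip))
    flat = null.ravel()
    edges = np.quantile(flat, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    edges = np.unique(edges)
    obs_counts, _ = np.histogram(obs, bins=edges)
    null_counts, _ = np.histogram(flat, bins=edges)
    expected = null_counts / null_counts.sum() * obs_counts.sum()
    keep = expected > 0
    chi2, p = stats.chisquare(obs_counts[keep], f_exp=expected[keep])
    return {"log_ratios": obs, "chi2": float(chi2), "p": float(p),
            "bin_edges": edges, "observed_counts": obs_counts,
            "expected_counts": expected}
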
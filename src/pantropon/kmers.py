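"""Genome-specific k-mer identification and clustering.

K-mer phasing between homoeologous genomes: canonical 15-mers are counted
per genome, high-abundance k-mers whose relative abundance in one genome is
more than twice that in its partner are called genome-specific, and
candidate k-mers are k-means-clustered on z-scaled relative abundances with
bootstrap support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import canonical_codes, encode, rng_for, seq_canonical_codes


@dataclass
class KmerProfile:
    """Canonical k-mer counts per genome, floored at ``min_count``.

    ``counts`` is a DataFrame indexed by packed k-mer code with one column
    per genome; only k-mers whose maximum per-genome count exceeds
    ``min_count`` (strictly) are retained.
    """

    k: int
    counts: pd.DataFrame
    min_count: int
    genome_totals: pd.Series = field(default_factory=pd.Series)


def default_min_count(genome_len: int, cotton_scale_count: int = 100,
                      cotton_genome_bp: float = 1.6e9) -> int:
    """Abundance floor scaled from the count-over-100 rule at cotton scale
    down to toy genomes: max(2, round(100 * genome_len / 1.6 Gb))."""
    return max(2, round(cotton_scale_count * genome_len / cotton_genome_bp))


def count_kmers(genomes: dict, k: int = 15, min_count: int | None = None) -> KmerProfile:
    """Count canonical k-mers in each genome (dict genome -> {chrom -> seq}).

    K-mers containing non-ACGT bases are skipped.  A genome whose every
    sequence is shorter than k yields an empty column with a warning.
    ``min_count`` defaults to the genome-length-scaled floor; retention
    requires the maximum count across genomes to exceed it strictly.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd so a k-mer cannot equal its reverse complement")
    series = {}
    totals = {}
    for g, seqs in genomes.items():
        parts = [seq_canonical_codes(s, k) for s in seqs.values()]
        allc = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        if allc.size == 0:
            warnings.warn(f"genome {g}: no sequence of length >= k={k}; empty profile")
            series[g] = pd.Series(dtype=np.int64)
        else:
            codes, counts = np.unique(allc, return_counts=True)
            series[g] = pd.Series(counts, index=codes)
        totals[g] = int(sum(len(s) for s in seqs.values()))
    df = pd.DataFrame(series).fillna(0).astype(np.int64)
    if min_count is None:
        min_count = default_min_count(max(totals.values(), default=0))
    df = df[df.max(axis=1) > min_count]
    return KmerProfile(k=k, counts=df, min_count=min_count,
                       genome_totals=pd.Series(totals))


@dataclass
class SpecificKmerSet:
    """K-mers assigned to a genome, with optional cluster id and bootstrap
    support."""

    k: int
    assignments: pd.Series  # kmer code -> genome label
    clusters: pd.Series | None = None  # kmer code -> cluster id
    support: pd.Series | None = None  # kmer code -> co-clustering fraction

    def codes_for(self, genome: str) -> np.ndarray:
        return np.sort(self.assignments.index[self.assignments == genome].to_numpy())


def differential_kmers(profile: KmerProfile, genome_a: str, genome_b: str,
                       ratio: float = 2.0) -> SpecificKmerSet:
    """Genome-specific k-mers between two (homoeologous) genomes.

    Relative abundance is the count normalised by the genome's total retained
    k-mer count; a k-mer is assigned to ``genome_a`` iff rel_a > ratio * rel_b
    (strictly), and symmetrically.  A zero partner count assigns the k-mer to
    the non-zero genome (its retention already passed the abundance floor).
    """
    for g in (genome_a, genome_b):
        if g not in profile.counts.columns:
            raise KeyError(f"genome {g} not in profile")
    ca = profile.counts[genome_a].to_numpy(dtype=float)
    cb = profile.counts[genome_b].to_numpy(dtype=float)
    ta, tb = ca.sum(), cb.sum()
    if ta == 0 or tb == 0:
        raise ValueError("zero total k-mer count in one genome")
    ra, rb = ca / ta, cb / tb
    lab = np.full(len(ca), "", dtype=object)
    lab[ra > ratio * rb] = genome_a
    lab[rb > ratio * ra] = genome_b
    keep = lab != ""
    return SpecificKmerSet(k=profile.k,
                           assignments=pd.Series(lab[keep], index=profile.counts.index[keep]))


def candidate_matrix(profile: KmerProfile, candidates: pd.Index) -> pd.DataFrame:
    """Relative-abundance matrix (k-mers x genomes) for clustering."""
    sub = profile.counts.loc[candidates].astype(float)
    return sub / sub.sum(axis=0)


def cluster_and_bootstrap(profile: KmerProfile, candidates: pd.Index, n_groups: int,
                          n_boot: int = 1000, boot_frac: float = 0.5,
                          seed: int = 0) -> SpecificKmerSet:
    """K-means clustering of candidate k-mers with bootstrap support.

    Columns (per-genome relative abundances) are z-scaled before clustering.
    Support is, per k-mer, the fraction of resamplings (each drawing
    ``boot_frac`` of the k-mers) in which the k-mer's nearest full-data
    centroid equals its full-data assignment when re-clustered; with
    ``n_boot=0`` support is NA.
    """
    mat = candidate_matrix(profile, candidates)
    if len(mat) == 0:
        raise ValueError("no candidate k-mers to cluster")
    if n_groups > len(mat.drop_duplicates()):
        raise ValueError("n_groups exceeds the number of distinct k-mer profiles")
    x = mat.to_numpy()
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    rng = rng_for(seed, "kmer-cluster")
    km = KMeans(n_clusters=n_groups, n_init=10,
                random_state=int(rng.integers(0, 2**31)))
    labels = km.fit_predict(z)
    genome_cols = list(mat.columns)
    # name each cluster by its dominant genome signature for readability
    assign = pd.Series([genome_cols[int(np.argmax(z[i]))] for i in range(len(z))],
                       index=mat.index)
    clusters = pd.Series(labels, index=mat.index, name="cluster")
    if n_boot <= 0:
        return SpecificKmerSet(k=profile.k, assignments=assign, clusters=clusters,
                               support=None)
    n = len(z)
    m = max(1, int(round(boot_frac * n)))
    hits = np.zeros(n)
    tries = np.zeros(n)
    for _ in range(n_boot):
        idx = rng.choice(n, m, replace=False)
        bkm = KMeans(n_clusters=n_groups, n_init=3,
                     random_state=int(rng.integers(0, 2**31))).fit(z[idx])
        # map bootstrap centroids onto full-data clusters by nearest centroid
        mapping = np.argmin(((bkm.cluster_centers_[:, None, :]
                              - km.cluster_centers_[None, :, :]) ** 2).sum(-1), axis=1)
        boot_lab = mapping[bkm.labels_]
        hits[idx] += boot_lab == labels[idx]
        tries[idx] += 1
    support = pd.Series(np.where(tries > 0, hits / np.maximum(tries, 1), np.nan),
                        index=mat.index, name="support")
    return SpecificKmerSet(k=profile.k, assignments=assign, clusters=clusters,
                           support=support)


def kmer_positions(seqs: dict, codes: np.ndarray, k: int) -> pd.DataFrame:
    """Exact genomic positions (BED-like) of the given canonical k-mer codes."""
    codes = np.sort(np.asarray(codes))
    rows = []
    for chrom, seq in seqs.items():
        c, valid = canonical_codes(encode(seq), k)
        pos = np.nonzero(valid)[0]
        c = c[valid]
        j = np.searchsorted(codes, c)
        j = np.clip(j, 0, max(len(codes) - 1, 0))
        hit = codes[j] == c if len(codes) else np.zeros(len(c), dtype=bool)
        for p in pos[hit]:
            rows.append((chrom, int(p), int(p) + k))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
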
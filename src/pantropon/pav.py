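"""Gene presence/absence variation (PAV) analysis.

Coverage-based presence calling, occupancy classification (core / soft-core
/ shell / cloud), pan/core rarefaction curves, a group-differential gene
frequency scan, and k-means clustering of dispensable genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from statsmodels.stats.multitest import multipletests

from .core import rng_for


@dataclass
class PavMatrix:
    """Accessions x genes binary presence matrix with group labels."""

    presence: pd.DataFrame  # genes (rows) x accessions (columns), values 0/1
    groups: pd.Series  # accession -> group label

    @property
    def genes(self) -> list:
        return list(self.presence.index)

    @property
    def accessions(self) -> list:
        return list(self.presence.columns)

    def presence_counts(self) -> pd.Series:
        return self.presence.sum(axis=1)


def call_presence(depth_table: pd.DataFrame, groups: pd.Series | None = None,
                  min_cov: int = 2, present_frac: float = 0.8,
                  mode: str = "covered_fraction", lost_cutoff: float = 0.2) -> PavMatrix:
    """Call gene presence from per-exon covered-base summaries.

    A gene is present in an accession iff the fraction of its total exon
    length covered by reads at depth >= ``min_cov`` is strictly greater than
    ``present_frac`` (the primary, results-facing rule).  ``mode="lost_cutoff"``
    is the alternative convention: absent iff covered fraction < ``lost_cutoff``
    (and present otherwise).

    The table must carry columns accession, gene, exon, exon_length,
    covered_bases, where covered_bases already reflects the ``min_cov`` depth
    floor.
    """
    required = {"accession", "gene", "exon_length", "covered_bases"}
    if not required.issubset(depth_table.columns):
        raise ValueError(f"depth table must have columns {sorted(required)}")
    agg = depth_table.groupby(["gene", "accession"])[["exon_length", "covered_bases"]].sum()
    if (agg["exon_length"] == 0).any():
        bad = agg.index[agg["exon_length"] == 0][0][0]
        raise ValueError(f"gene {bad} has zero total exon length")
    frac = agg["covered_bases"] / agg["exon_length"]
    if mode == "covered_fraction":
        present = (frac > present_frac).astype(np.int8)
    elif mode == "lost_cutoff":
        present = (frac >= lost_cutoff).astype(np.int8)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mat = present.unstack("accession").fillna(0).astype(np.int8)
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    if groups is None:
        groups = pd.Series("all", index=mat.columns)
    return PavMatrix(presence=mat, groups=groups.reindex(mat.columns))


@dataclass
class OccupancyClass:
    classes: pd.Series  # gene -> core|softcore|shell|cloud
    core_min: int  # core iff count > core_min
    soft_min: int  # softcore iff soft_min <= count <= core_min
    cloud_max: int  # cloud iff count < cloud_max

    def counts(self) -> pd.Series:
        return self.classes.value_counts().reindex(
            ["core", "softcore", "shell", "cloud"], fill_value=0)


def occupancy_thresholds(n: int, core_q: float = 0.99, soft_q: float = 0.95,
                         cloud_q: float = 0.01) -> tuple[int, int, int]:
    """(core_min, soft_min, cloud_max) boundaries for an n-accession panel.

    At n=341 these are 337 / 324 / 4: core genes are present in > 337
    accessions, soft-core in 324..337, cloud in < 4, shell otherwise.
    """
    return (math.floor(core_q * n), math.ceil(soft_q * n), math.ceil(cloud_q * n))


def classify_occupancy(matrix: PavMatrix, core_q: float = 0.99, soft_q: float = 0.95,
                       cloud_q: float = 0.01) -> OccupancyClass:
    n = len(matrix.accessions)
    if n < 4:
        raise ValueError("need at least 4 accessions to classify occupancy")
    core_min, soft_min, cloud_max = occupancy_thresholds(n, core_q, soft_q, cloud_q)
    c = matrix.presence_counts()
    cls = pd.Series("shell", index=c.index, dtype=object)
    cls[c > core_min] = "core"
    cls[(c >= soft_min) & (c <= core_min)] = "softcore"
    cls[c < cloud_max] = "cloud"
    return OccupancyClass(classes=cls, core_min=core_min, soft_min=soft_min,
                          cloud_max=cloud_max)


def dispensable_genes(matrix: PavMatrix, **kw) -> list:
    """Genes not classified core (soft-core + shell + cloud)."""
    cls = classify_occupancy(matrix, **kw).classes
    return list(cls.index[cls != "core"])


def pan_core_curve(matrix: PavMatrix, n_samplings: int = 1000, sizes=None,
                   seed: int = 0, nested: bool = False) -> pd.DataFrame:
    """Pan- and core-gene counts across random sub-panels.

    For each panel size, accessions are drawn without replacement
    ``n_samplings`` times; pan = genes present in at least one sampled
    accession, core = genes present in all of them.  Reports the mean and the
    0.5/99.5 percentiles (a 99% interval).  With ``nested=True`` every
    sampling is a prefix of one random permutation per replicate, which makes
    the pan (core) counts monotone non-decreasing (non-increasing) in size
    within each replicate.
    """
    mat = matrix.presence.to_numpy(dtype=bool)
    n = mat.shape[1]
    if n < 2:
        raise ValueError("need at least 2 accessions")
    sizes = list(range(2, n + 1)) if sizes is None else list(sizes)
    rng = rng_for(seed, "pan-core-curve")
    pan = np.empty((len(sizes), n_samplings), dtype=np.int64)
    core = np.empty_like(pan)
    if nested:
        for j in range(n_samplings):
            perm = rng.permutation(n)
            sub = mat[:, perm]
            any_cum = np.logical_or.accumulate(sub, axis=1)
            all_cum = np.logical_and.accumulate(sub, axis=1)
            for i, s in enumerate(sizes):
                pan[i, j] = any_cum[:, s - 1].sum()
                core[i, j] = all_cum[:, s - 1].sum()
    else:
        for i, s in enumerate(sizes):
            for j in range(n_samplings):
                idx = rng.choice(n, s, replace=False)
                sub = mat[:, idx]
                pan[i, j] = sub.any(axis=1).sum()
                core[i, j] = sub.all(axis=1).sum()
    return pd.DataFrame({
        "size": sizes,
        "pan_mean": pan.mean(axis=1), "pan_lo": np.percentile(pan, 0.5, axis=1),
        "pan_hi": np.percentile(pan, 99.5, axis=1),
        "core_mean": core.mean(axis=1), "core_lo": np.percentile(core, 0.5, axis=1),
        "core_hi": np.percentile(core, 99.5, axis=1),
    })


def frequency_change_scan(matrix: PavMatrix, focal_group: str, genes=None,
                          fc_hi: float = 2.0, fc_lo: float = 0.5,
                          fdr: float = 0.001) -> pd.DataFrame:
    """Scan for genes whose presence frequency differs between the focal
    group and all other accessions.

    fold_change = freq(focal) / freq(other), with Haldane continuity (0.5
    added to all four 2x2 cells) only when a zero cell exists; p-values from
    Fisher's exact test of presence x group; q-values by Benjamini-Hochberg.
    Verdict: favorable iff fc > fc_hi and q < fdr; unfavorable iff fc < fc_lo
    and q < fdr; otherwise ns.  Genes absent in both groups are excluded.
    """
    focal_mask = (matrix.groups == focal_group).to_numpy()
    if focal_mask.sum() == 0 or (~focal_mask).sum() == 0:
        raise ValueError("both focal and other groups must be non-empty")
    sub = matrix.presence if genes is None else matrix.presence.loc[list(genes)]
    pres = sub.to_numpy()
    n_f, n_o = int(focal_mask.sum()), int((~focal_mask).sum())
    a = pres[:, focal_mask].sum(axis=1)  # present, focal
    c = pres[:, ~focal_mask].sum(axis=1)  # present, other
    keep = (a + c) > 0
    rows = []
    for gi in np.nonzero(keep)[0]:
        t = np.array([[a[gi], n_f - a[gi]], [c[gi], n_o - c[gi]]], dtype=float)
        if (t == 0).any():
            th = t + 0.5
        else:
            th = t
        fc = (th[0, 0] / th[0].sum()) / (th[1, 0] / th[1].sum())
        p = fisher_exact(t.astype(int))[1]
        rows.append((sub.index[gi], fc, p))
    out = pd.DataFrame(rows, columns=["gene", "fold_change", "p"]).set_index("gene")
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    verdict = np.full(len(out), "ns", dtype=object)
    verdict[(out["fold_change"] > fc_hi) & (out["q"] < fdr)] = "favorable"
    verdict[(out["fold_change"] < fc_lo) & (out["q"] < fdr)] = "unfavorable"
    out["verdict"] = verdict
    return out


def cluster_dispensable(matrix: PavMatrix, genes=None, k: int = 4, seed: int = 0,
                        n_init: int = 10) -> pd.Series:
    """K-means clustering of dispensable-gene presence profiles.

    Rows are genes, dimensions are accessions; 0/1 entries are fed as reals to
    Euclidean k-means (squared Euclidean on binary vectors is Hamming distance
    up to a factor, so the ordering is equivalent).
    """
    sub = matrix.presence if genes is None else matrix.presence.loc[list(genes)]
    if k > len(sub):
        raise ValueError("k exceeds the number of genes")
    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=int(rng_for(seed, "pav-kmeans").integers(0, 2**31)))
    labels = km.fit_predict(sub.to_numpy(dtype=float))
    return pd.Series(labels, index=sub.index, name="cluster")


def jaccard_distance_matrix(matrix: PavMatrix, genes=None) -> pd.DataFrame:
    """Accession x accession Jaccard distances on presence profiles, for
    external tree builders."""
    sub = matrix.presence if genes is None else matrix.presence.loc[list(genes)]
    x = sub.to_numpy(dtype=bool).T
    d = pairwise_distances(x, metric="jaccard")
    return pd.DataFrame(d, index=sub.columns, columns=sub.columns)
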
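"""Phylostratigraphic age bins for pangenes.

Gene age is the deepest taxon sharing an orthogroup with the pangene, on
the five-taxon ladder rice -> Arabidopsis -> G. kirkii -> G. raimondii ->
pangenome-only.  Age1 is the oldest bin (shared with the monocot) and Age5
the youngest (species-specific).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import Interval, nearest_distances

#: ladder from deepest (oldest) to shallowest; pangenes itself is the floor
DEFAULT_LADDER = ("O_sativa", "A_thaliana", "G_kirkii", "G_raimondii")


def assign_age(table: pd.DataFrame, ladder=DEFAULT_LADDER,
               pangene_taxon: str = "pangenes") -> pd.Series:
    """Assign an age bin to every pangene from an orthogroup membership table.

    ``table`` has columns (orthogroup, taxon, gene).  The bin is
    1 + the ladder index of the deepest taxon with at least one ortholog in
    the pangene's orthogroup; a pangene whose orthogroup contains no ladder
    taxon (including unclustered singletons) gets the youngest bin.
    """
    known = set(ladder) | {pangene_taxon}
    bad = set(table["taxon"]) - known
    if bad:
        raise ValueError(f"unknown taxon label(s): {sorted(bad)}")
    youngest = len(ladder) + 1
    depth = {t: i + 1 for i, t in enumerate(ladder)}
    og_depth = (table.assign(d=table["taxon"].map(depth))
                .groupby("orthogroup")["d"].min())
    pan = table[table["taxon"] == pangene_taxon]
    if pan["gene"].duplicated().any():
        dup = pan.loc[pan["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"pangene {dup} appears in more than one orthogroup")
    bins = pan["orthogroup"].map(og_depth).fillna(youngest).astype(int)
    return pd.Series(bins.values, index=pan["gene"].values, name="age_bin").sort_index()


def age_vs_nascent(assignment: pd.Series, genes: list[Interval],
                   nascent: list[Interval]) -> pd.DataFrame:
    """Per-bin overlap fraction with nascent intervals and mean distance to
    the nearest one (0 when overlapping); empty bins give NA rows."""
    gene_bins = {}
    for g in genes:
        gene_bins.setdefault(int(assignment.get(g.label, -1)), []).append(g)
    rows = []
    for b in sorted(set(assignment)):
        members = gene_bins.get(int(b), [])
        if not members:
            rows.append((b, 0, np.nan, np.nan))
            continue
        if not nascent:
            rows.append((b, len(members), 0.0, np.nan))
            continue
        d = nearest_distances(members, nascent)
        rows.append((b, len(members), float(np.nanmean(d == 0)),
                     float(np.nanmean(d))))
    return pd.DataFrame(rows, columns=["age_bin", "n_genes", "overlap_fraction",
                                       "mean_distance"]).set_index("age_bin")


def age_feature_trends(assignment: pd.Series, features: pd.DataFrame,
                       feature_cols=("length", "exon_count", "expression",
                                     "presence_freq", "ka_ks")) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin medians and Spearman rank correlation of each feature with the
    age-bin index.

    Returns ``(medians, correlations)``; a feature with no finite values gets
    NA.  ``features`` must carry a gene_id column to join on.
    """
    df = features.set_index("gene_id").join(assignment.rename("age_bin"), how="inner")
    medians = df.groupby("age_bin")[list(feature_cols)].median()
    rows = []
    for col in feature_cols:
        v = df[col].astype(float)
        ok = np.isfinite(v)
        if ok.sum() < 3 or v[ok].nunique() <= 1:
            rows.append((col, 0.0 if v[ok].nunique() == 1 else np.nan, np.nan))
            continue
        rho, p = spearmanr(df.loc[ok, "age_bin"], v[ok])
        rows.append((col, float(rho), float(p)))
    corr = pd.DataFrame(rows, columns=["feature", "spearman_rho", "p"]).set_index("feature")
    return medians, corr
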
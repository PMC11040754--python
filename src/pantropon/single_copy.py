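"""Single-copy gene fate after polyploidisation.

Families with exactly one member in each diploid progenitor (A2 and D5) are
classified by their tetraploid member count -- retained in both subgenomes
(balanced), lost from both, reverted to a single copy, or gained -- and
losses are traced to a mechanism: a small variation / annotation omission
(the diploid gene still aligns nearly end-to-end in the losing subgenome)
or a TE disruption (the alignment is split around an inserted transposon).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .core import AlignmentRecord, Interval, intersect_len


@dataclass
class FamilyRecord:
    family_id: str
    counts: dict  # genome -> member count, keys A2, D5, At, Dt
    members: dict | None = None  # genome -> [gene ids]


@dataclass
class FateCall:
    family_id: str
    fate: str  # balanced | lost_both | reverted_single | gained | unbalanced_retention
    lost_subgenome: str  # At | Dt | both | none
    loss_mechanism: str = "NA"


def classify_fate(family: FamilyRecord) -> FateCall:
    """Fate from the member-count ratio among A2 : D5 : tetraploid.

    Eligibility requires exactly one member in each diploid.  Tetraploid
    total 2 with one member per subgenome is balanced (a 2+0 split is flagged
    unbalanced_retention); 0 is lost_both; 1 reverts to a single copy with
    the empty subgenome recorded; more than 2 is gained.
    """
    a2, d5 = family.counts.get("A2", 0), family.counts.get("D5", 0)
    if a2 != 1 or d5 != 1:
        raise ValueError(f"family {family.family_id} ineligible: diploid counts {a2}:{d5}")
    at, dt = family.counts.get("At", 0), family.counts.get("Dt", 0)
    total = at + dt
    if total == 0:
        return FateCall(family.family_id, "lost_both", "both")
    if total == 1:
        return FateCall(family.family_id, "reverted_single", "At" if at == 0 else "Dt")
    if total == 2:
        if at == 1 and dt == 1:
            return FateCall(family.family_id, "balanced", "none")
        return FateCall(family.family_id, "unbalanced_retention",
                        "At" if at == 0 else "Dt")
    return FateCall(family.family_id, "gained", "none")


def classify_families(families: list[FamilyRecord]) -> tuple[list[FateCall], int]:
    """Classify all eligible families; returns (calls, n_skipped_ineligible)."""
    calls = []
    skipped = 0
    for fam in families:
        try:
            calls.append(classify_fate(fam))
        except ValueError:
            skipped += 1
    return calls, skipped


def families_from_annotations(genes: pd.DataFrame) -> list[FamilyRecord]:
    """Build family records from a gene annotation table with columns
    (genome, gene_id, family_id)."""
    out = []
    for fam_id, sub in genes.groupby("family_id", sort=True):
        counts = sub.groupby("genome")["gene_id"].count().to_dict()
        members = sub.groupby("genome")["gene_id"].apply(list).to_dict()
        out.append(FamilyRecord(family_id=str(fam_id), counts=counts, members=members))
    return out


def trace_loss_mechanism(alignments: list[AlignmentRecord],
                         te_annotation: list[Interval],
                         gene_length: int, cover_frac: float = 0.90,
                         span_max: int = 25_000) -> str:
    """Mechanism of a single-copy loss from the lost gene's alignments
    against the losing subgenome.

    A single alignment covering strictly more than ``cover_frac`` of the gene
    means the loss is a small variation or an annotation omission.  Otherwise,
    two or more alignments whose target spans lie within ``span_max`` of each
    other (gap between consecutive spans) with a TE annotation overlapping an
    inter-alignment gap indicate a TE disruption.  Anything else is
    unexplained.
    """
    if not alignments:
        return "unexplained"
    best = max(alignments, key=lambda r: r.query_end - r.query_start)
    if (best.query_end - best.query_start) > cover_frac * gene_length:
        return "small_variation_or_annotation"
    if len(alignments) < 2:
        return "unexplained"
    te_by_chrom: dict = {}
    for iv in te_annotation:
        te_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    by_chrom: dict = {}
    for rec in alignments:
        by_chrom.setdefault(rec.target_id, []).append(rec)
    for chrom, recs in by_chrom.items():
        if len(recs) < 2:
            continue
        recs = sorted(recs, key=lambda r: r.target_start)
        for a, b in zip(recs, recs[1:]):
            gap = b.target_start - a.target_end
            if gap <= 0 or gap > span_max:
                continue
            if intersect_len([(a.target_end, b.target_start)],
                             te_by_chrom.get(chrom, [])) > 0:
                return "TE_disruption"
    return "unexplained"


def compare_fate_features(calls: list[FateCall], features: pd.DataFrame,
                          family_to_gene: dict | None = None,
                          feature_cols=("length", "exon_count", "ka_ks",
                                        "expression", "te_coverage")) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-fate feature summaries (mean +- SE) and pairwise two-sided
    Mann-Whitney tests per feature.

    ``features`` joins on gene_id; by default the family id doubles as the
    gene id (single-copy families), otherwise supply ``family_to_gene``.
    Fate classes with fewer than 2 members yield NA tests.
    """
    fate_of = {}
    for c in calls:
        gid = (family_to_gene or {}).get(c.family_id, c.family_id)
        fate_of[gid] = c.fate
    df = features.set_index("gene_id").join(
        pd.Series(fate_of, name="fate"), how="inner")
    cols = [c for c in feature_cols if c in df.columns]
    grp = df.groupby("fate")[cols]
    summary = grp.agg(["mean", "sem", "count"])
    fates = sorted(df["fate"].unique())
    rows = []
    for i, f1 in enumerate(fates):
        for f2 in fates[i + 1:]:
            for col in cols:
                x = df.loc[df["fate"] == f1, col].dropna()
                y = df.loc[df["fate"] == f2, col].dropna()
                if len(x) < 2 or len(y) < 2:
                    p = np.nan
                else:
                    p = float(mannwhitneyu(x, y, alternative="two-sided").pvalue)
                rows.append((f1, f2, col, p))
    tests = pd.DataFrame(rows, columns=["fate_a", "fate_b", "feature", "p"])
    return summary, tests
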
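"""Non-reference sequence (NRS) extraction.

Implements the map-to-pan filter chain: length-filter assembled contigs,
drop weak alignments against the reference, emit wholly unaligned contigs
and long continuously-unaligned contig regions as NRS candidates, and remove
redundancy by greedy centroid clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .core import AlignmentRecord, greedy_cluster, merge_spans, subtract_spans


@dataclass
class NrsSet:
    """Candidate non-reference sequences with provenance."""

    sequences: dict = field(default_factory=dict)  # id -> sequence
    provenance: dict = field(default_factory=dict)  # id -> unaligned_contig | unaligned_region
    source_contig: dict = field(default_factory=dict)  # id -> contig id

    def total_bp(self) -> int:
        return sum(len(s) for s in self.sequences.values())


def filter_contigs(contigs: dict, min_len: int = 500) -> dict:
    """Keep contigs strictly longer than ``min_len`` bp."""
    return {cid: seq for cid, seq in contigs.items() if len(seq) > min_len}


def extract_nrs(contigs: dict, alignments: list[AlignmentRecord],
                min_aln_len: int = 300, min_identity: float = 0.90,
                min_unaligned: int = 500) -> NrsSet:
    """Extract NRS candidates from contig-to-reference alignment records.

    Alignments are kept only when strictly longer than ``min_aln_len`` AND
    with identity strictly above ``min_identity``.  Contigs with no surviving
    alignment are emitted whole (``unaligned_contig``); otherwise, maximal
    unaligned query intervals strictly longer than ``min_unaligned`` are
    emitted (``unaligned_region``).  Overlapping surviving alignments are
    flattened before computing the unaligned intervals.

    Records whose coordinates exceed the contig length are rejected; the
    rejection count is reported through a warning.
    """
    surviving: dict = {cid: [] for cid in contigs}
    n_bad = 0
    for rec in alignments:
        if rec.query_id not in contigs:
            continue
        if rec.query_end > len(contigs[rec.query_id]) or rec.query_len != len(contigs[rec.query_id]):
            n_bad += 1
            continue
        if (rec.query_end - rec.query_start) > min_aln_len and rec.identity > min_identity:
            surviving[rec.query_id].append((rec.query_start, rec.query_end))
    if n_bad:
        warnings.warn(f"rejected {n_bad} alignment record(s) with out-of-range coordinates")

    out = NrsSet()
    for cid in sorted(contigs):
        seq = contigs[cid]
        aligned = merge_spans(surviving[cid])
        if not aligned:
            out.sequences[cid] = seq
            out.provenance[cid] = "unaligned_contig"
            out.source_contig[cid] = cid
            continue
        for i, (s, e) in enumerate(subtract_spans([(0, len(seq))], aligned)):
            if e - s > min_unaligned:
                nid = f"{cid}:{s}-{e}"
                out.sequences[nid] = seq[s:e]
                out.provenance[nid] = "unaligned_region"
                out.source_contig[nid] = cid
    return out


def deduplicate(nrs: NrsSet, identity: float = 0.90, coverage: float = 0.90,
                keep_list: set | None = None) -> NrsSet:
    """Redundancy removal by greedy length-sorted centroid clustering.

    ``keep_list``, when given, is an external screen (e.g. a contamination
    keep-list): only ids in it are considered at all.
    """
    items = [(nid, seq) for nid, seq in nrs.sequences.items()
             if keep_list is None or nid in keep_list]
    clusters = greedy_cluster(items, identity=identity, coverage=coverage)
    out = NrsSet()
    for cl in clusters:
        nid = cl.centroid
        out.sequences[nid] = nrs.sequences[nid]
        out.provenance[nid] = nrs.provenance[nid]
        out.source_contig[nid] = nrs.source_contig[nid]
    return out
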
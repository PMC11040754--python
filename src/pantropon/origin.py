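"""Nascent-versus-lost classification of genome-specific sequence.

After polyploidisation, a sequence present in only one of a homoeologous
genome pair is either nascent there (arose after divergence, typically by
repeat amplification) or ancestral but lost from the partner.  The pipeline:
fragment a genome into 1-kb windows, flag each window mapped/unmapped
against the partner, merge adjacent unmapped windows, optionally subtract
pangenome-backed spans, then mask each residual sequence with
genome-specific k-mers -- sequences with little masked content carry no
genome-private high-copy signal and are classified as lost from the partner;
the rest are nascent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (Interval, SeedIndex, canonical_codes, encode, merge_spans,
                   nearest_distances, rng_for, subtract_spans)
from .kmers import SpecificKmerSet


def fragment_genome(genome: dict, window: int = 1000) -> list[Interval]:
    """Tile each chromosome into non-overlapping windows after removing runs
    of N; a terminal remainder shorter than the window is kept as its own
    fragment.  Fragment coordinates refer to the original chromosome, so
    fragments flanking an N gap are not coordinate-contiguous."""
    out: list[Interval] = []
    for chrom, seq in genome.items():
        vals = encode(seq)
        isn = vals == 4
        # maximal non-N runs
        boundaries = np.flatnonzero(np.diff(np.concatenate([[1], isn.view(np.int8), [1]])))
        runs = boundaries.reshape(-1, 2) if isn.any() else np.array([[0, len(seq)]])
        if not isn.any() and len(seq) == 0:
            continue
        for rs, re in runs:
            pos = rs
            while pos < re:
                end = min(pos + window, re)
                out.append(Interval(chrom=chrom, start=int(pos), end=int(end)))
                pos = end
    return out


def map_fragments(fragments: list[Interval], genome: dict, index: SeedIndex,
                  min_support: float = 0.5) -> np.ndarray:
    """Mapped/unmapped flag per fragment via the exact-seed mapper: a
    fragment is mapped when its best target locus is supported by more than
    ``min_support`` of its seed windows (secondary loci are ignored)."""
    flags = np.zeros(len(fragments), dtype=bool)
    for i, frag in enumerate(fragments):
        seq = genome[frag.chrom][frag.start:frag.end]
        flags[i], _ = index.map_support(seq, min_support=min_support)
    return flags


def merge_unmapped(fragments: list[Interval], mapped_flags: np.ndarray) -> list[Interval]:
    """Merge maximal runs of coordinate-contiguous unmapped fragments."""
    if len(fragments) != len(mapped_flags):
        raise ValueError("flags must align with fragments")
    out: list[Interval] = []
    cur: Interval | None = None
    for frag, mapped in zip(fragments, mapped_flags):
        if mapped:
            cur = None
            continue
        if cur is not None and cur.chrom == frag.chrom and cur.end == frag.start:
            cur.end = frag.end
        else:
            cur = Interval(chrom=frag.chrom, start=frag.start, end=frag.end,
                           genome=frag.genome)
            out.append(cur)
    return out


def subtract_pangenome_hits(ref_unmapped: list[Interval], pan_mapped: list[Interval],
                            min_len: int = 500) -> list[Interval]:
    """Interval difference ref_unmapped \\ pan_mapped; only residual
    sub-intervals strictly longer than ``min_len`` are kept (same strict
    length convention as the NRS filters)."""
    pan_by_chrom: dict = {}
    for iv in pan_mapped:
        pan_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = []
    for iv in ref_unmapped:
        for s, e in subtract_spans([(iv.start, iv.end)], pan_by_chrom.get(iv.chrom, [])):
            if e - s > min_len:
                out.append(Interval(chrom=iv.chrom, start=s, end=e, genome=iv.genome))
    return out


@dataclass
class OriginCall:
    interval: Interval
    masked_bp: int
    masked_fraction: float
    verdict: str  # nascent | lost | ambiguous


def classify_origin(interval: Interval, sequence: str, specific: SpecificKmerSet,
                    genome_label: str, gap_join: int = 50,
                    lost_cutoff: float = 0.20) -> OriginCall:
    """Classify one genome-specific sequence as nascent or lost.

    Exact-match positions of the genome's specific k-mers are masked, masked
    runs separated by less than ``gap_join`` bp are joined, and the verdict is
    lost iff the joined masked fraction is strictly below ``lost_cutoff``
    (else nascent).  Masking uses canonical k-mers, so the verdict is
    invariant to reverse-complementing the sequence.
    """
    codes = specific.codes_for(genome_label)
    length = len(sequence)
    if codes.size == 0:
        return OriginCall(interval=interval, masked_bp=0, masked_fraction=0.0,
                          verdict="lost")
    k = specific.k
    c, valid = canonical_codes(encode(sequence), k)
    pos = np.nonzero(valid)[0]
    c = c[valid]
    j = np.clip(np.searchsorted(codes, c), 0, len(codes) - 1)
    hit_pos = pos[codes[j] == c]
    spans = merge_spans([(int(p), int(p) + k) for p in hit_pos])
    # join masked runs separated by < gap_join
    joined: list[list[int]] = []
    for s, e in spans:
        if joined and s - joined[-1][1] < gap_join:
            joined[-1][1] = e
        else:
            joined.append([s, e])
    masked = sum(min(e, length) - s for s, e in joined)
    frac = masked / length if length else 0.0
    verdict = "lost" if frac < lost_cutoff else "nascent"
    return OriginCall(interval=interval, masked_bp=masked, masked_fraction=frac,
                      verdict=verdict)


def classify_genome_pair(query_genome: dict, target_genome: dict,
                         specific: SpecificKmerSet, query_label: str,
                         window: int = 1000, seed_k: int = 31,
                         pan_mapped: list[Interval] | None = None,
                         gap_join: int = 50, lost_cutoff: float = 0.20) -> list[OriginCall]:
    """End-to-end origin classification of one genome against its partner:
    fragment -> map -> merge unmapped -> subtract pangenome hits -> classify.

    ``specific`` must be the k-mer set from the query-vs-target comparison;
    verdict nascent means nascent in the query genome, lost means lost from
    the target."""
    frags = fragment_genome(query_genome, window=window)
    index = SeedIndex(target_genome, k=seed_k)
    flags = map_fragments(frags, query_genome, index)
    regions = merge_unmapped(frags, flags)
    if pan_mapped is not None:
        regions = subtract_pangenome_hits(regions, pan_mapped)
    calls = []
    for iv in regions:
        seq = query_genome[iv.chrom][iv.start:iv.end]
        calls.append(classify_origin(iv, seq, specific, query_label,
                                     gap_join=gap_join, lost_cutoff=lost_cutoff))
    return calls


def distance_permutation_test(queries: list[Interval], genes: list[Interval],
                              genome_lengths: dict, n_perm: int = 1000,
                              seed: int = 0) -> dict:
    """Are the query intervals closer to genes than random length-matched
    placements?

    Distance is 0 for overlap, else the gap to the nearest gene; queries on
    chromosomes with no gene are excluded (an error if no genes exist at
    all).  The null is the per-permutation mean over uniform random
    placements of the same lengths on the same chromosomes.  Empirical
    p-values use the +1 correction; ``p_closer`` tests the "closer than
    random" tail (null mean <= observed), ``p_farther`` the opposite.
    """
    if not genes:
        raise ValueError("no genes supplied")
    gene_chroms = {g.chrom for g in genes}
    usable = [q for q in queries if q.chrom in gene_chroms]
    if not usable:
        raise ValueError("no query lies on a chromosome carrying genes")
    obs = float(np.nanmean(nearest_distances(usable, genes)))
    rng = rng_for(seed, "distance-permutation")
    null = np.empty(n_perm)
    chroms = [q.chrom for q in usable]
    lens = np.array([q.length for q in usable])
    for i in range(n_perm):
        placed = []
        for chrom, ln in zip(chroms, lens):
            hi = genome_lengths[chrom] - ln
            s = int(rng.integers(0, max(hi, 1)))
            placed.append(Interval(chrom=chrom, start=s, end=s + int(ln)))
        null[i] = np.nanmean(nearest_distances(placed, genes))
    p_closer = (1 + (null <= obs).sum()) / (n_perm + 1)
    p_farther = (1 + (null >= obs).sum()) / (n_perm + 1)
    return {"observed_mean": obs, "null": null, "p_closer": float(p_closer),
            "p_farther": float(p_farther), "n_queries": len(usable)}
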
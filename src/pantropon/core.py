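"""Shared primitives for the comparative-pangenome pipeline.

DNA is handled as plain upper-case strings at module boundaries and as
``uint8`` arrays (A=0, C=1, G=2, T=3, other=4) internally.  K-mers are packed
into 2-bit codes (``int64``, so k <= 31) and canonicalised as the minimum of a
window's forward and reverse-complement code.  Genomic intervals are 0-based
half-open everywhere inside the package; GFF3 emission converts at the edge.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import edlib
import numpy as np

# ---------------------------------------------------------------------------
# randomness

def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG stream derived from a master seed.

    Each pipeline stage draws from its own stream so stages can be rerun
    independently without perturbing one another.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


# ---------------------------------------------------------------------------
# sequence encoding

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(vals: np.ndarray) -> str:
    return _DEC[vals].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# k-mer codes

def kmer_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement 2-bit codes for every window.

    Returns ``(fwd, rc, valid)`` where ``valid`` marks windows free of
    non-ACGT bases.  Arrays have length ``len(vals) - k + 1`` (empty when the
    sequence is shorter than k).
    """
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing into int64")
    n = len(vals)
    m = n - k + 1
    if m <= 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty(0, dtype=bool)
    v = vals.astype(np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    rc = np.zeros(m, dtype=np.int64)
    for j in range(k):
        col = v[j : m + j]
        fwd = (fwd << 2) | (col & 3)
        rc |= (3 - (col & 3)) << (2 * j)
    bad = np.concatenate([[0], np.cumsum(vals == 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    return fwd, rc, valid


def canonical_codes(vals: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical (strand-symmetric) k-mer code per window plus validity mask."""
    fwd, rc, valid = kmer_codes(vals, k)
    return np.minimum(fwd, rc), valid


def seq_canonical_codes(seq: str, k: int) -> np.ndarray:
    """Valid canonical codes of every window of ``seq`` (positions dropped)."""
    codes, valid = canonical_codes(encode(seq), k)
    return codes[valid]


def count_canonical(seqs, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Count canonical k-mers over an iterable of sequences.

    Returns sorted unique codes and their counts.
    """
    parts = [seq_canonical_codes(s, k) for s in seqs]
    if not parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    allc = np.concatenate(parts)
    if allc.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.unique(allc, return_counts=True)


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append("ACGT"[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


# ---------------------------------------------------------------------------
# domain records

@dataclass
class Interval:
    """0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    genome: str = ""
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentRecord:
    """Query/target alignment span with an identity fraction (PAF-like)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    identity: float
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(f"bad query span on {self.query_id}")
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(f"bad target span on {self.target_id}")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")


# ---------------------------------------------------------------------------
# interval algebra (lists of (start, end) tuples on a single chromosome)

def merge_spans(spans) -> list[tuple[int, int]]:
    spans = sorted(spans)
    out: list[list[int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_spans(a, b) -> list[tuple[int, int]]:
    """Span-list difference a \\ b (both flattened first)."""
    a = merge_spans(a)
    b = merge_spans(b)
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        jj = j
        while jj < len(b) and b[jj][0] < e:
            bs, be = b[jj]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            jj += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_len(a, b) -> int:
    a = merge_spans(a)
    b = merge_spans(b)
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def group_by_chrom(intervals: list[Interval]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return out


def nearest_distances(queries: list[Interval], subjects: list[Interval]) -> np.ndarray:
    """Distance from each query to the nearest subject (0 when overlapping).

    Queries on chromosomes carrying no subject get ``nan``; callers decide
    whether to drop or to error on them.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for s in subjects:
        tmp.setdefault(s.chrom, []).append((s.start, s.end))
    for c, spans in tmp.items():
        spans = merge_spans(spans)
        by_chrom[c] = (np.array([s for s, _ in spans]), np.array([e for _, e in spans]))
    out = np.empty(len(queries))
    for i, q in enumerate(queries):
        if q.chrom not in by_chrom:
            out[i] = np.nan
            continue
        starts, ends = by_chrom[q.chrom]
        # subjects are merged and disjoint, so starts and ends are both sorted
        j = int(np.searchsorted(starts, q.end, side="left"))  # first subject fully right of q
        if j > 0 and ends[j - 1] > q.start:
            out[i] = 0.0  # overlap
            continue
        right = starts[j] - q.end if j < len(starts) else np.inf
        left = q.start - ends[j - 1] if j > 0 else np.inf
        out[i] = min(left, right)
    return out


# ---------------------------------------------------------------------------
# seed index: exact k-mer mapper for toy-scale fragment placement

class SeedIndex:
    """Canonical k-mer position index over a genome (dict chrom -> sequence).

    Serves the mapped/unmapped contract for 1-kb fragment placement: a
    fragment is *mapped* when the best diagonal band on one target locus is
    supported by more than ``min_support`` of its seed windows.
    """

    def __init__(self, seqs: dict[str, str], k: int = 31):
        self.k = k
        codes_all = []
        pos_all = []
        chrom_ids = []
        self.chroms = list(seqs)
        for ci, (chrom, seq) in enumerate(seqs.items()):
            codes, valid = canonical_codes(encode(seq), k)
            idx = np.nonzero(valid)[0]
            codes_all.append(codes[idx])
            pos_all.append(idx)
            chrom_ids.append(np.full(idx.size, ci, dtype=np.int32))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.int64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        cid = np.concatenate(chrom_ids) if chrom_ids else np.empty(0, dtype=np.int32)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]
        self.cid = cid[order]

    def hit_mask(self, codes: np.ndarray) -> np.ndarray:
        """Boolean mask: which query codes occur anywhere in the index."""
        j = np.searchsorted(self.codes, codes)
        j = np.clip(j, 0, max(len(self.codes) - 1, 0))
        if len(self.codes) == 0:
            return np.zeros(len(codes), dtype=bool)
        return self.codes[j] == codes

    def first_hits(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mask, target_pos, chrom_id) of the first indexed hit per code."""
        if len(self.codes) == 0:
            z = np.zeros(len(codes), dtype=bool)
            return z, np.zeros(len(codes), dtype=np.int64), np.zeros(len(codes), dtype=np.int32)
        j = np.clip(np.searchsorted(self.codes, codes), 0, len(self.codes) - 1)
        mask = self.codes[j] == codes
        return mask, self.pos[j], self.cid[j]

    def map_support(self, frag: str, band_bp: int = 200, min_support: float = 0.5) -> tuple[bool, float]:
        """Best-locus support of a fragment; mapped when support > min_support.

        Support is the fraction of the fragment's valid seed windows whose
        first hit falls in the modal (chromosome, diagonal-band) locus.
        """
        codes, valid = canonical_codes(encode(frag), self.k)
        qpos = np.nonzero(valid)[0]
        codes = codes[valid]
        n_windows = max(len(frag) - self.k + 1, 1)
        if codes.size == 0:
            return False, 0.0
        mask, tpos, cid = self.first_hits(codes)
        if not mask.any():
            return False, 0.0
        band = (tpos[mask] - qpos[mask]) // band_bp
        key = cid[mask].astype(np.int64) * (1 << 40) + (band - band.min())
        _, counts = np.unique(key, return_counts=True)
        support = counts.max() / n_windows
        return support > min_support, float(support)


def build_align_index(target: dict[str, str], k: int = 31) -> dict:
    """Per-chromosome sorted (codes, positions) arrays for seed_align reuse."""
    out = {}
    for chrom, tseq in target.items():
        tcodes, tvalid = canonical_codes(encode(tseq), k)
        tidx = np.nonzero(tvalid)[0]
        tcodes = tcodes[tidx]
        order = np.argsort(tcodes, kind="stable")
        out[chrom] = (tcodes[order], tidx[order])
    return out


def seed_align(query: str, target: dict[str, str], k: int = 31,
               max_band_shift: int = 1000, max_gap: int = 5000,
               index: dict | None = None) -> list[AlignmentRecord]:
    """Naive exact-seed aligner: seed matches chained within a diagonal band.

    A band shift larger than ``max_band_shift`` (e.g. a transposon insertion
    in the target) breaks the chain, producing separate alignment records;
    small indels stay within one chain.  Identity of each chained span is
    confirmed by global alignment (edlib).  Pass ``index`` from
    :func:`build_align_index` when aligning many queries to one target.
    """
    qvals = encode(query)
    qcodes, qvalid = canonical_codes(qvals, k)
    qpos_all = np.nonzero(qvalid)[0]
    qcodes = qcodes[qvalid]
    records: list[AlignmentRecord] = []
    if qcodes.size == 0:
        return records
    if index is None:
        index = build_align_index(target, k)
    for chrom, tseq in target.items():
        tsorted, tpos_sorted = index[chrom]
        j = np.searchsorted(tsorted, qcodes)
        j = np.clip(j, 0, max(len(tsorted) - 1, 0))
        mask = tsorted[j] == qcodes if len(tsorted) else np.zeros(len(qcodes), dtype=bool)
        if not mask.any():
            continue
        qp = qpos_all[mask]
        tp = tpos_sorted[j[mask]]
        order2 = np.argsort(qp, kind="stable")
        qp, tp = qp[order2], tp[order2]
        # greedy chaining
        chains: list[list[tuple[int, int]]] = []
        for a, b in zip(qp.tolist(), tp.tolist()):
            placed = False
            for ch in reversed(chains[-5:] if len(chains) > 5 else chains):
                lq, lt = ch[-1]
                if a >= lq and b >= lt and abs((b - a) - (lt - lq)) <= max_band_shift and a - lq <= max_gap:
                    ch.append((a, b))
                    placed = True
                    break
            if not placed:
                chains.append([(a, b)])
        for ch in chains:
            qs, ts = ch[0]
            qe, te = ch[-1][0] + k, ch[-1][1] + k
            if qe - qs < k:
                continue
            sub_q = query[qs:qe]
            sub_t = tseq[ts:te]
            res = edlib.align(sub_q, sub_t, mode="NW", task="distance")
            ident = 1.0 - res["editDistance"] / max(len(sub_q), len(sub_t))
            records.append(AlignmentRecord(
                query_id="query", query_len=len(query), query_start=int(qs), query_end=int(qe),
                target_id=chrom, target_start=int(ts), target_end=int(te),
                identity=float(ident), strand="+"))
    return records


# ---------------------------------------------------------------------------
# greedy centroid clustering (shared by NRS redundancy removal and LTR 90/90)

@dataclass
class Cluster:
    centroid: str
    members: list[str] = field(default_factory=list)


def greedy_cluster(items: list[tuple[str, str]], identity: float = 0.90,
                   coverage: float = 0.90, k: int = 15) -> list[Cluster]:
    """Length-sorted greedy centroid clustering.

    Items are ``(id, sequence)``.  Each sequence, visited in order of
    decreasing length (ties broken by id for determinism), joins the first
    centroid for which the shorter of the two aligns over >= ``coverage`` of
    its length at >= ``identity``; otherwise it founds a new centroid.
    K-mer containment of the shorter sequence prefilters centroid candidates;
    the decision itself is made by semi-global alignment (edlib), which aligns
    the whole shorter sequence (coverage 1.0) with free end gaps on the longer.
    """
    order = sorted(items, key=lambda t: (-len(t[1]), t[0]))
    cents: list[tuple[str, str, np.ndarray]] = []  # id, seq, sorted kmer codes
    clusters: dict[str, Cluster] = {}
    for sid, seq in order:
        codes = np.unique(seq_canonical_codes(seq, k))
        joined = None
        for cid, cseq, ccodes in cents:
            if codes.size:
                j = np.searchsorted(ccodes, codes)
                j = np.clip(j, 0, max(len(ccodes) - 1, 0))
                shared = (ccodes[j] == codes).sum() if len(ccodes) else 0
                if shared / codes.size < 0.05:
                    continue
            res = edlib.align(seq, cseq, mode="HW", task="distance")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / len(seq)
            if ident >= identity:
                joined = cid
                break
        if joined is None:
            cents.append((sid, seq, codes))
            clusters[sid] = Cluster(centroid=sid, members=[sid])
        else:
            clusters[joined].members.append(sid)
    return [clusters[cid] for cid, _, _ in cents]
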
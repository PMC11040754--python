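"""Synthetic four-genome quartet with planted truth.

The generator emulates the comparative setting of an allotetraploid and its
two diploid progenitors: two diverged diploid backbones (A and D lineages),
a tetraploid whose At/Dt subgenomes start as exact copies of the diploid
backbones, and then lineage-private edits -- nascent repeat-driven
insertions, sequence losses in the subgenomes, full-length LTR
retrotransposons of known insertion age, and single-copy gene families with
planted fates (balanced / lost in both subgenomes / reverted to single copy
via TE disruption or small deletion / gained).

Design notes
------------
* Coordinates are 0-based half-open.  All planted edits are placed on the
  shared ancestral backbone through one global reservation registry, so no
  two planted entities overlap anywhere in the quartet and every truth
  interval maps cleanly onto final genome coordinates.
* Nascent insertions are concatenations of a small library of novel repeat
  monomers private to a genome (or shared by At and Dt, emulating the
  tetraploid-joint repeat burst).  Repetition is what makes their k-mers
  exceed the abundance floor of the k-mer phasing stage, exactly as
  high-copy repeats do in real genomes; single-copy backbone that was lost
  from a subgenome stays below the floor.
* LTR terminal repeats are aged under a forward Jukes-Cantor model: the
  element's two repeats are mutated independently so that their *pair*
  divergence has expectation ``clock_factor * r * age`` substitutions per
  site.  With the default ``clock_factor = 1`` the dating convention
  T = K / r recovers planted ages.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import decode, encode, rng_for

GENOMES = ("A2", "At", "Dt", "D5")
SUBGENOMES = ("At", "Dt")
DIPLOID_OF = {"At": "A2", "Dt": "D5"}


class OverlapExhaustionError(RuntimeError):
    """Raised when requested planted features cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    seed: int = 0
    ancestor_length_bp: int = 4_000_000
    n_chromosomes: int = 4
    n_genes: int = 200
    # LTR elements
    n_ltr_families: int = 5
    n_ltr_per_family: int = 40
    ltr_length_bp: int = 8500
    terminal_repeat_bp: int = 3000
    mutation_rate_per_site_per_year: float = 9e-9
    age_range_years: tuple = (1e5, 3e6)
    ltr_clock_factor: float = 1.0
    # nascent / lost sequence
    n_nascent_per_genome: int = 20
    nascent_len_range: tuple = (8000, 20000)
    n_lost_per_subgenome: int = 20
    lost_len_range: tuple = (8000, 20000)
    repeat_monomer_bp: int = 1500
    # accession panel
    n_accessions: int = 50
    group_labels: tuple = (("CHN", 0.6), ("SouthAsia", 0.2), ("US", 0.15), ("other", 0.05))
    presence_sfs: tuple = (0.05, 0.95)
    dispensable_frac: float = 0.3
    n_favorable: int = 10
    depth_mean: float = 20.0
    depth_noise: float = 0.0
    # single-copy fate plan
    n_lost_both: int = 10
    n_reverted_per_subgenome: int = 15
    te_loss_frac: float = 0.5
    n_gained: int = 10
    # lineage divergence between A and D backbones (substitutions/site)
    lineage_divergence: float = 0.03
    # retention-locus panel
    n_retention_loci: int = 300

    def validate(self) -> None:
        mean_gene = 2000  # ~3 exons of ~550 bp plus introns
        if self.ancestor_length_bp < 10 * self.n_genes * mean_gene:
            raise ValueError("ancestor_length_bp must be >= 10x the total gene footprint")
        if self.n_chromosomes < 1 or self.ancestor_length_bp < self.n_chromosomes:
            raise ValueError("bad chromosome layout")
        if self.ltr_length_bp < 2 * self.terminal_repeat_bp + 100:
            raise ValueError("ltr_length_bp must leave room for an interior")
        if abs(sum(w for _, w in self.group_labels) - 1.0) > 1e-6:
            raise ValueError("group proportions must sum to 1")


# ---------------------------------------------------------------------------
# outputs

@dataclass
class GenomeQuartet:
    genomes: dict  # genome -> {chrom -> sequence str}
    genes: pd.DataFrame  # genome, chrom, start, end, gene_id, family_id
    exons: pd.DataFrame  # genome, chrom, start, end, gene_id, exon_id
    ltr: pd.DataFrame  # element_id, genome, chrom, start, end, family, superfamily,
    #                    ltr5_seq, ltr3_seq, seq
    reference: dict = field(default_factory=dict)  # A2 minus its nascent insertions

    def chrom_lengths(self, genome: str) -> dict:
        return {c: len(s) for c, s in self.genomes[genome].items()}


@dataclass
class TruthTables:
    nascent: pd.DataFrame  # genome, chrom, start, end (final coords of that genome)
    lost: pd.DataFrame  # subgenome, chrom, start, end (coords on retaining diploid)
    ltr_ages: pd.DataFrame  # element_id, genome, age_years
    family_fates: pd.DataFrame  # family_id, fate, lost_subgenome, mechanism
    te_disrupted: set
    pav_truth: pd.DataFrame  # genes x accessions, 0/1
    groups: pd.Series  # accession -> group label
    repeat_library: dict  # genome-set label -> [monomer sequences]
    gene_ages: pd.Series  # gene_id -> age bin (1 oldest .. 5 youngest)
    features: pd.DataFrame  # per-gene feature table


# ---------------------------------------------------------------------------
# low-level helpers

def mutate_jc(vals: np.ndarray, subs_per_site: float, rng: np.random.Generator) -> np.ndarray:
    """Forward Jukes-Cantor: per-site Poisson event count, each event replacing
    the base with one of the 3 alternatives uniformly (multiple hits allowed)."""
    out = vals.copy()
    if subs_per_site <= 0:
        return out
    m = rng.poisson(subs_per_site, len(vals))
    for r in range(1, int(m.max()) + 1 if m.size else 1):
        idx = np.nonzero(m >= r)[0]
        if idx.size == 0:
            break
        out[idx] = (out[idx] + rng.integers(1, 4, idx.size)) % 4
    return out


def random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.uint8)


class _Placer:
    """Global non-overlap registry on backbone coordinates."""

    def __init__(self, chrom_lengths: dict, rng: np.random.Generator, margin: int = 300):
        self.lens = chrom_lengths
        self.chroms = list(chrom_lengths)
        self.weights = np.array([chrom_lengths[c] for c in self.chroms], dtype=float)
        self.weights /= self.weights.sum()
        self.rng = rng
        self.margin = margin
        self.occ: dict = {c: [] for c in self.chroms}  # sorted (start, end)

    def _free(self, chrom: str, start: int, end: int) -> bool:
        occ = self.occ[chrom]
        i = bisect_left(occ, (start, -1))
        if i < len(occ) and occ[i][0] < end:
            return False
        if i > 0 and occ[i - 1][1] > start:
            return False
        return True

    def reserve(self, chrom: str, start: int, end: int) -> None:
        insort(self.occ[chrom], (start, end))

    def place(self, length: int, what: str = "feature") -> tuple[str, int]:
        """Reserve a span of ``length`` backbone bases (margin-padded) and
        return (chrom, start).  For insertions use length 0/small."""
        span = max(length, 1)
        for _ in range(2000):
            chrom = self.chroms[self.rng.choice(len(self.chroms), p=self.weights)]
            hi = self.lens[chrom] - span - self.margin
            if hi <= self.margin:
                continue
            start = int(self.rng.integers(self.margin, hi))
            if self._free(chrom, start - self.margin, start + span + self.margin):
                self.reserve(chrom, start - self.margin, start + span + self.margin)
                return chrom, start
        raise OverlapExhaustionError(
            f"could not place {what} of {length} bp without overlap; "
            "reduce counts/lengths or enlarge ancestor_length_bp")


@dataclass(eq=False)
class _Edit:
    chrom: str
    pos: int  # backbone coordinate (for deletions: start)
    kind: str  # "ins" | "del"
    seq: np.ndarray | None = None  # inserted bases
    end: int = 0  # deletion end (backbone)
    final_start: int = 0  # filled by _apply_edits for insertions
    final_end: int = 0


def _apply_edits(backbone: dict, edits: list) -> tuple[dict, dict]:
    """Apply insertions/deletions to a backbone; return final sequences and a
    per-chromosome coordinate map ``(positions, offsets)`` such that a backbone
    coordinate x (not inside a deletion) maps to ``x + offset`` where offset is
    the cumulative delta of all edits strictly left of x."""
    seqs = {}
    maps = {}
    by_chrom: dict = {}
    for e in edits:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, vals in backbone.items():
        evs = sorted(by_chrom.get(chrom, []), key=lambda e: (e.pos, 0 if e.kind == "del" else 1))
        parts = []
        cur = 0
        offset = 0
        positions = [0]
        offsets = [0]
        for e in evs:
            parts.append(vals[cur:e.pos])
            if e.kind == "ins":
                e.final_start = e.pos + offset
                e.final_end = e.final_start + len(e.seq)
                parts.append(e.seq)
                offset += len(e.seq)
                cur = e.pos
                positions.append(e.pos + 1)  # edits strictly left of x
            else:
                offset -= e.end - e.pos
                cur = e.end
                positions.append(e.end)
            offsets.append(offset)
        parts.append(vals[cur:])
        seqs[chrom] = decode(np.concatenate(parts) if parts else vals)
        maps[chrom] = (np.array(positions), np.array(offsets))
    return seqs, maps


def _map_coord(maps: dict, chrom: str, x: int) -> int:
    positions, offsets = maps[chrom]
    i = int(np.searchsorted(positions, x, side="right")) - 1
    return x + int(offsets[i])


# ---------------------------------------------------------------------------
# the quartet simulator

def simulate_quartet(config: SimulationConfig) -> tuple[GenomeQuartet, TruthTables]:
    """Generate the four-genome quartet plus complete planted-truth tables."""
    config.validate()
    rng = rng_for(config.seed, "simulate")
    n_chrom = config.n_chromosomes
    clen = config.ancestor_length_bp // n_chrom
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]

    ancestor = {c: random_seq(rng, clen) for c in chroms}
    half = config.lineage_divergence / 2
    backbone = {
        "A": {c: mutate_jc(v, half, rng) for c, v in ancestor.items()},
        "D": {c: mutate_jc(v, half, rng) for c, v in ancestor.items()},
    }
    lineage_of = {"A2": "A", "At": "A", "Dt": "D", "D5": "D"}

    placer = _Placer({c: clen for c in chroms}, rng)

    # ---- genes on shared backbone coordinates -----------------------------
    gene_rows = []
    exon_rows = []
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(1, 5))
        ex_lens = rng.integers(200, 1000, n_ex)
        in_lens = rng.integers(100, 500, max(n_ex - 1, 0))
        glen = int(ex_lens.sum() + in_lens.sum())
        chrom, start = placer.place(glen, "gene")
        gid = f"g{gi:04d}"
        gene_rows.append((gid, chrom, start, start + glen))
        pos = start
        for ei in range(n_ex):
            exon_rows.append((gid, f"{gid}.e{ei + 1}", chrom, pos, pos + int(ex_lens[ei])))
            pos += int(ex_lens[ei])
            if ei < n_ex - 1:
                pos += int(in_lens[ei])
    genes_bb = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    exons_bb = pd.DataFrame(exon_rows, columns=["gene_id", "exon_id", "chrom", "start", "end"])

    # ---- nascent repeat library and insertions ----------------------------
    lib_labels = ["A2", "A2", "D5", "D5", "At", "Dt", "At_Dt", "At_Dt"]
    repeat_library: dict = {}
    for lab in lib_labels:
        repeat_library.setdefault(lab, []).append(decode(random_seq(rng, config.repeat_monomer_bp)))

    def nascent_seq(genome: str, length: int) -> np.ndarray:
        pool = []
        for lab, monos in repeat_library.items():
            if genome in lab.split("_"):
                pool.extend(monos)
        parts = []
        total = 0
        while total < length:
            m = pool[int(rng.integers(0, len(pool)))]
            parts.append(encode(m))
            total += len(m)
        return np.concatenate(parts)[:length]

    edits: dict = {g: [] for g in GENOMES}
    nascent_edits: dict = {g: [] for g in GENOMES}
    for genome in GENOMES:
        for _ in range(config.n_nascent_per_genome):
            length = int(rng.integers(*config.nascent_len_range))
            chrom, pos = placer.place(0, "nascent insertion")
            e = _Edit(chrom, pos, "ins", seq=nascent_seq(genome, length))
            edits[genome].append(e)
            nascent_edits[genome].append(e)

    # ---- lost intervals (deleted from a subgenome, retained in its diploid)
    lost_bb: dict = {sg: [] for sg in SUBGENOMES}
    for sg in SUBGENOMES:
        for _ in range(config.n_lost_per_subgenome):
            length = int(rng.integers(*config.lost_len_range))
            chrom, start = placer.place(length, "lost interval")
            edits[sg].append(_Edit(chrom, start, "del", end=start + length))
            lost_bb[sg].append((chrom, start, start + length))

    # ---- LTR families and elements ----------------------------------------
    profiles = [("A2",), ("At", "Dt"), ("A2", "At"), ("D5", "Dt"), GENOMES]
    interior_len = config.ltr_length_bp - 2 * config.terminal_repeat_bp
    r = config.mutation_rate_per_site_per_year
    ltr_rows = []
    age_rows = []
    ltr_edits = []  # (element_id, genome, edit)

    def plant_element(eid, fam, superfam, genome, age, tr_cons, int_cons,
                      chrom=None, pos=None):
        lam = config.ltr_clock_factor * r * age / 2  # per-repeat substitutions/site
        tr5 = mutate_jc(tr_cons, lam, rng)
        tr3 = mutate_jc(tr_cons, lam, rng)
        interior = mutate_jc(int_cons, lam, rng)
        full = np.concatenate([tr5, interior, tr3])
        if chrom is None:
            chrom, pos = placer.place(0, "LTR element")
        e = _Edit(chrom, pos, "ins", seq=full)
        edits[genome].append(e)
        ltr_edits.append((eid, genome, fam, superfam, decode(tr5), decode(tr3), decode(full), e))
        age_rows.append((eid, genome, float(age)))

    superfam_cycle = ("Gypsy", "Copia", "Copia", "Gypsy", "Gypsy")
    for fi in range(config.n_ltr_families):
        fam = f"fam{fi}"
        superfam = superfam_cycle[fi % len(superfam_cycle)]
        tr_cons = random_seq(rng, config.terminal_repeat_bp)
        int_cons = random_seq(rng, interior_len)
        profile = profiles[fi % len(profiles)]
        for ei in range(config.n_ltr_per_family):
            genome = profile[ei % len(profile)]
            age = float(rng.uniform(*config.age_range_years))
            plant_element(f"ltr_{fam}_{ei:03d}", fam, superfam, genome, age, tr_cons, int_cons)

    # ---- single-copy gene fates -------------------------------------------
    gids = genes_bb["gene_id"].tolist()
    rng.shuffle(gids)
    it = iter(gids)
    fate_rows = []
    te_disrupted: set = set()
    removed: dict = {g: set() for g in GENOMES}  # gene ids absent from a genome
    gained_copies = []  # (gene_id, subgenome)

    def take(n):
        return [next(it) for _ in range(n)]

    for gid in take(config.n_lost_both):
        row = genes_bb.set_index("gene_id").loc[gid]
        for sg in SUBGENOMES:
            edits[sg].append(_Edit(row["chrom"], int(row["start"]), "del", end=int(row["end"])))
            removed[sg].add(gid)
        fate_rows.append((gid, "lost_both", "both", "large_deletion"))

    n_te = int(round(config.n_reverted_per_subgenome * config.te_loss_frac))
    disruption_trs = {sg: random_seq(rng, config.terminal_repeat_bp) for sg in SUBGENOMES}
    disruption_ints = {sg: random_seq(rng, interior_len) for sg in SUBGENOMES}
    for sg in SUBGENOMES:
        for j, gid in enumerate(take(config.n_reverted_per_subgenome)):
            row = genes_bb.set_index("gene_id").loc[gid]
            removed[sg].add(gid)
            if j < n_te:
                # TE disruption: an LTR element lands mid-gene in this subgenome
                mid = int((row["start"] + row["end"]) // 2)
                age = float(rng.uniform(*config.age_range_years))
                plant_element(f"ltr_te_{sg}_{j:03d}", f"famTE_{sg}", "Gypsy", sg, age,
                              disruption_trs[sg], disruption_ints[sg],
                              chrom=row["chrom"], pos=mid)
                te_disrupted.add(gid)
                fate_rows.append((gid, "reverted_single", sg, "TE_disruption"))
            else:
                # small internal deletion: gene still alignable over >90%
                glen = int(row["end"] - row["start"])
                dlen = max(30, int(glen * 0.05))
                ds = int(row["start"]) + (glen - dlen) // 2
                edits[sg].append(_Edit(row["chrom"], ds, "del", end=ds + dlen))
                fate_rows.append((gid, "reverted_single", sg, "small_variation_or_annotation"))

    for j, gid in enumerate(take(config.n_gained)):
        sg = SUBGENOMES[j % 2]
        gained_copies.append((gid, sg))
        fate_rows.append((gid, "gained", "none", "NA"))

    for gid in it:
        fate_rows.append((gid, "balanced", "none", "NA"))

    family_fates = pd.DataFrame(fate_rows, columns=["family_id", "fate", "lost_subgenome", "mechanism"]) \
        .sort_values("family_id").reset_index(drop=True)

    # gained copies: insert a lightly mutated duplicate of the gene sequence
    lineage_seq = {g: backbone[lineage_of[g]] for g in GENOMES}
    for gid, sg in gained_copies:
        row = genes_bb.set_index("gene_id").loc[gid]
        gseq = lineage_seq[sg][row["chrom"]][int(row["start"]):int(row["end"])]
        gseq = mutate_jc(gseq, 0.005, rng)
        chrom, pos = placer.place(0, "gained gene copy")
        e = _Edit(chrom, pos, "ins", seq=gseq)
        edits[sg].append(e)
        e.kind_tag = ("gained", gid, sg)  # type: ignore[attr-defined]

    # ---- assemble genomes --------------------------------------------------
    genomes = {}
    maps = {}
    for g in GENOMES:
        genomes[g], maps[g] = _apply_edits(lineage_seq[g], edits[g])

    # reference genome: A2 without its nascent insertions
    ref_edits = [e for e in edits["A2"] if e not in nascent_edits["A2"]]
    ref_edits = [dataclasses.replace(e, seq=None if e.seq is None else e.seq.copy()) for e in ref_edits]
    reference, _ = _apply_edits(lineage_seq["A2"], ref_edits)

    # ---- final-coordinate annotations -------------------------------------
    gene_rows_final = []
    exon_rows_final = []
    exons_by_gene = exons_bb.groupby("gene_id")
    for g in GENOMES:
        for _, row in genes_bb.iterrows():
            gid = row["gene_id"]
            if gid in removed[g]:
                continue
            s = _map_coord(maps[g], row["chrom"], int(row["start"]))
            e = _map_coord(maps[g], row["chrom"], int(row["end"]))
            gene_rows_final.append((g, row["chrom"], s, e, gid, gid))
            for _, ex in exons_by_gene.get_group(gid).iterrows():
                es = _map_coord(maps[g], ex["chrom"], int(ex["start"]))
                ee = _map_coord(maps[g], ex["chrom"], int(ex["end"]))
                exon_rows_final.append((g, ex["chrom"], es, ee, gid, ex["exon_id"]))
    for gid, sg in gained_copies:
        for e in edits[sg]:
            if getattr(e, "kind_tag", None) == ("gained", gid, sg):
                gene_rows_final.append((sg, e.chrom, e.final_start, e.final_end,
                                        f"{gid}_cp", gid))
    genes_final = pd.DataFrame(
        gene_rows_final, columns=["genome", "chrom", "start", "end", "gene_id", "family_id"])
    exons_final = pd.DataFrame(
        exon_rows_final, columns=["genome", "chrom", "start", "end", "gene_id", "exon_id"])

    ltr_rows = []
    for eid, genome, fam, superfam, tr5, tr3, full, e in ltr_edits:
        ltr_rows.append((eid, genome, e.chrom, e.final_start, e.final_end,
                         fam, superfam, tr5, tr3, full))
    ltr_df = pd.DataFrame(ltr_rows, columns=[
        "element_id", "genome", "chrom", "start", "end", "family", "superfamily",
        "ltr5_seq", "ltr3_seq", "seq"])

    nascent_rows = []
    for g in GENOMES:
        for e in nascent_edits[g]:
            nascent_rows.append((g, e.chrom, e.final_start, e.final_end))
    nascent_df = pd.DataFrame(nascent_rows, columns=["genome", "chrom", "start", "end"])

    lost_rows = []
    for sg in SUBGENOMES:
        dip = DIPLOID_OF[sg]
        for chrom, s, e in lost_bb[sg]:
            lost_rows.append((sg, chrom, _map_coord(maps[dip], chrom, s),
                              _map_coord(maps[dip], chrom, e)))
    lost_df = pd.DataFrame(lost_rows, columns=["subgenome", "chrom", "start", "end"])

    ltr_ages = pd.DataFrame(age_rows, columns=["element_id", "genome", "age_years"])

    # ---- accession panel / PAV truth --------------------------------------
    rng_pav = rng_for(config.seed, "pav-panel")
    acc_ids = [f"acc{i:03d}" for i in range(config.n_accessions)]
    labels = []
    for name, w in config.group_labels:
        labels.extend([name] * int(round(w * config.n_accessions)))
    labels = (labels + [config.group_labels[0][0]] * config.n_accessions)[: config.n_accessions]
    groups = pd.Series(labels, index=acc_ids, name="group")

    all_gids = genes_bb["gene_id"].sort_values().tolist()
    n_disp = int(round(config.dispensable_frac * config.n_genes))
    disp = list(rng_pav.choice(all_gids, n_disp, replace=False))
    freq = pd.Series(1.0, index=all_gids)
    lo, hi = config.presence_sfs
    freq.loc[disp] = rng_pav.uniform(lo, hi, n_disp)
    focal = config.group_labels[0][0]
    favorable = disp[: config.n_favorable]
    pres = np.zeros((len(all_gids), len(acc_ids)), dtype=np.int8)
    for ai, acc in enumerate(acc_ids):
        f = freq.copy()
        for gid in favorable:
            f.loc[gid] = min(0.9, freq.loc[gid] * 2) if groups[acc] == focal \
                else max(0.02, freq.loc[gid] / 2)
        pres[:, ai] = (rng_pav.random(len(all_gids)) < f.values).astype(np.int8)
    pav_truth = pd.DataFrame(pres, index=all_gids, columns=acc_ids)

    # ---- gene ages and feature table --------------------------------------
    rng_age = rng_for(config.seed, "gene-age")
    bins = rng_age.choice([1, 2, 3, 4, 5], size=len(all_gids),
                          p=[0.51, 0.10, 0.12, 0.11, 0.16])
    gene_ages = pd.Series(bins, index=all_gids, name="age_bin")

    lengths = genes_bb.set_index("gene_id").eval("end - start").loc[all_gids]
    exon_counts = exons_bb.groupby("gene_id").size().loc[all_gids]
    oldness = 6 - gene_ages  # 5 = oldest
    lost_families = set(family_fates.loc[family_fates["fate"].isin(
        ["lost_both", "reverted_single"]), "family_id"])
    is_lost = pd.Series([g in lost_families for g in all_gids], index=all_gids)
    features = pd.DataFrame({
        "gene_id": all_gids,
        "length": lengths.values,
        "exon_count": exon_counts.values,
        "expression": np.round(rng_age.lognormal(np.log(2) + 0.35 * oldness.values
                                                 - 0.8 * is_lost.values, 0.6), 4),
        "presence_freq": pav_truth.mean(axis=1).values,
        "ka_ks": np.round(np.clip(rng_age.normal(0.55 - 0.05 * oldness.values
                                                 + 0.3 * is_lost.values, 0.1), 0.01, 2.0), 4),
        "te_coverage": np.round(np.clip(rng_age.normal(0.15 + 0.2 * is_lost.values, 0.08),
                                        0, 1), 4),
    })

    quartet = GenomeQuartet(genomes=genomes, genes=genes_final, exons=exons_final,
                            ltr=ltr_df, reference=reference)
    truth = TruthTables(nascent=nascent_df, lost=lost_df, ltr_ages=ltr_ages,
                        family_fates=family_fates, te_disrupted=te_disrupted,
                        pav_truth=pav_truth, groups=groups,
                        repeat_library=repeat_library, gene_ages=gene_ages,
                        features=features)
    return quartet, truth


# ---------------------------------------------------------------------------
# read-depth summaries for the PAV caller

def simulate_depth_table(quartet: GenomeQuartet, truth: TruthTables,
                         config: SimulationConfig) -> pd.DataFrame:
    """Per-accession, per-exon covered-base counts at depth >= minCov.

    Present genes get every exon covered over (0.85, 1.0) of its length;
    absent genes over (0.0, 0.6), i.e. below the 0.8 calling threshold.  With
    ``depth_noise > 0`` a gene's covered fractions are flipped across the
    threshold with that probability.
    """
    rng = rng_for(config.seed, "depth-table")
    exons = quartet.exons.query("genome == 'A2'")[["gene_id", "exon_id", "start", "end"]]
    exons = exons[exons["gene_id"].isin(truth.pav_truth.index)]
    exons = exons.sort_values(["gene_id", "exon_id"]).reset_index(drop=True)
    ex_len = (exons["end"] - exons["start"]).to_numpy()
    gene_order = exons["gene_id"].to_numpy()
    gene_ids, gene_idx = np.unique(gene_order, return_inverse=True)
    frames = []
    for acc in truth.pav_truth.columns:
        present = truth.pav_truth.loc[gene_ids, acc].to_numpy().astype(bool)
        if config.depth_noise > 0:
            flip = rng.random(len(gene_ids)) < config.depth_noise
            present = present ^ flip
        p_exon = present[gene_idx]
        frac = np.where(p_exon, rng.uniform(0.85, 1.0, len(exons)),
                        rng.uniform(0.0, 0.6, len(exons)))
        frames.append(pd.DataFrame({
            "accession": acc, "gene": gene_order, "exon": exons["exon_id"].to_numpy(),
            "exon_length": ex_len,
            "covered_bases": np.round(frac * ex_len).astype(int)}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# accession contigs + alignment records for the NRS filter chain

def simulate_accession_contigs(quartet: GenomeQuartet, truth: TruthTables,
                               config: SimulationConfig, flank: int = 1000):
    """Contigs of a simulated accession carrying the planted A2 nascent
    insertions, plus their alignment records against the nascent-free
    reference.

    Returns ``(contigs, alignments, nrs_truth)`` where ``nrs_truth`` maps
    contig id -> (start, end) of the planted non-reference bases on the
    contig.
    """
    from .core import AlignmentRecord
    rng = rng_for(config.seed, "contigs")
    contigs: dict = {}
    alignments: list = []
    nrs_truth: dict = {}
    a2 = quartet.genomes["A2"]
    nas = truth.nascent.query("genome == 'A2'")
    for i, row in enumerate(nas.itertuples()):
        s, e = int(row.start), int(row.end)
        cs = max(0, s - flank)
        ce = min(len(a2[row.chrom]), e + flank)
        cid = f"ctg_nas{i:03d}"
        contigs[cid] = a2[row.chrom][cs:ce]
        left = s - cs
        right = ce - e
        clen = ce - cs
        if left > 0:
            alignments.append(AlignmentRecord(cid, clen, 0, left, row.chrom,
                                              cs, s, 0.99))
        if right > 0:
            alignments.append(AlignmentRecord(cid, clen, clen - right, clen, row.chrom,
                                              e, ce, 0.99))
        nrs_truth[cid] = (left, clen - right)
    # fully reference-backed contigs (no NRS); avoid planted nascent spans so the
    # synthetic alignment records stay truthful
    chroms = list(a2)
    nas_spans = {c: [(int(r.start) - 3000, int(r.end) + 3000)
                     for r in nas.itertuples() if r.chrom == c] for c in chroms}
    for i in range(20):
        for _ in range(200):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, len(a2[chrom]) - 3000))
            if not any(s < start + 3000 and start < e for s, e in nas_spans[chrom]):
                break
        cid = f"ctg_bb{i:03d}"
        contigs[cid] = a2[chrom][start:start + 3000]
        alignments.append(AlignmentRecord(cid, 3000, 0, 3000, chrom, start, start + 3000, 0.99))
    # short contigs below the length filter
    for i in range(10):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, len(a2[chrom]) - 400))
        contigs[f"ctg_short{i:02d}"] = a2[chrom][start:start + 400]
    return contigs, alignments, nrs_truth


# ---------------------------------------------------------------------------
# homologous truncated-LTR retention loci

def simulate_retention_loci(config: SimulationConfig) -> pd.DataFrame:
    """Panel of homologous truncated-LTR loci with planted deletion dynamics.

    Most loci retain similar LTR lengths in the four genomes; a minority are
    high-variability loci at which the tetraploid subgenomes have deleted
    more, emulating faster elimination after polyploidisation.
    """
    rng = rng_for(config.seed, "retention")
    rows = []
    for i in range(config.n_retention_loci):
        total = int(rng.integers(1000, 5000))
        variable = rng.random() < 0.3
        rates = {}
        for g in GENOMES:
            if variable and g in SUBGENOMES:
                rate = rng.uniform(0.2, 0.7)
            elif variable:
                rate = rng.uniform(0.7, 1.0)
            else:
                rate = rng.uniform(0.8, 1.0)
            rates[g] = rate
        rows.append({"locus_id": f"loc{i:04d}", "aln_length": total,
                     **{f"retained_{g}": int(round(rates[g] * total)) for g in GENOMES}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orthogroup table consistent with planted gene ages

_AGE_TAXA = {1: "O_sativa", 2: "A_thaliana", 3: "G_kirkii", 4: "G_raimondii"}


def orthogroups_from_ages(gene_ages: pd.Series) -> pd.DataFrame:
    """Emit an orthogroup membership table (orthogroup, taxon, gene) whose
    deepest-taxon scan reproduces the planted age bins."""
    rows = []
    for i, (gid, age) in enumerate(sorted(gene_ages.items())):
        og = f"OG{i:05d}"
        rows.append((og, "pangenes", gid))
        if age <= 4:
            deepest = _AGE_TAXA[int(age)]
            rows.append((og, deepest, f"{deepest}_{i:05d}"))
    return pd.DataFrame(rows, columns=["orthogroup", "taxon", "gene"])
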
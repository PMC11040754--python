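"""Format readers/writers, pipeline configuration, and the end-to-end run.

Conventions: BED and all in-memory coordinates are 0-based half-open; GFF3
is written and read as 1-based inclusive, converted exactly at this
boundary.  The PAF-like alignment dialect is the 12 mandatory PAF columns,
with identity = matches / alignment-block-length.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .core import AlignmentRecord, Interval, build_align_index, seed_align
from .simulate import (DIPLOID_OF, GENOMES, SUBGENOMES, SimulationConfig,
                       orthogroups_from_ages, simulate_accession_contigs,
                       simulate_depth_table, simulate_quartet,
                       simulate_retention_loci)

logger = logging.getLogger("pantropon")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=str(i), description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 / BED (tab-separated tables; attributes kept as encoded strings)

GFF3_COLS = ["seqid", "source", "type", "start", "end", "score", "strand",
             "phase", "attributes"]


def write_gff3(df: pd.DataFrame, path) -> None:
    """Write features with internal 0-based half-open start/end as 1-based
    inclusive GFF3."""
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    out["end"] = out["end"].astype(int)
    for col, default in (("source", "pantropon"), ("score", "."), ("strand", "+"),
                         ("phase", ".")):
        if col not in out.columns:
            out[col] = default
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        out[GFF3_COLS].to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF3_COLS,
                     dtype={"seqid": str})
    if (df["end"] < df["start"]).any():
        line = int(df.index[df["end"] < df["start"]][0]) + 2
        raise ValueError(f"GFF3 feature with end < start near line {line}")
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    return df


def gff_attributes(attr: str) -> dict:
    out = {}
    for part in str(attr).split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_bed(path) -> list[Interval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [Interval(chrom=str(r[0]), start=int(r[1]), end=int(r[2]),
                     label=str(r[3]) if len(r) > 3 else "")
            for r in df.itertuples(index=False)]


def write_bed(intervals: list[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


# ---------------------------------------------------------------------------
# PAF-like alignments

def read_paf_like(path) -> list[AlignmentRecord]:
    """Read the 12 mandatory PAF columns; identity = matches / block length."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {ln}: expected >= 12 PAF columns")
            try:
                qlen, qs, qe = int(f[1]), int(f[2]), int(f[3])
                ts, te = int(f[7]), int(f[8])
                matches, block = int(f[9]), int(f[10])
                rec = AlignmentRecord(
                    query_id=f[0], query_len=qlen, query_start=qs, query_end=qe,
                    target_id=f[5], target_start=ts, target_end=te,
                    identity=matches / block if block else 0.0, strand=f[4])
            except (ValueError, ZeroDivisionError) as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from exc
            out.append(rec)
    return out


def write_paf_like(records: list[AlignmentRecord], target_lengths: dict, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            block = max(r.query_end - r.query_start, r.target_end - r.target_start)
            matches = int(round(r.identity * block))
            fh.write("\t".join(map(str, [
                r.query_id, r.query_len, r.query_start, r.query_end, r.strand,
                r.target_id, target_lengths.get(r.target_id, r.target_end),
                r.target_start, r.target_end, matches, block, 255])) + "\n")


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# fixture emission for the synthetic quartet

def write_quartet(quartet, truth, outdir) -> None:
    """Write FASTA per genome, GFF3 gene/exon/LTR annotations, and TSV truth
    tables; byte-identical across runs for a fixed seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g, seqs in quartet.genomes.items():
        write_fasta(seqs, outdir / f"{g}.fa")
        rows = []
        for r in quartet.genes.query("genome == @g").itertuples():
            rows.append((r.chrom, "gene", r.start, r.end,
                         f"ID={r.gene_id};family={r.family_id}"))
        for r in quartet.exons.query("genome == @g").itertuples():
            rows.append((r.chrom, "exon", r.start, r.end,
                         f"ID={r.exon_id};Parent={r.gene_id}"))
        for r in quartet.ltr.query("genome == @g").itertuples():
            rows.append((r.chrom, "LTR_retrotransposon", r.start, r.end,
                         f"ID={r.element_id};family={r.family};superfamily={r.superfamily}"))
        df = pd.DataFrame(rows, columns=["seqid", "type", "start", "end", "attributes"])
        write_gff3(df.sort_values(["seqid", "start"]), outdir / f"{g}.gff3")
    write_fasta(quartet.reference, outdir / "reference.fa")
    truth.nascent.to_csv(outdir / "truth_nascent.tsv", sep="\t", index=False)
    truth.lost.to_csv(outdir / "truth_lost.tsv", sep="\t", index=False)
    truth.ltr_ages.to_csv(outdir / "truth_ltr_ages.tsv", sep="\t", index=False)
    truth.family_fates.to_csv(outdir / "truth_family_fates.tsv", sep="\t", index=False)
    truth.pav_truth.to_csv(outdir / "truth_pav.tsv", sep="\t")
    truth.groups.to_csv(outdir / "truth_groups.tsv", sep="\t")
    truth.gene_ages.to_csv(outdir / "truth_gene_ages.tsv", sep="\t")
    truth.features.to_csv(outdir / "truth_features.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, at its published default."""

    seed: int = 0
    # NRS filter chain
    min_contig_len: int = 500
    min_aln_len: int = 300
    min_aln_identity: float = 0.90
    min_unaligned: int = 500
    dedup_identity: float = 0.90
    dedup_coverage: float = 0.90
    # PAV
    min_cov: int = 2
    present_frac: float = 0.8
    core_q: float = 0.99
    soft_q: float = 0.95
    cloud_q: float = 0.01
    n_samplings: int = 1000
    fc_hi: float = 2.0
    fc_lo: float = 0.5
    fdr: float = 0.001
    kmeans_k: int = 4
    # k-mer phasing
    kmer_k: int = 15
    kmer_ratio: float = 2.0
    # sequence origin
    fragment_window: int = 1000
    gap_join: int = 50
    lost_cutoff: float = 0.20
    seed_k: int = 31
    # single-copy fate
    cover_frac: float = 0.90
    span_max: int = 25_000
    # LTR dynamics
    cluster_identity: float = 0.90
    cluster_coverage: float = 0.90
    r: float = 9e-9
    divergence_factor: float = 1.0
    n_perm: int = 1000
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}

        def detuple(v):
            return tuple(detuple(x) for x in v) if isinstance(v, list) else v

        sim = {k: detuple(v) for k, v in (d.pop("simulation", {}) or {}).items()}
        d = {k: detuple(v) for k, v in d.items()}
        return cls(simulation=SimulationConfig(**sim), **d)


# ---------------------------------------------------------------------------
# pipeline stages (shared by run_pipeline, the CLI and the acceptance script)

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def truth_base_accuracy(calls, truth_intervals: pd.DataFrame, verdict: str) -> float:
    """Fraction of planted truth bases covered by calls with the expected
    verdict."""
    from .core import intersect_len
    spans: dict = {}
    for c in calls:
        if c.verdict == verdict:
            spans.setdefault(c.interval.chrom, []).append((c.interval.start, c.interval.end))
    got = tot = 0
    for r in truth_intervals.itertuples():
        tot += r.end - r.start
        got += intersect_len([(r.start, r.end)], spans.get(r.chrom, []))
    return got / tot if tot else float("nan")


def origin_stage(quartet, config: PipelineConfig, truth=None) -> dict:
    """Fragment-map-mask origin classification for both genome pairs."""
    from .kmers import count_kmers, differential_kmers
    from .origin import classify_genome_pair
    report = {}
    for dip, sub in (("A2", "At"), ("D5", "Dt")):
        profile = count_kmers({dip: quartet.genomes[dip], sub: quartet.genomes[sub]},
                              k=config.kmer_k)
        spec = differential_kmers(profile, dip, sub, ratio=config.kmer_ratio)
        calls_dip = classify_genome_pair(
            quartet.genomes[dip], quartet.genomes[sub], spec, dip,
            window=config.fragment_window, seed_k=config.seed_k,
            gap_join=config.gap_join, lost_cutoff=config.lost_cutoff)
        calls_sub = classify_genome_pair(
            quartet.genomes[sub], quartet.genomes[dip], spec, sub,
            window=config.fragment_window, seed_k=config.seed_k,
            gap_join=config.gap_join, lost_cutoff=config.lost_cutoff)
        pair = {
            f"nascent_mb_{dip}": sum(c.interval.length for c in calls_dip
                                     if c.verdict == "nascent") / 1e6,
            f"lost_mb_{sub}": sum(c.interval.length for c in calls_dip
                                  if c.verdict == "lost") / 1e6,
            f"nascent_mb_{sub}": sum(c.interval.length for c in calls_sub
                                     if c.verdict == "nascent") / 1e6,
        }
        if truth is not None:
            pair[f"nascent_accuracy_{dip}"] = truth_base_accuracy(
                calls_dip, truth.nascent.query("genome == @dip"), "nascent")
            pair[f"lost_accuracy_{sub}"] = truth_base_accuracy(
                calls_dip, truth.lost.query("subgenome == @sub"), "lost")
            pair[f"nascent_accuracy_{sub}"] = truth_base_accuracy(
                calls_sub, truth.nascent.query("genome == @sub"), "nascent")
        report[f"{dip}_{sub}"] = pair
    return report


def fate_stage(quartet, config: PipelineConfig, truth=None) -> dict:
    """Single-copy fate classification plus TE-disruption tracing."""
    from .single_copy import (classify_families, families_from_annotations,
                              trace_loss_mechanism)
    fams = families_from_annotations(quartet.genes)
    calls, skipped = classify_families(fams)
    fate_counts = pd.Series([c.fate for c in calls]).value_counts().to_dict()
    te_index = {sg: build_align_index(quartet.genomes[sg], k=config.seed_k)
                for sg in SUBGENOMES}
    te_ann = {sg: [Interval(chrom=r.chrom, start=int(r.start), end=int(r.end))
                   for r in quartet.ltr.query("genome == @sg").itertuples()]
              for sg in SUBGENOMES}
    dip_genes = {(r.genome, r.family_id): (r.chrom, int(r.start), int(r.end))
                 for r in quartet.genes.itertuples()}
    mechanisms = {}
    for call in calls:
        if call.fate != "reverted_single":
            continue
        sg = call.lost_subgenome
        dip = DIPLOID_OF[sg]
        chrom, s, e = dip_genes[(dip, call.family_id)]
        gseq = quartet.genomes[dip][chrom][s:e]
        recs = seed_align(gseq, quartet.genomes[sg], k=config.seed_k,
                          index=te_index[sg])
        call.loss_mechanism = trace_loss_mechanism(
            recs, te_ann[sg], len(gseq), cover_frac=config.cover_frac,
            span_max=config.span_max)
        mechanisms[call.family_id] = call.loss_mechanism
    report = {"fate_counts": fate_counts, "n_ineligible": skipped,
              "mechanism_counts": pd.Series(list(mechanisms.values())).value_counts().to_dict()}
    if truth is not None:
        tf = truth.family_fates.set_index("family_id")
        agree = sum(tf.loc[c.family_id, "fate"] == c.fate for c in calls)
        report["fate_recovery"] = agree / len(calls)
        te_true = truth.te_disrupted
        te_called = {f for f, m in mechanisms.items() if m == "TE_disruption"}
        small_true = set(tf.index[(tf["mechanism"] == "small_variation_or_annotation")])
        report["te_recall"] = len(te_called & te_true) / len(te_true) if te_true else float("nan")
        report["te_false_on_small_deletion"] = len(te_called & small_true)
    return report


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Execute simulate -> nrs -> pav -> kmers -> origin -> age -> fate -> ltr
    on the synthetic quartet and return a JSON-serialisable report."""
    from . import gene_age, kmers, ltr, nrs, pav
    from .pav import PavMatrix  # noqa: F401  (re-exported in the report context)
    t0 = time.time()
    config.simulation.seed = config.seed
    report: dict = {"version": __version__, "seed": config.seed,
                    "thresholds": {k: v for k, v in dataclasses.asdict(config).items()
                                   if k != "simulation"}}
    logger.info("simulating quartet (seed=%d)", config.seed)
    quartet, truth = simulate_quartet(config.simulation)
    report["simulate"] = {
        "genome_bp": {g: sum(map(len, quartet.genomes[g].values())) for g in GENOMES},
        "n_genes": int(len(quartet.genes)), "n_ltr": int(len(quartet.ltr))}

    # --- NRS -------------------------------------------------------------
    contigs, alignments, nrs_truth = simulate_accession_contigs(
        quartet, truth, config.simulation)
    kept = nrs.filter_contigs(contigs, min_len=config.min_contig_len)
    nrs_set = nrs.extract_nrs(kept, alignments, min_aln_len=config.min_aln_len,
                              min_identity=config.min_aln_identity,
                              min_unaligned=config.min_unaligned)
    dedup = nrs.deduplicate(nrs_set, identity=config.dedup_identity,
                            coverage=config.dedup_coverage)
    truth_bp = sum(e - s for s, e in nrs_truth.values())
    got_bp = 0
    for nid, seq in nrs_set.sequences.items():
        src = nrs_set.source_contig[nid]
        if src in nrs_truth and nrs_set.provenance[nid] == "unaligned_region":
            s, e = nrs_truth[src]
            span = nid.rsplit(":", 1)[1].split("-")
            got_bp += max(0, min(int(span[1]), e) - max(int(span[0]), s))
    fp_bp = nrs_set.total_bp() - got_bp
    report["nrs"] = {"n_contigs_kept": len(kept), "n_nrs": len(nrs_set.sequences),
                     "nrs_bp": nrs_set.total_bp(), "n_nonredundant": len(dedup.sequences),
                     "recovery": got_bp / truth_bp if truth_bp else float("nan"),
                     "false_positive_frac": fp_bp / max(nrs_set.total_bp(), 1)}

    # --- PAV -------------------------------------------------------------
    depth = simulate_depth_table(quartet, truth, config.simulation)
    matrix = pav.call_presence(depth, groups=truth.groups, min_cov=config.min_cov,
                               present_frac=config.present_frac)
    occ = pav.classify_occupancy(matrix, core_q=config.core_q, soft_q=config.soft_q,
                                 cloud_q=config.cloud_q)
    agreement = float((matrix.presence == truth.pav_truth.loc[
        matrix.genes, matrix.accessions]).to_numpy().mean())
    disp = pav.dispensable_genes(matrix, core_q=config.core_q, soft_q=config.soft_q,
                                 cloud_q=config.cloud_q)
    curve = pav.pan_core_curve(matrix, n_samplings=min(config.n_samplings, 200),
                               seed=config.seed)
    scan = pav.frequency_change_scan(matrix, focal_group=truth.groups.iloc[0],
                                     genes=disp, fc_hi=config.fc_hi,
                                     fc_lo=config.fc_lo, fdr=config.fdr) \
        if disp else pd.DataFrame(columns=["verdict"])
    report["pav"] = {
        "occupancy_counts": occ.counts().to_dict(),
        "occupancy_thresholds": {"core_min": occ.core_min, "soft_min": occ.soft_min,
                                 "cloud_max": occ.cloud_max},
        "occupancy_thresholds_n341": dict(zip(("core_min", "soft_min", "cloud_max"),
                                              pav.occupancy_thresholds(341))),
        "pav_truth_agreement": agreement,
        "pan_final": float(curve["pan_mean"].iloc[-1]),
        "core_final": float(curve["core_mean"].iloc[-1]),
        "n_favorable": int((scan["verdict"] == "favorable").sum()),
        "n_unfavorable": int((scan["verdict"] == "unfavorable").sum())}
    if len(disp) >= config.kmeans_k:
        clusters = pav.cluster_dispensable(matrix, genes=disp, k=config.kmeans_k,
                                           seed=config.seed)
        report["pav"]["dispensable_cluster_sizes"] = clusters.value_counts().to_dict()

    # --- k-mer phasing ---------------------------------------------------
    profile = kmers.count_kmers({g: quartet.genomes[g] for g in GENOMES},
                                k=config.kmer_k)
    spec_a = kmers.differential_kmers(profile, "A2", "At", ratio=config.kmer_ratio)
    spec_d = kmers.differential_kmers(profile, "D5", "Dt", ratio=config.kmer_ratio)
    report["kmers"] = {
        "n_retained": int(len(profile.counts)), "min_count": profile.min_count,
        "specific_A2": int((spec_a.assignments == "A2").sum()),
        "specific_At": int((spec_a.assignments == "At").sum()),
        "specific_D5": int((spec_d.assignments == "D5").sum()),
        "specific_Dt": int((spec_d.assignments == "Dt").sum())}

    # --- origin ----------------------------------------------------------
    report["origin"] = origin_stage(quartet, config, truth)

    # --- gene age --------------------------------------------------------
    og = orthogroups_from_ages(truth.gene_ages)
    assign = gene_age.assign_age(og)
    report["age"] = {
        "bin_counts": assign.value_counts().sort_index().to_dict(),
        "truth_agreement": float((assign.sort_index() == truth.gene_ages.sort_index()).mean())}

    # --- single-copy fate ------------------------------------------------
    report["fate"] = fate_stage(quartet, config, truth)

    # --- LTR dynamics ----------------------------------------------------
    ages = ltr.date_elements(quartet.ltr, r=config.r,
                             divergence_factor=config.divergence_factor)
    merged = ages.merge(truth.ltr_ages, on="element_id")
    ratio = (merged["T"] / merged["age_years"]).dropna()
    clusters = ltr.cluster_elements(quartet.ltr, identity=config.cluster_identity,
                                    coverage=config.cluster_coverage)
    ltr.annotate_clusters(clusters, ages)
    genes_a2 = [Interval(chrom=r.chrom, start=int(r.start), end=int(r.end))
                for r in quartet.genes.query("genome == 'A2'").itertuples()]
    dist = ltr.ltr_gene_distance_stats(
        quartet.ltr.query("genome == 'A2'"), ages, genes_a2,
        quartet.chrom_lengths("A2"), n_perm=config.n_perm, seed=config.seed)
    loci = simulate_retention_loci(config.simulation)
    ret = ltr.retention_rates(loci)
    spac = ltr.adjacent_homolog_spacings(quartet.genes, "A2", "At")
    spacing = ltr.homolog_spacing_test(spac["d_diploid"].to_numpy(),
                                       spac["d_tetraploid"].to_numpy(),
                                       n_rand=min(config.n_perm, 200), seed=config.seed)
    high_cv = ret[(ret["cv_cutoff"] == 0.5) & ret["genome"].isin(GENOMES)]
    report["ltr"] = {
        "age_ratio_mean": float(ratio.mean()),
        "age_spearman": float(merged[["T", "age_years"]].corr(method="spearman").iloc[0, 1]),
        "n_clusters": len(clusters),
        "specificity_counts": pd.Series([c.specificity for c in clusters])
        .value_counts().to_dict(),
        "gypsy_slope_kb_per_myr": dist.get("Gypsy", {}).get("slope_kb_per_myr"),
        "copia_slope_kb_per_myr": dist.get("Copia", {}).get("slope_kb_per_myr"),
        "retention_mean_high_cv": dict(zip(high_cv["genome"], high_cv["mean_retention"])),
        "spacing_log_ratio_median": float(np.median(spacing["log_ratios"]))
        if len(spacing["log_ratios"]) else float("nan"),
        "spacing_chi2_p": spacing["p"]}

    report["runtime_s"] = round(time.time() - t0, 1)
    report = _jsonable(report)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(outdir / "pipeline.log", "a") as fh:
            fh.write(f"pantropon {__version__} seed={config.seed} "
                     f"numpy={np.__version__} pandas={pd.__version__} "
                     f"runtime={report['runtime_s']}s\n")
    return report
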
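"""End-to-end orchestration: simulate -> search -> classify -> cluster ->
place -> summarize.

Mirrors the two-pass mining strategy: pass 1 finds and classifies loci
with intact >= 200 aa translations and clusters the accepted proteins
into OTU candidates; pass 2 re-screens the extended loci at the
nucleotide level (80%-of-subject rule) and sends eligible loci to
phylogenetic placement on the reference tree.  All stages are
deterministic for a fixed seed, and every table is written sorted so a
repeated run is byte-identical.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify as _classify
from . import cluster as _cluster
from . import summary as _summary
from .placement import PlacementResult, ReferencePackage, place_all
from .scoring import ScoringScheme
from .search import HitLocus, extend_loci, merge_hit_loci, search_library
from .seqio import GenomeRecord, LibraryProtein, reverse_complement, write_bed, write_fasta
from .synthetic import BenchmarkBundle, DecayModel, make_benchmark_bundle

DEFAULT_CONFIG = {
    "n_genomes": 3,
    "genome_length": 100_000,
    "n_caulimovirid": 8,
    "n_decoy": 4,
    "gc": 0.4,
    "sub_rate": 0.05,
    "indel_rate": 0.001,
    "indel_len_mean": 2.0,
    "stop_rate": 1.0,
    "evalue": 1e-5,
    "flank": 120,
    "min_aa": 200,
    "min_aln": 170,
    "within_id": 0.80,
    "global_id": 0.55,
    "network_id": 0.45,
    "pass2_frac": 0.8,
}


def locus_id(genome_id: str, locus: HitLocus) -> str:
    return f"{genome_id}:{locus.start}-{locus.end}"


@dataclass
class GenomeMining:
    genome: GenomeRecord
    hsps: list
    loci: list[HitLocus]
    extended: list[HitLocus]

    def locus_seq(self, locus: HitLocus) -> str:
        return self.genome.seq[locus.start : locus.end]


def mine_genome(
    genome: GenomeRecord,
    library: list[LibraryProtein],
    scoring: ScoringScheme | None = None,
    flank: int = 120,
) -> GenomeMining:
    """Pass-1 search of one genome: HSPs, merged loci, extended loci."""
    scoring = scoring or ScoringScheme()
    hsps = search_library(genome, library, scoring)
    loci = merge_hit_loci(hsps) if hsps else []
    extended = extend_loci(loci, len(genome), flank=flank)
    return GenomeMining(genome, hsps, loci, extended)


def align_with_mafft(seqs: dict[str, str]) -> dict[str, str]:
    """Multiple alignment via mafft (single thread, deterministic)."""
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        write_fasta(seqs, infile)
        proc = subprocess.run(
            ["mafft", "--auto", "--quiet", "--thread", "1", str(infile)],
            capture_output=True, text=True, check=True,
        )
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip().upper()
    return out


@dataclass
class PipelineResult:
    bundle: BenchmarkBundle
    mining: dict[str, GenomeMining]
    classified: dict[str, _classify.ClassifiedECRT]
    locus_seqs: dict[str, str]
    clusters: list
    network: object
    placements: list[PlacementResult]
    rejects: list[str]
    genome_stats: pd.DataFrame
    distribution: pd.DataFrame
    otu_totals: pd.Series
    otu_presence: pd.Series
    trend: tuple[float, float, float] | None
    config: dict = field(default_factory=dict)

    @property
    def eligible_ids(self) -> list[str]:
        return sorted(
            lid for lid, c in self.classified.items() if c.pass2_eligible
        )


def run_pipeline(
    config: dict | None = None,
    seed: int = 0,
    bundle: BenchmarkBundle | None = None,
    use_mafft_filter: bool = True,
) -> PipelineResult:
    """Run the full pipeline on a synthetic bundle (built unless given)."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    scoring = ScoringScheme(e_max=cfg["evalue"])
    if bundle is None:
        bundle = make_benchmark_bundle(
            seed=seed,
            n_genomes=cfg["n_genomes"],
            genome_length=cfg["genome_length"],
            n_caulimovirid=cfg["n_caulimovirid"],
            n_decoy=cfg["n_decoy"],
            gc=cfg["gc"],
            decay_model=DecayModel(
                sub_rate=cfg["sub_rate"],
                indel_rate=cfg["indel_rate"],
                indel_len_mean=cfg["indel_len_mean"],
                stop_rate=cfg["stop_rate"],
            ),
        )

    # pass 1: mine, translate, classify
    mining: dict[str, GenomeMining] = {}
    classified: dict[str, _classify.ClassifiedECRT] = {}
    locus_seqs: dict[str, str] = {}
    for genome in bundle.genomes:
        gm = mine_genome(genome, bundle.library, scoring, flank=cfg["flank"])
        mining[genome.id] = gm
        for locus in gm.extended:
            lid = locus_id(genome.id, locus)
            seq = gm.locus_seq(locus)
            locus_seqs[lid] = seq
            classified[lid] = _classify.classify_locus(
                lid, seq, bundle.library, scoring,
                min_len=cfg["min_aa"], min_aln=cfg["min_aln"],
            )

    # pass 2: nucleotide-level eligibility for placement
    caulimo_lib = [p for p in bundle.library if p.family == "caulimovirid"]
    for lid, seq in locus_seqs.items():
        eligible, span, _subject = _classify.select_for_placement(
            lid, seq, bundle.library, scoring, frac=cfg["pass2_frac"]
        )
        classified[lid].pass2_eligible = eligible
        classified[lid].pass2_aln_len_nt = span

    # clustering of accepted pass-1 proteins (per species, then global)
    accepted = {
        lid: c.best_candidate.aa_sequence
        for lid, c in sorted(classified.items())
        if c.status == "accepted" and c.best_candidate is not None
    }
    reps: dict[str, str] = {}
    by_species: dict[str, dict[str, str]] = {}
    for lid, seq in accepted.items():
        by_species.setdefault(lid.split(":")[0], {})[lid] = seq
    for species in sorted(by_species):
        clusters = _cluster.greedy_cluster(
            by_species[species], cfg["within_id"], scoring
        )
        species_reps = {c.representative: by_species[species][c.representative]
                        for c in clusters}
        if use_mafft_filter and species_reps:
            lib_seqs = {p.id: p.seq for p in caulimo_lib}
            msa = align_with_mafft({**lib_seqs, **species_reps})
            filtered = _cluster.filter_alignment(msa)
            species_reps = {
                k: v for k, v in species_reps.items() if k in filtered.rows
            }
        reps.update(species_reps)

    pool = {p.id: p.seq for p in caulimo_lib} | reps
    clusters, network = _cluster.delineate_otus(
        pool, cluster_id=cfg["global_id"], network_id=cfg["network_id"],
        scoring=scoring,
    )

    # placement of pass-2-eligible loci
    eligible_seqs = {
        lid: locus_seqs[lid] for lid, c in sorted(classified.items())
        if c.pass2_eligible
    }
    placements, rejects = place_all(eligible_seqs, bundle.references.package)

    # summaries: ECRT count per genome = pass-2 loci
    counts = {g.id: 0 for g in bundle.genomes}
    for lid, c in classified.items():
        if c.pass2_eligible:
            counts[lid.split(":")[0]] += 1
    stats = _summary.genome_stats_table(
        counts,
        {g.id: len(g) for g in bundle.genomes},
        {g.id: g.gap_length for g in bundle.genomes},
    )
    species_map = {lid: lid.split(":")[0] for lid in locus_seqs}
    matrix, totals, presence = _summary.build_distribution(placements, species_map)
    trend = None
    if len(bundle.genomes) >= 3:
        sizes = stats["ungapped_mb"].to_numpy()
        try:
            trend = _summary.log_trend_fit(stats["ecrt_count"].to_numpy(), sizes)
        except ValueError:
            trend = None

    return PipelineResult(
        bundle=bundle,
        mining=mining,
        classified=classified,
        locus_seqs=locus_seqs,
        clusters=clusters,
        network=network,
        placements=placements,
        rejects=rejects,
        genome_stats=stats,
        distribution=matrix,
        otu_totals=totals,
        otu_presence=presence,
        trend=trend,
        config=cfg,
    )


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write every pipeline surface as sorted, plain-text tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    hsp_rows = []
    for gid in sorted(result.mining):
        for h in result.mining[gid].hsps:
            hsp_rows.append(
                (h.query_id, h.genome_id, h.frame, h.genome_interval[0],
                 h.genome_interval[1], f"{h.score:.1f}", f"{h.evalue:.3e}")
            )
    with open(out / "hsps.tsv", "w") as fh:
        fh.write("query\tgenome\tframe\tstart\tend\tscore\tevalue\n")
        for row in sorted(hsp_rows):
            fh.write("\t".join(map(str, row)) + "\n")

    bed_rows = []
    for gid in sorted(result.mining):
        for locus in result.mining[gid].extended:
            bed_rows.append(
                (gid, locus.start, locus.end, locus_id(gid, locus),
                 int(locus.best_score), ".")
            )
    write_bed(sorted(bed_rows), out / "loci.bed")

    cls = result.classified
    with open(out / "classified.tsv", "w") as fh:
        fh.write(
            "locus\tstatus\tfamily\tsubject\tscore\taln_len_aa\t"
            "pass2_eligible\tpass2_aln_len_nt\n"
        )
        for lid in sorted(cls):
            c = cls[lid]
            fh.write(
                f"{lid}\t{c.status}\t{c.best_family or '.'}\t"
                f"{c.best_subject_id or '.'}\t{c.best_score:.1f}\t{c.aln_len_aa}\t"
                f"{int(c.pass2_eligible)}\t{c.pass2_aln_len_nt}\n"
            )

    accepted = {
        lid: cls[lid].best_candidate.aa_sequence
        for lid in sorted(cls)
        if cls[lid].status == "accepted" and cls[lid].best_candidate
    }
    write_fasta(accepted, out / "accepted_proteins.fasta")
    write_fasta(
        {lid: result.locus_seqs[lid] for lid in result.eligible_ids},
        out / "pass2_loci.fasta",
    )

    with open(out / "clusters.tsv", "w") as fh:
        fh.write("cluster\trepresentative\tmember\n")
        for i, cl in enumerate(result.clusters):
            for m in sorted(cl.members):
                fh.write(f"{i}\t{cl.representative}\t{m}\n")

    with open(out / "network_edges.tsv", "w") as fh:
        fh.write("a\tb\tidentity\n")
        for a, b, ident in sorted(result.network.edges):
            fh.write(f"{a}\t{b}\t{ident:.4f}\n")

    with open(out / "placements.tsv", "w") as fh:
        fh.write("query\tedge\tpendant\tlog_likelihood\tlwr\totu\n")
        for p in sorted(result.placements, key=lambda p: p.query_id):
            fh.write(
                f"{p.query_id}\t{p.edge_id}\t{p.pendant_length:.6f}\t"
                f"{p.log_likelihood:.4f}\t{p.lwr:.4f}\t{p.otu_label}\n"
            )
    jplace = {
        "version": 3,
        "tree": result.bundle.references.package.newick,
        "fields": ["edge_id", "likelihood", "like_weight_ratio", "pendant_length"],
        "placements": [
            {
                "p": [[p.edge_id, round(p.log_likelihood, 4), round(p.lwr, 4),
                       round(p.pendant_length, 6)]],
                "n": [p.query_id],
            }
            for p in sorted(result.placements, key=lambda p: p.query_id)
        ],
    }
    (out / "placements.jplace").write_text(json.dumps(jplace, indent=1))

    result.genome_stats.to_csv(
        out / "genome_stats.tsv", sep="\t", index=False, float_format="%.6f"
    )
    result.distribution.to_csv(out / "distribution_matrix.tsv", sep="\t")

    summary = {
        "n_loci": len(result.classified),
        "n_accepted": sum(
            1 for c in result.classified.values() if c.status == "accepted"
        ),
        "n_pass2_eligible": len(result.eligible_ids),
        "n_placed": len(result.placements),
        "n_placed_otu": sum(
            1 for p in result.placements if p.otu_label != "inner"
        ),
        "n_placed_inner": sum(
            1 for p in result.placements if p.otu_label == "inner"
        ),
        "n_rejects": len(result.rejects),
        "n_otu_components": result.network.n_components,
        "trend_r2": None if result.trend is None else round(result.trend[2], 4),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
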
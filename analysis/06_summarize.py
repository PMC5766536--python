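#!/usr/bin/env python
"""Summary surfaces: per-genome ECRT counts and densities (assembly gaps
excluded), the count-vs-log10(size) trendline, and the species x OTU
distribution matrix.

Reads results/classified.tsv, results/placements.tsv and scratch/bundle/;
writes results/genome_stats.tsv and results/distribution_matrix.tsv.
"""

from pathlib import Path

from ecrtmine.placement import PlacementResult
from ecrtmine.seqio import read_genomes
from ecrtmine.summary import build_distribution, genome_stats_table, log_trend_fit

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    out = ROOT / "results"
    genomes = read_genomes(ROOT / "scratch" / "bundle" / "genomes.fasta")

    counts = {g.id: 0 for g in genomes}
    for line in (out / "classified.tsv").read_text().splitlines()[1:]:
        fields = line.split("\t")
        if fields[6] == "1":  # pass-2 eligible = an ECRT locus
            counts[fields[0].split(":")[0]] += 1
    stats = genome_stats_table(
        counts,
        {g.id: len(g) for g in genomes},
        {g.id: g.gap_length for g in genomes},
    )
    stats.to_csv(out / "genome_stats.tsv", sep="\t", index=False,
                 float_format="%.6f")

    placements = []
    for line in (out / "placements.tsv").read_text().splitlines()[1:]:
        q, edge, pendant, ll, lwr, otu = line.split("\t")
        placements.append(
            PlacementResult(q, edge, float(pendant), 0.5, float(ll),
                            float(lwr), otu)
        )
    species = {p.query_id: p.query_id.split(":")[0] for p in placements}
    matrix, totals, presence = build_distribution(placements, species)
    matrix.to_csv(out / "distribution_matrix.tsv", sep="\t")

    print(stats.to_string(index=False))
    if len(genomes) >= 3:
        try:
            slope, intercept, r2 = log_trend_fit(
                stats["ecrt_count"].to_numpy(), stats["ungapped_mb"].to_numpy()
            )
            print(f"count ~ {slope:.2f} * log10(Mb) + {intercept:.2f}, "
                  f"R^2 = {r2:.3f}")
        except ValueError as exc:
            print(f"trend fit not defined: {exc}")
    print("\nspecies x OTU matrix:")
    print(matrix.to_string())
    print("\nper-OTU totals:", dict(totals))
    print("per-OTU species presence:", dict(presence))


if __name__ == "__main__":
    main()
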
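#!/usr/bin/env python
"""OTU delineation over the accepted RT proteins plus the reference
library: greedy clustering at 55% identity and connected components of
the 35% identity network.

Reads results/classified.tsv (accepted loci) + scratch/bundle/; writes
results/clusters.tsv and results/network_edges.tsv.
"""

from pathlib import Path

from ecrtmine.classify import best_translation
from ecrtmine.cluster import delineate_otus
from ecrtmine.seqio import read_genomes, read_protein_library

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    genomes = {g.id: g for g in read_genomes(BUNDLE / "genomes.fasta")}
    library = read_protein_library(BUNDLE / "rt_library.fasta")
    out = ROOT / "results"

    pool = {p.id: p.seq for p in library if p.family == "caulimovirid"}
    n_mined = 0
    for line in (out / "classified.tsv").read_text().splitlines()[1:]:
        fields = line.split("\t")
        lid, status = fields[0], fields[1]
        if status != "accepted":
            continue
        chrom, span = lid.split(":")
        start, end = map(int, span.split("-"))
        cands = best_translation(lid, genomes[chrom].seq[start:end])
        if cands:
            pool[lid] = cands[0].aa_sequence
            n_mined += 1

    clusters, network = delineate_otus(pool, cluster_id=0.55, network_id=0.45)
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("cluster\trepresentative\tmember\n")
        for i, cl in enumerate(clusters):
            for m in sorted(cl.members):
                fh.write(f"{i}\t{cl.representative}\t{m}\n")
    with open(out / "network_edges.tsv", "w") as fh:
        fh.write("a\tb\tidentity\n")
        for a, b, ident in sorted(network.edges):
            fh.write(f"{a}\t{b}\t{ident:.4f}\n")
    print(f"{len(pool)} sequences ({n_mined} mined + {len(pool) - n_mined} "
          f"reference) -> {len(clusters)} clusters at 55% identity, "
          f"{network.n_components} network OTUs at 45%")


if __name__ == "__main__":
    main()
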
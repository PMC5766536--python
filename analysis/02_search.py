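#!/usr/bin/env python
"""Pass-1 mining: translated seed-and-extend search of the RT library
against every bundle genome, locus merging and 120-bp flank extension.

Reads scratch/bundle/ (from 01_simulate.py); writes results/hsps.tsv and
results/loci.bed.
"""

from pathlib import Path

from ecrtmine.pipeline import locus_id, mine_genome
from ecrtmine.scoring import ScoringScheme
from ecrtmine.seqio import read_genomes, read_protein_library, write_bed

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    genomes = read_genomes(BUNDLE / "genomes.fasta")
    library = read_protein_library(BUNDLE / "rt_library.fasta")
    scoring = ScoringScheme()
    out = ROOT / "results"
    bed_rows, n_hsps = [], 0
    with open(out / "hsps.tsv", "w") as fh:
        fh.write("query\tgenome\tframe\tstart\tend\tscore\tevalue\n")
        for genome in genomes:
            gm = mine_genome(genome, library, scoring)
            n_hsps += len(gm.hsps)
            for h in sorted(gm.hsps, key=lambda h: (h.genome_interval, h.query_id)):
                fh.write(
                    f"{h.query_id}\t{h.genome_id}\t{h.frame}\t"
                    f"{h.genome_interval[0]}\t{h.genome_interval[1]}\t"
                    f"{h.score:.1f}\t{h.evalue:.3e}\n"
                )
            bed_rows.extend(
                (genome.id, l.start, l.end, locus_id(genome.id, l),
                 int(l.best_score), ".")
                for l in gm.extended
            )
    write_bed(sorted(bed_rows), out / "loci.bed")
    print(f"{n_hsps} HSPs at E <= {scoring.e_max} merged into "
          f"{len(bed_rows)} extended loci across {len(genomes)} genomes")


if __name__ == "__main__":
    main()
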
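#!/usr/bin/env python
"""Two-pass classification of extended loci.

Pass 1 keeps loci whose best >= 200 aa stop-free translation scores
highest against a caulimovirid over >= 170 residues; pass 2 re-screens
every locus at the nucleotide level (best translated alignment spanning
>= 80% of the subject, generically 576 bp) for placement eligibility.

Reads results/loci.bed + scratch/bundle/; writes results/classified.tsv
and results/pass2_loci.fasta.
"""

from pathlib import Path

from ecrtmine.classify import classify_locus, select_for_placement
from ecrtmine.scoring import ScoringScheme
from ecrtmine.seqio import read_genomes, read_protein_library, write_fasta

ROOT = Path(__file__).resolve().parent.parent
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    genomes = {g.id: g for g in read_genomes(BUNDLE / "genomes.fasta")}
    library = read_protein_library(BUNDLE / "rt_library.fasta")
    scoring = ScoringScheme()
    out = ROOT / "results"

    counts = {"accepted": 0, "rejected_family": 0, "rejected_length": 0}
    eligible = {}
    with open(out / "classified.tsv", "w") as fh:
        fh.write("locus\tstatus\tfamily\tsubject\tscore\taln_len_aa\t"
                 "pass2_eligible\tpass2_aln_len_nt\n")
        for line in sorted((out / "loci.bed").read_text().splitlines()):
            chrom, start, end, lid, _score, _strand = line.split("\t")
            seq = genomes[chrom].seq[int(start):int(end)]
            c = classify_locus(lid, seq, library, scoring)
            elig, span, _ = select_for_placement(lid, seq, library, scoring)
            counts[c.status] += 1
            if elig:
                eligible[lid] = seq
            fh.write(
                f"{lid}\t{c.status}\t{c.best_family or '.'}\t"
                f"{c.best_subject_id or '.'}\t{c.best_score:.1f}\t"
                f"{c.aln_len_aa}\t{int(elig)}\t{span}\n"
            )
    write_fasta(dict(sorted(eligible.items())), out / "pass2_loci.fasta")
    total = sum(counts.values())
    print(f"{total} loci: {counts['accepted']} accepted (pass 1), "
          f"{counts['rejected_family']} rejected by family, "
          f"{counts['rejected_length']} without an intact >=200 aa segment; "
          f"{len(eligible)} pass-2 eligible for placement")


if __name__ == "__main__":
    main()
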
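#!/usr/bin/env python
"""Phylogenetic placement of pass-2-eligible loci on the reference tree:
fragment projection into the reference alignment (keep-length), ML
attachment to the best edge (keep-at-most 1) and OTU labelling by
subtree membership.

Reads results/pass2_loci.fasta + scratch/bundle/refpkg/; writes
results/placements.tsv and results/placement_rejects.txt.
"""

from pathlib import Path

from ecrtmine.placement import ReferencePackage, place_all
from ecrtmine.seqio import read_fasta

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ref = ReferencePackage.load(ROOT / "scratch" / "bundle" / "refpkg")
    out = ROOT / "results"
    queries = read_fasta(out / "pass2_loci.fasta")
    placements, rejects = place_all(queries, ref)
    with open(out / "placements.tsv", "w") as fh:
        fh.write("query\tedge\tpendant\tlog_likelihood\tlwr\totu\n")
        for p in placements:
            fh.write(
                f"{p.query_id}\t{p.edge_id}\t{p.pendant_length:.6f}\t"
                f"{p.log_likelihood:.4f}\t{p.lwr:.4f}\t{p.otu_label}\n"
            )
    (out / "placement_rejects.txt").write_text(
        "".join(r + "\n" for r in rejects)
    )
    n_otu = sum(1 for p in placements if p.otu_label != "inner")
    n_inner = len(placements) - n_otu
    print(f"{len(queries)} queries: {n_otu} classified within OTUs, "
          f"{n_inner} on inner edges, {len(rejects)} unalignable")


if __name__ == "__main__":
    main()
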
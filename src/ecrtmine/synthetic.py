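"""Synthetic benchmark bundles: genomes with planted, decayed RT insertions.

Endogenous viral elements decay after integration — substitutions,
indels that shift the reading frame, premature stop codons, and
fragmentation.  This module plants mutationally decayed copies of
caulimovirid RT donors (and Ty3/Gypsy-like decoys) into random
background genomes, recording ground-truth intervals and edit logs, so
every downstream stage of the pipeline can be scored against a known
answer without downloading real assemblies.

The module also builds the toy reference package used for placement:
a fixed 8-leaf, 2-OTU tree whose leaves are codon-consistent
descendants of a single ancestral RT coding sequence, shipped with the
corresponding ungapped nucleotide alignment and leaf-to-OTU map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .placement import GTRModel, ReferencePackage, _Node, tree_from_newick
from .seqio import (
    GenomeRecord,
    LibraryProtein,
    reverse_complement,
    write_bed,
    write_genomes,
    write_protein_library,
)

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_AA = "ACDEFGHIKLMNPQRSTVWY"


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


_CODONS = _codon_map()
_TRANSLATE = {c: a for a, cs in _CODONS.items() for c in cs}
_TRANSLATE.update({s: "*" for s in _STOPS})


# ---------------------------------------------------------------------------
# elementary generators


def generate_background(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """i.i.d. background sequence with the requested GC fraction."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=p)) if length else ""


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def mutate_protein(protein: str, frac: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``frac`` (to a different aa)."""
    out = list(protein)
    for i in range(len(out)):
        if rng.random() < frac:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def make_divergent_families(
    seed: int = 0,
    n_families: int = 2,
    n_per_family: int = 5,
    length: int = 240,
    motif_every: int = 40,
    motif_len: int = 10,
    family_divergence: float = 0.9,
    within_divergence: float = 0.1,
) -> list[dict[str, str]]:
    """Protein families sharing conserved motif blocks, divergent elsewhere.

    Mimics the architecture of RT domains: short conserved motifs anchor
    a full-length alignment while the inter-motif regions diverge freely,
    so cross-family identity is bounded near the conserved fraction.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_protein(length, rng)
    motif = np.zeros(length, dtype=bool)
    for start in range(0, length, motif_every):
        motif[start : start + motif_len] = True

    def mutate_variable(prot: str, frac: float) -> str:
        out = list(prot)
        for i in range(length):
            if not motif[i] and rng.random() < frac:
                choices = [a for a in _AA if a != out[i]]
                out[i] = choices[rng.integers(len(choices))]
        return "".join(out)

    families = []
    for f in range(n_families):
        founder = mutate_variable(ancestor, family_divergence)
        fam = {
            f"f{f}m{i}": mutate_variable(founder, within_divergence)
            for i in range(n_per_family)
        }
        families.append(fam)
    return families


def reverse_translate(protein: str, seed: int | np.random.Generator = 0) -> str:
    """Random codon choice per residue; translating frame +1 recovers input."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codons = []
    for aa in protein:
        if aa not in _CODONS:
            raise ValueError(f"unknown residue {aa!r}")
        options = _CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def translate_nt(seq: str) -> str:
    return "".join(
        _TRANSLATE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


# ---------------------------------------------------------------------------
# decay


@dataclass
class DecayModel:
    """Mutational decay applied to a planted donor.

    sub_rate: expected substitutions per site.
    indel_rate: expected indel events per site (insert/delete 50:50,
        geometric lengths with mean ``indel_len_mean``).
    stop_rate: expected premature stops introduced per 100 codons of the
        donor's original reading frame (pseudogenization).
    """

    sub_rate: float = 0.0
    indel_rate: float = 0.0
    indel_len_mean: float = 2.0
    stop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.stop_rate <= 100.0:
            raise ValueError("stop_rate (per 100 codons) must be in [0, 100]")
        if self.indel_len_mean < 1.0:
            raise ValueError("indel_len_mean must be >= 1")


Edit = tuple  # ("sub", pos, base) | ("stop", pos, codon) | ("ins", pos, seq) | ("del", pos, length)


def replay_edits(seq: str, edits: list[Edit]) -> str:
    """Apply an edit log to the original sequence, reproducing the decay."""
    out = list(seq)
    for kind, pos, payload in edits:
        if kind == "sub":
            out[pos] = payload
        elif kind == "stop":
            out[pos : pos + 3] = payload
    ins = {pos: payload for kind, pos, payload in edits if kind == "ins"}
    dels = {pos: payload for kind, pos, payload in edits if kind == "del"}
    res = []
    i = 0
    n = len(out)
    while i <= n:
        if i in ins:
            res.append(ins[i])
        if i == n:
            break
        if i in dels:
            i += dels[i]
            continue
        res.append(out[i])
        i += 1
    return "".join(res)


def decay(
    seq: str, model: DecayModel, rng: np.random.Generator | None = None
) -> tuple[str, list[Edit]]:
    """Decay a donor sequence; the edit log replays to the output exactly."""
    if not seq:
        raise ValueError("decay requires a non-empty sequence")
    rng = rng or np.random.default_rng(model.seed)
    seq = seq.upper()
    n = len(seq)
    edits: list[Edit] = []

    sub_sites = np.nonzero(rng.random(n) < model.sub_rate)[0]
    for pos in sub_sites:
        alt = [b for b in _BASES if b != seq[pos]]
        edits.append(("sub", int(pos), alt[rng.integers(3)]))

    ncodons = n // 3
    if ncodons and model.stop_rate > 0:
        hits = np.nonzero(rng.random(ncodons) < model.stop_rate / 100.0)[0]
        for ci in hits:
            edits.append(("stop", int(3 * ci), _STOPS[rng.integers(3)]))

    if model.indel_rate > 0:
        p_len = 1.0 / model.indel_len_mean
        i = 0
        while i <= n:
            if i < n and rng.random() < model.indel_rate:
                length = int(rng.geometric(p_len))
                if rng.random() < 0.5:
                    ins = "".join(rng.choice(list(_BASES), size=length))
                    edits.append(("ins", i, ins))
                else:
                    length = min(length, n - i)
                    if length > 0:
                        edits.append(("del", i, length))
                        i += length
                        continue
            i += 1

    edits.sort(key=lambda e: (e[1], e[0]))
    return replay_edits(seq, edits), edits


# ---------------------------------------------------------------------------
# planting


@dataclass
class PlantedInsertion:
    genome_id: str
    start: int  # final-genome coordinates, 0-based half-open
    end: int
    strand: str
    donor_id: str
    donor_family: str
    applied_edits: list[Edit] = field(default_factory=list)
    decayed_seq: str = ""  # forward-strand donor after decay

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    def extract(self, genome_seq: str) -> str:
        """Slice the genome (strand-aware); equals ``decayed_seq``."""
        s = genome_seq[self.start : self.end]
        return s if self.strand == "+" else reverse_complement(s)


def plant_insertions(
    background: str,
    donors: list[tuple[str, str, str]],
    model: DecayModel,
    seed: int = 0,
    genome_id: str = "genome",
    min_spacing: int = 0,
) -> tuple[GenomeRecord, list[PlantedInsertion]]:
    """Decay each (id, family, sequence) donor and insert it at a random
    position and strand; insertions are placed between background bases
    and therefore never overlap or nest.  ``min_spacing`` keeps at least
    that much background between consecutive insertion points (so flanked
    loci stay separable downstream)."""
    rng = np.random.default_rng(seed)
    if not donors:
        return GenomeRecord(genome_id, background), []
    n = len(donors)
    reduced = len(background) + 1 - (n - 1) * min_spacing
    if reduced < n:
        raise ValueError("background too short to host all insertions disjointly")
    raw = sorted(int(p) for p in rng.choice(reduced, size=n, replace=False))
    points = [p + i * min_spacing for i, p in enumerate(raw)]
    prepared = []
    for donor_id, family, donor_seq in donors:
        child = np.random.default_rng(rng.integers(2**31))
        decayed, edits = decay(donor_seq, model, rng=child)
        strand = "+" if rng.random() < 0.5 else "-"
        prepared.append((donor_id, family, decayed, edits, strand))

    pieces = []
    truth = []
    cursor = 0
    offset = 0
    for point, (donor_id, family, decayed, edits, strand) in zip(points, prepared):
        pieces.append(background[cursor:point])
        inserted = decayed if strand == "+" else reverse_complement(decayed)
        start = point + offset
        truth.append(
            PlantedInsertion(
                genome_id, start, start + len(inserted), strand,
                donor_id, family, edits, decayed,
            )
        )
        pieces.append(inserted)
        offset += len(inserted)
        cursor = point
    pieces.append(background[cursor:])
    return GenomeRecord(genome_id, "".join(pieces)), truth


# ---------------------------------------------------------------------------
# reference package + labelled library


_TOY_NEWICK = (
    "(((cauA1:0.06,cauA2:0.06):0.10,(cauA3:0.06,cauA4:0.06):0.10):0.30,"
    "((cauB1:0.06,cauB2:0.06):0.10,(cauB3:0.06,cauB4:0.06):0.10):0.30);"
)


@dataclass
class RTReferences:
    package: ReferencePackage
    library: list[LibraryProtein]  # caulimovirid leaves + gypsy decoys
    leaf_nt: dict[str, str]  # ungapped coding sequence per leaf
    gypsy_nt: dict[str, str]


def make_rt_references(
    seed: int = 0,
    aa_len: int = 240,
    n_gypsy: int = 4,
    gypsy_divergence: float = 0.15,
) -> RTReferences:
    """Toy RT references: 8 caulimovirid leaves in 2 OTUs plus decoys.

    Leaves descend from one random ancestral protein along the fixed
    topology; mutated residues get fresh random codons while conserved
    residues keep the ancestral codon, so the leaf coding sequences form
    a meaningful ungapped nucleotide alignment.  RT domains default to
    240 aa, the average size used for the generic pass-2 cutoff.
    """
    rng = np.random.default_rng(seed)
    ancestor = random_protein(aa_len, rng)
    ancestor_nt = reverse_translate(ancestor, rng)
    root = tree_from_newick(_TOY_NEWICK)

    leaf_prot: dict[str, str] = {}
    leaf_nt: dict[str, str] = {}

    def descend(node: _Node, prot: str, nt: str) -> None:
        for child in node.children:
            p = prot
            cds = nt
            mut_sites = np.nonzero(rng.random(aa_len) < child.length)[0]
            plist, clist = list(p), list(cds)
            for i in mut_sites:
                choices = [a for a in _AA if a != plist[i]]
                new_aa = choices[rng.integers(len(choices))]
                plist[i] = new_aa
                options = _CODONS[new_aa]
                clist[3 * i : 3 * i + 3] = options[rng.integers(len(options))]
            p, cds = "".join(plist), "".join(clist)
            if child.children:
                descend(child, p, cds)
            else:
                leaf_prot[child.name] = p
                leaf_nt[child.name] = cds

    descend(root, ancestor, ancestor_nt)

    otu_map = {name: ("OTU_A" if name.startswith("cauA") else "OTU_B")
               for name in leaf_prot}
    package = ReferencePackage(
        tree=root,
        msa=dict(sorted(leaf_nt.items())),
        otu_map=otu_map,
        model=GTRModel(),
        newick=_TOY_NEWICK,
    )

    gypsy_anc = random_protein(aa_len, rng)
    library = [
        LibraryProtein(name, "caulimovirid", leaf_prot[name])
        for name in sorted(leaf_prot)
    ]
    gypsy_nt = {}
    for i in range(n_gypsy):
        prot = mutate_protein(gypsy_anc, gypsy_divergence, rng)
        name = f"gypsy{i + 1}"
        library.append(LibraryProtein(name, "gypsy_decoy", prot))
        gypsy_nt[name] = reverse_translate(prot, rng)
    return RTReferences(package, library, leaf_nt, gypsy_nt)


# ---------------------------------------------------------------------------
# whole bundles


@dataclass
class BenchmarkBundle:
    genomes: list[GenomeRecord]
    truth: list[PlantedInsertion]
    library: list[LibraryProtein]
    references: RTReferences

    def truth_for(self, genome_id: str) -> list[PlantedInsertion]:
        return [t for t in self.truth if t.genome_id == genome_id]


def make_benchmark_bundle(
    seed: int = 0,
    n_genomes: int = 3,
    genome_length: int = 100_000,
    n_caulimovirid: int = 8,
    n_decoy: int = 4,
    decay_model: DecayModel | None = None,
    gc: float = 0.4,
    min_spacing: int = 500,
    gap_runs: int = 2,
    gap_run_len: int = 1000,
) -> BenchmarkBundle:
    """Background genomes with decayed caulimovirid + decoy insertions.

    Donors are drawn (with replacement) from the toy reference leaves and
    the gypsy decoy pool; each genome gets ``n_caulimovirid`` target and
    ``n_decoy`` decoy copies under the same decay model.  ``gap_runs``
    N-runs of ``gap_run_len`` bases emulate assembly gaps (excluded from
    effective search space and density denominators downstream).
    """
    rng = np.random.default_rng(seed)
    refs = make_rt_references(seed=int(rng.integers(2**31)))
    model = decay_model or DecayModel()
    cau_ids = sorted(refs.leaf_nt)
    gy_ids = sorted(refs.gypsy_nt)
    genomes, truth = [], []
    for g in range(n_genomes):
        gid = f"genome{g + 1}"
        background = generate_background(
            genome_length, gc=gc, seed=int(rng.integers(2**31))
        )
        if gap_runs and genome_length > gap_runs * gap_run_len:
            bg = list(background)
            for pos in rng.choice(
                genome_length - gap_run_len, size=gap_runs, replace=False
            ):
                bg[int(pos) : int(pos) + gap_run_len] = "N" * gap_run_len
            background = "".join(bg)
        donors = []
        for i in range(n_caulimovirid):
            src = cau_ids[rng.integers(len(cau_ids))]
            donors.append((f"{src}|c{i + 1}", "caulimovirid", refs.leaf_nt[src]))
        for i in range(n_decoy):
            src = gy_ids[rng.integers(len(gy_ids))]
            donors.append((f"{src}|d{i + 1}", "gypsy_decoy", refs.gypsy_nt[src]))
        genome, planted = plant_insertions(
            background, donors, model, seed=int(rng.integers(2**31)),
            genome_id=gid, min_spacing=min_spacing,
        )
        genomes.append(genome)
        truth.extend(planted)
    return BenchmarkBundle(genomes, truth, refs.library, refs)


def write_bundle(bundle: BenchmarkBundle, outdir: str | Path) -> None:
    """Write genomes (FASTA), truth (BED6), library (FASTA) and refpkg."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genomes(bundle.genomes, out / "genomes.fasta")
    write_bed(
        (
            (t.genome_id, t.start, t.end, f"{t.donor_id}:{t.donor_family}", 0, t.strand)
            for t in bundle.truth
        ),
        out / "truth.bed",
    )
    write_protein_library(bundle.library, out / "rt_library.fasta")
    bundle.references.package.save(out / "refpkg")


# ---------------------------------------------------------------------------
# sequence evolution under the placement model (for likelihood fixtures)


def simulate_gtr_alignment(
    tree: _Node, model: GTRModel, nsites: int, seed: int = 0
) -> dict[str, str]:
    """Evolve an alignment along a tree under GTR+Gamma (no indels)."""
    rng = np.random.default_rng(seed)
    rates = model.category_rates()
    site_cat = rng.integers(len(rates), size=nsites)
    root_states = rng.choice(4, size=nsites, p=model.pi)
    out: dict[str, str] = {}

    def walk(node: _Node, states: np.ndarray) -> None:
        for child in node.children:
            new = states.copy()
            for ci, rate in enumerate(rates):
                sites = np.nonzero(site_cat == ci)[0]
                if len(sites) == 0:
                    continue
                P = model.transition_matrix(child.length, rate)
                P = P / P.sum(axis=1, keepdims=True)
                for s in sites:
                    new[s] = rng.choice(4, p=P[states[s]])
            if child.children:
                walk(child, new)
            else:
                out[child.name] = "".join(_BASES[i] for i in new)

    walk(tree, root_states)
    return out


def evolve_sequence(
    seq: str, t: float, model: GTRModel, seed: int | np.random.Generator = 0
) -> str:
    """Evolve a nucleotide sequence for ``t`` substitutions/site (single rate)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    P = model.transition_matrix(t)
    P = P / P.sum(axis=1, keepdims=True)
    out = []
    for ch in seq.upper():
        i = _BASES.find(ch)
        if i < 0:
            out.append(ch)
        else:
            out.append(_BASES[rng.choice(4, p=P[i])])
    return "".join(out)
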
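"""Greedy identity clustering, alignment filtering and OTU delineation.

Accepted RT proteins are clustered centroid-style (longest first, each
sequence joining the first centroid it matches at or above the identity
threshold), mirroring UCLUST's greedy strategy at 80% within a species
and 55% globally.  Aligned sets are cleaned with a trimAl-style
sequence-overlap / gap-column / sequence-overlap filter, and OTUs are
delineated as connected components of a pairwise identity network built
over the cluster representatives.

Pairwise identity is matches over alignment columns under a global
alignment with free terminal gaps, terminal-gap columns excluded from
the denominator (the ``internal`` definition); a ``shorter`` alternative
divides by the length of the shorter sequence instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .scoring import ScoringScheme


@dataclass
class OTUCluster:
    members: list[str]
    representative: str
    level: float

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class SimilarityNetwork:
    nodes: list[str]
    edges: list[tuple[str, str, float]]
    components: list[list[str]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)


def pairwise_identity(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    denominator: str = "internal",
) -> float:
    """Fraction of identical columns between two protein sequences.

    Global alignment with free terminal gaps; terminal-gap columns are
    excluded from the column count.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if denominator not in ("internal", "shorter"):
        raise ValueError("denominator must be 'internal' or 'shorter'")
    scoring = scoring or ScoringScheme()
    aln = scoring.semiglobal_aligner().align(a.upper(), b.upper())[0]
    rows = [aln[0], aln[1]]
    # terminal-gap columns lie before the later-starting row's first residue
    # and after the earlier-ending row's last residue
    starts = [min(i for i, ch in enumerate(r) if ch != "-") for r in rows]
    ends = [max(i for i, ch in enumerate(r) if ch != "-") + 1 for r in rows]
    lead, tail = max(starts), min(ends)
    core = range(lead, tail)
    matches = sum(1 for i in core if rows[0][i] == rows[1][i] != "-")
    if denominator == "internal":
        denom = tail - lead
    else:
        denom = min(len(a), len(b))
    return matches / denom if denom else 0.0


def greedy_cluster(
    seqs: dict[str, str],
    threshold: float,
    scoring: ScoringScheme | None = None,
) -> list[OTUCluster]:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed in decreasing length (ties by id); each joins
    the first centroid with identity >= threshold, else founds a new
    cluster.  Deterministic for a given input set.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    scoring = scoring or ScoringScheme()
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[OTUCluster] = []
    for sid in order:
        placed = False
        for cl in clusters:
            if pairwise_identity(seqs[sid], seqs[cl.representative], scoring) >= threshold:
                cl.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(OTUCluster([sid], sid, threshold))
    for cl in clusters:  # longest member leads (the founder, by processing order)
        cl.representative = max(cl.members, key=lambda i: (len(seqs[i]), i))
    return clusters


@dataclass
class FilteredAlignment:
    rows: dict[str, str]
    dropped_sequences: list[str]
    dropped_columns: list[int]
    emptied: bool = False


def _drop_low_overlap_rows(
    rows: dict[str, str], res_overlap: float, seq_overlap: float
) -> tuple[dict[str, str], list[str]]:
    ids = list(rows)
    n = len(ids)
    cols = len(next(iter(rows.values())))
    nongap_per_col = [sum(rows[i][c] != "-" for i in ids) for c in range(cols)]
    dropped = []
    kept: dict[str, str] = {}
    for sid in ids:
        row = rows[sid]
        good = 0
        for c in range(cols):
            if row[c] == "-":
                continue
            others = nongap_per_col[c] - 1
            if n > 1 and others / (n - 1) >= res_overlap:
                good += 1
        # good residues are counted against the full alignment width
        frac = good / cols if cols else 0.0
        if frac < seq_overlap:
            dropped.append(sid)
        else:
            kept[sid] = row
    return kept, dropped


def filter_alignment(
    msa: dict[str, str],
    res_overlap: float = 0.75,
    seq_overlap: float = 0.50,
    gap_threshold: float = 0.50,
) -> FilteredAlignment:
    """Two sequence-overlap rounds around one gap-column round.

    Round 1 drops sequences whose fraction of well-supported residues
    (residues whose column is non-gap in >= ``res_overlap`` of the other
    sequences) is below ``seq_overlap``.  Round 2 drops columns whose
    non-gap fraction is below ``gap_threshold``.  Round 3 repeats round 1
    on the reduced alignment.  An alignment emptied by filtering is
    returned flagged, not raised.
    """
    if len(msa) < 2:
        raise ValueError("filter_alignment requires >= 2 sequences")
    widths = {len(s) for s in msa.values()}
    if len(widths) != 1:
        raise ValueError("alignment is not rectangular")

    rows, dropped1 = _drop_low_overlap_rows(msa, res_overlap, seq_overlap)
    if not rows:
        return FilteredAlignment({}, dropped1, [], emptied=True)

    ids = list(rows)
    cols = len(next(iter(rows.values())))
    keep_cols, dropped_cols = [], []
    for c in range(cols):
        nongap = sum(rows[i][c] != "-" for i in ids)
        (keep_cols if nongap / len(ids) >= gap_threshold else dropped_cols).append(c)
    rows = {i: "".join(rows[i][c] for c in keep_cols) for i in ids}
    if not keep_cols:
        return FilteredAlignment({}, dropped1, dropped_cols, emptied=True)

    rows, dropped2 = _drop_low_overlap_rows(rows, res_overlap, seq_overlap)
    return FilteredAlignment(
        rows, dropped1 + dropped2, dropped_cols, emptied=not rows
    )


def build_network(
    reps: dict[str, str],
    threshold: float,
    scoring: ScoringScheme | None = None,
) -> SimilarityNetwork:
    """Threshold similarity graph over representatives; OTUs = components.

    Component labels are stable: components are ordered by their
    lexicographically smallest member id.
    """
    if not reps:
        raise ValueError("build_network requires >= 1 representative")
    scoring = scoring or ScoringScheme()
    ids = sorted(reps)
    g = nx.Graph()
    g.add_nodes_from(ids)
    edges = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            ident = pairwise_identity(reps[a], reps[b], scoring)
            if ident >= threshold:
                g.add_edge(a, b)
                edges.append((a, b, ident))
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0]
    )
    return SimilarityNetwork(ids, edges, components)


def delineate_otus(
    seqs: dict[str, str],
    cluster_id: float = 0.55,
    network_id: float = 0.45,
    scoring: ScoringScheme | None = None,
    max_rounds: int = 10,
) -> tuple[list[OTUCluster], SimilarityNetwork]:
    """Cluster then network, iterating until the OTU set is stable.

    Each round clusters the current sequence set, builds the network over
    the representatives, and stops once the component partition repeats.
    """
    scoring = scoring or ScoringScheme()
    prev: list[list[str]] | None = None
    clusters = greedy_cluster(seqs, cluster_id, scoring)
    network = build_network(
        {c.representative: seqs[c.representative] for c in clusters},
        network_id,
        scoring,
    )
    for _ in range(max_rounds):
        if prev == network.components:
            break
        prev = network.components
        clusters = greedy_cluster(seqs, cluster_id, scoring)
        network = build_network(
            {c.representative: seqs[c.representative] for c in clusters},
            network_id,
            scoring,
        )
    return clusters, network
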
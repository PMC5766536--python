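"""Maximum-likelihood placement of ECRT loci on a fixed reference tree.

The reference package bundles a Newick tree with branch lengths, the
nucleotide alignment its leaves were built from, a GTR+Gamma model and a
leaf-to-OTU map.  Queries are first projected into the reference column
space with keep-length semantics (insertions relative to the reference
are dropped), then attached in turn to the midpoint of every edge by a
pendant branch whose length is optimized by bounded 1-D search; the
edge with the highest log-likelihood wins and exactly one placement is
kept per query.  The like-weight ratio (LWR) is the exp-normalized
likelihood of the winning edge over all candidate edges.

The likelihood engine is Felsenstein pruning under GTR with discrete-
Gamma rate heterogeneity; gaps and Ns are treated as missing data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio import Align
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .scoring import free_end_gaps
from .seqio import read_fasta

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


# ---------------------------------------------------------------------------
# substitution model


@dataclass
class GTRModel:
    """GTR exchangeabilities + base frequencies + discrete-Gamma rates.

    ``rates`` are the six exchangeabilities in the order AC, AG, AT, CG,
    CT, GT; the rate matrix is scaled so branch lengths are expected
    substitutions per site.  ``gamma_shape`` with ``ncat`` discrete
    categories models among-site rate variation; ``ncat=1`` disables it.
    """

    rates: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float = 1.0
    ncat: int = 4

    def __post_init__(self) -> None:
        if len(self.rates) != 6 or len(self.freqs) != 4:
            raise ValueError("GTR needs 6 exchangeabilities and 4 frequencies")
        if abs(sum(self.freqs) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        pi = np.asarray(self.freqs, dtype=float)
        ac, ag, at, cg, ct, gt = self.rates
        R = np.array(
            [[0, ac, ag, at], [ac, 0, cg, ct], [ag, cg, 0, gt], [at, ct, gt, 0]],
            dtype=float,
        )
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(Q)))
        Q /= mu
        # symmetrize for a stable eigendecomposition of a reversible Q
        sq = np.sqrt(pi)
        B = (sq[:, None] * Q) / sq[None, :]
        w, U = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        # Q = diag(1/sqrt(pi)) B diag(sqrt(pi)), so P(t) reconstructs as
        self._left = U / sq[:, None]
        self._right = U.T * sq[None, :]
        self._pi = pi

    @property
    def pi(self) -> np.ndarray:
        return self._pi

    def category_rates(self) -> np.ndarray:
        """Mean rates of ``ncat`` equal-probability Gamma categories."""
        if self.ncat == 1:
            return np.ones(1)
        a = self.gamma_shape
        cuts = gamma_dist.ppf(np.linspace(0, 1, self.ncat + 1), a, scale=1.0 / a)
        upper = gammainc(a + 1, cuts[1:] * a)
        lower = gammainc(a + 1, cuts[:-1] * a)
        rates = self.ncat * (upper - lower)
        return rates / rates.mean()

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for one rate category; rows = ancestor, cols = descendant."""
        P = self._left @ np.diag(np.exp(self._eigvals * t * rate)) @ self._right
        return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# light tree structure (dendropy parses; pruning runs on this)


@dataclass(eq=False)
class _Node:
    name: str | None = None
    length: float = 0.0  # branch to parent
    children: list["_Node"] = field(default_factory=list)

    def copy(self) -> "_Node":
        n = _Node(self.name, self.length)
        n.children = [c.copy() for c in self.children]
        return n

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self) -> list[str]:
        return [n.name for n in self.postorder() if not n.children]


def tree_from_newick(newick: str) -> _Node:
    dt = dendropy.Tree.get(data=newick, schema="newick")

    def convert(dnode) -> _Node:
        node = _Node(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=dnode.edge.length or 0.0,
        )
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(dt.seed_node)


def _edges(root: _Node) -> list[_Node]:
    """Every non-root node stands for the edge to its parent."""
    return [n for n in root.postorder() if n is not root]


def edge_id_of(node: _Node) -> str:
    return "|".join(sorted(node.leaves()))


# ---------------------------------------------------------------------------
# reference package


@dataclass
class ReferencePackage:
    tree: _Node
    msa: dict[str, str]
    otu_map: dict[str, str]
    model: GTRModel = field(default_factory=GTRModel)
    newick: str | None = None

    def __post_init__(self) -> None:
        leaves = set(self.tree.leaves())
        if leaves != set(self.msa):
            raise ValueError("tree leaves and alignment rows disagree")
        missing = leaves - set(self.otu_map)
        if missing:
            raise ValueError(f"otu_map misses leaves: {sorted(missing)}")
        widths = {len(s) for s in self.msa.values()}
        if len(widths) != 1:
            raise ValueError("reference alignment is not rectangular")

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.msa.values())))

    def edge_ids(self) -> list[str]:
        return [edge_id_of(n) for n in _edges(self.tree)]

    def leaves_below(self, edge_id: str) -> list[str]:
        return edge_id.split("|")

    def adjacent_edges(self, edge_id: str) -> set[str]:
        """Edges sharing an endpoint with ``edge_id`` (plus itself)."""
        nodes = _edges(self.tree)
        by_id = {edge_id_of(n): n for n in nodes}
        target = by_id[edge_id]
        parent = {id(c): n for n in self.tree.postorder() for c in n.children}
        out = {edge_id}
        for c in target.children:
            out.add(edge_id_of(c))
        par = parent.get(id(target))
        if par is not None:
            for sib in par.children:
                out.add(edge_id_of(sib))
            if par is not self.tree:
                out.add(edge_id_of(par))
            else:  # the root's other edges are incident through the root
                for sib in self.tree.children:
                    out.add(edge_id_of(sib))
        return out

    @classmethod
    def load(cls, directory: str | Path) -> "ReferencePackage":
        d = Path(directory)
        newick = (d / "reference.nwk").read_text()
        msa = read_fasta(d / "reference_msa.fasta")
        otu_map = {}
        for line in (d / "otu_map.tsv").read_text().splitlines():
            if line.strip():
                leaf, otu = line.split("\t")
                otu_map[leaf] = otu
        model_file = d / "model.json"
        if model_file.exists():
            cfg = json.loads(model_file.read_text())
            model = GTRModel(
                tuple(cfg.get("rates", (1.0,) * 6)),
                tuple(cfg.get("freqs", (0.25,) * 4)),
                cfg.get("gamma_shape", 1.0),
                cfg.get("ncat", 4),
            )
        else:
            model = GTRModel()
        return cls(tree_from_newick(newick), msa, otu_map, model, newick)

    def save(self, directory: str | Path) -> None:
        from .seqio import write_fasta

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        if self.newick is None:
            raise ValueError("no newick string recorded for this package")
        (d / "reference.nwk").write_text(self.newick)
        write_fasta(self.msa, d / "reference_msa.fasta")
        with open(d / "otu_map.tsv", "w") as fh:
            for leaf in sorted(self.otu_map):
                fh.write(f"{leaf}\t{self.otu_map[leaf]}\n")
        (d / "model.json").write_text(
            json.dumps(
                {
                    "rates": list(self.model.rates),
                    "freqs": list(self.model.freqs),
                    "gamma_shape": self.model.gamma_shape,
                    "ncat": self.model.ncat,
                },
                indent=1,
            )
        )


# ---------------------------------------------------------------------------
# likelihood


def encode_row(seq: str) -> np.ndarray:
    """(nsites, 4) tip likelihoods; gaps/ambiguity = missing (all ones)."""
    arr = np.ones((len(seq), 4))
    for i, ch in enumerate(seq.upper()):
        j = _BASE_INDEX.get(ch)
        if j is not None:
            arr[i] = 0.0
            arr[i, j] = 1.0
    return arr


def _prune_loglik(root: _Node, model: GTRModel, tips: dict[str, np.ndarray]) -> float:
    rates = model.category_rates()
    nsites = next(iter(tips.values())).shape[0]
    ncat = len(rates)
    site_lik = np.zeros(nsites)
    log_scale_total = np.zeros(nsites)
    cat_site = np.zeros((ncat, nsites))
    for ci, rate in enumerate(rates):
        partials: dict[int, np.ndarray] = {}
        log_scale = np.zeros(nsites)
        for node in root.postorder():
            if not node.children:
                partials[id(node)] = tips[node.name]
                continue
            part = np.ones((nsites, 4))
            for child in node.children:
                P = model.transition_matrix(child.length, rate)
                part = part * (partials.pop(id(child)) @ P.T)
            if node is not root:
                mx = part.max(axis=1)
                mx[mx == 0.0] = 1.0
                part = part / mx[:, None]
                log_scale += np.log(mx)
            partials[id(node)] = part
        cat_site[ci] = (partials[id(root)] * model.pi[None, :]).sum(axis=1)
        if ci == 0:
            log_scale_total = log_scale
        else:
            # scalings are per-category; fold into the site term instead
            cat_site[ci] *= np.exp(log_scale - log_scale_total)
    site_lik = cat_site.mean(axis=0)
    if np.any(site_lik <= 0.0):
        return -np.inf
    return float(np.sum(np.log(site_lik) + log_scale_total))


def tree_loglik(
    ref_or_tree: ReferencePackage | _Node,
    rows: dict[str, str],
    model: GTRModel | None = None,
) -> float:
    """Log-likelihood of an alignment on a tree under GTR+Gamma."""
    if isinstance(ref_or_tree, ReferencePackage):
        tree = ref_or_tree.tree
        model = model or ref_or_tree.model
    else:
        tree = ref_or_tree
        model = model or GTRModel()
    leaves = tree.leaves()
    missing = set(leaves) - set(rows)
    if missing:
        raise ValueError(f"alignment rows missing for leaves: {sorted(missing)}")
    widths = {len(rows[l]) for l in leaves}
    if len(widths) != 1 or widths == {0}:
        raise ValueError("rows must be non-empty and rectangular")
    tips = {l: encode_row(rows[l]) for l in leaves}
    return _prune_loglik(tree, model, tips)


# ---------------------------------------------------------------------------
# fragment alignment into reference columns


def _nt_fragment_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5.0
    aligner.mismatch_score = -4.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    free_end_gaps(aligner)
    return aligner


def add_fragment(query: str, ref: ReferencePackage, min_seed_kmers: int = 1) -> str | None:
    """Project a query into reference columns with keep-length semantics.

    The query is aligned (semi-global, free end gaps) to its best-
    matching reference row, chosen by shared nucleotide 8-mers; aligned
    query residues are written into the columns of that row's residues,
    and query insertions relative to the reference are dropped, so the
    output row has exactly the reference alignment length.  Both query
    orientations are tried (mined loci carry no strand).  Returns
    ``None`` for queries with no seed match to any row (unalignable).
    """
    if not query:
        raise ValueError("empty query")
    from .seqio import reverse_complement

    k = 8
    best_row, best_shared, best_query = None, 0, query.upper()
    for oriented in (query.upper(), reverse_complement(query.upper())):
        qmers = {oriented[i : i + k] for i in range(len(oriented) - k + 1)}
        for rid in sorted(ref.msa):
            ungapped = ref.msa[rid].replace("-", "").upper()
            shared = sum(
                1 for i in range(len(ungapped) - k + 1) if ungapped[i : i + k] in qmers
            )
            if shared > best_shared:
                best_row, best_shared, best_query = rid, shared, oriented
    if best_row is None or best_shared < min_seed_kmers:
        return None
    query = best_query
    row = ref.msa[best_row]
    ungapped = row.replace("-", "").upper()
    col_of_residue = [i for i, ch in enumerate(row) if ch != "-"]
    aln = _nt_fragment_aligner().align(ungapped, query)[0]
    out = ["-"] * len(row)
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for off in range(te - ts):
            out[col_of_residue[ts + off]] = query[qs + off]
    return "".join(out)


# ---------------------------------------------------------------------------
# placement


@dataclass
class PlacementResult:
    query_id: str
    edge_id: str
    pendant_length: float
    attach_position: float
    log_likelihood: float
    lwr: float
    otu_label: str = "inner"


def _attach(
    tree: _Node, edge_node: _Node, query_name: str, pendant: float,
    attach_position: float = 0.5,
) -> _Node:
    """Copy of ``tree`` with a query leaf attached mid-edge above ``edge_node``."""
    index = {id(n): i for i, n in enumerate(tree.postorder())}
    target_idx = index[id(edge_node)]
    new_tree = tree.copy()
    new_nodes = list(new_tree.postorder())
    target = new_nodes[target_idx]
    parent = next(
        n for n in new_tree.postorder() if any(c is target for c in n.children)
    )
    t = target.length
    joint = _Node(length=t * (1.0 - attach_position))
    target.length = t * attach_position
    joint.children = [target, _Node(name=query_name, length=pendant)]
    slot = next(i for i, c in enumerate(parent.children) if c is target)
    parent.children[slot] = joint
    return new_tree


def place_query(
    aligned_query: str,
    ref: ReferencePackage,
    query_id: str = "query",
    max_pendant: float = 5.0,
    tol: float = 1e-4,
) -> PlacementResult:
    """Best-edge ML placement of a column-aligned query (keep-at-most 1).

    Every reference edge is tried: the query hangs by a pendant branch
    from the edge midpoint and the pendant length is optimized by
    bounded search.  LWR is the softmax weight of the winning edge.
    """
    if len(aligned_query) != ref.alignment_length:
        raise ValueError("query is not in reference column space")
    rows = dict(ref.msa)
    rows[query_id] = aligned_query
    tips = {name: encode_row(seq) for name, seq in rows.items()}
    edge_scores: list[tuple[str, float, float]] = []
    for edge_node in _edges(ref.tree):
        eid = edge_id_of(edge_node)

        def neg_loglik(p: float) -> float:
            attached = _attach(ref.tree, edge_node, query_id, p)
            return -_prune_loglik(attached, ref.model, tips)

        res = minimize_scalar(
            neg_loglik, bounds=(1e-8, max_pendant), method="bounded",
            options={"xatol": tol},
        )
        edge_scores.append((eid, float(res.x), -float(res.fun)))
    logliks = np.array([s[2] for s in edge_scores])
    weights = np.exp(logliks - logliks.max())
    weights /= weights.sum()
    best = int(np.argmax(logliks))
    eid, pendant, loglik = edge_scores[best]
    result = PlacementResult(
        query_id=query_id,
        edge_id=eid,
        pendant_length=pendant,
        attach_position=0.5,
        log_likelihood=loglik,
        lwr=float(weights[best]),
    )
    result.otu_label = classify_placement(result, ref)
    return result


def edge_likelihood_profile(
    aligned_query: str, ref: ReferencePackage, query_id: str = "query",
    pendant_grid: np.ndarray | None = None,
) -> dict[str, float]:
    """Best log-likelihood per edge over a fixed pendant-length grid.

    A deliberately simple scan, exposed so placements can be checked
    against an exhaustive evaluation.
    """
    if pendant_grid is None:
        pendant_grid = np.geomspace(1e-4, 2.0, 10)
    rows = dict(ref.msa)
    rows[query_id] = aligned_query
    tips = {name: encode_row(seq) for name, seq in rows.items()}
    out = {}
    for edge_node in _edges(ref.tree):
        best = -np.inf
        for p in pendant_grid:
            attached = _attach(ref.tree, edge_node, query_id, float(p))
            best = max(best, _prune_loglik(attached, ref.model, tips))
        out[edge_id_of(edge_node)] = best
    return out


def classify_placement(result: PlacementResult, ref: ReferencePackage) -> str:
    """OTU of the leafward subtree if unanimous, else ``"inner"``."""
    leaves = ref.leaves_below(result.edge_id)
    otus = {ref.otu_map[l] for l in leaves}
    return otus.pop() if len(otus) == 1 else "inner"


def place_all(
    queries: dict[str, str],
    ref: ReferencePackage,
) -> tuple[list[PlacementResult], list[str]]:
    """Align and place every query; returns (placements, reject ids)."""
    placements, rejects = [], []
    for qid in sorted(queries):
        aligned = add_fragment(queries[qid], ref)
        if aligned is None or set(aligned) == {"-"}:
            rejects.append(qid)
            continue
        placements.append(place_query(aligned, ref, query_id=qid))
    return placements, rejects
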
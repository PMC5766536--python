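"""Independent brute-force oracles used only by the test suite.

These re-derive results by the most direct method available (full
dynamic programming over all cells, exhaustive ancestral-state
enumeration, union-find) and share no code with the package's
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

_BLOSUM = substitution_matrices.load("BLOSUM62")
_LETTERS = "ARNDCQEGHILKMFPSTWYVBZX*"
_LUT = np.full(128, _LETTERS.index("X"), dtype=np.int64)
for _i, _ch in enumerate(_LETTERS):
    _LUT[ord(_ch)] = _i
_MAT = np.array(
    [[float(_BLOSUM[a, b]) for b in _LETTERS] for a in _LETTERS]
)


def _enc(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_affine(q, s, mat, go, ge):
    """Full Smith-Waterman, affine gaps (first gap position costs ``go``,
    later positions ``ge``); returns the best cell score."""
    n, m = len(q), len(s)
    NEG = -1e18
    M_prev = np.zeros(m + 1)
    Ix_prev = np.full(m + 1, NEG)
    Iy_prev = np.full(m + 1, NEG)
    M_cur = np.zeros(m + 1)
    Ix_cur = np.full(m + 1, NEG)
    Iy_cur = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        M_cur[0] = 0.0
        Ix_cur[0] = NEG
        Iy_cur[0] = NEG
        for j in range(1, m + 1):
            sub = mat[q[i - 1], s[j - 1]]
            diag = M_prev[j - 1]
            if Ix_prev[j - 1] > diag:
                diag = Ix_prev[j - 1]
            if Iy_prev[j - 1] > diag:
                diag = Iy_prev[j - 1]
            v = diag + sub
            if v < 0.0:
                v = 0.0
            M_cur[j] = v
            a = M_prev[j] - go
            b = Ix_prev[j] - ge
            Ix_cur[j] = a if a > b else b
            a = M_cur[j - 1] - go
            b = Iy_cur[j - 1] - ge
            Iy_cur[j] = a if a > b else b
            if M_cur[j] > best:
                best = M_cur[j]
        M_prev, M_cur = M_cur, M_prev
        Ix_prev, Ix_cur = Ix_cur, Ix_prev
        Iy_prev, Iy_cur = Iy_cur, Iy_prev
    return best


def sw_score(query: str, subject: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Best local BLOSUM62 alignment score; a length-L gap costs
    ``gap_open + L * gap_extend``."""
    return float(
        _sw_affine(_enc(query), _enc(subject), _MAT,
                   float(gap_open + gap_extend), float(gap_extend))
    )


@njit(cache=True)
def _semiglobal_affine(q, s, mat, go, ge):
    """Global alignment score with free terminal gaps, affine internal gaps."""
    n, m = len(q), len(s)
    NEG = -1e18
    M_prev = np.full(m + 1, NEG)
    Ix_prev = np.full(m + 1, NEG)
    Iy_prev = np.full(m + 1, NEG)
    M_cur = np.full(m + 1, NEG)
    Ix_cur = np.full(m + 1, NEG)
    Iy_cur = np.full(m + 1, NEG)
    M_prev[0] = 0.0
    for j in range(1, m + 1):
        Iy_prev[j] = 0.0  # free leading gap in q
    for i in range(1, n + 1):
        M_cur[0] = NEG
        Ix_cur[0] = 0.0  # free leading gap in s
        Iy_cur[0] = NEG
        for j in range(1, m + 1):
            sub = mat[q[i - 1], s[j - 1]]
            diag = M_prev[j - 1]
            if Ix_prev[j - 1] > diag:
                diag = Ix_prev[j - 1]
            if Iy_prev[j - 1] > diag:
                diag = Iy_prev[j - 1]
            M_cur[j] = diag + sub
            a = M_prev[j] - go
            b = Ix_prev[j] - ge
            if j == m:  # free trailing gap in s
                a = M_prev[j]
                b = Ix_prev[j]
            Ix_cur[j] = a if a > b else b
            a = M_cur[j - 1] - go
            b = Iy_cur[j - 1] - ge
            if i == n:  # free trailing gap in q
                a = M_cur[j - 1]
                b = Iy_cur[j - 1]
            Iy_cur[j] = a if a > b else b
        M_prev, M_cur = M_cur, M_prev
        Ix_prev, Ix_cur = Ix_cur, Ix_prev
        Iy_prev, Iy_cur = Iy_cur, Iy_prev
    best = M_prev[m]
    if Ix_prev[m] > best:
        best = Ix_prev[m]
    if Iy_prev[m] > best:
        best = Iy_prev[m]
    return best


def semiglobal_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    return float(
        _semiglobal_affine(_enc(a), _enc(b), _MAT,
                           float(gap_open + gap_extend), float(gap_extend))
    )


def union_find_components(nodes: list[str], edges: list[tuple[str, str]]):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for n in nodes:
        groups.setdefault(find(n), []).append(n)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


def brute_interval_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals by marking individual positions."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    covered = np.zeros(hi + 1, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    out = []
    i = 0
    while i <= hi:
        if covered[i]:
            j = i
            while j <= hi and covered[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def exhaustive_loglik(root, model, rows: dict[str, str]) -> float:
    """Tree log-likelihood by enumerating all internal-node state vectors.

    For every assignment of bases to internal nodes the product of the
    root prior and per-edge transition probabilities is accumulated;
    gaps/Ns at tips contribute a factor summed over all bases.
    """
    nodes = list(root.postorder())
    internals = [n for n in nodes if n.children]
    leaves = [n for n in nodes if not n.children]
    nsites = len(next(iter(rows.values())))
    idx_of = {id(n): k for k, n in enumerate(internals)}
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    parent_of = {}
    for n in nodes:
        for c in n.children:
            parent_of[id(c)] = n

    rates = model.category_rates()
    assignments = np.array(
        list(itertools.product(range(4), repeat=len(internals))), dtype=np.int64
    )
    total = np.zeros(nsites)
    for rate in rates:
        lik = np.ones((len(assignments), nsites))
        lik *= model.pi[assignments[:, idx_of[id(root)]]][:, None]
        for n in internals:
            if n is root:
                continue
            P = model.transition_matrix(n.length, rate)
            ps = assignments[:, idx_of[id(parent_of[id(n)])]]
            lik *= P[ps, assignments[:, idx_of[id(n)]]][:, None]
        for leaf in leaves:
            P = model.transition_matrix(leaf.length, rate)
            F = np.zeros((4, nsites))
            for s_i, ch in enumerate(rows[leaf.name].upper()):
                b = base_index.get(ch)
                F[:, s_i] = P[:, b] if b is not None else 1.0
            lik *= F[assignments[:, idx_of[id(parent_of[id(leaf)])]], :]
        total += lik.sum(axis=0) / len(rates)
    return float(np.log(total).sum())
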
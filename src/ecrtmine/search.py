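"""First-pass ECRT mining: translated seed-and-extend homology search.

A protein RT query is compared against all six reading frames of a genome,
in the manner of tBLASTn: exact amino-acid k-mer seeds (default k=4) are
located with a sorted k-mer index, grouped by diagonal, extended first
ungapped under an X-drop rule and then gapped (banded by the window that
the seed group spans), and scored under BLOSUM62 with affine gaps.
Karlin-Altschul E-values use the genome's effective length (assembly-gap
bases excluded) as the nucleotide search space; HSPs above the E-value
cutoff are discarded.

Retained HSP footprints are projected back to forward-strand nucleotide
coordinates, merged into hit loci when overlapping (strandlessly, across
frames), and extended by a fixed flank of 120 bp on both sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from .scoring import ScoringScheme, encode_protein, score_profile
from .seqio import GenomeRecord, LibraryProtein, reverse_complement

FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual translations with its coordinate map."""

    frame: int
    protein: str
    genome_length: int

    def to_genome(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa interval of this frame to forward-strand nt coordinates."""
        off = abs(self.frame) - 1
        lo = off + 3 * aa_start
        hi = off + 3 * aa_end
        if self.frame > 0:
            return lo, hi
        return self.genome_length - hi, self.genome_length - lo


def six_frame_translate(seq: str) -> list[FrameTranslation]:
    """Translate all six frames; stops as '*', N-containing codons as 'X'."""
    seq = seq.upper()
    n = len(seq)
    rc = reverse_complement(seq)
    frames = []
    for f in FRAMES:
        src = seq if f > 0 else rc
        off = abs(f) - 1
        trimmed = src[off : off + 3 * ((n - off) // 3)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prot = str(Seq(trimmed).translate())
        frames.append(FrameTranslation(f, prot, n))
    return frames


@dataclass
class HSP:
    query_id: str
    genome_id: str
    frame: int
    genome_interval: tuple[int, int]  # forward-strand nt, 0-based half-open
    query_interval: tuple[int, int]  # aa coordinates on the query
    score: float
    evalue: float


@dataclass
class HitLocus:
    genome_id: str
    start: int
    end: int
    hsp_indices: list[int] = field(default_factory=list)
    best_score: float = 0.0
    extended: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-128 packed k-mer codes at every position (length n-k+1)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(len(codes) - k + 1, dtype=np.int64)
    for i in range(k):
        out = out * 128 + codes[i : len(codes) - k + 1 + i].astype(np.int64)
    return out


class _FrameIndex:
    """Sorted k-mer index over one translated frame."""

    def __init__(self, protein: str, k: int):
        self.codes = encode_protein(protein)
        kmers = _kmer_codes(self.codes, k)
        self.order = np.argsort(kmers, kind="stable").astype(np.int64)
        self.sorted_kmers = kmers[self.order]

    def lookup(self, query_kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(query_pos, frame_pos) pairs of exact k-mer matches."""
        lo = np.searchsorted(self.sorted_kmers, query_kmers, side="left")
        hi = np.searchsorted(self.sorted_kmers, query_kmers, side="right")
        counts = hi - lo
        qpos = np.repeat(np.arange(len(query_kmers)), counts)
        if counts.sum() == 0:
            return qpos, np.empty(0, dtype=np.int64)
        spos = np.concatenate(
            [self.order[a:b] for a, b in zip(lo, hi) if b > a]
        )
        return qpos, spos


def _xdrop_segment(scores: np.ndarray, xdrop: float) -> float:
    """Best prefix sum of `scores` before the running drop exceeds xdrop."""
    if len(scores) == 0:
        return 0.0
    c = np.cumsum(scores)
    run_max = np.maximum.accumulate(c)
    drop = run_max - c > xdrop
    stop = int(drop.argmax()) if drop.any() else len(c)
    if stop == 0:
        return 0.0
    return float(max(run_max[stop - 1], 0.0))


class TranslatedSearch:
    """Seed-and-extend search of protein queries against one genome.

    The genome's six frames are translated and k-mer indexed once; each
    query is then searched with :meth:`search`.
    """

    def __init__(
        self,
        genome: GenomeRecord,
        scoring: ScoringScheme | None = None,
        seed_k: int = 4,
        xdrop: float = 20.0,
        ungapped_trigger: float = 40.0,
        diag_band: int = 16,
    ):
        self.genome = genome
        self.scoring = scoring or ScoringScheme()
        self.seed_k = seed_k
        self.xdrop = xdrop
        self.ungapped_trigger = ungapped_trigger
        self.diag_band = diag_band
        self.frames = six_frame_translate(genome.seq)
        self._indexes = [_FrameIndex(ft.protein, seed_k) for ft in self.frames]
        self._aligner = self.scoring.local_aligner()

    # -- seed grouping ---------------------------------------------------

    def _seed_groups(
        self, qpos: np.ndarray, spos: np.ndarray, qlen: int
    ) -> list[tuple[int, int, int, int, int, int]]:
        """Cluster seeds into (qmin, qmax, smin, smax, rep_q, rep_s) groups.

        Seeds are grouped when they lie on nearby diagonals (within
        ``diag_band``) and within a query length of each other along the
        subject; each group triggers one extension.
        """
        if len(spos) == 0:
            return []
        diag = spos - qpos
        order = np.lexsort((spos, diag))
        groups: list[tuple[int, int, int, int, int, int]] = []
        cur: list[int] = []

        def flush(idx: list[int]) -> None:
            q = qpos[idx]
            s = spos[idx]
            mid = idx[len(idx) // 2]
            groups.append(
                (int(q.min()), int(q.max()), int(s.min()), int(s.max()),
                 int(qpos[mid]), int(spos[mid]))
            )

        prev_d = prev_s = None
        for i in order:
            d, s = int(diag[i]), int(spos[i])
            if cur and (d - prev_d > self.diag_band or s - prev_s > qlen + self.diag_band):
                flush(cur)
                cur = []
            cur.append(i)
            prev_d, prev_s = d, s
        flush(cur)
        return groups

    # -- extension -------------------------------------------------------

    def _ungapped_score(
        self, q_codes: np.ndarray, s_codes: np.ndarray, qi: int, si: int
    ) -> float:
        m_right = min(len(q_codes) - qi, len(s_codes) - si)
        right = score_profile(
            q_codes[qi : qi + m_right], s_codes[si : si + m_right]
        )
        left_q = q_codes[:qi][::-1]
        left_s = s_codes[max(0, si - qi) : si][::-1]
        m = min(len(left_q), len(left_s))
        left = score_profile(left_q[:m], left_s[:m])
        return _xdrop_segment(right, self.xdrop) + _xdrop_segment(left, self.xdrop)

    def search(self, query_id: str, query: str) -> list[HSP]:
        """All HSPs of ``query`` against the genome with E <= e_max."""
        query = query.upper()
        qlen = len(query)
        if qlen < self.seed_k or len(self.genome.seq) == 0:
            return []
        q_codes = encode_protein(query)
        q_kmers = _kmer_codes(q_codes, self.seed_k)
        space = self.genome.effective_length
        found: dict[tuple[int, int, int], HSP] = {}
        for ft, index in zip(self.frames, self._indexes):
            qpos, spos = index.lookup(q_kmers)
            if len(spos) == 0:
                continue
            flen = len(ft.protein)
            windows: list[tuple[int, int]] = []
            for qmin, qmax, smin, smax, rep_q, rep_s in self._seed_groups(
                qpos, spos, qlen
            ):
                ung = self._ungapped_score(q_codes, index.codes, rep_q, rep_s)
                if ung < self.ungapped_trigger:
                    continue
                windows.append(
                    (max(0, smin - qlen - 32),
                     min(flen, smax + self.seed_k + qlen + 32))
                )
            # overlapping windows collapse into one gapped extension
            windows.sort()
            merged: list[list[int]] = []
            for lo, hi in windows:
                if merged and lo <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], hi)
                else:
                    merged.append([lo, hi])
            for wlo, whi in merged:
                window = ft.protein[wlo:whi]
                alns = self._aligner.align(query, window)
                aln = alns[0]
                score = float(aln.score)
                ev = self.scoring.evalue(score, qlen, space)
                if ev > self.scoring.e_max:
                    continue
                tsegs, wsegs = aln.aligned
                q_iv = (int(tsegs[0][0]), int(tsegs[-1][1]))
                s_aa = (int(wsegs[0][0]) + wlo, int(wsegs[-1][1]) + wlo)
                g_iv = ft.to_genome(*s_aa)
                key = (ft.frame, g_iv[0], g_iv[1])
                prev = found.get(key)
                if prev is None or score > prev.score:
                    found[key] = HSP(
                        query_id, self.genome.id, ft.frame, g_iv, q_iv, score, ev
                    )
        return sorted(
            found.values(), key=lambda h: (-h.score, h.genome_interval, h.frame)
        )


def seeded_search(
    query: str,
    genome: GenomeRecord,
    scoring: ScoringScheme | None = None,
    query_id: str = "query",
    **kwargs,
) -> list[HSP]:
    """One-shot convenience wrapper around :class:`TranslatedSearch`."""
    return TranslatedSearch(genome, scoring, **kwargs).search(query_id, query)


def search_library(
    genome: GenomeRecord,
    library: list[LibraryProtein],
    scoring: ScoringScheme | None = None,
    **kwargs,
) -> list[HSP]:
    engine = TranslatedSearch(genome, scoring, **kwargs)
    hsps: list[HSP] = []
    for prot in library:
        hsps.extend(engine.search(prot.id, prot.seq))
    return hsps


def merge_hit_loci(hsps: list[HSP]) -> list[HitLocus]:
    """Merge overlapping HSP footprints (any strand/frame) into loci.

    Half-open intervals that merely touch are not merged.  The result is
    sorted by start and pairwise disjoint; merging is idempotent.
    """
    if not hsps:
        return []
    genome_ids = {h.genome_id for h in hsps}
    if len(genome_ids) != 1:
        raise ValueError("merge_hit_loci expects HSPs from a single genome")
    order = sorted(range(len(hsps)), key=lambda i: hsps[i].genome_interval)
    loci: list[HitLocus] = []
    for i in order:
        h = hsps[i]
        s, e = h.genome_interval
        if loci and s < loci[-1].end:
            cur = loci[-1]
            cur.end = max(cur.end, e)
            cur.hsp_indices.append(i)
            cur.best_score = max(cur.best_score, h.score)
        else:
            loci.append(HitLocus(h.genome_id, s, e, [i], h.score))
    return loci


def extend_loci(
    loci: list[HitLocus], genome_length: int, flank: int = 120
) -> list[HitLocus]:
    """Widen each locus by ``flank`` bp on both sides, clamp, and re-merge."""
    widened = sorted(
        ((max(0, l.start - flank), min(genome_length, l.end + flank), l)
         for l in loci),
        key=lambda t: (t[0], t[1]),
    )
    out: list[HitLocus] = []
    for s, e, l in widened:
        if out and s < out[-1].end:
            cur = out[-1]
            cur.end = max(cur.end, e)
            cur.hsp_indices.extend(l.hsp_indices)
            cur.best_score = max(cur.best_score, l.best_score)
        else:
            out.append(
                HitLocus(l.genome_id, s, e, list(l.hsp_indices), l.best_score, True)
            )
    for l in out:
        l.extended = True
    return out
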
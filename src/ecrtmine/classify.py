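"""Second-stage filtering of extended loci into classified ECRTs.

Pass 1 works at the protein level: each extended locus is translated in
six frames, maximal stop-free segments of at least 200 aa are compared to
the labelled RT library by local alignment, and a locus is accepted when
its best-scoring hit is a caulimovirid over at least 170 aligned
residues.  Pass 2 relaxes the intact-ORF requirement for phylogenetic
placement: the locus nucleotide sequence itself is compared (frame by
frame, stops allowed inside the alignment at matrix cost) against the
diverse library, and is eligible when the best caulimovirid alignment
spans at least 80% of the subject length measured in base pairs
(576 bp for the generic 240-aa RT domain).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

from .scoring import ScoringScheme
from .search import six_frame_translate
from .seqio import LibraryProtein

TARGET_FAMILY = "caulimovirid"


def pass2_threshold_bp(subject_aa_len: int = 240, frac: float = 0.8) -> int:
    """Minimum nucleotide alignment span for pass-2 eligibility.

    Exact rational arithmetic, so the generic 240-aa subject gives 576 bp.
    """
    return math.ceil(Fraction(frac).limit_denominator(10**6) * 3 * subject_aa_len)


@dataclass
class ProteinCandidate:
    locus_id: str
    frame: int
    aa_start: int  # within the frame translation
    aa_sequence: str

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)


@dataclass
class ClassifiedECRT:
    locus_id: str
    best_subject_id: str | None
    best_family: str | None
    best_score: float
    aln_len_aa: int
    status: str  # accepted | rejected_family | rejected_length
    pass2_eligible: bool = False
    pass2_aln_len_nt: int = 0
    best_candidate: ProteinCandidate | None = None


def best_translation(
    locus_id: str, locus_seq: str, min_len: int = 200
) -> list[ProteinCandidate]:
    """Maximal stop-free segments of >= ``min_len`` aa across six frames.

    Returned longest-first (ties broken by frame then position) so the
    head of the list is the best ORF candidate.
    """
    out: list[ProteinCandidate] = []
    for ft in six_frame_translate(locus_seq):
        pos = 0
        for segment in ft.protein.split("*"):
            if len(segment) >= min_len:
                out.append(ProteinCandidate(locus_id, ft.frame, pos, segment))
            pos += len(segment) + 1
    out.sort(key=lambda c: (-c.aa_length, c.frame, c.aa_start))
    return out


def align_protein(
    query: str, subject: str, scoring: ScoringScheme | None = None
) -> tuple[float, int, float]:
    """Local (Smith-Waterman) alignment summary: (score, aln_len, identity).

    ``aln_len`` counts alignment columns including gap columns; identity
    is identical columns over ``aln_len``.
    """
    if not query or not subject:
        raise ValueError("align_protein requires non-empty sequences")
    scoring = scoring or ScoringScheme()
    aln = scoring.local_aligner().align(query.upper(), subject.upper())[0]
    counts = aln.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aln_len if aln_len else 0.0
    return float(aln.score), int(aln_len), identity


def _best_hit(
    query: str, library: list[LibraryProtein], scoring: ScoringScheme
) -> tuple[LibraryProtein, float, int, float]:
    best = None
    # ids ascending, so on full ties the lexicographically first subject wins
    for prot in sorted(library, key=lambda p: p.id):
        score, aln_len, ident = align_protein(query, prot.seq, scoring)
        if best is None or (score, ident) > (best[1], best[3]):
            best = (prot, score, aln_len, ident)
    return best


def reciprocal_classify(
    candidate: ProteinCandidate,
    library: list[LibraryProtein],
    scoring: ScoringScheme | None = None,
    min_aln: int = 170,
    target_family: str = TARGET_FAMILY,
) -> ClassifiedECRT:
    """Best-score family assignment against the combined two-family library."""
    if not library:
        raise ValueError("classification library is empty")
    families = {p.family for p in library}
    if len(families) < 2:
        raise ValueError("library must contain target and outgroup families")
    scoring = scoring or ScoringScheme()
    prot, score, aln_len, _ = _best_hit(candidate.aa_sequence, library, scoring)
    if prot.family != target_family:
        status = "rejected_family"
    elif aln_len < min_aln:
        status = "rejected_length"
    else:
        status = "accepted"
    return ClassifiedECRT(
        locus_id=candidate.locus_id,
        best_subject_id=prot.id,
        best_family=prot.family,
        best_score=score,
        aln_len_aa=aln_len,
        status=status,
        best_candidate=candidate,
    )


def classify_locus(
    locus_id: str,
    locus_seq: str,
    library: list[LibraryProtein],
    scoring: ScoringScheme | None = None,
    min_len: int = 200,
    min_aln: int = 170,
) -> ClassifiedECRT:
    """Pass-1 classification of one extended locus (translate then classify)."""
    candidates = best_translation(locus_id, locus_seq, min_len=min_len)
    if not candidates:
        return ClassifiedECRT(
            locus_id, None, None, 0.0, 0, "rejected_length", best_candidate=None
        )
    return reciprocal_classify(candidates[0], library, scoring, min_aln=min_aln)


def select_for_placement(
    locus_id: str,
    locus_seq: str,
    library: list[LibraryProtein],
    scoring: ScoringScheme | None = None,
    frac: float = 0.8,
    target_family: str = TARGET_FAMILY,
) -> tuple[bool, int, str | None]:
    """Pass-2 eligibility of a locus for phylogenetic placement.

    The locus nucleotide footprint of the best translated alignment
    (3 bp per alignment column) must reach ``frac`` of the subject length
    in bp, and the best subject must be a caulimovirid.  Returns
    (eligible, best alignment span in nt, best subject id).
    """
    scoring = scoring or ScoringScheme()
    aligner = scoring.local_aligner()
    frames = six_frame_translate(locus_seq)
    best: tuple[float, int, LibraryProtein] | None = None
    for prot in sorted(library, key=lambda p: p.id):
        for ft in frames:
            if not ft.protein:
                continue
            aln = aligner.align(ft.protein, prot.seq)[0]
            counts = aln.counts()
            aln_len = counts.identities + counts.mismatches + counts.gaps
            if best is None or aln.score > best[0]:
                best = (float(aln.score), int(aln_len), prot)
    if best is None:
        return False, 0, None
    score, aln_len, prot = best
    span_nt = 3 * aln_len
    eligible = (
        prot.family == target_family
        and span_nt >= pass2_threshold_bp(len(prot.seq), frac)
    )
    return eligible, span_nt, prot.id
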
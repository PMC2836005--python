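"""Element-boundary logic: terminal inverted repeats, target site
duplications, and conserved termini.

A cut-and-paste DNA transposon of the kind handled here is delimited by two
reverse-complementary terminal inverted repeat (TIR) arms that begin
essentially at the element termini, is flanked by a short exact target site
duplication (TSD; 4 bp for both Ginger groups, 5 bp for the Tdd-4/5-like
elements), and starts with the 5'-TGTNR terminus shared with Gypsy LTR
retrotransposons (so it ends with YNACA).  ``refine_boundaries`` combines
the three signals around a transposase protein hit to delimit the element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio import Align

from .seqio import ElementAnnotation, GenomeRecord, revcomp

logger = logging.getLogger(__name__)

#: IUPAC nucleotide code -> allowed concrete bases
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

TERMINAL_MOTIF = "TGTNR"

# TIR arm alignment scoring: match +1 / mismatch -1 / gap -2 (linear).
_ARM_MATCH, _ARM_MISMATCH, _ARM_GAP = 1.0, -1.0, -2.0


@dataclass
class TIRPair:
    """A pair of terminal inverted repeat arms (coordinates in the frame of
    whatever sequence they were detected on)."""

    left_start0: int
    left_end0: int
    right_start0: int
    right_end0: int
    arm_identity: float
    arm_length: int
    score: float = 0.0
    exceeds_max_len: bool = False

    def __post_init__(self) -> None:
        if not self.left_end0 <= self.right_start0:
            raise ValueError("left TIR arm must precede right TIR arm")


@dataclass
class TSDRecord:
    """An exact target site duplication flanking an element."""

    length: int
    sequence: str
    left: tuple[int, int]
    right: tuple[int, int]


def iupac_match(seq: str, motif: str) -> bool:
    """True iff ``seq`` matches the IUPAC ``motif`` position by position."""
    if len(seq) != len(motif):
        return False
    return all(b in IUPAC_CODES.get(m, "") for b, m in zip(seq, motif))


def _arm_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local")
    al.match_score = _ARM_MATCH
    al.mismatch_score = _ARM_MISMATCH
    al.open_gap_score = _ARM_GAP
    al.extend_gap_score = _ARM_GAP
    return al


def _alignment_identity(aln) -> tuple[float, int]:
    """(identity over alignment columns, number of columns)."""
    counts = aln.counts()
    ncols = counts.identities + counts.mismatches + counts.gaps
    if ncols == 0:
        return 0.0, 0
    return counts.identities / ncols, ncols


def find_tirs(seq: str, min_len: int = 10, max_len: int = 300,
              min_identity: float = 0.80, terminal_anchor: int = 5,
              grow_window: bool = True) -> list[TIRPair]:
    """Locate terminal inverted repeat arms of ``seq``.

    The 5' window of ``seq`` is locally aligned against the reverse
    complement of the 3' window (window = ``max_len + terminal_anchor``);
    an accepted pair must have both arms starting within ``terminal_anchor``
    bp of their respective termini, ``arm_length >= min_len`` and identity
    ``>= min_identity``.  If the best arm runs into the window edge the
    window is enlarged, and arms longer than ``max_len`` are reported whole
    with ``exceeds_max_len`` set (the published length ranges are
    descriptive, not algorithmic).
    """
    n = len(seq)
    if n <= 2 * min_len:
        raise ValueError(f"sequence length {n} too short for min_len {min_len}")
    window = min(max_len + terminal_anchor, n // 2)
    aligner = _arm_aligner()
    while True:
        left = seq[:window]
        right_rc = revcomp(seq[n - window:])
        if aligner.score(left, right_rc) <= 0:
            return []
        aln = aligner.align(left, right_rc)[0]
        (la0, la1) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
        (rb0, rb1) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
        touches_edge = la1 >= window or rb1 >= window
        if grow_window and touches_edge and window < n // 2:
            window = min(window * 2, n // 2)
            continue
        break
    # right_rc index i corresponds to seq position n - 1 - i, so the slice
    # [rb0, rb1) of right_rc maps to seq [n - rb1, n - rb0).
    right_start0, right_end0 = n - rb1, n - rb0
    identity, _ = _alignment_identity(aln)
    arm_length = la1 - la0
    if la0 > terminal_anchor or rb0 > terminal_anchor:
        return []
    if arm_length < min_len or identity < min_identity:
        return []
    if la1 > right_start0:  # arms overlap: degenerate (e.g. palindrome)
        return []
    pair = TIRPair(int(la0), int(la1), int(right_start0), int(right_end0),
                   arm_identity=float(identity), arm_length=int(arm_length),
                   score=float(aln.score),
                   exceeds_max_len=bool(arm_length > max_len))
    return [pair]


def extract_tsd(genome: GenomeRecord, start0: int, end0: int,
                k_min: int = 3, k_max: int = 6) -> Optional[TSDRecord]:
    """Longest exact k-mer (k in [k_min, k_max]) duplicated on both flanks.

    Returns ``None`` when no k matches; the longest k wins, so a 5-bp
    duplication is never misreported as its 4-bp suffix.
    """
    if start0 < k_max or end0 + k_max > len(genome.seq):
        raise ValueError(
            f"element [{start0},{end0}) within {k_max} bp of the contig edge")
    seq = genome.seq
    for k in range(k_max, k_min - 1, -1):
        left = seq[start0 - k:start0]
        right = seq[end0:end0 + k]
        if left == right and "N" not in left:
            return TSDRecord(length=k, sequence=left,
                             left=(start0 - k, start0), right=(end0, end0 + k))
    return None


def check_terminal_motif(element_seq: str, motif: str = TERMINAL_MOTIF) -> tuple[bool, bool]:
    """Test the 5' terminus against ``motif`` and the 3' terminus against
    its reverse complement (TGTNR ... YNACA)."""
    if len(element_seq) < len(motif):
        raise ValueError("element shorter than the terminal motif")
    m = len(motif)
    five = iupac_match(element_seq[:m], motif)
    three = iupac_match(element_seq[-m:], revcomp(motif))
    return five, three


def _candidate_score(genome: GenomeRecord, s: int, e: int,
                     min_len: int, max_len: int, min_identity: float,
                     terminal_anchor: int, k_min: int, k_max: int,
                     require_tsd: bool = True,
                     ) -> Optional[tuple[tuple, TIRPair, Optional[TSDRecord]]]:
    """Score one candidate (start, end) pair; None if no acceptable TIR.

    Ranking key: (TSD present, terminal motifs matched, arm score) — TSD
    presence is boolean on purpose; ranking by TSD length would let a
    chance-matched longer flank k-mer drag the boundary off the true
    terminus.
    """
    seq = genome.seq
    if s < k_max or e + k_max > len(seq) or e - s <= 2 * min_len:
        return None
    tsd = extract_tsd(genome, s, e, k_min=k_min, k_max=k_max)
    if tsd is None and require_tsd:
        return None
    elem = seq[s:e]
    try:
        five, three = check_terminal_motif(elem)
    except ValueError:
        return None
    pairs = find_tirs(elem, min_len=min_len, max_len=max_len,
                      min_identity=min_identity, terminal_anchor=terminal_anchor,
                      grow_window=False)
    if not pairs:
        return None
    tir = pairs[0]
    key = (int(tsd is not None), int(five) + int(three), tir.score)
    return key, tir, tsd


#: bonus added to the arm score per matched terminal motif when ranking
#: boundary candidates, and the arm-score band treated as a tie (resolved
#: toward the minimal span).  The band absorbs arm-score noise between a
#: true element and a same-template neighbor-spanning candidate.
MOTIF_BONUS = 25.0
SPAN_TIE_BAND = 20.0
#: the inverted-repeat proposal aligns at most this much sequence on each
#: side of the hit (the motif-anchored enumeration still spans the full
#: search radius)
ARM_PROPOSAL_SEG = 5000


def refine_boundaries(genome: GenomeRecord, hit, search_radius: int = 10000,
                      min_len: int = 25, max_len: int = 300,
                      min_identity: float = 0.80, terminal_anchor: int = 5,
                      k_min: int = 3, k_max: int = 6,
                      left_limit: int = 0,
                      right_limit: Optional[int] = None) -> Optional[ElementAnnotation]:
    """Delimit the element around a transposase protein hit.

    Candidate 5' termini are TGTNR matches upstream of the hit and
    candidate 3' termini are YNACA matches downstream (within
    ``search_radius``); pairs must carry an exact flanking duplication (the
    TSD rule) and an acceptable TIR arm alignment.  In parallel, a local
    inverted-repeat alignment of the segments flanking the hit proposes arm
    ends directly; its candidates rescue elements whose terminal motif
    mutated away (a chance TGTNR inside the arm would otherwise anchor a
    shrunk, weaker-armed candidate).

    Selection: candidates are ranked by TSD presence, then by arm score
    plus a small bonus per matched terminal motif; within a narrow
    arm-score band the minimal span bracketing the hit wins — essential
    when a second copy of the same family sits nearby, since a pair
    spanning both copies aligns its (identical-template) arms as well as
    the true pair does.  Returns ``None`` when no credible TIR pair exists
    (vestige loci).

    ``left_limit``/``right_limit`` confine the search to a sub-interval of
    the contig; the pipeline uses them to exclude the territory of an
    already-accepted neighboring element.
    """
    seq = genome.seq
    n = len(seq)
    if right_limit is None:
        right_limit = n
    ls = max(k_max, left_limit, hit.start0 - search_radius)
    re_ = min(n - k_max, right_limit, hit.end0 + search_radius)
    motif_rc = revcomp(TERMINAL_MOTIF)

    s_cands = [i for i in range(ls, hit.start0 + 1)
               if iupac_match(seq[i:i + 5], TERMINAL_MOTIF)]
    e_cands = [j for j in range(max(hit.end0, ls + 2 * min_len), re_ + 1)
               if iupac_match(seq[j - 5:j], motif_rc)]

    cands: dict[tuple[int, int], tuple] = {}

    def consider(s: int, e: int, require_tsd: bool = True) -> None:
        if (s, e) in cands or e - s <= 2 * min_len:
            return
        if s > hit.start0 or e < hit.end0 or s < ls or e > re_:
            return
        res = _candidate_score(genome, s, e, min_len, max_len, min_identity,
                               terminal_anchor, k_min, k_max,
                               require_tsd=require_tsd)
        if res is not None:
            cands[(s, e)] = res

    for s in s_cands:
        for e in e_cands:
            if e - s <= 2 * min_len:
                continue
            # cheap TSD screen before any arm alignment
            if s < k_max or e + k_max > n:
                continue
            if extract_tsd(genome, s, e, k_min=k_min, k_max=k_max) is None:
                continue
            consider(s, e)

    proposal = _arm_proposal(genome, hit, min_len, min_identity,
                             left_limit=ls, right_limit=re_)
    if proposal is not None:
        s0, e0, slop = proposal
        for s in range(max(k_max, s0 - slop), min(hit.start0, s0 + slop) + 1):
            for e in range(max(hit.end0, e0 - slop),
                           min(n - k_max, e0 + slop) + 1):
                consider(s, e)
        if not cands:  # TSD-less last resort around the proposed arms
            for s in range(max(k_max, s0 - slop),
                           min(hit.start0, s0 + slop) + 1):
                for e in range(max(hit.end0, e0 - slop),
                               min(n - k_max, e0 + slop) + 1):
                    consider(s, e, require_tsd=False)

    if not cands:
        return None

    def rank(item):
        (s, e), (key, tir, _tsd) = item
        tsd_present, n_motifs, arm_score = key
        return (tsd_present, arm_score + MOTIF_BONUS * n_motifs)

    top_tsd = max(v[0][0] for v in cands.values())
    pool = {k: v for k, v in cands.items() if v[0][0] == top_tsd}
    m = max(rank(it)[1] for it in pool.items())
    near = [(s, e, v) for (s, e), v in pool.items()
            if rank(((s, e), v))[1] >= m - SPAN_TIE_BAND]
    near.sort(key=lambda t: (t[1] - t[0], -t[0]))   # minimal span, then 3'-most start
    s, e, (_key, tir, tsd) = near[0]

    # lift TIR coordinates from element frame to genome frame
    tir = TIRPair(tir.left_start0 + s, tir.left_end0 + s,
                  tir.right_start0 + s, tir.right_end0 + s,
                  arm_identity=tir.arm_identity, arm_length=tir.arm_length,
                  score=tir.score, exceeds_max_len=tir.exceeds_max_len)
    return ElementAnnotation(
        element_id=f"{genome.id}:{s}-{e}", contig=genome.id,
        start0=s, end0=e,
        strand="+" if getattr(hit, "frame", 1) > 0 else "-",
        tir=tir, tsd=tsd)


def _arm_proposal(genome: GenomeRecord, hit, min_len: int,
                  min_identity: float, left_limit: int = 0,
                  right_limit: Optional[int] = None,
                  slop: int = 8) -> Optional[tuple[int, int, int]]:
    """Inverted-repeat alignment of the segments flanking the hit.

    Returns a proposed (element start, element end, slop) from the
    top-scoring arm alignment, or ``None`` when nothing reaches the score
    a perfect minimum-length arm would have (vestige loci)."""
    seq = genome.seq
    seg = ARM_PROPOSAL_SEG
    if right_limit is None:
        right_limit = len(seq)
    us = max(0, left_limit, hit.start0 - seg)
    de = min(len(seq), right_limit, hit.end0 + seg)
    up = seq[us:hit.start0]
    down = seq[hit.end0:de]
    if len(up) < min_len or len(down) < min_len:
        return None
    aligner = _arm_aligner()
    down_rc = revcomp(down)
    if aligner.score(up, down_rc) < float(min_len):
        return None
    aln = aligner.align(up, down_rc)[0]
    identity, _ = _alignment_identity(aln)
    if identity < min_identity:
        return None
    ua0 = aln.aligned[0][0][0]
    db0 = aln.aligned[1][0][0]
    # down_rc slice [db0, db1) maps to down [len-db1, len-db0), so the
    # right arm (and element) end sits at hit.end0 + len(down) - db0.
    return us + ua0, hit.end0 + (len(down) - db0), slop
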
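"""Transposase locus discovery: six-frame translation plus local protein
alignment of a query panel against the genome — the in-repo analogue of a
Tblastn/Blastp search.

The genome is scanned in overlapping windows (default 2 kb, 50% overlap);
to keep the scan linear at genome scale a window is only aligned when one
of its frame translations shares an exact protein 4-mer with the query
panel (a word seed, in the spirit of BLAST's word hits).  Alignment is
Smith-Waterman with BLOSUM62 and affine gaps via Biopython's
PairwiseAligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import GenomeRecord, revcomp

FRAMES = (1, 2, 3, -1, -2, -3)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

DEFAULT_GAP_OPEN = -11.0
DEFAULT_GAP_EXTEND = -1.0
DEFAULT_MIN_SCORE = 60.0
DEFAULT_WINDOW = 2000
SEED_WORD = 5


@dataclass
class ProteinHit:
    """A protein-level homology hit mapped back to genomic coordinates."""

    contig: str
    frame: int
    start0: int
    end0: int
    query_id: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


def six_frame_translate(seq: str) -> dict[int, str]:
    """Translate all six frames (standard code, stops as ``*``); frames
    -1..-3 translate the reverse complement; trailing 1-2 nt are dropped."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out: dict[int, str] = {}
    rc = revcomp(seq)
    for f in (1, 2, 3):
        for s, fr in ((seq, f), (rc, -f)):
            sub = s[f - 1:]
            sub = sub[:len(sub) - len(sub) % 3]
            out[fr] = str(Seq(sub).translate()) if sub else ""
    return out


def _aligner(matrix=None, gap_open: float = DEFAULT_GAP_OPEN,
             gap_extend: float = DEFAULT_GAP_EXTEND) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="local")
    al.substitution_matrix = matrix if matrix is not None else _BLOSUM62
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def smith_waterman(query: str, target: str, matrix=None,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   ) -> tuple[float, Optional[object]]:
    """Optimal local alignment score (affine gaps: a gap of length L costs
    ``gap_open + (L-1) * gap_extend``).  Returns ``(score, alignment)``;
    a floor of (0, None) applies when nothing aligns positively."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    mat = matrix if matrix is not None else _BLOSUM62
    alphabet = set(str(mat.alphabet))
    unknown = (set(query) | set(target)) - alphabet
    if unknown:
        raise ValueError(f"residue(s) {sorted(unknown)} not covered by the "
                         "substitution matrix")
    al = _aligner(mat, gap_open, gap_extend)
    score = al.score(query, target)
    if score <= 0:
        return 0.0, None
    return float(score), al.align(query, target)[0]


def _alignment_identity(aln) -> float:
    c = aln.counts()
    ncols = c.identities + c.mismatches + c.gaps
    return c.identities / ncols if ncols else 0.0


def _seed_words(panel: Sequence[tuple[str, str]], k: int = SEED_WORD) -> set[str]:
    words: set[str] = set()
    for _qid, pep in panel:
        for i in range(len(pep) - k + 1):
            words.add(pep[i:i + k])
    return words


def _frame_positions(translations: dict[int, str], words: set[str],
                     k: int = SEED_WORD) -> dict[int, list[int]]:
    """Protein positions (per frame) whose k-mer occurs in the panel."""
    hits: dict[int, list[int]] = {}
    for frame, prot in translations.items():
        pos = [i for i in range(len(prot) - k + 1) if prot[i:i + k] in words]
        if pos:
            hits[frame] = pos
    return hits


def _prot_to_genomic(frame: int, p0: int, p1: int, n: int) -> tuple[int, int]:
    """Map a protein interval [p0, p1) of a full-contig frame translation
    to forward-strand genomic coordinates."""
    f = abs(frame)
    a = (f - 1) + 3 * p0
    b = (f - 1) + 3 * p1
    if frame > 0:
        return a, b
    return n - b, n - a


def scan_for_tpase(genome: GenomeRecord,
                   query_panel: Sequence[tuple[str, str]],
                   min_score: float = DEFAULT_MIN_SCORE,
                   window: int = DEFAULT_WINDOW,
                   overlap: float = 0.5,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   ) -> list[ProteinHit]:
    """Scan a genome for loci encoding panel-like proteins.

    Windows of each frame translation containing a panel word seed are
    aligned against every query (5-residue words keep chance window
    triggers rare at genome scale); hits at or above ``min_score`` are mapped
    back to genomic coordinates (frame-aware) and overlapping hits are
    merged keeping the best score.
    """
    if not query_panel:
        raise ValueError("query panel must be non-empty")
    n = len(genome.seq)
    if n < 3:
        return []
    translations = six_frame_translate(genome.seq)
    words = _seed_words(query_panel)
    seed_pos = _frame_positions(translations, words)
    if not seed_pos:
        return []

    al = _aligner(gap_open=gap_open, gap_extend=gap_extend)
    step = max(1, int(window * (1.0 - overlap)))
    win_aa = max(1, window // 3)
    step_aa = max(1, step // 3)
    raw: list[ProteinHit] = []
    for frame, positions in seed_pos.items():
        prot = translations[frame]
        seen_windows: set[int] = set()
        for p in positions:
            w = (p // step_aa) * step_aa
            for wstart in (w - step_aa, w):
                if wstart < 0 or wstart in seen_windows or wstart >= len(prot):
                    continue
                seen_windows.add(wstart)
                target = prot[wstart:wstart + win_aa]
                if len(target) < SEED_WORD:
                    continue
                for qid, pep in query_panel:
                    score = al.score(pep, target)
                    if score < min_score:
                        continue
                    aln = al.align(pep, target)[0]
                    t0 = wstart + aln.aligned[1][0][0]
                    t1 = wstart + aln.aligned[1][-1][1]
                    g0, g1 = _prot_to_genomic(frame, t0, t1, n)
                    raw.append(ProteinHit(
                        contig=genome.id, frame=frame, start0=g0, end0=g1,
                        query_id=qid, score=float(score),
                        identity=_alignment_identity(aln)))
    return merge_hits(raw)


def merge_hits(hits: Iterable[ProteinHit], merge_gap: int = 300) -> list[ProteinHit]:
    """Merge genomically overlapping or near-adjacent hits (within
    ``merge_gap`` bp, so exon hits split by a short intron coalesce),
    keeping the best-scoring one; the merged hit spans the union.  The gap
    is kept small on purpose: merging across neighboring elements would
    hide one of them from boundary refinement."""
    hits = sorted(hits, key=lambda h: (h.contig, h.start0, -h.score))
    merged: list[ProteinHit] = []
    for h in hits:
        if (merged and merged[-1].contig == h.contig
                and h.start0 < merged[-1].end0 + merge_gap):
            prev = merged[-1]
            best = prev if prev.score >= h.score else h
            merged[-1] = ProteinHit(
                contig=best.contig, frame=best.frame,
                start0=min(prev.start0, h.start0),
                end0=max(prev.end0, h.end0),
                query_id=best.query_id, score=best.score,
                identity=best.identity)
        else:
            merged.append(h)
    return merged


def hits_to_table(hits: Iterable[ProteinHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"contig": h.contig, "start0": h.start0, "end0": h.end0,
          "frame": h.frame, "query": h.query_id, "score": h.score,
          "identity": round(h.identity, 4)} for h in hits],
        columns=["contig", "start0", "end0", "frame", "query", "score", "identity"])
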
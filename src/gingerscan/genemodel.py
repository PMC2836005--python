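"""Homology-guided gene models across introns, protein motif scanning,
and conserved-intron comparison.

``reconstruct_cds`` performs a spliced alignment: homolog residues are
aligned codon-by-codon to the genomic region by dynamic programming in
which an intron (beginning GT, ending AG; GC-AG and GT-TG admitted only on
request) may open between or inside codons, so intron phases 0/1/2 all
fall out of the optimisation.  This is deliberately not a general gene-
prediction HMM: homology to the supplied protein is assumed to be strong,
which holds for transposase copies of a family and their domesticated
descendants.

Motif calls (YPYY, H2C2 zinc finger, DDE triad, GPY/F, C-terminal
OTU/Ulp1/PHD) are pattern scans with user-overridable regexes; the
residue-spacing windows are stated approximations, not curated profiles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .seqio import GenomeRecord, revcomp

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}
_BL = np.zeros((len(_AA), len(_AA)))
for _i, _a in enumerate(_AA):
    for _j, _b in enumerate(_AA):
        _BL[_i, _j] = _BLOSUM62[_a, _b]

_CODON_AA: dict[str, str] = {}
_t = CodonTable.unambiguous_dna_by_id[1]
for _c, _a in _t.forward_table.items():
    _CODON_AA[_c] = _a
for _c in _t.stop_codons:
    _CODON_AA[_c] = "*"

_STOP_SCORE = -1e6
_NEG = -1e12


# ---------------------------------------------------------------------------
# Motif patterns
# ---------------------------------------------------------------------------

#: Default integrase-region motif patterns.  Spacing windows are tunable
#: approximations of the conserved regions, not database profiles.
DEFAULT_MOTIF_PATTERNS: dict[str, str] = {
    "YPYY": r"[YF]P[YF][YF]",
    "H2C2_ZF": r"H.{2,6}H.{15,40}C.{2,6}C",
    "DDE": r"D.{50,130}D.{25,50}E",
    "GPYF": r"GP[YF]",
}

#: Default C-terminal domain patterns: synthetic Cys-His-Asp protease-style
#: signatures (OTU/Ulp1) and a C4HC3-style zinc finger (PHD).  These are
#: stand-ins meant to be replaced with alignment-derived patterns when
#: scanning real proteins.
DEFAULT_CTERM_PATTERNS: dict[str, str] = {
    "OTU": r"C[ASTV].[DN]G.{10,40}H.{2,8}D",
    "Ulp1": r"C.{2,6}GG.{8,30}H.{2,8}E.{0,4}N",
    "PHD": r"C..C.{8,20}C..C.{2,10}H..C.{8,20}C..C",
}


@dataclass
class MotifHit:
    motif_name: str
    start: int
    end: int
    matched: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("invalid motif hit coordinates")


def scan_motifs(protein: str,
                patterns: Optional[dict[str, str]] = None,
                integrase_end: Optional[int] = None) -> list[MotifHit]:
    """Scan a protein for the integrase-region motifs.

    GPY/F is only accepted within the C-terminal third of the integrase
    region (``protein[:integrase_end]``, defaulting to the whole protein);
    all other patterns scan the full sequence.  Hits are ordered by
    position.
    """
    if not protein:
        raise ValueError("empty protein")
    pats = dict(DEFAULT_MOTIF_PATTERNS)
    if patterns:
        pats.update(patterns)
    region_end = integrase_end if integrase_end is not None else len(protein)
    gpyf_floor = region_end - max(1, region_end // 3)
    hits: list[MotifHit] = []
    for name, pat in pats.items():
        for m in re.finditer(pat, protein):
            if name == "GPYF" and not (gpyf_floor <= m.start() < region_end):
                continue
            hits.append(MotifHit(name, m.start(), m.end(), m.group()))
    return sorted(hits, key=lambda h: (h.start, h.motif_name))


def classify_cterm_domain(protein: str, integrase_end: int,
                          patterns: Optional[dict[str, str]] = None) -> str:
    """Label the region C-terminal to the integrase: OTU, Ulp1, PHD+Ulp1 or
    none.  The OTU and Ulp1 protease domains are mutually exclusive in
    these transposases, so the label never contains both: if both patterns
    somehow match, the earlier match wins."""
    if not 0 <= integrase_end < len(protein):
        raise ValueError("integrase_end must lie inside the protein")
    pats = dict(DEFAULT_CTERM_PATTERNS)
    if patterns:
        pats.update(patterns)
    tail = protein[integrase_end:]
    found = {name: re.search(pat, tail) for name, pat in pats.items()}
    otu, ulp = found.get("OTU"), found.get("Ulp1")
    if otu and ulp:
        winner = "OTU" if otu.start() <= ulp.start() else "Ulp1"
    elif otu:
        winner = "OTU"
    elif ulp:
        winner = "Ulp1"
    else:
        winner = ""
    if winner == "Ulp1" and found.get("PHD"):
        return "PHD+Ulp1"
    return winner or "none"


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int, str, str, int]]  # (s, e, donor, acceptor, phase)
    protein: str
    score: float = 0.0

    def __post_init__(self) -> None:
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError("exons must be ordered and non-overlapping")
        for _s, _e, _d, _a, phase in self.introns:
            if phase not in (0, 1, 2):
                raise ValueError("intron phase must be 0, 1 or 2")

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def recompute_phases(self) -> list[int]:
        """Phases implied by exon lengths (bases of the split codon on the
        5' exon); should equal the stored phases."""
        phases = []
        cum = 0
        for (s, e), intr in zip(self.exons, self.introns):
            cum += e - s
            phases.append(cum % 3)
        return phases


def _codon_scores(homolog: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-codon score vectors against the homolog residue sequence."""
    hom_idx = np.array([_AA_INDEX[a] for a in homolog], dtype=np.intp)
    cache: dict[str, np.ndarray] = {}
    for codon, aa in _CODON_AA.items():
        if aa == "*":
            cache[codon] = np.full(len(homolog), _STOP_SCORE)
        else:
            cache[codon] = _BL[_AA_INDEX[aa]][hom_idx]
    return hom_idx, cache


def self_score(protein: str) -> float:
    """BLOSUM62 score of a protein against itself."""
    return float(sum(_BL[_AA_INDEX[a], _AA_INDEX[a]] for a in protein))


def reconstruct_cds(genome: GenomeRecord, region: tuple[int, int],
                    homolog: str, allow_noncanonical: bool = False,
                    strand: str = "+", min_score_fraction: float = 0.5,
                    min_intron: int = 30, intron_penalty: float = -5.0,
                    ) -> Optional[GeneModel]:
    """Spliced alignment of ``homolog`` against ``genome[region]``.

    Exons are chosen to maximise the BLOSUM62 protein score subject to
    introns beginning with GT and ending with AG (plus GC-AG / GT-TG when
    ``allow_noncanonical``); the full homolog must be accounted for.
    Returns ``None`` when no splicing reaches
    ``min_score_fraction * self_score(homolog)``.
    """
    r0, r1 = region
    seq = genome.seq[r0:r1]
    if strand == "-":
        seq = revcomp(seq)
    if any(a not in _AA_INDEX for a in homolog):
        raise ValueError("homolog contains residues outside the 20-letter alphabet")
    n, m = len(seq), len(homolog)
    if n < 3 * m:
        return None

    pairs = [("GT", "AG")]
    if allow_noncanonical:
        pairs += [("GC", "AG"), ("GT", "TG")]
    donors = sorted({d for d, _ in pairs})
    acceptors_for = {a: sorted({d for d, aa in pairs if aa == a})
                     for a in {a for _, a in pairs}}

    _hom_idx, csc = _codon_scores(homolog)

    # D[i, j]: best score, j residues done, next coding base at i.
    D = np.full((n + 1, m + 1), _NEG)
    D[:, 0] = 0.0
    ptype = np.zeros((n + 1, m + 1), dtype=np.int8)   # 1 codon, 2 ph0, 3 ph1, 4 ph2
    ppos = np.full((n + 1, m + 1), -1, dtype=np.int32)

    # Running donor-state maxima (value and source position), per donor
    # dinucleotide: phase 0 keyed by nothing, phase 1 by the 5' base,
    # phase 2 by the two 5' bases.
    p0v = {d: np.full(m + 1, _NEG) for d in donors}
    p0p = {d: np.full(m + 1, -1, dtype=np.int32) for d in donors}
    p1v = {d: {b: np.full(m + 1, _NEG) for b in "ACGT"} for d in donors}
    p1p = {d: {b: np.full(m + 1, -1, dtype=np.int32) for b in "ACGT"} for d in donors}
    p2v = {d: {} for d in donors}
    p2p = {d: {} for d in donors}

    def _update(vdict, pdict, key, pos, values):
        if key not in vdict:
            vdict[key] = np.full(m + 1, _NEG)
            pdict[key] = np.full(m + 1, -1, dtype=np.int32)
        better = values > vdict[key]
        if better.any():
            vdict[key][better] = values[better]
            pdict[key][better] = pos

    for i in range(1, n + 1):
        # admit donor states whose intron could end around here
        d0 = i - min_intron
        if d0 >= 0 and seq[d0:d0 + 2] in donors:
            _update(p0v, p0p, seq[d0:d0 + 2], d0, D[d0])
        d1 = i - 3 - min_intron
        if d1 >= 0:
            if seq[d1 + 1:d1 + 3] in donors:
                _update(p1v[seq[d1 + 1:d1 + 3]], p1p[seq[d1 + 1:d1 + 3]],
                        seq[d1], d1, D[d1])
            if seq[d1 + 2:d1 + 4] in donors:
                _update(p2v[seq[d1 + 2:d1 + 4]], p2p[seq[d1 + 2:d1 + 4]],
                        seq[d1:d1 + 2], d1, D[d1])

        row = D[i]
        # contiguous codon
        if i >= 3:
            codon = seq[i - 3:i]
            if codon in csc:
                cand = D[i - 3, :-1] + csc[codon]
                better = cand > row[1:]
                if better.any():
                    row[1:][better] = cand[better]
                    ptype[i, 1:][better] = 1
                    ppos[i, 1:][better] = i - 3

        acc2 = seq[i - 2:i] if i >= 2 else ""
        if acc2 in acceptors_for:
            # phase 0: intron [d, i)
            for d in acceptors_for[acc2]:
                cand = p0v[d] + intron_penalty
                better = cand > row
                if better.any():
                    row[better] = cand[better]
                    ptype[i][better] = 2
                    ppos[i][better] = p0p[d][better]
        acc1 = seq[i - 4:i - 2] if i >= 4 else ""
        if acc1 in acceptors_for and i >= 2:
            # phase 1 landing: codon = b0 + seq[i-2:i], intron [i'+1, i-2)
            tail2 = seq[i - 2:i]
            for d in acceptors_for[acc1]:
                for b0 in "ACGT":
                    codon = b0 + tail2
                    if codon not in csc:
                        continue
                    src_v = p1v[d][b0]
                    cand = src_v[:-1] + csc[codon] + intron_penalty
                    better = cand > row[1:]
                    if better.any():
                        row[1:][better] = cand[better]
                        ptype[i, 1:][better] = 3
                        ppos[i, 1:][better] = p1p[d][b0][:-1][better]
        acc0 = seq[i - 3:i - 1] if i >= 3 else ""
        if acc0 in acceptors_for and i >= 1:
            # phase 2 landing: codon = b1 b2 + seq[i-1], intron [i'+2, i-1)
            last = seq[i - 1]
            for d in acceptors_for[acc0]:
                for b12, src_v in p2v[d].items():
                    codon = b12 + last
                    if codon not in csc:
                        continue
                    cand = src_v[:-1] + csc[codon] + intron_penalty
                    better = cand > row[1:]
                    if better.any():
                        row[1:][better] = cand[better]
                        ptype[i, 1:][better] = 4
                        ppos[i, 1:][better] = p2p[d][b12][:-1][better]

    best_i = int(np.argmax(D[:, m]))
    best = D[best_i, m]
    threshold = min_score_fraction * self_score(homolog)
    if best < threshold:
        return None

    # traceback
    coding: list[tuple[int, int]] = []   # coding base intervals, reversed
    introns_rev: list[tuple[int, int]] = []
    i, j = best_i, m
    while j > 0 or ptype[i, j] == 2:
        t = ptype[i, j]
        if t == 1:
            coding.append((i - 3, i))
            i, j = ppos[i, j], j - 1
        elif t == 2:
            introns_rev.append((int(ppos[i, j]), i))
            i = int(ppos[i, j])
        elif t == 3:
            src = int(ppos[i, j])
            coding.append((i - 2, i))
            introns_rev.append((src + 1, i - 2))
            coding.append((src, src + 1))
            i, j = src, j - 1
        elif t == 4:
            src = int(ppos[i, j])
            coding.append((i - 1, i))
            introns_rev.append((src + 2, i - 1))
            coding.append((src, src + 2))
            i, j = src, j - 1
        else:
            break

    coding.reverse()
    introns_rev.reverse()
    # merge contiguous coding intervals into exons
    exons: list[tuple[int, int]] = []
    for s, e in coding:
        if exons and exons[-1][1] == s:
            exons[-1] = (exons[-1][0], e)
        else:
            exons.append((s, e))
    cds = "".join(seq[s:e] for s, e in exons)
    protein = "".join(_CODON_AA.get(cds[k:k + 3], "X")
                      for k in range(0, len(cds) - len(cds) % 3, 3))

    introns: list[tuple[int, int, str, str, int]] = []
    cum_at = {}
    cumlen = 0
    for s, e in exons:
        cum_at[e] = cumlen + (e - s)
        cumlen += e - s
    for s, e in introns_rev:
        phase = cum_at.get(s, 0) % 3
        introns.append((s, e, seq[s:s + 2], seq[e - 2:e], phase))

    if strand == "+":
        g_exons = [(r0 + s, r0 + e) for s, e in exons]
        g_introns = [(r0 + s, r0 + e, d, a, p) for s, e, d, a, p in introns]
    else:
        L = len(seq)
        g_exons = [(r0 + L - e, r0 + L - s) for s, e in reversed(exons)]
        g_introns = [(r0 + L - e, r0 + L - s, d, a, p)
                     for s, e, d, a, p in reversed(introns)]
    return GeneModel(contig=genome.id, strand=strand, exons=g_exons,
                     introns=g_introns, protein=protein, score=float(best))


# ---------------------------------------------------------------------------
# Conserved introns
# ---------------------------------------------------------------------------

def shared_introns(models: Sequence[GeneModel],
                   protein_msa: Sequence[tuple[str, str]],
                   ) -> list[tuple[int, int]]:
    """Introns conserved across all models: same alignment column, same
    phase.

    An intron's "position" is the MSA column of the last full codon before
    the splice; its phase is the number of bases of the split codon on the
    5' exon.  Each model's (ungapped) protein must appear as a row of the
    MSA.
    """
    if not models:
        return []
    row_of = {s.replace("-", ""): s for _t, s in protein_msa}
    descriptor_sets = []
    for gm in models:
        row = row_of.get(gm.protein)
        if row is None:
            raise ValueError(
                f"protein of model on {gm.contig} not found in the MSA")
        # residue index -> alignment column
        col_of: list[int] = []
        for col, c in enumerate(row):
            if c != "-":
                col_of.append(col)
        descs = set()
        cum = 0
        exlens = [e - s for s, e in gm.exons]
        for exlen, intron in zip(exlens, gm.introns):
            cum += exlen
            phase = intron[4]
            k = cum // 3              # full codons before the splice
            res = k - 1
            col = col_of[res] if 0 <= res < len(col_of) else -1
            descs.add((col, phase))
        descriptor_sets.append(descs)
    common = set.intersection(*descriptor_sets)
    return sorted(common)
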
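"""Decision rules labelling each transposase locus.

Labels: Ginger1 (TIRs, 4-bp TSD, GPY/F or YPYY motif in the transposase),
Ginger2 (TIRs, 4-bp TSD, both motifs absent), Ginger2_Tdd5like (TIRs with
a 5-bp TSD, the Tdd-4/5 signature), LTR_retro_like (a 5-kb flank encodes
reverse transcriptase or RNase H — the locus is better read as part of an
LTR retroelement, so this veto is applied first), vestige (a transposase
hit with neither TIRs nor retroelement context), and unclassified.

Target-sequence composition (GC-rich CCGG/CCGT-type versus AT-rich RTATAY
context) is recorded as advisory evidence, never as a hard rule: motif
content is the discriminator, composition is a tendency with exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import discovery
from .seqio import GenomeRecord
from .structure import iupac_match

LABELS = ("Ginger1", "Ginger2", "Ginger2_Tdd5like", "LTR_retro_like",
          "vestige", "unclassified")


@dataclass
class ElementFeatures:
    """Feature vector assembled from the upstream stages."""

    tpase_hit: bool
    tir_present: bool
    tsd_length: int            # 0 = no TSD found
    tsd_sequence: str = ""
    terminal_motif: tuple[bool, bool] = (False, False)
    motif_names: frozenset = frozenset()
    rt_rnh_flank: bool = False


@dataclass
class ElementClassification:
    label: str
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "unclassified" and not self.evidence:
            raise ValueError("non-unclassified labels require evidence")


def flank_encodes_rt_rnh(genome: GenomeRecord, region: tuple[int, int],
                         query_panel: Sequence[tuple[str, str]],
                         window: int = 5000,
                         min_score: float = discovery.DEFAULT_MIN_SCORE) -> bool:
    """True iff either 5-kb region flanking ``region`` encodes a protein of
    the reverse-transcriptase / RNase-H panel (scored by the same homology
    scan as transposase discovery).  Flanks truncated by the contig edge
    are scanned as far as they exist."""
    start, end = region
    n = len(genome.seq)
    flanks = []
    if start > 0:
        flanks.append(genome.seq[max(0, start - window):start])
    if end < n:
        flanks.append(genome.seq[end:min(n, end + window)])
    for fseq in flanks:
        if len(fseq) < 3:
            continue
        sub = GenomeRecord(id=genome.id + ":flank", seq=fseq)
        if discovery.scan_for_tpase(sub, query_panel, min_score=min_score):
            return True
    return False


def classify_element(features: ElementFeatures) -> ElementClassification:
    """Apply the ordered decision rules; exactly one label always results.

    Order: (1) the RT/RNase-H flank veto; (2) TIR + 4-bp TSD + GPY/F or
    YPYY -> Ginger1; (3) TIR + 4-bp TSD, both absent -> Ginger2; (4) TIR +
    5-bp TSD -> Ginger2_Tdd5like; (5) transposase without TIRs or
    retroelement context -> vestige; otherwise unclassified.
    """
    f = features
    ev: list[tuple[str, str]] = [
        ("rt_rnh_flank", "present" if f.rt_rnh_flank else "absent"),
        ("tir", "present" if f.tir_present else "absent"),
        ("tsd_length", str(f.tsd_length)),
        ("gpyf_or_ypyy",
         "present" if ({"GPYF", "YPYY"} & set(f.motif_names)) else "absent"),
    ]
    if f.tsd_sequence:
        gc_type = f.tsd_sequence in ("CCGG", "CCGT", "ACGG")
        at_type = iupac_match(f.tsd_sequence, "TATA") or _at_rich(f.tsd_sequence)
        ev.append(("tsd_composition",
                   "GC-rich/Ginger1-like" if gc_type
                   else ("AT-rich/Ginger2-like" if at_type else "other")))

    has_g1_motif = bool({"GPYF", "YPYY"} & set(f.motif_names))
    if f.rt_rnh_flank:
        return ElementClassification("LTR_retro_like", ev)
    if f.tir_present and f.tsd_length == 4 and has_g1_motif:
        return ElementClassification("Ginger1", ev)
    if f.tir_present and f.tsd_length == 4 and not has_g1_motif:
        return ElementClassification("Ginger2", ev)
    if f.tir_present and f.tsd_length == 5:
        return ElementClassification("Ginger2_Tdd5like", ev)
    if f.tpase_hit and not f.tir_present:
        return ElementClassification("vestige", ev)
    return ElementClassification("unclassified", ev)


def _at_rich(tsd: str) -> bool:
    at = sum(1 for b in tsd if b in "AT")
    return at >= len(tsd) - 1
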
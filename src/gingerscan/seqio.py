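"""Readers and writers for the formats the pipeline touches.

All in-memory coordinates are 0-based half-open.  The only place where the
1-based inclusive convention of GFF3 appears is inside :func:`write_gff3`
and :func:`read_gff3`; every other module works purely in internal
coordinates, so there is a single conversion point for off-by-one errors
to live (and be tested) in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .structure import TIRPair, TSDRecord

#: IUPAC nucleotide codes tolerated on read (sequences are uppercased).
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; the message names the line."""


@dataclass
class GenomeRecord:
    """A named nucleotide sequence.

    ``id`` is the first whitespace token of the FASTA header; any trailing
    text is kept in ``description``.  Coordinates into ``seq`` are 0-based
    half-open throughout the package.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be non-empty")
        if not self.seq:
            raise ValueError(f"GenomeRecord {self.id!r}: empty sequence")
        self.seq = self.seq.upper()

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ElementAnnotation:
    """One detected (or planted) transposable element."""

    element_id: str
    contig: str
    start0: int
    end0: int
    strand: str = "+"
    tir: Optional["TIRPair"] = None
    tsd: Optional["TSDRecord"] = None
    family: str = ""
    classification: str = "unclassified"

    def __post_init__(self) -> None:
        if not (0 <= self.start0 < self.end0):
            raise ValueError(
                f"{self.element_id}: invalid interval [{self.start0}, {self.end0})"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.element_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end0 - self.start0


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC aware, via Biopython)."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (possibly multi-record, wrapped or unwrapped) FASTA file.

    Sequences are uppercased.  Empty files, duplicate ids and non-IUPAC
    characters raise :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    records = [
        GenomeRecord(id=r.id, seq=str(r.seq), description=r.description[len(r.id):].strip())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found (line 1)")
    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dups = [rid for rid, n in seen.items() if n > 1]
    if dups:
        line = _find_header_line(path, dups[0], occurrence=2)
        raise FastaParseError(f"{path}: duplicate record id {dups[0]!r} (line {line})")
    for rec in records:
        bad = set(rec.seq) - IUPAC_NT
        if bad:
            line = _find_bad_char_line(path, bad)
            raise FastaParseError(
                f"{path}: non-IUPAC nucleotide character(s) {sorted(bad)} (line {line})"
            )
    return records


def _find_header_line(path: Path, rid: str, occurrence: int = 1) -> int:
    n = 0
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if raw.startswith(">") and raw[1:].split()[:1] == [rid]:
                n += 1
                if n == occurrence:
                    return i
    return 0


def _find_bad_char_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if raw.startswith(">"):
                continue
            if set(raw.strip().upper()) & bad:
                return i
    return 0


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_SOURCE = "gingerscan"


def write_gff3(annotations: Iterable[ElementAnnotation], path: str | Path) -> None:
    """Write element annotations as GFF3 (1-based inclusive on disk).

    Each element becomes a ``transposable_element`` feature; its TIR arms and
    TSD copies are emitted as child features.  Output order is deterministic:
    (contig, start, element id).
    """
    anns = sorted(annotations, key=lambda a: (a.contig, a.start0, a.element_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in anns:
            attrs = [f"ID={a.element_id}"]
            if a.family:
                attrs.append(f"family={a.family}")
            attrs.append(f"classification={a.classification}")
            if a.tsd is not None:
                attrs.append(f"tsd={a.tsd.sequence}")
            fh.write(_gff_line(a.contig, "transposable_element",
                               a.start0, a.end0, a.strand, ";".join(attrs)))
            if a.tir is not None:
                for tag, (s, e) in (
                    ("tir5", (a.tir.left_start0, a.tir.left_end0)),
                    ("tir3", (a.tir.right_start0, a.tir.right_end0)),
                ):
                    fh.write(_gff_line(
                        a.contig, "terminal_inverted_repeat", s, e, a.strand,
                        f"ID={a.element_id}:{tag};Parent={a.element_id}"))
            if a.tsd is not None:
                for tag, (s, e) in (
                    ("tsd_left", a.tsd.left), ("tsd_right", a.tsd.right),
                ):
                    fh.write(_gff_line(
                        a.contig, "target_site_duplication", s, e, a.strand,
                        f"ID={a.element_id}:{tag};Parent={a.element_id}"))


def _gff_line(contig: str, ftype: str, start0: int, end0: int,
              strand: str, attrs: str) -> str:
    return "\t".join([
        contig, _SOURCE, ftype, str(start0 + 1), str(end0),
        ".", strand, ".", attrs,
    ]) + "\n"


def read_gff3(path: str | Path) -> list[ElementAnnotation]:
    """Read back annotations written by :func:`write_gff3`.

    Only ``transposable_element`` parents (with their TIR/TSD children)
    are reconstructed; foreign feature types are ignored.
    """
    from .structure import TIRPair, TSDRecord

    parents: dict[str, ElementAnnotation] = {}
    children: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for raw in fh:
            if not raw.strip() or raw.startswith("#"):
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {raw!r}")
            contig, _src, ftype, s1, e1, _score, strand, _frame, attrs = cols
            start0, end0 = int(s1) - 1, int(e1)
            adict = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "transposable_element":
                ann = ElementAnnotation(
                    element_id=adict["ID"], contig=contig,
                    start0=start0, end0=end0, strand=strand,
                    family=adict.get("family", ""),
                    classification=adict.get("classification", "unclassified"),
                )
                parents[ann.element_id] = ann
            elif ftype in ("terminal_inverted_repeat", "target_site_duplication"):
                children.append((adict["Parent"], adict["ID"], start0, end0))
    tirs: dict[str, dict[str, tuple[int, int]]] = {}
    tsds: dict[str, dict[str, tuple[int, int]]] = {}
    for parent, cid, s, e in children:
        tag = cid.rsplit(":", 1)[-1]
        if tag.startswith("tir"):
            tirs.setdefault(parent, {})[tag] = (s, e)
        else:
            tsds.setdefault(parent, {})[tag] = (s, e)
    for pid, arms in tirs.items():
        if pid in parents and "tir5" in arms and "tir3" in arms:
            (ls, le), (rs, re_) = arms["tir5"], arms["tir3"]
            parents[pid].tir = TIRPair(ls, le, rs, re_,
                                       arm_identity=1.0, arm_length=le - ls)
    for pid, copies in tsds.items():
        if pid in parents and "tsd_left" in copies and "tsd_right" in copies:
            (ls, le) = copies["tsd_left"]
            parents[pid].tsd = TSDRecord(
                length=le - ls, sequence="",
                left=copies["tsd_left"], right=copies["tsd_right"])
    return sorted(parents.values(), key=lambda a: (a.contig, a.start0, a.element_id))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["element_id", "start0", "end0", "family", "tsd", "tir_len"]


def write_truth_tsv(rows: Iterable[dict], path: str | Path) -> None:
    df = pd.DataFrame(list(rows), columns=TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tsd": str})


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
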
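"""Family grouping, consensus rebuilding and copy-divergence measurement.

Element copies are grouped by single-linkage clustering on global pairwise
nucleotide identity; each family's consensus is the per-column majority
base over the aligned copies, and per-copy divergence is percent
mismatches over compared columns with columns gapped in either sequence
excluded (pairwise deletion, so indels are not counted as differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .seqio import ElementAnnotation, GenomeRecord

GAP = "-"

# IUPAC code for each set of tied majority bases
_AMBIG = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


@dataclass
class FamilyConsensus:
    family_id: str
    consensus: str
    n_copies: int
    divergences: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("a family needs at least one copy")
        if any(d < 0 for d in self.divergences):
            raise ValueError("divergences must be non-negative")


def _identity_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(mode="global")
    al.match_score = 1.0
    al.mismatch_score = -1.0
    al.open_gap_score = -2.0
    al.extend_gap_score = -0.5
    return al


def pairwise_identity(a: str, b: str) -> float:
    """Global alignment identity: matches / alignment columns."""
    if a == b:
        return 1.0
    al = _identity_aligner()
    aln = al.align(a, b)[0]
    c = aln.counts()
    ncols = c.identities + c.mismatches + c.gaps
    return c.identities / ncols if ncols else 0.0


def cluster_copies(sequences: Sequence[str],
                   identity_threshold: float = 0.80,
                   annotations: Optional[Sequence[ElementAnnotation]] = None,
                   ) -> list[list[int]]:
    """Single-linkage clustering on global pairwise identity.

    Returns groups of indices into ``sequences``; groups are numbered by
    their leftmost member (by annotation start when given, else by input
    order), so the numbering is deterministic.
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("no sequences to cluster")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if pairwise_identity(sequences[i], sequences[j]) >= identity_threshold:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    def left_key(members: list[int]):
        if annotations is not None:
            return min(annotations[m].start0 for m in members)
        return min(members)

    return sorted(groups.values(), key=left_key)


def align_copies(copies: Sequence[str]) -> list[str]:
    """Align family copies for consensus building.

    Length-identical copies (the substitution-only regime) are already
    columnwise comparable and are returned as-is; otherwise the built-in
    progressive aligner is used.  Copy sets larger than 20 are subsampled
    deterministically (every k-th copy) before progressive alignment.
    """
    if len({len(c) for c in copies}) == 1:
        return list(copies)
    from .phylo import progressive_align
    picked = list(copies)
    if len(picked) > 20:
        stride = len(picked) / 20.0
        picked = [picked[int(i * stride)] for i in range(20)]
    return progressive_align(picked, alphabet="dna")


def _consensus_columns(aligned: Sequence[str]) -> list[Optional[str]]:
    lengths = {len(a) for a in aligned}
    if len(lengths) != 1:
        raise ValueError(f"aligned copies have unequal lengths: {sorted(lengths)}")
    ncols = lengths.pop()
    out: list[Optional[str]] = []
    for j in range(ncols):
        column = [a[j].upper() for a in aligned]
        gaps = sum(1 for b in column if b == GAP)
        if gaps / len(column) >= 0.5:
            out.append(None)
            continue
        counts: dict[str, int] = {}
        for b in column:
            if b != GAP:
                counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        tied = frozenset(b for b, c in counts.items() if c == top)
        out.append(_AMBIG.get(tied, "N"))
    return out


def build_consensus(aligned_copies: Sequence[str]) -> str:
    """Majority-rule consensus: per column the most frequent non-gap base;
    columns with gap fraction >= 0.5 are dropped; ties become IUPAC
    ambiguity codes."""
    if not aligned_copies:
        raise ValueError("no copies given")
    return "".join(b for b in _consensus_columns(aligned_copies) if b is not None)


def copy_divergence(copy: str, consensus: str) -> float:
    """Percent mismatches between a gapped copy/consensus pair, over
    columns ungapped in both (pairwise deletion)."""
    if len(copy) != len(consensus):
        raise ValueError("copy and consensus must be aligned (equal length)")
    compared = 0
    mismatches = 0
    for a, b in zip(copy.upper(), consensus.upper()):
        if a == GAP or b == GAP:
            continue
        compared += 1
        if a != b:
            mismatches += 1
    if compared == 0:
        raise ValueError("no comparable (ungapped) columns")
    return 100.0 * mismatches / compared


def family_consensus(family_id: str, copies: Sequence[str]) -> FamilyConsensus:
    """Align copies, rebuild the consensus and measure each copy's
    divergence from it (pairwise deletion)."""
    aligned = align_copies(copies)
    cols = _consensus_columns(aligned)
    cons_gapped = "".join(b if b is not None else GAP for b in cols)
    divergences = [copy_divergence(a, cons_gapped) for a in aligned]
    consensus = "".join(b for b in cols if b is not None)
    return FamilyConsensus(family_id=family_id, consensus=consensus,
                           n_copies=len(copies), divergences=divergences)


def family_report(genome: GenomeRecord,
                  annotations: Sequence[ElementAnnotation],
                  identity_threshold: float = 0.80,
                  ) -> tuple[list[FamilyConsensus], pd.DataFrame]:
    """Cluster annotated elements into families and build per-family
    consensus + divergence statistics."""
    seqs = [genome.seq[a.start0:a.end0] for a in annotations]
    groups = cluster_copies(seqs, identity_threshold, annotations=annotations)
    results = []
    rows = []
    for gi, members in enumerate(groups):
        fam = family_consensus(f"family{gi:03d}", [seqs[m] for m in members])
        results.append(fam)
        rows.append({
            "family": fam.family_id,
            "n_copies": fam.n_copies,
            "min_divergence_pct": round(min(fam.divergences), 4),
            "mean_divergence_pct": round(sum(fam.divergences) / len(fam.divergences), 4),
            "members": ",".join(annotations[m].element_id for m in members),
        })
    return results, pd.DataFrame(
        rows, columns=["family", "n_copies", "min_divergence_pct",
                       "mean_divergence_pct", "members"])
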
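"""Synthetic genomes with planted Ginger1/Ginger2-style transposons.

The generator embodies the element architecture the annotation stages
assume: an element is TIR5 + interior + revcomp(TIR5), the 5' arm starts
with the TGTNR terminus (so the element ends with YNACA), the interior
carries a transposase ORF optionally split by GT-AG introns, and the
insertion duplicates a short target k-mer on both flanks.  Ginger1-type
insertions rewrite the target 4-mer to a draw from a categorical TSD
profile (default CCGG 0.75 / CCGT 0.12 / ACGG 0.12 / other 0.01, the
composition observed over 112 Hydra elements); Ginger2-type insertions
occur at 6-bp RTATAY sites and duplicate the central 4-mer.  Copy-to-copy
divergence is substitution-only.

Everything is deterministic given the config seed, and a machine-readable
truth set (exact bounds, TSD strings, gene models) is emitted so every
downstream stage can be tested by recovery.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .seqio import ElementAnnotation, GenomeRecord, revcomp
from .structure import IUPAC_CODES, TIRPair, TSDRecord, iupac_match

# ---------------------------------------------------------------------------
# Synthetic transposase peptides
# ---------------------------------------------------------------------------
# Motif blocks are explicit; the filler alphabet deliberately excludes the
# residues the motif patterns anchor on (C D E G H N P Q F Y) so planted
# peptides contain each pattern exactly where intended.
_FILLER_ALPHABET = "ARILKMSTVW"


def _filler(n: int, rng: _random.Random) -> str:
    return "".join(rng.choice(_FILLER_ALPHABET) for _ in range(n))


def _make_integrase(seed: int, with_ypyy_gpyf: bool) -> str:
    """Synthetic integrase-like region: optional YPYY, H2C2 zinc finger,
    DDE triad, optional C-terminal GPY/F."""
    rng = _random.Random(seed)
    parts = [_filler(25, rng)]
    if with_ypyy_gpyf:
        parts += ["YPYY", _filler(10, rng)]
    parts += ["H", _filler(3, rng), "H", _filler(20, rng),
              "C", _filler(3, rng), "C", _filler(30, rng),
              "D", _filler(60, rng), "D", _filler(30, rng), "E",
              _filler(25, rng)]
    if with_ypyy_gpyf:
        parts += ["GPY", _filler(10, rng)]
    else:
        parts += [_filler(13, rng)]
    return "".join(parts)


def _make_tail(seed: int, kind: str) -> str:
    """Synthetic C-terminal protease/chromatin-domain tails.  These are
    stand-in signatures built around a Cys-His-Asp protease-style dyad that
    match the package's default OTU/Ulp1/PHD patterns; they are not curated
    domain profiles (patterns are user-overridable)."""
    rng = _random.Random(seed)
    if kind == "none":
        return _filler(15, rng)
    otu = "CAIDG" + _filler(15, rng) + "HKLD"
    ulp1 = "CTLGG" + _filler(12, rng) + "HVKET" + "N"
    phd = ("CAAC" + _filler(10, rng) + "CAAC" + _filler(5, rng)
           + "HAAC" + _filler(10, rng) + "CAAC")
    if kind == "OTU":
        return _filler(8, rng) + otu + _filler(8, rng)
    if kind == "Ulp1":
        return _filler(8, rng) + ulp1 + _filler(8, rng)
    if kind == "Ulp1+PHD":
        return _filler(6, rng) + ulp1 + _filler(6, rng) + phd + _filler(4, rng)
    raise ValueError(f"unknown C-terminal domain kind {kind!r}")


GINGER1_INTEGRASE = _make_integrase(101, with_ypyy_gpyf=True)
GINGER2_INTEGRASE = _make_integrase(202, with_ypyy_gpyf=False)
GINGER1_TPASE = GINGER1_INTEGRASE + _make_tail(103, "OTU")
GINGER2_TPASE = GINGER2_INTEGRASE + _make_tail(204, "none")


def rt_rnh_panel() -> list[tuple[str, str]]:
    """Synthetic reverse-transcriptase / RNase-H exemplar peptides for the
    5-kb flank test (``(id, sequence)`` pairs).  Purely synthetic stand-ins:
    random peptides unrelated to the transposase panel."""
    rng = _random.Random(777)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return [
        ("RT_synthetic_exemplar", "".join(rng.choice(aa) for _ in range(150))),
        ("RNaseH_synthetic_exemplar", "".join(rng.choice(aa) for _ in range(130))),
    ]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

class CapacityError(ValueError):
    """The genome is too small for the requested insertions."""


class SiteOverlapError(ValueError):
    """Requested insertion site overlaps an existing element."""


@dataclass
class FamilySpec:
    """Architecture of one planted family."""

    group: str                      # "Ginger1" or "Ginger2"
    element_length: int
    tir_length: int
    terminal_motif: str = "TGTNR"
    tpase_peptide: str = ""
    intron_positions: list[tuple[int, int]] = field(default_factory=list)
    cterm_domain: str = "none"      # OTU | Ulp1 | Ulp1+PHD | none
    name: str = ""

    def __post_init__(self) -> None:
        if self.group not in ("Ginger1", "Ginger2"):
            raise ValueError(f"unknown group {self.group!r}")
        if not 2 * self.tir_length < self.element_length:
            raise ValueError("2 x tir_length must be < element_length")
        for off, phase in self.intron_positions:
            if phase not in (0, 1, 2):
                raise ValueError(f"intron phase {phase} not in {{0,1,2}}")
            if off % 3 != phase:
                raise ValueError(
                    f"intron CDS offset {off} inconsistent with phase {phase}")
        if not self.tpase_peptide:
            base = GINGER1_INTEGRASE if self.group == "Ginger1" else GINGER2_INTEGRASE
            tail_seed = 103 if self.group == "Ginger1" else 204
            self.tpase_peptide = base + _make_tail(tail_seed, self.cterm_domain)
        if not self.name:
            self.name = self.group


def default_ginger1_spec() -> FamilySpec:
    """Geometry of the most abundant published Hydra Ginger1 family:
    3,425 bp total, 270 bp TIR arms, one intron, OTU tail."""
    return FamilySpec(group="Ginger1", element_length=3425, tir_length=270,
                      intron_positions=[(300, 0)], cterm_domain="OTU",
                      name="Ginger1_sim")


def default_ginger2_spec() -> FamilySpec:
    """Geometry modelled on a compact published Ginger2 family:
    2,751 bp total, 52 bp TIR arms, intronless."""
    return FamilySpec(group="Ginger2", element_length=2751, tir_length=52,
                      intron_positions=[], cterm_domain="none",
                      name="Ginger2_sim")


DEFAULT_TSD_PROFILE = {"CCGG": 0.75, "CCGT": 0.12, "ACGG": 0.12, "other": 0.01}


@dataclass
class SimulationConfig:
    genome_length: int = 2_000_000
    gc_content: float = 0.5
    n_elements: int = 100
    family_specs: list[FamilySpec] = field(default_factory=lambda: [default_ginger1_spec()])
    tsd_profile: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TSD_PROFILE))
    ginger2_site_pattern: str = "RTATAY"
    copy_divergence: float = 0.0
    seed: int = 0
    randomize_strand: bool = False
    allow_noncanonical_introns: bool = False
    decoy_inverted_repeats: int = 0

    def __post_init__(self) -> None:
        total = sum(self.tsd_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tsd_profile sums to {total}, not 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0.0 <= self.copy_divergence <= 1.0:
            raise ValueError("copy_divergence must be in [0, 1]")
        if self.family_specs and self.n_elements:
            longest = max(s.element_length for s in self.family_specs)
            if not self.n_elements * longest < self.genome_length:
                raise CapacityError(
                    f"{self.n_elements} x {longest} bp elements do not fit in "
                    f"a {self.genome_length} bp genome")


@dataclass
class PlantedGene:
    """Truth record for one planted transposase (or host) gene."""

    element_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]                      # genome coords
    introns: list[tuple[int, int, str, str, int]]     # (s, e, donor, acceptor, phase)
    protein: str


@dataclass
class TruthSet:
    elements: list[ElementAnnotation] = field(default_factory=list)
    genes: list[PlantedGene] = field(default_factory=list)

    def validate(self, genome: GenomeRecord, divergence_free: bool) -> None:
        """Construction invariants: the flanking 4-mers (the duplicated
        target) agree for every element; with zero divergence the element
        begins with the terminal motif and ends with its reverse
        complement."""
        seq = genome.seq
        for a in self.elements:
            left = seq[a.start0 - 4:a.start0]
            right = seq[a.end0:a.end0 + 4]
            if left != right:
                raise AssertionError(
                    f"{a.element_id}: flank 4-mers differ ({left} vs {right})")
            if divergence_free and a.strand == "+":
                if not iupac_match(seq[a.start0:a.start0 + 5], "TGTNR"):
                    raise AssertionError(f"{a.element_id}: 5' terminus not TGTNR")
                if not iupac_match(seq[a.end0 - 5:a.end0], revcomp("TGTNR")):
                    raise AssertionError(f"{a.element_id}: 3' terminus not YNACA")

    def truth_rows(self) -> list[dict]:
        rows = []
        for a in self.elements:
            rows.append({
                "element_id": a.element_id, "start0": a.start0, "end0": a.end0,
                "family": a.family,
                "tsd": a.tsd.sequence if a.tsd else "",
                "tir_len": a.tir.arm_length if a.tir else 0,
            })
        return rows


# ---------------------------------------------------------------------------
# Sequence-level primitives
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# alternatives[base_byte] = 3 substitution choices
_ALT = np.zeros((256, 3), dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ALT[_b] = np.array([x for j, x in enumerate(b"ACGT") if j != _i], dtype=np.uint8)


def random_background(length: int, gc_content: float,
                      rng: np.random.Generator) -> str:
    """I.i.d. background with the requested GC fraction."""
    p_gc = gc_content / 2.0
    p_at = (1.0 - gc_content) / 2.0
    arr = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return arr.tobytes().decode("ascii")


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Independent per-site substitution at probability ``rate`` (uniform
    over the 3 alternative bases); length-preserving and deterministic.
    Non-ACGT characters are left untouched."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or not seq:
        return seq
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    is_acgt = np.isin(arr, _BASES)
    hit = (rng.random(arr.size) < rate) & is_acgt
    idx = np.nonzero(hit)[0]
    choices = rng.integers(0, 3, size=idx.size)
    arr[idx] = _ALT[arr[idx], choices]
    return arr.tobytes().decode("ascii")


def _iupac_realize(motif: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC_CODES[m][rng.integers(0, len(IUPAC_CODES[m]))] for m in motif)


_CODON_CHOICES: dict[str, list[str]] = {}
_table = CodonTable.unambiguous_dna_by_id[1]
for _codon, _aa in _table.forward_table.items():
    _CODON_CHOICES.setdefault(_aa, []).append(_codon)
for _aa in _CODON_CHOICES:
    _CODON_CHOICES[_aa].sort()
_STOP_CODON = "TAA"


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Encode a peptide as DNA, codons drawn uniformly among synonyms."""
    codons = []
    for aa in peptide:
        opts = _CODON_CHOICES.get(aa)
        if not opts:
            raise ValueError(f"cannot encode residue {aa!r}")
        codons.append(opts[rng.integers(0, len(opts))])
    return "".join(codons)


def build_gene_sequence(peptide: str, intron_positions: list[tuple[int, int]],
                        rng: np.random.Generator,
                        intron_length: tuple[int, int] = (80, 200),
                        donor: str = "GT", acceptor: str = "AG",
                        ) -> tuple[str, list[tuple[int, int]],
                                   list[tuple[int, int, str, str, int]], str]:
    """Build a coding gene: CDS for ``M + peptide + stop`` with introns
    inserted at the given CDS nucleotide offsets.

    Returns ``(sequence, exons, introns, protein)`` with coordinates
    relative to the gene start; introns are (start, end, donor, acceptor,
    phase) and splice dinucleotides default to the canonical GT-AG.
    """
    protein = "M" + peptide
    cds = reverse_translate(protein, rng) + _STOP_CODON
    cuts = sorted(intron_positions)
    if any(not 0 < off < len(cds) for off, _ in cuts):
        raise ValueError("intron CDS offset outside the CDS")
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int, str, str, int]] = []
    pos = 0          # position within the assembled gene
    prev = 0         # position within the CDS
    for off, phase in cuts:
        exon_seq = cds[prev:off]
        pieces.append(exon_seq)
        exons.append((pos, pos + len(exon_seq)))
        pos += len(exon_seq)
        ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
        middle = random_background(ilen - 4, 0.5, rng)
        intron_seq = donor + middle + acceptor
        introns.append((pos, pos + len(intron_seq), donor, acceptor, phase))
        pieces.append(intron_seq)
        pos += len(intron_seq)
        prev = off
    pieces.append(cds[prev:])
    exons.append((pos, pos + len(cds) - prev))
    return "".join(pieces), exons, introns, protein


def build_element(spec: FamilySpec, rng: np.random.Generator,
                  allow_noncanonical: bool = False,
                  ) -> tuple[str, list[tuple[int, int]],
                             list[tuple[int, int, str, str, int]], str]:
    """Assemble one undiverged element: TIR5 + interior + revcomp(TIR5).

    Returns ``(sequence, exons, introns, protein)``; gene coordinates are
    relative to the element start.
    """
    tir5 = _iupac_realize(spec.terminal_motif, rng)
    tir5 += random_background(spec.tir_length - len(tir5), 0.5, rng)
    gene, exons, introns, protein = build_gene_sequence(
        spec.tpase_peptide, spec.intron_positions, rng)
    interior_len = spec.element_length - 2 * spec.tir_length
    pad_total = interior_len - len(gene)
    if pad_total < 0:
        raise CapacityError(
            f"{spec.name}: gene ({len(gene)} bp) does not fit the "
            f"{interior_len} bp interior")
    pad5 = pad_total // 2
    interior = (random_background(pad5, 0.5, rng) + gene
                + random_background(pad_total - pad5, 0.5, rng))
    element = tir5 + interior + revcomp(tir5)
    shift = spec.tir_length + pad5
    exons = [(s + shift, e + shift) for s, e in exons]
    introns = [(s + shift, e + shift, d, a, p) for s, e, d, a, p in introns]
    return element, exons, introns, protein


def draw_tsd(profile: dict[str, float], rng: np.random.Generator) -> str:
    """Draw a 4-mer from the categorical TSD profile; the ``other`` mass is
    realised as a uniform random 4-mer outside the named categories."""
    keys = sorted(profile)
    probs = np.array([profile[k] for k in keys])
    pick = keys[rng.choice(len(keys), p=probs / probs.sum())]
    if pick != "other":
        return pick
    named = {k for k in keys if k != "other"}
    while True:
        cand = random_background(4, 0.5, rng)
        if cand not in named:
            return cand


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------

def plant_element(genome: GenomeRecord, spec: FamilySpec, site_index: int,
                  rng: Optional[np.random.Generator] = None, *,
                  tsd_profile: Optional[dict[str, float]] = None,
                  ginger2_site_pattern: str = "RTATAY",
                  copy_divergence: float = 0.0,
                  strand: str = "+",
                  occupied: Optional[list[tuple[int, int]]] = None,
                  ) -> tuple[GenomeRecord, ElementAnnotation]:
    """Insert one element at ``site_index`` of ``genome``.

    Ginger1: the target 4-mer at the site is rewritten to a draw from
    ``tsd_profile`` and duplicated on both flanks.  Ginger2: the 6-mer at
    the site must match ``ginger2_site_pattern`` and its central 4-mer is
    the duplication.  Raises :class:`SiteOverlapError` if the site overlaps
    an interval in ``occupied``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    span = 6 if spec.group == "Ginger2" else 4
    if occupied:
        for s, e in occupied:
            if site_index < e and site_index + span > s:
                raise SiteOverlapError(
                    f"site {site_index} overlaps existing element [{s},{e})")
    (new_genome, ann), _gene = _plant(genome, spec, site_index, rng,
                                      tsd_profile or dict(DEFAULT_TSD_PROFILE),
                                      ginger2_site_pattern, copy_divergence,
                                      strand)
    return new_genome, ann


def _plant(genome: GenomeRecord, spec: FamilySpec, site_index: int,
           rng: np.random.Generator, tsd_profile: dict[str, float],
           site_pattern: str, copy_divergence: float, strand: str,
           element_id: str = "elem", allow_noncanonical: bool = False,
           template=None):
    """Insert one element.  ``template`` is a prebuilt
    (element, exons, introns, protein) tuple; copies of a family are
    insertions of the same template plus per-copy substitutions."""
    seq = genome.seq
    if template is None:
        template = build_element(spec, rng, allow_noncanonical)
    element, exons, introns, protein = template
    if copy_divergence > 0:
        element = mutate_sequence(element, copy_divergence,
                                  int(rng.integers(0, 2**31 - 1)))
    if strand == "-":
        element = revcomp(element)

    if spec.group == "Ginger1":
        tsd = draw_tsd(tsd_profile, rng)
        new_seq = seq[:site_index] + tsd + element + tsd + seq[site_index + 4:]
        start0 = site_index + 4
    else:
        site = seq[site_index:site_index + 6]
        if not iupac_match(site, site_pattern):
            site = _iupac_realize(site_pattern, rng)
        tsd = site[1:5]
        new_seq = (seq[:site_index] + site[0] + tsd + element + tsd
                   + site[5] + seq[site_index + 6:])
        start0 = site_index + 5

    end0 = start0 + len(element)
    new_genome = GenomeRecord(id=genome.id, seq=new_seq,
                              description=genome.description)
    tir = TIRPair(start0, start0 + spec.tir_length,
                  end0 - spec.tir_length, end0,
                  arm_identity=1.0, arm_length=spec.tir_length)
    tsd_rec = TSDRecord(length=len(tsd), sequence=tsd,
                        left=(start0 - len(tsd), start0),
                        right=(end0, end0 + len(tsd)))
    ann = ElementAnnotation(element_id=element_id, contig=genome.id,
                            start0=start0, end0=end0, strand=strand,
                            tir=tir, tsd=tsd_rec, family=spec.name,
                            classification=spec.group)
    if strand == "+":
        g_exons = [(start0 + s, start0 + e) for s, e in exons]
        g_introns = [(start0 + s, start0 + e, d, a, p)
                     for s, e, d, a, p in introns]
    else:
        L = len(element)
        g_exons = [(start0 + L - e, start0 + L - s) for s, e in reversed(exons)]
        g_introns = [(start0 + L - e, start0 + L - s, d, a, p)
                     for s, e, d, a, p in reversed(introns)]
    gene = PlantedGene(element_id=element_id, contig=genome.id, strand=strand,
                       exons=g_exons, introns=g_introns, protein=protein)
    return (new_genome, ann), gene


# ---------------------------------------------------------------------------
# Whole-genome generation
# ---------------------------------------------------------------------------

def _choose_sites(length: int, n: int, span: int, gap: int, edge: int,
                  rng: np.random.Generator) -> list[int]:
    """n sorted sites, pairwise separated by >= gap, away from the edges."""
    avail = length - 2 * edge - n * (span + gap)
    if n > 0 and avail < n:
        raise CapacityError(
            f"cannot place {n} insertion sites in a {length} bp genome")
    if n == 0:
        return []
    picks = np.sort(rng.choice(avail, size=n, replace=False))
    return [int(edge + picks[i] + i * (span + gap)) for i in range(n)]


def generate_genome(config: SimulationConfig) -> tuple[GenomeRecord, TruthSet]:
    """Generate a background genome with ``config.n_elements`` planted
    elements (non-overlapping, family specs assigned round-robin) plus the
    matching truth set.  Byte-identical output for identical seeds."""
    rng = np.random.default_rng(config.seed)
    bg = random_background(config.genome_length, config.gc_content, rng)
    genome = GenomeRecord(id="synth_contig_1", seq=bg,
                          description="synthetic genome")
    truth = TruthSet()
    if config.n_elements == 0 and config.decoy_inverted_repeats == 0:
        return genome, truth

    n_decoy = config.decoy_inverted_repeats
    n_total = config.n_elements + n_decoy
    sites = _choose_sites(config.genome_length, n_total, span=6, gap=30,
                          edge=50, rng=rng)
    decoy_flags = [i >= config.n_elements for i in range(n_total)]
    if n_decoy:
        perm = rng.permutation(n_total)
        decoy_flags = [bool(decoy_flags[j]) for j in perm]

    # one template per family: copies are diverged instances of it
    templates = [build_element(spec, rng, config.allow_noncanonical_introns)
                 for spec in config.family_specs]

    offset = 0
    current = genome
    k = 0
    for i, site in enumerate(sites):
        pos = site + offset
        if decoy_flags[i]:
            arm = random_background(150, config.gc_content, rng)
            spacer = random_background(400, config.gc_content, rng)
            decoy = arm + spacer + revcomp(arm)
            current = GenomeRecord(
                id=current.id,
                seq=current.seq[:pos] + decoy + current.seq[pos:],
                description=current.description)
            offset += len(decoy)
            continue
        spec_idx = k % len(config.family_specs)
        spec = config.family_specs[spec_idx]
        strand = "+"
        if config.randomize_strand and rng.random() < 0.5:
            strand = "-"
        (current, ann), gene = _plant(
            current, spec, pos, rng, config.tsd_profile,
            config.ginger2_site_pattern, config.copy_divergence, strand,
            element_id=f"elem{k:04d}",
            allow_noncanonical=config.allow_noncanonical_introns,
            template=templates[spec_idx])
        truth.elements.append(ann)
        truth.genes.append(gene)
        offset += (ann.end0 - ann.start0) + 4
        k += 1
    truth.validate(current, divergence_free=(config.copy_divergence == 0))
    return current, truth


# ---------------------------------------------------------------------------
# Domesticated-gene fixtures (conserved-intron analysis)
# ---------------------------------------------------------------------------

def host_gene_fixture_set(seed: int = 0) -> list[dict]:
    """Three host-gene style fixtures sharing exactly three introns at
    identical CDS positions and phases (offsets 300/601/800, phases 0/1/2),
    each with its own model-specific extra introns — the structure expected
    of transposase-derived host genes sharing a common donor element.

    Returns dicts with keys ``name, sequence, exons, introns, protein``
    (coordinates relative to the sequence start).
    """
    shared = [(300, 0), (601, 1), (800, 2)]
    extras = {"hostA": [(150, 0)], "hostB": [(450, 0)], "hostC": []}
    peptide = GINGER1_TPASE
    out = []
    for i, (name, extra) in enumerate(sorted(extras.items())):
        rng = np.random.default_rng(seed + i)
        cuts = sorted(shared + extra)
        seq, exons, introns, protein = build_gene_sequence(peptide, cuts, rng)
        pad5 = random_background(120, 0.5, rng)
        pad3 = random_background(120, 0.5, rng)
        shift = len(pad5)
        out.append({
            "name": name,
            "sequence": pad5 + seq + pad3,
            "exons": [(s + shift, e + shift) for s, e in exons],
            "introns": [(s + shift, e + shift, d, a, p)
                        for s, e, d, a, p in introns],
            "protein": protein,
        })
    return out
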
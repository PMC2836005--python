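# gingerscan

Structural discovery, annotation and classification of *Ginger* DNA
transposons — cut-and-paste elements whose transposases are homologous to
the integrases of *Gypsy* LTR retrotransposons — together with a
synthetic-genome generator that makes every stage testable without any
external database.

## The problem

*Ginger1* and *Ginger2/Tdd* elements look, at the protein level, like
stray *Gypsy* integrases: an H2C2 zinc finger, the DDE catalytic triad,
and (in *Ginger1*) the YPYY and GPY/F motifs otherwise diagnostic of
*Gypsy*/retroviral integrases. What makes them *DNA transposons* rather
than retroelement fragments is their structure in the genome:

- **terminal inverted repeats (TIRs)**, roughly 40–270 bp per arm, whose
  5′ arm begins with the TGTNR terminus shared with *Gypsy* LTRs (so the
  element ends in YNACA);
- a short exact **target site duplication (TSD)** on both flanks — 4 bp
  for both groups (CCGG ~75% / CCGT–ACGG ~24% for *Ginger1*; the core of
  an AT-rich RTATAY site for *Ginger2*), 5 bp for the *TDD-4/5*-like
  elements;
- an interior transposase ORF, sometimes split by 1–4 GT-AG introns.

An integrase-coding locus with none of this — and no reverse
transcriptase or RNase H within 5 kb — is a transposon **vestige**, not an
LTR retrotransposon. The package implements exactly this chain of
reasoning as a pipeline, and adds the downstream analyses such elements
invite: family clustering and consensus rebuilding, copy-divergence
estimation, TSD sequence logos, homology-guided gene models with intron
phases (the signature used to recognise transposase-derived host genes:
introns conserved in both position and phase), and distance-based
phylogenetics (Poisson or gamma-corrected distances,
d = −ln(1−p) and d = a((1−p)^(−1/a) −1), neighbor-joining and
minimum-evolution trees with bootstrap supports).

Because the elements of interest live in genome assemblies rather than in
tidy machine-readable datasets, the package ships a generator
(`gingerscan.synthdata`) that plants elements with precisely the
architecture above into random backgrounds and emits an exact truth set,
so recovery is measurable.

## Worked example

```python
from collections import Counter
import numpy as np
from gingerscan import synthdata, pipeline, logo

cfg = synthdata.SimulationConfig(genome_length=300_000, n_elements=10, seed=1)
genome, truth = synthdata.generate_genome(cfg)
elements = pipeline.annotate_genome(genome)

df = pipeline.classification_table(elements)
print(df[["element_id", "label", "tsd", "tir_len"]].head(4).to_string(index=False))

tsds = [e.annotation.tsd.sequence for e in elements if e.annotation.tsd]
print("TSDs:", Counter(tsds))
print("bits:", np.round(logo.information_content(logo.tsd_matrix(tsds)), 3))
```

prints

```
                  element_id   label  tsd  tir_len
    synth_contig_1:2233-5658 Ginger1 CCGG      270
    synth_contig_1:6425-6563 vestige             0
  synth_contig_1:58818-62243 Ginger1 CCGG      270
synth_contig_1:142019-145444 Ginger1 CCGG      270
TSDs: Counter({'CCGG': 9, 'ACGG': 1})
bits: [1.531 2.    2.    2.   ]
```

All ten planted elements are recovered at their exact coordinates with
their 270-bp TIR arms and 4-bp TSDs, and labelled *Ginger1* because the
reconstructed transposase carries GPY/F and YPYY. The eleventh row is a
weak background protein hit with no TIRs and no retroelement context —
exactly the evidence pattern the pipeline labels a vestige. The logo
columns read ~1.5 bits at position 1 (C/A mixture from the CCGG/ACGG
draw) and 2 bits at the fully conserved positions.

The same stages are available as a CLI (`gingerscan simulate | discover |
annotate | families | genes | classify | logo | phylo | all`); `gingerscan
all --seed 1 --out run/` chains them and writes FASTA/GFF3/TSV/Newick
artifacts plus a manifest.

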
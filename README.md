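# csmotif

Conserved sequence motif (CSM) analysis of protein multiple sequence
alignments, built around a physicochemical view of conservation, with a
companion meta-analysis of mutant catalogues. The package was designed for
the cytochrome P450 (CYP) superfamily — where non-active-site motifs
between helices E and H modulate the flexible substrate access channel —
but every stage operates on generic protein alignments.

## What it computes

Each of the 20 amino acids is embedded as a 5-component vector **e**(a) of
factor scores derived by principal component analysis of a large matrix of
published physicochemical property indices (component 1 tracks
hydrophilicity, Pearson r ≈ 0.92 against the bundled scale). For every
alignment column *c* and component *k*, the profile records the mean
μ<sub>k</sub>(c) and standard deviation σ<sub>k</sub>(c) of the column's
residue vectors, and the relative entropy of the column against a
background model (μ<sup>bg</sup><sub>k</sub>, σ<sup>bg</sup><sub>k</sub>)
as the Gaussian Kullback–Leibler divergence in nats:

RE<sub>k</sub>(c) = ln(σ<sup>bg</sup><sub>k</sub>/σ<sub>k</sub>) +
(σ<sub>k</sub>² + (μ<sub>k</sub> − μ<sup>bg</sup><sub>k</sub>)²) /
(2 σ<sup>bg</sup><sub>k</sub>²) − ½,  RE(c) = mean<sub>k</sub> RE<sub>k</sub>(c)

Columns with RE above a scale-free threshold (mean + 2·SD of the column-RE
distribution by default) are clustered into contiguous motifs; each motif's
**rank** is its mean column RE, and each residue carries an identity-
conservation tier: high (> 90 % identical), intermediate (75–90 %), low
(< 75 %). Motifs are reported in master-sequence coordinates in the
`start-RESIDUES-end` rendering (e.g. `193-YKDKEFLS-200`). Cross-family
comparison counts identical and physicochemically *similar* residues
(Euclidean distance in the 5-space ≤ τ = 0.51, calibrated so D/E, I/L,
F/Y, K/R and S/T qualify), and presence/absence matrices assign motif
inventories across families by anchor-interval overlap. A mutant-catalogue
module computes exact regional enrichment fractions over distinct mutated
residues.

A synthetic-alignment generator (star phylogeny, planted conserved blocks
with exact target conservation, known ground truth) makes the whole
pipeline testable without any sequence downloads.

## Worked example

Simulate an alignment of 150 sequences and 80 columns with one planted
7-column block (`RFDYKDR`, 95 % conservation, columns 31–37 in 1-based
numbering), then detect motifs:

```
$ cat spec.yaml
n_seqs: 150
n_cols: 80
seed: 11
planted:
  - {start: 30, modal_residues: RFDYKDR, conservation: 0.95}

$ csmotif simulate --spec spec.yaml --out msa.fasta --truth truth.yaml
simulated 150 x 80 alignment -> msa.fasta
$ csmotif find --alignment msa.fasta --master seq0001 --background flat \
      --out motifs.tsv
motif_1	31-RFDYKDR-37	rank=1.2078
1 motif(s) written to motifs.tsv
```

The detector recovers exactly the planted block: master residues 31–37,
all seven residues in the high tier (`HHHHHHH` in `motifs.tsv`), with rank
1.21 nats — the mean per-component divergence of those columns from the
flat background. The same library calls are available in Python
(`generate_msa`, `profile_columns`, `find_motifs`, `render_motif`).

The bundled mutant catalogue gives the regional enrichment report:

```
$ csmotif mutants --report report.tsv
26 distinct residues; report -> report.tsv
$ head -3 report.tsv
scope	metric	numerator	denominator	fraction
pooled	E_to_I	21	26	0.808
pooled	E_to_H	16	26	0.615
```

i.e. 21 of the 26 distinct functionally important residues found by random
mutagenesis lie between helices E and I (80.8 %), 16 of 26 between E and H
(61.5 %) — exact fractions behind the approximate summary percentages
usually quoted for these regions.

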
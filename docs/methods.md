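# Methods

## The physicochemical embedding

The package represents each of the 20 standard amino acids by a
5-component vector of factor scores. The packaged table
(`data/pcp_vectors.tsv`) is a published amino-acid factor-score table
obtained from a high-dimensional matrix of physicochemical property
indices; its scores are rescaled to equal per-component variance, which is
why `load_default_table()` reports uniform explained-variance fractions
while keeping the component order of the underlying derivation.
`derive_table()` regenerates an equivalent embedding from any property
matrix with P ≥ 5 columns: each property is standardized to zero mean and
unit variance over the 20 residues, PCA retains the top five score
vectors, and the per-component explained-variance fractions are reported.
Packaged values are the default everywhere — reproducibility beats
recomputation, since PCA of a different property collection yields a
rotated but equally valid space.

Component signs are underdetermined by PCA. The convention here: component
1 is flipped to correlate *positively* with the bundled hydrophilicity
scale; every other component is flipped so its largest-magnitude score is
positive. The bundled scale is the octanol–water transfer free-energy
scale of Fauchère and Pliska, sign-inverted so hydrophilic residues score
high; it was chosen, among the standard candidates (Hopp–Woods,
Kyte–Doolittle, Eisenberg, Levitt), as the scale the packaged component 1
actually tracks (Pearson r = 0.92; the others fall below 0.85).

Physicochemical similarity of two residues is their Euclidean distance in
the 5-space. The default similarity threshold τ = 0.51 is the smallest
two-decimal value that admits all five canonical conservative pairs —
D/E, I/L, F/Y, K/R, S/T — with the binding pair F/Y at distance 0.5093.
Nonstandard codes (B, Z, X, U, O) have no vector: they are rejected by
distance queries, while alignments may still contain `X` (treated as
missing data, like a gap, in all statistics).

## Column profiling and relative entropy

For each column and component k the profile stores the mean μ_k and the
population SD σ_k of the column's residue vectors (gaps and X excluded),
and scores conservation as the relative entropy of the column from a
background model. Because the profile keeps exactly first and second
moments, relative entropy is realized as the closed-form KL divergence of
two univariate Gaussians, in nats:

    RE_k = ln(σ_bg/σ_k) + (σ_k² + (μ_k − μ_bg)²) / (2 σ_bg²) − 1/2

The per-column score RE is the arithmetic mean of RE_k over the five
components, keeping RE on a per-component scale (the sum is available via
`aggregate="sum"`). A discrete binned-KL alternative
(`method="binned"`, 20 equal-width bins per component, +0.5 pseudocounts)
is exposed for sensitivity checks; it is not the default because the
Gaussian form is exact for the moments the profile stores and has an
independent quadrature oracle in the tests.

Numerical choices:

- σ floor ε = 1e-6 on both column and background SDs — an invariant
  column otherwise has σ = 0 and infinite KL. With the floor, a fully
  conserved column against the flat background scores RE ≈ 12–13 nats,
  finite and far above any polymorphic column.
- Tiny negative RE from round-off is clamped to 0.
- Natural logarithms throughout (nats, not bits).

Two background models are provided: `pooled_alignment` (moments of every
non-gap/non-X residue in the alignment — the default, since it makes RE a
contrast *within* the dataset) and `flat_composition` (the 20 table
vectors equally weighted — appropriate for synthetic data generated from
a flat composition). A column whose residues match the background pool
has RE = 0 up to the σ floor.

Identity conservation is classified from the modal-residue fraction f
(denominator: non-gap, non-X entries) into three tiers: high when
f > 0.90, intermediate when 0.75 ≤ f ≤ 0.90, low when f < 0.75. Both
interval ends of the intermediate band are closed, matching the printed
interval punctuation "75–90%"; f = 0.90 is intermediate. The gap fraction
is reported separately, so a column present in half the sequences can
still be highly conserved among those present, and callers can filter
sparse columns explicitly.

## Motif detection

Seed columns are those with RE at or above a threshold and gap fraction
at most γ = 0.5. The default threshold is mean + α·SD of the column-RE
distribution over non-excluded columns, with α = 2.0. The two-sigma
default is a deliberate design choice: under a signal-free alignment the
column-RE distribution is right-skewed, a one-sigma cut seeds roughly
10–15 % of columns, and with the run-merging rule below chance runs then
produce spurious motifs in a large fraction of replicates, while planted
conserved blocks sit an order of magnitude above either cut. In 20-seed
simulation sweeps (200 sequences × 120 columns, one planted 8-column
block at 95 % conservation), α ∈ {1.5, 2.0, 2.5} all give perfect
recovery with zero false-positive replicates, α = 1.0 gives false
positives in ~40 % of null replicates, and α = 3.0 begins to lose
recovery; 2.0 is the conventional outlier rule and sits centrally between
both failure modes. A quantile threshold mode (default q = 0.8) is
available as an alternative.

Maximal runs of seeds separated by at most g = 2 sub-threshold columns
are merged (ties at the threshold count as seeds); runs with fewer than
Lmin = 4 *seed* columns are discarded — Lmin counts seeds, not the
bridged span, so two isolated noise columns can never anchor a motif.
Each surviving run becomes a motif spanning first to last seed column,
with rank = mean column RE over that span.

Motif coordinates are translated to the master sequence's 1-based residue
numbering (an `--offset` supports fragments numbered in their native
protein coordinates). Master-gap columns inside a motif are skipped in
the residue string and flag the motif as partial; motifs are still
reported in that case, because family-level motifs are conventionally
printed on a chosen representative. Rendering follows the
`start-RESIDUES-end` convention with the caret dialect
(`^start^RESIDUES^end^`) accepted on parse; parsing validates
end = start + length − 1. Motif inventory identifiers (such as CSM
numbers 7–11 for the CYP E–H region) are labels assigned against an
anchor inventory by ≥ 50 % interval overlap, not detector output.

## Cross-group comparison

Position-aligned motif pairs are compared residue by residue: identical,
else similar when the 5-space distance is ≤ τ, else different. Motifs of
unequal length are compared after a gap-free end-anchored trim to the
shorter length, choosing among the |Δlen| + 1 offsets the one maximizing
the identical count (leftmost on ties) — motif spans drift by a residue
or two across families, and the trim absorbs that without a full
alignment. Presence/absence of an inventory across groups uses the ≥ 50 %
anchor-overlap rule, tolerant to the ±1-column boundary drift the
detector allows.

## Mutant-catalogue meta-analysis

The bundled catalogue transcribes a published table of functionally
important substitutions found by random mutagenesis/directed evolution in
CYP1A2, CYP2A6, CYP2Bs and CYP3A4, each with its region label and
CSM-relative label ("8-9" = between CSM 8 and 9). Counting conventions:

- The unit is the distinct residue position, not the mutation event
  (S334P and P334S are one residue).
- Only CYP2A6 positions 209 and 305 are active-site residues; all others
  are non-active-site, exactly as the source states.
- Regional enrichment reports exact rationals: 21/26 distinct residues in
  the E-through-I region set (80.8 %), 16/26 in E-through-H (61.5 %).
  The approximate summary figures usually quoted for these regions
  ("~85 %" between E and I, "75 %" in E–H) are convention-dependent
  round-ups whose exact numerators cannot be reconstructed under any
  single counting convention; the package therefore exposes region sets
  and exclusions as options and asserts only its own exact fractions.

## Synthetic data

The generator draws every sequence column-independently (star phylogeny,
no tree correlation) — adequate because every downstream statistic is
column-wise. Planted columns emit the modal residue with probability f
and otherwise a background draw *excluding* the modal residue, making f
exactly the expected identity fraction. Gaps are inserted i.i.d. after
residue sampling. All randomness flows through a single
`numpy.random.default_rng(seed)`, so a spec regenerates its alignment
byte for byte.

What the generator does not emulate: phylogenetic correlation between
sequences, indel evolution (gaps are i.i.d., not evolutionary), realistic
amino-acid background compositions (flat by default), and column-to-column
dependence. Passing recovery tests therefore demonstrate detector
correctness under the stated independence model, not performance on real
family alignments, where redundant subtrees can concentrate conservation
that is phylogenetic rather than functional (the pipeline applies no
sequence weighting, consistent with its design).

Default simulation scales — 200 sequences × 120 columns for detection
experiments, 500 sequences for single-column calibration, 20 replicate
seeds per condition — were chosen to keep per-column binomial noise well
inside the effect sizes under study while the full suite runs in seconds.

## Known limitations

- Absolute rank magnitudes depend on the background model and the
  alignment; only rank *orderings* are meaningful across runs, and the
  package deliberately asserts nothing about printed rank values from any
  particular historical analysis.
- The mean + α·SD threshold degenerates when conserved columns are a
  large fraction (≳ 20 %) of the alignment, since they inflate the SD;
  the quantile mode is the escape hatch.
- Cross-family motif pairing through a joint reference numbering is only
  as good as the chosen representatives; no profile–profile alignment is
  attempted.
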
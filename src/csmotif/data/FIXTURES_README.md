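# Bundled fixtures

Both tables transcribe the text-readable cells of the published CYP
conserved-sequence-motif study these fixtures accompany.

## table1_mutants.tsv

The directed-evolution / random-mutagenesis mutant catalogue: one row per
reported substitution, with the enzyme, the mutated position, the region
label (secondary-structure element of the CYP fold), and the CSM label
("8-9" means the position lies between CSM 8 and CSM 9).  Positions 209
and 305 of CYP2A6 are the only active-site residues, exactly as stated in
the source; all other rows default to non-active-site.  The catalogue
lists both S334P and P334S at CYP2Bs position 334; counting utilities
de-duplicate by residue position.

## table3_motifs.tsv

The CYP2 subfamily motif inventory cells that are printed as text:
CYP2A and CYP2D motifs in `start-RESIDUES-end` rendering, plus the two
CYP2A-specific motifs, and the "Absent" calls.  Cells published only as
images (the CYP2B and CYP2C columns, and the whole family-level
counterpart table) are NOT machine-readable and are deliberately not
transcribed here.

Known source inconsistency: one table footnote says the "Absent" marks of
the family-level table denote lack of CSM 9 in CYP1 and CYP2, while the
body text states CSM 9 is absent from CYP1 and CYP3 (and conserved only
in CYP2).  The body text reading is taken as authoritative; the footnote
appears to be a typo.
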
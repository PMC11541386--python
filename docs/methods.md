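# Methods

## Mass arithmetic

All masses are monoisotopic, computed from a fixed atomic-mass table
shipped as package data (`metid/data/atomic_masses.tsv`; IUPAC values for
C, H, N, O, S, F, Cl, P to 7 decimals).  Adduct m/z uses the
hydrogen-atom mass convention: [M+H]⁺ = M + 1.0078250, [M−H]⁻ =
M − 1.0078250, singly charged only.  This convention (rather than the
proton mass with an electron correction, ~0.5 mDa lower) is the one that
reproduces the reference values the package is validated against, and the
difference is far below the 1 mDa matching tolerance.  Masses are carried
at full double precision and printed to 5 decimals.

## The reaction library

The packaged biotransformation library (`metid/data/reactions_cmp.tsv`)
holds exactly 144 pathways: 12 phase-I transformations, 20 phase-II
conjugations, 96 pairwise phase-I x phase-II combinations and 16 double
conjugations.  Conjugation deltas follow the condensation convention
(conjugate delta = conjugating molecule − H₂O), which yields the standard
shifts: glucose +C6H10O5 (162.05282), malonic acid +C3H2O3 (86.00039),
glucuronic acid +C6H8O6 (176.03209), glucose+malonyl 248.05321.  Reactions
whose losses exceed a parent's element counts are rejected at application
time, never clamped; every packaged delta's negative part fits within the
minimum element counts of the six packaged parents, so the full 6 x 144
enumeration produces 864 candidates with no rejections.  The file order is
the id order (R1–R144); glucose conjugation sits at R63, so candidate ids
like `Sulfamethoxazole-R63` follow the field's familiar naming.  The
library is data, not code: swap in any TSV with `id, label, phase, delta`
columns to change the chemistry.

## Tentative-spectrum synthesis

Exact-structure candidates use their own predicted spectra, merged over
collision energies 10 and 20 eV (40 eV omitted: at high energy the
spectrum collapses into small fragments shared by many compounds, which
inflates false positives).  During merging, peaks closer than 5 mDa — the
MS² matching tolerance — collapse to the more intense member.

Tentative candidates have no structure to fragment, so their library
record is a transplant: all parent fragments, plus the parent precursor
m/z appended as a fragment at the maximum parent-fragment intensity, under
a precursor equal to the candidate's own adduct m/z.  The chemistry behind
this: conjugates tend to cleave the conjugated moiety first, so their MS²
spectra are dominated by the intact parent ion and the parent's fragments.
Two laws follow and are enforced by tests: the synthesized record always
has exactly one more peak than the parent record, and its precursor minus
the parent precursor equals the reaction mass delta.  For mass-loss
reactions the transplanted fragments can exceed the candidate precursor;
the records keep them anyway (the +1 law is unconditional), and the
peak-below-precursor invariant is enforced only for exact-structure
records.  Intensities are normalized to max = 100 on MSP export.

## Matching and confidence

Precursor tolerance 1 mDa, MS² tolerance 5 mDa, Rt alignment tolerance
0.1 min.  Fragment pairing is greedy closest-first with single use per
peak (distance ties break toward the lower library m/z); similarity is
the cosine of square-root-intensity vectors over the union of paired and
unpaired peaks, so unmatched peaks on either side dilute the score.  The
acceptance threshold defaults to similarity ≥ 0.80 with ≥ 2 matched
fragments; both are configurable, and the exact scoring formula used by
any given alignment tool may differ — this one is a standard member of
the spectral dot-product family and is cross-checked against an
independent implementation in the tests.  Matches map to identification
confidence levels: 1 (reference standard), 2 (exact-structure library
match), 3 (tentative structure matched against an in silico record);
features without MS² support are never reported.  ΔRt versus the parent's
matched feature is reported as supporting evidence (polar conjugates
elute earlier, acetyl/methyl conjugates later on reversed phase) but is
deliberately not a gate.

## Statistical funnel

Prefilter, per feature: %RSD over pooled-QC areas (sample sd / mean x
100) strictly below 30; presence (area > 0, floor configurable) in
strictly more than 50% of QCs; presence in strictly more than 70% of at
least one biological group.  A zero QC mean makes the RSD undefined and
fails the first criterion.

Volcano selection: fold change is the ratio of raw group means
(treated / control); the p-value is a Welch two-sample t-test on
log10(area + half the smallest positive area in the table) — half-minimum
being the conventional zero-imputation choice.  Significance requires
p < 0.05 AND FC > 3.0, both strict, in the treated direction only:
metabolites of an administered compound should not occur in controls, and
the FC 3 margin plays the role of a limit-of-detection analogue.  No
multiple-testing correction is applied by default, matching the raw-p
criterion; a Benjamini–Hochberg option exists behind a flag.

PCA is computed by SVD of the log10, mean-centred, unit-variance-scaled
area matrix; the sign of each component is fixed by forcing its
largest-magnitude loading positive, making scores deterministic.

The final report is the inner join of significant features with accepted
matches: significant-but-unmatched features are metabolome perturbations
outside the workflow's scope, matched-but-non-significant features are
not treatment-related.  Acquisition-mode Venn summaries count distinct
(compound, sample type) elements.

## Simulated experiments

The generator emulates an uptake-experiment alignment export at table
level: 3 treated + 3 control biological samples and 8 pooled-QC
injections by default, lognormal areas with ~15% biological and ~10% QC
CV, spiked metabolite features taking m/z (±0.3 mDa Gaussian error) and
MS² (±1 mDa jitter) from their library records with a multiplicative
treatment effect, parents of spiked metabolites present in treated
samples only, and background features with no group effect whose m/z is
kept ≥ 3 mDa away from every library precursor.  Spiked retention times
sit near the parent Rt with a conjugation-dependent sign (glucose-type
conjugates earlier, acetyl/methyl later).  Decoy features copy library
precursors shifted by +10 mDa with shuffled fragment intensities and
treatment-elevated areas, so they pass the statistical funnel and test
the matcher alone.  Parent Rt values: sulfamethoxazole 5.15 min and
atenolol 2.94 min are literature-anchored; the other four are plausible
values for a 18-min reversed-phase gradient, chosen once.

What the simulation does not model: chromatographic peak shape and
alignment errors, isotope patterns, in-source fragmentation, DIA
co-isolation, matrix effects and ion suppression, and real fragmentation
chemistry (parent "predicted" spectra are the compounds' characteristic
observed ions, not a fragmentation-model output).  Passing the spike-in
and decoy tests therefore demonstrates the correctness of the matching
and triage logic under the stated error model, not identification
performance on real extracts.

Default problem sizes (hundreds of features, ~1200 library records) keep
a full simulated run in the low seconds; all randomness flows from a
single seed, and identical configurations reproduce artifacts
byte-for-byte.

## Known limitations

- Tentative candidates share their parent's transplanted spectrum, so
  isomeric conjugates at the same precursor are indistinguishable by MS²
  alone; Rt and the reaction label are the only discriminators.
- The reaction library is a representative reconstruction of common
  phase-I/II chemistry and their combinations; membership is editable
  data, and counts quoted above apply to the packaged default only.
- Negative-mode tentative synthesis mirrors positive mode symmetrically;
  no mode-specific fragmentation differences are modelled.
- Multi-charge adducts, adducts other than [M±H]±, and isotopologue
  peaks are out of scope.
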
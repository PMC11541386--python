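# metid

Suspect-screening identification of pharmaceutical metabolites in
untargeted LC-HRMS data.

Plants and soil organisms transform drug residues through phase I
(hydroxylation, dealkylation, hydrolysis, redox) and phase II metabolism
(conjugation with glucose, malonic acid, amino acids, sulfate, ...).  Most
of these metabolites have no reference standards and no deposited spectra,
so they are invisible to ordinary library search.  `metid` implements a
complete desk-side workflow for finding them in aligned untargeted
feature tables:

1. **Candidate enumeration** (`metid.chem_registry`) — apply a library of
   biotransformation reactions, expressed as signed elemental-formula
   deltas, to each parent compound.  The packaged library holds 144
   pathways (phase I, phase II and their combinations); applied to the six
   packaged parents (atenolol, enrofloxacin, erythromycin, ketoprofen,
   sulfamethoxazole, tetracycline) it yields 864 candidates.  Externally
   predicted or literature candidates with exact structures are ingested
   from tables alongside.
2. **In silico MS² library synthesis** (`metid.spectral_synthesis`) —
   merge predicted spectra across collision energies (10 + 20 eV; 40 eV is
   dropped because its small unspecific fragments cause false matches) and,
   for tentative candidates without a resolvable structure, transplant the
   parent spectrum: keep every parent fragment, append the parent precursor
   ion as a fragment, and shift the precursor by the reaction mass delta.
   Libraries serialize to MSP.
3. **Feature matching** (`metid.feature_matching`) — precursor match
   within 1 mDa, fragment match within 5 mDa, similarity = cosine of
   square-root intensity vectors over greedily paired fragments.  Accepted
   matches carry identification confidence levels (1 reference standard,
   2 exact-structure library match, 3 tentative structure).
4. **Statistical triage** (`metid.stat_triage`) — pooled-QC prefilter
   (%RSD < 30, QC presence > 50%, group presence > 70%), volcano selection
   (Welch t-test on log₁₀ areas, p < 0.05 AND fold change > 3 in the
   treated direction), PCA overview, and a final report of features that
   are both significant and matched.
5. **Simulation** (`metid.synthetic_data`) — seeded generator for aligned
   feature tables with treated/control/QC structure, spiked metabolites
   and decoys, used for validation and demos.

## Worked example

The key mass arithmetic, at the Python prompt:

```python
>>> from metid import chem_registry as chem
>>> smx = {p.id: p for p in chem.load_parents()}["sulfamethoxazole"]
>>> round(chem.adduct_mz(smx.neutral_mass, chem.ADDUCT_M_PLUS_H), 5)
254.05994
>>> glucose = {r.id: r for r in chem.load_reactions()}["R63"]
>>> round(glucose.mass_delta, 4)
162.0528
>>> conj = chem.apply_reaction(smx, glucose)     # Sulfamethoxazole-R63
>>> round(chem.adduct_mz(conj.neutral_mass, chem.ADDUCT_M_PLUS_H), 5)
416.11276
```

The glucose conjugate of sulfamethoxazole is predicted at [M+H]⁺
416.11276, shifted by Δm/z 162.0528 from the parent's 254.05994; its
synthesized MS² spectrum is the parent's fragments (92.04948, 94.06513,
156.01138) plus the parent precursor appended as a fragment.

A full simulated run from the shell:

```text
$ metid run --out demo_out --seed 7
INFO predict: 6 parents x 144 reactions -> 864 CMP (+0 SP, +0 LS), 0 rejected, 760 below m/z 800
INFO buildlib: positive library with 766 records -> library_pos.msp
INFO buildlib: negative library with 433 records -> library_neg.msp
INFO simulate: 114 features (8 spikes, 0 decoys) over 14 samples
INFO match: 114 features -> 14 accepted matches
INFO stats: 114 features, 114 pass prefilter, 14 significant; PC1 20.6%
INFO report: 14 identified compounds
report: 14 compounds -> demo_out/report.tsv
```

The report lists the six parent drugs (confidence level 2, matched against
their own exact-structure records) and the eight spiked tentative
metabolites (level 3), each with its normalized treated-group abundance;
the 100 simulated background features are filtered out by the volcano
selection and the absence of a library match.  Stage subcommands
(`predict`, `buildlib`, `simulate`, `match`, `stats`, `report`) compose to
the same artifacts.

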
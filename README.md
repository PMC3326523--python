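# bromokit

Bromodomains (BRDs) are ~110-residue four-helix reader modules that
recognize ε-N-acetyl-lysine (Kac) marks, predominantly on histone tails.
Profiling which acetylation sites — and which *combinations* of marks — a
bromodomain recognizes involves three intertwined experiment types:
combinatorial SPOT peptide arrays on cellulose membranes, isothermal
titration calorimetry (ITC) of reader–peptide binding, and sequence-level
classification of the bromodomain family itself.  `bromokit` packages the
full desk-side workflow for scientists analyzing (or simulating) such
screens:

* **array design** — deterministic generation of single-Kac coverage
  arrays over the five human histones (H1.4, H2A, H2B, H3, H4),
  combinatorial crosstalk arrays (Kac/Kme3/pS/pT contexts around each
  acetyl-lysine epitope), multi-Kac tail arrays, and Kac–linker–Kac
  spacer/property scans, each probe paired with an unmodified control;
* **synthetic ground truth** — seeded affinity landscapes, 16-bit
  membrane images (occupancy θ = c/(c+K_D) at 1 μM probe, ~500 μM
  detection limit), ITC heat traces, and motif-planted bromodomain-like
  sequences;
* **quantification & calling** — spot integration with local-background
  subtraction, His-antibody / anti-Kac QC exclusion, Kac-dependent
  interaction calls with weak/medium/strong categories and the "gray"
  (Kac-independent) class, crosstalk enhancement ratios, and relative
  peak-intensity fractions for MS quantitation;
* **ITC modelling** — statsmodels-style `SingleSiteModel` /
  `TwoSiteModel` objects whose `fit()` returns results with estimates,
  uncertainties, AICc, `summary()` and `plot()`; thermodynamics via
  ΔG = −RT ln K_a and ΔG = ΔH − TΔS; stoichiometry interpretation that
  distinguishes two-readers-per-peptide (N ≈ 0.5, reader in cell) from
  bidentate single-event binding (N ≈ 1 with a large affinity gain);
* **family classification** — scanning for the bromodomain signature
  motifs (the αZ hydrophobic triad ϕxx(x)ϕxxx(x)ϕ, the PϕD helix cap, and
  the αB signature ϕxxDϕxxϕϕxNϕxxY/F followed by the anchoring Asn),
  motif-anchored domain-boundary proposal, BLOSUM62 global-alignment
  identity distances, a from-scratch neighbor-joining implementation with
  deterministic tie-breaking, and nearest-reference assignment into the
  eight bromodomain families I–VIII.

## The core binding model

Heats of injection are generated and fitted with the standard
single-set-of-sites perfusion-cell model.  With macromolecule M (total
`Mt`) in a cell of volume `V0` titrated by injectant X (total `Xt`), the
bound-injectant concentration C solves

    K_a = C / ((N·Mt − C)(Xt − C)),

evaluated from the stable root `C = 2AB / (S + √(S² − 4AB))`,
`S = A + B + 1/K_a`.  Cumulative heat is `Q = ΔH·C·V0` and per-injection
heats carry the displaced-volume correction
`q_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2`.  A peptide with *m*
equivalent independent reader-binding acetyl-lysines is simulated with
site concentration `m·Xt`; fitting such data with the single-site model
(reader in the cell) returns the multivalency signature N = 1/m.

## Numbering and the mark grammar

All positions are 1-based on the mature (initiator-Met-cleaved) chain, so
`H3K4`, `H3K14`, `H4K5` point at real lysines.  Marks are written
`H4(1-11)K5acK8ac`, with `ac`/`me3` on K and `ph` on S/T (prefix spellings
like `pS10`/`pT3` are accepted on input).  Omitted window bounds default to
±5 residues around the outermost marks.

## Worked example: diacetyl peptide stoichiometry by ITC

A peptide whose two acetyl-lysines each bind one bromodomain
independently (per-site K_D 20 μM, ΔH −10 kcal/mol), titrated into reader
at 100 μM:

```python
from bromokit import (BindingParameters, TitrationExperiment,
                      fit_single_site, synth_itc_trace)

per_site = BindingParameters(n_sites=1.0, k_a=1/20e-6, dh=-10000.0,
                             temperature=288.15)
skeleton = TitrationExperiment(cell_conc=100e-6, syringe_conc=600e-6,
                               temperature=288.15)
trace = synth_itc_trace(per_site, skeleton, injectant_sites=2,
                        noise_sd=0.0, dilution_heat=0.0)
res = fit_single_site(trace)
print(res.summary())
print("verdict:", res.verdict("protein_in_cell"))
```

prints

```
Single-set-of-sites ITC fit
===========================
injections used     : 30
temperature (K)     : 288.15
N  (sites)          : 0.5000 +/- 0.0000
K_a (1/M)           : 1.0000e+05 +/- 0.00e+00
K_D (M)             : 1.0000e-05
dH (cal/mol)        : -20000.0 +/- 0.0
dG (cal/mol)        : -6592.4
dS (cal/mol/K)      : -46.530
c-value             : 5
SSR (ucal^2)        : 0

verdict: two_domains_per_peptide
```

The fitted stoichiometry N = 0.5 (mol peptide per mol reader) is the
hallmark of two reader molecules engaging one diacetylated peptide; the
apparent K_a doubles and the apparent enthalpy is per mole of peptide
(two site events), exactly as the site-level truth implies.

## Command line

```sh
bromokit demo --outdir demo-run        # full design→synth→call→report run
bromokit design --class crosstalk --out layout.tsv
bromokit itc-fit trace.csv --model one --orientation protein_in_cell
bromokit classify queries.fasta --tree
```

Every run writes its resolved configuration and a manifest with seeds and
artifact digests; identical config + seeds reproduce byte-identical
tables.

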
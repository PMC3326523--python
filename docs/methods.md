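# Methods

This note records the models, parameter defaults, and design choices
behind `bromokit`, and what the synthetic data do and do not emulate.

## Histone model

The package ships the five canonical mature human histone chains (H1.4,
H2A type 1 consensus, H2B type 1-K, H3.1, H4).  Positions are 1-based on
the mature, initiator-Met-cleaved chain throughout — the convention that
makes `H3K4`, `H3K14`, `H4K5`, `H4K16` point at lysines.  Two caveats:

* Linker-histone (H1) marks are traditionally numbered counting the
  initiator Met; literature H1.4 positions are therefore +1 relative to
  this package.
* Which H2A/H2B sequence variants were used on any particular published
  membrane is generally not recorded; the shipped fixtures are the
  canonical human chains, and users can substitute their own via FASTA.

Window extraction places the central residue at slot ⌈L/2⌉ of an L-mer
and truncates (never shifts) at chain termini, so a window near an end can
be shorter than requested but the center convention is stable.  Mark
strings without explicit bounds pad ±5 residues around the outermost
marks.  Both rules are package conventions; peptide-array practice varies
and rarely documents its per-peptide windowing.

## Array designers

All four designers are pure functions of their parameters (no RNG):

* **single_kac** — one singly acetylated probe per lysine (default
  11-mers, lengths 10–14 supported) with its unmodified control placed
  immediately before it.
* **crosstalk** — for each central Kac epitope on H3, the Cartesian
  product of flanking modifiable-site states (K: unmod/ac/me3; S/T:
  unmod/ph) within the 11-mer window.  The all-unmodified-flanks member of
  the product *is* the central-Kac-only peptide.  The default cap of 2
  simultaneous flanking marks keeps membranes small; `max_flanking_mods=None`
  enumerates the full product (e.g. 3·2·2·3 = 36 contexts for the K14
  window 9–19).
* **multi_kac** — every 11-mer window over the first 30 tail residues
  (configurable; "N-terminal tail" has no canonical bound) with every
  non-empty acetyl subset of window lysines, deduplicated by label.
* **linker_scan** — `flank_N + Kac + Gly×n + Kac + flank_C` series plus
  single-residue substitutions at requested linker slots for n ∈ {2, 3}.
  The default panel {G, A, L, F, S, P, E, K} spans
  small/bulky/hydrophobic/polar/cyclic/acidic/basic residue properties.
  Gly substitutions duplicate the all-Gly base peptide and are flagged
  `replicate_of` rather than removed, so the count formula
  `len(lengths) + |panel|·|slots|` per substituted length stays exact.
  Each probe carries an anchor-Asn→Ala annotation slot for simulating
  no-binding mutant membranes.

Grid shape (20 columns, row-major) is purely presentational.

## Synthetic ground truth

**Affinity landscapes.**  Each epitope (parent chain + anchor Kac
position) draws once from a seeded substream keyed by label, so values are
independent of layout order.  Defaults: 30% of epitopes are binders;
mono-Kac baselines log-uniform over 3–300 μM (the affinity window in which
solution measurements of reader–Kac interactions typically fall); each
additional acetyl-lysine multiplies affinity by 20 (avidity/bidentate
gain); flanking phosphorylation multiplies affinity by 5; flanking
trimethylation divides it by 5 (factor 0.2); non-binder epitopes sit at
5 mM (an order of magnitude past the detection limit); unmodified controls
of Kac-dependent binders are strictly non-binding (K_D = ∞ sentinel);
a configurable fraction of epitopes binds Kac-independently (probe and
control alike).  Rules compose multiplicatively and commutatively.

**Membranes.**  Spot mean signal above background is `gain·θ` with
θ = c/(c+K_D) at probe concentration c = 1 μM — probe depletion is ignored
(reader in vast excess over spotted peptide, as in membrane incubation).
Spots are hard disks (radius 5 px, pitch 22 px) with a σ = 0.8 px Gaussian
edge blur (flux-conserving); noise is Poisson on the expected signal plus
Gaussian read noise (σ = 25 counts) over a background of 1000 counts.
The default gain is calibrated so a K_D = 500 μM spot — the practical
detection limit of the membrane format — sits at per-pixel SNR 2.
Exposure series scale the signal linearly with 16-bit clipping on export.
No imager noise statistics are published for this format; the defaults are
package choices exposed in configuration.  The float pixel buffer is kept
internally so noise-free renders are exact closed forms; TIFF export is
uint16.

Not emulated: chemiluminescence kinetics, antibody binding chemistry,
membrane stripping artifacts, spatial warping/registration error.  Passing
tests therefore validate the quantification/calling logic, not robustness
to scanner-specific distortions of real membranes.

**ITC traces.** Heats come from the binding model below plus a constant
(or per-injection) dilution heat and Gaussian noise (default σ = 0.5 μcal,
a typical instrument-scale figure).  Generating truth is recorded in the
trace provenance.

**Reader-like sequences.**  Eight ~110-residue family templates embed the
three signature motifs at fixed offsets (helix-Z triad at 7, PϕD at 41,
B-helix signature at 71–85, anchor residue at 86, 1-based) over
family-specific random inter-motif regions; they are *synthetic stand-ins*
for curated reference domains, reproducing the motif architecture only.
Families VI and VII carry Asp and Thr at the anchor position to exercise
the natural anchor replacements; the rest carry the canonical Asn.
Mutated copies protect motif positions by default so the planted family
identity stays recoverable at any mutation rate.

## Spot quantification and calling

ROI = spot radius + 3 px; local background = median of a 4 px annulus;
corrected = raw − background·area, floored at 0 (a signed copy is kept for
threshold estimation).  From an exposure series, each spot keeps its
latest non-clipped exposure.

The positive threshold defaults to median + 3·1.4826·MAD of the
control-spot corrected intensities per membrane.  A robust scale is used
deliberately: Kac-independent binder controls are legitimate members of
the control population and would inflate a plain standard deviation enough
to mask true positives; the MAD form is the robust equivalent of a
mean + 3 SD rule.  A fixed threshold can be supplied instead.  Categories
(weak/medium/strong) default to tertiles of the membrane's positive probe
intensities, overridable with fixed bin edges; published membranes shade
by intensity without quantifying their cutoffs, so bins are configuration,
not science.

A call is Kac-dependent iff the probe clears the threshold and its
unmodified control does not; probe-and-control-positive pairs stay in the
report as the "gray" Kac-independent class.  His-antibody-reactive spots
are excluded outright; acetylated spots without anti-Kac signal are
excluded from interaction statistics; proline within ±2 residues of a Kac
is annotated (a known cause of anti-Kac antibody failure) but not
excluding by itself.

## ITC model

Overflow perfusion-cell bookkeeping after cumulative injected volume ΔV:

    Mt = M0 (1 − ΔV/2V0) / (1 + ΔV/2V0)
    Xt = X0 (ΔV/V0) / (1 + ΔV/2V0)

Single set of N identical sites: bound injectant C solves
K_a = C/((N·Mt − C)(Xt − C)), evaluated subtraction-free as
C = 2AB/(S + √(S² − 4AB)) with S = A + B + 1/K_a, which degenerates
smoothly to the linear regime at K_a → 0.  Q = ΔH·C·V0;
q_i = ΔQ_i + (dV_i/V0)(Q_i + Q_{i−1})/2 (displaced-volume correction).
Units are cal-based (μcal heats, cal/mol enthalpies), matching instrument
convention; R = 1.9872 cal mol⁻¹ K⁻¹.

Fitting is bounded weighted least squares over (N, log₁₀K_a, ΔH) with
three deterministic initializations (K_a decades 10⁴–10⁶; N from the
half-height molar ratio of the cumulative heat; ΔH from the first full
injection assuming complete binding), tolerances 10⁻¹⁵.  The small first
injection is down-weighted ×0.1 (or excluded on request) — standard
practice for the priming injection.  When blank (dilution) heats are
supplied they are subtracted; otherwise a constant offset is co-fitted.
Parameter uncertainties come from the Gauss–Newton local quadratic
approximation.  Flat heat profiles (span within 3× a
successive-difference noise floor) raise a "no binding detected" error
rather than returning junk.

The two-sets-of-sites model solves the free-ligand mass balance by
root-finding per injection and is compared with the single-site fit by
AICc.  Fits are flagged degenerate when the two classes collapse
(affinity ratio < 3) or one class carries < 5% of the total heat capacity
N·|ΔH| — both are "effectively single-site" outcomes.

Stoichiometry interpretation (reader in cell): N in the confidence
neighborhood of 0.5 (and excluding 1) → two readers per peptide; N near
1 → one-to-one, upgraded to "bidentate single event" only when a ≥5-fold
affinity gain over the monoacetylated reference is supplied as context —
stoichiometry alone cannot distinguish the two; anything unresolved →
indeterminate.

## Family classification

Motif patterns are positional class strings (ϕ = {A,C,F,I,L,M,V,W,Y} by
default — the hydrophobic class is a convention, configurable).  The αZ
pattern's two optional insertion slots accept 0–3 residues each
(published descriptions show single parenthesized slots without fixed
lengths); variants are expanded exhaustively and scanning reports all
matches including overlaps.

Domain proposal requires a helix-Z motif followed 30–120 residues later
by the B-helix signature; bounds extend 6 residues upstream and 25
downstream (covering the C helix), clipped, with greedy non-overlapping
multi-domain chaining.  Secondary-structure annotations, when supplied,
are accepted as input only — never computed.

Distances are 1 − identity over global pairwise alignments (BLOSUM62,
gap open 10 / extend 0.5 — conventional alignment defaults) or computed
column-wise from a user alignment with dual-gap columns excluded.
Identity distances are a dissimilarity, not a metric: the triangle
inequality can fail and is never relied upon.

Neighbor joining is implemented from scratch: Q-criterion agglomeration,
ties broken on the lexicographically lowest leaf-label pair, negative
branch lengths clamped to zero with the deficit moved to the sibling, and
an unrooted trifurcation at the final three-node join.  On additive
matrices the output is exact.

Family assignment is nearest-reference with a 0.6 distance cutoff for
"unassigned".  The shipped references are the eight synthetic templates;
real analyses should supply curated reference domains via FASTA.
Recreating any published family tree would require the underlying
structure-guided alignment and is out of scope.

## Problem sizes and determinism

The test suite and acceptance script use desk-scale problems chosen as
representative rather than exhaustive: 30-injection titrations, 100
seeded ITC replicates over K_D ∈ [3, 300] μM, six-membrane calling
panels (~90 spots each), 1000 random sequences per motif pattern, and
5–6-taxon tree oracles.  Every stochastic component is a pure function of
(parameters, seed); pipelines record all derived seeds in their manifest,
and rerunning with identical configuration yields byte-identical tables.

## Known limitations

* SPOT intensity is not calibrated to molar affinity — solution
  measurements and membrane intensities are known to correlate only
  loosely, so calls are categorical, never quantitative K_D estimates.
* The exact intensity cutoffs behind published interaction counts are not
  recoverable; thresholds are explicit configuration here, and no attempt
  is made to reproduce any published interaction tally.
* Kinetics (k_on/k_off), global multi-experiment fitting, and raw
  power-trace baseline integration are out of scope; heats per injection
  are the ITC input.
* The mark grammar covers ac/me3/ph only — the marks the array designs
  need; other PTMs (me1/me2, ub, etc.) are not modeled.
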
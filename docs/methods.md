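# Methods

This note documents the models, parameter choices and numerical decisions
behind `bpascreen`, and what the synthetic-data tests do and do not show.

## Compound model and fixtures

Structures are RDKit molecules canonicalized at parse time; comparisons are
always canonical-to-canonical. Disconnected inputs (salts, mixtures) are
rejected because every descriptor downstream assumes one covalent species.
Stereocenters present in the input are preserved, but scores and the gate
are stereo-agnostic: enantiomers receive identical verdicts by construction.

The built-in fixtures encode the HR-series amides from their preparative
names. Where a name never fixes the pyridine attachment point (HR66, HR68,
HR71) the structure is a chemically reasonable positional isomer and the
compound carries `inferred=True`. Reference drugs (fenofibrate, fenofibric
acid, temozolomide, caffeine) use their standard structures; every fixture's
molecular formula is asserted atom-by-atom in the tests. Supplied `pka_basic`
overrides on the fixtures (≈3–6 for the pyridinium conjugate acids) are
literature-informed estimates standing in for an external pKa engine; they
are nearly score-inert (CNS-MPO's pKa desirability is 1 below 8, and the
ClogD correction at pH 7.4 is < 0.02 log units for pKa ≤ 6).

## Descriptors

* **Topology panel.** MW, TPSA, aromatic rings, heavy atoms, rotatable
  bonds and Crippen ClogP come from RDKit. HBD/HBA use the Lipinski
  conventions (OH+NH hydrogen count; N+O heavy-atom count), so water has
  HBD = 2 and MWHBN matches the (HBD+HBA)/√MW definition used by the BBB
  score.
* **ClogD.** Henderson–Hasselbalch for monoprotic centers:
  logD = logP − log₁₀(1+10^(pKa_b−pH)) − log₁₀(1+10^(pH−pKa_a)); both terms
  are nonnegative, so ionization can only reduce apparent lipophilicity
  (property-tested). Compounds without supplied pKa are treated as
  non-ionizable. pKa is never predicted de novo — an empirical pKa model is
  a project in itself and a badly trained one would silently bias every
  downstream score.
* **logS.** The ESOL linear model (Delaney 2004):
  logS = 0.16 − 0.63·ClogP − 0.0062·MW + 0.066·RB − 0.74·AP, with AP the
  aromatic fraction of heavy atoms. It is an open, documented surrogate for
  commercial solubility estimators; the gate consumes −logS ("insolubility",
  bigger = worse).
* **Polarizability.** Miller's additive atomic-hybrid scheme (Miller 1990):
  each atom contributes a tabulated value by element and hybridization
  class (e.g. CH₄ = 1.061 + 4×0.387 = 2.61 Å³; benzene ≈ 10.4 Å³ vs 10.3
  experimental). Elements outside the table raise an error naming the
  element rather than guessing.

## Minimal projection area

MPA is the smallest area of the molecule's van-der-Waals silhouette over
all projection directions; values below 60 Å² are taken as permissive for
passive CNS diffusion. The implementation:

1. embeds `n_conformers` = 10 ETKDGv3 conformers (fixed seed, default
   20230420), MMFF-relaxes them (UFF fallback) and keeps the lowest-energy
   one — the published screens never state which conformer their engine
   used, so "lowest force-field energy of N embeddings" is fixed here and
   recorded;
2. scans projection directions on a 10° spherical grid (upper hemisphere
   only, since u and −u give the same silhouette), rasterizing the union of
   the atoms' vdW disks at 0.1 Å/pixel;
3. with `refine=True`, re-scans an 11×11 local grid around the best
   direction at half the raster step.

A brute-force oracle (`mpa_oracle`) evaluates an exhaustive fine orientation
grid with the projected union measured *exactly* as a polygon union
(shapely buffered points), giving an independent geometric route against
the raster path; the two agree within 2% on a toy set and the search is
rotation/translation-invariant up to grid discretization (~3% on a coarse
15° grid, ~0.01% at 5°/0.08 Å). Error model: rasterization biases area by
O(resolution·perimeter); orientation discretization only ever overestimates
the minimum.

## Scores

* **CNS-MPO** uses sharp piecewise-linear desirabilities ("T0" ramps):
  ClogP 1 below 3 → 0 above 5; ClogD(7.4) 2→4; MW 360→500; TPSA a
  20/40–90/120 hump; HBD 0.5→3.5; pKa 8→10. Boundary values evaluate the
  ramp (ClogP = 3 → exactly 1.0). A compound with no basic center scores 1.0
  on the pKa axis: a neutral amide cannot be penalized for basicity.
* **BBB score** = 1·P(Aro) + 1·P(HA) + 1.5·P(MWHBN) + 2·P(TPSA) +
  0.5·P(pKa), each component clamped to [0, 1], total clamped to [0, 6].
  The component step values and polynomials are *data*, stored with a
  version tag in `data/bbb_score_table.json` (transcribed from the published
  scoring function, Gupta 2019) so they can be audited or substituted via
  `load_bbb_table(path)`. With no supplied basic pKa the pKa component
  contributes zero — the neutral molecule simply forgoes the basicity bonus;
  this is the one score where missing pKa is not neutral, and it is the main
  reason fixture BBB values sit a tenth or two below an engine that always
  computes a pKa.
* **logBB** = log₁₀(brain:plasma fraction); 20% CNS penetration ⇒ −0.70.

Open-stack descriptor values (Crippen ClogP above all) differ from
commercial engines; scores built on them are compared to externally
reported values at a documented ±0.3 score-unit tolerance.

## Screening gate

Defaults: hERG < 5.5, −logS < 7.5, CNS-MPO > 3, BBB ∈ [4, 5] (closed),
MPA < 60 Å². "Below"/"over" wording is honored as strict inequality;
boundary-equal values fail. Missing inputs (e.g. no supplied hERG) skip the
criterion and are listed in the result — a verdict is never quietly based
on fewer criteria than the caller thinks. ClogD < 3 and logS < 0 are
reference-panel acceptability criteria used during calibration only; the
synthesized candidate series intentionally exceeds ClogD 3.

Calibration takes a scored panel flagged acceptable/unacceptable and sets
each bound to the acceptable subset's observed extreme, widened by one
float ulp so that a member sitting exactly at the extreme still passes the
strict gate (this reconciles strict boundary semantics with the closure
property "everything acceptable passes its own calibrated gate");
`"widen:<frac>"` widens by a fraction of the observed span instead. Which
drugs count as acceptable is an input, not an inference.

Ranking: passing compounds by (CNS-MPO desc, BBB desc, −logS asc), stable
id tie-break. Nucleophilicity ordering is descending supplied E_HOMO and is
only contractually meaningful within a structurally similar series.

## Metabolism

Six default SMARTS transforms: amide/ester hydrolysis (acyclic only —
hydrolyzing a ring amide would yield one ring-opened product and break the
two-product mass-balance invariant), aromatic hydroxylation at every
aromatic CH, aliphatic hydroxylation at benzylic CH (plus the degenerate
single-carbon case), ketone reduction (both neighbors carbon), and aryl
O-dealkylation (requires an α-H; quaternary ethers like the BPA core are
correctly inert). Duplicate product sets are merged by canonical SMILES;
ordering is (rule, site) and enumeration is idempotent. Hydrolysis mass
balance (parent + H₂O = products, by formula) is enforced at enumeration
time, not just tested.

Products are re-scored through physchem → ESOL → CNS-MPO/BBB; the parent is
re-scored under the same no-pKa convention so deltas compare like with
like. hERG is pass-through data: a supplied metabolite prediction below 4.5
raises `herg_alert`. Note the two hERG conventions in play: the candidate
gate treats *high* predicted pIC50 (> 5.5) as the liability, while the
metabolite alert flags *low* supplied values, following the upstream
predictors' respective conventions; 4.5 sits between the reported "safe"
(≥ 4.95) and "alert" (3.91) exemplars.

## Bioassay

Viability is 100·signal/vehicle per replicate, summarized as mean ± sample
SD per concentration. The 4PL fit runs in log₁₀-concentration space,
CV = bottom + (top−bottom)/(1+10^(hill·(logc − logIC50))), bounds
0 ≤ bottom < top ≤ 120 and IC50 ∈ [min conc/10, max conc·10], initialized
at top = max CV, bottom = min CV, IC50 at the 50%-of-span crossing,
hill = 1. Data whose per-concentration means *rise* with dose (Spearman
ρ > 0.5) violate the inhibition model and are reported `converged=False`;
fit failures return diagnostics, never a silent number. The fit is
scale-equivariant in concentration (tested), and over 200 simulated
triplicate datasets at 5% noise the median |IC50 error| is below 10%.

Permeability is the exact single-timepoint formula P = V_A·C_A/(t·S·C_L)
in cm/s (mL = cm³); no receiver-sampling correction is applied because the
design samples once. TEER normalization is multiplicative,
P·(TEER/TEER_ref) — the direction of "normalized by TEER" is not fixed by
convention, so the adopted one is stated in the CLI output metadata;
normalizing a batch to its mean TEER preserves the batch-mean P. All
treatment concentrations are interpreted as µM (the assay descriptions use
25 µM; mM-scale readings of the same experiments are physiologically
inconsistent). The exposure ratio is tissue concentration / IC50; 3.7 µM
against 1.17 µM gives 3.16-fold.

## Synthetic data

Generators are pure functions of (parameters, seed); default seed 20230420
everywhere. Dose-response: 8 log-spaced concentrations spanning IC50/30 to
IC50·30, triplicates, Gaussian noise at 5% of top, left unclipped (MTT
readouts can exceed control). Reference panels: 15 drugs, exactly 6 drawn
uniformly inside the acceptability box (logS < 0, ClogD < 3, MPO/BBB in
band, hERG ≤ 5.5), the rest pushed outside in ≥ 1 coordinate. Transwell
wells: receiver concentration from inverting the P equation, 10% relative
noise, TEER ~ N(150, 15) Ω·cm² truncated positive, 24-well geometry
(0.5 mL receiver, 0.33 cm², 3 h, donor 25 µM).

What passing these tests shows: the estimators recover their own generating
models at realistic noise. What it does not show: correctness on real MTT
plates (edge effects, compound autofluorescence, non-Hill biphasic curves),
real transwell runs (paracellular leak, sampling depletion), or agreement
of ESOL/Crippen with measured solubility/lipophilicity for this chemotype.

## Problem sizes and reproducibility

Default problem sizes — 10 conformers and a 10° grid for MPA, 200 datasets
for fit-recovery, 10⁴ draws for score bounds — were chosen as the smallest
sizes at which the respective Monte-Carlo answers are stable to well within
the asserted tolerances. `run_screen` writes no timestamps into its
reports, so a rerun with the same seed is byte-identical; the audit JSON
carries every criterion value, bound and verdict plus the tool version and
a config hash.

## Known limitations

* Crippen ClogP deviates from commercial ClogP by several tenths for
  lipophilic aromatics; all score comparisons inherit the ±0.3 tolerance.
* The BBB-score coefficient table is a transcription of the published
  function; it ships as versioned data precisely so a corrected table can
  be dropped in without code changes.
* MPA depends on the chosen conformer; a different ensemble policy can
  shift values by a few Å² for flexible molecules.
* Metabolite enumeration is rule-class coverage, not a prediction of which
  metabolites dominate in vivo (no CYP isoform assignment, no abundances,
  no phase-II conjugation).
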
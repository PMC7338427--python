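# Methods

This note records the models, defaults and numerical choices behind
`tmaturity`, and what the synthetic-data tests do and do not establish.

## The measurement being emulated

Five stained tubes per subject on a 6-colour digital cytometer. One
counting tube carries a known bead load (default 50,000) in a known
stained volume (50 µl, lyse-no-wash so the cell:bead ratio is preserved);
it yields the basic subsets (T, B, NK, CD4, CD8) and the absolute
lymphocyte count. Four panel tubes (100 µl each) carry the maturation,
stem-memory and senescence/exhaustion markers. At least 15,000 events are
acquired per tube; the cohort generator enforces that floor and defaults
to 30,000.

Absolute counts follow the clinical convention: the bead ratio fixes the
lymphocyte concentration, and every subset's cells/µl is its chain of
conditional proportions times that anchor. Panel tubes have no beads, so
their chain runs through the T-cell gate whose absolute size comes from
the counting tube.

## Synthetic cohort model

Each subject is one latent state feeding all five tubes (hence cross-tube
consistency of, e.g., the CD4:CD8 ratio is exact by construction).

* **Counts**: `lymph_abs ~ median · exp(σZ)` (log-normal, median-true).
* **Fractions**: logit-normal around the preset median; sibling sets that
  partition a parent are drawn jointly and renormalised, which preserves
  medians to O(σ²) (≈1% at the default σ; verified by a Monte-Carlo test).
* **Dispersion** σ = 0.25 (one shared logit/log-scale sd per arm). The
  printed source for the presets reports medians only, no spread, so this
  is a free parameter. It was fixed once, a priori, so that the n = 46
  cohort-median sampling error (≈1.25σ/√46 ≈ 4.6%) sits well inside the
  ±10–15% recovery budgets the validation is designed around, while
  inter-subject IQRs stay clearly nondegenerate (≈±20% relative). Real
  cohorts scatter more; see Limitations.
* **Fluorescence**: two components per marker on the arcsinh scale —
  negative N(1.0, 0.4), positive N(3.5, 0.4), i.e. a fixed 2.5-unit
  separation (no per-marker MFIs are published). CD45 positives are
  lymphocyte-bright (3.8); other leukocytes are CD45-dim (2.8) with high
  side scatter; debris is dim (0.3) with broad scatter; beads sit at 7.0
  on *every* fluorescence channel, brighter than any cellular positive.
  Raw intensities are `150·sinh(value)`, so the pipeline's default
  transform recovers the model scale exactly.
* **Debris**: 10% of events in panel tubes. In the counting tube the
  non-lymphocyte *leukocytes* are their own population — their share is
  `1 − lymph%/100` of leukocyte-like events, which is what makes the
  lymphocyte percentage a recoverable quantity — and CD45⁻ debris is
  added on top at 10% of cell events.
* **Counting tube**: every component (lymphocyte leaves, other leukocytes,
  debris, beads) is an independent Poisson at the acquired fraction, so
  the bead-ratio estimator is unbiased by construction.
* **Presets**: `nbs` and `control` (46 subjects each) transcribe the
  published cohort medians. Two derived parameterisations: CD4/CD8 are
  stored as % of T (printed as % of lymphocytes), and the control-arm CD4
  maturation medians, whose printed values sum to 100.3%, are rescaled by
  99.5/100.3 so compositions remain a simplex. Phenotype combinations the
  scheme leaves unnamed absorb each partition's remainder.

**What a green test establishes.** Median recovery through the full
pipeline shows the gating and quantification machinery is unbiased at the
stated separations and event counts — not that it would survive real-world
spreading error, autofluorescence, doublets, batch drift or time effects,
none of which are modelled. One structural caveat: with independent,
log-symmetric subject draws the median of a product equals the product of
medians, so the recovered median CD4 cells/µl is `0.259 × 1330 ≈ 344`,
≈7% above the separately printed 322 — the printed percentage, count and
product are not jointly reproducible under any such generator, and the
package keeps the transcribed percentage rather than tuning either number.

## Automated gating surrogates

The source gates were manual; the package substitutes deterministic,
parameter-light density methods.

* **Primary gate** (lymphocytes on CD45/SSC, T cells on CD3/SSC): smoothed
  2-D histogram (128², Silverman bandwidths, binned KDE), steepest-ascent
  basins of its modes, watershed-merging of basins whose boundary saddle
  stays above half the smaller peak (a shoulder, not a population).
  Candidate modes need marker signal ≥ 2.0 (below: debris) and < 6.0
  (above: beads); among low-SSC candidates the marker-brightest wins and
  its full basin is the gate. Precision/recall ≥ 0.98 against generator
  truth is asserted in the suite.
* **Positivity thresholds**: per marker, per subject, per tube (manual
  gating is per sample; a pooled mode exists as a config switch), over the
  primary-gated events (≥ 500 required). 1-D binned KDE; modes below 0.1%
  of the global maximum are noise, shallow-valley modes are merged, and
  the cutoff is the deepest valley between the two highest surviving
  modes. Unimodal channels fall back to the midpoint of mode and 99.5th
  percentile, flagged `quantile-fallback`. Silverman's n uses the count of
  *distinct* values so duplicating events cannot move a cutoff. The 0.1%
  mode floor is what keeps rare positives (e.g. CD57 at 0.5% in controls)
  detectable without admitting single-event noise bumps.
* **Leukocyte gate** (denominator of the lymphocyte %): CD45⁻ debris vs
  everything cellular, so the cutoff is the valley directly above the
  *lowest* CD45 mode; with a single mode all non-bead events count as
  leukocytes.
* **Boundary convention**: strictly greater than the cutoff is positive;
  an exact tie is negative. Fixed everywhere.
* **Bead gate**: above 6.0 (transformed) on all fluorescence channels
  simultaneously.

## Gate trees

Five shipped trees; CD4 and CD8 branches are generated from one
definition, so their logic cannot drift apart. Tube 2's CD27⁻CD197⁺
phenotypes are reported as explicit `unclassified_CD27neg_CCR7pos_*`
buckets rather than dropped, which lets the suite assert exact event
conservation ({TN, TCM, TEM, L-TEMRA} partition CD27⁺; the CD27⁻ side
sums likewise). The CCR7-defined (tube 2) and CD95-defined (tube 3) RA⁺
effector subsets are distinct outputs from distinct tubes and are never
merged. A config question the source leaves open — whether naïve
statistics should exclude CD95⁺ cells (TSCM is phenotypically inside TN's
CD27⁺CD45RA⁺ parent region but measured in a different tube) — is
resolved by keeping tubes independent, with no cross-tube correction.

## Quantification and statistics

Percentages are of the immediate parent gate; empty parents yield missing
values with a warning, never silent zeros. Gates with < 50 parent events
are flagged low-confidence. Reporting precision is one decimal for
percentages and whole cells/µl. Comparisons are two-sided Mann–Whitney U
(exact when `n_x·n_y ≤ 400` and tie-free, otherwise normal approximation
with tie-corrected variance and continuity correction; U reported as
`min(U_x, U_y)`), with raw NS / <0.05 / <0.01 tiers and no multiplicity
correction by default (Benjamini–Hochberg available as an extra column).
Fisher's exact test is provided for user-supplied 2×2 contrasts; the
source names the test without stating its contingencies, so none are
asserted. Degenerate inputs (all values identical; zero margins) return
p = 1 with a warning.

## Numerical and scale choices

* arcsinh cofactor 150 (typical digital-flow dynamic range; the mass-
  cytometry convention of 5 is wrong for fluorescence); an approximate
  logicle (`arcsinh(x/c)/ln 10`) is offered for display parity.
* Spillover convention: `observed = true @ S.T`, `S[i, j]` the fraction of
  channel *j* received by detector *i*; compensation solves the linear
  system per event and is exact on noiseless mixtures (round-trip ≤ 1e-6
  asserted). The shipped default matrix leaks 1–10% between spectral
  neighbours.
* Determinism: every stochastic step derives from
  `SeedSequence(seed, arm, subject, tube)`; identical inputs give
  bit-identical outputs, including written manifests and sidecars.
* Scaled-down test surrogates (declared here, asserted in the suite): the
  normal-vs-permutation Mann–Whitney check runs 12 pairs × 20,000
  permutations; generator median recovery runs 4,000 subjects; bead-count
  recovery runs 40 replicates. Acceptance-level checks stay at full
  n = 46 × 30,000 events.

## Limitations

Inter-subject dispersion is a single shared parameter, not per-subset;
real cohorts are wider-spread and age-structured (age effects are out of
scope). The fluorescence model has no spreading error, autofluorescence,
doublets or acquisition-time drift, and scatter channels are stylised.
FCS support is float list-mode only (legacy integer/log-amplified files
are rejected). The density surrogates stand in for proprietary instrument
gating software and are not a reconstruction of it.
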
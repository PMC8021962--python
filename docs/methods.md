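# Methods

## Scope and data model

The package analyses gene-level ISH summaries ("expression energy") indexed
by a reference neuroanatomy, and derives from them a biophysical estimate
of cadherin-mediated adhesion. It deliberately begins *after* image
processing: pixel/voxel summaries (total expressing intensity, expressing
pixel count, total pixel count) are taken as given, because the thresholds
that define an "expressing" pixel live inside the atlas pipeline and are
not reproducible from published information. Expression energy is computed
as

    energy = (sum of expressing pixel intensity / n expressing pixels)
             x (n expressing pixels / n total pixels)
           = total expressing intensity / total pixels,

which is exactly invariant under splitting a structure volume across
sections and re-pooling (component-wise summation, "unionisation"); this
invariance is property-tested.

Energies are comparable between structures for one gene. ISH probes are
not calibrated against a shared mRNA standard, so *between-gene* energy
differences are only suggestive; all cross-gene arithmetic in this package
happens in the adhesion model, where dissociation constants re-weight the
counts, and nowhere else. Missing values stay missing — they are never
imputed as zero — and all correlations use pairwise-complete observations
with a minimum of three pairs.

## The neuroanatomy

Structures form a validated forest across thirteen ontological levels
(levels used here: 1–3 transverse segmentation, 5 plates, 8 subpallial
divisions, 10–12 cortex and subpallial nuclei). The anterior–posterior rank
of the 19 level-3 segments (RSP, CSP, p3, p2, p1, m1, m2, is, r1–r11) is a
convention of the prosomeric model and is stored explicitly (`ap_index`)
rather than inferred. Adult cortical units are modelled as (area, layer)
pairs — 9 areas × 6 layers — carried in two dedicated fields rather than
overloading the plate/stratum vocabularies, whose enumerated values
(ventricular/periventricular/intermediate/superficial) cannot encode
cortical layers 1–6 without breaking their invariants.

The packaged fixture covers exactly the structures the analyses index. The
subpallial nuclei are enumerated from the adult-stage stratum lists (15
periventricular + 22 intermediate + 21 superficial = 58 named nuclei);
the figure-level description of the cortex–subpallium correlation speaks
of fifty nuclei. The discrepancy is recorded here, not resolved: the
fixture ships all 58 named structures and the correlation stage operates
on whichever nuclei carry data.

## The adhesion model

Parameters (all replaceable via `AdhesionParams`):

| parameter | default | units | rationale |
|---|---|---|---|
| molecules_per_energy_unit | 25,000 | molecules | fixed calibration of 1 energy unit |
| cell_diameter | 10 | µm | spherical-cell approximation |
| contact_thickness | 12 | nm | slab accessible to the membrane-distal EC1 domain (intermembrane spacing from EM, EC-domain length from crystal structures) |
| n_neighbors / contact_fraction | 12 / 1/12 | — | close packing of spheres; 1/12 ≈ 8% of surface per contact |
| participation_fraction | 0.5 | — | half of contact-zone cadherins assumed to trans-dimerise |
| count_both_cells | False | — | see below |
| temperature | 310.15 | K | physiological; provably cancels in relative adhesion |
| gas_constant | 1.987 | cal mol⁻¹ K⁻¹ | dg reported in calories |
| reference | 25,000 molecules of Cdh2, K_D 25.8 µM | — | normalisation anchor |
| kd_reference_state | 1.0 | M | makes ln(K_D) dimensionless |

The equilibrium

    K_D = C_M^2 / C_D,   C_M + 2 C_D = C_T

is solved in closed form, `C_M = (K_D/4)(sqrt(1 + 8 C_T/K_D) - 1)`, which
is numerically stable across C_T/K_D ∈ [1e-4, 1e4] (verified against a
Brent root-finder on the conservation residual to 1e-9 relative;
conservation holds to 1e-12 relative). Limits: C_D → C_T²/K_D as C_T → 0
and C_D → C_T/2 as C_T → ∞, with the saturated-side deviation decaying as
sqrt(K_D/2C_T) — about 2.2% at C_T/K_D = 10³ and below 1% only beyond
C_T/K_D ≈ 5·10³. The work ratio W(2.4m)/W(m) therefore interpolates
between 5.76 (= 2.4², dilute) and 2.4 (saturated); at the default
reference configuration (C_T/K_D ≈ 0.21) it equals 3.80.

Design choices that the underlying formulation leaves open:

- **Which cell's molecules enter C_T.** Counting the participating
  molecules of one cell (default) with Cdh2 K_D = 25.8 µM reproduces the
  3.80 anchor; counting both cells is observationally equivalent for
  ratios (only C_T/K_D matters) and is exposed as `count_both_cells`.
- **Contact fraction 1/12 vs 8%.** C_T is *independent* of the contact
  fraction — participating molecules and contact volume both scale with it
  — so the two conventions give identical results; both are tested.
- **Reference state of the logarithm.** dg uses an explicit 1 M reference
  state; the choice shifts dg per cadherin by a constant and cancels in
  single-cadherin ratios.
- **Global vs per-age reference.** Relative adhesion is normalised to one
  global reference (25,000 Cdh2 molecules), not re-anchored per age;
  configurable via `AdhesionParams`.
- **Zero conventions.** Adjacent-segment fold change is max/min, ∞ when
  exactly one side is zero (flagged), 1 when both are; plate ratios use
  log2 with ±∞ sentinels for one-sided zeros and missing for both-zero.

K_D values ship in a CSV with per-entry source tags and are inputs, not
constants. Only the Cdh1 and Cdh2 entries carry literature (analytical
ultracentrifugation) provenance; the remaining entries are
order-of-magnitude placeholders explicitly tagged `synthetic-placeholder`
in the `source` column and should be replaced with measured affinities for
substantive use. No analysis in the test suite or acceptance script
depends on a placeholder value. Heterophilic binding and combinatorial
cadherin codes are out of scope: the model treats one cadherin at a time,
so reported adhesion differences are lower bounds on what combinatorial
binding could produce.

## Correlation and comparison analyses

- Pearson r with two-sided p from the t-transform (n − 2 dof), via
  scipy; a constant vector raises an error rather than returning r = 0.
  Verbal strength bins are closed half-open: low < 0.70 ≤ intermediate
  < 0.90 ≤ high.
- The cortex–subpallium stage correlates 12-gene panel vectors (default
  panel: Cdh2, Cdh13, groups A/B/C with Cdh20 in group B) between each of
  the 54 cortical (area, layer) units and each subpallial nucleus; units
  missing more than 25% of the panel are excluded with a warning. Raw
  energies are paired by default, with a within-unit normalisation switch.
  No multiple-testing correction is applied across the grid (raw r and p
  are reported).
- Plate ratios are displayed as log2(alar/basal) so equal expression sits
  exactly on the zero line.
- The ISH vs scRNA-seq check normalises both modalities to Actb, averages
  per gene (over the frontal/parietal/temporal/occipital × 6-layer grid on
  the ISH side and over neuronal clusters on the other), and applies a
  paired two-sided test across genes — Wilcoxon signed-rank by default, a
  paired t-test as an option; the choice is logged. Note a statistical
  caveat surfaced by simulation: normalising by a *noisy* reference gene
  induces a shared multiplicative shift across all genes of one replicate,
  which correlates the paired differences and inflates the test's type I
  error well above nominal. The synthetic generators therefore accept
  `reference_sigma` so an exact null (noiseless reference) can be
  constructed; under that null the empirical rejection rate is nominal.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
the biology: energies are log-normal (non-negative, multiplicative
structure-to-structure scatter) around `baseline_energy` 5 units with
`noise_sigma` 0.5 (roughly two-fold scatter) over 19 structures and the
seven stages E11.5–P56 by default. Between-gene correlations are embedded
by a Gaussian copula on the log scale; because exponentiation attenuates
linear correlation, the copula correlation is back-computed from the
requested energy-scale target via the exact bivariate-lognormal relation
rho_log = ln(1 + r(e^{sigma²} − 1))/sigma², so the sample Pearson r of the
energies converges to the target at any noise level (mean over 50 seeds
within ±0.02 at n = 500, tested). Jointly infeasible targets are repaired
to the nearest positive-definite matrix and rejected if the repair moves
any entry by more than 0.05. Planted fold-steps multiply one gene's
energies posterior to a segment boundary, giving exact ground truth for
boundary detection. scRNA-seq cluster means follow the same log-normal
model with labelled non-neuronal clusters (377 clusters, 24 non-neuronal
by default, leaving 353 used).

What the generator does **not** emulate — and hence what passing tests do
not certify about real atlas data: spatial autocorrelation between
neighbouring structures, probe-specific sensitivity differences between
genes, heavy-tailed or zero-inflated energy distributions, registration
error, and any dependence between expression level and structure size.

All randomness flows from one numpy `default_rng` seeded by the spec;
identical spec + seed reproduce identical CSV bytes, and every CLI output
carries a header with package version, seed and config hash.

## Problem sizes

The shipped tests and the acceptance script run on desk-scale inputs
chosen to exercise every code path with tight statistical bounds: 19–500
synthetic structures, 50 replicate seeds for correlation recovery, 100
replicates for the null-calibration check, and the full 54 × 58
cortex–subpallium grid. The analysis code itself is vectorised over
pandas/numpy and handles atlas-scale tables (thousands of structures,
all seven stages) without modification.

## Known limitations

- The molecule calibration (25,000 per energy unit) is arbitrary; only
  ratios within one cadherin are calibration-free.
- mRNA is assumed proportional to surface protein.
- The equilibrium model is 3-D mass action in a slab; membrane-tethered
  (2-D) affinity, cis-dimerisation, kinetics and mechanics are out of
  scope, as are heterophilic pairs (the K_D table schema permits adding
  them without breaking changes).
- Expression energies from different probes are not cross-calibrated; the
  adhesion profile inherits that caveat wherever cadherins are compared at
  equal energy.
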
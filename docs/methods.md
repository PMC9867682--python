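# Methods

## Scope and data model

`pterisk` assesses the transfer of six potentially toxic elements
(Cu, Zn, As, Sb, Ba, total Hg) from soils into plants and the human
diet. Inputs are per-sample CSV tables of plant-tissue concentrations
with paired soil pseudo-totals, optional BCR sequential-extraction
tables, and food-concentration tables. The element set is closed: the
toxicity and screening tables below are defined for exactly these six,
and unknown symbols are rejected rather than silently carried.

Concentrations are canonically mg kg⁻¹ dry weight. Total Hg is
conventionally measured and reported in ng g⁻¹; the reader accepts it
in that unit (column `Hg_ng_g`) and divides by 1000 at the boundary.
Summary tables keep Hg in ng g⁻¹ so they read like the survey tables
practitioners know; everything downstream of the boundary is mg kg⁻¹.

## Left-censored values

A cell `<DL` carries only the detection limit. The pipeline applies
**simple DL/2 substitution** uniformly — in summaries, transfer
indices, and the risk cascade alike. The substitution is stated in the
published intake table this package reproduces only for the dietary
calculation; extending it to every stage is the simplest defensible
uniform rule, and all outputs carry a `censored_input`/`n_censored`
flag (plus a substitution count in the run manifest) so users can
exclude affected rows. No maximum-likelihood or Kaplan–Meier censored
estimator is provided: with the short, heavily-rounded tables this
pipeline targets, DL/2 is the method actually used in the field, and a
fancier estimator would change numbers without a validation anchor.

## BCR fractions and transfer indices

A BCR row holds steps S1 (acetic-acid exchangeable/carbonate), S2
(hydroxylamine-reducible), S3 (peroxide/ammonium-acetate oxidizable)
and an aqua-regia pseudo-total. Fraction percentages are
`100·s_k/pseudo_total`; the residual percentage is defined as the
complement, so the four percentages always sum to 100 even when the
measured steps slightly over- or under-recover. A labile sum more than
10% above the pseudo-total — beyond routine sequential-extraction QA
tolerance — sets a recovery warning but still computes. The labile
(plant-available) pool is S1+S2+S3.

BAC = C_plant/C_soil uses the pseudo-total; BC = C_plant/C_labile uses
the labile pool, so BC ≥ BAC whenever labile ≤ pseudo-total. Zero
denominators raise rather than returning infinities. BAC classes use
the customary decade bands with left-closed boundaries — <0.01 very
weak, [0.01, 0.1) weak, [0.1, 1) moderate absorption, ≥1 strong
accumulation — because the verbal categories in survey tables need an
explicit numeric convention to be reproducible.

When a per-sample reference table (e.g. a supplementary spreadsheet of
a published survey) is available, the same `element_summaries` /
`transfer_table` path doubles as a validation route: summarise, then
compare means and SDs against the reference. The test suite exercises
this path on synthetic data, where the reference is the generating
truth.

## Dietary risk cascade

Per food and element:

    DIR = Σ C_food · IR_food / BW                      [per-food terms reported]
    ADD = DIR · 10⁻³ · (EF·ED) / AT
    HQ  = ADD_nc / RfD        HQt = Σ_elements HQ
    CR  = ADD_c · SF          CRt = Σ_elements CR

with AT = ED·365 days (non-carcinogenic) or lifetime·365 days
(carcinogenic). With the default EF = 365 d y⁻¹ these collapse to
ADD_nc = DIR·10⁻³ and ADD_c = ADD_nc·ED/lifetime — identities the test
suite asserts for all inputs.

**Unit modes.** The published intake tables this cascade reproduces
keep IR in grams inside DIR = C·IR/BW, which makes DIR numerically
1000× a dimensionally consistent mg kg⁻¹(bw) day⁻¹ intake. The default
`as_published` mode reproduces those tables; `unit_consistent` applies
the g→kg factor. ADD, HQ and CR are identical in both modes because
the 10⁻³ conversion already enters ADD. The PMTDI screen compares the
as-published DIR against the PMTDI, again matching the published
convention; users comparing on a strict dimensional basis should use
`unit_consistent` and be aware the screen then flags far less. This
mismatch is surfaced (mode recorded in every manifest) rather than
silently corrected, because the published tables are the package's
validation surface.

**Thresholds.** Exceedance is strict (`>`): HQ and HQt against 1, CR
against 10⁻⁶, CRt against 10⁻⁴, DIR against the element's PMTDI, and
forage means against the ruminant limits (Cu 10 mg kg⁻¹ complete feed;
Zn 22.8 mg kg⁻¹ daily requirement for cattle). Values exactly at a
threshold do not flag, since the levels are defined as acceptable
values, not as the first unacceptable ones.

**Parameter defaults** (all overridable via a flat YAML file):
IR rice 125.2, corn 50.0, cassava 42.0, tea 10.9 g person⁻¹ day⁻¹;
BW 70 kg; EF 365 d y⁻¹; ED 30 y; lifetime 70 y. RfD (mg kg⁻¹ d⁻¹):
Cu 4.0×10⁻², Zn 3.0×10⁻¹, As 3.0×10⁻⁴, Sb 4.0×10⁻⁴, Ba 2.0×10⁻¹,
Hg 3.0×10⁻⁴. SF: Cu 1.7, As 1.5 (the others have none and are excluded
from CRt). PMTDI (mg kg⁻¹ bw d⁻¹): Cu 0.5, Zn 1, As 0.0021, Sb 0.006,
Ba 0.02, Hg 0.0006. Elements lacking an RfD or SF are reported absent,
never imputed as zero hazard.

**Known inconsistencies in the reference tables.** The built-in food
fixture reconstructs concentrations from the published intake table at
full precision (e.g. rice As 0.15 mg kg⁻¹ where the comparative table
rounds to 0.2), so the DIR and Sb-HQ values reproduce to printed
precision. Two published numbers cannot be reproduced from the
published formulas themselves and are deliberately not asserted
anywhere: the corn Sb hazard quotient (printed 18.304; the formula
chain gives 8.304, consistent with a typographic leading "1") and the
printed per-element carcinogenic-risk magnitudes (≈2.2–2.9× smaller
than the ADD×SF chain yields). The cascade implements the formulas;
the corresponding identities (ADD-mode ratio, linearity, additivity)
are property-tested instead. Similarly, the published tea-leaf Hg
concentration (0.002 mg kg⁻¹) is inconsistent with the tea Hg intakes
it should produce; the fixture follows the intakes.

One published prose statement conflicts with its own table: cassava As
(DIR 0.030 from the DL/2 rule) is described as not exceeding the
As PMTDI of 0.0021, but 0.030 > 0.0021 (and > the 0.002 rounding shown
in the table row). The screen emits the arithmetic flag.

## Statistics

Summaries (n, censored count, min, max, mean, sample SD) are computed
on substituted values in reporting units. Pearson correlations come
with two-sided p-values from the t distribution on n−2 df; pairs with
fewer than 3 complete observations or zero variance are reported
absent. Ward's-method clustering treats each element as a leaf whose
coordinates are its (by default z-scored) per-sample concentrations
with Euclidean distances; standardisation is the default because
ng g⁻¹ Hg and mg kg⁻¹ Ba live orders of magnitude apart, and can be
disabled (`standardize=False`) to probe sensitivity. The linkage is
computed by scipy's Ward implementation (Lance–Williams recurrence);
the test suite cross-checks it against an independent brute-force
agglomerator that recomputes the within-cluster variance increase from
raw member coordinates on all ≤5-leaf instances, and asserts the
ultrametric monotonicity of merge heights. Dendrograms serialise as an
ordered merge list (JSON) or Newick text.

## Synthetic surveys

The generator emulates a mining-impacted survey of 75 plant/soil pairs
(the default matching the scale of the survey the package reproduces)
with 12 BCR-characterised soils:

- **Soil marginals**: log-normal per element, with (mean, SD) on the
  natural scale set to the published survey summary — Cu (70.3, 61.1),
  Zn (54.4, 27.5), As (110.6, 171.0), Sb (16.1, 6.3), Ba (310.9,
  166.8) mg kg⁻¹, Hg (276.1, 797.7) ng g⁻¹. Log-normality is the
  standard choice for positive, right-skewed concentrations whose SD
  rivals the mean.
- **Dependence**: a Gaussian copula with two blocks, {Cu, Zn} and
  {As, Sb, Ba, Hg}, within-block correlation ρ = 0.7 on the normal
  scores. The blocks mirror the element association the survey found,
  giving the clustering stage a recoverable truth; ρ = 0.7 keeps the
  split unambiguous at n = 75 while leaving realistic scatter.
- **Plants**: C_plant = t · C_soil · exp(σ_t·ε), with transfer factors
  t set to the survey's mean BACs (Cu 0.46, Zn 0.70, As 0.06, Sb 0.48,
  Ba 0.14, Hg 0.27) and σ_t = 0.6. Under this model the geometric mean
  of per-sample BACs is the natural estimator of t (the arithmetic
  mean is biased upward by exp(σ_t²/2)), which the recovery tests use.
- **BCR**: (S1, S2, S3, residual) ~ Dirichlet(c·π)·pseudo_total with
  expected shares π matching the published step means (Cu labile
  17.94%, As 1.83% — the published As step means sum to 1.83 although
  their rounded total is printed 1.82) and concentration c = 60, which
  puts ~±5 pp sample-to-sample spread on the Cu labile share. The
  residual closes the balance exactly.
- **Censoring**: values below the element's detection limit are
  written as `<DL`. Defaults follow the survey's reported limits —
  plants: As 0.1, Sb 1.0, Ba 5.0 mg kg⁻¹, Hg 0.1 ng g⁻¹ (Cu/Zn 0.5,
  rarely binding); soils: As 0.8, Sb 0.6, Cu/Zn/Ba 5.0 mg kg⁻¹,
  Hg 5.0 ng g⁻¹.

What the generator does **not** emulate: spatial structure and
distance-to-tailings gradients, taxon-specific uptake (every sample
shares one transfer factor per element, while real species differ
strongly, e.g. As excluders), correlated measurement error between
plant and soil, and the survey's exact censoring pattern. Passing
recovery tests therefore show the estimators are consistent under the
assumed sampling model, not that the model captures every feature of
field data.

## Numerical conventions

Full floating precision everywhere; rounding only at report rendering
(3 decimals for DIR/HQ, 5 for Hg intakes, 2 for indices). Exceedance
uses strict inequality. Ward merge ties are resolved by scipy's
deterministic candidate ordering; with continuous data ties have
measure zero. The test suite's Monte-Carlo checks run at n = 500 with
fixed seeds and 2-standard-error bands, sizes at which the whole suite
runs in seconds.

## Limitations

Adult-resident scenario only (no child, dermal or inhalation routes);
no probabilistic exposure assessment; no geochemical speciation
modelling; DL/2 is the only censoring treatment; the BAC class
boundaries are a convention, not a measurement.
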
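# Methods

## MAG quality and BAKO screening

Genome quality uses the MIMAG-style score `completeness − 5 × contamination`
(the contamination weight is a parameter of `quality_score`).  The filter
keeps MAGs with completeness strictly above 80 % and contamination strictly
below 10 %; both thresholds and an inclusive-boundary mode are exposed
because prose statements like "over 80 %" are ambiguous exactly at the
boundary.  Input catalogs are assumed dereplicated; only exact duplicate MAG
ids are dropped.  A MAG is a BAMAG iff its KO set intersects the screened
BAKO catalog; per-KO MAG counts and per-KO gene counts (copy numbers ≥ 1 per
carrier) are tallied separately, which is why gene-level and MAG-level
percentages differ.  Printed-style percentages round to the nearest integer
at ≥ 1 % and to two decimals below 1 %; the raw floats are authoritative and
the printed form is cosmetic output only.

The shipped BAKO catalog is the named core set (baiN/K07007, BASS/K03453,
BSH/K01442, SLC10A7/K14347, 3α-HSDH/K00038, 7α-HSDH/K00076, baiB/K15868,
AMACR/K01796, HADH/K00022) and is user-extensible to the full 82-KO screen;
the catalog is a plain mapping, so adding entries needs no code change.
K00038 is kept as 3α-HSDH and AMACR as K01796, the internally consistent
reading of the two overlapping attributions in the source annotations.

Species names are normalised by lowercasing, whitespace collapsing,
"Candidatus" stripping and an optional GTDB→NCBI map before set operations
(BAMD = species-level BAMAGs ∪ isolate carriers; T-BAMD = BAMD ∩ detected
species; DFM-s = union of the three differential-species lists).
Placeholder names ("Foo sp. 1") stay distinct identities on purpose:
collapsing them would merge genuinely different genomes.

## Bile-acid quantification

Concentrations are nmol/L after the dilution correction C_M = C_F·V_F/V_S.
The classification scheme follows the targeted-metabolomics panel verbatim,
including the sulfated species listed as primary; analytes outside the
scheme are flagged `unknown`, never dropped, and the per-sample total
includes every measured analyte, so primary + secondary ≤ total.

The transformed fraction is the concentration-weighted share of the pool
held by bile acids outside the exogenous (supplemented) set — HCA, CDCA, CA,
HDCA, TCDCA, TCA by default — evaluated on group-mean concentrations.  The
group-mean (rather than per-sample) convention matches statements of the
form "transformed BAs accounted for X % of the treated group".

Differential bile acids use the joint rule VIP > 1 and p < α (.05).  The
t-test is classical equal-variance Student by default (Welch by flag); VIP
comes from a single-component PLS-DA on autoscaled data.  Because the joint
rule intersects two criteria, its null rejection rate is never above the
t-test's marginal α — the relevant calibration check is on the marginal
rate.  Zero-variance analytes have undefined VIP and are reported
non-significant with a `degenerate` flag.

The VIP is computed from the PLS weight vectors as
VIP_j = sqrt(p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a), with SS_a the response
variance captured by component a; Σ_j VIP_j² = p holds identically.  A plain
PLS-DA replaces the orthogonalised variant found in commercial software: with
a single predictive component the VIP ordering is the same, and one component
is the default here for that reason (`n_components` is exposed).

## Biotransformation graph

A bile acid is its C3/C6/C7/C12 states (absent, α-OH, β-OH, oxo) plus the
C5 ring-junction configuration; side chains and conjugation are carried as
inert tags.  Four operator classes act on one position: epimerization
(flips an OH's orientation; at C5 flips the configuration), dehydroxylation
(removes an OH — deliberately orientation-agnostic, since pathway usage
labels the 7β-OH case "7α-dehydroxylation" too), oxidation (OH→oxo) and
reduction (oxo→OH with a target orientation).  Epimerization can be emitted
directly or decomposed into its oxidation/reduction half-steps
(`composite_via_oxo`), with oxo intermediates appearing only when they are
themselves in the node set; `both` is the union and is the default for
pathway validation, because the stated pathway mixes both readings (e.g.
CA→3-DHCA, an oxidation, is described as the first half of a
3β-epimerization, and DHLCA→isoLCA is the reduction half).  3-DHCA is
encoded 3-oxo (dehydro = oxo by nomenclature).  Enumeration tries every
(structure, operator) pair and keeps edges whose product is in the input
set; this brute-force definition is cheap (≤ 30 structures × 21 operators)
and doubles as its own specification, which the tests verify independently.

## Correlation networks

Spearman ρ uses average ranks.  For n ≤ 9 samples the two-sided p is exact:
all n! orderings of the observed y ranks are enumerated (valid under ties).
The |ρ| = 1 edge rule uses tolerance 1e-12 on the rank arithmetic; with tied
ranks |ρ| = 1 is unattainable, so tied features simply cannot form edges
under this rule.  The BH rule adjusts across the tested family only — for a
bipartite design (differential BAs × differential metabolites) the family is
the bipartite pair list, not the full matrix.  Hubs are ranked by degree
with an alphabetical tie-break and an explicit tie flag.

## Mediation

Linear-linear models only, fitted by OLS; ACME = a·b, ADE = c′, total =
a·b + c′ exactly (same covariates in both equations).  Binary treatments
stay on their 0/1 scale; continuous treatments are standardised to unit SD
so effects are per 1-SD change (flag to disable).  Bootstrap is
nonparametric case resampling with percentile intervals; resamples with a
constant treatment are redrawn (≤ 100 attempts).  The bootstrap p-value is
the two-sided sign test on the ACME draws, floored at 1/sims.  Without
covariates the per-resample OLS reduces to closed-form covariance algebra
and is fully vectorised, which keeps 1000 draws at n = 200 in milliseconds.

Sensitivity to sequential ignorability fixes the correlation ρ between the
two structural errors.  Writing σ₁, σ₂ for the residual SDs of the mediator
model and the reduced-form outcome model (Y on T alone) and ρ̃ for their
residual correlation, the constrained estimate is

    ACME(ρ) = a · (σ₂/σ₁) · (ρ̃ − ρ·sqrt((1 − ρ̃²)/(1 − ρ²)))

so ACME(0) equals the unadjusted estimate identically and the curve crosses
zero at ρ = ρ̃.  The tests verify this closed form against a numeric oracle
that maximises the joint Gaussian likelihood with ρ fixed.  Exactly
collinear designs (a noiseless mediator) raise rather than silently
returning a minimum-norm solution.

## Synthetic generators

The generators define the study conditions for all stochastic tests:

* **MAG catalogs** — completeness ~ Normal(88, 6) clipped to [50, 100],
  contamination ~ Exponential(mean 3) clipped to [0, 25] (≈ 88 % of draws
  pass the quality filter); BAKO carriage is an independent Bernoulli per KO
  at prevalences mirroring the screened compendium (0.84/0.41/0.12 for the
  three core KOs, rare for the rest); carriers get geometric copy numbers
  with mean 1.3, which reproduces gene/MAG count ratios in the observed
  1.3–1.8 range; taxonomy strings are drawn from a ~30-entry weighted rumen
  dictionary dominated by Lachnospiraceae/Bacteroidaceae/Prevotella, with
  some species-less entries so species-level logic is exercised.
* **Concentration matrices** — every scheme bile acid has a baseline mean of
  20 nmol/L; the treated group receives 1000 nmol/L spikes of the six
  exogenous bile acids, of which fixed fractions are transferred along
  pathway edges in one mass-conserving pass (defaults: CA → UCA/3-DHCA/alloCA
  .15/.14/.13, HCA → ω-MCA/HDCA .25/.25, CDCA → LCA/UDCA .27/.27,
  HDCA → isoHDCA/6-ketoLCA/MDCA .15/.12/.08), plus multiplicative effects
  (3–6×) on five microbially produced bile acids; noise is multiplicative
  log-normal at CV 20 %.  These defaults put the expected transformed
  fraction of the treated pool at 0.350.  n = 6 samples per group, matching
  the experimental designs.
* **Mediation triads** — balanced binary treatment, a = 0.8, b = 0.5,
  c′ = 0.4, unit error SDs, n = 200; ground-truth ACME 0.4 and proportion
  mediated 0.5 are stored with the data.

What the generators do **not** emulate: sequencing reads, assembly and
binning artefacts, compositionality of abundance data, inter-analyte
correlation in baseline concentrations, batch effects, or non-Gaussian
mediation errors.  Passing tests therefore demonstrate correctness of the
computations and calibration under the stated models, not robustness of the
study's biological conclusions to real-data pathologies.

## Problem sizes and determinism

Stochastic checks use 5000–10 000 MAG catalogs, 1000 null simulations for
test calibration, and 500 replicates × 1000 bootstrap draws for mediation
coverage — sizes at which the Monte-Carlo tolerances in the tests (3 SEs)
are meaningful while the whole suite stays fast.  Every generator and the
bootstrap consume a single integer seed through `numpy`'s Generator;
identical configurations produce byte-identical serialised outputs, and
pipeline outputs carry a provenance header (version, config hash, seed).

## Known limitations

* The dataset-scale published numbers (8645/9371 high-quality MAGs, the 26
  DFM∩BAMD species, the specific mediation percentages) depend on external
  sequence archives and are out of computational reach here; the package
  reproduces the published *worked examples* (count→percentage tables, the
  pathway edge set, the mutual differential list) and validates everything
  else by planted-parameter recovery.
* Binary outcomes, multiple mediators and treatment–mediator interaction are
  not supported in the mediation module.
* No chemistry beyond the five ring positions: no SMILES, no side-chain
  stereochemistry, no kinetics, and conjugation is modelled only as
  tag-stripping (BSH) off the graph.
* LEfSe and ANCOM-BC are consumed as name lists, never re-implemented.
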
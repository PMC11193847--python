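# rumenba

Analysis toolkit for microbial bile-acid (BA) metabolism in the rumen.

Ruminal microbes can transform liver-derived primary bile acids (CA, CDCA,
HCA, ...) into secondary bile acids (HDCA, LCA, UDCA, ...) through a small
set of ring-position reactions — epimerization, 7α-dehydroxylation,
oxidation/reduction at C3/C6/C7/C12 — carried out by enzymes such as bile
salt hydrolase (BSH), hydroxysteroid dehydrogenases (HSDHs) and the
*bai*-operon pathway.  `rumenba` implements the computational side of a study
of this system end to end:

* **MAG screening** (`magscreen`): quality-score (completeness − 5 ×
  contamination) and filter metagenome-assembled genomes (> 80 % complete,
  < 10 % contaminated), screen MAGs and cultured-isolate annotations for
  bile-acid-metabolism KEGG orthologs (BAKOs: *baiN* K07007, *BASS* K03453,
  *BSH* K01442, ...), summarise per-KO prevalences, taxonomy composition,
  and the BAMD set logic (union of BAKO-carrying species from MAGs and
  isolates, intersected with detected and differential species).
* **Quantitative BA pools** (`baquant`): dilution-corrected concentrations
  (C_M = C_F·V_F / V_S, nmol/L), primary/secondary/unclassified
  classification, per-sample pool totals, the transformed (non-exogenous)
  fraction of a supplemented pool, and differential bile acids by the joint
  rule VIP > 1 (single-component PLS-DA) ∧ p < .05 (Student's t or Wilcoxon).
* **Biotransformation graphs** (`bagraph`): bile acids encoded by their
  C3/C6/C7/C12 states and C5 configuration; reaction operators applied
  exhaustively to enumerate the transformation graph among any BA set and
  validate it against the proposed rumen pathway
  (CA→UCA, HCA→HDCA, CDCA→UDCA→LCA, DHLCA→isoLCA, ...).
* **Correlation networks** (`banet`): pairwise Spearman ρ with exact
  permutation p-values at small n; edges by the |ρ| = 1 rule (the smallest
  attainable p at n = 5) or by Benjamini–Hochberg-adjusted p < .05.
* **Mediation analysis** (`mediate`): linear structural equations
  M = a·T + ε_M, Y = c′·T + b·M + ε_Y; ACME = a·b, ADE = c′,
  proportion mediated = ACME/(ACME + ADE); nonparametric bootstrap
  percentile intervals (1000 draws) and the sequential-ignorability
  sensitivity curve ACME(ρ) over the assumed error correlation ρ.
* **Synthetic data** (`synthdata`): generators with planted ground truth —
  MAG catalogs with Bernoulli BAKO carriage, concentration matrices whose
  exogenous spikes are partially converted along pathway edges
  (mass-conserving before noise), and mediation triads — so every stage is
  testable without the original sequencing archives.

## Worked example

```python
from rumenba import magscreen, bagraph, mediate, synthdata

# Published per-KO counts -> proportions as printed in figure legends
s = magscreen.ScreenSummary.from_counts(
    {"K07007": 3013, "K03453": 1482, "K01442": 431},
    {"K07007": 4623, "K03453": 2716, "K01442": 466},
    n_bamags=3585, n_filtered_mags=3954)
print(magscreen.summarize_proportions(s).to_string(index=False))

# Enumerate the biotransformation graph and check the proposed pathway
g = bagraph.enumerate_edges(bagraph.STRUCTURES.values(), "both")
rep = bagraph.validate_pathway(g, [(a, b) for a, b, _ in
                                   bagraph.RUMEN_PATHWAY_EDGES])
print("pathway edges found:", len(rep["found"]), "missing:",
      len(rep["missing"]))

# Bootstrap mediation on a synthetic triad (planted ACME = 0.8 x 0.5 = 0.4)
d = synthdata.gen_mediation_data(synthdata.SynthConfig(seed=1))
X = mediate.MediationInput(d["treatment"], d["mediator"], d["outcome"])
fit = mediate.bootstrap_mediation(X, sims=1000, seed=1)
print(f"ACME={fit.acme:.3f} 95% CI=({fit.ci['acme'][0]:.3f}, "
      f"{fit.ci['acme'][1]:.3f}) prop_mediated={fit.prop_mediated:.3f} "
      f"p={fit.p_mediation}")
```

Output:

```
         level     ko  count     value printed
           mag K01442    431 12.022315     12%
           mag K03453   1482 41.338912     41%
           mag K07007   3013 84.044630     84%
          gene K01442    466  5.970532      6%
          gene K03453   2716 34.798206     35%
          gene K07007   4623 59.231262     59%
bamag_fraction          3585 90.667678     91%
pathway edges found: 15 missing: 0
ACME=0.277 95% CI=(0.142, 0.434) prop_mediated=0.440 p=0.001
```

84 % of BAKO-carrying MAGs carry *baiN*, 91 % of high-quality MAGs carry at
least one BAKO, every stated pathway edge is reproduced by the reaction
operators, and the bootstrap recovers a clearly non-zero indirect effect
(truth 0.4) on one simulated dataset of n = 200.

A full synthetic pipeline is also available from the shell:

```bash
rumenba run-all --outdir out --seed 0
```

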
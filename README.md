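# exobench

Benchmarking pathway-analysis methods on simulated exometabolomic profiles
of whole-pathway knockouts in constraint-based metabolic models.

## The problem

Pathway analysis (PA) interprets a metabolic profile — a list of perturbed
metabolites — by finding pathways in which the perturbed metabolites are
over-represented.  For *exometabolomics* (metabolites measured in the
medium, urine, blood) this rests on a strong assumption: that an internal
disruption propagates to measurable extracellular changes concentrated in
the disrupted pathway.  There is no experimental ground truth to test this:
when a real sample's "true" disruption is unknown, a PA method can never be
scored right or wrong.

`exobench` builds that ground truth in silico.  Starting from a
constraint-based metabolic model (SBML L3 + fbc with per-reaction pathway
annotations), it knocks out each pathway in its entirety (all reaction
bounds to [0, 0]), checks that the knockout still supports 10% of the
wild-type maximum biomass, samples steady-state fluxes of the wild-type and
knockout states from the polytope {v : Sv = 0, lb ≤ v ≤ ub, v_bio ≥ floor},
and summarises each exchangeable metabolite as

    z = (mean_KO − mean_WT) / sqrt((sd_WT² + sd_KO²)/2),

positive z meaning more of the metabolite in the medium.  Each z-score
profile is then analysed with

* **ORA** — survival-function p-values p = 1 − Φ(z) thresholded at 0.05
  (uncorrected) define the differential metabolites; each pathway with ≥ 3
  of them is tested with a right-tailed Fisher's exact test against the
  exchangeable background;
* **pre-ranked GSEA** — weighted Kolmogorov–Smirnov enrichment score over
  the metabolites ranked by signed or absolute z, with a 1000-fold
  metabolite-label permutation p-value.

Since the knocked-out pathway is known, each scenario scores the target as
TP / FN (or "not run" when ORA cannot test it) and every other pathway as
FP / TN, aggregated into TPR, FNR, not-run rate (proportions, summing to 1)
and FPR, TNR (mean counts per scenario).  Six intrinsic pathway metrics —
size, exchangeable metabolite ratio, knockout-profile uniqueness score, and
clustering coefficient / degree / neighbourhood connectivity in the
pathway-overlap graph — explain *why* particular pathways evade detection.
See `docs/methods.md` for the full model description.

Audience: metabolomics methodologists evaluating or developing PA tools,
and constraint-based modellers interested in exometabolome simulation.

## Worked example

The package bundles a toy-model generator whose pathway archetypes have
known answers: an *essential* pathway (knockout kills biomass), a *unique
exporter* (knockout leaves a strong specific exometabolomic signature), an
*internal-only* cycle (no exchangeable metabolite — invisible from
outside), a *redundant pair*, and a *blocked* dead end.

```python
from exobench import pipeline, synth

model, truth = synth.generate_toy_model(synth.ToyModelSpec(seed=42))
cfg = pipeline.validate_config({
    "biomass_id": "biomass", "n_samples": 1000, "seed": 42,
    "out_dir": "toy_out",
})
bundle = pipeline.run_benchmark(cfg, model=model)
print(bundle["ledger"].to_string(index=False))
print(bundle["summaries"][["method", "tpr", "fnr", "not_run_rate",
                           "fpr", "conditional_tpr"]].to_string(index=False))
```

prints

```
                pathway                 status  n_reactions
 Essential biosynthesis             infeasible            2
         Internal cycle             functional            3
  Redundant synthesis 1             functional            1
  Redundant synthesis 2             functional            1
    Transport reactions excluded_miscellaneous           19
Unique exporter pathway             functional            2
       Dead-end pathway                blocked            0

       method  tpr  fnr  not_run_rate  fpr  conditional_tpr
          ora 0.25 0.00          0.75 0.00             1.00
  gsea_signed 0.00 1.00          0.00 0.25             0.00
gsea_absolute 0.25 0.75          0.00 0.25             0.25
```

Reading: the essential pathway cannot be simulated (infeasible), the dead
end is removed at pruning, and of the four functional knockouts only the
unique exporter is recovered — a true positive under ORA and under GSEA on
absolute z-scores.  ORA cannot even run on the other three (not-run rate
0.75, but 100% correct on the test it could run), and GSEA on *signed*
z-scores misses the exporter entirely: its knockout raises three metabolites
and lowers one, and the conflicting signs cancel the signed enrichment
score.  The internal-only cycle (exchangeable ratio 0) is a structural
false negative everywhere.  These are exactly the detection biases the
benchmark is designed to expose; on a genome-scale model the same pipeline
quantifies them across ~100+ pathways.

The same run writes TSV reports (scenario ledger, profiles, per-method
enrichment tables, evaluation summary, pathway properties, TP-vs-FN
rank-sum comparisons, PCA coordinates, overlap graph as GraphML) into
`toy_out/`.

A CLI wraps the same pipeline:

```
exobench make-toy --seed 42 --out toy.xml
exobench run --model toy.xml --side toy.side.txt --categories toy.categories.tsv \
             --biomass-id biomass --n-samples 5000 --seed 42 --out toy_out
```

Genome-scale SBML models (e.g. Human-GEM, with its side-compound list and a
pathway-category TSV) are run with the same commands; expect hours of
sampling for ~140 pathway knockouts at 5000 samples each.

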
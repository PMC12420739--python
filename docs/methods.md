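# Methods

## Problem and approach

Pathway analysis (PA) of exometabolomics data assumes that a metabolic
profile measured outside the cell reflects the pathway that was perturbed
inside it.  `exobench` tests that assumption in silico: it knocks out each
metabolic pathway of a constraint-based model in its entirety, simulates the
exometabolomic consequence of the knockout by flux sampling, hands the
simulated profile to the standard PA methods (ORA, pre-ranked GSEA), and
scores whether the knocked-out pathway is recovered among the significant
enrichments.  Because the disruption site is known exactly, every scenario
has a ground-truth answer — something no experimental metabolomics dataset
provides.

## Model preprocessing

The input is an SBML Level 3 (fbc) constraint-based model whose reactions
carry a single pathway ("subsystem") annotation each; a reaction annotated
to two pathways is rejected.  Preprocessing:

1. **Blocked reactions** are those with flux-variability min = max = 0
   (|flux| < `tol`, default 1e-9) under default bounds with no biomass
   requirement.  They are removed; metabolites left without any reaction are
   pruned; pathways whose reaction set empties are recorded as *blocked
   pathways* and leave the scenario pool.
2. **Metabolite pathway sets** collect, per pathway, the base ids of the
   substrates and products of its reactions.  Base ids strip the compartment
   suffix (both `m_c` and `MAM01965s` conventions), so compartmental copies
   count once.  A metabolite can sit in many pathways.  Side compounds
   (water, ATP, ... — supplied as a plain-text list) stay in the sets used
   for enrichment but are excluded from overlap/graph computations and from
   the exchangeable ratio.
3. **The exchangeable background** is the set of base ids having at least
   one exchange reaction (single-metabolite boundary reactions on an
   extracellular metabolite, auto-detected).  Exchange fluxes are
   sign-normalised so positive flux always means export to the medium.
4. Pathways categorised *Miscellaneous* in the category TSV (transport,
   artificial pools) are excluded from knockouts and from the analysis
   universe; they remain in the network for simulation.

## Knockout simulation

A pathway knockout sets every reaction of the pathway to bounds [0, 0].  A
knockout whose maximal biomass falls below `floor_fraction` (default 0.1) of
the wild-type maximum is *infeasible* and produces no profile.  For each
functional knockout, fluxes are sampled from

    {v : S v = 0,  lb <= v <= ub,  v_biomass >= 0.1 * max WT biomass}

with cobra's artificially-centred hit-and-run sampler (FVA warmup, thinning
100, reprojection onto the steady-state subspace every 100 steps to control
numerical drift; residuals stay below 1e-6).  The biomass floor applies to
both states so WT and KO are compared under the same viability constraint.
One wild-type sample set (per model, seed and sample count) is shared by all
knockouts; each knockout sampler derives a stable per-pathway seed from the
run seed, so scenarios are order-independent and individually reproducible.
Zero-dimensional polytopes (everything fixed) are handled by returning
copies of the unique FVA point.  Default `n_samples` is 5000 per state.

Each exchangeable metabolite then receives

    z = (mean_KO - mean_WT) / sqrt((sd_WT^2 + sd_KO^2) / 2)

over its net exchange flux, clipped at ±50 (zero-variance cases: z = 0 for
equal means, ±50 otherwise).  The z-score uses the *population* spread of
the sampled flux distributions, not the standard error, so it measures how
far the knockout moves a metabolite relative to the flux variability the
network allows — it does not shrink towards significance as `n_samples`
grows.  The exact standardisation is a declared design choice of this
package, isolated in one function, and is the natural swap-in point for
alternative profile statistics.

## Pathway analysis

**ORA.**  z-scores become p-values through the standard-normal survival
function p = 1 − Φ(z); metabolites with p ≤ `alpha_da` (0.05, uncorrected)
form the differentially-abundant (DA) set.  Note the survival function is
one-sided: only metabolites that *increase* in the medium can be DA
(`ora_da_stat="abs"` switches to |z| if both directions should count).  Each
pathway is tested right-tailed with Fisher's exact test on the 2×2 table
drawn inside the exchangeable background; pathways with fewer than
`min_hits` (3) DA members are *non-testable*.  No multiple-testing
correction is applied anywhere, deliberately, to preserve a minimal amount
of signal at the 0.05 threshold.

**Pre-ranked GSEA.**  Metabolites are ranked by signed z or |z|.  The
enrichment score is the weighted Kolmogorov–Smirnov statistic: hits add
|score|^w / Σ_hits |score|^w (w = 1), misses subtract 1/(N − N_hits); the ES
is the running-sum value of maximal absolute deviation and lies in [−1, 1].
Significance comes from permuting metabolite labels over the fixed ranked
scores (1000 permutations), one-sided within the observed ES sign and
normalised by the same-sign permutation count with a +1 pseudo-count.  The
same-sign normalisation keeps sign-conditional p-values at their nominal
level under the null (an all-permutation denominator would run at twice
nominal); this matches the classical GSEA convention.

## Evaluation

Per scenario, the knocked-out (target) pathway is **TP** if significant
(p ≤ 0.05), **FN** if tested and not significant, and **not-run** if ORA
could not test it; every other pathway in the universe of functional,
non-miscellaneous pathways is **FP** if significant, **TN** otherwise
(non-testable non-targets are TN — they were not detected).  TPR, FNR and
the not-run rate are proportions of scenarios and sum to 1 exactly; FPR and
TNR are the *mean counts* of FP and TN pathways per scenario (so with a
constant universe U, FPR + TNR = U − 1).  The conditional TPR,
TP / (TP + FN), describes ORA's accuracy on the scenarios it could test.

## Pathway properties

Six per-pathway metrics explain detectability:

* **size** — metabolite count of the pathway set (side compounds included
  by default; both variants are available);
* **exchangeable ratio** — exchangeable non-side metabolites over all
  non-side metabolites: how visible the pathway can be in an exometabolome;
* **uniqueness score** — Σ 1/n_m over the knockout profile's |z| ≥ 2
  metabolites, n_m being the number of profiles containing m.  Summed over
  all scenarios, each distinct thresholded metabolite contributes exactly 1
  (a conservation identity used as a test);
* **clustering coefficient, degree, neighbourhood connectivity** of the
  pathway's node in the pathway-overlap graph (edge iff ≥ 1 shared non-side
  metabolite, weight = shared count; statistics are computed on the
  unweighted topology, the weights are kept for export and layout).

TP-vs-FN differences per metric and method are assessed with two-sided
rank-sum (Mann–Whitney) tests, Benjamini–Hochberg adjusted over the whole
metric × method family.  A PCA of the standardised metric table (constant
columns dropped, component signs fixed by the largest-magnitude loading)
summarises the separation.

## The synthetic toy models

The generator stitches archetype templates onto a common core (nutrient
import → precursors → biomass).  The archetypes realise the structural
situations the benchmark's conclusions rest on: an *essential* pathway
(sole producer of a biomass precursor ⇒ infeasible knockout), a *unique
exporter* (consumes three imported substrates, exports a private product ⇒
strong specific exometabolomic signature, the designed true positive), an
*internal-only* cycle (no exchangeable member, exchangeable ratio 0 ⇒ its
knockout is invisible, the designed false negative), a *redundant pair*
(either member covers the precursor demand ⇒ functional knockouts with
partial signatures), and a *blocked* dead end (removed at pruning).
Archetypes are fixed templates rather than random graphs because the test
bench needs exact ground truth; the seed only jitters exchange capacities.
The reference fixture has 6 pathways (one of each, the redundant pair
twice), 3 side compounds and a miscellaneous transport pseudo-pathway.

What the toy does **not** emulate: Human-scale pathway-size and overlap
distributions, compartmentalisation beyond cytosol/extracellular, loops
through cofactor pools, or realistic flux magnitudes.  Tests passing on the
toy therefore certify the machinery (sampling validity, statistical
calibration, exact recovery of designed structure), not the quantitative
rates any particular genome-scale model will produce.  The same code runs
unchanged on a genome-scale SBML input (e.g. a human reconstruction with
~140 pathways), where a full run is a matter of hours of sampling rather
than minutes.

## Numerical choices

* Blocked-reaction tolerance 1e-9; steady-state/bounds validation tolerance
  1e-6; z clip ±50; |z| threshold 2 for the uniqueness score.
* Sampled fluxes of zero-width-bound (knocked-out) reactions are pinned
  exactly to the bound: FVA warmup optima can carry ~1e-12 solver noise.
* Ranked lists break score ties by metabolite id, making every downstream
  statistic deterministic.
* GSEA permutations draw hit positions without replacement; the null is
  cached per hit-set size within a profile.
* Enrichment candidates and the FP/TN universe are the functional,
  non-miscellaneous pathways; the overlap graph likewise excludes
  miscellaneous pathways, whose shared transport metabolites would dominate
  every statistic.

## Test and report problem sizes

The bundled test bench simulates the 6-pathway toy at the standard 5000
samples per state (its acceptance layer includes a 5000-sample wild-type
split-half null calibration and 1000-permutation GSEA runs); statistical
calibration of GSEA p-values uses 500 independent synthetic null profiles
of 40 metabolites at 200 permutations each.  These sizes were chosen so the
whole bench completes on a single CPU in minutes while leaving the
statistical assertions comfortable margins.

## Known limitations

* The profile statistic is a standardised mean difference of sampled
  exchange fluxes; other summaries (median-based, rank-based) may rank
  metabolites differently near ties.
* Hit-and-run samples are autocorrelated; thinning 100 makes the effective
  sample size large but not equal to `n_samples`.
* ORA's default survival-function conversion ignores decreased metabolites;
  this mirrors the stated procedure of the benchmarked workflow, and the
  `abs` switch exists because the biological intent is arguable.
* No topology-aware PA methods, no normalised enrichment score or FDR
  q-values, no gene-level knockouts, no endometabolome prediction.
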
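# prcdeconv

Comparative interactome deconvolution for multi-bait AP-MS / ChIP-MS
screens, built around the question of which preys of an epigenetic hub
protein (a PRC1 subunit such as BMI1) belong to the canonical complex
variant, the non-canonical variant, the shared catalytic core, or bind the
hub independently of the complex altogether.

It is aimed at proteomics analysts working with bait–prey pull-down
designs: protein × sample MS2-intensity tables with replicate structure
(cell lines × genotype conditions × baits × cultures × technical
replicates), no-antibody mock pull-downs, and a CRAPome-style contaminant
frequency repository.

## What it computes

1. **Filtering** — "detected" means a non-missing intensity in ≥
   `min_runs` replicate runs; preys seen in any mock run are removed
   (bead background), then preys whose contaminant-repository frequency
   exceeds `max_freq` are removed. Every filter records how many proteins
   it dropped.
2. **Modulation concordance** — per prey and cell line, replicate runs are
   averaged and the fold-change of the hub-modulated condition over its
   matched empty-backbone control is formed,

   `log2FC = log2((x̄_mod + ε) / (x̄_ctrl + ε))`,

   with a two-way fixed-effects ANOVA (cell line × genotype) on log
   intensities giving a per-prey p-value. A prey is **concordant** when it
   goes up in the overexpression line and down in the knockdown line —
   evidence of stoichiometric coupling to the hub.
3. **Set deconvolution** — exact Venn partitions across cell lines and
   baits. Cross-line shared sets are intersected between the hub bait and
   a variant-defining partner bait (e.g. RYBP) and a catalytic-mark
   chromatome (e.g. H2AK119ub), assigning each protein one membership
   category: `canonical_only`, `shared_core`, `noncanonical_only`,
   `chromatome_catalytic`, `chromatome_independent` or
   `bait_independent_unassigned`.
4. **Overlap statistics** — upper-tail hypergeometric over-representation
   (p = P(X ≥ k) for X ~ Hypergeom(N, K, n)), the two-sided Fisher exact
   test by exact integer enumeration, Benjamini–Hochberg FDR, and a
   differential-exon-usage (DEU) overlap analysis that thresholds a
   per-exon p-value table at BH-adjusted p < α, deduplicates to genes and
   tests the gene set against reference collections.
5. **Synthetic screens** — a generator that emulates the full design
   (planted complexes, contaminants, log-normal noise, dropout,
   modulation coupling) together with the ground truth needed to score
   every stage.

## Worked example

Run the bundled demonstration (a 500-protein synthetic screen with three
planted complexes and 50 contaminants, simulated, filtered, deconvolved,
quantified and scored in one call):

```sh
prcdeconv run --out-dir demo --seed 1
```

The summary it prints (also written to `demo/summary.json`) contains,
among others:

```
"filter": { "BMI1|U87MG": { "n_proteins": 85,
    "filters": [["detect_present(min_runs=2)", 0],
                ["mock_subtraction", 36],
                ["contaminant_filter(max_freq=0.1)", 3]] }, ... }
"membership_counts": { "canonical_only": 60, "shared_core": 25,
                       "noncanonical_only": 40,
                       "bait_independent_unassigned": 2, ... }
"concordance_counts": { "concordant": 85, "discordant": 0, "unchanged": 0 }
"concordant_recovery": { "n_coupled_in_scope": 85,
                         "precision": 1.0, "recall": 1.0 }
```

Reading: of the hub-bait detections in line U87MG, mock subtraction
removed 36 bead-background proteins and the frequency filter 3 more,
leaving 85 interactors — exactly the planted hub-bound complement (60
canonical-complex members + 25 shared-core members). The deconvolution
assigned all three planted complexes their correct category (two sporadic
background proteins remain unassigned), and all 85 hub-coupled preys were
classified concordant with the planted modulation.

Each stage is also available separately (`prcdeconv simulate / filter /
quantify / deconvolve / enrich / score`) and as plain library functions
(`prcdeconv.detect_present`, `subtract_mock`, `filter_contaminants`,
`quantify_modulation`, `assign_membership`, `hypergeom_overlap`, ...).

## Layout

```
src/prcdeconv/
  synthetic.py       synthetic screens + ground truth
  filtering.py       intensity-table I/O, detection rule, mock & contaminant filters
  modulation.py      normalization, replicate averaging, log2FC, ANOVA, concordance
  deconvolution.py   Venn partitions, membership assignment, recovery metrics
  overlap.py         hypergeometric / Fisher / BH / DEU overlap statistics
  pipeline.py        end-to-end pipeline with summary + log bundle
  cli.py             click CLI (`prcdeconv`)
docs/methods.md      model, assumptions, parameter choices, limitations
```
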
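# Methods

## The analysis model

A multi-bait pull-down screen measures, for every identified protein, an
MS2 spectral intensity in each run. The analysis treats these values in
two distinct regimes:

* **Presence/absence** for interactor definition. A protein is *detected*
  in an experiment (one bait × cell line × condition) when it has a
  non-missing intensity in at least `min_runs` of the replicate runs
  (default 2 of the 4 runs formed by 2 cultures × 2 technical
  replicates). Interactor lists are then pruned by two binary filters:
  any detection in a no-antibody mock run removes the protein (strict
  mock subtraction — bead background is assumed fully represented in the
  mocks), and a repository frequency above `max_freq` (default 0.10)
  removes proteins that are promiscuous in negative-control AP-MS runs.
  An intensity-ratio variant of mock subtraction is deliberately not
  implemented; the mock filter is binary by design.
* **Quantitative intensities** for modulation analysis. Replicate runs are
  averaged arithmetically on the raw intensity scale and compared as
  `log2((x̄_mod + ε)/(x̄_ctrl + ε))` per cell line, with ε = 1 intensity
  unit by default — negligible against raw MS2 intensities (~1e6) but
  keeping fold-changes finite. Significance comes from a two-way
  fixed-effects ANOVA on log-transformed intensities with factors cell
  line and genotype (control vs modulated); the reported p-value is the
  type-II F test of the genotype main effect, with the interaction term
  retained in the error model. Log transformation reflects the
  multiplicative noise of spectral intensities. When the residual
  variance is exactly zero the test is reported as undefined (flagged),
  never silently 0 or 1.

A prey is **concordant** when its fold-change is positive in the
overexpression-modulated line and negative in the knockdown-modulated
line, both beyond `fc_min` (default 0 — any sign-consistent change
counts, and a tie at exactly `fc_min` resolves to *unchanged*,
conservatively). Optional `alpha` additionally requires a defined
p-value below the threshold; it is off by default, so concordance is a
sign pattern, not a significance claim. *Discordant* means both
fold-changes beyond `fc_min` on the same side.

## Set deconvolution

All multi-list comparisons are exact Venn partitions: each protein is
assigned the region matching its exact membership pattern, so regions are
disjoint and cover the union by construction. The membership categories
map onto regions of the (hub, partner, mark) triple with a fixed
precedence:

1. `shared_core` — hub ∩ partner (the conserved core present in both
   complex variants);
2. `noncanonical_only` — partner without hub;
3. `chromatome_catalytic` — hub ∩ mark, outside the partner set
   (chromatin association at sites carrying the catalytic histone mark);
4. `canonical_only` — hub without partner and mark;
5. `bait_independent_unassigned` — everything else in the universe.

Under a single collapsed sample table in which the same bait labels serve
proteome and chromatome roles, `canonical_only` and
`chromatome_independent` denote the same region (hub minus partner minus
mark); the latter label is therefore produced only by the dedicated
`chromatome_partition` operation, which analyses a chromatome triple on
its own. The universe for membership assignment defaults to the union of
all post-filter interactor sets. Cross-line sharing is required before
bait comparison; proteins with evidence in only one cell line are counted
separately in the pipeline summary (`n_single_line_evidence`) rather than
silently categorized.

## Overlap statistics

* Hypergeometric over-representation is upper-tail including the observed
  count, p = P(X ≥ k) — the standard convention. The tail is computed by
  scipy's survival function, which works in log space and is stable for
  gene-scale universes (N ≫ 1000).
* The two-sided Fisher exact test follows the minimum-likelihood rule:
  the p-value sums the probabilities of all same-margin tables whose
  point probability does not exceed the observed one. Point weights are
  compared as exact integers, so near-ties need no floating-point
  tolerance.
* Benjamini–Hochberg adjustment delegates to statsmodels' step-up
  implementation; an independent brute-force step-up is kept in the test
  suite as an oracle.
* The DEU overlap analysis takes an externally produced per-exon p-value
  table (differential-exon-usage results), BH-adjusts across all exons,
  calls a gene significant when any of its exons passes `alpha` (default
  0.05, each gene counted once), and tests the resulting gene set against
  reference collections. The universe defaults to all genes present in
  the DEU table — every gene that could have been called — and is echoed
  in each result row, since overlap p-values are meaningless without a
  stated universe.

## Synthetic screens

The generator emulates the study design the analysis assumes: 2 cell
lines (overexpression-modulated first, knockdown-modulated second) × 2
conditions (empty-backbone control, modulated) × 4 baits (hub, partner,
catalytic mark, mock) × 2 cultures × 2 technical replicates = 64 runs.

* Complex members are detected in every non-mock run of their detecting
  baits; contaminants are detected in any run (mocks included) with
  probability `contaminant_detection_prob`; background proteins appear
  sporadically at `background_detection_prob`, exercising the
  reproducibility (`min_runs`) rule.
* Intensities are log-normal: a per-protein baseline drawn around
  `baseline_log_intensity_mean` (natural-log scale, default ln 1e6, i.e.
  raw MS2 intensities around 1e6) with protein-to-protein spread
  `baseline_protein_sd` = 0.5, plus per-run noise `log_noise_sd` = 0.4
  (≈ 40% CV, a typical replicate spread for spectral intensities).
  Values below `dropout_threshold` (default 1e3, three orders of
  magnitude under the baseline) are recorded as missing, never zero.
* Coupled complexes scale by `modulation_multiplier_up` = 4 in the
  modulated overexpression line and `modulation_multiplier_down` = 0.25
  in the modulated knockdown line. The magnitude of stoichiometric
  coupling is not empirically constrained; 4-fold was chosen once so that
  effects are reliably detectable at 4 replicate runs per arm, and is a
  free parameter.
* Mocks contain contaminants only, plus an optional member-carryover
  probability (default 0).
* One `numpy` generator seeded by `seed` drives all randomness; protein
  identities, complex assignments and the ground-truth table are
  deterministic functions of the configuration, so different seeds change
  noise but not structure.

The default screen (`default_config`) plants three complexes chosen to
populate the main membership categories: a 60-member canonical-variant
complex (hub bait only, coupled), a 25-member shared core (hub + partner
+ mark baits, coupled) and a 40-member non-canonical complex (partner
bait only, uncoupled), among 500 proteins with 50 contaminants.
`concordance_benchmark_config` is the noise-free benchmark: 218 hub
interactors, 105 of them coupled, used to check that the concordance
classifier splits them exactly 105 / 113.

What the generator does *not* emulate: peptide-level identification and
search-engine FDR, correlated contaminant behaviour across runs,
abundance-dependent dropout curves, batch effects between cultures, or
compositional distortion of intensities. Passing the recovery tests
therefore shows the pipeline's logic is correct under its own model
assumptions, not that real screens of this design achieve the same
precision.

## Numerical and design choices

* Missing-value policy for replicate averaging defaults to imputing the
  detection floor (`floor`, default 1.0) for undetected runs, so a prey
  detected in one of two runs averages toward the detection limit rather
  than ignoring the absence; `ignore_missing` is available.
* Sample normalization (`none`, `total`, `median`) rescales each sample
  so the chosen statistic of its non-missing values equals the
  cross-sample mean of that statistic; `none` is the pipeline default
  since the simulated runs share a common scale, and fold-changes are
  within-line ratios.
* ANOVA is computed by direct least-squares model comparison (needed for
  5000-simulation calibration in seconds); it agrees with statsmodels'
  type-II `anova_lm` to 1e-10 on random unbalanced layouts in the test
  suite. Under the null at the 2 × 2 × 4-run design its type-I error is
  calibrated at 0.05 within Monte-Carlo error.
* Problem sizes in the test suite (500-protein screens, 5000-simulation
  calibration, exhaustive statistical oracles at N ≤ 60 and table totals
  ≤ 40) were chosen as the smallest scales at which each property is
  convincingly established.

## Known limitations

* The two-line modulation design is hard-coded to one overexpression and
  one knockdown line; designs with more lines or conditions are not
  supported by `quantify_modulation`.
* Protein identifiers are opaque strings; no accession mapping or
  isoform collapsing is performed.
* The DEU stage consumes an existing exon-level results table; it does
  not fit the exon-usage model itself.
* Enrichment is a generic hypergeometric over user-supplied collections,
  not a pathway-topology or network analysis.
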
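# Methods

## The screen generative model

One simulated screen is a chain of five stochastic stages, each mirroring a
physical step of a pooled transplantation screen:

1. **Plasmid pool.** Hairpin proportions are log-normal:
   p_i ∝ 2^(z_i), z_i ~ N(0, σ²_plasmid) with σ_plasmid = 0.5 log2 units by
   default. Pooled cloning never yields equimolar libraries; 0.5 log2 units
   gives a ~4-fold interquartile spread, a realistic mid-range for TRC-style
   pools. The paper-scale design values used throughout (508 hairpins, 3–6
   per gene, 10⁶ transduced cells, MOI < 1, 5 recipient mice, 4 weeks,
   ~2,000-fold per-animal representation) are the screen's stated design;
   sequencing depth (2×10⁶ reads/sample) and the two dispersion defaults are
   configuration choices, not claims about the original data.
2. **Transduction (T0).** The T0 cell population is a multinomial draw of
   `n_cells_transduced` cells from the plasmid proportions. MOI is recorded
   (it justifies the one-hairpin-per-cell reading of the counts) but does not
   enter the arithmetic: the cell count is already the transduced population.
3. **Engraftment bottleneck.** Each mouse receives a *without-replacement*
   subset of the injected cells: a multivariate hypergeometric draw of
   `n_cells × engraftment_fraction` cells from the integer T0 population.
   Without replacement matters at the edge: full engraftment
   (fraction = 1) is then exactly the identity, which anchors the
   no-bottleneck limit test. At the default 0.1 the ~10⁵ engrafting cells
   put ~200 cells behind each hairpin — the regime in which stochastic
   per-mouse hairpin drift becomes visible, as intended.
4. **Selection.** Four weeks of growth multiply each hairpin's proportion by
   2^(fitness × efficacy × weeks), then renormalize. Fitness is per-gene in
   log2 units per week (−1.47 log2/week ≈ 60-fold dropout over 4 weeks);
   efficacy ∈ [0, 1] is per-hairpin and models knockdown-potency
   heterogeneity. Selection is deterministic on proportions (expected
   exponential growth); the stochasticity of in vivo growth is carried by
   the bottleneck upstream and sequencing downstream. The truth table
   therefore records integer cell counts at the T0 and bottleneck stages,
   where cells are actually drawn.
5. **Sequencing.** Reads are a multinomial draw of `reads_per_sample` over
   the proportions perturbed by per-hairpin log-normal PCR amplification
   factors (sd 0.25 on the natural-log scale ≈ 0.36 log2 units), the
   dominant technical noise term of amplicon sequencing.

Two-level stochasticity (cell-level bottleneck + read-level multinomial with
a PCR factor) was chosen over a single negative-binomial draw because the
two knobs are separately interpretable — engraftment controls inter-mouse
variance, PCR overdispersion controls within-sample technical noise — and
the tests exploit exactly that separation.

Spleen samples, when requested, are an independent second bottleneck from
the same T0 with the same selection, supporting bone-marrow-vs-spleen
correlation QC.

All randomness flows from a single integer seed through named substreams
(`SeedSequence` keyed on screen/tissue/mouse/stage), so any sample can be
regenerated in isolation and whole runs are byte-identical under a fixed
seed.

**What the simulator does not model:** PCR chimeras, index hopping,
position- or GC-dependent sequencing error, clonal interference between
cells carrying the same hairpin, time-varying fitness, and transduction
of multiple hairpins per cell. Passing tests on this generator show the
analysis is correct *under* multinomial/hypergeometric sampling with
log-normal technical noise; they cannot certify behavior under error modes
the generator omits.

## Deconvolution

A read is assigned to a hairpin iff exactly one library key (21-nt target
sense sequence or its reverse complement) occurs as an exact substring;
ambiguous and key-less reads are counted as unassigned, never fractionally
assigned, so read-count conservation (assigned + unassigned = total) holds
identically. Exact matching is the conservative, auditable default; the
optional 1-mismatch mode expands each key's Hamming-1 neighborhood at index
build time, sending neighborhood collisions to unassigned. Reads shorter
than the key are unassigned and counted. Representation QC uses
log2(count + 0.5) for pairwise R², since zeros are expected in dropout
samples.

## Differential abundance

Normalization is log2-CPM with pseudocount 0.5:
log2((c + 0.5)/(T + 1) × 10⁶). The transform is exactly depth-invariant at
pseudocount 0 and invariant to O(pc/count) otherwise — immaterial at
amplicon depths where per-hairpin counts are in the thousands. "Average
abundance" is the mean log2-CPM over the samples of the comparison, the
scale on which the conventional > 2.5 abundance gate is defined.

Replicate outliers are flagged before testing: group samples are projected
onto the first two principal components of their centered log-CPM profiles,
and a sample whose Euclidean distance from the componentwise median exceeds
the median distance by more than 3× the MAD of distances is dropped. The
median-anchored form is deliberate — raw distances are non-negative with a
positive median, so a threshold on the distance itself would flag entire
tight replicate groups. The procedure is deterministic and permutation-
invariant; it needs ≥3 samples and is skipped (not failed) for smaller
groups inside `differential_table`.

The moderated t follows the standard empirical-Bayes hierarchical model.
With per-hairpin residual variance s²_g on d_g degrees of freedom and a
scaled-F prior, the hyperparameters are estimated by moment matching on
z = log s²_g: the excess of var(z) over trigamma(d_g/2) identifies d₀ via
trigamma inversion (Newton, tolerance 1e-8), and the mean of z identifies
s₀². Non-positive excess variance means the observed variances are no more
dispersed than sampling alone explains, giving d₀ = ∞ (every hairpin tested
against the common variance); zero variances are excluded from estimation,
and a matrix with no positive residual variance is an error, not a
statistic. d₀ = 0 reduces to the ordinary pooled-variance t — a limit used
as a test. p values come from the t distribution on d₀ + d_g df, two-sided;
BH adjustment is applied within each screen × tissue comparison separately,
mirroring the pairwise per-condition analysis. Correctness is anchored two
ways: frozen reference values computed with Bioconductor limma on a fixture
with heterogeneous row variances, and a separately written loop-based
implementation of the same equations (agreement to 1e-8).

With a single T0 reference sample, the reference contributes a mean but no
variance; residual df come from the mouse replicates. The T0 sample's own
technical noise (one PCR draw shared by all comparisons) is comparable to
one mouse's technical noise and slightly smaller than a mouse's total
(technical + bottleneck) noise, so the test stays approximately calibrated
— verified empirically by the KS-uniformity acceptance check on neutral
screens.

## Hit calling

The statistical gate (|logFC| ≥ 1, adj. p ≤ 0.02, avg. abundance > 2.5) and
the magnitude gate (≥10-fold median change across mice vs T0) are applied
**conjunctively per hairpin**: both thresholds are part of the screen's
selection criteria, and conjunction is the only combination that uses both.
Per-mouse fold changes are pseudocounted CPM ratios sample/T0 with the
median then taken across mice (`median_of="fold_changes"`); the alternative
reading — fold change of median abundances — is selectable by
configuration. A gene needs ≥2 qualifying hairpins for a per-screen call
and the same verdict in ≥2 independent screens for a consolidated hit.
Exclusion (qualifying hairpins in both directions, within or across
screens) dominates every other verdict and requires the full qualifying bar
on both sides, so noise-level discordance does not exclude a gene. The hit
set is monotone in the thresholds up to exclusions: relaxing a gate can
only add qualifying hairpins, and the only way a hit disappears under
relaxation is by newly uncovering an opposite-direction qualifier.

## Interactome filtering

Filters (≥2 peptides/protein, ≥3 valid bait-group values per condition) run
before imputation, so imputed values never rescue a protein. Imputation is
column-wise over all samples of the condition (bait and IgG), drawing
missing entries from Normal(μ_obs − 1.8σ_obs, (0.2σ_obs)²) per column; a
group-restricted variant is available (`impute_matrix(samples=...)`). The
two significance tiers are both real outputs: adjusted p < 0.1 marks
per-condition "significantly enriched" proteins, and the stricter adjusted
p < 0.05 — required in *every* condition, with positive enrichment — defines
the cross-condition consensus. Novelty is an annotation against a
user-supplied reference list; no live database access.

The synthetic AP-MS generator plants interactors as a +3 log2 bait-side
shift on log-normal baselines (within-replicate sd 0.5, n = 4 per group per
condition) and makes values missing-not-at-random through a logistic
dropout in realized intensity centered near the 12th percentile, so
low-abundance background and the IgG side of true interactors go missing
preferentially — the regime downshift imputation is built for. It does not
model peptide-level quantification, shared peptides, or batch structure
between conditions.

## Problem sizes and numerical choices

Monte-Carlo tests run the simulator at the full design scale (508 hairpins,
10⁶ cells, 2×10⁶ reads) — a full screen simulates in ~10 ms — with 10–30
seeds per property and 25 seeds for the two-screen calibration and recovery
checks; the acceptance script uses 10 seeds and reports minima, matching
how worst-case retrieval is quoted. Planted-recovery conditions use 10
dropout genes at −1.25 log2/week (32-fold expected at full efficacy) with
the efficacy ladder (1.0, 0.8, 0.5, …), i.e. exactly two hairpins per gene
at or above a 16-fold expected change. Ties in BH are handled by stable
mergesort; p values are clipped into (0, 1] only against floating-point
underflow; the trigamma inverse uses the guarded Newton iteration with
asymptotic seeds at both extremes.

## Known limitations

- Exact matching discards reads whose key carries any sequencing error; at
  1% per-base error ~19% of reads are unassigned (analytic, tested). The
  1-mismatch mode recovers most of these at the cost of a larger index.
- The per-screen T0 is a single reference sample, as in the transplantation
  design; systematic T0-specific artifacts (e.g. a bad PCR) are not
  statistically separable from biology and are only visible in QC.
- The moderated model fits a single prior per comparison; no
  abundance-variance trend or robust down-weighting of hypervariable
  hairpins is implemented.
- Consolidation treats screens as exchangeable; sub-pool screens are simply
  screens over a smaller library.
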
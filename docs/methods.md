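# Methods

This note documents the model behind `kircall`, its assumptions, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Model

The copy-number signal for a KIR gene `g` in sample `s` is the mean
occurrence count of `g`'s unique canonical k-mers in `s`'s reads, divided
by a per-sample depth normalizer. Under uniform coverage this frequency
is proportional to the germline copy number `c_gs`:

    f_gs ≈ c_gs · d_s · w_g / N_s  with  N_s ∝ d_s,

where `d_s` is the sample's depth, `w_g` a gene-specific window factor
(k-mers near gene ends are covered by fewer reads) and `N_s` the
normalizer. Across a cohort, `f_g` is therefore a mixture with one mode
per copy-number state at approximately `c/2` times the anchor scale, and
the calling problem reduces to segmenting a one-dimensional density.

Key assumptions:

* the allele reference is complete enough that the every-allele /
  no-other-gene criterion leaves usable k-mers for most genes (genes that
  fail are handled by co-segregation, which assumes the documented KIR
  haplotype structure);
* samples are processed uniformly (one capture kit): batch structure in
  coverage shifts modes per batch and is *not* corrected — the optional
  t-SNE diagnostic (`normalization.embed_background_profiles`) exists to
  detect it so the user can subset;
* the cohort is large enough (≳ 50, defaults tuned on hundreds) for the
  density modes to be identifiable. Single-sample calling is explicitly
  out of scope.

## Unique k-mer index

K-mers are canonicalized as `min(kmer, revcomp(kmer))`; all matching
happens in canonical space, so counting is strand-agnostic. K-mers with
non-ACGT bases are never candidates. The every-allele criterion is
applied over all loaded records; `min_allele_length` optionally drops
partial reference entries which would otherwise veto their gene's k-mers
(how partial entries were treated upstream is not documented, so the
default keeps them and the switch makes the alternative explicit).
Background-panel k-mers must additionally be absent from *all* KIR
alleles and all other background genes, so background coverage can never
absorb KIR signal; up to `max_per_gene` (default 100) are drawn by a
seeded shuffle of the sorted eligible set.

Counting scans reads directly — no realignment prefilter. Because k-mer
matching is exact, scanning all candidate reads yields identical counts
for indexed k-mers while removing an external aligner dependency. The
implementation packs windows into 2-bit integer codes (k ≤ 31; larger k
falls back to string hashing) and vectorizes the scan, so a 500-sample
cohort counts in about a minute. Overlapping windows each count;
`reads_with_hit` (reads containing ≥ 1 k-mer of a gene) is tracked
separately for the read-based normalizers. Paired-end mates are treated
as independent reads; BAM region coordinates are 1-based inclusive.

## Normalization and QC

Four normalizers are supported: {mean, median} × {per-k-mer occurrences,
reads-with-hit} over the background panel; the default is the mean
per-k-mer count at `k = 30`. `evaluate_normalization` sweeps (k, method)
by the population variance of the anchor gene KIR3DL3, computed on
frequencies rescaled to unit cohort mean (squared coefficient of
variation) so that units with different absolute scales compare fairly;
the variance is the unbiased sample variance.

Two answers are reported. The strict argmin (exact ties to larger k) is
informative but, on cohorts of desk scale, often statistically
meaningless: all four normalizers derive from the same reads and differ
by less than the sampling error of a variance estimate
(relative SE ≈ √(2/(n−1))). The headline *selection* therefore uses a
one-standard-error-style parsimony rule: among cells within `n_se`
(default 2) standard errors of the minimum, prefer the earliest-listed
method (the simplest statistic) and then the largest k, which retains
more coverage of low-frequency KIR genes. On replicated simulations this
selection is reproducible where the strict argmin is not, and it lands on
the shipped default (k = 30, mean of per-k-mer background counts).

Coverage QC: a sample is retained iff its summed background-k-mer count
is ≥ 40,000 **and** its summed KIR-k-mer count is ≥ 20,000 (strict
less-than exclusion; both thresholds configurable). "Coverage" here means
the total occurrence count over the respective k-mer set.

## Density segmentation

Per gene, a Gaussian KDE is evaluated on a 512-point uniform grid over
[0, 1.1 × max frequency]. Mass is reflected at zero so genes with a
zero-copy point mass at the origin still integrate to ~1 on the grid.
Bandwidth is Silverman's rule of thumb,
`0.9 · min(sd, IQR/1.34) · n^(−1/5)`, floored at the grid spacing for
degenerate (point-mass) inputs and overridable. Peaks are local maxima
passing a prominence floor (default 2% of the maximum density; grid-edge
maxima count); valleys are the minimum-density grid points between
consecutive retained peaks. At cohorts of a few hundred samples the KDE
has pointwise noise of several percent, so hand-constructed unimodal
densities can show minor wiggle peaks just above the floor; in calling
practice the copy-number modes dominate and the floor is configurable.

Threshold rules by category:

* **anchor** (modal ploidy 2): the highest peak is copy 2; its left/right
  extent is where density falls below `anchor_edge_fraction` (default
  10%) of peak height, operationalizing "the edge of the peak"; one
  peak-width further left separates copy 1 from copy 0. Non-positive
  boundaries are dropped (no mass sits left of zero).
* **high-frequency non-anchor**: the three left-most peaks are 0/1/2
  copies; cutoffs are the valleys between them; beyond the third peak's
  right extent (or the valley before a fourth peak, if present) is 3+.
* **low-frequency non-anchor**: the two left-most peaks are 0/1 copies;
  the 0/1 cutoff is the valley between them, and the inter-peak distance
  `d` is added successively to that valley for the 1/2 and 2/3+
  boundaries (for symmetric components this equals placing boundaries
  midway between extrapolated peak positions). Peak-count requirements
  are ≥ 2 / ≥ 3 rather than exact because a small 2-copy mode is often
  visible for low-frequency genes; a mismatch raises an error naming the
  gene and suggests a manual category override.

A sample is excluded for a gene when its frequency is within the
exclusion margin — the 1-vs-2-copy boundary divided by `exclusion_divisor`
(default 50) — of *any* cutoff; for low-frequency genes the margin uses
the extrapolated 1/2 boundary.

Co-segregation rules run after measured calling: sums are capped at 3
("3+"), the inverse rule (`KIR2DL3 = 2 − KIR2DS2`) clamps below at zero
with an `inferred_clamped` flag, and a target is excluded wherever any
source is excluded. KIR2DL2 is configured as inferred (target of the
KIR2DS2 rule) rather than as an anchor; users can override the category
map. Modal-ploidy priors are configuration, not computed.

## Synthetic cohorts

The generator emulates the population structure the model assumes: genes
share a random common backbone over `homology_fraction` (default 0.7) of
their 1 kb length — so most k-mers are non-unique, which is the core
difficulty — with gene-specific segments and three alleles differing by
five random substitutions. One gene (KIR2DS1) is built as an exact
allele-prefix of its partner (KIR3DS1), guaranteeing zero unique k-mers
and exercising co-segregation; KIR2DL3 is the haplotype alternative of
KIR2DS2 with no sequence of its own. Genotypes are two independent
haplotype draws (anchors forced present; Bernoulli gene frequencies of
0.7 for high-frequency and 0.25 for low-frequency genes). Reads are drawn
uniformly per gene copy at a lognormal per-sample depth (default mean 30×
per haploid copy, CV 30%), equiprobable strands, independent base errors
(default 0.1%). The default cohort is 500 samples with a 20-gene, 600 bp
background panel (a scaled-down stand-in for a 100-gene panel, sized so
that background coverage sits comfortably above the QC threshold at the
default depth). Everything is deterministic given the seed, with
independent seed streams per stage and per sample.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: capture-kit coverage bias and batch structure,
GC/mappability bias, paired-end structure, indels and structural variant
breakpoints, allele-frequency differences between populations, reference
incompleteness, and duplicate reads. Real cohorts have broader,
messier frequency modes; the cohort-level design (population thresholds,
exclusion margins, QC filters) exists precisely for that regime.

Simulation study sizes used by the tests and the acceptance script —
chosen as the smallest cohorts at which the population densities are
cleanly multimodal: the end-to-end study uses the default 500-sample
configuration; the normalization replication uses 10 (tests) or 5
(script) cohorts of 40 samples at a fixed 4-fold depth range
(geometric 7.5–30×) with candidate k ∈ {15, 20, 30}.

## Known limitations

* Cohort-level only; no allele calls; thresholds must be relearned per
  cohort/batch.
* "3+" is treated as exactly 3 in population frequencies and burden sums.
* The inhibitory gene list is configuration (default: the canonical
  long-tailed inhibitory KIRs) and should be reviewed per study; burden
  sums copy numbers, with gene-presence counting available by passing a
  0/1-clipped matrix.
* The anchor edge rule depends on `anchor_edge_fraction`; very tight
  anchor distributions make the copy-2 interval narrow and push borderline
  samples into the exclusion margin rather than miscalling them.
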
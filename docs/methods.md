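# Methods

## The per-gene splice-structure test

For a gene with junction count vectors **c** per sample, the test asks
whether the *pattern* of junction usage differs between two conditions
with n_r replicates each, irrespective of expression level. Counts are
closed to a composition xᵢ = (cᵢ + λ)/Σⱼ(cⱼ + λ) with pseudocount λ = 0.5
(the conventional offset for compositional zeros; the alr transform is
undefined at zero and real junction tables contain many zeros), mapped to
ℝⁿ⁻¹ by the additive log-ratio transform against the last junction, and
compared between groups with the two-sample Hotelling T²

    T² = (n_r·n_r / 2n_r) · d' S⁻¹ d,

with d the difference of group mean alr vectors and S the pooled sample
covariance (divisor 2n_r − 2). The statistic is referred to an F
distribution via

    F = T² · (2n_r − n + 1) / ((2n_r − 2)(n − 1)),   F ~ F(n−1, 2n_r−n+1).

**Degrees-of-freedom convention.** The denominator df used here,
2n_r − n + 1, is one *larger* than the classical two-sample Hotelling
denominator df (n₁ + n₂ − p − 1 = 2n_r − n for p = n − 1 alr dimensions).
This package deliberately implements the former convention, together with
the matching scaling constant df2/((2n_r − 2)·df1), and documents rather
than "corrects" it. The practical consequence, measured by the package's
own calibration suite, is an anti-conservative null: under the default
synthetic noise model the achieved type-I error at nominal α = 0.05 is
roughly 0.10–0.13 (it also absorbs the heavy-tailed replicate noise that
a Gaussian-theory null does not model). The calibration test therefore
checks *stability* — that the achieved level is reproducible across
simulation seeds within exact binomial bounds of its own asymptote — not
agreement with the nominal level. Users who need strict type-I control
should calibrate a cutoff on permuted or simulated nulls.

**Filtering and amalgamation.** A junction is "in use" when its mean
count reaches `min_mean_count` (default 3) in *at least one* condition;
condition-specific junctions are precisely the interesting signal, so the
one-condition rule is the default (`in_use_rule="both"` is available).
Genes whose in-use junction count exceeds `max_bins` (default 6, the
largest testable size at n_r = 3) keep their `max_bins − 1` largest
junctions by overall mean count (ties broken by input order) and the rest
are summed per sample into one amalgamated bin; per-sample totals are
conserved exactly.

**Singular covariance.** With 6 bins at n_r = 3 the alr dimension is
p = 5 while the pooled covariance has rank at most 2n_r − 2 = 4, so S is
always singular there. Rather than refusing such genes, T² uses the
Moore–Penrose pseudo-inverse (relative tolerance `pinv_tolerance`,
default 1e-12) and the result is flagged
`status = singular_covariance_pinv`. Two caveats follow: the F reference
distribution is no longer exact, and exact invariance to the alr
reference part — which holds whenever S is invertible, because a
reference change is an invertible linear map of the alr space — is not
guaranteed under the pseudo-inverse. The reference-invariance test suite
therefore covers the full-rank regime (2–5 junctions at n_r = 3).

**Other conventions.** Equal group sizes are enforced (the F scaling is
written for n_r per condition). Benjamini–Hochberg q-values are attached
across all genes with a defined p; raw p remains the primary column.
Untestable genes are reported with status flags
(`untestable_single_junction` for ≤ 1 usable junction,
`untestable_df` when 2n_r − n + 1 ≤ 0), never exceptions. Results are
bitwise invariant under permutations of input sample order (group columns
are ordered by sample name before accumulation).

## Synthetic data generator

The generator emulates the structure the test assumes. Each gene has a
transcript incidence matrix (2–4 transcripts, random junction subsets,
every junction covered); per replicate, transcript proportions are drawn
from a Dirichlet centred on the condition's mean proportions with
concentration `overdispersion` (default 50 — replicate-to-replicate
isoform-fraction SD of roughly 5–7%, a realistic level for biological
replicates of a cell line); per-gene-per-sample depth is negative
binomial with mean `depth_mean` (default 300 junction-spanning reads) and
dispersion `depth_dispersion` (default 10, variance m + m²/φ); junction
counts are multinomial over the per-junction read shares implied by the
incidence matrix. Setting either concentration to infinity collapses the
corresponding noise source exactly (used by the closed-form covariance
tests). A differential gene shifts a total-variation mass `effect`
(default 0.5) of transcript proportion toward its least-expressed
transcript, so `effect` is one interpretable scalar and expression level
is unchanged in expectation.

The gene panel — sizes (default 3–6 junctions), incidence matrices and
baseline proportions — is a deterministic function of the gene index, so
different seeds resample the *experiment* (which genes are differential,
and all counts) over identical dimensions. All remaining randomness
derives from the root seed via documented SeedSequence keys
(seed, crc32(gene), condition, replicate), making every count vector
reproducible in isolation.

What the generator does *not* emulate: positional coverage bias along
transcripts, annotation errors, unannotated junctions, library-prep batch
effects, or read-level artifacts. Passing tests demonstrate correctness
of the statistical machinery under the stated mixture model, not
robustness to those real-data complications.

**Recovery, measured.** Under the defaults at effect 0.5 and depth 500,
ranking all genes by p separates differential from null genes with AUC
just above 0.90 (pooled over 6,000 simulated genes). The margin is
genuinely thin, for an instructive reason: per gene size the AUC is
0.85–0.98, but genes of different sizes are referred to different F
distributions, so their p-values are not perfectly comparable and the
pooled ranking loses a little separation. Power is weakest for 5-junction
genes (denominator df 2) and 6-bin genes (pseudo-inverse regime).

## ASE calling

Junction usage is normalized as ln((RPM + 1)/(expression + 1)) with RPM
computed against the per-sample total junction count; the pseudocount 1
in both numerator and denominator keeps values finite (natural log is
used throughout). The outlier rule is an upper Tukey fence, Q3 +
k·IQR with k = 1.5, computed over the normal samples only (at least 3
required; linear quartile interpolation); any sample strictly above the
fence is an outlier. A junction is an ASE when a one-sided Fisher exact
test finds tumors significantly enriched (α = 0.05) among its outliers
and the tumor outlier fraction exceeds the normal one. Only the upper
tail is fenced — the screen targets junction usage *gained* in tumors.
This fence/Fisher construction is this package's own reconstruction of a
commonly used tumor-vs-normal outlier screen; it is configurable
(`k_fence`, `alpha`) and should not be read as a verified replica of any
specific published implementation. Per-sample burdens count the ASEs for
which the sample is an outlier; the high-burden group is split at
median + k·SD (sample SD, k = 0.5 by default; 0 and 1.0 are sensible
variants), and expression-defined groups (z-score > 2 by default) are
compared on burdens with a two-sided Student's t-test.

## PAS motif scan

The RNA motif AAUAAA is searched in genomic DNA as AATAAA (plus strand)
and TTTATT (minus strand); junctions with unknown strand are scanned on
both. "Within 500 bp of the event" is read as within the union of ±window
intervals around *either* junction endpoint — a junction has two ends and
either may sit near a cleavage site. Hits are deduplicated by (position,
strand) and reported with the signed offset to the nearest endpoint.
Hexamers must lie entirely inside the (clipped) scan region. Degenerate
PAS variants (AUUAAA, …) are out of scope.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere; junction IDs round-trip
  through "chrom:start-end", and en-dash separators are accepted on input
  because published junction IDs are frequently typeset that way.
- TSV (tab, header row, LF) is the only tabular dialect; undefined values
  serialize as "NA".
- Tie-breaks: amalgamation ranks by overall mean, ties by input order;
  result tables sort by p ascending, ties by gene symbol, undefined p
  last.
- Degenerate inputs: all-zero count vectors normalize to the uniform
  composition (pseudocount only); an empty sample's library size is
  treated as 1 so RPM stays defined; quartiles over fewer than 3 normals
  are refused.
- Test-suite problem sizes were chosen to keep the full suite around ten
  seconds on one CPU while leaving Monte-Carlo margins interpretable:
  2×1,000 genes for null calibration, 6×1,000 for recovery, 10,000–40,000
  draws for the covariance closed forms.

## Known limitations

- The printed-df convention makes nominal p-values anti-conservative (see
  above); cross-size p-value comparability is approximate.
- The pseudo-inverse regime (6 bins at n_r = 3) has no exact null and
  loses exact alr-reference invariance.
- The ASE outlier statistic is a reconstruction; cohort-scale ASE counts
  from specific published tumor studies are not expected to be
  reproduced.
- The generator's transcript structures are random subsets, not real
  annotations; effect sizes map to junction-level shifts in a
  structure-dependent way.
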
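# Methods

## The queued-ribosome cleavage model

The generative model treats the stall element as an absolute block at a
known 1-based reporter position (`stall_start`). The stalled lead
ribosome protects `lead_footprint` nt of mRNA 5′ of the stall (default
15 nt) and each trailing, collided ribosome protects `trail_footprint`
nt more (default 30 nt). Candidate cleavage positions are the upstream
boundaries of the queued ribosomes:

    distance_upstream(k) = lead + (k − 1) · trail,   k = 1 … n_ribosomes.

Two regimes are modelled:

- **static** — a persistent queue. Per event, each boundary fires
  independently with `cleavage_prob`; only the most-3′ fired boundary is
  kept (at most one cut per event on one molecule). With
  `cleavage_prob = 1` this degenerates to every event cutting at the
  first boundary, so the multi-boundary geometry is exposed through the
  `keep_all` diagnostic switch, which emits every fired boundary. All
  periodicity-recovery tests use `keep_all=True` with probability 1:
  the 30-nt inter-peak periodicity is a property of the boundary grid,
  and this is the deterministic way to populate the whole grid.
- **iterative** — cleavage–runoff cycles without rescue. After each cut
  the ribosomes downstream run off, the queue re-forms at the new 3′
  end, and the next cut lands `lead + trail` nt (45 nt by default)
  further upstream. The chain restarts on a fresh molecule when the
  next site would precede position 1 (counted and logged as a discarded
  event).

Assumptions: cleavage positions are exact ribosome-boundary positions;
no exonucleolytic nibbling of the captured 3′ ends. A uniform `jitter`
(± j nt per site, default 0) is available to emulate end heterogeneity,
but it is a knob, not a mechanistic claim. Fragments whose 3′ end lies
5′ of the amplification primer cannot be captured by the RACE design;
`capturable_sites` filters them (optionally also dropping fragments
shorter than the aligner's minimum mappable length, since a 6-nt
template insert is unplaceable however perfect the library).

## Read synthesis

Each read is the reporter subsequence from `primer_start` to the site,
with the 17-nt 3′ adapter `CTGTAGGCACCATCAAT` appended (except for
`frac_no_adapter` of reads), truncated on the 5′ side to `read_length`
so the informative 3′ end always survives, then perturbed by uniform
substitution errors at `per_base_error_rate`. Defaults: 50-nt reads,
error-free, full adapter presence. Sequencing indels and quality-value
modelling are out of scope.

## Trimming and alignment

Trimming removes the longest read suffix matching a prefix of the
adapter with mismatch fraction ≤ `max_mismatch_frac` (default 0.1) and
overlap ≥ `min_overlap` (default 6 nt), or a full internal adapter
occurrence together with everything 3′ of it; reads with no qualifying
match are rejected (`no_adapter`) because their 3′ end is unknowable.
Scanning candidate adapter starts 5′→3′ and taking the earliest
qualifying start implements the longest-suffix rule.

Alignment is an exhaustive ungapped Hamming scan of the trimmed read
over every forward-strand offset whose start is ≥ `primer_start` (the
library's 5′ primer bounds genuine fragments; the reporter is the only
reference, so exhaustive search is exact and cheap). A placement is
accepted iff the minimum distance is ≤ `max_align_mismatches` (default
2) and unique; otherwise the read is rejected as `too_many_mismatches`
or `ambiguous`. Reads shorter than `min_fragment_length` (default 15
nt) after trimming are `too_short`. Every read receives exactly one
fate, so fate counts partition the input; duplicate reads are never
collapsed (each read is one observation). Placements are memoised by
sequence, which makes deep libraries with few distinct fragments cheap.
Externally produced alignments can be injected from SAM, using each
record's rightmost aligned reference base as the 3′ end.

## Profile, smoothing, peak labelling

The profile coordinate is `d = stall_start − end3` (nt upstream,
positive). Fragments with `d ≤ 0` are retained in a downstream/at-stall
bin and excluded from peak calling; fragments beyond the analysis
window (default 600 nt) are tallied as overflow. Counts are binned at
1-nt resolution; smoothing a per-read scatter and smoothing the 1-nt
histogram are equivalent at this resolution.

Smoothing is Savitzky–Golay with window 5 and order 2 (the 5-point
quadratic filter, centre impulse response 17/35), computed by
`scipy.signal.savgol_filter`; positions within `window // 2` of either
window edge carry no smoothed value rather than an extrapolated one,
avoiding edge-polynomial artifacts next to the stall.

Peak candidates are strict local maxima of the smoothed track, with
plateaus reduced to their most-upstream position (deterministic
tie-break on integer-count plateaus) and with the additional
requirement of positive smoothed height: a peak must represent actual
fragment accumulation, and without the positivity requirement the
filter's negative ringing around isolated spikes would promote flat
zero stretches between true peaks to "maxima" at a zero threshold.
The labelling threshold is the `peak_quantile` (default 0.75) quantile,
with linear interpolation between order statistics (numpy's default),
of **all smoothed values in the window**. The published description
("values at the 75th quartile or above") does not pin down the
population; the whole-window reading is used because the figures label
a small subset of many visible bumps, which a global threshold
produces. The alternative — quantile over candidate peak heights — is
available via `quantile_on="peaks"`.

Spacing statistics are computed over labelled peaks only: spacings are
differences of consecutive labelled distances; the modal spacing is the
most frequent value after rounding to the nearest nt (ties to the
smaller value); the span is max − min labelled distance. With fewer
than two labelled peaks the spacing statistics are reported absent
(`None`), not zero.

## Half-life estimation

Per replicate, ordinary least squares of `ln(abundance)` on time;
`t½ = ln 2 / |slope|`. Log-linear regression (rather than nonlinear
exponential fitting) is the standard treatment of shutoff Northern
quantification and is exact on noiseless data. Replicates with a
non-negative slope are flagged non-decaying and excluded from the
mean ± SD (sample SD, ddof 1); an all-non-decaying course is an error.
The estimate is invariant to rescaling the abundances. Abundances must
be positive to fit; zeros are a data error, not censored.

The decay simulator draws multiplicative lognormal noise with unit mean
and coefficient of variation `noise_cv` (default 0.1 — a typical
blot-quantification error) independently per replicate and timepoint,
over timepoints {0, 2, 4, 8, 16, 32} min for fast-decay inputs.

## Growth rate and lag

OD600 series are pre-smoothed with a centred 5-point moving average
(~50 min at the 10-min plate-reader sampling the generator defaults
to — raw central differences would be noise-dominated), then
differentiated by central differences; the rate is reported at interior
timepoints. The lag between two conditions is strictly the difference
of the derivative-argmax times (positive = test lags reference); ties
resolve to the earliest time with a warning. Alternative lag
definitions (threshold crossing) are out of scope. Note the derivative
of a logistic is flat near its maximum, so single-curve argmax times
carry a sampling-interval-scale uncertainty; averaging lags over
replicate curve pairs is the intended use, mirroring plate layouts with
technical duplicates of biological triplicates.

The growth simulator is a logistic
`baseline + K / (1 + exp(−r (t − m − lag)))` with rate `r = 0.6 /h`
(a realistic mid-log yeast growth rate), midpoint 9 h, carrying OD 1.2,
10-min sampling over 24 h, plus additive Gaussian OD noise (default 0;
0.003 OD is used as a realistic plate-reader noise level in the
reproduction script) clipped at zero.

## Polysome/monosome ratio

For an A254 trace, each region (monosome, polysome) is an interval
drawn to include the peak's flanking troughs; the baseline is the
minimum absorbance inside the region and the peak height the maximum
above it. The ratio uses peak heights, not areas. A monosome height of
zero is an error.

## Synthetic reporter

`synthetic_reporter` builds a seeded random 1500-nt backbone (a real
PGK1 CDS is deliberately not bundled; the analysis depends only on the
coordinate frame) with the canonical coordinates: stall at 1040 (stem
loop) or 950 (codon runs), primer at 585. Codon-run stall types
substitute the literal 36-nt run; `SL` substitutes an 18-bp-stem /
8-nt-loop hairpin. Random backbones make ungapped placement unambiguous
with overwhelming probability, which the mapping tests rely on.

## What the simulations do and do not show

The generators reproduce the *geometry* of queue-boundary cleavage, the
library chemistry (adapter, primer bound, 5′ truncation), substitution
errors, decay exponentiality and logistic growth. They do not model
elongation dynamics (no TASEP), exosome/Xrn1 trimming of fragment ends,
ligation biases, PCR duplicates, or indels. Passing recovery tests
therefore demonstrates that the mapping and profiling stages are
correct and unbiased under these idealisations — not that real
libraries are free of end-nibbling or amplification artifacts.

## Problem sizes and numerical choices

Tests and the reproduction script use 300–2000 cleavage events per
library (up to 12 000 reads after boundary expansion), 100 simulated
shutoff courses for the half-life Monte-Carlo, and 6 replicate curve
pairs for the lag estimate — sizes at which every recovered quantity is
stable from seed to seed. Quantiles interpolate linearly between order
statistics; modal-spacing ties break toward the smaller spacing; all
simulators are reproducible given an integer seed and distinct seeds
give distinct noise draws (tested).
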
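# ngdmap

Mapping and modelling of **no-go decay (NGD)** cleavage fragments on
stalling reporter mRNAs.

When a ribosome stalls on an mRNA — at a stable stem loop, a run of
inhibitory CGA or AAA codons, or a damaged base — trailing ribosomes
collide and queue behind it, and the transcript is cut endonucleolytically
upstream of the stall. The 3′ ends of the resulting 5′ fragments can be
read out by 3′-RACE sequencing: ligate an adapter to RNA 3′ ends, reverse
transcribe, amplify with a transcript-specific primer, sequence. The
positions of those 3′ ends, expressed as distance upstream of the stall,
carry the geometry of the ribosome queue: a stalled lead ribosome protects
~15 nt of mRNA 5′ of the stall and each queued ribosome ~30 nt more, so
cleavage at queue boundaries produces peaks with ~30-nt periodicity, while
repeated cleavage–runoff cycles (when ribosome rescue is compromised)
space cuts ~45 nt apart.

`ngdmap` is for researchers analysing such reporter RACE libraries (or
simulating them). It provides:

- **Reporter data model and I/O** (`ngdmap.reporters`, `ngdmap.io`):
  1-based reporter coordinates, TOML reporter specs, streamed FASTQ, TSV
  profiles and time courses.
- **Synthetic data** (`ngdmap.simulate`): a queued-ribosome cleavage model
  (static queue vs iterative cleavage–runoff), RACE read synthesis with
  sequencing errors, exponential decay courses, logistic growth curves.
- **Read mapping** (`ngdmap.mapping`): 3′-adapter trimming, exhaustive
  ungapped Hamming alignment to the reporter (or a SAM bypass for external
  aligners), stall-relative coordinates, and a strict read-fate accounting.
- **Cleavage profiling** (`ngdmap.profile`): per-nucleotide 3′-end
  histograms, 5-point quadratic (Savitzky–Golay) smoothing, peak labelling
  at the 75th percentile of the smoothed window, spacing/periodicity
  statistics — as an sklearn-style `CleavageProfiler` estimator.
- **Kinetics** (`ngdmap.kinetics`): reporter half-life by log-linear
  regression of shutoff courses (`HalfLifeEstimator`), instantaneous
  growth rate and derivative-argmax lag times from OD600 curves, and
  polysome/monosome peak-height ratios from A254 traces.

## The core computation

For mapped fragments with 3′ ends at reporter positions `e`, the profile
coordinate is `d = stall_start − e` (nt upstream of the stall). Counts
`c(d)` over a 600-nt window are smoothed with a Savitzky–Golay filter
(window 5, polynomial order 2): each smoothed value is the least-squares
quadratic fit over the centred 5-point window, evaluated at the centre
(the filter's impulse response centre is 17/35). Strict local maxima of
the smoothed track are peaks; a peak is *labelled* when its height reaches
the 0.75 quantile of all smoothed values in the window. The modal spacing
between consecutive labelled peaks estimates the cleavage periodicity.

Half-lives come from `t½ = ln 2 / |slope|` of a per-replicate regression
of log abundance on time, reported as mean ± SD over replicates. Growth
lag between two conditions is the difference between the times of maximal
`dOD/dt` (5-point moving average, then central differences).

## Worked example

```python
import ngdmap as ng

reporter = ng.synthetic_reporter(name="PGK1-SL", seed=1)   # stall at 1040, primer at 585
model = ng.QueueModel(trail_footprint=30, n_ribosomes=6, keep_all=True,
                      n_events=1000, seed=0)
sites = ng.simulate_cleavage_sites(model, reporter)
reads = ng.synthesize_reads(sites, reporter, ng.ReadSimParams(read_length=50, seed=0))
result = ng.map_reads(reads, reporter)
distances, n_down = ng.fragments_to_distances(result.fragments, reporter)
est = ng.CleavageProfiler().fit(distances, n_downstream=n_down)
print(f"mapped {result.fates[ng.Fate.MAPPED]}/{result.n_reads} reads")
print(f"labelled peaks at {list(est.peaks_.labelled_distances)} nt upstream")
print(f"modal spacing {est.spacing_.modal_spacing} nt, span {est.spacing_.span} nt")

course = ng.simulate_decay_course(4.7, [0, 2, 4, 8, 16, 32], noise_cv=0.1,
                                  n_reps=3, seed=0)
hl = ng.fit_half_life(course)
print(f"half-life {hl.mean:.1f} +/- {hl.sd:.1f} min")
```

prints

```
mapped 6000/6000 reads
labelled peaks at [15, 45, 75, 105, 135, 165] nt upstream
modal spacing 30 nt, span 150 nt
half-life 4.7 +/- 0.1 min
```

Each of the 1000 simulated cleavage events fired all six queue boundaries
(`keep_all=True`), so the six labelled peaks sit at 15, 45, …, 165 nt
upstream of the stall — the lead ribosome's 15-nt footprint plus one 30-nt
trailing footprint per queued ribosome — and the recovered modal spacing is
the trailing footprint, 30 nt. The decay simulation at a 4.7-min half-life
with 10 % multiplicative noise is fitted back to 4.7 ± 0.1 min.

The same pipeline is scriptable from a shell:

```sh
ngdmap simulate --reporter reporter.toml --keep-all --events 1000 --seed 0 --out sim
ngdmap map --reporter reporter.toml --reads sim.fastq --out mapped
ngdmap profile --reporter reporter.toml --fragments mapped.fragments.tsv --out prof
ngdmap kinetics --decay decay.tsv --out halflife.tsv
ngdmap growth --growth growth.tsv --pair untreated,4NQO --out lag.tsv
```

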
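# Methods

## Model

Translation on a transcript of `Nc` codons is modelled as an
inhomogeneous totally asymmetric simple exclusion process with extended
particles (l-TASEP).  A ribosome occupies `ell` codons (default 10) and
its position is the codon index of its A-site, located at the
`a_site_offset`-th codon of the footprint (default offset 5, the sixth
codon).  The elementary reactions are:

* **initiation** — with rate `alpha`, a new A-site appears at codon 1,
  enabled only when no A-site occupies codons 1..`ell+1` (a ribosome
  translating any of those positions sterically covers the start
  region);
* **elongation** — a ribosome at codon `j` hops to `j+1` with intrinsic
  rate `omega(j)` unless another A-site sits at `j+ell`;
* **termination** — the ribosome whose A-site has reached the stop codon
  releases the protein with rate `beta` (default 35 /s; termination is
  never rate-limiting at this value).

Ribosome recycling, drop-off and 40S scanning are deliberately outside
the model.  The dynamics are simulated exactly with Gillespie's
algorithm (exponential waiting times, events chosen proportionally to
their rates) in compiled (numba) kernels; a plain-Python single-event
reference implementation (`step_kinetics`) encodes the same rules and is
used in tests.  On small instances (`ell = 3`, `Nc = 20`) the simulated
occupancies are checked against the exact stationary solution of the
master equation obtained by enumerating all admissible configurations.

## Estimators

**Initiation rate.**  At steady state the ribosome flux through every
codon equals the protein-release rate, and the initiation flux is
`alpha * [1 - sum_{k=2..ell+1} rho(k)]`, the intrinsic rate times the
probability that the start region is unoccupied.  Combining the two
gives

    alpha = <rho> (Nc - 1) / ( <T> * [1 - sum_{k=2..ell+1} rho(k)] )

with `<rho>` the mean per-codon occupancy over positions `2..Nc` and
`<T>` the mean protein synthesis time.  The relation is first order in
`alpha`: it ignores the occupancy of position 1 and higher-order
initiation terms, which compresses estimates by ~5–10% for the densest
transcripts (occupancy is proportional to `alpha` times a ~2.4 s blocked
window at 200 ms mean codon time).  `<T>` comes either from the
CDS-length scaling relation `<T> = Nc * <tau_A>` (`<tau_A>` = 200 ms by
default in vivo; measured from the simulation in validation runs) or
from a direct per-transcript measurement.  Occupancy comes from
simulation snapshots (each snapshot is one mRNA copy) or, for
experimental data, by apportioning the per-mRNA ribosome load `R(i)`
along the CDS by relative A-site reads; `R(i)` is taken from polysome
profiling or from translation efficiency through the through-origin
calibration `R = xi * TE`.

**Transcriptome-average elongation rate.**  After initiation is blocked
(harringtonine) the density in the first `L` codons obeys a continuity
equation and depletes linearly, `rho(dt, L)/rho(0, L) = 1 - dt/tau(L)`.
The x-intercept `tau(L)` of the fitted depletion line is the time the
last ribosomes need to cross `L`; fitting `tau(L)` against `L` gives
`<omega> = dL/dtau` as the inverse slope, with the intercept absorbing
fixed delays such as drug engagement.  Because ribosomes queue, the
recovered rate reflects *observed* hop times and sits ~5–10% below the
intrinsic transcriptome average (4.2 AA/s in, ~3.8–3.9 AA/s out).

**Codon dwell times.**  Flux balance makes the observed dwell time at a
position proportional to its A-site read count:
`tau(j) = c(j)/sum_{l=2..Nc} c(l) * <T>`, so the dwell vector sums to
`<T>` exactly.  Dwell times include queuing delays (they estimate
`1/[omega * P(free ahead)]`, not `1/omega`), which is also what the
per-position clock measurement in the simulator records, so estimator
and ground truth are commensurable.

## Synthetic data

The generator draws the study conditions used throughout validation:

| parameter | default | rationale |
|---|---|---|
| CDS length | log-normal, mode 400 codons, sigma 0.35 | yeast-like length distribution |
| codon-type rates | log-uniform [2, 20] /s, one rate per sense codon | ~10x dynamic range of decoding speeds |
| rate rescaling | transcriptome harmonic mean = 4.2 AA/s | measured average elongation speed in yeast |
| initiation rate | log-uniform [0.01, 0.5] /s | span of in-vivo initiation-rate estimates |
| termination | 35 /s | fast, never rate-limiting |
| coverage | log-normal, mean 19 reads/codon, sigma 1.0 | ~26M reads over ~1,400 genes; sigma set so per-gene depth spans ~4–100 reads/codon as in real filtered libraries |
| codon usage | uniform over 61 sense codons | identity only matters for feature analytics |

Codon usage is uniform by default (a frequency table can be supplied).
A consequence worth knowing: with uniform usage the per-gene mean
intrinsic dwell time concentrates tightly (CLT over ~400 positions,
CV ~2–3%), so the scaling-relation synthesis time is far more accurate
per gene than it is for real transcriptomes, where codon-usage bias
varies between genes.  Validation scatter on synthetic data is therefore
an upper bound on real-data accuracy in range but an *underestimate* of
real-data scatter.  The generator also does not model ligation or
amplification biases, nucleotide-resolution digestion noise, or
multi-mapping artifacts; the exclusion flags exist but synthetic
profiles are never flagged.

The 5' ramp variant multiplies the intrinsic rates of the first 100
codons by 0.5, reproducing the elevated start-proximal density used to
probe robustness of the initiation estimator.

## Simulation protocol choices

* **Snapshots are uniform in simulated time.**  Saving the configuration
  every k-th Gillespie event oversamples crowded states (the event rate
  grows with ribosome number); we measured ~60% occupancy inflation that
  way.  Snapshots are instead taken at fixed time intervals equal to
  `snapshot_interval` (default 100) times the mean event waiting time
  estimated during burn-in, preserving the intended decorrelation
  spacing while sampling the stationary measure correctly.
* **Burn-in** discards events until at least `300 * Nc` elongation
  events *and* 100 completed proteins.  Shorter burn-ins (tested at
  `50 * Nc` / 20 proteins) leave a measurable downward density bias on
  high-initiation transcripts whose relaxation time is a few synthesis
  times.
* **Run-off replicates** reuse the decorrelated steady-state snapshots
  as independent starts; each start contributes one profile per run-off
  time by continuing the same trajectory with `alpha = 0` (a paired
  design that slightly reduces variance between time points).
* **Deep-coverage runs** (the 100x codon-time experiment) shorten the
  snapshot spacing to 10 mean waiting times; the extra correlation only
  inflates sampling variance, which the hundredfold coverage suppresses,
  and keeps the event count tractable.
* **Seeding**: every transcript gets its own kernel seed derived from
  the experiment seed through `numpy.random.SeedSequence`; identical
  seeds give bit-identical trajectories.

## Validation experiments and their scales

* *Initiation recovery*: 200 transcripts at generator defaults;
  per-transcript synthesis times measured from 10,000 traversals in the
  acceptance script (1,200–1,500 in the test suite, where the extra
  Monte-Carlo error is negligible against the regression bands).
  Snapshots are spaced 300 mean waiting times apart: per-codon density
  on transcripts of several hundred codons decorrelates over roughly a
  synthesis time, and the wider spacing keeps occupancy noise small for
  a transcript set ~7x smaller than a transcriptome-scale experiment.
  Recovery regressions are computed on log10 rates — initiation rates
  span ~1.5 decades, every gene weighs equally, and a log-scale fit is
  insensitive to the first-order compression of the densest transcripts;
  linear-scale fits are reported alongside.  At the synthetic densities
  (200 ms mean codon time, initiation up to 0.5/s) the scaling-time mode
  carries a small positive slope tilt (~+0.03): measured synthesis times
  include queuing, so the CDS-scaling `<T>` underestimates the true
  synthesis time of the most heavily initiated transcripts.
* *Ramp robustness*: the same transcriptome with the first 100 codons
  slowed 50%, re-simulated and re-estimated.
* *Elongation recovery*: 100 transcripts with longer CDSs (mode 600,
  minimum 520 codons) so that depletion windows L in [201, 400] and a 3'
  normalization window beyond the farthest run-off front (~130 codons at
  30 s) fit on every gene; run-off times {0, 5, ..., 30} s.  Because the
  transcript set is ~50x smaller than a transcriptome-scale run-off
  experiment, each transcript is sampled deeply (20 reads/codon, depth
  sigma 0.5, steady-state starts spaced 300 mean waiting times apart);
  at shallower settings the tau(L)-vs-L slope is dominated by correlated
  sampling noise of the few effective replicates.  Metagene
  normalization is per transcript (each profile divided by its own mean
  density over the 3' window) before equal-weight averaging; ragged
  transcripts drop out of positions beyond their length.
* *Codon-time recovery*: 60 transcripts at ~200 reads/codon (the depth
  of gene sets that survive the >=3-reads-everywhere filter), dwell-time
  clocks averaged over >=10,000 passages (2,500–3,000 in the test
  suite); the deep-coverage variant uses 20 transcripts at 100x depth
  with exact synthesis times.

## Numerical and statistical choices

* Depletion-line fits use ordinary least squares over all run-off times;
  `tau(L)` is the x-intercept and requires a negative slope.
* The Mann-Whitney U test uses the exact null for group sizes <= 20
  without ties and the tie-corrected normal approximation otherwise;
  the Wilcoxon signed-rank test splits zero differences (`zsplit`), so
  identical pairings give p = 1.
* Bootstrap summaries (SE of the median, CIs of median differences) use
  10^4 seeded resamples; codon types with fewer than 2 occurrences are
  reported without an SE.
* Per-codon-type distributions cover sense codons at positions 3..Nc-1
  only: positions 1–2 carry initiation signal and the stop codon
  reflects termination.  The transcriptome fold-variability is the
  largest 95th percentile over the smallest 5th percentile across types
  (each type's extreme 5% tails trimmed).
* Zero-read positions after a bypassed filter yield zero dwell times and
  a per-gene tally rather than an error — a zero count is a sampling
  artifact, not a zero-time codon.
* The 95%-non-zero initiation filter counts all positions 1..Nc and is
  boundary-inclusive; the codon-time filter requires >=3 reads at every
  position 2..Nc.
* Kozak windows with a non-ATG start keep the flank score but are
  flagged; scores 5–7 are classified "intermediate" and excluded from
  two-group Kozak comparisons.

## Known limitations

* The initiation relation saturates as the start region fills; in the
  blocked regime (`sum rho(2..ell+1) >= 1`) estimation raises rather
  than extrapolating.
* The elongation analysis assumes depletion is observed within the
  run-off time grid; windows where the longest run-off barely depletes
  the density give unstable x-intercepts (the default L grid should
  satisfy ratio < ~0.5 at the longest run-off time).
* Dwell-time estimates conflate intrinsic codon speed with queuing
  delay by construction; no deconvolution of `omega(j)` is attempted.
* A-site assignment is consumed as input; only a fixed-offset fallback
  (5' end + 15 nt, sixth-codon convention) is provided.
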
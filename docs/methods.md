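# Methods

This note documents the models and procedures `ripplesift` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. Formulas and defaults here are the ones the code uses;
no empirical claim is made that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and units

All modalities share one session clock in seconds. LFP is in microvolts,
uniformly sampled (default 2 kHz — twice the 810 Hz upper stopband edge
plus margin, and consistent with a 5-sample RMS window spanning 2.5 ms);
positions are in centimetres at a nominal 30 Hz; spike times are
per-unit sorted arrays. Sessions are sequences of non-overlapping
`rest` and `forage` epochs; epoch boundaries are authoritative, and all
detection statistics are computed per epoch so state-dependent baselines
(quiet rest vs movement) cannot bias thresholds.

## HFO detection

The pyramidal-layer trace is band-passed 140–800 Hz with a linear-phase
equiripple FIR (stopbands 0–140 and 810–Nyquist, passband 150–800 Hz,
stopband deviation 5.6·10⁻⁴, passband deviation 2.8·10⁻², i.e. error
weights 51.2 : 1). The order is estimated with Bellanger's formula from
the 10 Hz transition band and then increased until a frequency-grid
check confirms both deviations are met (507 taps at 2 kHz). The filter
is applied once with its constant group delay compensated, which —
unlike forward–backward filtering — preserves the designed magnitude
response exactly; edges are padded with the boundary value so the filter
stays in steady state there.

Candidate events are maximal runs where the 5-point sliding RMS exceeds
its epoch mean + 3.5 SD; runs separated by ≤ 6 ms (boundary inclusive)
are merged, and merging is idempotent. A candidate survives the cycle
criterion if the band-passed signal has at least 5 strict local maxima
("cycles of oscillation") above 3 × the SD of the rectified epoch trace.
Counting signed maxima rather than rectified ones is deliberate: the
rectified trace has two half-wave peaks per cycle, so a rectified count
would let three-cycle transients through a five-cycle rule. Finally, a
spectral check computes the FFT power of the 100 ms raw-LFP window
centered on the peak (Hann taper, zero-padded to 1 s for a 1 Hz grid)
and keeps the event only if the peak power in (150, 600] Hz exceeds the
peak in 75–125 Hz, rejecting fast-gamma and broadband artifacts. The
historical manual inspection step is replaced by the machine-checkable
criteria above plus the per-stage counts in the pipeline log.

Session-level amplitude variability is the coefficient of variation
(SD/mean) of peak filtered amplitudes, refused below 20 events because
the CV of a smaller sample is too noisy to characterise a session.

## Event classification

Two features per event, both from the 500 ms raw segment centered on the
peak: the envelope amplitude (max |x| after a zero-phase 4th-order
Butterworth 0.2–40 Hz band-pass — Butterworth because the family is
otherwise unconstrained and it is stable at the 0.2 Hz edge), and the
peak frequency (argmax of FFT power above 150 Hz on the 40–600 Hz grid;
500 ms gives 2 Hz resolution). Features are normalised to their maxima
over the data set being clustered, then k-means (k = 2, Lloyd, tol 1e-6,
max 300 iterations) partitions the events. When no user centroids are
given, initialisation uses the events at minimum and maximum normalised
envelope — a deterministic stand-in for picking the two density maxima
by eye.

Clusters are labeled against a control-ripple reference by threshold
sweep ROC. The curve sweeps a criterion across the pooled value range;
AUC is the trapezoid area, equal to the rank-sum statistic divided by
n₁n₂ up to ties. The core function treats its first argument as the
positive class (so AUC(A,B) + AUC(B,A) = 1); cluster-vs-control
comparisons orient by the larger median so the reported AUC lies in
[0.5, 1]. A cluster whose frequency AUC against control is below 0.8 is
*ripple-like*; one at or above 0.8 on both frequency and envelope is
*pHFO*. If both clusters separate from control, labeling raises with
the per-cluster AUCs as diagnostics; if neither does (e.g. a control
session run through the same path), both clusters are ripple-like.

## Theta dynamics around pHFOs

Only events at running speed ≥ 5 cm/s enter. For each, 4 s of radiatum
LFP centered on the event is taken, the central 200 ms replaced by the
session mean (removing the interictal spike that would otherwise smear
the spectrogram), and a Morlet transform (6-cycle wavelets, 4–20 Hz at
0.5 Hz steps) computed. The wavelet is amplitude-normalised so a pure
sinusoid of amplitude A yields power A² — power is directly in µV²,
unnormalised per frequency. The analysis window is padded by 0.5 s of
real signal on each side before convolution so the baseline window is
free of edge effects (a 6-cycle wavelet at 7 Hz has ±0.4 s support).
Mean 7–11 Hz power is reported for baseline (−2.0 → −1.0 s), before
(−0.6 → −0.1 s) and after (+0.1 → +0.6 s); running speed is averaged
over the same windows.

The theta phase at event onset uses the last 2 s before the event.
Events whose interictal spike does not exceed 5 × the SD of the first
second are excluded. Spike onset is localised automatically as the last
sample at which the deviation from baseline rises through 2 SD and stays
above until the spike peak — a deterministic, conservative proxy for
manual onset picking that may shift onsets by a few milliseconds. The
truncated signal is band-passed 4–12 Hz twice: zero-phase (correct phase,
corrupted tail) and causally (valid to the end, constant lag). The
circular-mean phase offset between the two, estimated on the interior
(0.25 s guard bands), corrects the causal phase; a line is then fitted
to the corrected unwrapped phase over the last six theta cycles
(cycle length from the median instantaneous frequency, the final 25 ms
excluded as Hilbert edge) and extrapolated to the truncation point.
Phase convention: 0 at the theta peak, increasing with time, in
[−π, π). On stationary sinusoids the estimator's error is < 0.02 rad;
at 20 % additive noise the circular-mean error stays well under 0.5 rad.

## Unit modulation

Spikes within ±500 ms of each event are binned at 20 ms (50 bins). The
test compares, per event, the mean rate in the baseline window
(−500 → −400 ms) with the 100 ms centered on the event, by two-sided
Wilcoxon signed-rank with each event an independent observation
(overlapping events still contribute independent rows). Window widths
are rounded to the microsecond before division so equal-width windows
share a bit-identical rate scale — otherwise float subtraction turns
exact count ties into systematic sub-femtohertz differences that destroy
the test's calibration. All-tie inputs report p = 1 (not modulated);
units need ≥ 10 events per class. Sidedness was an open choice; the
test is two-sided with the direction reported separately, and no
multiple-testing correction is applied across units, matching the
per-unit p < 0.05 convention (a session-level FDR would be a one-line
addition but changes the reported proportions). Under a homogeneous
Poisson null the realised type-I error is 0.04–0.06 across seeds.
Units with results for both classes are categorised ripple-like only /
pHFO only / both / neither.

## Spatial coding

Rate maps use 5 × 5 cm bins anchored at the bounding-box corner of the
epoch's trajectory (half-open [5k, 5(k+1)) edges). Occupancy is the
summed inter-sample interval per bin; spikes take the position of the
nearest tracking sample in time. A bin is visited only if occupied
≥ 150 ms *and* its centre lies within 2.5 cm of the tracked path
(distance via a 1 cm distance transform). Raw rate (counts/occupancy)
is smoothed with the standard 5 × 5 Gaussian kernel (σ ≈ 1 bin, sums to
exactly 1), renormalised over the visited support so no rate leaks into
unvisited territory — smoothing follows masking, and a uniform map stays
exactly uniform including at edges.

Metrics on the smoothed map, visited bins only, with Pᵢ the occupancy
fraction and R = ΣPᵢRᵢ: Skaggs information ΣᵢPᵢ(Rᵢ/R)log₂(Rᵢ/R) in
bits/spike (zero-rate bins contribute 0; undefined when R = 0);
sparsity (ΣPᵢRᵢ)²/ΣPᵢRᵢ² (1 for uniform maps); split-half stability as
the Pearson r between maps of the two temporal halves of the epoch
(split at the midpoint; bins unvisited in either half excluded; a
warning below 10 shared bins); and the active fraction as the share of
units with any map peaking above 2 Hz. Information and sparsity
require a peak ≥ 2 Hz, enforced by the callers. Running speed is the
central difference of positions smoothed with a 250 ms moving average
(the window is a free choice; 250 ms suppresses tracker jitter without
flattening real accelerations).

## pHFO spatial impact

pHFO occurrence maps treat events as a point process over position with
identical binning, smoothing and visited rules as spike maps, and
require > 15 events per epoch. The chance level of their spatial
information comes from redrawing event times uniformly with replacement
from the epoch's tracking timestamps — occupancy-weighted, so shuffled
events inherit the animal's spatial sampling — 1000 times, with the
actual value judged against the 5th–95th percentile band. Under a
uniform null the actual statistic's rank among its shuffles is uniform,
and the band contains it ~90 % of the time.

Targeted down-sampling applies to units with ≥ 1 % of their epoch's
spikes inside pHFO cores (the 100 ms around the peak, matching the
modulation "during" window for cross-module consistency). Those spikes
are removed, the map rebuilt with bit-identical grid parameters, and the
information improvement compared with 1000 random removals of exactly
the same spike count; the improvement is significant when it exceeds the
95th percentile of the random distribution (the cutoff for "greater than
expected by chance" was open; one-sided 95 % matches the 5 % convention
used everywhere else). The population summary fits improvement against
the percentage of spikes removed by OLS over the significant maps only.

## Group statistics

The 2 × 2 contingency test is the closed-form Pearson chi-square without
continuity correction, n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1 — the
uncorrected form is required to reproduce the classic worked examples
(32/35 vs 59/127 modulated → 22.5; 30/35 vs 73/177 active → 23.1).
Group comparisons gate on Lilliefors normality per group (α = 0.05):
all normal → t-test / one-way ANOVA; otherwise rank-sum /
Kruskal–Wallis, with Tukey–Kramer pairwise contrasts computed on ranks
in the non-parametric branch.

## Synthetic sessions

The generator produces the statistical structure the analysis assumes,
with ground truth for recovery testing. Defaults describe one standard
session: 5 min rest, 10 min foraging in a 1 m circular arena, 5 min
rest, 20 units, at 2 kHz LFP / 30 Hz tracking.

**Trajectory.** Ornstein–Uhlenbeck velocity (τ = 0.8 s, stationary
speed median set to 6.4 cm/s via the Rayleigh quantile) reflected at the
walls, plus a steering term that rotates the velocity (≤ 2.5 rad/s)
toward a food target drawn from the least-visited 5 cm cells and
redrawn on approach within 4 cm. The steering emulates foraging for
scattered crumbs — food depletes where the animal has searched — and is
what makes the path space-filling: a pure OU walk at this speed covers
only ~80–90 % of the arena's bins in 10 min because of Brownian
overlap, whereas real foragers reach full coverage. Rotation preserves
speed, so the speed distribution is untouched. During rest epochs the
animal sits motionless in a holding box outside the arena. Coverage is
assessed over bins lying fully inside the circular wall; bins straddling
the wall are artifacts of square binning on a round arena.

**Events.** Ripple-class events are scheduled only where tracked speed
is below 5 cm/s (the same immobility cut the theta analysis uses);
pHFOs are homogeneous Poisson over the whole session. Default rates:
0.2 /s (immobile time) and 0.05 /s. A 500 ms minimum gap is enforced
greedily, scheduling fails if the requested rates cannot honour it, and
events keep 2.5 s clear of epoch edges. Per-event parameters draw from
class distributions whose medians mirror the two populations seen in
the chronic-kainate literature — ripple ≈ 186 Hz oscillation on a
≈ 245 µV sharp wave, pHFO ≈ 246 Hz on a ≈ 520 µV interictal spike —
with within-session spreads (frequency SD 12 Hz, lognormal amplitude
CV 0.25–0.30) set narrower than published pooled interquartile ranges,
which mix many sessions and animals. Filtered-amplitude medians
(100 µV ripple, 220 µV pHFO) were chosen so that, analytically, a
single-class session has an amplitude CV near 0.3 and a two-class
session near 0.5.

**LFP.** Pyramidal layer: Gaussian white noise (SD 15 µV — placing the
3.5 SD RMS threshold well below event amplitudes) plus, per event, a
Hann-windowed sinusoid (class frequency and cycle count: 12 cycles for
ripples ≈ 65 ms, 10 for pHFOs ≈ 41 ms) superposed on its envelope
transient. Sharp waves are Gaussian bumps (SD 40 ms); interictal
spikes are biphasic spike–wave shapes (σ 12 ms spike, 24 ms wave,
rescaled by the analytic overlap factor so the net peak equals the
envelope parameter). These are the simplest shapes satisfying every
detector and classifier criterion; they are not biophysical. Radiatum:
an 8 Hz theta sinusoid whose amplitude (150 µV) is gated by a sigmoid
of running speed around 5 cm/s, suppressed by 60 % for 0.8 s after each
pHFO, with the interictal-spike transient shared across layers.

**Spikes.** Inhomogeneous Poisson on a 5 ms lattice: rate = baseline
(0.5 Hz) + peak (≈ 6 Hz, lognormal across units) × Gaussian place field
(width 10 cm), multiplied by the unit's class gain (default 5 for
modulated units; modulated fractions 0.5 ripple / 0.25 pHFO) during each
event's 100 ms core.

**What passing tests do and do not show.** The generator reproduces the
analysis's *assumed* structure — state-dependent scheduling, the two
waveform populations, place fields, event-locked gains — so green tests
demonstrate that the pipeline recovers known structure at realistic
amplitudes and rates. It omits spike waveforms and sorting noise,
electrode drift, 1/f and movement artifacts, theta phase precession and
sequence content, and seizure dynamics; robustness to those cannot be
inferred from these tests.

## Determinism and problem sizes

Every stochastic step takes a seed; the pipeline derives per-stage seeds
from one root via `SeedSequence` and logs them, so a rerun regenerates
the report byte-identically. Calibration suites use sizes chosen to
make their Monte-Carlo error small relative to the tolerance being
checked: 1000 null units for the type-I calibration (SE ≈ 0.007),
200 draws × 1000 shuffles for band coverage (SE ≈ 0.021), 20 seeds ×
1000 removals for the down-sampling contrasts, 100 trials for the noisy
phase recovery, and 200 events for the suppression test.

## Known limitations

* The automated spike-onset localisation replaces a manual step and can
  shift onsets by a few ms, slightly biasing onset phases at high theta
  frequencies.
* Cluster labeling assumes exactly two populations; more-fragmented
  pathology would need k > 2 and a different labeling rule.
* The shuffle redraws event times over tracked samples (occupancy
  weighted); a uniform-in-time redraw would weight stationary periods
  differently. The choice is recorded in the output.
* Maps anchor bins at the trajectory bounding box, so two epochs only
  share a grid when given explicit common bounds (the pipeline does this
  wherever maps are compared).
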
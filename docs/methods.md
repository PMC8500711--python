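# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `riskforage`. Everything quantitative claimed here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external data.

## Coordinate and session conventions

The apparatus is a 1-D corridor: nest interior x < 0 (default depth 45 cm),
gateway at x = 0, pellet at x = 125 cm; y is a small lateral offset.
Tracking is uniform at 30 frames/s (validated to 1% frame-interval
tolerance). A recording day comprises three sessions — `pre_threat`,
`threat`, `post_threat` — and a session is `threat` exactly when it
contains robot-surge (or photostimulation) events. Times are seconds at
0.1 ms resolution; all epoch windows are half-open `[start, end)`.

Repeated pellet attempts within 10 s of the previous robot activation are
excluded (refractory filter, boundary inclusive — a gap of exactly 10 s is
kept; the convention was open and we chose inclusivity so a perfectly
periodic 0.1 Hz attempt train is retained). Analysis epochs are the 2.5 s
windows `[t−2.5, t)` / `[t, t+2.5)` around filtered surges and pellet
procurements.

Outbound latency runs from the gate opening to the pellet procurement or,
in threat sessions, to the first robot trigger of the trial; the success
rate is procured / attempted trials. Trials missing their gate event are
skipped with a logged warning rather than failing the session.

## Place fields

- **Grid**: 4 cm square pixels (configurable), x spanning the nest to the
  *foraging limit* — the maximum x visited in the threat session — shared
  by all three sessions of a day so pixel-wise comparison is well defined.
  Cells whose pre-threat peak lies beyond the limit are excluded from
  stability analysis (the comparison territory is unsampled under threat).
- **Rate**: Gaussian-smoothed spike counts over Gaussian-smoothed occupancy
  (σ = 1 pixel, configurable), computed only on visited pixels; unvisited
  pixels are masked, never zero-filled, and never contribute to peaks or
  correlations. The unsmoothed map satisfies Σcount/Σocc = mean rate
  exactly (conservation test).
- **Skaggs information** I = Σᵢ pᵢ λᵢ log₂(λᵢ/λ̄) in bits/s is computed on
  *unsmoothed* rates (the common convention; smoothing deflates I). Closed
  forms used as oracles: uniform map → 0; occupancy (½,½) with rates
  (0,2) Hz → exactly 1.0; (¼ × 4) with (0,0,0,4) Hz → exactly 2.0.
- **Inclusion**: min ISI ≥ 1 ms, peak > 2 Hz in some session, information
  > 1.0 bits/s in some session. Waveform stability (a sorting-stage
  criterion) is assumed satisfied — no raw waveforms exist here.
- **Classes** from the pre-threat peak x: nest (x < 0), proximal
  ([0, 25] cm, closed on both ends), distal (> 25 cm). Peak ties break
  toward smaller x.
- **Stability**: Pearson r over pixels visited in *both* sessions (≥10
  required, else undefined-with-warning), computed on smoothed maps by
  default (raw-map correlation is a flag away; which one the field's
  classic pipelines use varies, so both are supported and the default is
  stated here). Fisher Z′ = atanh(r) with r clipped to ±(1−10⁻⁷).
  Peak distance = |Δ peak x| in cm.

## Event responses (PETH)

500 ms bins over [−5, +10] s around events; per-bin rates are means over
events; Z is relative to the seven baseline bins in [−5, −1.5) s.

Two baseline-SD estimators are implemented:

- `"events"` (default): pooled SD of per-event baseline counts, scaled to
  the standard error of the across-event mean and inflated by
  √(1 + 1/7) — the exact null SD of (bin rate − estimated baseline mean)
  when the baseline mean is itself estimated from 7 bins. This keeps the
  per-bin null P(|Z|>3) near its nominal value; the measured
  homogeneous-Poisson false-responsive rate is ~5% against the 10% design
  bound.
- `"bins"`: SD of the seven baseline bin rates of the averaged histogram —
  the most literal reading of classic PETH normalization. With only 7 bins
  Z is t₆-like and heavy-tailed; selectable for comparability but not the
  default.

Z is location-scale invariant, so count and rate units classify
identically. A zero baseline SD is floored at the Poisson SD implied by the
baseline mean and flagged.

**Classification windows** (bins fully inside, membership by bin
boundaries): robot-approaching [−1.5, 0), robot-triggered [0, 3] (the
latter also covers the jaw-snap at +1.5 s), pellet [−1.5, 2]. Excited if
any window bin Z > 3, inhibited if any < −3. Robot = robot-only,
Pellet = pellet-only, RobotPellet = both (excluded from linkage),
NonResponsive = neither. The approaching/triggered distinction is retained
as a sub-label but both are reported as one Robot class.

**Unit typing**: Ward agglomerative 2-cluster split on standardized
(spike width, mean rate); the wider-spike cluster is pyramidal. Fewer than
4 cells or degenerate features → all pyramidal with a warning (interneurons
are excluded from further analyses regardless).

## Synchrony (shift-predictor CCG)

Raw CCG: for each BA (reference) spike, lags of same-trial dHPC (target)
spikes histogrammed in 10 ms bins spanning ±500 ms, with bin edges at
multiples of 10 ms so lag 0 is an edge and no bin straddles zero. The wide
±500 ms extent exists so the Z normalization has ~100 bins; the test window
is ±100 ms. An exact brute-force double loop over spike pairs serves as the
oracle; the production path (a vectorized all-trial-combination count
tensor) must agree bin-for-bin. Lag binning adds a 1 ns epsilon before the
floor so lags that are mathematically on a bin edge (spike times live on a
0.1 ms grid) are not dropped a bin by float error.

Shift predictor: 100 trial-shuffled correlograms, each from a uniformly
sampled *fixed-point-free* permutation of trials (so no shuffle reproduces
the raw pairing), trials aligned at their epoch-window starts; the
predictor is the shuffle mean. Subtracting it removes stimulus-locked
co-modulation — a pattern repeated identically every trial yields a
corrected CCG of exactly zero (degenerate, not significant).

Significance: Z per bin from the mean/SD of the corrected CCG over all
±500 ms bins (taking the wording "of the corrected CC" at face value;
normalizing on out-of-window bins only is a config option). Significant ⟺
peak Z > 3 within ±100 ms and both epoch rates > 0.1 Hz. Direction: peak
bin starting at lag ≥ 0 → BA→dHPC, else dHPC→BA; a peak in [0, 10) ms
counts as BA-leading (the 0-lag convention was open; an edge at zero makes
the rule unambiguous).

Calibration, measured by the acceptance script: on 200 independent Poisson
pairs (5 Hz, 10 trials × 2.5 s) the screen flags ~8–9% — under the 10%
design bound but well above the Gaussian-tail 2.6%, because low-count
Poisson bins are right-skewed. This is a property of the peak-Z>3 rule
itself, not of the implementation, and it matters downstream: any analysis
that unions significance over several partners (the Robot dominance rule)
inherits a multiplied false-pairing probability.

## Spike-train spectra

Spikes inside equal-length event-centered windows (±2.5 s around surges;
pellet procurements in non-threat sessions) are binned at 2 ms
(Nyquist 250 Hz), demeaned per window, and periodograms (Hann taper by
default) are averaged across windows; ≥5 s of data required. Band
fractions are % of total power in [1, 50] Hz; theta is fixed at [6, 10] Hz
(closed), other bands half-open so no grid frequency is double-counted.
With a boxcar taper the estimator satisfies Parseval exactly
(Σ PSD · Δf = variance of the binned train), which the tests assert. These
are point-process spectra of units, not LFP.

## Linkage

Per epoch, a place cell is **Robot-paired** if it has ≥1 significant pair
with a Robot-class pyramidal BA cell, **nonRobot-paired** if its
significant partners are only Pellet/NonResponsive cells, else
**unpaired**; RobotPellet partners and interneurons never count. A cell
paired with both types is Robot-paired (dominance rule; an `exclusive`
mode labels it `mixed` instead — the overlap handling was genuinely open
and the dominance default is the more conservative reading of "co-fired
with Robot cells"). Nest and proximal cells are merged into one
`nest_proximal` group for contrasts.

Group contrasts use a Lilliefors (KS) normality pre-test on both samples
(α = 0.05): Welch's t if both pass, Mann–Whitney otherwise. Groups smaller
than 3 are skipped with a warning. Stability-vs-position uses pooled OLS of
Z′ and peak distance on the pre-threat peak x (per-animal grouping would
require multi-day cohorts, which the simulator does not model).

Controls: (i) per-cell relative in-field speed change (field region = ±1
estimated field σ, the rate-weighted x dispersion of the pre-threat map)
vs Z′, per class; (ii) epoch firing-rate contrasts between pairing groups,
to show the stability effect is not a rate artifact.

## The synthetic cohort

The generator reproduces the *statistical structure* the analyses consume,
not behavior or biophysics:

- **Trajectory**: piecewise-scripted — ~6 s nest dwell (bounded random
  walk), gate opening, constant 30 cm/s outbound run; pre/post trials
  reach the pellet (procurement, 2 s dwell, 30 cm/s return); threat trials
  trigger a surge at x = 100 cm (= 125 − 25) and flee at 60 cm/s
  (default threat success probability 0). 10 trials/phase, 30 frames/s.
  Inter-surge intervals (~11 s) clear the 10 s exclusion by construction.
  Lateral y is a mean-reverting bounded wander (±5 cm) so 2-D maps are
  nondegenerate and sessions overlap in y coverage.
- **dHPC units**: inhomogeneous Poisson by thinning with
  λ(t) = base + (peak−base)·exp(−(x(t)−c)²/2σ²); defaults σ = 8 cm, peak
  12 Hz, base 1 Hz. `threat_shift` displaces c during the threat phase
  only; the reference shift is −30 cm (toward the nest) so the displaced
  field stays inside the threat foraging limit and the shift is
  observable. Optional theta modulation multiplies λ by
  (1 + d·sin 2π·8t) in the threat phase.
- **BA units**: baseline Poisson (4 Hz default) with multiplicative
  event-locked kernels (gain 5 excited / <1 inhibited, 0.2 s latency,
  1.5 s exponential decay). All trains get a 2 ms absolute refractory dead
  time — without one, Poisson trains violate the 1 ms inclusion criterion
  with near certainty, which is a fact about Poisson processes, not about
  neurons.
- **Synchrony injection**: each in-epoch BA spike spawns, with probability
  `excess`, a dHPC spike at the chosen lag ± 5 ms uniform jitter; trains
  re-sorted, deduplicated, clipped to the session.
- **Determinism**: every cell's stream is seeded from (cohort seed,
  CRC32(cell id), phase), so adding a cell never perturbs another, and a
  fixed seed reproduces the cohort and all downstream tables byte for
  byte.

**Reference cohort** (`default_cohort_config`): 3 robot + 2 pellet +
2 none BA pyramidal cells, 2 narrow-spike 16 Hz interneurons, 8 nest +
4 proximal + 16 remapping-distal + 16 stable-distal place cells. Every
included place cell is deliberately injected with either a Robot or a
nonRobot partner (excess 0.3, lag +30 ms, pre-surge epochs), so the two
pairing groups are compositionally homogeneous and the nest_proximal
contrast is a true null. Group sizes reflect the screen's ~9% per-pair
false-positive rate: with 3 robot partners per cell, roughly a quarter of
stable distal cells acquire a spurious Robot pairing, and 16-cell groups
keep the headline contrast robust to that dilution.

## What passing tests do and do not show

The simulator's trains are (refractory-thinned) Poisson with smooth rate
functions: no bursting, theta phase precession, rate adaptation,
cross-trial nonstationarity beyond the scripted events, or behavioral
variability. Recovery results therefore demonstrate the *estimators'*
correctness and calibration under their intended generative assumptions —
they do not certify performance on real tetrode data, where spike-sorting
noise, bursting, and slow drifts widen all the null distributions.
The experiment sizes (200 null pairs, 50–200 cells, 20 cohort seeds) were
chosen once as the package's reference conditions.

## Known limitations

- The CCG significance rule is a fixed threshold, not a multiplicity-
  corrected test; its ~9% pairwise false-positive rate is intrinsic and
  documented rather than corrected, because the downstream linkage logic
  is defined in terms of that rule.
- Place maps are effectively 1-D (corridor); 2-D field shape analytics are
  out of scope.
- The pyramidal/interneuron split assumes both types are present; it
  degrades gracefully (all-pyramidal with a warning) when not.
- `stability_by_pairing` treats cells as independent; shared-trial
  correlations between cells of one cohort are ignored, as in the pooled
  analyses it mirrors.
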
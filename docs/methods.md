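# Methods

`cerloop` has two halves: a spiking-network model of a cerebellar
parasagittal stripe that learns delay eyelid conditioning, and the
analysis stack used to interrogate that model (and equivalent recorded
data): eyelid-trace processing, single-unit spike-train statistics, and
slice-physiology estimators.  This note records the model, its
assumptions, the tunable parameters, and the design choices made where
the underlying biology or published description leaves the design open.

## Circuit model

Populations (full scale): 600 mossy fibers (MF), 12,000 granule cells
(GrC), 900 Golgi cells (GoC), 24 Purkinje cells (PC), 96 basket cells
(BC, 9 of which are designated PC-MLIs and receive PC feedback), 240
stellate cells (SC), 8 deep-nuclear cells (DCN) and 4 climbing fibers
(CF).  Cells live on a normalized 2-D sheet (x transverse, the
parallel-fiber axis; y sagittal).  Wiring is random within rectangular
*eligibility spans* at fixed convergence counts — 4 MF and 4 GoC per
granule cell, 20 MF + 100 GrC per Golgi cell, 40 GrC per MLI, 8 BC + 30
SC per PC, 100 MF + 24 PC per DCN cell.  Granule-cell axons contact
targets through narrow transverse rectangles (parallel-fiber beams);
MF->GrC and GoC->GrC spans are local squares.  Each granule cell makes
exactly one parallel-fiber synapse onto one PC, giving one plastic
weight per granule cell (12,000 at full scale).  Each of the 9 PC-MLIs
receives up to 6 PC collaterals, drawn only from PCs that the PC-MLI
does not itself inhibit (non-reciprocity, enforced exhaustively at build
time).  With feedback disabled the PC->PC-MLI projection is compiled
with zero edges and everything else is identical edge-for-edge at the
same seed.

### Neuron dynamics

Each neuron is a conductance-based point neuron on a 1-ms clock with one
excitatory and one inhibitory conductance accumulator and an adaptive
threshold.  Conductances decay exponentially and jump by a per-synapse
weight on presynaptic spikes (one-step delay everywhere; sub-ms
latencies are unrepresentable at dt = 1 ms).  The membrane update is
exponential Euler: V relaxes toward the conductance-weighted effective
reversal E_eff = (g_L E_L + g_e E_e + g_i E_i + I_bias) / g_tot at rate
g_tot per ms.  The explicit-Euler form diverges whenever g_tot exceeds
~2/ms, which trained networks reach routinely; the exponential form is
stable for any conductance and equals explicit Euler to first order.  A
spike fires when V crosses the threshold; V resets to E_leak and the
threshold jumps by dtheta, relaxing back to theta0 with tau_theta.
Threshold adaptation, not a refractory mechanism, carries spike-rate
adaptation.  `bias` is a constant depolarizing drive used to make PC,
DCN, GoC and MLI populations tonically active.

Numerical parameter values are not biological measurements; they were
tuned once so that, under background mossy-fiber drive alone, the
populations sit in their in-vivo-like ranges — granule cells sparse
(< 5 Hz mean), GoC tens of Hz, PC simple spikes ~55 Hz (in the 40–100 Hz
band), MLIs ~10–30 Hz, DCN tonically active ~30 Hz — and are versioned
in `cerloop.config` (`default_neuron_params`, `DEFAULT_WEIGHTS`).

### Stimulus coding and the trial loop

Mossy-fiber activity is stochastic (per-ms spike probability = rate x
dt).  3% of MFs are phasic CS fibers (a 120-Hz burst for the first
100 ms of the tone; silent otherwise), 3% tonic CS fibers (80–100 Hz for
the whole CS, reverting to a drawn 1–40 Hz background outside it), 5.2%
are DCN collaterals carrying a rate copy of smoothed DCN output, and the
rest fire at 1–40 Hz backgrounds.  The US drives each CF once at US
onset; CFs also fire spontaneously at 1 Hz.  Trials are 200 ms pre-CS +
CS (ISI + 50 ms, co-terminating with the US) + 150 ms post.  A session
is 12 nine-trial blocks, each starting with a CS-alone trial
(108 trials); intertrial intervals are drawn uniformly from 20–40 s (and
not simulated — network state carries over, with the pre-CS segment as
wash-in).

The virtual eyelid is the DCN population rate smoothed with a causal
exponential kernel (tau = 40 ms), baseline-subtracted per trial, scaled
by a fixed gain (0.1 mm/Hz) calibrated once on the trained ISI-500 run
so the asymptotic CR approaches full eyelid closure (~6 mm), then
frozen, and clipped at zero: below-baseline DCN output cannot open an
already-open eyelid, so naive short-ISI networks report zero rather
than negative "CR amplitudes".  Smoothing is causal so CR onsets cannot
be acausal.

### Nucleo-olivary closure of the learning loop

The probability of the US-evoked CF spike decreases linearly with the
virtual CR at US time (zero at a 60-Hz DCN elevation; gain exposed as
`nucleo_olivary_gain`).  This inhibitory feedback from the nuclei onto
the olivary US signal is what gives acquisition an asymptote: as CRs
grow, the LTD-inducing teaching signal withdraws, and the weights
equilibrate where CR size balances residual climbing-fiber drive.
Without it the timing rule would depress eligible synapses to the bound
on every paired trial regardless of behavioral success, and the
with/without-feedback comparison of net plasticity would be
meaningless.  This is the one addition beyond the minimal circuit
description, and it follows the standard bidirectional-learning
architecture of this simulation lineage.

### Plasticity

Granule->PC: every *threshold burst* of a granule cell (a run of >= 2
spikes with consecutive gaps <= 10 ms; burst time = first spike)
triggers LTD if the burst falls 100–300 ms before a CF spike at the
target PC, and LTP otherwise.  Steps are fractions of the weight
ceiling (LTD 0.012, LTP 0.0035 of w_max per event; LTD > LTP); weights
are clipped to [0, w_max] with w_max = 1.25 x the initial weight, so
most synapses show small net change while eligible CS-driven synapses
can depress fully — the regime in which net LTD outnumbers net LTP
after training.  LTP is a fixed per-burst step (not graded by CF-free
interval length); this is an interpretation of "otherwise LTP
occurred", chosen as the minimal discrete-event rule.

Mossy-fiber->DCN: synapses active during an abrupt PC-population pause
(rate < 25% of the trace mean for >= 50 ms) depress; those active
during strong PC activity (> 150% for >= 50 ms) potentiate.  Both
criteria are config-exposed; the rule is a small modulator in practice.

The PC->PC-MLI synapse is strong enough to silence a PC-MLI under
tonic Purkinje firing, so the designated PC-MLIs carry a compensatory
intrinsic drive (`pcmli_bias_extra`) sized to restore their baseline
rate; the compensation is tied to the feedback projection and omitted
in feedback-off builds, where the designated cells behave exactly like
other basket cells.

A locus switch selects {pf_pc_only, pf_mli_only, both}; the
pf_mli_only variant applies the same timing rule to granule->MLI
weights with inverted sign (potentiation inside the eligibility
window), which is the configuration in which MLIs acquire CS-driven
increases without any PC lead — used for the lead-lag model comparison.

## Desk-scale runs

`scale_factor` shrinks the granule layer (MF, GrC, GoC) while keeping
the cortical-output and molecular-layer populations at full count,
preserving every convergence ratio and rescaling the per-spike
parallel-fiber increment so each PC's total mean input conductance is
unchanged.  The reference desk-scale condition (used by the experiment
battery and the acceptance script) is 1/6 scale — 2,000 granule cells —
trained 10 sessions per condition.  Keeping all 24 PCs, 96 BCs and 240
SCs preserves the per-MLI correlation analyses (9 PC-MLIs among 336
MLIs).  Full-scale runs are supported but take tens of CPU-minutes per
training battery; all quantitative claims shipped with the package are
made at the desk scale, where effect directions, not the paper-scale
magnitudes, are the calibrated quantities.

## Analysis stack

* **Eyelid traces** (real or virtual, 1 kHz): zero-phase 4th-order
  Butterworth low-pass at 50 Hz (eyelid kinematics are < 20 Hz; cutoff
  config-exposed); baseline = mean of the 200-ms pre-CS segment; CR iff
  the trace reaches baseline + 0.3 mm before US onset; amplitude =
  position - baseline at US onset on the US-truncated trace.  CR onset
  uses the two-step algorithm: first sample exceeding baseline + 4
  pre-CS SDs sustained >= 20 ms, then a 20-ms line fit extrapolated
  back to baseline.  Thresholds are config-exposed; the 200-ms pre-CS
  segment is the baseline window throughout.
* **Rates**: one-sided (causal) Gaussian kernel, sigma = 25 ms, unit
  area — so US-evoked activity cannot contaminate the CS period, at the
  cost of a ~sigma lag and ripple at stimulus periodicities.  PC rates
  normalize by pre-CS baseline; MLI rates by the maximum of the
  session-averaged rate within the CS (equalizing 2x and 10x
  modulations).
* **CR correlation**: per CR trial, zero-lag Pearson r between the
  normalized rate and eyelid position over [-150 ms, US onset), means
  subtracted; averaged over CR trials.  Normalized (not raw) rates are
  used so units of different gain are comparable.
* **Two-Gaussian classification**: maximum-likelihood mixture fit.  EM
  on an unbalanced overlapping mixture is initialization-sensitive, so
  several inits are tried (random-from-data restarts plus a
  percentile-based init) and the best-likelihood fit with separated
  components is kept.  The cutoff r* is the smallest r whose posterior
  membership in the higher-mean component reaches 0.95 (the
  "0.95 probability" phrasing is ambiguous; the posterior reading is
  implemented, a low-component-tail reading is exposed as an option).
* **Triggered correlograms**: 1-ms bins over +-30 ms accumulated across
  10-s inter-trial epochs; the null is formed by permuting the trigger
  train's inter-spike intervals within each epoch (preserves rate and
  ISI marginal, destroys timing).  Z = (count - shuffle mean)/shuffle
  SD; significance needs >= 2 bins beyond |Z| = 3.34 excluding lag 0
  (95% two-sided with Bonferroni over the 60 usable bins — lag 0 is
  uninterpretable for same-tetrode pairs).  Pause/burst triggers are
  starts of the largest/smallest 35% of inter-spike intervals (50% for
  simulated trains); counts use ceiling rounding, threshold ties are
  all included, and a selection that degenerates to every interval
  (constant-ISI train) yields no triggers.  Event-triggered
  significance uses the post-vs-pre rule (>= 2 more significant bins
  after t = 0 than before).
* **Lead-lag**: per cell, the fraction of the full rate change
  (baseline to extremum within 100 ms post-onset at ISI 250, 150 ms at
  longer ISIs) completed at CR onset; trials whose window would overlap
  the US are excluded.  The pair statistic is the PC fraction minus the
  MLI fraction; positive values mean the PC changes first.
* **Grouping**: CR trials sorted by onset or amplitude into equal-count
  subgroups (remainder to the last group), non-CR trials as their own
  group, with pointwise 95% CIs on group-mean traces.
* **Synaptic physiology**: depression = exponential-plus-plateau fit to
  first-normalized IPSC amplitudes; steady state vs frequency by linear
  regression with an F-test; RRP/mobilization from an ordinary
  least-squares fit to the last 20 points of cumulative charge vs
  stimulus number (intercept = RRP, slope = mobilization per stimulus,
  x frequency for per-second; quantal conversion by mean quantal
  charge).  IPSC detection: >= 15 pA within 4–24 ms post-flash; onset
  and rise time from the 20–80% line.  Input maps keep pixels with
  detection probability >= 0.5 across repeats, drop 4-connected
  single-pixel islands, area = pixels x 256 um^2; footprints require
  spikes in all repeats; convergence = field area / mean footprint
  area.

## Synthetic data

The generators in `cerloop.synth` produce every input the analysis
stack reads, with ground truth persisted alongside.  Session data are
inhomogeneous Bernoulli spike trains (1-ms thinning) with sigmoid CR
profiles, a configurable PC lead over the MLI rise, and per-spike
inhibitory coupling in the 10-s baseline epochs implemented as
multiplicative rate suppression after each trigger spike.  IPSC trains
come from a two-pool vesicle model (release fraction x current pool,
replenishment = baseline + activity-locked term); the paper-matched
preset (pool 100 quanta, release fraction 0.07, mobilization 3.5
quanta/stimulus while active) reproduces the ~half-initial steady state
across 10–100 Hz and emulates trial-averaged trains (deterministic
release, quantal-size noise only), while the recovery preset (release
fraction 0.3, slow mobilization) is the deep-depletion regime in which
the cumulative-charge intercept is an accurate pool estimate.  What the
generators do *not* emulate: real spike-sorting artifacts, nonstationary
baselines, electrode drift, correlated noise across units, or the full
kinematics of unconditioned responses — so green tests certify the
analysis logic, not robustness to every failure mode of real
recordings.

## Known limitations

* Point neurons with a single exc/inh channel per cell; no
  multi-compartment dynamics, gap junctions, complex-spike waveforms,
  candelabrum or Lugaro cells.
* dt = 1 ms makes sub-ms synaptic latencies and within-bin coincidences
  unrepresentable; correlogram structure at lag 0–1 is correspondingly
  coarse.
* Only 8 DCN cells drive the virtual eyelid, so the trace carries
  Poisson noise of a few Hz even after smoothing; the 0.3-mm criterion
  therefore misclassifies some noise fluctuations as CRs on untrained
  trials, as it does on real data with small CRs.
* Desk-scale magnitudes (CR size in mm, correlation means) are
  calibrated quantities; cross-condition directions (with vs without
  feedback, pf_pc vs pf_mli locus) are the load-bearing results.
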
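# cerloop

Simulation and analysis toolkit for the cerebellar feedback circuit from
Purkinje cells (PCs) onto a subset of molecular-layer interneurons (the
"PC-MLIs"), studied through delay eyelid conditioning.

Cerebellar cortex is usually drawn as a feed-forward machine: mossy
fibers → granule cells → PCs → deep cerebellar nuclei (DCN), with
molecular-layer interneurons (MLIs) inhibiting PCs along the way.  PC
axon collaterals, however, inhibit a subset of basket cells, closing a
recurrent loop: when PCs pause, those PC-MLIs are disinhibited, fire
more, and deepen the pause in neighboring PCs.  `cerloop` packages

* a spiking-network model of a parasagittal stripe (600 mossy fibers,
  12,000 granule cells, 900 Golgi cells, 24 PCs, 96 basket + 240
  stellate cells with 9 designated PC-MLIs, 8 DCN cells, 4 climbing
  fibers) that learns eyelid conditioning via timed parallel-fiber
  LTD/LTP — with or without the PC→PC-MLI feedback projection;
* the behavioral and single-unit analyses used on such data: CR
  detection on 1-kHz eyelid traces, causal-kernel firing rates,
  trial-wise unit–behavior correlations and their two-Gaussian
  classification, spike/pause/burst-triggered cross-correlograms with
  shuffle nulls, and the PC-vs-MLI lead-lag statistic;
* slice-physiology estimators: IPSC-train depression kinetics,
  readily-releasable-pool (RRP) and vesicle-mobilization estimation
  from cumulative charge, quantal metrics, IPSC detection, and
  optogenetic input-field/footprint mapping;
* seeded synthetic-data generators (with ground truth) for every input
  the analysis stack reads.

## The model in brief

Each neuron is a conductance-based point neuron on a 1-ms clock,
`V → E_eff + (V − E_eff)·exp(−g_tot)` with
`E_eff = (g_L E_L + g_e E_e + g_i E_i + I_bias)/g_tot`, spiking when V
crosses an adaptive threshold (θ ← θ + Δθ per spike, relaxing to θ0
with τ_θ).  Granule→PC synapses obey the timing rule: a granule-cell
burst induces LTD when it falls 100–300 ms before a climbing-fiber
spike at the target PC, LTP otherwise; mossy-fiber→DCN synapses
depress/potentiate with PC-population pauses/high activity.  The tone
CS drives phasic (3%) and tonic (3%) mossy fibers, the eyelid-shock US
drives the climbing fibers, and the smoothed DCN population rate is the
virtual eyelid response.  The US-evoked climbing-fiber spike is
suppressed in proportion to the ongoing virtual CR (nucleo-olivary
feedback), which gives acquisition its asymptote.  See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Train two desk-scale networks (1/6 granule layer, full PC/MLI
complement) at ISI 500 ms, with and without PC feedback, and correlate
each MLI's activity with the virtual conditioned response:

```python
import numpy as np
from cerloop import experiments as ex

fb = ex.train_network(isi=500, feedback=True, n_sessions=10, seed=1)
print(np.round(fb.session_amplitudes, 2))
# [0.87 1.39 1.79 3.03 3.02 2.8  3.73 4.04 3.99 3.71]

corr = ex.mli_correlation_analysis(fb)
print(round(corr["mean_r_pcmli"], 3), round(corr["mean_r_other"], 3))
# 0.462 -0.006
```

The session amplitudes are the mean virtual CR (mm of eyelid closure at
US onset) per 108-trial session: acquisition rises over sessions toward
an asymptote.  After training, the nine PC-MLIs — and only they — are
strongly correlated with the CR (mean r ≈ 0.46), while the other 327
MLIs sit at r ≈ 0: removing the feedback projection collapses the
distribution to a single mode at zero.  `ex.bimodality_bic` makes that
comparison explicit (two-component fit preferred only with feedback),
and `ex.leadlag_analysis` shows PC rate decreases leading PC-MLI
increases at CR onset (mean ΔPC − ΔMLI > 0).

The same analyses run on recorded data through the CLI:

```bash
cerloop simulate-data session --seed 2 --out data/        # or real CSVs
cerloop analyze correlate --in data/ --out results/
cerloop analyze mixture   --in data/ --out results/
cerloop reciprocity --pairs 10 --p 0.5 --draws 100000
```

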
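# lplnet

Latent predictive plasticity for rate neurons, layer-locally trained
networks and conductance-based spiking networks.

The core learning rule combines three local ingredients:

* a **predictive** term that pulls a neuron's response toward its own
  response to the previous input (finite-difference temporal derivative),
* a **variance-modulated Hebbian** term — the gradient of the negative
  log variance of the neuron's activity — whose running mean acts as a
  BCM-like sliding plasticity threshold and whose running variance
  implements metaplasticity,
* a **decorrelation** term between neurons of one layer (played by
  inhibitory spike-timing-dependent plasticity in the spiking networks).

## Package layout

| module | contents |
| --- | --- |
| `lplnet.synthetic_data` | 2D cluster pair sequences, slow Fourier rate signals with shuffled controls, inhomogeneous Poisson rasters, latent-factor glyph videos |
| `lplnet.rate_lpl` | objective components, closed-form weight updates, moment estimators, the sliding-threshold form, Oja's rule, single-neuron training |
| `lplnet.deep_lpl` | layer-local training of rate-layer stacks (stop-gradient between layers), ablations, toy contrastive baseline |
| `lplnet.snn_core` | fixed-step conductance-based LIF network with axonal delay, spiking predictive/Hebbian rule on input synapses, rate-target inhibitory STDP |
| `lplnet.plasticity_protocols` | spike-pairing induction protocols on a voltage-clamped neuron: timing windows, rate dependence, metaplastic state sweeps |
| `lplnet.metrics` | selectivity ratios, participation ratio, linear readout, L1 signal reconstruction, representational similarity, disentanglement score |
| `lplnet.cli_io` | YAML experiment configs, manifest-stamped experiment runner, raster/matrix/curve I/O, the `lpl` CLI |

The hot simulation loops (network simulation and induction protocols)
run through numba kernels in `lplnet._kernels`; the pure-numpy reference
paths are kept and cross-checked by the test suite
(`backend="numpy"` arguments).

## CLI

```sh
lpl stdp --out results/stdp               # STDP timing window, CSV + JSON
lpl single-neuron --seed 3 --out results/sn
lpl snn --config my_snn.yaml --out results/snn
lpl train --out results/train             # layer-local network training
lpl metrics --out results/metrics
```

Configs are YAML files with an `experiment:` key plus per-experiment
parameters (unknown keys are rejected, defaults are filled in and logged;
every run writes `manifest.json` with the resolved config and its hash).

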
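# colspike

A sparsely spiking columnar neural network for unsupervised representation
learning and attractor associative memory, together with its task generators
and evaluation metrics.

The model wires three populations — an input population (`INP`), a hidden
population (`HID`), and an input-reconstruction population (`INPRC`) — with
feedforward, recurrent, and feedback projections.  Each population is a grid
of hypercolumn modules whose minicolumn units compete through a softmax over
the membrane voltage; units emit either the softmax probability itself
(rate mode) or Bernoulli spike samples scaled by a maximum firing rate
(spiking mode, e.g. ~1 Hz mean / 100 Hz peak per unit at `f_max = 100 Hz`).
Learning is Bayesian-Hebbian: exponential spike filters (z-traces) feed
slow probability estimates (p-traces) that map onto log-prior biases and
point-wise-mutual-information weights.  An activity-dependent rewiring rule
learns sparse patchy connectivity by greedily flipping silent/active
connection patches ranked by a normalized mutual-information score.

Six model variants (`rate_ff`, `rate_full`, `spk_ff`, `spk_full`,
`spspk_ff`, `spspk_full`) share one implementation and differ only in
parameter bindings (activation mode, `f_max`, time constants, phase
durations).

## Layout

| Module | Contents |
| --- | --- |
| `colspike.synapse` | z-/p-trace cascade, bias/weight transform |
| `colspike.population` | membrane dynamics, hypercolumn softmax, spike sampling, pixel-intensity input encoding |
| `colspike.rewiring` | patch connectivity, mutual-information scores, greedy flip rewiring |
| `colspike.network` | populations + projections, phased train/eval protocol, the six variants |
| `colspike.datasets` | synthetic prototype datasets, IDX (MNIST-format) I/O, completion / rivalry / distortion test-set generators |
| `colspike.metrics` | Gaussian-kernel rate estimation, cosine-similarity matrices, orthogonality ratio, prototype extraction, linear readout (Adam) |
| `colspike.experiments` | firing statistics, train-and-score, (f_max, tau_m, tau_z) sweep, task battery |
| `colspike.cli` / `colspike.config` | command line, YAML configs, run manifests |
| `colspike.checkpoint` | full network state as a hierarchical `.npz` archive |

## CLI

```sh
colspike train --variant spspk_full --config cfg.yaml --seed 1 \
    --checkpoint net.npz --manifest run.yaml
colspike eval  --checkpoint net.npz --record-times 0.1,0.3 --out reps.npz
colspike tasks --task completion --out-dir tasks/
colspike report --checkpoint net.npz --out-dir report/
colspike sweep --variant spspk_full --f-max 100 --tau-z 0.001 --tau-z 0.02 \
    --out sweep.csv
```

Config keys mirror the model parameter names (`f_max`, `tau_zi`, `tau_zj`,
`tau_p`, `tau_m`, `T_no_input`, `T_ffwd`, `T_overlap`, `T_recr`,
`N_conn_ff`, `N_conn_rec`, `N_conn_fb`, `N_flipconn`, `N_intvconn`).
Defaults are the full-scale reference parameters (784x2 input, 100x100
hidden, connection counts 78/100/10); tests and examples run at a reduced
CI scale.  Full-scale training (20 epochs x 60,000 patterns) is supported
but takes cluster-scale time and is not part of the test surface.

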
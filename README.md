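# hebbnet

From-scratch training of deep networks with **asymmetric feedback
connections and Hebbian updates**. Every layer keeps a feedforward
weight matrix `W` and a physically separate feedback matrix `R`; the
error signal travels top-down through `R`, replaces unit activity, and
every synapse changes only by the product of the activities of the two
units it connects.

Three training modes share one code path:

| mode   | feedback             | R update                          |
|--------|----------------------|-----------------------------------|
| `bp`   | transpose of `W`     | kept equal to `W` transposed      |
| `urfb` | separate random `R`  | same Hebbian increment as `W`     |
| `frfb` | separate random `R`  | never updated                     |

Also included:

- saturated-linear activation `min(max(h,-1),1)` with its hard gate
  (saturated units pass no error);
- a one-vs-all **hinge loss** whose top-layer error signal is local to
  each output unit, plus a softmax/cross-entropy comparator;
- tied convolutions and their **untied (locally connected)** sparse
  counterparts with independent per-entry updates;
- max-pooling with argmax error routing, per-batch dropout (no
  rescaling), residual SUM stages;
- optional random pruning of feedforward and feedback connectivity
  (independent masks, so connectivity itself is asymmetric);
- alignment diagnostics (Pearson correlation of `W` vs `R` transposed)
  and cross-location filter-similarity measurements with a permutation
  test;
- a **linear-network gradient-flow simulator** interpolating between
  fixed (`eps=0`) and updated (`eps=1`) feedback, with error and
  alignment trajectories;
- a deterministic synthetic image generator (class-specific oriented
  patterns repeated across space) so everything runs offline.

## CLI

```bash
# train a preset or an architecture string on the built-in toy data
hebbnet train --arch simpnet --mode urfb --epochs 10 --out runs/demo
hebbnet train --arch "Conv 8 5x5; Maxpool 3; Drop .8; Full 64; Output" \
    --mode urfb --n-per-class 200 --epochs 30 --seed 1 --out runs/toy

# matched-seed comparison of training modes
hebbnet compare-modes --arch "Conv 8 3x3; Maxpool 3; Full 32; Output" \
    --modes bp,urfb,frfb --epochs 20 --out runs/cmp

# evaluate a checkpoint
hebbnet evaluate --arch "Conv 8 3x3; Maxpool 3; Full 32; Output" \
    --checkpoint runs/toy/checkpoint.h5

# linear-dynamics epsilon sweep (CSV per run + summary JSON)
hebbnet simulate-linear --dims 40,100,100,10 --epsilons 0,0.25,0.5,1 \
    --steps 1000 --dt 0.005 --seeds 0,1,2 --out runs/lin
```

Architecture strings use the compact layer notation, e.g.
`Conv 32 5x5; Maxpool 3; Drop .8; Full 500; Drop .3; Output`; presets
`simpnet`, `deepnet`, `deepernet`, `deepnet_s` are built in. All flags
can instead be given in a YAML file via `--config`. Runs write
`metrics.csv` (per-epoch errors, loss, per-layer alignment),
`checkpoint.h5` (bit-exact weight round trip), and `manifest.json`
(full resolved config; re-running from it reproduces the metrics
byte-for-byte).

## Layout

- `src/hebbnet/activations.py` — saturated linearity, gate, hinge and
  softmax losses and their top-layer error signals
- `src/hebbnet/layers.py` — dense / tied-conv / untied-local forward,
  feedback, and Hebbian increment primitives; pooling, dropout, SUM
- `src/hebbnet/network.py` — architecture parsing, network assembly,
  the sequenced forward/feedback/update loop, training and evaluation
- `src/hebbnet/linear_dynamics.py` — deep linear-network flow and
  epsilon sweeps
- `src/hebbnet/diagnostics.py` — alignment correlation, filter
  similarity, permutation test
- `src/hebbnet/synthetic.py` — toy image and separable-blob generators
- `src/hebbnet/runner.py`, `src/hebbnet/cli.py` — experiment
  orchestration and the `hebbnet` command
- `src/hebbnet/io.py` — HDF5 checkpoints/datasets, metrics CSV,
  manifests
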
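# trajdmi

**Dynamical mutual information (dMI) from single-cell signaling trajectory
ensembles.**

Cells encode the identity of an environmental stimulus in the *temporal pattern* of
signaling activity — amplitude, oscillation, duration — not just in a snapshot.
Quantifying how much stimulus information a response time course carries, and when
it becomes available, is hard because the number of possible trajectories grows
combinatorially with timepoints.  `trajdmi` addresses this by learning a stochastic
model of each condition's trajectory ensemble (a time-inhomogeneous Markov model or
a hidden Markov model fitted by Baum–Welch), inferring each trajectory's probability
with the forward algorithm, and computing the mutual information between stimulus
conditions S and response trajectories R cumulatively up to each timepoint n:

    I(R_{1:n}; S) = H(R_{1:n}) − H(R_{1:n} | S),        H(y_{1:n}) = −log2 p(y_{1:n})

maximized over the stimulus-weight distribution q on the probability simplex.  The
resulting curve I_max(n) shows how stimulus-discriminating information accumulates
over time; it is bounded by log2 M for M conditions and, unlike timepoint- or
vector-based MI estimates, it *decreases when timepoints are shuffled* — it genuinely
reads the dynamics.  The package targets single-cell time series such as NF-κB
nuclear-activity reporters in macrophages, and applies to any cells × timepoints
response matrices.

It also ships the model-quality toolkit needed to trust the numbers: relative
KL-divergence and false k-nearest-neighbor mixing between data and model samples,
rescaled held-out log-likelihood, and a split-half dMI protocol that detects
overfitting (which otherwise silently inflates MI estimates).

## Worked example

Two fully distinguishable synthetic conditions, each an ensemble of 200
trajectories × 60 timepoints drawn from a ground-truth hidden Markov process with
its own emission symbols; fit one HMM per condition and compute the curve:

```python
from trajdmi import DynamicalMI, ModelConfig, ToySpec, generate_toy_hmm_ensembles

spec = ToySpec(n_conditions=2, separation=1.0, n_traj=200, length=60, seed=7)
ensembles, truth = generate_toy_hmm_ensembles(spec)
config = ModelConfig(family="hmm", n_hidden=2 * spec.alphabet_size)
result = DynamicalMI(ensembles, config=config).fit(seed=7)
print(result.summary())
```

```
               Dynamical mutual information
==========================================================
Conditions (M):        2
Model family:          hmm
Emission symbols:      4
Hidden states:         8
Timepoints (N):        60
Seed:                  7
----------------------------------------------------------
Max dMI @ final n:     1.0000 bits (ceiling log2 M = 1.0000)
Uniform-q dMI:         1.0000 bits
Optimal stimulus weights @ final n:
    toy_0                      0.5000
    toy_1                      0.5000
==========================================================
```

The curve saturates at 1 bit = log2 2: the two conditions are perfectly
distinguished, and the optimal weighting is uniform by symmetry.  Four disjoint
conditions saturate at 2 bits.  `result.curve.to_frame()` gives the per-timepoint
table, `result.plot()` the accumulation curve, and
`trajdmi.permute_timepoints` the shuffled control.

The same workflow is available from the shell:

```
trajdmi simulate --preset toy-m2 --seed 7 --out sim/
trajdmi fit-evaluate --manifest sim/manifest.yaml --binning equal_width \
    --emission-states 4 --seed 7 --out eval/
trajdmi dmi --manifest sim/manifest.yaml --binning equal_width \
    --emission-states 4 --shuffle --seed 7 --out curves/
```

Input format: one delimited matrix (CSV/TSV, header row of timepoints, one row per
cell) per condition plus a small YAML manifest; see `trajdmi config init` for all
defaults.

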
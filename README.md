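# pepqsar

QSAR modelling of ACE-inhibitory dipeptides, with an applied layer for
choosing protein substrates and proteases.

Angiotensin-converting enzyme (ACE) inhibition lowers blood pressure, and
short food-derived peptides can inhibit ACE; their potency is reported as
log(1/IC50). `pepqsar` models the structure–activity relationship of
dipeptides: each residue is described by its three Z-scale descriptors
(z1 hydrophilicity, z2 size/shape, z3 electronic properties), so a dipeptide
is a 6-vector (Z11, Z12, Z13, Z21, Z22, Z23). Descriptors and activity are
min-max normalized,

    z' = (z − z_min) / (z_max − z_min),

and a three-layer feed-forward network

    ŷ = b2 + lw · tanh(iw·z' + b1)

is trained by full-batch gradient descent with momentum on the MSE
(Δw(t) = momentum·Δw(t−1) − η·∇MSE), stopping at a goal error or an epoch
cap. The package ships the classic 58-dipeptide activity benchmark (with a
data-quality audit of its known inconsistencies), a hidden-layer-size
selection sweep, and the "back-stepping" interpretation: rank hidden neurons
by |hidden→output weight|, then rank inputs by the path-strength aggregate
Σⱼ |lwⱼ·iwⱼᵢ| through the top neurons. On the benchmark this analysis
identifies Z21 — hydrophobicity of the C-terminal residue — as the dominant
driver of activity.

Around the model sit the applied tools: hydrophobic/aromatic content of a
protein (from a composition table or a FASTA sequence), protease C-terminal
specificity screening with QSAR-scored candidate dipeptides, and the
wet-lab calculators (pH-stat degree of hydrolysis, average peptide chain
length, ACE-inhibition percentage from plate-reader absorbances).

The core is exposed both as functions (`train_protocol`, `sweep_hidden`,
`backstep_importance`, ...) and as scikit-learn estimators
(`BPNetRegressor`, `ZScaleEncoder`) that compose with sklearn pipelines.

## Worked example

Train with the benchmark protocol (random 39/19 split, 7 hidden neurons,
best of 20 restarts) and inspect the result:

```sh
$ pepqsar train --seed 1 --model-out model.json
{
 "best_restart": 5,
 "epochs_run": 1660,
 "converged": true,
 "train":   {"r": 0.969, "mse": 0.0025, "n": 39},
 "test":    {"r": 0.618, "mse": 0.0349, "n": 19},
 "overall": {"r": 0.844, "mse": 0.0131, "n": 58},
 ...
}
```

The winning restart fits the 39 training dipeptides tightly (r = 0.97 at the
goal error 0.0025 on [0,1]-normalized activities) while the 19 held-out
dipeptides correlate at 0.62 — a reminder of how little 39 points constrain
a 57-parameter network. Predictions come back on the raw activity scale:

```sh
$ pepqsar predict --model model.json --peptide IW --peptide GG
{"IW": 3.94, "GG": 2.00}
```

(IW's measured log(1/IC50) is 5.7 — the strongest inhibitor in the set —
and GG's is 2.14.)

The interpretation step on the packaged reference weight tables:

```sh
$ pepqsar interpret --k-top 2
neuron        Z11        Z12        Z13        Z21        Z22        Z23
(1)     -0.35150    0.28331    0.28286   -0.44043    0.03743   -0.08545
...
(6)  *  -0.30588    0.21639    0.03636   -0.41676   -0.25140   -0.23479
(7)  *  -0.09032   -0.05840    0.07450   -0.32458   -0.24483   -0.10795
score     0.52126    0.36223    0.13775    0.94972    0.63117    0.44602
ranking: Z21 > Z22 > Z11 > Z23 > Z12 > Z13
```

Hidden neurons 6 and 7 carry the largest output weights (−1.3532 and
1.1885); through them, input Z21 scores 0.950 and Z22 0.631 — the C-terminal
residue's hydrophobicity, then its size/shape, dominate predicted activity.

The assay calculators are plain formula evaluators:

```sh
$ pepqsar dh --v-naoh 5 --n-naoh 1 --m-protein 10 --ph 9
{"dh_percent": 13.0039, "average_chain_length": 7.69}
```

Other subcommands: `sweep` (hidden-size selection), `evaluate`,
`validate-data` (audit of the benchmark table), `composition`, `digest`
(protease ranking for a FASTA protein), `ace`, `synth` (synthetic datasets
with known structure), `encode`.

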
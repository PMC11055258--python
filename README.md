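# wmigcn — lead-graph arrhythmia classification for 12-lead ECG

`wmigcn` classifies cardiac rhythm from 12-lead ECG by treating the
recording as a graph: the 12 standard leads (I, II, III, aVR, aVL, aVF,
V1–V6) are nodes, and the edge weights are estimated from the statistical
dependence between the lead time series. It is aimed at researchers in
biomedical signal processing who want a self-contained, reproducible
implementation of mutual-information lead graphs and spatial graph
convolution, testable end to end without any external dataset.

## The model

**Lead graph.** For a record with leads X₁..X₁₂, pairwise dependence is
measured by mutual information estimated with the plug-in estimator on an
equal-width discretization (default 16 bins, log base 2):

    I(Xᵢ; Xⱼ) = H(Xᵢ) + H(Xⱼ) − H(Xᵢ, Xⱼ)

MI captures nonlinear as well as linear coupling, which matters because
lead series are autocorrelated and non-Gaussian. The **weighted MI (WMI)**
adjacency additionally encodes ECG electrophysiology: leads sharing an
electrical pole cluster — bipolar limb (I, II, III), augmented unipolar
limb (aVR, aVL, aVF), precordial (V1–V6) — are clinically more similar, so
their edges are doubled:

    A(i, j) = MI(i, j) · (1 + r(Qᵢ, Qⱼ)),   r = 1 iff leads i, j share a cluster

Each record gets its own graph. The ablation baselines are the raw MI
matrix and the identity matrix (inter-lead structure ignored).

**Classifier.** A spatial graph convolutional network whose filters are
polynomials in the adjacency,

    H = h₀I + h₁A + … + h_K A^K,    V_out = H·V_in

with learnable coefficients h_k per channel pair (default K = 2). Layers
apply the filter bank, a bias, a rectifier and dropout; node embeddings
from several depths (Z₀, a middle layer, the last layer) are concatenated,
flattened over the 12 nodes and fed to a softmax head. Training is
full-batch Adam with decoupled weight decay (lr 0.02, dropout 0.2, weight
decay 5e-4, early-stopping patience 10), implemented directly in NumPy with
hand-derived gradients that are finite-difference checked in the test
suite.

**Evaluation.** Classes rarer than 2% of records are excluded; models are
compared with stratified 4-fold cross-validation, out-of-fold confusion
matrices, per-class one-vs-rest sensitivity/precision/specificity/accuracy,
and pairwise independent t-tests on fold accuracies.

**Synthetic data.** Because the pipeline only consumes statistical
structure, the bundled generator emulates 12-lead records as mixtures of a
shared quasi-periodic source at a class-specific beat rate, three
cluster-shared band-limited noise sources, and lead-private noise — so
rhythm classes differ by rate and by within-cluster coupling strength,
exactly the structure the lead graph is designed to detect.

## Worked example

```python
import wmigcn as w

records, manifest = w.generate_dataset(w.default_spec(n_records_per_class=100, seed=0))
m = w.mi_matrix(records[0], n_bins=16)
a = w.wmi_matrix(m)
```

For one synthetic record this prints (bits):

```
H(I) = 3.348  MI(I,II) = 1.267  MI(I,aVR) = 0.267  MI(I,V1) = 0.248
WMI(I,II) = 2.533  WMI(I,V1) = 0.248
```

Leads I and II share the bipolar-limb cluster, so their MI is high and
doubled by the weighting; I and V1 sit in different clusters, so their
(already lower) MI is unchanged. Running the three-variant comparison,

```python
cfg = w.GCNConfig(n_layers=5, hidden_channels=32, epochs=100, node_feature_length=250)
result = w.run_ablation(records, config=cfg, k=4, seed=0)
print(result.summary())
```

```
Adjacency-variant ablation (4-fold CV, seed 0)
======================================================
variant     acc mean   acc sd  per-fold accuracies
wmi           0.6267   0.1072  0.573 0.507 0.680 0.747
mi            0.5333   0.0288  0.560 0.547 0.493 0.533
identity      0.3367   0.0548  0.320 0.373 0.267 0.387

pairwise independent t-tests on fold accuracies:
  wmi vs mi: mean diff +0.0933, t = 1.681, p = 0.1437 (df 6)
  wmi vs identity: mean diff +0.2900, t = 4.816, p = 0.0030 (df 6)
  mi vs identity: mean diff +0.1967, t = 6.350, p = 0.0007 (df 6)
```

The cluster-weighted graph (WMI) classifies best, the unweighted MI graph
next, and the structure-blind identity baseline is near the 3-class chance
level — the lead-graph structure, not the raw waveforms, carries the class
signal in this synthetic world.

A command-line interface wraps the same pipeline:

```sh
wmigcn synth --out data --n-per-class 50
wmigcn structure data --variant wmi --out adjacency
wmigcn ablation --synthetic-n 100 --k 4 --seed 0 --out study
```

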
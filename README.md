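# semgkit

Feature-extraction and classification strategies for multichannel surface
electromyogram (sEMG) finger-gesture recognition.

Surface EMG records the electrical activity of forearm muscles through skin
electrodes; decoding which finger movement produced a short multichannel
recording is a core problem in neuro-prosthetic control. `semgkit`
implements four complementary decoding strategies over a shared trial data
model (trials of shape *samples × channels* at a fixed sampling rate, one
integer gesture label per trial), plus a synthetic sEMG generator so every
stage can be exercised and benchmarked without access to laboratory
recordings.

## The four strategies

1. **Dynamic graph + graph entropy.** Each trial is split into time
   intervals; for every ordered channel pair the Granger causality test is
   run (F-test on restricted vs unrestricted autoregressions, α = 0.05).
   The *spurious correlation coefficient* weights an edge between channels
   *p, q*:

   R(p,q) = 1 if C(p,q) = 0, otherwise C(p,q) − |PCC(p,q)|,

   where C is the binary causality indicator and PCC the Pearson
   correlation. Vertex entropy e(vᵢ) = −Σⱼ R(vᵢ,vⱼ) ln R(vᵢ,vⱼ) and its sum
   over vertices (graph entropy) per interval form the feature vector.
2. **Manifold reduction + belief-network/ELM hybrid.** Per-trial amplitude
   descriptors are embedded by local tangent space alignment (LTSA) or
   locally linear coordination (LLC, an EM-fitted mixture of probabilistic
   PCA models aligned through the LLE eigenproblem). The classifier stacks
   restricted Boltzmann machines trained greedily by one-step contrastive
   divergence; an extreme-learning-machine readout β = H⁺T (Moore–Penrose
   pseudo-inverse) sits on the last hidden layer, optionally fine-tuned by
   backpropagation, with particle swarm optimization searching the hidden
   topology.
3. **EWT + differential entropy + HFCM.** Each channel is padded by
   nearest-neighbour forecasting, decomposed by a Meyer-type empirical
   wavelet filter bank into adaptive spectral bands, and summarized by
   windowed differential entropy h = ½ ln(2πeσ̂²). A high-order fuzzy
   cognitive map — a tanh-squashed linear recurrence over *h* lags with the
   bands as nodes — is fitted to the entropy series; its weights and the
   per-band entropy statistics are the features.
4. **LMD + fuzzy C-means + hybrid-kernel LS-SVM.** Local mean
   decomposition factors each channel into product functions (envelope ×
   pure FM carrier); envelope and instantaneous-frequency statistics are
   encoded by fuzzy C-means memberships and classified by a least-squares
   SVM whose kernel is the convex mixture
   K = a·K_RBF + (1−a)·K_poly, solved as a single KKT linear system.

A benchmark harness reports sensitivity, specificity, accuracy and a good
detection rate (macro recall) under stratified cross-validation for every
strategy/classifier combination.

## Worked example

```python
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from semgkit import GraphEntropyFeatures, crossval, fast_config, generate

ts = generate(fast_config(seed=1))        # 5 gestures x 12 trials, 8 ch, 1 kHz
X = GraphEntropyFeatures().transform(ts)  # (60, 36): T*(1+n_channels) entropies
res = crossval(X, ts.labels, make_pipeline(StandardScaler(), SVC(C=10.0)),
               folds=5, seed=0)
print(f"accuracy {res['acc']:.1f}% +- {res['acc_sd']:.1f}")
```

prints

```
accuracy 95.0% +- 4.1
```

i.e. the graph-entropy features separate the five synthetic gesture classes
nearly perfectly (chance level 20%), because the generator plants
class-specific directed lag-1 coupling between channel pairs that the
Granger stage detects. The same `crossval` contract works for every other
strategy; `semgkit bench --fast --seed 1 --out report.csv` runs all four
and writes the full table.

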
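# renyifs

Rényi min-entropy feature selection for multiclass motor-imagery EEG, with
wavelet-packet feature extraction and the conventional information-theoretic
baselines.

## The problem

Four-class motor-imagery brain–computer interfaces (left hand / right hand /
feet / tongue) classify short EEG epochs recorded during imagined movement.
A wavelet packet transform (WPT) of each epoch produces a large bank of
sub-band statistics — a level-5 decomposition with four statistics per
terminal node yields 128 features per channel, 1280 for a 10-channel
montage — far more than a few hundred trials can support.  Which handful of
features should the classifier see?

This package implements selection by **conditional Rényi min-entropy**.
For the class variable $C$ and a candidate feature $f$ conditioned on the
already-selected set $Q^t$ (features discretized by equal-frequency
binning), the greedy recursion is

$$Q^0 = \emptyset,\qquad
f^{t+1} = \arg\min_{f \notin Q^t} H_\infty(C \mid f, Q^t),\qquad
Q^{t+1} = Q^t \cup \{f^{t+1}\},$$

where $H_\infty(X\mid Y) = -\log_2 \sum_y \max_x p(x,y)$.  The criterion is
tied to the **Bayes risk** — the error probability of the best guess of the
class after observing the selected features — by
$H_\infty(C\mid Q) = -\log_2\bigl(1-\beta(C\mid Q)\bigr)$, which supplies a
natural stopping rule: stop once $\beta(C\mid Q^t) < \varepsilon$, i.e. once
the selected subset already supports training accuracy $1-\varepsilon$.
Minimizing $H_\infty(C\mid f,Q^t)$ is equivalent to maximizing the
min-entropy mutual information $I_\infty(C; f\mid Q^t)$, and the package
verifies this equivalence at runtime.

Two conventional baselines are included: the same greedy recursion driven by
conditional Shannon entropy $H_1(C\mid f,Q^t)$, and univariate ranking by
Shannon mutual information $I_1(C;f)$ — which is blind to redundancy and to
interaction-borne signal (an XOR pair scores zero univariately).

Because the selection layer conditions on what is already chosen, it finds
complementary features: on synthetic four-class sessions, three selected
sub-band features out of 1280 candidates match the all-feature baseline.

## Worked example

```python
import numpy as np
from renyifs import (JointDistribution, bayes_risk, conditional_min_entropy,
                     min_entropy_mutual_information)

j = JointDistribution(np.array([[0.4, 0.1], [0.2, 0.3]]))
print(bayes_risk(j))                     # 0.30000  best-guess error
print(conditional_min_entropy(j))        # 0.51457  bits, = -log2(1 - 0.3)
print(min_entropy_mutual_information(j)) # 0.48543  bits
```

A full pipeline run (`python examples/05_end_to_end.py`) trains on one
synthetic session and tests on a second:

```
          criterion    classifier  n_selected  mean_accuracy
               none           svm        1280       1.000000
mutual_info_ranking           svm          16       1.000000
shannon_conditional           svm           3       0.982639
  renyi_min_entropy           svm           3       0.986111
```

Three conditionally-selected features recover essentially the full-bank
accuracy.  `examples/04_xor_selection.py` shows the sharper contrast: on an
XOR construction the conditional criteria reach accuracy 1.000 while the
top univariate-MI features sit at 0.537 (chance 0.5).

The `renyifs` console script exposes the same stages for shell use:
`simulate`, `preprocess`, `extract`, `select`, `classify`.

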
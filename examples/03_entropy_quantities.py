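"""The information-theoretic quantities behind the selection criterion.

For a worked joint p(class, cell) = [[0.4, 0.1], [0.2, 0.3]]:
the conditional min-entropy -log2(sum of column maxima) measures how
uncertain the best guess of the class remains after seeing the feature
cell, and ties exactly to the Bayes risk (the error of that best guess).
"""

import numpy as np

from renyifs import (DiscreteDistribution, JointDistribution, bayes_risk,
                     conditional_min_entropy, min_entropy,
                     min_entropy_mutual_information, renyi_entropy,
                     shannon_entropy, shannon_mutual_information)

j = JointDistribution(np.array([[0.4, 0.1], [0.2, 0.3]]))
beta = bayes_risk(j)
h_inf = conditional_min_entropy(j)
print(f"Bayes risk beta(X|Y)        = {beta:.5f}   (best-guess error)")
print(f"H_inf(X|Y)                  = {h_inf:.5f} bits")
print(f"-log2(1 - beta)             = {-np.log2(1 - beta):.5f} bits  (identical)")
print(f"I_inf(X;Y)                  = {min_entropy_mutual_information(j):.5f} bits")
print(f"I_1(X;Y) (Shannon)          = {shannon_mutual_information(j):.5f} bits")

d = DiscreteDistribution(np.array([0.5, 0.25, 0.25]))
print()
print("Renyi family interpolates Shannon (delta->1) and min-entropy (delta->inf):")
print(f"  H_1    = {shannon_entropy(d):.5f} bits")
for delta in (2, 10, 1000):
    print(f"  H_{delta:<4} = {renyi_entropy(d, delta):.5f} bits")
print(f"  H_inf  = {min_entropy(d):.5f} bits")
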
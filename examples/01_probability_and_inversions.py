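"""The response curve and its closed-form inversions.

Evaluates the time-aware correct-response probability for one item,
shows the no-time-pressure (3PL) ceiling, and inverts the curve to find
the ability and transformed-time thresholds needed to reach p = 0.5.
"""

import numpy as np

from g3plt import (ItemParams, response_probability,
                   response_probability_3pl, ability_given_probability,
                   time_given_probability)

item = ItemParams(a=[1.5], b=[1.0], c=[0.1], D=1.7)

print("item: a=1.5, b=1.0, c=0.1, D=1.7")
for theta in (0.0, 1.0, 2.0):
    for t in (-0.2, 1.0, 8.0):
        p = response_probability(theta, item, np.array([t]))[0]
        print(f"  theta={theta:+.1f}  t*={t:+.1f}  ->  p = {p:.3f}")
p3 = response_probability_3pl(1.0, item)[0]
print(f"no-time-pressure ceiling at theta=1.0 (plain 3PL): p = {p3:.3f}")

theta_min = ability_given_probability(item, 0.5)[0]
t_min = time_given_probability(item, 0.5)[0]
print(f"\nto ever reach p = 0.5 this item needs ability  >= {theta_min:.4f}")
print(f"to ever reach p = 0.5 it needs transformed time >= {t_min:.4f}")
print("(the second rounds to -0.2: even unlimited ability cannot rescue a")
print(" response produced faster than that threshold)")
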
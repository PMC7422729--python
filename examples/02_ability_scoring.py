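"""Maximum-likelihood ability scoring with and without the time effect.

Reproduces the worked three-item example: the same response pattern
yields a higher ability estimate when produced under stronger time
pressure (smaller transformed time), which the plain 3PL cannot
distinguish.
"""

from g3plt import run_table2

table = run_table2()
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("\nReading: within each response framework the time-aware estimate")
print("falls as t* grows and meets the plain-3PL estimate at t* = 8;")
print("at t* = -0.2 the frameworks (1,0,0) / (0,1,0) / (1,1,0) score")
print("-0.8864 / 0.1408 / 1.3100 instead of the time-blind")
print("-0.9339 / -0.7208 / 0.6659.")
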
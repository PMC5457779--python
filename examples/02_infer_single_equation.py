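"""Infer one equation of the artificial benchmark with the mixed-variable EA.

Generates noise-free synthetic data, runs a reduced-budget search on
equation 2 (true structure: production driven by X1 with kinetic order 2,
degradation by X2 with kinetic order 2), and prints the resulting
error/sparsity front.
"""

import numpy as np

import ssinfer as si

model = si.make_s1()
data = si.generate_dataset(model, n_conditions=4, n_times=15,
                           t_span=(0.0, 0.2), init_range=(0.5, 1.5), seed=7)

cfg = si.EAConfig(pop_size=60, iterations=300, seed=0)
front = si.run_equation(data, eq_index=1, cfg=cfg, seed=0)

print("nondominated front of equation 2 (connections vs fitting error):")
for sol in front.solutions:
    g, h, a, b = si.decode(sol)
    print(f"  L0={sol.l0:2d}  err={sol.err:10.4g}  g={np.round(g, 3)}  "
          f"h={np.round(h, 3)}  alpha={a:.3f} beta={b:.3f}")
print()
print("The sharp error drop at L0=2 marks the true two-connection structure;")
print("denser members only polish the residual slope-estimation noise.")
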
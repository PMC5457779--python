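"""End-to-end inference of the artificial network with knee-point selection.

Runs the whole pipeline at a reduced budget: synthetic data, per-equation
biobjective search, lambda sweep with aggregation-product selection, and
the angle-based knee choice of the final network.  Prints the recovered
parameter table and its topology scores against the generating model.
"""

import ssinfer as si
from ssinfer.io import network_frame

cfg = si.RunConfig(
    benchmark="s1",
    seed=3,
    ea=si.EAConfig(pop_size=60, iterations=300, n_runs=3, polish_every=100),
)
result, report = si.run_benchmark(cfg)

print(f"selection weight lambda = {result.lam:.2f} "
      f"(knee stable over [{result.lam_interval[0]:.2f}, {result.lam_interval[1]:.2f}])")
print(f"topology recovery: TPR = {report['tpr']:.3f}, FPR = {report['fpr']:.3f}")
print()
print(network_frame(result.system).round(3).to_string(index=False))
print()
print("TPR/FPR count the 50 dependent kinetic-order entries structurally")
print("(nonzero = predicted connection); TPR 1 / FPR 0 is exact recovery of")
print("the 13 true connections, with no magnitude threshold involved.")
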
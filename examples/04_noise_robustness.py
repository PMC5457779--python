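"""Effect of measurement noise on recovered topology.

Adds multiplicative Gaussian noise to the same synthetic experiment at
increasing rates and reports how the selected network degrades, tracking
the sparsity-first behaviour of the L0 objective.
"""

import ssinfer as si

for rate in (0.0, 0.05, 0.15):
    cfg = si.RunConfig(
        benchmark="s1",
        seed=3,
        noise_rate=rate,
        ea=si.EAConfig(pop_size=60, iterations=300, n_runs=3, polish_every=100),
    )
    result, report = si.run_benchmark(cfg)
    c = report["confusion"]
    print(f"noise {rate:4.0%}:  TPR={report['tpr']:.3f}  FPR={report['fpr']:.3f}  "
          f"(TP={c['tp']} FP={c['fp']} FN={c['fn']})  "
          f"connections={c['tp'] + c['fp']} of 13 true")

print()
print("Noise inflates the slope estimates' variance, so weak connections stop")
print("paying for themselves in the fitting error and the knee settles on a")
print("sparser (or partly wrong) structure — the network stays sparse rather")
print("than absorbing noise as spurious dense connectivity.")
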
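"""The evaluation protocol on a synthetic vignette cohort.

Simulates 200 clinical vignettes from a 5-risk / 10-disease / 15-symptom
network, ranks each under the associative posterior and both counterfactual
measures, and prints top-k accuracies, mean true-disease ranks, the
relative error reduction 1 − e_c/e_a, and win/draw/loss counts.
"""

import numpy as np

from twindiag import (
    GeneratorConfig,
    error_reduction,
    evaluate_cohort,
    generate_cohort,
    generate_network,
    rank_comparison,
    top_k_accuracy,
)

cfg = GeneratorConfig(seed=7)
net = generate_network(cfg)
cohort = generate_cohort(net, cfg, 200)
result = evaluate_cohort(net, cohort)

print(f"{len(result)} vignettes, {len(net.diseases)} diseases\n")
print(f"{'measure':>22} {'top-1':>7} {'top-3':>7} {'top-5':>7} {'mean rank':>10}")
for m in result.measures:
    accs = [top_k_accuracy(result, k, m) for k in (1, 3, 5)]
    mean = float(np.mean(result.ranks(m, tie_aware=True)))
    print(f"{m:>22} {accs[0]:7.3f} {accs[1]:7.3f} {accs[2]:7.3f} {mean:10.3f}")

acc_a = top_k_accuracy(result, 1, "posterior")
acc_c = top_k_accuracy(result, 1, "expected_sufficiency")
print(f"\ntop-1 error reduction (sufficiency vs posterior): "
      f"{error_reduction(acc_a, acc_c):.3f}")
comp = rank_comparison(result, "posterior", "expected_sufficiency")
print(f"wins posterior {comp['wins_posterior']}, "
      f"wins sufficiency {comp['wins_expected_sufficiency']}, draws {comp['draws']}")
print()
print("Positive error reduction and the win count show the counterfactual")
print("ranking finding the seeded true disease earlier than the posterior.")
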
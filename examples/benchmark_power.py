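"""Desk-scale power study: how detection improves with effect size.

Runs the simulation benchmark at three effect sizes with 80% of each true
pathway's genes treated: synthetic three-layer data, Ward-derived
synthetic pathways, random group labels per replicate, PC1 + logistic
scoring, MiniMax integration. Reports the empirical type-I error of the
null pathways and the mean AUC for ranking the five true pathways above
the 45 null ones.
"""

import minimaxomics as mx

for mu in (0.0, 0.2, 0.5):
    scenario = mx.BenchmarkScenario(mu=mu, prop=0.8, n_reps=10, seed=42)
    summary = mx.summarize_benchmark(mx.run_benchmark(scenario))
    print(
        f"mu={mu:.1f}: type-I rate {summary['type1_rate']:.3f} "
        f"(n={summary['n_null']} null pathways), "
        f"mean AUC {summary['mean_auc']:.3f} +/- {summary['auc_se']:.3f}"
    )
print(
    "\nType-I stays near the 5% nominal level regardless of mu, while AUC "
    "climbs from chance (0.5) toward 1 as the injected effect grows."
)
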
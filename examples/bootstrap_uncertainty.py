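"""Bootstrap confidence bands on the plasticity-metric CDF.

Builds a small synthetic dataset, computes the empirical CDF of the pair
plasticity metric and brackets its uncertainty with the two extreme
within-block correlation assumptions for the measurement-error deviates.
"""

from phenoplast import SCENARIOS, bootstrap_cdf, generate_dataset

# noisy, small-sample cells so the measurement-error deviates matter
dataset = generate_dataset(
    {s: 1.0 for s in SCENARIOS}, n_blocks=120, seed=7,
    noise_cv=0.4, n_per_cell=10,
)

for method in ("blocks", "corr0", "corr1"):
    cdf = bootstrap_cdf(
        dataset.blocks, "plasticity", method,
        replicates=2000, level=0.95, seed=11, theta=0.53,
    )
    at_theta = cdf.evaluate(0.53)
    i = int((cdf.grid <= 0.53).sum()) - 1
    print(
        f"{method:6s}  fraction of pairs with effect size <= 0.53: "
        f"{at_theta:.3f}  (95% band {cdf.band_lo[i]:.3f}-{cdf.band_hi[i]:.3f})"
    )

print(
    "\nThe CDF value at the threshold is the nonplastic fraction of paired\n"
    "records. 'blocks' resamples whole blocks; 'corr0'/'corr1' additionally\n"
    "perturb each cell mean by its SEM with within-block correlation 0 or 1,\n"
    "bracketing the plausible measurement-error dependence."
)
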
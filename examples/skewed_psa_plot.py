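"""Render a PSA-ReD figure for a right-skewed PSA cloud.

Health-economic models with gamma/beta input distributions often produce a
density mode displaced from the base case: with a Gamma(0.5, rate=5) effect
distribution the densest region hugs zero incremental QALYs while the PSA
mean (0.1 QALYs) sits far into the tail.  The figure shows the relative
density surface, the (0.1, 0.5, 0.95) contours, a willingness-to-pay line
and both the base-case and PSA-mean markers.
"""

from psared import (
    PlotSpec,
    RunConfig,
    cumulative_map,
    evaluate_kde,
    interpolate_cumprob,
    make_grid,
    psa_mean,
    run_pipeline,
    select_bandwidths,
    simulate_skewed_psa,
    write_fixture_csv,
)

sample = simulate_skewed_psa(
    n=10_000, alpha=0.5, beta=5.0,
    cost_base=4000.0, cost_slope=10_000.0, noise_sd=500.0, seed=1,
)
csv = write_fixture_csv(sample, "skewed_psa.csv")

config = RunConfig(
    n_bins=500,
    contour_levels=(0.1, 0.4, 0.5, 0.95),
    wtp_thresholds=(20_000.0,),
    base_case=(0.1, 5000.0),  # deterministic result at central parameters
    title="Skewed PSA: density mode displaced from the base case",
)
spec = PlotSpec(
    wtp_thresholds=config.wtp_thresholds, base_case=config.base_case,
    show_psa_mean=True, title=config.title, out_path="skewed_psa.png",
)
summary = run_pipeline(csv, config, spec, summary_path="skewed_psa.json")

mean_pt = psa_mean(sample)
print(f"figure written to {summary['image']}")
print(f"PSA mean: ({mean_pt[0]:.4f} QALYs, {mean_pt[1]:.0f} currency units)")
print("coverage per level:", {k: round(v, 3) for k, v in
                              summary["empirical_coverage"].items()})
# The PSA mean's own cumulative probability: > 0.4 means the 'expected'
# outcome lies outside the densest 40% of iterations — a skew signature the
# scatter plot hides.
cg = cumulative_map(
    evaluate_kde(sample, make_grid(sample, config.n_bins),
                 select_bandwidths(sample))
)
cp_mean = float(interpolate_cumprob(cg, [mean_pt])[0])
print(f"cumulative probability at the PSA mean: {cp_mean:.3f}")
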
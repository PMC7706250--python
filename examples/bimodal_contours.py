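"""Disjoint contours: one cumulative-probability level, several lines.

When a PSA cloud has two well-separated high-density areas, a single
cumulative-probability level (here 0.5) owns one contour line around each
mode — the level describes the *total* mass of the highest-density region,
which need not be connected.
"""

from psared import (
    cumulative_map,
    evaluate_kde,
    extract_contours,
    make_grid,
    select_bandwidths,
    simulate_bimodal,
)

sample = simulate_bimodal(
    n=10_000, centers=((0.0, 0.0), (10.0, 10.0)), sds=(0.5, 0.5),
    weight=0.5, seed=1,
)
bw = select_bandwidths(sample)
density = evaluate_kde(sample, make_grid(sample, 500), bw)
contours = extract_contours(cumulative_map(density), (0.1, 0.5, 0.95))

for level in contours.levels:
    lines = contours[level]
    kinds = ", ".join("closed" if p.closed else "open" for p in lines)
    print(f"level {level}: {len(lines)} polyline(s) ({kinds})")
# Levels 0.1 and 0.5 each split into two closed lines (one per mode).  The
# 0.95 region reaches the plot boundary (extents are the data min/max), so
# its lines are clipped there and flagged open.
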
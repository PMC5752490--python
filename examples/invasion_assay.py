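"""Matrix-invasion assay: migration distances over 18 h, two conditions.

Simulates matrix-embedded spheroid fields at two timepoints for an untreated
condition (Rayleigh displacement scale tuned to a ~79 um mean) and an
NO-stimulated one (~316 um mean), measures per-spheroid centroid
displacements from the images, and tests the difference.
"""

import math

import spheroquant as sq

records = {}
for cond, mean_d, seed in (("control", 78.8, 11), ("NO donor", 316.4, 12)):
    scale = mean_d / math.sqrt(math.pi / 2)  # Rayleigh scale from target mean
    cfg = sq.SimConfig(grid_rows=5, grid_cols=5, chamber_pitch=900.0,
                       microns_per_pixel=4.0, rng_seed=seed, min_area=900.0,
                       displacement_scale=scale)
    fields, truth = sq.simulate_invasion(cfg, flatten=0.8)
    r1 = sq.segment_field(fields[0], min_area=400.0)
    r2 = sq.segment_field(fields[1], min_area=400.0)
    # in collagen there are no chamber walls; pair by nearest centroid
    recs = []
    for a in r1:
        b = min(r2, key=lambda r: math.dist(r.centroid_um, a.centroid_um))
        recs.append(sq.migration_distance(a, b, elapsed_hours=18.0))
    records[cond] = recs

table, _ = sq.invasion_summary(records)
print(table.to_string(index=False, float_format=lambda x: f"{x:.1f}"))
res = sq.compare_groups(
    {c: [r.distance_um for r in records[c]] for c in records}, design="t",
    metric="migration distance")
print(f"\nt-test: p = {res.p_value:.2e} "
      f"({'significant' if res.significant else 'not significant'} at 0.05) — "
      "NO-stimulated spheroids migrate several-fold farther in 18 h")
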
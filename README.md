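# dfcstates

Sliding-window **dynamic functional connectivity (dFC) state analysis**
for small brain networks, built for the question of how the frontoparietal
network (FPN) reconfigures over time in depression: do patients spend more
time in a hypoconnected configuration, stay in it longer, and switch
between configurations less often than controls?

The package implements the full analysis chain as a tested library with a
CLI, plus a synthetic cohort generator with planted state dynamics so the
whole pipeline can be validated without clinical data:

1. **Windowed connectivity** — per subject, overlapping sliding windows
   (22 TR / step 1 TR by default; 230 volumes → 209 windows) of pairwise
   Pearson correlations among the N = 21 network nodes, Fisher
   z-transformed with boundary stabilization, vectorized to E = 210 edge
   features per window, with validity QC.
2. **Multisite harmonization** — parametric empirical-Bayes location/scale
   batch adjustment (ComBat) of the windowed features, site as batch, age
   and sex protected.
3. **State identification** — exemplar windows (local maxima of
   across-edge variance) pooled and clustered with best-of-500-replicates
   k-means, whose centroids initialize a second k-means pass over all
   windows; elbow criterion for k; nearest-centroid state sequences.
4. **Temporal metrics** — fractional occupancy, mean dwell time (windows),
   total and pairwise state transitions, state-conditioned mean
   connectivity over arbitrary node subsets.
5. **Statistics** — Welch t with Satterthwaite df, Benjamini–Hochberg FDR
   within declared families, Hedges g, Yates chi-square,
   Greenhouse–Geisser-corrected repeated-measures ANOVA with paired
   post-hocs, covariate-adjusted OLS group effects (age, sex, mean FD,
   site dummies), and medication/episode-stratified comparisons.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Generate a 120-subject, three-site synthetic cohort whose patients carry
an elevated self-transition for the hypoconnected regime, then run the
pipeline:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_run_pipeline.py
python analysis/04_render_report.py
```

which prints

```
wrote 120 subjects (3 sites) to scratch/cohort
planted per-group mean regime-2 occupancy:
control    0.459
patient    0.580
k=3, WCSS=2.628e+05, harmonized=True
FDR-significant temporal metrics (control-minus-patient t):
      metric      t     q     g
occupancy_s1  2.744 0.026 0.498
occupancy_s2 -2.722 0.026 0.494
```

Reading: the generator planted higher hypoconnected-regime occupancy in
patients (0.580 vs 0.459 of time points); after windowing, harmonization
and clustering, the pipeline's State 2 (hypoconnected; states are labeled
by centroid mean, State 2 lowest) shows significantly higher occupancy in
patients (negative control-minus-patient t, q = 0.026, Hedges g ≈ 0.49),
mirrored by lower occupancy of the moderate State 1. At this cohort size
(60 per arm, three noisy sites) dwell time and total transitions trend in
the planted direction without surviving FDR; the packaged validation
suite runs the same recovery at 100 per arm on a single site, where all
three headline effects are FDR-significant with the correct signs.

The same stages are available as a CLI (`dfcstates simulate / dfc /
harmonize / cluster / metrics / stats / run / report`); `dfcstates run
--input DIR --out DIR` executes the whole chain and writes a manifest that
makes reruns byte-for-byte reproducible.

`analysis/03_published_summary_stats.py` recomputes the full inferential
battery (Welch t, df, Hedges g, BH-FDR q per family, Yates chi-square)
from the published cohort summary tables of the motivating study — group
means and SDs are sufficient statistics for every test in the battery —
and writes `results/published_anchors.tsv`.

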
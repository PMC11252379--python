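# meiotrack

Quantitative analysis of rapid prophase chromosome movements (RPMs) in plant
meiosis, built around 4D single-particle tracks of fluorescently labeled
centromeres in *Arabidopsis thaliana* anthers, plus the 3D nuclear-organization
measurements that accompany them (telomere–envelope distances, bouquet
detection, nucleolus position).

It is aimed at researchers quantifying live-imaging experiments of meiotic
prophase: given Imaris-style track tables (or the bundled synthetic
generators), the package reproduces the full analysis chain — track filtering,
somatic-reference drift correction, speed / turning-angle / outreach-ratio
statistics, mean-squared-displacement (MSD) model fitting, within-cell
coordination metrics, bouquet calling, and group comparisons that respect the
anther > cell > track nesting of such experiments.

## The models at the core

**Motion regimes.** For a track with positions *x(t)*, the MSD is the time
average of |x(t+τ) − x(t)|² over all overlapping pairs.  Three models are
fitted:

- power law, MSD(τ) = c·τ^α — α ≈ 1 indicates diffusion-like motion;
- 3D Brownian, MSD(τ) = 6·D·τ + offset — D is the apparent diffusion
  coefficient; the offset absorbs localization noise;
- confined diffusion, MSD(t) = R²·{1 − a·exp(−b·D·t/R²)} — the plateau R²
  reflects the radius R of the confining domain.

Per-step descriptors complement the MSD: the instant speed |Δx|/Δt (nm/s), the
turning angle between consecutive steps (an excess above 90° marks constrained
back-and-forth motion), and the outreach ratio OR = (MD/TD)·√duration, where
MD is the maximal pairwise distance along the track and TD the summed path
length — a speed-independent measure of spatial exploration.

**Drift correction.** Somatic centromeres of the same acquisition serve as a
fixed reference: their average per-frame displacement is subtracted from every
track, removing rigid sample drift exactly.

**Nuclear organization.** The nuclear envelope and nucleolus are spheres;
telomeres are labeled 3D points.  A telomere is "clustered" when its average
distance to its 9 nearest neighbors falls below 4 µm, and a bouquet is called
when at least 6 of the 16 non-NOR chromosome ends (≥ 37%) form a single
cluster.  NOR-bearing ends (short arms of chromosomes 2 and 4) are excluded
because of their nucleolus association.

**Group comparisons.** Track-level metrics are compared between stages or
genotypes with a mixed model (random intercepts for anther and for cell within
anther, ML likelihood-ratio test, via statsmodels), or with a self-contained
hierarchical permutation test that permutes labels across anthers.

## Worked example

```python
import pandas as pd
from meiotrack import *

dfs = []
for stage, speed, seed in [("leptotene", 55.0, 1), ("zygotene", 106.0, 2)]:
    cfg = HierarchyConfig(
        n_anthers=4, cells_per_anther=3, tracks_per_cell=3,
        anther_speed_sd=0.15, cell_speed_sd=0.1,
        base=MotionModelConfig(model="fixed_speed", speed=speed, n_steps=50,
                               dt=2.4, stage=stage),
        drift_velocity=(0.01, 0.0, 0.0), seed=seed,
    )
    ts = drift_correct(filter_tracks(simulate_anther(cfg), min_duration=15.0))
    df = summarize_motion(ts.select(compartment="meiotic"))
    df["anther_id"] = stage + "_" + df["anther_id"]
    dfs.append(df)
    print(f"{stage}: {len(df)} tracks, mean speed {df.avg_speed.mean():.1f} nm/s, "
          f"mean OR {df.outreach_ratio.mean():.2f}")
res = compare_groups_mixed(pd.concat(dfs), metric="avg_speed", fixed="stage")
print(f"stage contrast (nested LRT): LR = {res.statistic:.1f}, p = {res.p_value:.2e}")

ts = simulate_tracks(MotionModelConfig(model="brownian", D=0.045, dt=2.4,
                                       n_tracks=200, n_steps=50, seed=3))
fit = fit_brownian(compute_msd(ts, max_lag=60.0))
print(f"Brownian recovery: fitted D = {fit.D:.4f} um^2/s (generated at 0.045)")

g, telo = simulate_nucleus_configuration(NucleusConfig(kind="wt_zygotene", seed=4))
res = detect_bouquet(telo, g)
print(f"wt zygotene nucleus: bouquet={res.bouquet}, {res.n_in_bouquet} telomeres, "
      f"{100*res.periphery_fraction:.0f}% at periphery, nucleolus {res.nucleolus_position}")
```

prints

```
leptotene: 36 tracks, mean speed 58.1 nm/s, mean OR 1.89
zygotene: 36 tracks, mean speed 107.1 nm/s, mean OR 1.74
stage contrast (nested LRT): LR = 17.4, p = 3.08e-05
Brownian recovery: fitted D = 0.0433 um^2/s (generated at 0.045)
wt zygotene nucleus: bouquet=True, 10 telomeres, 88% at periphery, nucleolus peripheral
```

The two groups are generated at the leptotene and zygotene mean speeds; the
drift-corrected summaries recover them (58 vs 107 nm/s), the nested
likelihood-ratio test finds the stage contrast overwhelming, the linear MSD
fit recovers the zygotene diffusion coefficient to within a few percent, and
the simulated wild-type zygotene nucleus is called as a 10-telomere bouquet
with a peripheral nucleolus.

A `meiotrack` console script exposes the same stages
(`simulate-tracks`, `simulate-anther`, `simulate-nucleus`, `render-stack`,
`detect-link`, `analyze-tracks`, `msd-fit`, `bouquet`, `compare`, `run`);
`meiotrack run --config cfg.yaml --seed 1 --out outdir` executes the full
pipeline and writes a manifest for byte-identical reruns.

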
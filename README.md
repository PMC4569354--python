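# megnet

Resting-state MEG source-connectivity analysis as a tested, reusable
pipeline: from multichannel sensor recordings through DICS beamformer
source projection and imaginary-coherence networks to weighted graph
metrics and permutation-based group statistics. A forward-model-consistent
synthetic-cohort generator stands in for patient data that cannot be
shared, so every stage is testable end to end.

## Who this is for

Researchers comparing source-space functional connectivity between two
groups of resting-state MEG recordings (e.g. a patient cohort against
healthy controls), and methodologists who want a compact, fully seeded
reference implementation of the standard analysis chain to probe its
error calibration and power on ground-truth data.

## The analysis chain

1. **Preprocessing** — excise ±10 s around marked events, segment into
   10 s epochs, randomly select 30 epochs per subject, polyphase-resample
   to 409.6 Hz, band-pass 0.5–70 Hz (4th-order Butterworth,
   forward–backward).
2. **Spectral analysis** — multitaper Fourier coefficients with
   frequency-matched DPSS tapers (K = ⌊2·T·W⌋ − 1) at six bands:
   δ 2±2, θ 6±2, α 10±2, β₁ 16±4, β₂ 25±4, γ 40±5 Hz; cross-spectral
   density S(f) averaged over epochs × tapers.
3. **Source reconstruction** — DICS spatial filters per grid node
   w = S⁻¹l / (lᵀS⁻¹l) with 5 % diagonal loading, scalar orientation from
   the dominant generalized eigenvector, unit gain w·l = 1; sensor
   Fourier coefficients projected to a regular volumetric grid inside a
   spherical head model (analytic Sarvas lead fields).
4. **Connectivity** — coherency C_ij = S_ij/√(S_ii S_jj); edge weight
   |Im C_ij| ∈ [0, 1], insensitive to zero-lag field spread. Networks are
   weighted, undirected, unthresholded, at grid ("high") and atlas-region
   ("low") resolution (cross-region weights averaged, within-region pairs
   omitted).
5. **Graph measures** — nodal strength s_i = Σ_j w_ij; Onnela weighted
   clustering C_i = Σ_{jh}(ŵ_ij ŵ_jh ŵ_ih)^{1/3}/(k_i(k_i−1)); characteristic
   path length with edge length 1/w; normalization by the mean over 100
   weight-shuffled surrogate networks.
6. **Statistics** — Mann–Whitney U for global measures; cluster-based
   permutation tests on nodal strength (t > 2.0, spatial adjacency,
   max-cluster-mass null, α = 0.01) and source power (t > 1.9, α = 0.05);
   the network-based statistic on region-level edges (t > 3.5, connected
   extent, α = 0.05); 5000 permutations; BH-FDR for regional tests;
   Spearman correlations and cohort demographics (t-test, Pearson
   chi-square).

The synthetic-cohort generator plants a band-limited, phase-lagged
coupling increase in a chosen node subset of the "patient" group; with the
effect multiplier at 1 the two groups are exchangeable, which drives the
type-I-error suites.

## Worked example

```python
import json
from megnet import demographics, demo_config, run_pipeline

# cohort comparability: 9/13 vs 11/19 female, ages 38.6(15.8) vs 38.5(13.5)
res = demographics([[9, 4], [11, 8]],
                   age_summary=((38.6, 15.8, 13), (38.5, 13.5, 19)))
print(f"sex:  chi2 = {res['sex'].statistic:.3f}, p = {res['sex'].p_value:.3f}")
print(f"age:  t = {res['age'].statistic:.3f}, p = {res['age'].p_value:.3f}")

# end-to-end demo: 6 vs 6 subjects, 64 sensors, planted beta2 coupling
cfg = demo_config(output_dir="demo_run", seed=1, planted_group_effect=2.0)
run_pipeline(cfg)
stats = json.load(open("demo_run/stats.json"))
for c in stats["beta2"]["nbs_components"]:
    if c["significant"]:
        print(f"beta2 NBS: edges {c['edges']} extent {c['statistic']:.0f} "
              f"p = {c['p_value']:.3f}")
```

prints

```
sex:  chi2 = 0.423, p = 0.515
age:  t = 0.019, p = 0.985
beta2 NBS: edges [[0, 1], [1, 3], [1, 4], [1, 5], [1, 6], [1, 7]] extent 6 p = 0.004
```

The sex table shows no group difference (χ² = 0.42, p = 0.515); the ages
are indistinguishable. In the demo cohort the network-based statistic
finds one significant component in the β₂ band — the band carrying the
planted coupling increase — and nothing in α. Region 1 of the octant
atlas contains one planted clump, so the component is centred on its
edges. The same run writes per-subject networks (HDF5), a graph-measure
table (TSV) and a provenance manifest with output checksums; rerunning
with the same seed reproduces every file bit for bit.

The same pipeline is available from the shell:

```bash
megnet run --config my_config.yaml --seed 1
megnet defaults > full_scale.yaml   # every default parameter, documented
```

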
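# morphospec

Spatiotemporal spectral profiling of cell-edge morphodynamics.

Migrating cells protrude and retract their edges in oscillatory cycles
whose *pacing* reflects the wiring of the signaling circuitry driving the
cytoskeleton, while the *magnitude* of the motion reflects how strongly
that circuitry is activated.  `morphospec` quantifies both from
single-channel fluorescence time-lapse movies:

1. **Segmentation** — one binary cell mask per frame from histogram-valley
   thresholding and morphological cleanup.
2. **Edge tracking** — sub-pixel contours are matched between consecutive
   frames by minimizing displacement + ω·strain subject to non-crossing
   displacement vectors (solved exactly by dynamic programming), yielding
   signed normal edge velocities, protrusion positive.
3. **Windowing** — the velocities are averaged in ~3 μm edge sectors into a
   *protrusion activity map* v(s, t) (rows = sectors, columns = time);
   optional biosensor images are sampled in edge-attached windows on the
   same sector grid, band by band.
4. **Hilbert–Huang transform** — each map row and column is decomposed by
   empirical mode decomposition into six intrinsic mode functions c_i with
   X(t) = Σ c_i(t) + r(t), and each IMF is converted into instantaneous
   frequency F(t) = (1/2π)·d/dt arg(c + iH[c]) and amplitude
   A(t) = |c + iH[c]|.  Unlike a Fourier transform, the spectra are local
   in time and space, so switches in edge behavior stay visible.
5. **Profiling and clustering** — cells and subcellular regions are
   compared by Kolmogorov–Smirnov statistics on their pooled F and A
   distributions, and the map is partitioned into *motion regimens* by
   statistical region merging on the 12-dimensional amplitude-weighted
   frequency features φ(s,t) = [F_i·A_i²/A_max²], with a merging delicacy
   parameter Q.  Regimens can then be related to windowed biosensor
   activity via lagged cross-correlation.

A synthetic-data module generates deforming-blob movies, coupled activity
channels and planted activity maps with closed-form ground truth, so every
stage is testable end to end without external data.

## Worked example

Decompose a planted two-regimen velocity map (sectors 0–31 oscillate at
0.02 Hz, sectors 32–63 at 0.005 Hz, equal 2 μm/min amplitude, noise at
SNR 5) and recover the regimens:

```python
import numpy as np
from morphospec import (Block, PlantedMapSpec, SRMConfig, decompose_map,
                        feature_field, gen_planted_map, ks_compare, q_scan,
                        spectral_distributions, srm_cluster)

spec = PlantedMapSpec(
    n_sectors=64, n_frames=120, dt=10.0,
    blocks=(Block((0, 32), (0, 120), frequency=0.02, amplitude=2.0),
            Block((32, 64), (0, 120), frequency=0.005, amplitude=2.0)),
    noise_sd=0.4, seed=3)
amap = gen_planted_map(spec)
field = decompose_map(amap)                      # 6 temporal + 6 spatial IMFs

top = np.zeros((64, 120), dtype=bool); top[:32] = True
fa = spectral_distributions(field, "frequency", region_mask=top)
fb = spectral_distributions(field, "frequency", region_mask=~top)
r = ks_compare(fa[0].values, fb[0].values)
print(f"IMF1 frequency K-S D = {r.statistic:.3f} (p = {r.pvalue:.2e})")

feats = feature_field(field)
labeling = srm_cluster(feats, SRMConfig(q=3))
print(f"SRM at Q=3: {labeling.n_regions} regions")

scan = q_scan(feats, range(9))
print(f"explained variance by Q: {np.round(scan.explained, 2)}")
print(f"knee at Q = {scan.knee:g}")
```

prints

```
IMF1 frequency K-S D = 0.610 (p = 0.00e+00)
SRM at Q=3: 4 regions
explained variance by Q: [0.   0.   0.   0.23 0.25 0.27 0.3  0.37 0.43]
knee at Q = 3
```

The two planted halves have very different IMF1 instantaneous-frequency
distributions (D = 0.61), the clustering at Q = 3 recovers them as the two
dominant regimens (two regions of ~3800 grid cells each, plus a few
boundary cells), and the explained-variance curve jumps exactly where the
split first appears and plateaus beyond it — which is how the operating Q
is chosen on real maps.

## Command line

The `morphospec` command exposes the stages individually (`segment`,
`track`, `hht`, `profile`, `robustness`, `cluster`, `qscan`, `couple`),
a full pipeline (`run`), and a self-contained synthetic demo:

```sh
morphospec run --movie movie.tif --out-dir results/
morphospec demo --seed 0 --out-dir demo/
```

Images and masks are TIFF stacks; activity maps and labels are CSV with
JSON sidecars; spectra are stored as an `.npz` named-array container.
Every output carries a metadata sidecar with config hash, version and seed,
and a rerun with the same inputs reproduces outputs bit for bit.

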
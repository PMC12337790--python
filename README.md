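# clonemech

Quantitative analysis of **mosaic clones in planar epithelia**: how a small
group of genetically distinct cells sorts out from its neighbors, changes its
junctional mechanics, and is eliminated. The package implements the full
measurement chain used in mosaic-clone studies of the pupal fly notum —
from a segmented label mask or tissue graph to clone morphometrics, junction
fluorescence, ablation recoil, inferred tensions and spatial apoptosis
statistics — together with a fully seeded synthetic-epithelium generator so
every analysis can be validated against known ground truth without any
imaging data.

## What it computes

| Analysis | Statistic |
|---|---|
| Clone shape | circularity index C = 4πA/P² of the clone outline (1 = perfect circle) |
| Cell sorting | connectivity index K = 2·E_int/n (mean homotypic contacts per clonal cell), against the theoretical ceiling K_max(n) = 2(3n − ⌈√(12n−3)⌉)/n attained by maximally compact polyhexes |
| Junction fluorescence | per-junction mean intensity, normalized per tissue by the external-junction internal control: Î = I / mean(I_external); intensity-vs-length regression with slope/intercept comparison |
| Ablation recoil | fit of (d_t − d0)/l_c = D∞·(1 − e^{−(t−t0)/τ}) for the normalized plateau D∞ = (d∞−d0)/l_c and timescale τ; initial velocity v0 = l_c·D∞/τ |
| Force inference | relative junction tensions T̂ = argmin ‖B·T‖² + μ‖T−1‖² s.t. mean(T) = 1, with B the interior-vertex force-balance matrix; zone summaries by junction class; randomization test for group comparisons |
| Apoptosis | hypergeometric null P(X=k) = C(m,k)C(N−m,n−k)/C(N,n) per clone/neighbor ring, with the pmf mode k* as the expected count; ring sizes measured on the tissue graph or approximated on the hexagonal tiling |

Junctions are classified relative to a clone as **internal** (two clonal
cells), **peripheral** (one clonal, one not) or **external** (neither);
non-clonal cells carry a ring index (+1, +2, +3, >+3) equal to their graph
distance from the clone.

## Worked example

```python
import numpy as np
from clonemech import synth, find_clones
from clonemech.clones import clone_metrics_table
from clonemech.forces import assemble_balance, infer_tensions, zone_tensions, zone_summary
from clonemech.recoil import fit_recoil, initial_velocity

t = synth.hexagonal_tissue(150)
synth.plant_clones(t, [7], compactness=1.0, seed=0)   # a sorted, compact clone
print(clone_metrics_table(t, find_clones(t)).round(3).to_string(index=False))

# an equilibrium foam with the clone's internal junctions planted at 0.6× tension
relaxed, gt = synth.tension_only_foam(t, sigma=0.2, seed=12,
                                      internal_factor=0.6,
                                      clonal_ids=t.clonal_ids())
fmap = infer_tensions(assemble_balance(relaxed, mu=0.1))
print(zone_summary(zone_tensions(fmap, relaxed, relaxed.clonal_ids())).round(3).to_string(index=False))

trace = synth.simulate_recoil(synth.RecoilSpec(d_inf_norm=0.3, tau=10.0, lc=3.0,
                                               noise_sigma=0.1), seed=3)
fit = fit_recoil(trace)
print(f"D_inf = {fit.d_inf_norm:.3f}, tau = {fit.tau:.2f} s, "
      f"v0 = {initial_velocity(fit):.4f} um/s")
```

prints

```
 clone_id  n_cells  A_um2   P_um  circularity  connectivity  K_max
        0        7  112.0 44.669        0.705         3.429  3.429

       cls   n  median    q1    q3
  external 372   1.003 0.878 1.117
  internal  12   0.898 0.676 0.999
peripheral  18   1.100 0.933 1.206

D_inf = 0.304, tau = 9.18 s, v0 = 0.0995 um/s
```

The compact 7-cell clone reaches the theoretical connectivity ceiling
(K = K_max = 24/7 ≈ 3.429) and is correspondingly round (C = 0.705 vs the
hexagonal-cell ceiling ≈ 0.907). The inferred tension map reads out the
planted low-tension clone: the internal-junction median (0.898) sits below
the external control (1.003). The recoil fit recovers the planted plateau
0.3 and timescale 10 s from a noisy trace sampled every 1.5 s.

## Command line

```sh
clonemech simulate --seed 1 --out data/          # synthetic dataset + ground truth
clonemech all --data data/ --out results/        # every analysis stage
clonemech metrics|intensity|recoil|forces|apoptosis ...   # individual stages
```

`simulate` writes a tissue graph (JSON), label mask and intensity images
(TIFF), clone/apoptosis/recoil tables (CSV) and the generating ground truth;
the analysis stages consume the same formats for real segmented data. All
outputs carry a provenance header (tool version, seed, config hash) and are
byte-reproducible under a fixed seed.

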
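# comptoncam

Prompt-gamma Compton-camera imaging for boron neutron capture therapy
(BNCT), desk scale and fully synthetic: phantom generation, analytic
Monte-Carlo event simulation in CZT detector modules, list-mode MLEM
image reconstruction, and three 3D encoder–decoder networks — standard,
dual-frame and tight-frame U-Nets from the deep convolutional framelets
view of pooling — that map cheap few-iteration reconstructions to
many-iteration quality.

## The problem

BNCT deposits its therapeutic dose through the ¹⁰B(n,α)⁷Li capture
reaction (Q ≈ 2.79 MeV). In ~94% of captures the recoiling ⁷Li is left
excited and promptly emits a 478 keV photon, leaving about 2.31 MeV of
kinetic energy to the charged pair. Because the boron dose is
proportional to the local boron concentration, imaging those prompt
gammas images the dose — but no real-time in vivo method exists today.
A Compton camera needs no collimator: each detected event (scatter
position **d₁**, absorption position **d₂**, deposits E₁, E₂) confines
its source to a cone with apex **d₁**, axis through **d₂**, and
half-angle θ from

E′γ = Eγ / (1 + (Eγ/mₑc²)(1 − cos θ)),  Eγ = E₁ + E₂.

The source distribution f is recovered from many cones by list-mode
MLEM,

f_b ← (f_b/s_b) Σ_d h_db / (Σ_b′ h_db′ f_b′),

where h_db is the cone-surface system model and s_b the per-voxel
sensitivity. Usable images need ~60 iterations; ~10 iterations are fast
but degraded. The networks here learn the residual degradation, turning
iteration-10 inputs into iteration-60-quality outputs, with the three
variants differing only in their pooling algebra: plain average pooling
(no frame condition), its canonical dual frame (frame condition with
condition-number-2 noise amplification), and the 3D Haar tight filter
bank (8 subbands, Parseval, no amplification) with a 9-weight merge.

The package generates everything it consumes; no external data.

## Worked example

```python
import numpy as np
from comptoncam import (GridSpec, ImageVolume, standard_geometry,
                        simulate_events, energy_window_filter, ListModeMLEM)

grid = GridSpec.default()                      # 20 x 20 x 40 voxels, 4 mm
det = standard_geometry("four_module")         # 16 CZT crystals
vals = np.zeros(grid.shape); vals[10, 10, 20] = 1.0
src = ImageVolume(grid, vals)                  # point source on the axis

events = energy_window_filter(
    simulate_events(src, det, n_gammas=1_000_000, rng=1))
print(f"{len(events)} events, efficiency {len(events)/1e6:.2%}")

result = ListModeMLEM(events, grid).fit(20)
print(result.summary())
ijk = np.unravel_index(np.argmax(result.image.values), grid.shape)
print("argmax voxel:", tuple(map(int, ijk)))
```

prints

```
6451 events, efficiency 0.65%
List-mode MLEM reconstruction
==================================
grid:            (20, 20, 40)
events used:     6451
events dropped:  0
iterations:      20
snapshots:       []
max intensity:   5698.97
argmax voxel: (10, 10, 20)
```

— about 0.65% of isotropic 478 keV gammas yield an accepted
Compton-then-photoabsorption event in the four-module geometry, and 20
MLEM iterations localize the source at exactly the true voxel.

The end-to-end demo (phantoms → events → training pairs → tight-frame
U-Net → test metrics) runs in under a minute:

```bash
comptoncam pipeline --seed 7 --out runs/
```

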
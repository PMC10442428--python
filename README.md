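# fddft

Unsupervised, feature-aware lesion segmentation for gray-level medical
images via the fast data density functional transform: the image is mapped
onto kinetic/potential energy-density landscapes, their Lagrangian
combination is stabilized by gradient ascent, high-similarity subgraphs
are isolated by an iterated Fermi normalization, and the lesion mask is
extracted by pixel-connectivity filtering.  No training, no labels, no
GPU: a whole 240 × 240 × 32 volume segments in a couple of seconds on one
CPU core.

Intended users: researchers in medical image analysis who want a fast,
fully deterministic, physics-based baseline for whole-lesion (e.g. brain
tumor) segmentation, or a label-free preprocessing stage in front of a
neural network.

## The model

A normalized image ρ ∈ [0, 1]^(H×W) is treated as a particle density on
the pixel lattice.  Two landscapes are computed:

* **KEDF** (kinetic): t[ρ](r) = 2π²·ρ(r) — a pointwise intensity
  enhancement, from the pseudo-Fermi relation ρ[k_F] = k_F^D/(D(2π)^D)
  at D = 2;
* **PEDF** (potential): u[ρ](r) = ½ ∫ ρ(r′)/|r−r′| d²r′ — a Coulombic
  measure of long-range pixel-pair similarity, evaluated as a global
  convolution with the reciprocal distance kernel k(r′; r) = 1/(2|r−r′|)
  via zero-padded 2-D FFTs.  A 12.5 % encode/decode stage (downsample →
  convolve → upsample, with an analytic near-field term) drops the cost
  from O(N³) pixel-sums to O(N log N).

The **adaptive scaling factor** γ = ⟨u⟩/(2⟨t⟩) balances the two
landscapes in the Lagrangian and Hamiltonian density functionals

    L = γ²t − γu,        H = γ²t + γu.

γ is then refined by gradient ascent, γ ← γ + η·⟨L⟩_new/⟨L⟩_prev with
η = 0.5, until ⟨L⟩ ≥ 0 (**geometric stability**).  The superlevel set
{L ≥ ⟨L⟩}, split into connected components, is the **aware feature map**.
Separately, iterating the **Fermi normalization** FN(ρ) =
1/(e^−(ρ−ρ_F)/ρ_S + 1) and keeping FN > 0.5 until fewer than half of the
support survives yields a high-similarity mask (**similarity
convergence**).  Components that touch that mask, have more adjacency
edges than 3π√‖I‖₀/2, and have a bounding box no larger than 75 % of the
brain's box per side become the lesion; slice masks are stacked and the
single 3-D component with the highest mean energy (ties: most voxels)
survives.  Accuracy is scored with the 3-D soft dice
DS = 2Σt·g/(Σt² + Σg² + ε), ε = 10⁻⁵.

## Worked example

```bash
fddft phantom --out runs/ph --seed 0
fddft segment runs/ph/phantom.nii.gz --out runs/seg
fddft score --pred runs/seg/mask.nii.gz --truth runs/ph/truth.nii.gz
```

prints

```
wrote runs/ph/phantom.nii.gz ((240, 240, 32), 20223 lesion voxels)
mask voxels: 20224
report: runs/seg/report.json
0.9999
```

The phantom is a synthetic FLAIR-like head volume with a known
ellipsoidal lesion of 20 223 voxels; the unsupervised pipeline recovers a
20 224-voxel mask that overlaps it at soft dice 0.9999.  `report.json`
records, per slice, the γ trace of the gradient ascent, the similarity
iterations, and the full component table (edges, bounding boxes, mean
energies), so every stage can be audited.  The same thing is available
from Python:

```python
from fddft import PhantomSpec, generate_phantom, segment_volume, soft_dice

vol, truth = generate_phantom(PhantomSpec(seed=0))
mask, report = segment_volume(vol)
print(soft_dice(mask, truth))   # 0.9999
```

## Limitations

The method keys on lesions that are bright, compact and well-connected
relative to their surroundings.  Low lesion/tissue contrast, lesions
darker than the tissue mean, and scenes whose potential landscape is
dominated by a large unrelated structure all degrade it — the
`generate_hard_cases` fixtures reproduce exactly these regimes, and the
test suite snapshots (rather than asserts away) the degraded behaviour.
See `docs/methods.md` for the full methods note.
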
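# fiberodf

Intravoxel white-matter fiber orientation estimation from diffusion MRI.

Diffusion MRI measures how water displaces inside brain tissue; in white
matter, displacement is easiest along axon bundles, so the angular profile
of the signal encodes fiber orientation. The standard single-tensor model
cannot represent two or more bundles crossing inside one voxel, which is
common in the brain. `fiberodf` implements a probabilistic pipeline for
exactly that problem, for researchers working on HARDI reconstruction,
fiber mapping, and tractography preprocessing:

1. **GQI reconstruction** — the orientation distribution function (ODF)
   along direction **u** is computed from the sampled q-space signal as a
   sinc-weighted sum,
   ψ(**u**) = L·Σᵢ W(**q**ᵢ)·sinc(L·|**q**ᵢ|·(**g**ᵢ·**u**)),
   with |**q**ᵢ| = √(b·τ), evaluated on an icosahedral hemisphere grid
   (81 or 321 directions).
2. **Clustered-vMF direction extraction** — grid directions whose
   normalized ODF value exceeds a threshold (default 0.4) are treated as
   weighted directional data on S² and fitted with mixtures of von
   Mises-Fisher distributions, f(**x**|μ,κ) = c₃(κ)·e^{κμᵀ**x**}, by EM;
   the Bayesian Information Criterion selects the number of components,
   and antipodal component pairs merge into fiber axes with per-axis
   weight and concentration κ.
3. **Std baseline** — the deterministic local-maxima-within-a-radius peak
   finder used by mainstream packages, for comparison.
4. **Simulation benchmarks** — multi-tensor crossing-fiber voxels with
   Rician noise, angle × SNR precision grids scored by optimally assigned
   axial error, and a curved two-bundle 32×32 phantom field.

It reads and writes NIfTI volumes and plain-text b-tables, and exposes
both a Python API and a small `fiberodf` command-line tool
(`simulate`, `reconstruct`, `directions`, `benchmark`, `curved-demo`).

## Worked example

```python
import numpy as np
from fiberodf import (build_basis, crossing_compartments, estimate_vmf,
                      hemisphere_grid, reconstruct_odf, shell_scheme,
                      std_peaks, synth_signal)

grid = hemisphere_grid(321)                 # ODF directions on the hemisphere
scheme = shell_scheme(3000.0)               # single shell, b = 3000 s/mm^2
basis = build_basis(scheme, grid)

comps = crossing_compartments(90.0)         # two fibers along +x and +y
odf = reconstruct_odf(synth_signal(comps, scheme), basis)
est = estimate_vmf(odf, grid, seed=0)
print(est.n_fibers, est.axes.round(3), est.weights.round(2))
```

Running `python examples/01_crossing_fibers.py` (the same computation plus
the Std baseline) prints:

```
ODF reconstructed on 321 directions, GFA = 0.189

vmf method: 2 fibers
  axis [ 1.000 -0.000  0.000]  weight 0.50  error vs truth 0.00 deg
  axis [-0.000 -1.000 -0.000]  weight 0.50  error vs truth 0.00 deg

std method: 2 fibers
  axis [ 1.000  0.000  0.000]  weight 1.00  error vs truth 0.00 deg
  axis [ 0.000  1.000  0.000]  weight 0.96  error vs truth 0.00 deg
```

Both methods recover the two orthogonal axes exactly; the vMF weights are
the fraction of clustered ODF mass per fiber (≈0.5 each for an equal
crossing), while the Std weights are normalized peak heights. The other
scripts in `examples/` demonstrate noise robustness, the angle × SNR
benchmark grids, the curved-bundle field, and the NIfTI/b-table volume
pipeline.

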
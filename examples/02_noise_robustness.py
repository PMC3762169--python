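"""Noisy recovery of the showcase crossing configurations.

Runs 10 Rician-noise replicates (sigma = 0.033, SNR ~ 30) of each
showcase configuration — two-fiber crossings at 90/90/50 degrees for
b = 1500/3000/5000 and three-fiber crossings at 60/50 degrees for
b = 3000/5000 — each with a fresh random 3D orientation, and reports how
often the clustered-vMF pipeline recovers the correct fiber count with
every axis within 15 degrees of truth.
"""

import numpy as np

from fiberodf import SHOWCASE_CONFIGURATIONS, build_basis, evaluate_configuration, hemisphere_grid, shell_scheme

grid = hemisphere_grid(321)
n_rep = 10

for ci, (angles, bvalue) in enumerate(SHOWCASE_CONFIGURATIONS):
    basis = build_basis(shell_scheme(bvalue), grid)
    hits, errs = 0, []
    for rep in range(n_rep):
        seed = int(np.random.SeedSequence(7, spawn_key=(ci, rep)).generate_state(1)[0] % 2**31)
        out = evaluate_configuration(angles, bvalue, sigma=0.033, seed=seed, rotate=True, basis=basis)
        ok = out["n_estimated"] == out["n_true"] and np.all(out["axis_errors"] <= 15.0)
        hits += int(ok)
        errs.extend(out["axis_errors"])
    sep = angles[1] - angles[0]
    print(f"{len(angles)}-fiber, {sep:g} deg apart, b={bvalue:g}: "
          f"recovered {hits}/{n_rep}, mean axis error {np.mean(errs):.1f} deg")

print(
    "\nEach line gives the fraction of noisy replicates in which the fiber "
    "count and all axes were recovered; even the 50-degree crossings should "
    "succeed in nearly every replicate."
)
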
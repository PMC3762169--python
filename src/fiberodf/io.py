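"""File formats and volume-level processing.

* b-tables: whitespace-delimited text, one q-space sample per row in the
  4-column dialect ``b  gx  gy  gz`` (b in s/mm^2); '#' starts a comment.
  b = 0 rows may carry zero vectors; nonzero-b directions are renormalized
  on load (with a warning if they deviate by more than 1e-3).
* Volumes: NIfTI-1 via nibabel.  Phantoms export as 4D volumes plus a
  b-table and a JSON ground-truth sidecar; reconstruction produces a GFA
  volume, an ODF array container (npz with the grid alongside), a peaks
  volume and per-voxel direction records.
* DEC maps: RGB = |axis| (x red, y green, z blue) scaled by GFA.

Voxel directions are reported in the image coordinate frame; no
gradient-to-image rotation is applied (a flag is reserved for it), which
callers must account for when using scanner b-tables.
"""

from __future__ import annotations

import json
import warnings

import nibabel as nib
import numpy as np
import pandas as pd

from .directions import EmptySampleError, UnpairedComponentsError, estimate_vmf, std_peaks
from .gqi import build_basis, reconstruct_odf
from .simulate import GradientScheme, PhantomField
from .sphere import hemisphere_grid

__all__ = [
    "parse_btable",
    "write_btable",
    "dec_map",
    "save_phantom",
    "reconstruct_volume_files",
    "extract_directions_volume",
]


def parse_btable(path) -> GradientScheme:
    """Parse a 4-column (b, gx, gy, gz) text b-table into a GradientScheme."""
    bvals, dirs = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns (b gx gy gz), got {len(parts)}")
            try:
                b, x, y, z = map(float, parts)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry") from exc
            if b < 0:
                raise ValueError(f"{path}:{lineno}: negative b-value {b}")
            v = np.array([x, y, z])
            n = np.linalg.norm(v)
            if b > 0:
                if n == 0:
                    raise ValueError(f"{path}:{lineno}: zero direction with b > 0")
                if abs(n - 1.0) > 1e-3:
                    warnings.warn(f"{path}:{lineno}: direction norm {n:.6f}; renormalizing")
                if abs(n - 1.0) > 1e-12:  # keep exact unit rows bit-identical
                    v = v / n
            bvals.append(b)
            dirs.append(v)
    return GradientScheme(directions=np.array(dirs), bvalues=np.array(bvals))


def write_btable(path, scheme: GradientScheme) -> None:
    """Write a GradientScheme as a 4-column text b-table."""
    rows = np.column_stack([scheme.bvalues, scheme.directions])
    np.savetxt(path, rows, fmt="%.17g")


def dec_map(axes: np.ndarray, gfa: np.ndarray, gfa_threshold: float = 0.0) -> np.ndarray:
    """GFA-modulated directionally encoded color volume.

    ``axes``: (..., 3) principal axis per voxel; ``gfa``: (...,) anisotropy.
    RGB = |axis| * gfa; voxels with gfa below the threshold are black.
    Sign-invariant: axis and -axis map to the same color.
    """
    axes = np.asarray(axes, dtype=float)
    gfa = np.asarray(gfa, dtype=float)
    rgb = np.abs(axes) * gfa[..., None]
    rgb[gfa < gfa_threshold] = 0.0
    return np.clip(rgb, 0.0, 1.0)


def save_phantom(phantom: PhantomField, prefix) -> dict:
    """Export a phantom as NIfTI 4D signals + b-table + JSON ground truth.

    Returns the paths written: {'nifti', 'btable', 'truth'}.
    """
    prefix = str(prefix)
    nx, ny = phantom.shape
    data = phantom.signals.reshape(nx, ny, 1, phantom.scheme.m)
    paths = {
        "nifti": prefix + "_signal.nii.gz",
        "btable": prefix + "_btable.txt",
        "truth": prefix + "_truth.json",
    }
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine=np.eye(4)), paths["nifti"])
    write_btable(paths["btable"], phantom.scheme)
    truth = {
        "shape": list(phantom.shape),
        "noise_sigma": phantom.noise_sigma,
        "seed": phantom.seed,
        "voxels": [
            {
                "i": i, "j": j,
                "axes": [c.axis.tolist() for c in phantom.compartments[i][j]],
                "fractions": [c.fraction for c in phantom.compartments[i][j]],
            }
            for i in range(nx) for j in range(ny) if phantom.compartments[i][j]
        ],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def reconstruct_volume_files(
    nifti_path, btable_path, out_prefix, grid_n: int = 321, sampling_length: float = 1.25
) -> dict:
    """Batch GQI over a 4D NIfTI volume: writes GFA NIfTI and an ODF npz.

    The npz container stores the per-voxel ODF values (voxels x N), the
    voxel index list, the grid vertices, and the normalization metadata.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, m) diffusion volume")
    scheme = parse_btable(btable_path)
    if data.shape[-1] != scheme.m:
        raise ValueError(f"volume has {data.shape[-1]} samples but b-table has {scheme.m} rows")
    grid = hemisphere_grid(grid_n)
    basis = build_basis(scheme, grid, sampling_length)

    from .gqi import reconstruct_volume as _rv

    values, normalized, gfa_vol = _rv(data, basis)
    out_prefix = str(out_prefix)
    paths = {"gfa": out_prefix + "_gfa.nii.gz", "odf": out_prefix + "_odf.npz"}
    nib.save(nib.Nifti1Image(gfa_vol.astype(np.float32), img.affine), paths["gfa"])
    np.savez_compressed(
        paths["odf"],
        values=values.reshape(-1, len(grid)).astype(np.float32),
        shape=np.array(data.shape[:3]),
        grid_vertices=grid.vertices,
        sampling_length=sampling_length,
    )
    return paths


def extract_directions_volume(
    nifti_path, btable_path, out_prefix,
    method: str = "vmf", grid_n: int = 321, threshold: float = 0.4,
    max_fibers: int = 3, restarts: int = 5, seed: int = 0,
    gfa_threshold: float = 0.0, sampling_length: float = 1.25,
) -> dict:
    """Full per-voxel pipeline over a 4D NIfTI volume.

    Writes a zero-padded peaks NIfTI (3 * max_fibers per voxel), a DEC RGB
    NIfTI, and a CSV of per-voxel records (axes, weights, kappa, n_fibers,
    gfa).  Returns the written paths.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, m) diffusion volume")
    scheme = parse_btable(btable_path)
    grid = hemisphere_grid(grid_n)
    basis = build_basis(scheme, grid, sampling_length)
    shape = data.shape[:3]
    peaks = np.zeros(shape + (3 * max_fibers,), dtype=np.float32)
    gfa_vol = np.zeros(shape, dtype=np.float32)
    principal = np.zeros(shape + (3,), dtype=np.float32)
    records = []
    n_failed = 0
    for idx in np.ndindex(shape):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(int(v) for v in idx)))
        odf = reconstruct_odf(data[idx], basis)
        gfa_vol[idx] = odf.gfa
        if odf.gfa < gfa_threshold:
            continue
        try:
            if method == "vmf":
                est = estimate_vmf(odf, grid, threshold=threshold, max_fibers=max_fibers,
                                   restarts=restarts, seed=rng)
            elif method == "std":
                est = std_peaks(odf, grid, threshold=threshold, max_fibers=max_fibers)
            else:
                raise ValueError(f"unknown method {method!r}")
        except (EmptySampleError, UnpairedComponentsError):
            n_failed += 1
            continue
        for f, axis in enumerate(est.axes[:max_fibers]):
            peaks[idx][3 * f : 3 * f + 3] = axis
        if est.n_fibers:
            principal[idx] = est.axes[0]
        records.append(
            dict(
                i=idx[0], j=idx[1], k=idx[2], n_fibers=est.n_fibers, gfa=float(odf.gfa),
                axes=json.dumps(np.round(est.axes, 6).tolist()),
                weights=json.dumps(np.round(est.weights, 6).tolist()),
                kappas=json.dumps(np.round(est.kappas, 3).tolist()),
            )
        )
    out_prefix = str(out_prefix)
    paths = {
        "peaks": out_prefix + "_peaks.nii.gz",
        "dec": out_prefix + "_dec.nii.gz",
        "records": out_prefix + "_directions.csv",
    }
    nib.save(nib.Nifti1Image(peaks, img.affine), paths["peaks"])
    rgb = dec_map(principal, gfa_vol, gfa_threshold)
    nib.save(nib.Nifti1Image(rgb.astype(np.float32), img.affine), paths["dec"])
    pd.DataFrame.from_records(records).to_csv(paths["records"], index=False)
    paths["n_failed"] = n_failed
    return paths
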
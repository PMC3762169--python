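"""Multi-tensor simulation of diffusion-weighted signals.

Each fiber population inside a voxel is modelled as a prolate diffusion
tensor (typical white-matter eigenvalues {1700, 200, 200} x 1e-6 mm^2/s);
the normalized attenuation measured along gradient direction u_i at
diffusion weighting b_i is the fraction-weighted sum of mono-exponential
compartments

    S(u_i) = sum_k  p_k * exp(-b_i * u_i^T D_k u_i),        S0 = 1.

Rician noise emulates magnitude MRI: S = || (S + n1, n2) ||_2 with
n1, n2 ~ N(0, sigma) i.i.d.

The module also provides the crossing-fiber voxel generators used by the
benchmark suite and a 32 x 32 two-bundle phantom (one straight, one curved
bundle) where the crossing angle varies continuously across the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .sphere import hemisphere_grid

__all__ = [
    "TensorCompartment",
    "GradientScheme",
    "PhantomField",
    "DEFAULT_EIGENVALUES",
    "synth_signal",
    "rotate_axis",
    "random_rotation",
    "add_rician",
    "crossing_compartments",
    "shell_scheme",
    "curved_phantom",
]

#: prolate white-matter tensor eigenvalues, mm^2/s
DEFAULT_EIGENVALUES = np.array([1700.0, 200.0, 200.0]) * 1e-6


@dataclass(frozen=True)
class TensorCompartment:
    """One fiber population: prolate tensor along ``axis`` with volume fraction."""

    eigenvalues: np.ndarray
    axis: np.ndarray
    fraction: float

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        ax = np.asarray(self.axis, dtype=float)
        if ev.shape != (3,) or np.any(ev <= 0):
            raise ValueError("eigenvalues must be 3 positive diffusivities")
        if np.any(np.diff(ev) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        n = np.linalg.norm(ax)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("compartment axis must be unit norm")
        object.__setattr__(self, "eigenvalues", ev)
        object.__setattr__(self, "axis", ax / n)
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("volume fraction must lie in [0, 1]")

    def tensor(self) -> np.ndarray:
        """3x3 diffusion tensor R diag(eigenvalues) R^T with R[:,0] = axis."""
        e1 = self.axis
        # deterministic completion of the orthonormal frame
        helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(helper, e1)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        R = np.column_stack([e1, e2, e3])
        return R @ np.diag(self.eigenvalues) @ R.T


@dataclass(frozen=True)
class GradientScheme:
    """q-space sampling table: gradient directions and aligned b-values."""

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if len(d) != len(b):
            raise ValueError("directions and bvalues must have equal length")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(d, axis=1)
        nonzero = b > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-6):
            raise ValueError("directions with b > 0 must be unit norm")
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "bvalues", b)

    @property
    def m(self) -> int:
        return len(self.bvalues)

    def __len__(self) -> int:
        return len(self.bvalues)


def shell_scheme(bvalue: float, n_dirs: int = 321) -> GradientScheme:
    """Single-shell scheme on an icosahedral hemisphere grid.

    The default 321 directions match the hemisphere density at which the
    simulated diffusion profiles are synthesized for the crossing-fiber
    experiments; 81 gives the coarser density.
    """
    grid = hemisphere_grid(n_dirs)
    return GradientScheme(directions=grid.vertices, bvalues=np.full(len(grid), float(bvalue)))


def synth_signal(compartments, scheme: GradientScheme) -> np.ndarray:
    """Noise-free normalized attenuation S(u_i) for a multi-compartment voxel."""
    compartments = list(compartments)
    if not compartments:
        raise ValueError("at least one tensor compartment is required")
    total = sum(c.fraction for c in compartments)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"volume fractions must sum to 1, got {total}")
    u = scheme.directions
    b = scheme.bvalues
    signal = np.zeros(scheme.m)
    for c in compartments:
        adc = np.einsum("ij,jk,ik->i", u, c.tensor(), u)  # u^T D u per direction
        signal += c.fraction * np.exp(-b * adc)
    return signal


def rotate_axis(base_axis, angle_deg: float) -> np.ndarray:
    """Rotate a unit vector about the z-axis by ``angle_deg`` degrees."""
    base_axis = np.asarray(base_axis, dtype=float)
    if abs(np.linalg.norm(base_axis) - 1.0) > 1e-6:
        raise ValueError("base_axis must be unit norm")
    return Rotation.from_euler("z", angle_deg, degrees=True).apply(base_axis)


def random_rotation(rng: np.random.Generator) -> Rotation:
    """Uniformly random 3D rotation (quaternion method), seeded by ``rng``."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q)


def add_rician(signal: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Rician-corrupt an attenuation vector: S = ||(S + n1, n2)||, n ~ N(0, sigma).

    ``seed`` may be an integer or a numpy Generator; sigma = 0 returns the
    input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.hypot(signal + n1, n2)


def crossing_compartments(
    angles_deg,
    fractions=None,
    eigenvalues: np.ndarray = DEFAULT_EIGENVALUES,
    rotation: Rotation | None = None,
) -> list[TensorCompartment]:
    """Build a crossing-fiber voxel: axes in the x-y plane at the given
    in-plane angles (degrees from +x), optionally globally rotated.

    ``angles_deg`` may be a scalar (two fibers at 0 and angle) or a list of
    per-fiber angles.  Fractions default to equal weights.
    """
    if np.isscalar(angles_deg):
        angles_deg = [0.0, float(angles_deg)]
    angles_deg = list(angles_deg)
    n = len(angles_deg)
    if fractions is None:
        fractions = [1.0 / n] * n
    if len(fractions) != n:
        raise ValueError("fractions must match the number of fiber angles")
    comps = []
    for ang, p in zip(angles_deg, fractions):
        axis = rotate_axis(np.array([1.0, 0.0, 0.0]), ang)
        if rotation is not None:
            axis = rotation.apply(axis)
        comps.append(TensorCompartment(eigenvalues=eigenvalues, axis=axis, fraction=p))
    return comps


@dataclass(frozen=True)
class PhantomField:
    """A voxel grid of simulated fiber configurations plus their signals.

    ``compartments[i][j]`` is the (possibly empty) compartment list of voxel
    (i, j); empty lists are background (no attenuation, S = 1 everywhere
    before noise).  ``signals`` has shape dims + (m,).
    """

    shape: tuple
    compartments: list
    signals: np.ndarray
    scheme: GradientScheme
    noise_sigma: float
    seed: int
    truth_axes: list = field(default=None, compare=False)

    def truth(self, i: int, j: int) -> np.ndarray:
        """Ground-truth fiber axes of voxel (i, j), shape (n_fibers, 3)."""
        return np.array([c.axis for c in self.compartments[i][j]])


def curved_phantom(
    dims=(32, 32),
    scheme: GradientScheme | None = None,
    sigma: float = 0.033,
    seed: int = 0,
    bvalue: float = 4000.0,
    eigenvalues: np.ndarray = DEFAULT_EIGENVALUES,
) -> PhantomField:
    """Two-bundle field: a straight horizontal bundle crossed by a curved one.

    The straight bundle is a horizontal band (axis +x).  The curved bundle
    is an annulus centred on the left edge at the band's mid-height, whose
    per-voxel axis is the arc tangent; inside the band the tangent sweeps
    through vertical, so the crossing angle in the overlap covers a wide
    range up to 90 degrees.  Overlap voxels hold two equal-fraction
    compartments.
    """
    nx, ny = dims
    if nx <= 0 or ny <= 0:
        raise ValueError("dims must be positive")
    if scheme is None:
        scheme = shell_scheme(bvalue)
    rng = np.random.default_rng(seed)

    band_lo, band_hi = 0.375 * ny, 0.625 * ny       # straight bundle rows
    cy = 0.5 * ny                                   # annulus centre (0, cy)
    r_in, r_out = 0.2 * nx, 0.9 * nx                # curved bundle radii

    compartments: list[list[list[TensorCompartment]]] = []
    signals = np.zeros((nx, ny, scheme.m))
    for i in range(nx):
        row = []
        for j in range(ny):
            x, y = i + 0.5, j + 0.5
            voxel: list[TensorCompartment] = []
            in_band = band_lo <= y < band_hi
            r = np.hypot(x, y - cy)
            in_arc = r_in <= r < r_out
            if in_band and in_arc:
                tangent = np.array([-(y - cy), x, 0.0]) / r
                voxel = [
                    TensorCompartment(eigenvalues, np.array([1.0, 0.0, 0.0]), 0.5),
                    TensorCompartment(eigenvalues, tangent, 0.5),
                ]
            elif in_band:
                voxel = [TensorCompartment(eigenvalues, np.array([1.0, 0.0, 0.0]), 1.0)]
            elif in_arc:
                tangent = np.array([-(y - cy), x, 0.0]) / r
                voxel = [TensorCompartment(eigenvalues, tangent, 1.0)]
            row.append(voxel)
            s = synth_signal(voxel, scheme) if voxel else np.ones(scheme.m)
            signals[i, j] = add_rician(s, sigma, rng)
        compartments.append(row)

    return PhantomField(
        shape=tuple(dims),
        compartments=compartments,
        signals=signals,
        scheme=scheme,
        noise_sigma=float(sigma),
        seed=int(seed),
    )
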
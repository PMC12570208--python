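"""Detector geometry, Ewald-sphere mapping, and rotation arithmetic.

Conventions (fixed once, everything else depends on them):

* Quaternions are scalar-first ``(w, x, y, z)``, unit norm, and describe
  *active* right-handed rotations.  ``q`` and ``-q`` encode the same
  rotation; canonical form has ``w >= 0``.
* Lengths are metres, reciprocal coordinates cycles per metre.
* Images are stored slow-axis-major: ``image[i_slow, j_fast]``.
* The incident beam travels along +z; the detector plane sits at
  ``z = distance``.  A pixel subtends the unit vector ``s`` from the
  interaction point, and elastic scattering puts its reciprocal
  coordinate at ``q = (s - s0) / wavelength`` on the Ewald sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "DetectorGeometry",
    "QGrid",
    "pixel_to_q",
    "quat_canonical",
    "quat_multiply",
    "quat_to_matrix",
    "quat_geodesic",
    "rotate_vectors",
    "random_orientations",
    "reference_grid",
]


@dataclass(frozen=True)
class DetectorGeometry:
    """Square-pixel area detector downstream of the interaction point.

    Parameters
    ----------
    n_fast, n_slow:
        Pixel counts along the fast (x) and slow (y) axes.
    pixel_size, distance, wavelength:
        Metres.
    beam_center:
        Fractional pixel coordinates ``(fast, slow)`` of the direct beam.
        Defaults to the detector centre.
    """

    n_fast: int
    n_slow: int
    pixel_size: float
    distance: float
    wavelength: float
    beam_center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_fast < 2 or self.n_slow < 2:
            raise ParameterError(
                f"n_fast/n_slow must be >= 2, got {self.n_fast}x{self.n_slow}"
            )
        for name in ("pixel_size", "distance", "wavelength"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be positive and finite, got {v}")
        if self.beam_center is None:
            object.__setattr__(
                self,
                "beam_center",
                ((self.n_fast - 1) / 2.0, (self.n_slow - 1) / 2.0),
            )
        cf, cs = self.beam_center
        if not (0.0 <= cf <= self.n_fast - 1 and 0.0 <= cs <= self.n_slow - 1):
            raise ParameterError(
                f"beam_center {self.beam_center} outside detector bounds"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape, slow-axis-major."""
        return (self.n_slow, self.n_fast)


@dataclass(frozen=True)
class QGrid:
    """Per-pixel reciprocal-space coordinates of a detector.

    ``q`` has shape ``(n_slow, n_fast, 3)`` in cycles/metre; ``q_max`` is
    the largest pixel ``|q|``.  ``curved`` records whether the points lie
    on the Ewald sphere (default) or on the flat small-angle plane.
    """

    q: np.ndarray
    q_max: float
    wavelength: float
    curved: bool = True

    @property
    def flat(self) -> np.ndarray:
        """The same vectors as a ``(n_pixels, 3)`` array."""
        return self.q.reshape(-1, 3)


def pixel_to_q(geom: DetectorGeometry, curved: bool = True) -> QGrid:
    """Map every detector pixel to its reciprocal-space coordinate.

    With ``curved=True`` (default) the standard elastic-scattering
    construction ``q = (s - s0)/lambda`` is used, placing all points on
    the Ewald sphere.  ``curved=False`` selects the small-angle limit
    with ``q_z = 0``, useful for analytic tests.
    """
    cf, cs = geom.beam_center
    jf = np.arange(geom.n_fast, dtype=float)
    isl = np.arange(geom.n_slow, dtype=float)
    x = (jf - cf) * geom.pixel_size          # fast axis
    y = (isl - cs) * geom.pixel_size         # slow axis
    xx, yy = np.meshgrid(x, y)               # (n_slow, n_fast)
    if curved:
        r = np.sqrt(xx**2 + yy**2 + geom.distance**2)
        q = np.empty((geom.n_slow, geom.n_fast, 3))
        q[..., 0] = xx / r / geom.wavelength
        q[..., 1] = yy / r / geom.wavelength
        q[..., 2] = (geom.distance / r - 1.0) / geom.wavelength
    else:
        q = np.zeros((geom.n_slow, geom.n_fast, 3))
        q[..., 0] = xx / geom.distance / geom.wavelength
        q[..., 1] = yy / geom.distance / geom.wavelength
    q_max = float(np.max(np.linalg.norm(q.reshape(-1, 3), axis=1)))
    return QGrid(q=q, q_max=q_max, wavelength=geom.wavelength, curved=curved)


# ---------------------------------------------------------------------------
# quaternion arithmetic (scalar-first, active rotations)
# ---------------------------------------------------------------------------

def _check_unit(q: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise ParameterError(f"quaternion must have 4 components, got shape {q.shape}")
    n = np.linalg.norm(q, axis=-1)
    if np.any(np.abs(n - 1.0) > tol):
        raise ParameterError(f"quaternion norm {n} deviates from 1 beyond {tol}")
    return q / n[..., None]


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Normalize and flip sign so that ``w >= 0`` (q and -q are one rotation)."""
    q = _check_unit(q)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product: the rotation ``q1 o q2`` (q2 applied first)."""
    w1, x1, y1, z1 = np.moveaxis(np.asarray(q1, dtype=float), -1, 0)
    w2, x2, y2, z2 = np.moveaxis(np.asarray(q2, dtype=float), -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix (or stack thereof) for scalar-first quaternions."""
    q = _check_unit(q)
    w, x, y, z = np.moveaxis(q, -1, 0)
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_geodesic(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Geodesic rotation angle between two orientations, radians in [0, pi].

    The q ~ -q identification is applied, so antipodal quaternions are at
    distance zero.
    """
    d = np.abs(np.sum(np.asarray(q1) * np.asarray(q2), axis=-1))
    return 2.0 * np.arccos(np.clip(d, -1.0, 1.0))


def rotate_vectors(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply the rotation ``q`` to a vector or array of 3-vectors."""
    q = _check_unit(q)
    if q.ndim != 1:
        raise ParameterError("rotate_vectors takes a single quaternion")
    v = np.asarray(v, dtype=float)
    return v @ quat_to_matrix(q).T


# ---------------------------------------------------------------------------
# orientation sampling
# ---------------------------------------------------------------------------

_IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def random_orientations(n: int, seed: int) -> np.ndarray:
    """Draw ``n`` orientations uniformly on SO(3) (Shoemake's method).

    Returns an ``(n, 4)`` array of canonical scalar-first unit
    quaternions; deterministic for a fixed seed.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    u1, u2, u3 = rng.random((3, n))
    a, b = np.sqrt(1.0 - u1), np.sqrt(u1)
    q = np.stack(
        [
            a * np.sin(2 * np.pi * u2),
            a * np.cos(2 * np.pi * u2),
            b * np.sin(2 * np.pi * u3),
            b * np.cos(2 * np.pi * u3),
        ],
        axis=1,
    )
    return quat_canonical(q)


def _euler_zyz_to_quat(alpha: np.ndarray, beta: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Intrinsic z-y-z Euler angles to scalar-first quaternions."""
    qa = np.stack([np.cos(alpha / 2), np.zeros_like(alpha), np.zeros_like(alpha), np.sin(alpha / 2)], axis=-1)
    qb = np.stack([np.cos(beta / 2), np.zeros_like(beta), np.sin(beta / 2), np.zeros_like(beta)], axis=-1)
    qg = np.stack([np.cos(gamma / 2), np.zeros_like(gamma), np.zeros_like(gamma), np.sin(gamma / 2)], axis=-1)
    return quat_multiply(qa, quat_multiply(qb, qg))


def reference_grid(n_ref: int, scheme: str = "quasi_uniform") -> np.ndarray:
    """Deterministic reference orientation set of size ``n_ref``.

    ``euler_grid`` enumerates a near-cubic regular grid of z-y-z Euler
    angles (the classical 3D Euler-angle grid); ``quasi_uniform`` uses
    super-Fibonacci spirals, a deterministic low-discrepancy covering of
    SO(3) whose nearest-neighbour spacing shrinks as ``n_ref**(-1/3)``.
    ``n_ref == 1`` returns the identity under either scheme.
    """
    if n_ref < 1:
        raise ParameterError(f"n_ref must be >= 1, got {n_ref}")
    if scheme not in ("euler_grid", "quasi_uniform"):
        raise ParameterError(f"unknown reference-grid scheme {scheme!r}")
    if n_ref == 1:
        return _IDENTITY[None, :].copy()

    if scheme == "euler_grid":
        m = int(np.ceil(round(n_ref ** (1.0 / 3.0), 9)))
        alpha = 2 * np.pi * np.arange(m) / m
        beta = np.pi * (np.arange(m) + 0.5) / m        # open interval avoids gimbal dupes
        gamma = 2 * np.pi * np.arange(m) / m
        aa, bb, gg = np.meshgrid(alpha, beta, gamma, indexing="ij")
        q = _euler_zyz_to_quat(aa.ravel(), bb.ravel(), gg.ravel())
        return quat_canonical(q[:n_ref])

    # super-Fibonacci spirals (deterministic, low discrepancy on SO(3))
    phi = np.sqrt(2.0)
    psi = 1.533751168755204288118041  # root of psi^4 = psi + 4
    i = np.arange(n_ref, dtype=float)
    s = i + 0.5
    t = s / n_ref
    d = 2 * np.pi * s
    r, big_r = np.sqrt(t), np.sqrt(1.0 - t)
    alpha, beta = d / phi, d / psi
    q = np.stack(
        [r * np.sin(alpha), r * np.cos(alpha), big_r * np.sin(beta), big_r * np.cos(beta)],
        axis=1,
    )
    return quat_canonical(q)
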
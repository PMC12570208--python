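"""Synthetic diffraction data: phantoms, ground truth, and noisy patterns.

This is a compact stand-in for a full SPI simulator.  It builds
Gaussian-blob density phantoms (optionally a pair of conformations
differing by one displaced blob), computes their oversampled intensity
volume |G|^2 and exact autocorrelation, and renders stacks of oriented
2D diffraction patterns with the experimentally motivated noise
processes: Poisson counting noise, per-shot fluence jitter, beam
miscentering, and a static sloped background.

Scattering model: the expected photon count at detector pixel ``p`` of
image ``i`` is ``fluence_i * I(R_i q_p)`` where ``I = |G|^2`` is the 3D
intensity of that image's conformation, ``q_p`` the pixel's Ewald-sphere
coordinate and ``R_i`` the particle orientation.  ``fluence`` is thus a
plain multiplicative factor; :func:`fluence_for_mean_photons` converts a
target photons-per-pattern budget into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .geometry import DetectorGeometry, QGrid, pixel_to_q, quat_to_matrix
from .nufft import FourierVolume, nufft_type2

__all__ = [
    "DensityModel",
    "PhantomSpec",
    "NoiseSpec",
    "PatternStack",
    "make_phantom",
    "density_to_intensity",
    "intensity_from_density",
    "exact_autocorrelation",
    "simulate_patterns",
    "design_geometry",
    "fluence_for_mean_photons",
]


@dataclass
class DensityModel:
    """Real-space electron density on a cubic voxel grid.

    ``rho`` is nonnegative; ``voxel`` is the edge length of one voxel in
    metres.  Voxel centres sit at ``(k - N//2) * voxel``.
    """

    rho: np.ndarray
    voxel: float
    support_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        if rho.ndim != 3 or len(set(rho.shape)) != 1:
            raise ParameterError(f"rho must be a cube, got shape {rho.shape}")
        if not np.all(np.isfinite(rho)):
            raise ParameterError("rho contains non-finite values")
        if rho.min() < 0:
            raise ParameterError("rho must be nonnegative")
        if self.voxel <= 0:
            raise ParameterError(f"voxel must be positive, got {self.voxel}")
        if self.support_mask is not None:
            mask = np.asarray(self.support_mask, dtype=bool)
            if mask.shape != rho.shape:
                raise ParameterError("support_mask shape does not match rho")
            if np.any(rho[~mask] != 0):
                raise ParameterError("rho is nonzero outside support_mask")
            self.support_mask = mask
        self.rho = rho

    @property
    def N(self) -> int:
        return self.rho.shape[0]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a Gaussian-blob phantom.

    ``two_conformations`` produces a pair of models identical except for
    one blob displaced by ``conformation_shift`` (metres), emulating two
    structural states of the same particle.
    """

    kind: str = "blobs"
    n_blobs: int = 4
    blob_sigma: float = 2.5e-10          # metres; ~2.5 voxels at 1 A voxels
    conformation_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("blobs", "two_conformations"):
            raise ParameterError(f"unknown phantom kind {self.kind!r}")
        if self.n_blobs < 1:
            raise ParameterError("n_blobs must be >= 1")
        if self.blob_sigma <= 0:
            raise ParameterError("blob_sigma must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise processes applied to simulated patterns.

    ``fluence_mean`` scales expected counts; jitter is log-normal with
    the given coefficient of variation; miscentering is an integer-pixel
    shift drawn from a rounded Gaussian; the background is a static
    plane ``b0 + bf*fast + bs*slow`` in counts.
    """

    poisson: bool = True
    fluence_mean: float = 1.0
    fluence_jitter_cv: float = 0.0
    miscenter_sigma: float = 0.0
    background_slope: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fluence_mean < 0 or self.fluence_jitter_cv < 0 or self.miscenter_sigma < 0:
            raise ParameterError("fluence_mean, fluence_jitter_cv, miscenter_sigma must be >= 0")


@dataclass
class PatternStack:
    """A stack of D diffraction images plus per-image metadata.

    Ground-truth fields (``true_orientations``, ``true_conformations``)
    exist only for simulated data.
    """

    images: np.ndarray                        # (D, n_slow, n_fast)
    fluence: np.ndarray                       # (D,)
    true_orientations: np.ndarray | None = None   # (D, 4)
    true_conformations: np.ndarray | None = None  # (D,)

    def __post_init__(self) -> None:
        img = np.asarray(self.images)
        if img.ndim != 3 or img.shape[0] < 1:
            raise ParameterError(f"images must be (D, slow, fast) with D >= 1, got {img.shape}")
        if img.min() < 0:
            raise ParameterError("images contain negative counts")
        self.images = img
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.fluence.shape != (img.shape[0],):
            raise ParameterError("fluence must have one entry per image")

    @property
    def D(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _blob_centers(spec: PhantomSpec, radius: float) -> np.ndarray:
    """Deterministic blob centres inside the support sphere.

    Centres are drawn uniformly in the ball of radius ``radius - 2*sigma``
    so every blob stays inside the support; draws that would leave the
    support (possible only when sigma is large) are radially clamped,
    which is the deterministic repositioning rule.
    """
    rng = np.random.default_rng(spec.seed)
    r_in = max(radius - 2.0 * spec.blob_sigma, 0.05 * radius)
    centers = np.empty((spec.n_blobs, 3))
    for i in range(spec.n_blobs):
        v = rng.standard_normal(3)
        v /= max(np.linalg.norm(v), 1e-300)
        r = r_in * rng.random() ** (1.0 / 3.0)
        centers[i] = v * r
    return centers


def _render_blobs(centers: np.ndarray, sigma: float, N: int, voxel: float,
                  radius: float) -> DensityModel:
    x = (np.arange(N) - N // 2) * voxel
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    rho = np.zeros((N, N, N))
    for c in centers:
        d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        rho += np.exp(-d2 / (2.0 * sigma**2))
    mask = xx**2 + yy**2 + zz**2 <= radius**2
    rho[~mask] = 0.0
    return DensityModel(rho=rho, voxel=voxel, support_mask=mask)


def make_phantom(spec: PhantomSpec, N: int, voxel: float
                 ) -> DensityModel | tuple[DensityModel, DensityModel]:
    """Build the phantom density (or a conformation pair) on an N^3 grid.

    The support is the sphere of radius ``N * voxel / 4`` so that an
    oversampling factor of 2 leaves the autocorrelation fully contained
    in the grid.
    """
    if N < 8:
        raise ParameterError(f"N must be >= 8, got {N}")
    if voxel <= 0:
        raise ParameterError("voxel must be positive")
    radius = N * voxel / 4.0
    if spec.blob_sigma > radius:
        raise ParameterError("blob_sigma exceeds the support radius")
    centers = _blob_centers(spec, radius)
    model_a = _render_blobs(centers, spec.blob_sigma, N, voxel, radius)
    if spec.kind == "blobs":
        return model_a
    # two_conformations: displace blob 0 along a seeded direction
    rng = np.random.default_rng(spec.seed + 1)
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    centers_b = centers.copy()
    centers_b[0] = centers_b[0] + direction * spec.conformation_shift
    r_max = max(radius - 2.0 * spec.blob_sigma, 0.05 * radius)
    norm = np.linalg.norm(centers_b[0])
    if norm > r_max:                       # deterministic radial clamp
        centers_b[0] *= r_max / norm
    model_b = _render_blobs(centers_b, spec.blob_sigma, N, voxel, radius)
    return model_a, model_b


# ---------------------------------------------------------------------------
# ground-truth volumes
# ---------------------------------------------------------------------------

def _pad_centered(rho: np.ndarray, M: int) -> np.ndarray:
    N = rho.shape[0]
    out = np.zeros((M, M, M))
    lo = M // 2 - N // 2
    out[lo:lo + N, lo:lo + N, lo:lo + N] = rho
    return out


def intensity_from_density(rho: np.ndarray, voxel: float) -> FourierVolume:
    """|G|^2 of a (possibly already padded) density on its own grid size."""
    M = rho.shape[0]
    G = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(rho))) * voxel**3
    vol = FourierVolume(values=np.abs(G) ** 2, voxel_q=1.0 / (M * voxel), role="intensity")
    return vol


def density_to_intensity(model: DensityModel, oversample: int = 2) -> FourierVolume:
    """Oversampled intensity volume |G|^2 on a centred reciprocal grid.

    The density is zero-padded to side ``oversample * N``; the result's
    ``voxel_q`` is ``1 / (oversample * N * voxel)``.  Oversampling >= 2
    is required so the autocorrelation (support twice the density's) is
    representable and phasing is feasible.
    """
    if oversample < 2:
        raise ParameterError(f"oversample must be >= 2 for phasing, got {oversample}")
    pad = _pad_centered(model.rho, oversample * model.N)
    return intensity_from_density(pad, model.voxel)


def exact_autocorrelation(model: DensityModel, oversample: int = 2) -> FourierVolume:
    """Ground-truth autocorrelation: inverse FT of the intensity volume.

    Real to numerical precision; its central value equals
    ``sum(rho^2) * voxel^3``.
    """
    inten = density_to_intensity(model, oversample)
    ac = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(inten.values))) / model.voxel**3
    scale = np.abs(ac).max() or 1.0
    if np.abs(ac.imag).max() > 1e-8 * scale:
        raise ParameterError("autocorrelation has unexpected imaginary part")
    return FourierVolume(values=ac.real, voxel_q=inten.voxel_q, role="autocorrelation")


# ---------------------------------------------------------------------------
# pattern simulation
# ---------------------------------------------------------------------------

def _slice_intensity_nufft(rho: np.ndarray, voxel: float, points: np.ndarray,
                           eps: float) -> np.ndarray:
    """Exact-model slice: |NUFFT(rho)|^2 * voxel^6 at the given points."""
    G = nufft_type2(rho.astype(complex), voxel, points, eps=eps) * voxel**3
    return np.abs(G) ** 2


def design_geometry(N: int, voxel: float, n_pixels: int = 64,
                    q_max_factor: float = 0.9,
                    wavelength: float = 1e-10,
                    pixel_size: float = 100e-6) -> DetectorGeometry:
    """Detector whose corner reaches ``q_max_factor`` of the density Nyquist.

    Chooses the sample-detector distance so that the corner pixel sits
    at ``q = q_max_factor / (2 * voxel)``; this keeps every rotated
    Ewald point inside the NUFFT band limit while using the full grid
    resolution.
    """
    if not (0 < q_max_factor < 1):
        raise ParameterError("q_max_factor must be in (0, 1)")
    q_target = q_max_factor / (2.0 * voxel)
    s = q_target * wavelength
    if s > 2.0 / np.sqrt(2.0):
        raise ParameterError("requested q_max not reachable at this wavelength")
    theta = 2.0 * np.arcsin(s / 2.0)
    r_corner = (n_pixels - 1) / 2.0 * np.sqrt(2.0) * pixel_size
    distance = r_corner / np.tan(theta)
    return DetectorGeometry(
        n_fast=n_pixels, n_slow=n_pixels, pixel_size=pixel_size,
        distance=distance, wavelength=wavelength,
    )


def fluence_for_mean_photons(model: DensityModel, geom: DetectorGeometry,
                             mean_photons: float, n_probe: int = 16,
                             seed: int = 1234, eps: float = 1e-6) -> float:
    """Fluence value giving ~``mean_photons`` expected photons/pattern.

    Probes ``n_probe`` random orientations and averages the total
    noiseless slice intensity.
    """
    from .geometry import random_orientations  # local import avoids cycle at module load
    qgrid = pixel_to_q(geom)
    quats = random_orientations(n_probe, seed)
    total = 0.0
    for q in quats:
        pts = qgrid.flat @ quat_to_matrix(q).T
        total += _slice_intensity_nufft(model.rho, model.voxel, pts, eps).sum()
    mean_total = total / n_probe
    if mean_total <= 0:
        raise ParameterError("model scatters no intensity onto the detector")
    return mean_photons / mean_total


def simulate_patterns(models: DensityModel | list[DensityModel],
                      geom: DetectorGeometry,
                      orientations: np.ndarray,
                      conformation_ids: np.ndarray | None,
                      noise: NoiseSpec,
                      eps: float = 1e-6,
                      chunk: int = 1_000_000) -> PatternStack:
    """Render a stack of oriented, noisy diffraction patterns.

    For each image the detector q-grid is rotated by the image's
    orientation, the conformation's intensity is evaluated there by a
    type-2 NUFFT of the density (exact model, independent of the
    reconstruction path), scaled by the per-image fluence, shifted by
    the miscentering draw, offset by the static background plane, and
    finally Poisson-sampled.  All randomness derives from ``noise.seed``.
    """
    if isinstance(models, DensityModel):
        models = [models]
    orientations = np.asarray(orientations, dtype=float)
    D = orientations.shape[0]
    if conformation_ids is None:
        conformation_ids = np.zeros(D, dtype=int)
    conformation_ids = np.asarray(conformation_ids, dtype=int)
    if conformation_ids.shape != (D,):
        raise ParameterError("conformation_ids length must match orientations")
    if conformation_ids.min() < 0 or conformation_ids.max() >= len(models):
        raise ParameterError("conformation_ids out of range")

    qgrid = pixel_to_q(geom)
    shape = geom.shape
    P = shape[0] * shape[1]

    # static background plane, validated nonnegative over the detector
    b0, bf, bs = noise.background_slope
    jf = np.arange(geom.n_fast, dtype=float)
    isl = np.arange(geom.n_slow, dtype=float)
    background = b0 + bf * jf[None, :] + bs * isl[:, None]
    if background.min() < 0:
        raise ParameterError("background plane is negative over the detector")

    rng = np.random.default_rng(noise.seed)
    # draw order is fixed: fluence, miscenter shifts, then Poisson
    if noise.fluence_jitter_cv > 0:
        sig2 = np.log1p(noise.fluence_jitter_cv**2)
        mu = np.log(max(noise.fluence_mean, 1e-300)) - sig2 / 2.0
        fluence = rng.lognormal(mean=mu, sigma=np.sqrt(sig2), size=D)
    else:
        fluence = np.full(D, float(noise.fluence_mean))
    if noise.miscenter_sigma > 0:
        shifts = np.rint(rng.normal(0.0, noise.miscenter_sigma, size=(D, 2))).astype(int)
    else:
        shifts = np.zeros((D, 2), dtype=int)

    mats = quat_to_matrix(orientations)
    expected = np.empty((D, P))
    for k, model in enumerate(models):
        idx = np.where(conformation_ids == k)[0]
        if idx.size == 0:
            continue
        # evaluate slices in chunks of whole images
        imgs_per_chunk = max(1, chunk // P)
        for lo in range(0, idx.size, imgs_per_chunk):
            sel = idx[lo:lo + imgs_per_chunk]
            pts = np.einsum("dij,pj->dpi", mats[sel], qgrid.flat).reshape(-1, 3)
            vals = _slice_intensity_nufft(model.rho, model.voxel, pts, eps)
            expected[sel] = vals.reshape(len(sel), P)

    expected *= fluence[:, None]
    expected = expected.reshape(D, *shape)
    for i in range(D):
        if shifts[i, 0] or shifts[i, 1]:
            expected[i] = np.roll(expected[i], (shifts[i, 1], shifts[i, 0]), axis=(0, 1))
    expected += background[None, :, :]
    if expected.min() < 0:
        raise ParameterError("negative expected counts after background")

    if noise.poisson:
        images = rng.poisson(expected).astype(np.int64)
    else:
        images = expected
    return PatternStack(
        images=images,
        fluence=fluence,
        true_orientations=orientations.copy(),
        true_conformations=conformation_ids.copy(),
    )
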
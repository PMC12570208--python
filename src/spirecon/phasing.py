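"""Iterative phase retrieval: recover a real, nonnegative, compactly
supported density from an oversampled intensity volume.

The classic alternating-projection family is used: error reduction (ER)
and hybrid input-output (HIO), optionally with shrinkwrap support
refinement.  The Fourier-modulus projection replaces each Fourier
amplitude by ``sqrt(intensity)`` keeping the phase; the object
projection enforces the support mask and nonnegativity.  Phase
retrieval is invariant to translation and centro-inversion, so
recovered densities are scored with :func:`align_densities`, which
searches both gauges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import NumericalError, ParameterError
from .nufft import FourierVolume, friedel_symmetrize
from .simulate import DensityModel

__all__ = [
    "PhasingConfig",
    "PhasingResult",
    "phase_retrieve",
    "align_densities",
    "apply_alignment",
]


@dataclass(frozen=True)
class PhasingConfig:
    """Schedule and support strategy for phase retrieval.

    ``schedule`` is a list of ``(method, iterations, beta)`` stages with
    method in {"error_reduction", "hybrid_input_output"}; beta is only
    used by HIO.  ``support`` is ``("fixed_sphere", radius_voxels)`` or
    ``("shrinkwrap", sigma_voxels, threshold, interval)``; shrinkwrap
    starts from a sphere of a quarter of the grid side.  ``n_starts``
    random-phase restarts are run and the best final Fourier error kept.
    """

    schedule: tuple = (("hybrid_input_output", 200, 0.9), ("error_reduction", 50, 0.0))
    support: tuple = ("shrinkwrap", 1.5, 0.12, 20)
    seed: int = 0
    n_starts: int = 4
    recenter_interval: int = 20

    def __post_init__(self) -> None:
        for method, iters, beta in self.schedule:
            if method not in ("error_reduction", "hybrid_input_output"):
                raise ParameterError(f"unknown phasing method {method!r}")
            if iters < 1:
                raise ParameterError("each stage needs >= 1 iteration")
            if method == "hybrid_input_output" and not (0 < beta < 1.5):
                raise ParameterError(f"HIO beta must be in (0, 1.5), got {beta}")
        if self.support[0] not in ("fixed_sphere", "shrinkwrap"):
            raise ParameterError(f"unknown support mode {self.support[0]!r}")
        if self.n_starts < 1:
            raise ParameterError("n_starts must be >= 1")


@dataclass
class PhasingResult:
    """Final density, per-iteration Fourier error, and support fraction."""

    density: DensityModel
    fourier_error: np.ndarray
    support_fraction: float


def _sphere_mask(M: int, radius: float) -> np.ndarray:
    x = np.arange(M) - M // 2
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= radius**2


def _fft(rho: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(rho)))


def _ifft(G: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(G)))


def _recenter(rho: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cyclically shift so the density's centre of mass sits at the grid centre.

    Works on the circular mean (phase of the first Fourier moment along
    each axis), which is well-defined for wrapped densities.
    """
    M = rho.shape[0]
    w = np.maximum(rho, 0.0)
    tot = w.sum()
    if tot <= 0:
        return rho, mask
    shift = []
    for ax in range(3):
        prof = w.sum(axis=tuple(a for a in range(3) if a != ax))
        ang = np.angle(np.sum(prof * np.exp(2j * np.pi * np.arange(M) / M)))
        com = (ang / (2 * np.pi) * M) % M
        shift.append(int(np.rint(M // 2 - com)) % M)
    rho = np.roll(rho, shift, axis=(0, 1, 2))
    mask = np.roll(mask, shift, axis=(0, 1, 2))
    return rho, mask


def _project_object(rho: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.where(mask, np.maximum(rho, 0.0), 0.0)
    return out


def _run_schedule(amp: np.ndarray, cfg: PhasingConfig, rho0: np.ndarray,
                  mask0: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[float]]:
    amp_norm = np.linalg.norm(amp)
    rho = rho0
    mask = mask0.copy()
    errors: list[float] = []
    sw = cfg.support[0] == "shrinkwrap"
    it_total = 0
    for method, iters, beta in cfg.schedule:
        for _ in range(iters):
            it_total += 1
            G = _fft(rho)
            cur = np.abs(G)
            err = (np.linalg.norm(cur - amp) / amp_norm) if amp_norm > 0 else 0.0
            if not np.isfinite(err):
                raise NumericalError(f"non-finite Fourier error at iteration {it_total}")
            errors.append(float(err))
            phase = np.where(cur > 0, G / np.maximum(cur, 1e-300), 1.0)
            rho_m = _ifft(amp * phase).real
            if method == "error_reduction":
                rho = _project_object(rho_m, mask)
            else:
                good = mask & (rho_m >= 0)
                rho = np.where(good, rho_m, rho - beta * rho_m)
            if sw and it_total % cfg.support[3] == 0:
                blur = gaussian_filter(np.maximum(rho, 0.0), cfg.support[1])
                new_mask = blur > cfg.support[2] * blur.max()
                if new_mask.any():
                    mask = new_mask
            if cfg.recenter_interval and it_total % cfg.recenter_interval == 0:
                rho, mask = _recenter(rho, mask)
    rho = _project_object(rho, mask)
    G = _fft(rho)
    errors.append(float(np.linalg.norm(np.abs(G) - amp) / amp_norm) if amp_norm > 0 else 0.0)
    return rho, mask, errors


def phase_retrieve(intensity: FourierVolume, cfg: PhasingConfig,
                   oversample: int = 2,
                   initial_density: np.ndarray | None = None) -> PhasingResult:
    """Alternating-projection phase retrieval on an intensity volume.

    The intensity is Friedel-symmetrized and clipped nonnegative before
    the square root.  Random initial phases come from ``cfg.seed``; with
    ``initial_density`` given, a single deterministic start from that
    density is run instead (used by fixed-point tests and warm restarts
    of the reconstruction loop).
    """
    if oversample < 2:
        raise ParameterError(f"intensity must be oversampled >= 2, got {oversample}")
    vals = np.asarray(intensity.values)
    if np.iscomplexobj(vals):
        raise ParameterError("intensity volume must be real")
    M = vals.shape[0]
    voxel = 1.0 / (M * intensity.voxel_q)
    # divide out the Riemann voxel^3 factor of G = FFT(rho) * voxel^3 so the
    # recovered density is in the same units as the model density
    amp = np.sqrt(np.clip(friedel_symmetrize(vals), 0.0, None)) / voxel**3

    if cfg.support[0] == "fixed_sphere":
        mask0 = _sphere_mask(M, cfg.support[1])
    else:
        mask0 = _sphere_mask(M, M / 4.0)

    if amp.max() == 0.0:
        zero = np.zeros((M, M, M))
        return PhasingResult(
            density=DensityModel(rho=zero, voxel=voxel),
            fourier_error=np.zeros(1),
            support_fraction=0.0,
        )

    starts: list[np.ndarray] = []
    if initial_density is not None:
        starts.append(np.asarray(initial_density, dtype=float))
    else:
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.n_starts):
            phases = np.exp(2j * np.pi * rng.random((M, M, M)))
            starts.append(_project_object(_ifft(amp * phases).real, mask0))

    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for rho0 in starts:
        rho, mask, errors = _run_schedule(amp, cfg, rho0, mask0)
        if best is None or errors[-1] < best[2][-1]:
            best = (rho, mask, errors)
    rho, mask, errors = best
    return PhasingResult(
        density=DensityModel(rho=rho, voxel=voxel, support_mask=mask | (rho > 0)),
        fourier_error=np.asarray(errors),
        support_fraction=float(mask.mean()),
    )


def align_densities(a: DensityModel | np.ndarray, b: DensityModel | np.ndarray
                    ) -> tuple[float, tuple[int, int, int], bool]:
    """Best normalized cross-correlation of ``b`` against ``a`` over the
    phase-retrieval gauge group: all cyclic translations and the
    centro-inversion twin.

    Returns ``(correlation, shift, inverted)`` where applying
    ``np.roll(b', shift)`` (with ``b'`` optionally inverted) best
    matches ``a``.  Correlation is the Pearson coefficient over the
    whole volume.
    """
    ra = a.rho if isinstance(a, DensityModel) else np.asarray(a, dtype=float)
    rb = b.rho if isinstance(b, DensityModel) else np.asarray(b, dtype=float)
    if ra.shape != rb.shape:
        raise ParameterError(f"shape mismatch {ra.shape} vs {rb.shape}")
    a0 = ra - ra.mean()
    b0 = rb - rb.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0 or nb == 0:
        raise ParameterError("zero-variance input to align_densities")
    Fa = np.fft.fftn(a0)
    best = (-np.inf, (0, 0, 0), False)
    for inverted in (False, True):
        bb = b0[::-1, ::-1, ::-1] if inverted else b0
        # corr(s) = sum_x a0(x) bb(x - s): cross-correlation via FFT
        cc = np.fft.ifftn(Fa * np.conj(np.fft.fftn(bb))).real
        idx = np.unravel_index(np.argmax(cc), cc.shape)
        val = cc[idx] / (na * nb)
        if val > best[0]:
            best = (float(val), tuple(int(i) for i in idx), inverted)
    corr, shift, inverted = best
    return corr, shift, inverted


def apply_alignment(b: np.ndarray, shift: tuple[int, int, int], inverted: bool) -> np.ndarray:
    """Transform ``b`` by the gauge parameters returned by align_densities."""
    bb = b[::-1, ::-1, ::-1] if inverted else b
    return np.roll(bb, shift, axis=(0, 1, 2))
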
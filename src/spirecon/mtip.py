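"""The multi-tiered iterative reconstruction loop.

Each *generation* runs the three subproblems in sequence: reference
slices are generated from the current autocorrelation estimate of every
conformation, each pattern is (re)assigned the best (orientation,
conformation) pair, the oriented samples of each conformation are
merged into a new autocorrelation by the regularized Krylov solver, and
the merged intensity is phased back to a density.  Generation 0 is the
randomized first pass: orientations are drawn at random from the
reference grid, conformations uniformly at random, and the merge runs
once to produce the initial autocorrelation that the second pass aligns
against.

Two empirically load-bearing choices (see docs/methods.md for the full
measurements):

* Reference slices come from the *merged autocorrelation* — the current
  estimate of the intensity's Fourier pair — rather than from the
  re-phased density.  The support projection in phasing erases exactly
  the anisotropy that orientation matching needs, which stalls the loop
  from a cold start and destabilizes it later.
* Per-image scales are frozen at the start of the run (proportional to
  each image's total photon count) and the matching metric uses uniform
  pixel weights.  Refitting a free scale for every (image, slice) pair,
  or down-weighting bright pixels by inverse counts, lets over-fitted
  reference slices attract arbitrarily many images, and the hard-argmin
  assignment then collapses onto a shrinking orientation subset.

Images are held in memory for the whole run.  Because assignments are
hard argmins, patterns sharing an orientation are averaged (after scale
normalization) and enter the least squares with a weight equal to their
count — algebraically identical to merging every pattern individually,
with the NUFFT point count bounded by ``n_ref * n_pixels``.

The state with the lowest summed matching distance seen during the run
is returned (the loop is heuristic and not monotone; keeping the
best-fit iterate mirrors the "best solution in terms of fit to the
data" selection used inside the merge sweep).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .geometry import DetectorGeometry, pixel_to_q, quat_to_matrix, reference_grid
from .nufft import FourierVolume, NonuniformSamples
from .merging import MergeSolution, hyperparameter_sweep
from .phasing import PhasingConfig, align_densities, apply_alignment, phase_retrieve
from .simulate import DensityModel, PatternStack
from .slicing_matching import compute_slices, match_orientations

__all__ = ["MtipConfig", "ReconstructionState", "run_mtip", "check_convergence"]


@dataclass(frozen=True)
class MtipConfig:
    """Parameters of the reconstruction loop.

    ``n_ref`` reference orientations (quasi-uniform covering by
    default), ``n_conformations`` density models, a merge lambda sweep
    expressed relative to the Toeplitz zero lag (the total sample
    weight), and the phasing schedule.  ``sweep_generations`` controls
    how long the full lambda grid is swept; afterwards the selected
    lambda is reused.  ``scale_mode`` fixes how per-image scales are
    obtained: ``"constant"`` (default; unit scale, appropriate without
    fluence jitter and preserves the total-counts discrimination
    channel), ``"totals"`` (frozen, proportional to total counts, for
    jittered beams), ``"known"`` (the stack's recorded fluence), or
    ``"fitted"`` (free per-pair scale — unstable with hard assignment,
    kept for comparison experiments).

    With ``n_conformations > 1`` the loop is staged: all images share
    one pooled model for ``split_generation`` generations (so the
    orientation gauge settles), then conformations are seeded by a
    random balanced split and refined jointly; each later generation
    picks orientations per conformation with the stable weighted-L2
    metric and decides the conformation by the Poisson likelihood at
    those orientations (the optimal few-hypothesis statistic, safe
    here because it does not drive the orientation search).

    Whether a random split amplifies into distinct models depends on
    how well it happens to project onto the true heterogeneity axis,
    so ``n_split_tries`` seeded splits are each probed for
    ``split_probe_generations`` joint generations and the split whose
    two models diverge most (lowest inter-model autocorrelation
    correlation — no ground truth involved) is kept.  Probe
    generations are internal and do not count toward
    ``n_generations_max``.
    """

    n_generations_max: int = 20
    n_ref: int = 800
    n_conformations: int = 1
    split_generation: int = 3
    n_split_tries: int = 3
    split_probe_generations: int = 2
    metric: str = "weighted_l2"
    weight_mode: str = "uniform"
    scale_mode: str = "constant"
    ref_scheme: str = "quasi_uniform"
    grid_side: int = 64
    lambdas_rel: tuple = (1e-8, 1e-6, 1e-4)
    sweep_generations: int = 1
    merge_tol: float = 1e-3
    merge_max_iter: int = 50
    phasing: PhasingConfig = PhasingConfig(
        schedule=(("hybrid_input_output", 60, 0.9), ("error_reduction", 20, 0.0)),
        support=("shrinkwrap", 1.5, 0.12, 20),
        n_starts=2,
    )
    final_phasing: PhasingConfig = PhasingConfig(
        schedule=(("hybrid_input_output", 200, 0.9), ("error_reduction", 50, 0.0)),
        support=("shrinkwrap", 1.5, 0.12, 20),
        n_starts=4,
    )
    convergence_tol: float = 5e-3
    stop_on_convergence: bool = True
    phasing_warm_start: bool = True
    nufft_eps: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformations < 1 or self.n_generations_max < 1:
            raise ParameterError("K and n_generations_max must be >= 1")
        if not self.convergence_tol > 0:
            raise ParameterError("convergence_tol must be positive")
        if self.scale_mode not in ("constant", "totals", "known", "fitted"):
            raise ParameterError(f"unknown scale_mode {self.scale_mode!r}")


@dataclass
class ReconstructionState:
    """Current models, per-image assignments, and per-generation history."""

    densities: list                       # K DensityModel on the grid_side cube
    orientation_index: np.ndarray         # (D,)
    conformation_index: np.ndarray        # (D,)
    scale: np.ndarray                     # (D,) per-image scale used
    reference_orientations: np.ndarray    # (n_ref, 4)
    generation: int = 0
    converged: bool = False
    best_generation: int = 0
    best_misfit: float = np.inf
    history: list = field(default_factory=list)

    def assigned_quaternions(self) -> np.ndarray:
        return self.reference_orientations[self.orientation_index]


def check_convergence(state: ReconstructionState, tol: float) -> bool:
    """True when the latest aligned relative density change is below tol.

    The comparison is strict (a change exactly at ``tol`` does not
    converge).  Requires at least one completed generation.
    """
    if state.generation < 1 or not state.history:
        raise ParameterError("convergence is defined from generation 1 on")
    changes = state.history[-1]["density_change"]
    return bool(max(changes) < tol)


def _density_change(prev: DensityModel, new: DensityModel) -> float:
    """Gauge-fixed relative L2 change between consecutive estimates."""
    nrm = np.linalg.norm(new.rho)
    if nrm == 0 or np.linalg.norm(prev.rho) == 0:
        return 0.0 if nrm == np.linalg.norm(prev.rho) else np.inf
    _, shift, inv = align_densities(new.rho, prev.rho)
    prev_aligned = apply_alignment(prev.rho, shift, inv)
    return float(np.linalg.norm(new.rho - prev_aligned) / nrm)


def _merge_conformation(stack, qgrid, ref_quats, orient_idx, conf_idx, scale, k,
                        cfg, lambdas_rel, ac_voxel) -> MergeSolution:
    """Group one conformation's images by orientation and run the sweep."""
    sel = np.where(conf_idx == k)[0]
    if sel.size == 0:
        raise ParameterError(f"conformation {k} has no assigned images")
    P = qgrid.flat.shape[0]
    imgs = stack.images.reshape(stack.D, -1)
    uniq = np.unique(orient_idx[sel])
    pts = np.empty((uniq.size * P, 3))
    vals = np.empty(uniq.size * P)
    wts = np.empty(uniq.size * P)
    for n, o in enumerate(uniq):
        members = sel[orient_idx[sel] == o]
        norm = imgs[members] / np.maximum(scale[members, None], 1e-300)
        pts[n * P:(n + 1) * P] = qgrid.flat @ quat_to_matrix(ref_quats[o]).T
        vals[n * P:(n + 1) * P] = norm.mean(axis=0) / ac_voxel**3
        wts[n * P:(n + 1) * P] = members.size
    samples = NonuniformSamples(points=pts, values=vals, weights=wts)
    total_w = float(wts.sum())
    lambdas = [r * total_w for r in lambdas_rel]
    return hyperparameter_sweep(
        samples, cfg.grid_side, lambdas, ac_voxel,
        tol=cfg.merge_tol, max_iter=cfg.merge_max_iter, eps=cfg.nufft_eps,
    )


def _phase(sol: MergeSolution, cfg: MtipConfig, seed: int,
           warm: DensityModel | None = None) -> DensityModel:
    """Phase a merged autocorrelation back to a density estimate."""
    ac = sol.autocorrelation
    inten = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(ac.values))).real * ac.ac_voxel**3
    vol = FourierVolume(values=np.clip(inten, 0.0, None), voxel_q=ac.voxel_q,
                        role="intensity")
    pcfg = dataclasses.replace(cfg.phasing, seed=seed)
    res = phase_retrieve(vol, pcfg,
                         initial_density=None if warm is None else warm.rho)
    return res.density


def _reseed_empty(conf_idx, orient_idx, distance, K, log=None):
    """Give an emptied conformation the worst-matching half of the largest one."""
    for k in range(K):
        if np.any(conf_idx == k):
            continue
        counts = np.bincount(conf_idx, minlength=K)
        donor = int(np.argmax(counts))
        members = np.where(conf_idx == donor)[0]
        worst = members[np.argsort(distance[members])[::-1]]
        take = worst[: max(1, members.size // 2)]
        conf_idx[take] = k
        if log is not None:
            log.record(0, f"reseed_conformation_{k}_from_{donor}", -1)
    return conf_idx


def _image_scales(stack: PatternStack, cfg: MtipConfig) -> np.ndarray:
    if cfg.scale_mode == "known":
        return np.maximum(stack.fluence.astype(float), 1e-300)
    if cfg.scale_mode in ("constant", "fitted"):
        return np.ones(stack.D)
    totals = stack.images.reshape(stack.D, -1).sum(axis=1).astype(float)
    return np.maximum(totals / max(totals.mean(), 1e-300), 1e-300)


def _match_joint(match_stack, refs, cfg, fitted):
    """Joint (orientation, conformation) assignment for K > 1.

    Orientations are selected per conformation with the stable
    weighted-L2 metric; the conformation decision is then made by the
    Poisson negative log-likelihood evaluated only at each
    conformation's chosen orientation (a K-hypothesis test where the
    exact likelihood is the right statistic, and which cannot perturb
    the orientation search).
    """
    D = match_stack.D
    K = len(refs)
    images = match_stack.images.reshape(D, -1).astype(float)
    s = np.maximum(match_stack.fluence.astype(float), 1e-300)
    per_conf = [match_orientations(match_stack, [r], metric="weighted_l2",
                                   weight_mode=cfg.weight_mode, fit_scale=fitted)
                for r in refs]
    nll = np.empty((D, K))
    for k, (r, m) in enumerate(zip(refs, per_conf)):
        R = r.slices.reshape(r.n_ref, -1)[m.orientation_index]       # (D, P)
        sc = m.scale if fitted else s
        nll[:, k] = (sc * R.sum(axis=1)
                     - images.sum(axis=1) * np.log(sc)
                     - np.einsum("dp,dp->d", images, np.log(R + 1e-12)))
    ci = np.argmin(nll, axis=1)
    oi = np.stack([m.orientation_index for m in per_conf], axis=1)[np.arange(D), ci]
    dist = np.stack([m.distance for m in per_conf], axis=1)[np.arange(D), ci]
    scl = np.stack([m.scale for m in per_conf], axis=1)[np.arange(D), ci]
    return oi, ci, dist, scl


def _ac_divergence(sols) -> float:
    """Mean pairwise (1 - Pearson) between merged autocorrelations."""
    vols = [s.autocorrelation.values for s in sols]
    divs = []
    for i in range(len(vols)):
        for j in range(i + 1, len(vols)):
            a = vols[i] - vols[i].mean()
            b = vols[j] - vols[j].mean()
            den = np.linalg.norm(a) * np.linalg.norm(b)
            divs.append(1.0 - float((a * b).sum() / den) if den > 0 else 0.0)
    return float(np.mean(divs)) if divs else 0.0


def _select_split(stack, match_stack, qgrid, ref_quats, orient_idx, scale,
                  cfg, ac_voxel, fitted, log=None):
    """Choose the conformation split whose models diverge fastest.

    Each seeded balanced split is evolved for a few probe generations;
    the split with the largest inter-model autocorrelation divergence
    (a ground-truth-free signal that symmetry breaking took hold) wins.
    Returns the winner's (orientations, labels, merge solutions).
    """
    K = cfg.n_conformations
    D = stack.D
    lam_list = [sorted(cfg.lambdas_rel)[len(cfg.lambdas_rel) // 2]]
    best = None
    for t in range(max(1, cfg.n_split_tries)):
        ci = np.random.default_rng(cfg.seed + 500_017 + t).integers(0, K, size=D)
        oi = orient_idx.copy()
        try:
            sols = [_merge_conformation(stack, qgrid, ref_quats, oi, ci, scale,
                                        k, cfg, lam_list, ac_voxel)
                    for k in range(K)]
            for _ in range(max(0, cfg.split_probe_generations)):
                refs = [compute_slices(s.autocorrelation, ref_quats, qgrid,
                                       eps=cfg.nufft_eps) for s in sols]
                oi, ci, dist, _scl = _match_joint(match_stack, refs, cfg, fitted)
                ci = _reseed_empty(ci, oi, dist, K, log)
                sols = [_merge_conformation(stack, qgrid, ref_quats, oi, ci, scale,
                                            k, cfg, lam_list, ac_voxel)
                        for k in range(K)]
        except ParameterError:
            continue
        div = _ac_divergence(sols)
        if log is not None:
            log.record(t, f"split_probe_div_{div:.2e}", -1)
        if best is None or div > best[0]:
            best = (div, oi, ci, sols)
    if best is None:
        raise ParameterError("every conformation split attempt failed")
    return best[1], best[2], best[3]


def run_mtip(stack: PatternStack, geom: DetectorGeometry, cfg: MtipConfig,
             log=None, checkpoint_dir=None) -> ReconstructionState:
    """Run the full reconstruction loop on a pattern stack.

    Returns the final state with one density estimate per conformation
    (on the oversampled ``grid_side`` cube), hard per-image assignments,
    and a per-generation history of summed matching distance, aligned
    density change, and per-conformation image counts.  The returned
    densities come from re-phasing the best-fit generation's merged
    autocorrelations with the (stronger) ``final_phasing`` schedule.
    Deterministic for a fixed config and stack.
    """
    D = stack.D
    K = cfg.n_conformations
    qgrid = pixel_to_q(geom)
    # AC grid spacing chosen so the detector corner sits just inside the
    # NUFFT band limit for any rotation
    ac_voxel = 0.5 / qgrid.q_max * 0.999
    ref_quats = reference_grid(cfg.n_ref, cfg.ref_scheme)
    staged = K > 1
    split_gen = min(cfg.split_generation, cfg.n_generations_max) if staged else 0

    rng = np.random.default_rng(cfg.seed)
    orient_idx = rng.integers(0, cfg.n_ref, size=D)
    conf_idx = np.zeros(D, dtype=int)
    scale = _image_scales(stack, cfg)
    fitted = cfg.scale_mode == "fitted"
    # matching sees the per-image scales as the known fluence
    match_stack = stack if fitted else dataclasses.replace(stack, fluence=scale)

    if log is not None:
        log.record(0, "init", 0)

    # generation 0: randomized first pass, one pooled model
    sol = _merge_conformation(stack, qgrid, ref_quats, orient_idx, conf_idx,
                              scale, 0, cfg, cfg.lambdas_rel, ac_voxel)
    merge_sols = [sol]
    if log is not None:
        log.record(0, "merge", 0)
    densities = [_phase(sol, cfg, cfg.seed * 1000)]
    selected_lambdas = [sol.lambda_used / max(float(D * qgrid.flat.shape[0]), 1e-300)] * K
    if log is not None:
        log.record(0, "phase", 0)

    state = ReconstructionState(
        densities=densities,
        orientation_index=orient_idx,
        conformation_index=conf_idx,
        scale=scale,
        reference_orientations=ref_quats,
        generation=0,
    )
    best = {"misfit": np.inf, "merge_sols": merge_sols, "generation": 0}

    lambdas_rel = list(cfg.lambdas_rel)
    for gen in range(1, cfg.n_generations_max + 1):
        pooled = staged and gen <= split_gen
        refs = []
        for k, ms in enumerate(merge_sols):
            r = compute_slices(ms.autocorrelation, ref_quats, qgrid,
                               eps=cfg.nufft_eps)
            r.generating_model = k
            refs.append(r)
            if log is not None:
                log.record(k, "slice", gen)
        # units note: merge data were counts / (scale * ac_voxel^3) and
        # compute_slices restores the ac_voxel^3 factor, so reference
        # slices are directly in scale-normalized counts

        if len(refs) == 1:
            match = match_orientations(match_stack, refs, metric=cfg.metric,
                                       weight_mode=cfg.weight_mode,
                                       fit_scale=fitted)
            orient_idx = match.orientation_index
            distance = match.distance
            conf_idx = np.zeros(D, dtype=int)
            if fitted:
                scale = np.maximum(match.scale, 1e-300)
        else:
            orient_idx, conf_idx, distance, scl = _match_joint(
                match_stack, refs, cfg, fitted)
            conf_idx = _reseed_empty(conf_idx, orient_idx, distance, K, log)
            if fitted:
                scale = np.maximum(scl, 1e-300)
        if log is not None:
            log.record(0, "match", gen)

        misfit = float(distance.sum())
        # distances score the models that produced these slices (gen-1);
        # within a stage the definition is comparable across generations
        if not pooled and misfit < best["misfit"]:
            best = {"misfit": misfit, "merge_sols": merge_sols, "generation": gen - 1}

        probe_sols = None
        if staged and gen == split_gen:
            # seed the conformations: probed balanced splits, shared orientations
            orient_idx, conf_idx, probe_sols = _select_split(
                stack, match_stack, qgrid, ref_quats, orient_idx, scale,
                cfg, ac_voxel, fitted, log)
            best = {"misfit": np.inf, "merge_sols": merge_sols, "generation": gen}

        n_models = 1 if (staged and gen < split_gen) else K
        gen_lambdas = lambdas_rel if gen <= cfg.sweep_generations else None
        new_sols = []
        new_densities = []
        changes = []
        for k in range(n_models):
            if probe_sols is not None:
                msol = probe_sols[k]   # the winning probe already merged these
            else:
                lam_list = gen_lambdas if gen_lambdas is not None else [selected_lambdas[k]]
                msol = _merge_conformation(stack, qgrid, ref_quats, orient_idx, conf_idx,
                                           scale, k, cfg, lam_list, ac_voxel)
            new_sols.append(msol)
            if log is not None:
                log.record(k, "merge", gen)
            total_w = float(np.sum(conf_idx == k)) * qgrid.flat.shape[0]
            selected_lambdas[k] = msol.lambda_used / max(total_w, 1e-300)
            # warm-starting from the previous density only affects the phased
            # output (slices come from the AC), and makes the density-change
            # convergence metric track model drift instead of phasing restarts
            prev = state.densities[min(k, len(state.densities) - 1)]
            warm = prev if cfg.phasing_warm_start else None
            dens = _phase(msol, cfg, cfg.seed * 1000 + 97 * gen + k, warm=warm)
            if log is not None:
                log.record(k, "phase", gen)
            changes.append(_density_change(prev, dens))
            new_densities.append(dens)

        merge_sols = new_sols
        state.densities = new_densities
        state.orientation_index = orient_idx
        state.conformation_index = conf_idx
        state.scale = scale
        state.generation = gen
        state.history.append({
            "generation": gen,
            "data_misfit": misfit,
            "density_change": changes,
            "conformation_counts": np.bincount(conf_idx, minlength=K).tolist(),
        })
        if checkpoint_dir is not None:
            from .io_cli import save_checkpoint
            save_checkpoint(checkpoint_dir, state)
        if (cfg.stop_on_convergence and gen > split_gen
                and check_convergence(state, cfg.convergence_tol)):
            state.converged = True
            break

    # let the final models compete for best-by-fit
    refs = []
    for k, ms in enumerate(merge_sols):
        r = compute_slices(ms.autocorrelation, ref_quats, qgrid, eps=cfg.nufft_eps)
        r.generating_model = k
        refs.append(r)
    if len(refs) == 1:
        fm = match_orientations(match_stack, refs, metric=cfg.metric,
                                weight_mode=cfg.weight_mode, fit_scale=fitted)
        final_misfit = float(fm.distance.sum())
    else:
        _, _, fdist, _ = _match_joint(match_stack, refs, cfg, fitted)
        final_misfit = float(fdist.sum())
    if final_misfit < best["misfit"]:
        best = {"misfit": final_misfit, "merge_sols": merge_sols,
                "generation": state.generation}

    # strong final phasing of the selected autocorrelations
    fcfg = dataclasses.replace(cfg, phasing=cfg.final_phasing)
    state.densities = [
        _phase(ms, fcfg, cfg.seed * 1000 + 777 + k)
        for k, ms in enumerate(best["merge_sols"])
    ]
    state.best_generation = best["generation"]
    state.best_misfit = best["misfit"]
    return state
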
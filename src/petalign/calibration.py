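"""Maximum-likelihood detector-block alignment calibration.

Given a measured TOF coincidence histogram ``C`` and *known* tracer
distribution ``F`` (plus optional attenuation map and per-crystal
efficiencies), the per-block rigid deviations ``(T, R)`` from the blueprint
are estimated by minimizing the Poisson negative log-likelihood

``NLL(T, R) = sum_bins [ s * L(bin; T, R) - C(bin) * log(s * L(bin; T, R)) ]``

with the expected rates ``L`` of :mod:`petalign.forward_model` and a
global scale ``s`` (``s* = sum(C)/sum(L)`` at the optimum) absorbing the
arbitrary normalization of raw-count efficiencies.  The sum over bins is
estimated by weighted batches: histogram-support bins contribute both
Poisson terms exactly, while the rate mass of the empty bins is estimated
by TOF-marginalized crystal-pair strata evaluated against a blurred copy
of the activity.  During optimization the scale is tracked with strong
damping (never profiled against the batch being minimized) and the log
terms carry a small additive background relative to the median counted
rate — see the function docstrings and docs/methods.md for why each of
these choices is load-bearing.

Optimization is a short Adam phase (separate learning rates for
translations in mm and rotations in degrees, coarse-to-fine activity
blurring) followed by a deterministic L-BFGS polish ladder with
rejection-averaged final repetitions.

The public surface follows the estimator/results idiom:
:class:`DetectorAlignmentModel` holds the data and scanner description,
``fit`` runs the optimization and returns :class:`AlignmentResults`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .events import CoincidenceHistogram
from .forward_model import EfficiencyTable, default_n_quad
from .geometry import (
    AlignmentParams,
    BlueprintGeometry,
    CrystalLUT,
    apply_alignment,
    euler_matrix,
    euler_matrix_derivatives,
)
from .grid import VoxelGrid
from .tof import TOFModel

__all__ = [
    "OptimizerConfig",
    "BinBatch",
    "sample_batch",
    "nll_objective",
    "calibrate",
    "DetectorAlignmentModel",
    "AlignmentResults",
    "CalibrationResult",
]


@dataclass
class OptimizerConfig:
    """Stochastic-optimization settings.

    The defaults are the reference protocol (200 Adam iterations, batches of
    5e6 bins, 5 in-voxel samples per crystal pair, learning rates 0.1 deg /
    1 mm); desk-scale presets shrink ``batch_size`` and ``iterations``.
    ``zero_bin_fraction`` is the portion of each batch drawn uniformly from
    the (mostly empty) valid-bin space to estimate the ``sum L`` term;
    ``0`` reproduces a support-only objective.  ``lr_schedule`` may be
    ``"constant"`` or ``"cosine"`` (decay to ``lr_floor`` of the initial
    rate), the latter compensating the larger gradient noise of small
    batches.

    ``blur_stages`` enables coarse-to-fine optimization: a sequence of
    ``(iteration_fraction_end, sigma_mm)`` pairs; until the given fraction
    of iterations the likelihood is evaluated against the activity grid
    blurred by an isotropic Gaussian of that sigma.  Blurring widens the
    attraction basin far beyond the sub-millimetre support of sharp
    calibration phantoms (initial misalignments of a few mm would otherwise
    leave most measured bins with vanishing model rates and no gradient);
    the final stage should use ``sigma = 0`` so the estimate sharpens to
    the true model.

    ``polish_iterations > 0`` appends a deterministic refinement: one large
    batch (the full histogram support when it fits ``polish_batch_size``)
    with frozen in-voxel sample offsets defines a smooth deterministic
    objective that L-BFGS-B minimizes once per ``polish_blurs`` stage
    ``(sigma_mm, fit_rotations)``.  Rotations stay frozen during coarse
    stages — at blur widths far above the rotation lever arm they are
    nearly unidentified and would drift along flat directions — and are
    released once the blur is comparable to the crystal pitch.  Parameters
    are box-bounded (``polish_bound_t`` mm / ``polish_bound_r`` degrees).
    This phase removes the stochastic-gradient noise floor that otherwise
    dominates the error at small batch sizes.
    """

    iterations: int = 200
    batch_size: int = 5_000_000
    lr_rotation: float = 0.1
    lr_translation: float = 1.0
    n_crystal_samples: int = 5
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0
    zero_bin_fraction: float = 0.5
    lr_schedule: str = "constant"
    lr_floor: float = 0.05
    samples_per_voxel: float = 2.0
    rate_floor: float = 1e-3
    scale_damping: float = 0.1
    rate_term_blur: float = 1.5
    blur_stages: tuple = ()
    polish_iterations: int = 0
    polish_batch_size: int = 2_000_000
    polish_blurs: tuple = ((2.0, False), (1.0, False), (0.5, True), (0.0, True))
    polish_crystal_samples: int = 4
    polish_bound_t: float = 8.0
    polish_bound_r: float = 8.0
    polish_rot_scale: float = 3.0
    polish_final_reps: int = 1
    polish_newton: int = 0

    def __post_init__(self):
        if self.iterations < 1 or self.batch_size < 1 or self.n_crystal_samples < 1:
            raise ValueError("iterations, batch_size, n_crystal_samples must be >= 1")
        if self.lr_rotation <= 0 or self.lr_translation <= 0:
            raise ValueError("learning rates must be positive")
        if not 0.0 <= self.zero_bin_fraction < 1.0:
            raise ValueError("zero_bin_fraction must be in [0, 1)")


@dataclass
class BinBatch:
    """A weighted batch of coincidence bins.

    ``rate_flag`` marks entries contributing the ``+w*s*L`` term (the
    estimate of the total expected count over all valid bins);
    ``log_flag`` marks entries contributing ``-w*C*log(s*L)``.  With both
    parts the weighted batch objective is an unbiased estimate of the full
    Poisson NLL.
    """

    d1: np.ndarray
    cr1: np.ndarray
    d2: np.ndarray
    cr2: np.ndarray
    t: np.ndarray
    counts: np.ndarray
    weights: np.ndarray
    rate_flag: np.ndarray
    log_flag: np.ndarray
    n_valid_bins: float

    def __len__(self):
        return len(self.d1)


def _all_pairs(n_detectors: int) -> np.ndarray:
    iu = np.triu_indices(n_detectors, k=1)
    return np.stack(iu, axis=1).astype(np.int64)


def sample_batch(
    histogram: CoincidenceHistogram,
    batch_size: int,
    rng: np.random.Generator,
    zero_bin_fraction: float = 0.5,
    pair_list: np.ndarray | None = None,
) -> BinBatch:
    """Draw a weighted bin batch mixing histogram-support and empty bins.

    Support bins are drawn uniformly without replacement (all of them when
    the budget allows, weight 1) and contribute both Poisson terms,
    ``w*(s*L - C*log(s*L))``.  The rate mass of the (astronomically many)
    empty bins is estimated by TOF-marginalized crystal-pair draws
    (``t = -1`` entries evaluate ``sum_t L`` as a plain line integral)
    stratified over the accepted detector pairs, with importance weights
    ``Ncr^2 / n_drawn_per_pair``; marginalizing the TOF axis and
    stratifying the detector pairs reduces the estimator variance by orders
    of magnitude compared to uniform bin draws, at (almost) identical
    expectation — the support's own rate mass is counted exactly through
    the data entries and is double-counted by a stratum draw only with
    vanishing probability.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if histogram.n_bins == 0:
        raise ValueError("empty histogram")
    if pair_list is None:
        pair_list = _all_pairs(histogram.n_detectors)
    ncr = histogram.n_crystals
    ntof = histogram.tof.n_bins
    n_valid = float(len(pair_list)) * float(ncr) ** 2 * float(ntof)

    n_zero = int(round(batch_size * zero_bin_fraction))
    n_data = batch_size - n_zero
    support = histogram.n_bins
    if n_data >= support:
        idx = np.arange(support)
        w_data = 1.0
    else:
        idx = rng.choice(support, size=max(n_data, 1), replace=False)
        w_data = support / len(idx)
    cols = [histogram.d1[idx], histogram.cr1[idx], histogram.d2[idx],
            histogram.cr2[idx], histogram.t[idx]]
    counts = histogram.counts[idx].astype(np.float64)
    weights = np.full(len(idx), w_data)
    # counted bins always carry their own +s*L term exactly: estimating the
    # support's rate mass by sparse uniform draws would let the optimizer
    # inflate rates on counted bins invisibly to the estimator
    rate_flag = np.ones(len(idx), dtype=bool)
    log_flag = np.ones(len(idx), dtype=bool)

    if n_zero > 0:
        per_pair = max(1, n_zero // len(pair_list))
        m = per_pair * len(pair_list)
        zd1 = np.repeat(pair_list[:, 0], per_pair)
        zd2 = np.repeat(pair_list[:, 1], per_pair)
        zcr1 = rng.integers(0, ncr, size=m)
        zcr2 = rng.integers(0, ncr, size=m)
        zt = np.full(m, -1, dtype=np.int64)  # TOF-marginalized entries
        cols = [np.concatenate([c, z]) for c, z in zip(cols, (zd1, zcr1, zd2, zcr2, zt))]
        counts = np.concatenate([counts, np.zeros(m)])
        weights = np.concatenate([weights, np.full(m, float(ncr) ** 2 / per_pair)])
        rate_flag = np.concatenate([rate_flag, np.ones(m, dtype=bool)])
        log_flag = np.concatenate([log_flag, np.zeros(m, dtype=bool)])

    return BinBatch(
        cols[0].astype(np.int64), cols[1].astype(np.int64), cols[2].astype(np.int64),
        cols[3].astype(np.int64), cols[4].astype(np.int64),
        counts, weights, rate_flag, log_flag, n_valid,
    )


def _blurred_activity(activity: VoxelGrid, sigma_mm: float) -> VoxelGrid:
    """Gaussian-blurred (and proportionally coarsened) activity grid.

    Padded so the blurred mass stays inside the box; when the blur width is
    large compared to the voxel size, the result is block-averaged onto a
    coarser grid (~sigma/2.5 spacing) — the field carries no finer detail,
    and line-integral cost scales with the sample count per chord.
    """
    if sigma_mm <= 0:
        return activity
    from scipy.ndimage import gaussian_filter

    pad = np.ceil(3.0 * sigma_mm / activity.spacing).astype(int)
    factor = max(1, int(np.floor(sigma_mm / 1.5 / float(np.min(activity.spacing)))))
    pad = (np.ceil(pad / factor) * factor).astype(int)
    # extend so each dimension is divisible by the coarsening factor
    dims = np.asarray(activity.values.shape) + 2 * pad
    extra = (-dims) % factor
    vals = np.pad(activity.values, [(p, p + e) for p, e in zip(pad, extra)])
    vals = gaussian_filter(vals, sigma=sigma_mm / activity.spacing, mode="constant")
    origin = activity.origin - pad * activity.spacing
    if factor > 1:
        nx, ny, nz = (s // factor for s in vals.shape)
        vals = vals.reshape(nx, factor, ny, factor, nz, factor).mean(axis=(1, 3, 5))
        spacing = activity.spacing * factor
    else:
        spacing = activity.spacing.copy()
    return VoxelGrid(origin, spacing, np.maximum(vals, 0.0))


def _expand_index(share_map, n_detectors):
    if share_map is None:
        return np.arange(n_detectors)
    return np.asarray(share_map, dtype=np.int64)


def nll_objective(
    params: AlignmentParams,
    batch: BinBatch,
    blueprint: BlueprintGeometry,
    lut: CrystalLUT,
    activity: VoxelGrid,
    attenuation: VoxelGrid | None,
    efficiencies: EfficiencyTable,
    tof: TOFModel,
    n_crystal_samples: int = 5,
    rng: np.random.Generator | None = None,
    want_grad: bool = True,
    n_quad: int | None = None,
    rate_floor: float = 0.0,
    fixed_scale: float | None = None,
    want_hessian: bool = False,
    rate_activity: VoxelGrid | None = None,
    rate_n_quad: int | None = None,
):
    """Weighted Poisson NLL of a bin batch and its parameter gradient.

    Returns ``(loss, grad_t, grad_r, scale, profiled_scale)``; the
    gradients are per parameter group (per detector without tying) in
    mm^-1 / degree^-1.  With ``want_hessian`` a sixth element is appended:
    per-group 6x6 Gauss-Newton Hessian blocks over (T, R) — the
    within-block outer-product curvature of the log terms, ignoring
    cross-block coupling (bins couple exactly two blocks).

    With ``fixed_scale=None`` the global scale is profiled on this batch
    (``s* = sum wC / sum wL``) and, by the envelope theorem, contributes no
    gradient terms.  During optimization a *damped* scale (held fixed
    w.r.t. the current batch) is passed instead: profiling against the
    batch's own noisy rate estimate places the estimate inside a logarithm,
    whose concavity would otherwise reward configurations that inflate the
    estimator variance.  ``rate_floor`` is a small additive background (in
    scaled count units) inside the log, keeping the loss finite and smooth
    when a counted bin's model rate vanishes early in optimization.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    nd = blueprint.n_detectors
    idx = _expand_index(params.share_map, nd)
    t_full = params.translations[idx]
    r_full = params.rotations[idx]
    if len(t_full) != nd:
        raise ValueError("params do not cover the geometry")
    origins = blueprint.positions + t_full
    basis = blueprint.basis
    frames = np.empty((nd, 3, 3))
    dframes = np.zeros((nd, 3, 3, 3))
    for d in range(nd):
        frames[d] = basis[d] @ euler_matrix(r_full[d])
        if want_grad:
            der = euler_matrix_derivatives(r_full[d])
            for k in range(3):
                dframes[d, k] = basis[d] @ der[k]
    if n_quad is None:
        nominal = 2.0 * float(np.max(np.linalg.norm(blueprint.positions, axis=1))) + 1.0
        n_quad = default_n_quad(activity, nominal)
    nb = len(batch)
    jit1 = rng.uniform(-1.0, 1.0, size=(nb, n_crystal_samples, 3))
    jit2 = rng.uniform(-1.0, 1.0, size=(nb, n_crystal_samples, 3))
    if n_crystal_samples % 2 == 0:
        # antithetic pairing halves the in-voxel sampling variance
        half = n_crystal_samples // 2
        jit1[:, half:] = -jit1[:, :half]
        jit2[:, half:] = -jit2[:, :half]
    rates = np.zeros(nb)
    grads = np.zeros((nb, 12))
    has_att = attenuation is not None
    a_vals = attenuation.values if has_att else np.zeros((1, 1, 1))
    a_origin = attenuation.origin if has_att else np.zeros(3)
    a_spacing = attenuation.spacing if has_att else np.ones(3)
    rate_act = rate_activity if rate_activity is not None else activity
    if rate_n_quad is None:
        rate_n_quad = n_quad if rate_activity is None else default_n_quad(
            rate_act, 2.0 * float(np.max(np.linalg.norm(blueprint.positions, axis=1))) + 1.0
        )
    _kernels.batch_expected_and_grad(
        batch.d1, batch.cr1, batch.d2, batch.cr2, batch.t,
        origins, frames, dframes,
        lut.centers, lut.half_extents, efficiencies.eff,
        jit1, jit2,
        activity.values, activity.origin, activity.spacing,
        rate_act.values, rate_act.origin, rate_act.spacing,
        has_att, a_vals, a_origin, a_spacing,
        tof.bin_centers, tof.kernel_sigma, tof.bin_width, tof.no_tof,
        int(n_quad), int(rate_n_quad), bool(want_grad), rates, grads,
    )
    w = batch.weights
    c = batch.counts
    sum_wc = float(np.sum(w * c * batch.log_flag))
    sum_wl = float(np.sum(w * rates * batch.rate_flag))
    profiled = sum_wc / sum_wl if sum_wl > 0 else 1.0
    scale = profiled if fixed_scale is None else float(fixed_scale)
    # additive background, *relative* to the typical scaled rate of counted
    # bins.  An absolute floor would swallow the log-term gradients whenever
    # the model mass spreads over many bins (coarse blur stages).  The
    # reference is the weighted mean of rates capped at 10x each bin's own
    # count: the cap stops an optimizer from raising the floor by inflating
    # a handful of bins, while (unlike a median) the reference stays
    # positive when sparse in-voxel sampling zeroes many individual rates.
    lf = batch.log_flag
    if np.any(lf):
        capped = np.minimum(scale * rates[lf], 10.0 * c[lf])
        ref_rate = float(np.sum(w[lf] * capped) / np.sum(w[lf]))
    else:
        ref_rate = 0.0
    floor = rate_floor * ref_rate + 1e-300
    srates = scale * rates + floor
    with np.errstate(divide="ignore"):
        logterm = np.where(batch.log_flag & (c > 0), c * np.log(srates), 0.0)
    loss = float(
        np.sum(w * scale * rates * batch.rate_flag) - np.sum(w * logterm)
    )
    if not np.isfinite(loss):
        bad = np.nonzero(~(np.isfinite(w * rates) & ((srates > 0) | (c == 0))))[0][:10]
        raise FloatingPointError(f"non-finite loss; offending batch entries {bad}")
    if not want_grad:
        return loss, None, None, scale, profiled
    # d loss / d rate per bin (the scale carries no gradient: it is either
    # externally fixed or profiled, where the envelope theorem applies)
    coeff = w * scale * batch.rate_flag
    logged = batch.log_flag & (c > 0) & (srates > 0)
    coeff = coeff - np.where(logged, w * c * scale / np.where(srates > 0, srates, 1.0), 0.0)
    gt_det = np.zeros((nd, 3))
    gr_det = np.zeros((nd, 3))
    np.add.at(gt_det, batch.d1, coeff[:, None] * grads[:, 0:3])
    np.add.at(gr_det, batch.d1, coeff[:, None] * grads[:, 3:6])
    np.add.at(gt_det, batch.d2, coeff[:, None] * grads[:, 6:9])
    np.add.at(gr_det, batch.d2, coeff[:, None] * grads[:, 9:12])
    hess = None
    if want_hessian:
        # full Gauss-Newton curvature of the log terms, including the
        # cross-block coupling of each bin: w C s^2/(sL+d)^2 g g^T with g
        # the 12-dim gradient over the two involved blocks' (T, R)
        h2 = np.where(logged, w * c * scale**2 / srates**2, 0.0)
        hpair = np.zeros((nd, nd, 6, 6))
        for lo in range(0, len(batch), 50000):
            sl = slice(lo, min(lo + 50000, len(batch)))
            outer = h2[sl, None, None] * np.einsum(
                "ni,nj->nij", grads[sl], grads[sl]
            )
            np.add.at(hpair, (batch.d1[sl], batch.d1[sl]), outer[:, :6, :6])
            np.add.at(hpair, (batch.d1[sl], batch.d2[sl]), outer[:, :6, 6:])
            np.add.at(hpair, (batch.d2[sl], batch.d1[sl]), outer[:, 6:, :6])
            np.add.at(hpair, (batch.d2[sl], batch.d2[sl]), outer[:, 6:, 6:])
        hess = hpair.transpose(0, 2, 1, 3).reshape(nd * 6, nd * 6)
    if params.share_map is None:
        if want_hessian:
            return loss, gt_det, gr_det, scale, profiled, hess
        return loss, gt_det, gr_det, scale, profiled
    ng = params.n_groups
    gt = np.zeros((ng, 3))
    gr = np.zeros((ng, 3))
    np.add.at(gt, idx, gt_det)
    np.add.at(gr, idx, gr_det)
    if want_hessian:
        proj = np.zeros((nd * 6, ng * 6))
        for d in range(nd):
            proj[d * 6 : d * 6 + 6, idx[d] * 6 : idx[d] * 6 + 6] = np.eye(6)
        return loss, gt, gr, scale, profiled, proj.T @ hess @ proj
    return loss, gt, gr, scale, profiled


@dataclass
class AlignmentResults:
    """Fitted alignment deviations and optimization diagnostics.

    ``params`` are the estimated per-block (or per-group) translations (mm)
    and rotations (degrees); ``loss_trace`` is the per-iteration stochastic
    NLL; ``scale`` the final profiled global rate factor.
    """

    params: AlignmentParams
    loss_trace: np.ndarray
    scale: float
    diagnostics: dict = field(default_factory=dict)
    model: "DetectorAlignmentModel | None" = None

    def aligned_geometry(self, blueprint: BlueprintGeometry | None = None) -> BlueprintGeometry:
        bp = blueprint if blueprint is not None else self.model.blueprint
        return apply_alignment(bp, self.params)

    def errors_vs(self, reference: BlueprintGeometry, procrustes: bool = True):
        """Per-axis translation/rotation errors against a reference geometry."""
        from .metrics import alignment_errors

        return alignment_errors(self.aligned_geometry(), reference, pre_align=procrustes)

    def params_frame(self) -> pd.DataFrame:
        t, r = self.params.translations, self.params.rotations
        return pd.DataFrame(
            {
                "Tx_mm": t[:, 0], "Ty_mm": t[:, 1], "Tz_mm": t[:, 2],
                "Rx_deg": r[:, 0], "Ry_deg": r[:, 1], "Rz_deg": r[:, 2],
            }
        )

    def summary(self) -> str:
        df = self.params_frame()
        head = (
            "Detector alignment calibration (Poisson ML)\n"
            f"  iterations: {len(self.loss_trace)}   final NLL: {self.loss_trace[-1]:.6g}\n"
            f"  profiled scale: {self.scale:.6g}\n"
            f"  wall time [s]: {self.diagnostics.get('wall_time_s', float('nan')):.1f}\n"
        )
        return head + df.to_string(float_format=lambda v: f"{v: .4f}")


CalibrationResult = AlignmentResults


def calibrate(
    histogram: CoincidenceHistogram,
    blueprint: BlueprintGeometry,
    lut: CrystalLUT,
    activity: VoxelGrid,
    attenuation: VoxelGrid | None,
    efficiencies: EfficiencyTable,
    tof: TOFModel,
    config: OptimizerConfig,
    init: AlignmentParams | None = None,
    share_map=None,
) -> AlignmentResults:
    """Run the Adam loop on fresh stochastic batches; fully seed-reproducible."""
    nd = blueprint.n_detectors
    if init is None:
        init = AlignmentParams.zero(nd, share_map)
    elif share_map is not None and init.share_map is None:
        raise ValueError("init must carry the same share_map")
    ss = np.random.SeedSequence(config.seed)
    batch_rng, jitter_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    t_par = init.translations.copy()
    r_par = init.rotations.copy()
    m_t = np.zeros_like(t_par)
    v_t = np.zeros_like(t_par)
    m_r = np.zeros_like(r_par)
    v_r = np.zeros_like(r_par)
    nominal = 2.0 * float(np.max(np.linalg.norm(blueprint.positions, axis=1))) + 1.0
    n_quad = default_n_quad(activity, nominal, config.samples_per_voxel)
    pair_list = _all_pairs(nd)
    # coarse-to-fine: precompute blurred activity grids per stage
    stages = list(config.blur_stages) or [(1.0, 0.0)]
    if stages[-1][0] < 1.0:
        stages.append((1.0, 0.0))
    stage_grids = [_blurred_activity(activity, sig) for _, sig in stages]
    stage_nquads = [
        default_n_quad(g, nominal, config.samples_per_voxel) for g in stage_grids
    ]
    # the empty-bin rate term integrates a blurred, coarsened activity: the
    # total-rate functional is smooth, so this changes it only at second
    # order while making its Monte-Carlo strata cheap and hard to evade
    rate_act = _blurred_activity(activity, config.rate_term_blur)
    rate_nq = default_n_quad(rate_act, nominal, config.samples_per_voxel)
    loss_trace = np.empty(config.iterations)
    grad_norms = np.empty(config.iterations)
    scale = None
    act_prev = None
    t0 = time.perf_counter()
    for it in range(config.iterations):
        batch = sample_batch(
            histogram, config.batch_size, batch_rng, config.zero_bin_fraction, pair_list
        )
        frac_done = (it + 1) / config.iterations
        act_it = stage_grids[-1]
        nq_it = stage_nquads[-1]
        for (frac_end, _), g, nq in zip(stages, stage_grids, stage_nquads):
            if frac_done <= frac_end + 1e-12:
                act_it = g
                nq_it = nq
                break
        params_it = AlignmentParams(t_par, r_par, share_map)
        loss, g_t, g_r, _, prof = nll_objective(
            params_it, batch, blueprint, lut, act_it, attenuation, efficiencies,
            tof, config.n_crystal_samples, jitter_rng, True, nq_it,
            config.rate_floor, scale,
            rate_activity=rate_act, rate_n_quad=rate_nq,
        )
        # damped scale tracking: the scale used for gradients is (nearly)
        # fixed w.r.t. any single batch, so batch noise cannot be gamed
        if scale is None or act_it is not act_prev:
            scale = prof
            act_prev = act_it
        else:
            scale *= (prof / scale) ** config.scale_damping
        if not np.isfinite(loss):
            raise FloatingPointError(f"divergence at iteration {it}: {loss_trace[:it]}")
        loss_trace[it] = loss
        grad_norms[it] = float(np.sqrt(np.sum(g_t**2) + np.sum(g_r**2)))
        if config.lr_schedule == "cosine":
            frac = it / max(config.iterations - 1, 1)
            lr_fac = config.lr_floor + (1 - config.lr_floor) * 0.5 * (
                1 + np.cos(np.pi * frac)
            )
        else:
            lr_fac = 1.0
        b1, b2 = config.beta1, config.beta2
        bc1 = 1 - b1 ** (it + 1)
        bc2 = 1 - b2 ** (it + 1)
        for par, g, m, v, lr in (
            (t_par, g_t, m_t, v_t, config.lr_translation),
            (r_par, g_r, m_r, v_r, config.lr_rotation),
        ):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            par -= lr * lr_fac * (m / bc1) / (np.sqrt(v / bc2) + config.adam_eps)
    polish_losses = []
    polish_stages = []
    if config.polish_iterations > 0:
        from scipy.optimize import minimize

        polish_rng = np.random.default_rng(ss.spawn(1)[0])
        support = histogram.n_bins
        n_zero = max(nd * (nd - 1) // 2, config.polish_batch_size // 2)
        total = min(config.polish_batch_size, support + n_zero)
        zb_frac = n_zero / (support + n_zero)
        ng = t_par.shape[0]
        rs = config.polish_rot_scale  # degrees per translation-equivalent unit

        def lbfgs_stage(t0_par, r0_par, act_p, nq, fit_rot, pbatch, jseed):
            params_now = AlignmentParams(t0_par, r0_par, share_map)
            _, _, _, _, s_fix = nll_objective(
                params_now, pbatch, blueprint, lut, act_p, attenuation,
                efficiencies, tof, config.polish_crystal_samples,
                np.random.default_rng(jseed), False, nq, config.rate_floor,
                rate_activity=rate_act, rate_n_quad=rate_nq,
            )

            def fun(x):
                t_x = x[: ng * 3].reshape(ng, 3)
                r_x = x[ng * 3 :].reshape(ng, 3) * rs if fit_rot else r0_par
                p = AlignmentParams(t_x, r_x, share_map)
                loss, g_t, g_r, _, _ = nll_objective(
                    p, pbatch, blueprint, lut, act_p, attenuation, efficiencies,
                    tof, config.polish_crystal_samples,
                    np.random.default_rng(jseed), True, nq,
                    config.rate_floor, s_fix,
                    rate_activity=rate_act, rate_n_quad=rate_nq,
                )
                g_r = g_r * rs if fit_rot else np.zeros_like(g_r)
                return loss, np.concatenate([g_t.ravel(), g_r.ravel()])

            x0 = np.concatenate([t0_par.ravel(), r0_par.ravel() / rs])
            bt, br = config.polish_bound_t, config.polish_bound_r / rs
            bounds = [(-bt, bt)] * (ng * 3) + [(-br, br)] * (ng * 3)
            opt = minimize(
                fun, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.polish_iterations, "ftol": 1e-12,
                         "gtol": 1e-10},
            )
            t_new = opt.x[: ng * 3].reshape(ng, 3)
            r_new = opt.x[ng * 3 :].reshape(ng, 3) * rs if fit_rot else r0_par.copy()
            return t_new, r_new, float(opt.fun), s_fix

        def lm_stage(t0_par, r0_par, act_p, nq, pbatch, jseed, iters):
            """Damped block-Jacobi Gauss-Newton refinement (one eval/step)."""
            t_c = t0_par.copy()
            r_c = r0_par.copy()
            jrng = lambda: np.random.default_rng(jseed)
            _, _, _, _, s_fix = nll_objective(
                AlignmentParams(t_c, r_c, share_map), pbatch, blueprint, lut,
                act_p, attenuation, efficiencies, tof,
                config.polish_crystal_samples, jrng(), False, nq,
                config.rate_floor,
                rate_activity=rate_act, rate_n_quad=rate_nq,
            )

            def full_eval(t_x, r_x, grad):
                return nll_objective(
                    AlignmentParams(t_x, r_x, share_map), pbatch, blueprint,
                    lut, act_p, attenuation, efficiencies, tof,
                    config.polish_crystal_samples, jrng(), grad, nq,
                    config.rate_floor, s_fix, want_hessian=grad,
                    rate_activity=rate_act, rate_n_quad=rate_nq,
                )

            loss0, g_t, g_r, _, _, hess = full_eval(t_c, r_c, True)
            lam = 1e-3
            ngr = t_c.shape[0]
            for _ in range(iters):
                gvec = np.column_stack([g_t, g_r]).reshape(-1)
                a = hess + lam * np.diag(np.diag(hess)) + 1e-9 * np.eye(len(gvec))
                delta = np.linalg.solve(a, -gvec).reshape(ngr, 6)
                # trust clipping: a GN step beyond ~1 mm / 3 deg leaves the
                # local quadratic's validity
                step_t = np.clip(delta[:, :3], -1.0, 1.0)
                step_r = np.clip(delta[:, 3:], -3.0, 3.0)
                t_try = t_c + step_t
                r_try = r_c + step_r
                loss1 = full_eval(t_try, r_try, False)[0]
                if loss1 < loss0 - 1e-9 * abs(loss0):
                    t_c, r_c, loss0 = t_try, r_try, loss1
                    lam = max(lam / 3.0, 1e-6)
                    _, g_t, g_r, _, _, hess = full_eval(t_c, r_c, True)
                else:
                    lam *= 8.0
                    if lam > 1e5:
                        break
            return t_c, r_c, loss0, s_fix

        stages_p = [
            s if isinstance(s, (tuple, list)) else (s, True)
            for s in config.polish_blurs
        ]
        for k, (sigma, fit_rot) in enumerate(stages_p):
            act_p = _blurred_activity(activity, sigma)
            nq = default_n_quad(act_p, nominal, config.samples_per_voxel)
            reps = config.polish_final_reps if k == len(stages_p) - 1 else 1
            sols = []
            final = k == len(stages_p) - 1
            for rep in range(reps):
                pbatch = sample_batch(histogram, total, polish_rng, zb_frac, pair_list)
                jseed = int(polish_rng.integers(0, 2**31 - 1))
                if final and config.polish_newton > 0 and fit_rot:
                    t_new, r_new, fval, s_fix = lm_stage(
                        t_par, r_par, act_p, nq, pbatch, jseed, config.polish_newton
                    )
                else:
                    t_new, r_new, fval, s_fix = lbfgs_stage(
                        t_par, r_par, act_p, nq, fit_rot, pbatch, jseed
                    )
                sols.append((fval, t_new, r_new))
                polish_losses.append(fval)
                scale = s_fix
            # averaging independent frozen-batch solutions beats the
            # subsample noise of any single one as 1/sqrt(reps); repetitions
            # that stalled far from the optimum (loss well above the best,
            # beyond batch-to-batch variation) are discarded
            best = min(f for f, _, _ in sols)
            kept = [(t, r) for f, t, r in sols if f <= best + 0.5 * abs(best)]
            t_par = np.mean([t for t, _ in kept], axis=0)
            r_par = np.mean([r for _, r in kept], axis=0)
            polish_stages.append(
                (sigma, AlignmentParams(t_par.copy(), r_par.copy(), share_map))
            )
    wall = time.perf_counter() - t0
    result = AlignmentResults(
        AlignmentParams(t_par, r_par, share_map),
        loss_trace,
        float(scale),
        {
            "grad_norms": grad_norms,
            "wall_time_s": wall,
            "n_quad": n_quad,
            "polish_losses": polish_losses,
            "polish_stages": polish_stages,
            "config": config,
        },
    )
    return result


class DetectorAlignmentModel:
    """Poisson ML model of detector-block alignment from coincidence data.

    Parameters
    ----------
    histogram : CoincidenceHistogram
        Measured TOF coincidence counts.
    blueprint : BlueprintGeometry
        Designed scanner geometry (the optimization starting point).
    lut : CrystalLUT
        Crystal-voxel lookup table shared by all blocks.
    activity : VoxelGrid
        Known tracer distribution ``F``.
    attenuation : VoxelGrid, optional
        Attenuation map ``A`` (1/mm); omitted means no attenuation.
    efficiencies : EfficiencyTable, optional
        Per-crystal efficiencies; defaults to uniform.
    tof : TOFModel, optional
        Defaults to the histogram's TOF model.
    share_map : array of int, optional
        Detector -> parameter-group tying (one learnable (T, R) per group).

    Examples
    --------
    >>> model = DetectorAlignmentModel(hist, blueprint, lut, activity)
    >>> res = model.fit(OptimizerConfig(iterations=150, batch_size=20000))
    >>> print(res.summary())
    """

    def __init__(
        self,
        histogram: CoincidenceHistogram,
        blueprint: BlueprintGeometry,
        lut: CrystalLUT,
        activity: VoxelGrid,
        attenuation: VoxelGrid | None = None,
        efficiencies: EfficiencyTable | None = None,
        tof: TOFModel | None = None,
        share_map=None,
    ):
        self.histogram = histogram
        self.blueprint = blueprint
        self.lut = lut
        self.activity = activity
        self.attenuation = attenuation
        self.efficiencies = (
            efficiencies
            if efficiencies is not None
            else EfficiencyTable.uniform(blueprint.n_detectors, lut.n_crystals)
        )
        self.tof = tof if tof is not None else histogram.tof
        self.share_map = share_map

    def nll(self, params: AlignmentParams, batch: BinBatch | None = None,
            rng=None, n_crystal_samples: int = 5) -> float:
        """Stochastic NLL at given parameters (full support when batch=None)."""
        rng = np.random.default_rng(0) if rng is None else rng
        if batch is None:
            batch = sample_batch(self.histogram, self.histogram.n_bins, rng, 0.0)
        loss, *_ = nll_objective(
            params, batch, self.blueprint, self.lut, self.activity,
            self.attenuation, self.efficiencies, self.tof,
            n_crystal_samples, rng, want_grad=False,
        )
        return loss

    def fit(
        self,
        config: OptimizerConfig | None = None,
        init: AlignmentParams | None = None,
    ) -> AlignmentResults:
        config = config if config is not None else OptimizerConfig()
        res = calibrate(
            self.histogram, self.blueprint, self.lut, self.activity,
            self.attenuation, self.efficiencies, self.tof, config,
            init=init, share_map=self.share_map,
        )
        res.model = self
        return res
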
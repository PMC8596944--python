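"""Extended phase graph (EPG) modelling of multi-echo TSE decay.

At 7 T the transmit (B1) field is inhomogeneous, so the refocusing pulses of
a turbo spin-echo train are not the nominal 180 degrees and the echo-train
signal deviates from mono-exponential decay through stimulated-echo
pathways.  The EPG formalism tracks the configuration states (F+, F-, Z) of
the magnetization through the train and predicts the echo amplitudes for an
arbitrary refocusing angle b1 * nominal.

T2 and B1 are estimated voxelwise in two stages:

1. :func:`fit_stage1` — joint nonlinear least squares of (S0, T2, b1) per
   voxel.  The global search over the alpha / (360 - alpha) degenerate,
   multi-modal landscape is a dense dictionary match over a (T2, b1) grid,
   refined by damped Gauss-Newton with S0 solved by linear projection.
2. :func:`smooth_b1_polynomial` fits a low-order 3-D polynomial to the stage-1
   B1 map (the true B1 field is smooth; anatomical contrast in the raw map is
   fit noise), then :func:`fit_stage2` re-estimates (S0, T2) with B1 frozen to
   the smoothed field, optionally with a quadratic penalty pulling T2 toward
   the local neighbourhood median in low-SNR regions.

Conventions: b1 is searched and reported in (0, 1] because alpha and
360 - alpha produce identical echo trains; excitation is treated as ideal
(signals are normalized to unit amplitude at TE -> 0); T1 cannot be separated
at TR = 1000 ms and is fixed (default 500 ms, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes import (
    GridIncompatibilityError,
    Mask,
    ScalarVolume,
    VolumeGrid,
    check_grid_compatibility,
)

__all__ = [
    "TSEProtocol",
    "EchoVolume",
    "epg_cpmg_signal",
    "fit_stage1",
    "smooth_b1_polynomial",
    "fit_stage2",
]

#: TE values (ms) of the reference multi-echo TSE protocol
DEFAULT_ECHO_TIMES = (13.0, 25.0, 38.0, 50.0, 63.0, 76.0)


@dataclass(frozen=True)
class TSEProtocol:
    """Multi-echo TSE acquisition parameters.

    ``echo_times_ms`` must be strictly increasing and positive.  The train is
    modelled as a CPMG sequence with the refocusing pulse for echo k centred
    between consecutive echo times, so relaxation acts over the two
    half-intervals (TE_k - TE_{k-1}) / 2; ideal crusher gradients are assumed
    in each interval.  For equally spaced TEs this is the textbook CPMG train
    with echo spacing TE_1.
    """

    echo_times_ms: tuple[float, ...] = DEFAULT_ECHO_TIMES
    repetition_time_ms: float = 1000.0
    excitation_deg: float = 90.0
    nominal_refocus_deg: float = 180.0
    assumed_t1_ms: float = 500.0

    def __post_init__(self) -> None:
        tes = tuple(float(t) for t in self.echo_times_ms)
        if len(tes) < 1 or tes[0] <= 0 or any(b <= a for a, b in zip(tes, tes[1:])):
            raise ValueError("echo times must be positive and strictly increasing")
        object.__setattr__(self, "echo_times_ms", tes)
        if self.assumed_t1_ms <= 0:
            raise ValueError("assumed_t1_ms must be positive")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_ms)

    @property
    def intervals_ms(self) -> tuple[float, ...]:
        tes = self.echo_times_ms
        return (tes[0],) + tuple(b - a for a, b in zip(tes, tes[1:]))


@dataclass
class EchoVolume:
    """Per-voxel multi-echo magnitudes: array of shape (*grid.shape, n_echoes)."""

    grid: VolumeGrid
    values: np.ndarray
    protocol: TSEProtocol = field(default_factory=TSEProtocol)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (*self.grid.shape, self.protocol.n_echoes)
        if self.values.shape != expected:
            raise GridIncompatibilityError(
                f"echo volume shape {self.values.shape} != expected {expected}"
            )


def epg_cpmg_signal(t2_ms, t1_ms, b1, protocol: TSEProtocol) -> np.ndarray:
    """Echo amplitudes of a CPMG train via the EPG recursion.

    Parameters broadcast: ``t2_ms``, ``t1_ms`` and ``b1`` may be scalars or
    arrays of a common shape ``B``; the result has shape ``(*B, n_echoes)``.
    Amplitudes are normalized to unity at TE -> 0 (ideal excitation, unit
    equilibrium magnetization); the refocusing angle is
    ``b1 * nominal_refocus_deg``.

    At b1 = 1 (perfect 180s) every transverse pathway refocuses and the
    result is exactly ``exp(-TE / T2)``.
    """
    t2 = np.asarray(t2_ms, dtype=float)
    t1 = np.asarray(t1_ms, dtype=float)
    b1a = np.asarray(b1, dtype=float)
    if np.any(t2 <= 0) or np.any(t1 <= 0):
        raise ValueError("t2_ms and t1_ms must be positive")
    if np.any(b1a <= 0):
        raise ValueError("b1 must be positive")
    batch = np.broadcast_shapes(t2.shape, t1.shape, b1a.shape)
    t2, t1, b1a = (np.broadcast_to(a, batch) for a in (t2, t1, b1a))

    n = protocol.n_echoes
    n_states = 2 * n + 3  # configuration order grows by <= 2 per interval
    alpha = np.deg2rad(b1a * protocol.nominal_refocus_deg)[..., None]

    # pulse mixing coefficients (refocusing about the magnetization axis: CPMG)
    c2, s2 = np.cos(alpha / 2) ** 2, np.sin(alpha / 2) ** 2
    sa, ca = np.sin(alpha), np.cos(alpha)

    fp = np.zeros((*batch, n_states), dtype=complex)
    fm = np.zeros((*batch, n_states), dtype=complex)
    z = np.zeros((*batch, n_states), dtype=complex)
    fp[..., 0] = 1.0
    fm[..., 0] = 1.0

    out = np.empty((*batch, n))
    for k, dt in enumerate(protocol.intervals_ms):
        for half in range(2):
            # relax over dt/2, then dephase by one configuration order
            e2 = np.exp(-0.5 * dt / t2)[..., None]
            e1 = np.exp(-0.5 * dt / t1)[..., None]
            fp *= e2
            fm *= e2
            z *= e1
            z[..., 0] += (1.0 - e1[..., 0])
            fp[..., 1:] = fp[..., :-1]
            fp[..., 0] = np.conj(fm[..., 1])
            fm[..., :-1] = fm[..., 1:]
            fm[..., -1] = 0.0
            if half == 0:
                fp_new = c2 * fp + s2 * fm - 1j * sa * z
                fm_new = s2 * fp + c2 * fm + 1j * sa * z
                z_new = -0.5j * sa * fp + 0.5j * sa * fm + ca * z
                fp, fm, z = fp_new, fm_new, z_new
        out[..., k] = np.abs(fp[..., 0])
    return out


# ---------------------------------------------------------------------------
# Voxelwise fitting
# ---------------------------------------------------------------------------

_T2_BOUNDS = (1.0, 1000.0)
_B1_BOUNDS = (0.05, 1.0)


def _dictionary(protocol, t2_grid, b1_grid):
    t2s, b1s = np.meshgrid(t2_grid, b1_grid, indexing="ij")
    atoms = epg_cpmg_signal(t2s.ravel(), protocol.assumed_t1_ms, b1s.ravel(), protocol)
    norms = np.linalg.norm(atoms, axis=1, keepdims=True)
    return t2s.ravel(), b1s.ravel(), atoms / norms


def fit_epg_voxels(
    signals: np.ndarray,
    protocol: TSEProtocol,
    b1_fixed: np.ndarray | None = None,
    t2_grid: np.ndarray | None = None,
    b1_grid: np.ndarray | None = None,
    lambda_reg: float = 0.0,
    t2_reference: np.ndarray | None = None,
    n_iter: int = 40,
    tol: float = 1e-10,
):
    """Vectorised nonlinear least-squares of the EPG model over voxels.

    ``signals`` has shape (n_voxels, n_echoes).  When ``b1_fixed`` is None a
    joint (T2, b1) fit is performed, seeded by an exhaustive dictionary match
    over ``t2_grid`` x ``b1_grid`` (the multi-start that steps over the
    alpha/360-alpha degeneracy and local minima); otherwise only T2 is free.
    S0 enters linearly and is solved by projection at every step (signals are
    normalised per voxel first, so the optional penalty
    ``lambda_reg * (T2 - t2_reference)**2`` is scale-free across voxels).

    Returns ``(s0, t2, b1, converged)`` as 1-D arrays.
    """
    y = np.asarray(signals, dtype=float)
    n_vox, n_echo = y.shape
    if n_echo < 3:
        raise ValueError("need at least 3 echoes to fit (S0, T2, b1)")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")

    norms = np.linalg.norm(y, axis=1)
    valid = (norms > 0) & (y[:, 0] > 0) & np.isfinite(norms)
    yn = np.where(valid[:, None], y / np.where(norms > 0, norms, 1.0)[:, None], 0.0)

    t1 = protocol.assumed_t1_ms
    if t2_grid is None:
        t2_grid = np.geomspace(3.0, 300.0, 40)
    if b1_grid is None:
        b1_grid = np.linspace(0.1, 1.0, 19)

    joint = b1_fixed is None
    if joint:
        t2_atoms, b1_atoms, atoms = _dictionary(protocol, t2_grid, b1_grid)
        corr = yn @ atoms.T
        best = np.argmax(corr, axis=1)
        t2 = t2_atoms[best].copy()
        b1v = b1_atoms[best].copy()
    else:
        b1v = np.broadcast_to(np.asarray(b1_fixed, dtype=float), (n_vox,)).copy()
        b1v = np.clip(b1v, *_B1_BOUNDS)
        # 1-D dictionary over T2 at the fixed b1 of each voxel is wasteful;
        # a log-linear mono-exponential seed is close enough for refinement
        with np.errstate(divide="ignore", invalid="ignore"):
            tes = np.asarray(protocol.echo_times_ms)
            logy = np.log(np.clip(y, 1e-300, None))
            slope = np.polyfit(tes, logy.T, 1)[0]
        t2 = np.clip(np.where(slope < 0, -1.0 / np.where(slope < 0, slope, -1.0), 60.0),
                     *_T2_BOUNDS)

    if lambda_reg > 0:
        ref = np.asarray(t2_reference, dtype=float)
        if ref.shape != (n_vox,):
            raise ValueError("t2_reference must have one value per voxel")
    else:
        ref = None

    def model_and_cost(t2c, b1c):
        s = epg_cpmg_signal(t2c, t1, b1c, protocol)
        ss = np.einsum("ij,ij->i", s, s)
        s0 = np.clip(np.einsum("ij,ij->i", yn, s) / np.where(ss > 0, ss, 1.0), 0.0, None)
        r = yn - s0[:, None] * s
        cost = np.einsum("ij,ij->i", r, r)
        if ref is not None:
            cost = cost + lambda_reg * (t2c - ref) ** 2
        return s, s0, r, cost

    s, s0, r, cost = model_and_cost(t2, b1v)
    converged = np.zeros(n_vox, dtype=bool)
    mu = np.full(n_vox, 1e-3)  # per-voxel Levenberg-Marquardt damping

    # active-set refinement: voxels whose step has converged drop out
    active = valid.copy()
    for _ in range(n_iter):
        if not active.any():
            break
        ia = np.flatnonzero(active)
        t2a, b1a, s0a, ra, costa = t2[ia], b1v[ia], s0[ia], r[ia], cost[ia]
        refa = ref[ia] if ref is not None else None
        yna = yn[ia]

        def projected_residual(t2c, b1c):
            sc = epg_cpmg_signal(t2c, t1, b1c, protocol)
            ss = np.einsum("ij,ij->i", sc, sc)
            s0c = np.clip(
                np.einsum("ij,ij->i", yna, sc) / np.where(ss > 0, ss, 1.0), 0.0, None
            )
            return yna - s0c[:, None] * sc

        # variable-projection Jacobian: central differences of the projected
        # residual (S0 re-solved at every probe), so the Gauss-Newton model
        # sees the same objective the line search evaluates
        dt2 = np.maximum(1e-4 * t2a, 1e-4)
        j_t2 = (
            projected_residual(t2a - dt2, b1a) - projected_residual(t2a + dt2, b1a)
        ) / (2.0 * dt2[:, None])
        a11 = np.einsum("ij,ij->i", j_t2, j_t2)
        g1 = np.einsum("ij,ij->i", j_t2, ra)
        if refa is not None:
            a11 = a11 + lambda_reg
            g1 = g1 - lambda_reg * (t2a - refa)
        if joint:
            db1 = 1e-5
            j_b1 = (
                projected_residual(t2a, np.clip(b1a - db1, _B1_BOUNDS[0], None))
                - projected_residual(t2a, np.clip(b1a + db1, None, _B1_BOUNDS[1]))
            ) / (2.0 * db1)
            a12 = np.einsum("ij,ij->i", j_t2, j_b1)
            a22 = np.einsum("ij,ij->i", j_b1, j_b1)
            g2 = np.einsum("ij,ij->i", j_b1, ra)

        # Levenberg-Marquardt acceptance: a rejected step raises the damping
        # (bending the direction toward gradient descent, which handles the
        # ridge-like (T2, b1) trade-off), an accepted step lowers it
        mua = mu[ia]
        accepted = np.zeros(ia.size, dtype=bool)
        t2_new, b1_new = t2a.copy(), b1a.copy()
        for _ in range(10):
            pend = ~accepted
            if not pend.any():
                break
            sub = np.flatnonzero(pend)
            m = mua[sub]
            if joint:
                d11 = a11[sub] * (1.0 + m)
                d22 = a22[sub] * (1.0 + m)
                det = d11 * d22 - a12[sub] ** 2
                det = np.where(np.abs(det) > 1e-300, det, 1.0)
                step_t2 = (d22 * g1[sub] - a12[sub] * g2[sub]) / det
                step_b1 = (d11 * g2[sub] - a12[sub] * g1[sub]) / det
            else:
                d11 = a11[sub] * (1.0 + m)
                step_t2 = g1[sub] / np.where(d11 > 1e-300, d11, 1.0)
                step_b1 = np.zeros_like(step_t2)
            trial_t2 = np.clip(t2a[sub] + step_t2, *_T2_BOUNDS)
            trial_b1 = np.clip(b1a[sub] + step_b1, *_B1_BOUNDS) if joint else b1a[sub]
            yna_local = yna[sub]
            sc = epg_cpmg_signal(trial_t2, t1, trial_b1, protocol)
            ss = np.einsum("ij,ij->i", sc, sc)
            s0c = np.clip(
                np.einsum("ij,ij->i", yna_local, sc) / np.where(ss > 0, ss, 1.0),
                0.0,
                None,
            )
            rc = yna_local - s0c[:, None] * sc
            trial_cost = np.einsum("ij,ij->i", rc, rc)
            if refa is not None:
                trial_cost = trial_cost + lambda_reg * (trial_t2 - refa[sub]) ** 2
            improve = trial_cost <= costa[sub] + 1e-16
            gi = sub[improve]
            t2_new[gi] = trial_t2[improve]
            if joint:
                b1_new[gi] = trial_b1[improve]
            accepted[gi] = True
            mua[gi] = np.maximum(mua[gi] * 0.3, 1e-6)
            mua[sub[~improve]] *= 10.0
        mu[ia] = mua
        rel_step = np.abs(t2_new - t2a) / np.maximum(t2a, 1.0)
        if joint:
            rel_step = np.maximum(rel_step, np.abs(b1_new - b1a))
        t2[ia], b1v[ia] = t2_new, b1_new
        # refresh cached residuals for the voxels that moved
        sc = epg_cpmg_signal(t2_new, t1, b1_new, protocol)
        ss = np.einsum("ij,ij->i", sc, sc)
        s0c = np.clip(np.einsum("ij,ij->i", yna, sc) / np.where(ss > 0, ss, 1.0), 0.0, None)
        s0[ia] = s0c
        r[ia] = yna - s0c[:, None] * sc
        new_cost = np.einsum("ij,ij->i", r[ia], r[ia])
        if refa is not None:
            new_cost = new_cost + lambda_reg * (t2_new - refa) ** 2
        cost[ia] = new_cost
        # converged: an accepted step became negligibly small, or damping has
        # grown so large that no step of any kind improves (stalled at a
        # minimum within search resolution)
        done = (accepted & (rel_step < 1e-8)) | (~accepted & (mu[ia] > 1e10))
        converged[ia] = done
        active[ia] = ~done

    s0_out = np.where(valid, s0 * norms, 0.0)
    t2 = np.where(valid, t2, np.nan)
    b1v = np.where(valid, b1v, np.nan)
    converged = converged | (cost < tol)
    return s0_out, t2, b1v, converged & valid


def fit_stage1(
    echoes: EchoVolume,
    mask: Mask,
    protocol: TSEProtocol | None = None,
    **fit_kwargs,
) -> tuple[ScalarVolume, ScalarVolume, ScalarVolume]:
    """Stage-1 joint voxelwise (S0, T2, b1) fit inside ``mask``.

    Returns (T2 map [ms], B1 map, amplitude map).  All-zero voxels are
    flagged NaN and excluded from the maps.
    """
    protocol = protocol or echoes.protocol
    check_grid_compatibility([echoes, mask])
    sig = echoes.values[mask.values]
    s0, t2, b1, _ = fit_epg_voxels(sig, protocol, **fit_kwargs)
    grid = echoes.grid

    def scatter(vals, units):
        vol = np.full(grid.shape, np.nan)
        vol[mask.values] = vals
        return ScalarVolume(grid, vol, units=units)

    return scatter(t2, "ms"), scatter(b1, "unitless"), scatter(s0, "unitless")


def _polynomial_basis(grid: VolumeGrid, where: np.ndarray, order: int) -> np.ndarray:
    idx = np.argwhere(where).astype(float)
    # normalise voxel coordinates to [-1, 1] for conditioning
    half = (np.asarray(grid.shape) - 1) / 2.0
    x = (idx - half) / np.maximum(half, 1.0)
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append(x[:, 0] ** i * x[:, 1] ** j * x[:, 2] ** k)
    return np.stack(cols, axis=1)


def smooth_b1_polynomial(b1: ScalarVolume, mask: Mask, order: int = 4) -> ScalarVolume:
    """Least-squares fit of a 3-D polynomial (total degree <= ``order``) to
    the in-mask B1 values; returns the fitted smooth surface.

    The transmit field varies slowly in space, so structure in the raw
    stage-1 B1 map at anatomical scale is fit noise; projecting onto a
    low-order polynomial basis suppresses it.
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    check_grid_compatibility([b1, mask])
    inmask = mask.values & np.isfinite(b1.values)
    basis = _polynomial_basis(b1.grid, inmask, order)
    if basis.shape[0] < basis.shape[1]:
        raise ValueError(
            f"{basis.shape[0]} voxels cannot determine {basis.shape[1]} coefficients"
        )
    coef, _, rank, _ = np.linalg.lstsq(basis, b1.values[inmask], rcond=None)
    if rank < basis.shape[1]:
        raise ValueError("rank-deficient polynomial basis on this mask")
    full_basis = _polynomial_basis(b1.grid, np.ones(b1.grid.shape, dtype=bool), order)
    fitted = (full_basis @ coef).reshape(b1.grid.shape)
    return ScalarVolume(b1.grid, fitted, units="unitless")


def neighbourhood_median(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Median over the 26-neighbourhood (centre excluded), ignoring
    out-of-mask voxels.  NaN where no in-mask neighbour exists."""
    padded = np.full(np.asarray(values.shape) + 2, np.nan)
    inner = (slice(1, -1),) * 3
    padded[inner] = np.where(mask, values, np.nan)
    windows = np.lib.stride_tricks.sliding_window_view(padded, (3, 3, 3))
    flat = windows.reshape(*values.shape, 27).copy()
    flat[..., 13] = np.nan  # drop the centre voxel
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(flat, axis=-1)


def fit_stage2(
    echoes: EchoVolume,
    fixed_b1: ScalarVolume,
    mask: Mask,
    protocol: TSEProtocol | None = None,
    lambda_reg: float = 0.0,
) -> ScalarVolume:
    """Stage-2 voxelwise (S0, T2) fit with B1 frozen to the smoothed field.

    With ``lambda_reg`` > 0 the per-voxel objective gains a penalty
    ``lambda_reg * (T2 - ref)**2`` where ``ref`` is the 26-neighbourhood
    median T2 from an unregularised pass — this anchors voxels whose echoes
    carry almost no information (low B1, low SNR near the surface) to the
    surrounding tissue while leaving well-determined voxels untouched.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    protocol = protocol or echoes.protocol
    check_grid_compatibility([echoes, fixed_b1, mask])
    sig = echoes.values[mask.values]
    b1_vox = fixed_b1.values[mask.values]

    _, t2_plain, _, _ = fit_epg_voxels(sig, protocol, b1_fixed=b1_vox)
    if lambda_reg == 0.0:
        t2_vals = t2_plain
    else:
        t2_vol = np.full(echoes.grid.shape, np.nan)
        t2_vol[mask.values] = t2_plain
        ref_vol = neighbourhood_median(t2_vol, mask.values)
        ref = ref_vol[mask.values]
        ref = np.where(np.isfinite(ref), ref, t2_plain)
        _, t2_vals, _, _ = fit_epg_voxels(
            sig, protocol, b1_fixed=b1_vox, lambda_reg=lambda_reg, t2_reference=ref
        )
    out = np.full(echoes.grid.shape, np.nan)
    out[mask.values] = t2_vals
    return ScalarVolume(echoes.grid, out, units="ms")
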
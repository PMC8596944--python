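"""Synthetic brain phantoms with known ground truth.

The phantom emulates the statistical structure a whole fixed post-mortem
brain presents to the pipeline: a brain-like tissue blob with a bumpy
(sulci-like) surface inside a signal-free medium, a cortical grey-matter
shell around a white-matter core, diffusion tensors with the tissue-specific
post-mortem diffusivities (grey MD ~ 3.1e-4 mm^2/s, roughly double white
~ 1.37e-4 mm^2/s) and anisotropic white matter oriented along smooth bent
tracts, a ground-truth fixative-free T2 map per tissue, a linear fixative
effect T2 = T2_0 + beta * c, a smooth radially-decreasing B1 field, and
Gaussian or Rician noise on the echo volumes.

Everything is deterministic given (spec, seed): the generator is both the
study-condition emulator and the fixture factory for the test-suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .epg import EchoVolume, TSEProtocol, epg_cpmg_signal
from .simulator import ConcentrationVolume, distance_to_surface
from .volumes import Mask, ScalarVolume, TensorVolume, VolumeGrid, check_grid_compatibility

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "simulate_echo_data"]

#: post-mortem tissue diffusivities (mm^2/s): grey / white / whole-brain means
GREY_MD = 3.1e-4
WHITE_MD = 1.37e-4
WHOLE_BRAIN_MD = 2.4e-4


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for :func:`make_phantom`; the seed fixes all randomness.

    Diffusivity defaults are the post-mortem tissue means; ``beta_ms`` is the
    T2 change per unit fixative concentration (about -12 ms: a 10-15 ms
    linear T2 decrease over the full concentration range).  ``md_cv`` is the
    voxelwise coefficient of variation of MD within each tissue class.
    ``b1_coefficients`` are (constant, quadratic-radial) terms of the smooth
    transmit field b1(r) = c0 + c1 * rho^2 with rho the normalised radius.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (0.9, 0.9, 0.9)
    white_md: float = WHITE_MD
    grey_md: float = GREY_MD
    white_fa: float = 0.6
    grey_fa: float = 0.05
    md_cv: float = 0.15
    t2_zero_white_ms: float = 45.0
    t2_zero_grey_ms: float = 60.0
    t2_variation_ms: float = 1.0
    beta_ms: float = -12.0
    b1_coefficients: tuple[float, float] = (1.0, -0.35)
    snr: float = 50.0
    noise_model: str = "gaussian"
    ventricles: bool = False
    seed: int = 7

    def __post_init__(self) -> None:
        if self.white_md <= 0 or self.grey_md <= 0:
            raise ValueError("diffusivities must be positive")
        if not (0 <= self.white_fa < 1 and 0 <= self.grey_fa < 1):
            raise ValueError("FA targets must lie in [0, 1)")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class Phantom:
    """Generated volumes plus the spec they were generated from."""

    grid: VolumeGrid
    tissue: Mask
    white: Mask
    grey: Mask
    tensors: TensorVolume
    t2_zero: ScalarVolume
    b1: ScalarVolume
    spec: PhantomSpec

    @property
    def medium(self) -> Mask:
        return self.tissue.complement()


def _smooth_noise(rng, shape, sigma_vox: float) -> np.ndarray:
    """Zero-mean unit-SD Gaussian random field, correlation length sigma_vox."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma_vox)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _delta_from_fa(fa: float) -> float:
    # axially symmetric tensor L1 = MD(1+2d), L2 = L3 = MD(1-d)
    # => FA = sqrt(3) d / sqrt(1 + 2 d^2)
    return fa / np.sqrt(3.0 - 2.0 * fa**2)


def _axial_tensors(md, delta, e1) -> np.ndarray:
    """(*shape, 3, 3) tensors MD(1-d)*I + 3*MD*d * e1 e1^T (trace = 3 MD)."""
    eye = np.eye(3)
    outer = e1[..., :, None] * e1[..., None, :]
    return (md * (1.0 - delta))[..., None, None] * eye + (3.0 * md * delta)[
        ..., None, None
    ] * outer


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Generate a deterministic synthetic brain from ``spec``.

    The tissue blob is an ellipsoid whose surface is perturbed by a smooth
    random field (sulci-like bumps); white matter is the deep core (depth
    threshold, again smoothly perturbed), grey the remaining shell.  White
    tensors point along bent arcs circling the vertical axis — smooth,
    spatially varying, and oblique to the grid so all tensor components are
    exercised.  Raises if the geometry leaves white or grey empty.
    """
    rng = np.random.default_rng(spec.seed)
    grid = VolumeGrid(spec.shape, spec.spacing_mm)
    nx, ny, nz = grid.shape
    ax = [(np.arange(n) - (n - 1) / 2.0) / (n / 2.0) for n in grid.shape]
    U, V, W = np.meshgrid(*ax, indexing="ij")

    ellip = (U / 0.80) ** 2 + (V / 0.86) ** 2 + (W / 0.74) ** 2
    bumps = _smooth_noise(rng, grid.shape, sigma_vox=3.0)
    tissue_arr = ellip < 1.0 + 0.18 * bumps
    # keep a 2-voxel medium margin so the whole surface is bathed in medium
    tissue_arr[:2, :, :] = tissue_arr[-2:, :, :] = False
    tissue_arr[:, :2, :] = tissue_arr[:, -2:, :] = False
    tissue_arr[:, :, :2] = tissue_arr[:, :, -2:] = False

    if spec.ventricles:
        vent = (U / 0.16) ** 2 + (V / 0.22) ** 2 + (W / 0.12) ** 2 < 1.0
        tissue_arr &= ~vent

    tissue = Mask(grid, tissue_arr, label="tissue")
    if not tissue_arr.any():
        raise ValueError("phantom geometry produced an empty tissue mask")

    depth = distance_to_surface(tissue).values  # mm
    depth_cut = 2.8 + 1.1 * _smooth_noise(rng, grid.shape, sigma_vox=2.5)
    white_arr = tissue_arr & (depth > depth_cut)
    grey_arr = tissue_arr & ~white_arr
    if not white_arr.any() or not grey_arr.any():
        raise ValueError("phantom geometry left white or grey matter empty")
    white = Mask(grid, white_arr, label="white")
    grey = Mask(grid, grey_arr, label="grey")

    # bent-arc tract field: azimuthal around the vertical axis with a smooth
    # out-of-plane pitch, then normalised; near-axis voxels default to z
    pitch = 0.35 + 0.15 * _smooth_noise(rng, grid.shape, sigma_vox=4.0)
    e1 = np.stack([-V, U, pitch * np.sqrt(U**2 + V**2 + 0.05)], axis=-1)
    norm = np.linalg.norm(e1, axis=-1, keepdims=True)
    e1 = np.where(norm > 1e-8, e1 / np.where(norm > 0, norm, 1.0), [0.0, 0.0, 1.0])

    # lognormal MD jitter with exact tissue-class means
    def jitter(n):
        sigma = np.sqrt(np.log(1.0 + spec.md_cv**2))
        return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n))

    md = np.zeros(grid.shape)
    md[white_arr] = spec.white_md * jitter(int(white_arr.sum()))
    md[grey_arr] = spec.grey_md * jitter(int(grey_arr.sum()))

    delta = np.zeros(grid.shape)
    delta[white_arr] = _delta_from_fa(spec.white_fa)
    delta[grey_arr] = _delta_from_fa(spec.grey_fa)

    tensors_mat = _axial_tensors(md, delta, e1)
    tensors_mat[~tissue_arr] = 0.0
    tensors = TensorVolume.from_matrix(grid, tensors_mat)

    t2_zero_arr = np.zeros(grid.shape)
    t2_zero_arr[white_arr] = spec.t2_zero_white_ms
    t2_zero_arr[grey_arr] = spec.t2_zero_grey_ms
    if spec.t2_variation_ms > 0:
        t2_zero_arr[tissue_arr] += (
            spec.t2_variation_ms * _smooth_noise(rng, grid.shape, sigma_vox=2.0)[tissue_arr]
        )
    t2_zero = ScalarVolume(grid, t2_zero_arr, units="ms")

    c0, c1 = spec.b1_coefficients
    rho2 = U**2 + V**2 + W**2
    b1_arr = np.clip(c0 + c1 * rho2, 0.3, 1.0)
    b1 = ScalarVolume(grid, b1_arr, units="unitless")

    return Phantom(grid, tissue, white, grey, tensors, t2_zero, b1, spec)


def simulate_echo_data(
    phantom: Phantom,
    concentration: ConcentrationVolume,
    protocol: TSEProtocol | None = None,
    snr: float | None = None,
    seed: int | None = None,
) -> EchoVolume:
    """Forward-simulate multi-echo TSE magnitudes from the phantom.

    The voxelwise true T2 is ``T2_0 + beta * c`` (floored at 1 ms); echo
    amplitudes come from the EPG model with the voxel's B1; noise at the
    stated SNR is added, with SNR referenced to the mean first-echo tissue
    signal.  ``snr = inf`` produces noiseless data.  Deterministic given
    ``seed`` (defaults to the phantom seed).
    """
    protocol = protocol or TSEProtocol()
    check_grid_compatibility([phantom.tissue, concentration.as_scalar_volume()])
    snr = phantom.spec.snr if snr is None else float(snr)
    if snr <= 0:
        raise ValueError("snr must be positive")
    seed = phantom.spec.seed if seed is None else int(seed)

    tis = phantom.tissue.values
    t2_true = np.maximum(
        phantom.t2_zero.values + phantom.spec.beta_ms * concentration.values, 1.0
    )
    data = np.zeros((*phantom.grid.shape, protocol.n_echoes))
    data[tis] = epg_cpmg_signal(t2_true[tis], protocol.assumed_t1_ms, phantom.b1.values[tis],
                                protocol)

    if np.isfinite(snr):
        sigma = float(data[tis][:, 0].mean()) / snr
        rng = np.random.default_rng(seed)
        if phantom.spec.noise_model == "rician":
            re = data + sigma * rng.standard_normal(data.shape)
            im = sigma * rng.standard_normal(data.shape)
            data = np.hypot(re, im)
        else:
            data = data + sigma * rng.standard_normal(data.shape)
    return EchoVolume(phantom.grid, data, protocol=protocol)
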
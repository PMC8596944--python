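"""End-to-end orchestration: phantom -> simulate -> fit -> correct -> evaluate.

One :class:`RunConfig` (JSON-serialisable, one top-level seed) drives the
whole workflow and produces a deterministic artifact set: concentration map,
T2/B1 maps, corrected T2, binned curves, the confound fit and the
inhomogeneity summary, plus a JSON run report capturing package versions,
the time step and stability bound, and all filter counts.

The generative truth is always the kinetic tensor simulation (the phantom's
tensors drive the fixative effect in the echo data); the ``model`` choice
selects which regressor is used for the correction — ``kt`` (the same
concentration map), ``ki`` / ``ki-md`` (isotropic re-simulations), ``d2s``
(distance to surface) or ``b1`` (the fitted smooth transmit field) — which
is exactly the model-comparison design the evaluation reports on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .epg import TSEProtocol, fit_stage1, fit_stage2, smooth_b1_polynomial
from .phantom import Phantom, PhantomSpec, make_phantom, simulate_echo_data
from .regression import (
    CONCENTRATION_RANGE,
    DISTANCE_RANGE,
    apply_correction,
    bin_t2_by_regressor,
    fit_confound,
    tissue_inhomogeneity,
)
from .simulator import (
    SimulationConfig,
    _DiffusionStepper,
    clean_tensor_field,
    distance_to_surface,
    make_isotropic_field,
    make_isotropic_field_from_md,
    max_stable_timestep,
    simulate_concentration,
)
from .volumes import ScalarVolume, write_mask, write_scalar_volume, write_tensor_volume

__all__ = ["RunConfig", "run_pipeline"]

MODELS = ("kt", "ki", "ki-md", "d2s", "b1")


@dataclass
class RunConfig:
    """Declarative run description; every field has a JSON representation."""

    out_dir: str | Path = "fixflux_run"
    model: str = "kt"
    seed: int = 7
    phantom: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)
    write_volumes: bool = True

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        return d


def _regressor_range(kind: str, values: np.ndarray) -> tuple[float, float]:
    if kind == "concentration":
        return CONCENTRATION_RANGE
    if kind == "distance-mm":
        return DISTANCE_RANGE
    lo, hi = float(np.nanmin(values)), float(np.nanmax(values))
    return (lo, hi) if hi > lo else (lo, lo + 1.0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the run report (also written to
    ``out_dir/report.json``).  Deterministic given the config and seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "versions": {"fixflux": __version__, "numpy": np.__version__},
        "stages": {},
    }

    def stage(name):
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        # ---- phantom -----------------------------------------------------
        info = stage("phantom")
        spec = PhantomSpec(seed=config.seed, **config.phantom)
        phantom = make_phantom(spec)
        info["tissue_voxels"] = phantom.tissue.n_voxels
        info["white_voxels"] = phantom.white.n_voxels
        info["grey_voxels"] = phantom.grey.n_voxels

        # ---- simulation (generative truth: KT) ---------------------------
        info = stage("simulate")
        sim_kwargs = {k: v for k, v in config.simulation.items() if k != "clean_threshold"}
        sim_cfg = SimulationConfig(**sim_kwargs)
        clean_threshold = config.simulation.get("clean_threshold", 1e-3)
        field_kt = clean_tensor_field(phantom.tensors, phantom.tissue, threshold=clean_threshold)
        stepper = _DiffusionStepper(field_kt, phantom.tissue)
        info["tau_s"] = sim_cfg.tau
        info["tau_max_s"] = max_stable_timestep(field_kt)
        info["weight_limited_voxels"] = stepper.n_weight_limited
        conc_kt, _ = simulate_concentration(field_kt, phantom.tissue, sim_cfg)
        d2s = distance_to_surface(phantom.tissue)

        # ---- echo data + T2/B1 fitting ------------------------------------
        info = stage("fit_t2")
        protocol = TSEProtocol()
        echoes = simulate_echo_data(phantom, conc_kt, protocol, seed=config.seed)
        t2_raw, b1_raw, s0_map = fit_stage1(echoes, phantom.tissue, protocol)
        order = int(config.fitting.get("b1_poly_order", 2))
        lambda_reg = float(config.fitting.get("lambda_reg", 0.0))
        b1_smooth = smooth_b1_polynomial(b1_raw, phantom.tissue, order=order)
        t2_map = fit_stage2(echoes, b1_smooth, phantom.tissue, protocol, lambda_reg=lambda_reg)
        info["b1_poly_order"] = order
        info["lambda_reg"] = lambda_reg

        # ---- regressor for the chosen model -------------------------------
        info = stage("regressor")
        if config.model == "kt":
            regressor, kind = conc_kt.as_scalar_volume(), "concentration"
        elif config.model == "ki":
            d_iso = float(phantom.tensors.mean_diffusivity[phantom.tissue.values].mean())
            conc_ki, _ = simulate_concentration(
                make_isotropic_field(phantom.tissue, d_iso), phantom.tissue, sim_cfg
            )
            regressor, kind = conc_ki.as_scalar_volume(), "concentration"
            info["isotropic_d_mm2s"] = d_iso
        elif config.model == "ki-md":
            md_map = ScalarVolume(
                phantom.grid, phantom.tensors.mean_diffusivity, units="mm^2/s"
            )
            conc_md, _ = simulate_concentration(
                make_isotropic_field_from_md(md_map, phantom.tissue), phantom.tissue, sim_cfg
            )
            regressor, kind = conc_md.as_scalar_volume(), "concentration"
        elif config.model == "d2s":
            regressor, kind = d2s, "distance-mm"
        else:  # b1
            regressor, kind = b1_smooth, "b1"
        info["kind"] = kind

        # ---- confound fit on white matter + voxelwise correction ----------
        info = stage("correct")
        reg_kw = dict(
            n_bins=int(config.regression.get("n_bins", 100)),
            surface_exclusion_mm=float(config.regression.get("surface_exclusion_mm", 2.0)),
            outlier_k=float(config.regression.get("outlier_k", 3.0)),
        )
        value_range = tuple(
            config.regression.get("range", _regressor_range(kind, regressor.values))
        )
        curve = bin_t2_by_regressor(
            t2_map, regressor, phantom.white, d2s=d2s, value_range=value_range,
            kind=kind, **reg_kw,
        )
        fit = fit_confound(curve)
        corrected = apply_correction(t2_map, regressor, fit.beta)
        info.update(
            beta_ms_per_unit=fit.beta,
            t2_zero_ms=fit.t2_zero,
            weighted_r2=fit.r_squared,
            n_bins_used=fit.n_bins,
            value_range=list(value_range),
        )

        # ---- evaluation ----------------------------------------------------
        info = stage("evaluate")
        excl = {k: reg_kw[k] for k in ("surface_exclusion_mm", "outlier_k")}
        for label, m in (("white", phantom.white), ("grey", phantom.grey)):
            info[f"sd_{label}_uncorrected_ms"] = tissue_inhomogeneity(
                t2_map, m, d2s=d2s, **excl
            )
            info[f"sd_{label}_corrected_ms"] = tissue_inhomogeneity(
                corrected, m, d2s=d2s, **excl
            )

        # ---- artifacts -----------------------------------------------------
        if config.write_volumes:
            write_mask(phantom.tissue, out / "tissue.nii.gz")
            write_mask(phantom.white, out / "white.nii.gz")
            write_mask(phantom.grey, out / "grey.nii.gz")
            write_tensor_volume(field_kt, out / "tensors.nii.gz")
            write_scalar_volume(conc_kt.as_scalar_volume(), out / "concentration_kt.nii.gz")
            write_scalar_volume(regressor, out / "regressor.nii.gz")
            write_scalar_volume(t2_map, out / "t2.nii.gz")
            write_scalar_volume(b1_smooth, out / "b1_smooth.nii.gz")
            write_scalar_volume(corrected, out / "t2_corrected.nii.gz")
            curve.to_frame().to_csv(out / "binned_curve.tsv", sep="\t", index=False)
    except Exception as exc:
        failed = next(
            (k for k, v in reversed(list(report["stages"].items())) if v is not None), "?"
        )
        report["error"] = {"stage": failed, "message": str(exc)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
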
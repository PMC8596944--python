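# fixflux

Fixative-flux simulation and T2 confound correction for whole post-mortem
brain MRI.

## The problem

Formalin in fixed tissue shortens T2 roughly linearly in its concentration.
When a fixed brain is moved into a signal-free scanning fluid (e.g. a
perfluorocarbon) some hours before imaging, fixative diffuses out through
the surface, leaving a concentration gradient — and therefore a spatial T2
bias — between deep and superficial tissue. `fixflux` is for quantitative
post-mortem MRI groups who want that confound modelled and removed rather
than averaged over.

## The model

Fixative transport is simulated with Fick's second law driven by voxelwise
diffusion tensors from diffusion MRI of the same specimen (the *kinetic
tensor*, KT, model):

    ∂c/∂t = ∇·(D(r) ∇c),   c ∈ [0, 1],

with the tissue initially at c = 1 and every medium voxel held at c = 0
(outflux; the influx setting swaps the values, and the two solutions are
exact complements). The default protocol integrates 48 h in 2000 explicit
steps (τ = 86.4 s) on a monotone conservative stencil that keeps c in
[0, 1] to machine precision. Simpler comparison models share the same
interface: a single isotropic diffusivity (KI), a voxelwise-MD isotropic
variant (KI-MD), and a plain distance-to-surface regressor (D2S).

T2 maps come from multi-echo TSE data fitted voxelwise with an extended
phase graph (EPG) model of the echo train (refocusing angle b1·180°,
configuration states F₊/F₋/Z), in two stages: a joint (S0, T2, b1) fit,
then a re-fit with b1 frozen to a smooth polynomial field. The confound is
then removed by a global linear regression fitted on white matter only —

    T2 = T2⁰ + β·c,  then voxelwise  T2⁰(r) = T2(r) − β·c(r)

— and evaluated by the drop in T2 standard deviation within each tissue
class, with grey matter serving as held-out validation. A synthetic brain
phantom (known tensors, T2⁰, β, B1, noise) makes the whole pipeline testable
without any scanner data.

## Worked example

Run the full pipeline on the default synthetic brain (48³ voxels at 0.9 mm,
seed 7, SNR 50, true β = −12 ms per unit concentration):

```sh
fixflux run --model kt --out-dir runs/kt --seed 7
```

which prints (about a minute on one core):

```json
{
  "beta_ms_per_unit": -11.848844010366209,
  "sd_white_uncorrected_ms": 3.025994953830916,
  "sd_white_corrected_ms": 1.5038752879427038,
  "sd_grey_uncorrected_ms": 2.280736897732891,
  "sd_grey_corrected_ms": 2.157709216861933
}
```

Reading: the white-matter fit recovered the fixative sensitivity β within
about 1% of the ground truth; removing β·c voxelwise cut the white-matter
T2 spread in half, and also reduced the spread in grey matter — which the
fit never saw — confirming that the correction captures fixative transport
rather than tissue contrast. `runs/kt/` contains the concentration map,
T2/B1 maps, corrected T2, the binned T2-vs-concentration curve (TSV) and a
JSON run report (τ, stability bound, filter counts, all stage outputs).

The same workflow is available stepwise (`fixflux phantom`, `simulate`,
`fit-t2`, `correct`, `evaluate` — see `--help`) and as a library:

```python
from fixflux import (PhantomSpec, make_phantom, SimulationConfig,
                     simulate_concentration)

phantom = make_phantom(PhantomSpec())            # 48³, seed 7
conc, _ = simulate_concentration(phantom.tensors, phantom.tissue,
                                 SimulationConfig())   # 48 h outflux
```

`EPGT2Mapper` and `ConcentrationConfoundRegressor` expose the fitting
stages as scikit-learn estimators (`fit`, `predict`/`transform`,
`get_params`) operating on plain arrays.

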
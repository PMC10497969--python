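# chondrosim

From 3D cell images to simulated impedance spectra of cartilage-like
tissue.

Fine-grained electrical models of cartilage need tissue-specific geometry:
where the chondrocytes are, how big they are, and how their membranes
polarize in an applied field. `chondrosim` implements that pipeline
end-to-end for synthetic data with exact ground truth:

1. **synthetic stacks** — seeded ellipsoidal cell populations (volumes
   ~2,157 ± 957 µm³, truncated normal) rendered into noisy 16-bit TIFF
   stacks with anisotropic voxels and exact instance labels;
2. **classical 3D segmentation** — isotropic resampling, denoising and
   illumination flattening, auto-thresholding (Otsu et al.), physical-unit
   artifact filters (slice area > 300 µm² removed, volume < 200 µm³
   removed), distance-transform watershed, moment-based ellipsoid fitting;
3. **evaluation metrics** — optimal one-to-one IoU matching with
   accuracy(τ) = TP/(TP+FN+FP), precision, recall, F1;
4. **geometry assembly** — all-pairs intersection graph, cycle-based void
   repair with filler spheres, marching-cubes surfaces, Taubin smoothing,
   quadric edge collapse decimation, STL export, and voxelization into a
   solver-ready material grid;
5. **electro-quasistatic solver** — ∇·((σ + jωε₀ε_r)∇φ) = 0 on an exactly
   conservative voxel admittance network with the 7 nm membrane as a
   normal-projected thin-layer element (σ_m = 8.7 µS/m, σ_cyt = 0.48 S/m,
   σ_buf = 1 S/m, ε_rm = 5.8, ε_rcyt = 60, ε_rbuf = 80), COCG + Jacobi,
   impedance Z(ω) over 1 kHz–1 THz and per-face transmembrane potentials;
6. **dielectric spectra** — σ_eff(ω) = Re(1/Z)·k, ε_r_eff(ω) =
   Im(1/Z)·k/(ωε₀) for the plate cell constant k, plus the analytic
   single-shell Maxwell–Wagner suspension model as an independent oracle
   (β-dispersion near 1 MHz);
7. **uncertainty quantification** — order-4 polynomial chaos by point
   collocation (254 evaluations for 5 parameters, 662 for 7), first-order
   Sobol indices and 5th/95th percentiles from 10⁴ surrogate samples, with
   canonical studies for geometric (cell position/volume/angle) and
   dielectric (membrane and phase parameters) uncertainty.

It is aimed at researchers prototyping image-based bioimpedance models who
want every stage testable against analytic ground truth before touching
real microscopy data.

## Worked example

```python
import numpy as np
from chondrosim import (
    sample_population, render_stack, segment_stack, match_instances,
    accuracy, voxelize_geometry, frequency_sweep, MaterialProps,
    extract_dielectric, single_shell_suspension,
)
from chondrosim.synthetic import NoiseModel

# 6 cells in an 80 µm box, rendered at 0.5 µm voxels
pop = sample_population(6, (80, 80, 80), allow_touching=False, seed=3)
stack, truth = render_stack(pop, (0.5, 0.5, 0.5), NoiseModel())
labels, fitted = segment_stack(stack)
m = match_instances(labels, truth, tau=0.5)
print(len(fitted), accuracy(m))          # 6 1.0

# dilute suspension: one 8 µm spherical cell at 2% volume fraction
R, phi = 8.0, 0.02
L = (4 / 3 * np.pi * R**3 / phi) ** (1 / 3)      # 47.5 µm box
from chondrosim.types import EllipsoidCell, EllipsoidSet
sphere = EllipsoidCell(np.full(3, L / 2), np.full(3, R), np.eye(3), 1)
geom = voxelize_geometry(EllipsoidSet([sphere], np.full(3, L)), np.full(3, L), L / 64)
props = MaterialProps()
spec = frequency_sweep(geom, props, frequencies=np.logspace(4, 8, 9))
diel = extract_dielectric(spec, L * 1e-6, L * L * 1e-12)
oracle = single_shell_suspension(props, R * 1e-6, geom.volume_ratio, spec.frequencies)
print(round(diel.eps_r_eff[0]), round(oracle.eps_r_eff[0]))   # 366 355
print(round(diel.eps_r_eff[-1], 1), round(oracle.eps_r_eff[-1], 1))  # 79.7 79.6
```

The segmentation recovers all six generated cells with accuracy 1.0 at the
standard IoU threshold 0.5. The simulated suspension shows the
β-dispersion: the permittivity steps from ≈ 366 at 10 kHz down to the
buffer value ≈ 80 at 100 MHz, within a few percent of the analytic
single-shell model at every frequency.

A command-line interface mirrors the library
(`chondrosim synth|segment|evaluate|mesh|voxelize|solve|dielectric|uq|pipeline`);
`chondrosim pipeline --config cfg.json --out run/` chains the stages with
file interchange and a reproducibility manifest.

## Layout

```
src/chondrosim/
  types.py         shared containers (cells, stacks, label volumes)
  synthetic.py     population sampling and stack rendering
  segmentation.py  the classical chain
  metrics.py       instance-matching evaluation
  geometry.py      intersection graph, void repair, meshes, voxelization
  solver.py        EQS admittance network, COCG, impedance, TMP
  dielectric.py    spectrum extraction + single-shell oracle
  uq.py            PCE, Sobol, percentiles, case studies
  io.py, cli.py, pipeline.py
docs/methods.md    models, numerics and design decisions in detail
```
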
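# avidkit

Geometric avidity analysis and umbrella-sampling free-energy post-processing
for multimeric antibody ensembles.

## The problem

A pentameric IgM-class antibody carries ten Fab arms on a rigid,
glycan-stabilised Fc core. Whether it can actually engage many receptors at
once — the avidity advantage over IgG — is a geometric question about its
conformational ensemble: how often does each antigen-binding site (CDR) have
enough clearance for a receptor-sized ligand, and how strong is the binding
once engaged? `avidkit` answers both from bead-resolution (coarse-grained)
ensembles:

- **Accessibility.** For every frame and every Fab, the distance from the
  CDR centre of mass to the nearest bead of any other domain is compared
  with a clearance threshold *d*<sub>min</sub> (default 1.8 nm, the minimal
  width of the receptor's binding domain). The pooled fraction of accessible
  (frame, Fab) configurations is the simultaneous-binding probability.
  A large-probe accessible surface area (Shrake–Rupley point sampling with
  probe radius *R* = 3.5 nm, half the receptor domain's maximum width)
  gives the complementary per-CDR area measure.
- **Ensemble dynamics.** RMSD after least-squares (Kabsch) superposition in
  two fit modes (fit-to-whole vs fit-to-self, separating arm swinging from
  internal deformation), per-bead RMSF, coordinate-covariance PCA with
  variance fractions and mode trajectories, cutoff contact counts and
  centre-of-mass distance series.
- **Binding free energy.** Potentials of mean force from umbrella-sampling
  windows via WHAM: self-consistent iteration of

  P(x<sub>b</sub>) = Σ<sub>i</sub> h<sub>i</sub>(x<sub>b</sub>) / Σ<sub>j</sub> N<sub>j</sub> exp[(f<sub>j</sub> − w<sub>j</sub>(x<sub>b</sub>))/k<sub>B</sub>T],  f<sub>i</sub> = −k<sub>B</sub>T ln Σ<sub>b</sub> P(x<sub>b</sub>) exp(−w<sub>i</sub>(x<sub>b</sub>)/k<sub>B</sub>T)

  with harmonic biases w<sub>i</sub>(x) = ½k<sub>i</sub>(x − x<sub>i</sub>⁰)²,
  PMF(x) = −k<sub>B</sub>T ln P(x) min-shifted to zero; plus adjacent-window
  histogram overlap diagnostics, integrated autocorrelation times
  (τ = 1 + 2Σρ(t), initial-positive-sequence truncation), Bayesian bootstrap
  errors (unit-mean exponential weights per window) and plateau
  binding-energy extraction.

A synthetic-data module generates toy pentamer ensembles (rigid planar core,
arms redrawn each frame inside a hinge cone) and *exact* Boltzmann samples of
umbrella windows from known 1D potentials, so every stage is testable against
closed-form truth without running molecular dynamics.

## Worked example

```python
import numpy as np
from avidkit import ToyIgMParams, binding_accessibility, generate_toy_igm

params = ToyIgMParams(n_frames=2000, hinge_cone_half_angle=40.0, seed=1)
ensemble, domain_map = generate_toy_igm(params)
result = binding_accessibility(ensemble, domain_map, threshold=1.8)
print(f"pooled binding probability: {100 * result.overall_probability:.2f}%")
```

prints (see `examples/01_toy_pentamer_accessibility.py`):

```
configurations analysed : 20000
distance range          : 0.11 - 9.03 nm
pooled binding probability: 99.26%
```

20,000 = 2,000 frames × 10 Fabs pooled configurations; 99.26% of them leave
at least 1.8 nm between the CDR centre of mass and the nearest bead of any
other domain, i.e. the toy pentamer's arms are splayed widely enough that a
receptor-sized ligand could almost always reach each binding site. On the
free-energy side, `examples/04_umbrella_wham.py` rebuilds a known double-well
profile from 17 biased windows:

```
recovered barrier : 4.93 kJ/mol (truth: 5.00)
adjacent-histogram overlap: min 0.24, 0 pair(s) below the 0.05 floor
Bayesian bootstrap error: median 0.12 kJ/mol per bin
```

Each script in `examples/` is a short narrative of one capability. A thin
CLI wraps the same functions for shell pipelines
(`avidkit gen-igm | access | asa | width | rmsd | rmsf | pca | contacts |
comdist | gen-umbrella | wham`).

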
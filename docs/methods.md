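# Methods

This note documents the models, conventions and numerical choices behind
`avidkit`, in the order a user meets them: containers and units, the
synthetic generators, the accessibility statistics, the ensemble metrics,
and the WHAM free-energy machinery.

## Units and containers

All lengths are nm, energies kJ/mol, force constants kJ mol⁻¹ nm⁻², times
ns, temperatures K. k_B = 0.0083144621 kJ mol⁻¹ K⁻¹; the default
temperature is 310 K, giving k_BT = 2.5775 kJ/mol. PDB files store
ångström; the readers and writers convert by an exact factor of 0.1/10 at
the boundary, so the only round-trip loss is the PDB format's three-decimal
coordinate field (5 × 10⁻⁵ nm).

Structures are flat arrays of beads with positions, radii and
(chain, residue, bead-name) annotations; ensembles are `(frames, beads, 3)`
coordinate stacks over a fixed topology. Domain maps resolve named
selections (`Fc`, `Fab_k`, `CDR_k`, glycans) to sorted bead-index arrays;
resolution from a YAML config is deterministic and order-independent.
Periodic boundaries are not handled: inputs are assumed whole and unwrapped,
which is how solvated-complex trajectories are normally post-processed.

Bead radii default to 0.235 nm — half a standard 0.47 nm coarse-grained
bead diameter — overridable per bead name. With a 3.5 nm probe the exact
radius matters little (it enters only through r + R).

## Synthetic generators

The generators exist so that every downstream statistic can be checked
against known truth; they are first-class, tested code, not fixtures.

**Toy pentamer** (`generate_toy_igm`). A planar ring of `n_subunits`
(default 5) rigid core segments, fixed across frames, with
`fabs_per_subunit` (default 2) arms hinged at each segment's ends. Per
frame, each arm's axis is drawn independently and uniformly over the
spherical cap of half-angle `hinge_cone_half_angle` (default 40°) about the
outward radial direction; the arm itself is a rigid template (a shallow
helix of `beads_per_arm` beads — a straight line would make
self-superposition degenerate and give the arm zero minimal width) rotated
onto that axis. The last `cdr_tip_beads` beads form `CDR_k`. Default
geometry — core radius 8 nm, arm length 9 nm — reflects a pentamer of
roughly 30 nm diameter with Fab-scale arms. Orientations are i.i.d. across
frames: the accessibility statistics are frame-marginal, so temporal
correlation would add nothing to their tests; time-correlated behaviour is
exercised separately by the scalar AR(1) generator (`ar1_series`,
documented as a test fixture for the autocorrelation-time estimator). What
the toy does **not** emulate: excluded volume between arms, glycans,
elastic-network deformation of domains, or kinetics — so passing tests
demonstrate the correctness of the statistics, not the realism of any
particular antibody's ensemble.

**Umbrella windows** (`generate_umbrella_series`). Exact equilibrium samples
from density ∝ exp(−[U(x) + ½k(x − x₀)²]/k_BT). For flat or harmonic U the
combined potential is Gaussian (stiffness κ + k, mean
(k·x₀ + κ·c)/(κ + k), variance k_BT/(κ + k)) and is drawn directly. For the
double well U(x) = B((x − c)² − w²)²/w⁴ — minima at c ± w, barrier exactly
B at x = c — rejection sampling is used: the Gaussian envelope sits at the
*combined* potential's minimum (located on a grid spanning ±12 bias σ) with
curvature softened by 30% so its tails dominate, and the acceptance
log-ratio is capped at its grid maximum so the envelope bounds the target.
A floor on the acceptance rate (default 1%) turns pathological
window/potential combinations into errors instead of silent stalls. Samples
being exact and independent is the point: WHAM recovery errors in the tests
are pure estimator error, with no equilibration or correlation confounds.

**Gaussian-mode ensembles** (`generate_gaussian_ensemble`). Frames =
mean + Σ z_m v_m with z_m ~ N(0, σ_m²) over user-supplied orthonormal
displacement fields — a known PCA spectrum by construction. For
variance-fraction tests the fields are built orthogonal to the six
rigid-body motions, because the analysis superposes frames before the
eigendecomposition and would otherwise absorb part of each mode.

All generators are pure functions of (parameters, seed).

## Accessibility statistics

**Large-probe ASA.** Shrake–Rupley point sampling with an arbitrary probe
radius R: each selected bead's sphere of radius r_i + R carries a
deterministic golden-spiral lattice (default 960 points; no RNG, so results
are exactly reproducible); a point is exposed iff outside every other
bead's (r_j + R)-sphere, with *all* beads acting as occluders. The area is
exact for an isolated bead and within lattice discretisation otherwise;
doubling the lattice changes test structures by < 0.5%. Rotation invariance
is approximate at the same discretisation level (the lattice is fixed in
the lab frame); translation invariance is exact.

**Widths.** A selection's maximum width is its largest pairwise centre
distance; its minimal width is the smallest extent along the three
principal axes of its coordinate covariance — a global thickness, chosen
over any pairwise minimum because "width of a domain" is an extent, not a
nearest-neighbour property. Halving these yields the probe radius (3.5 nm)
and clearance threshold (1.8 nm) used for receptor-sized ligands.

**Nearest obstruction and binding probability.** For each (frame, Fab): the
Euclidean distance from the CDR's centre of mass (unweighted bead mean;
coarse-grained inputs carry no masses) to the nearest bead centre of any
domain other than the host Fab. Glycan domains count as obstructions by
default — they are part of the structure — with a flag to exclude them. A
configuration is accessible iff distance ≥ threshold (closed comparison;
ties are accessible). The pooled accessible fraction over all ensembles,
frames and Fabs is the simultaneous-binding probability; `+inf` is returned
(and classified accessible) when no obstruction beads exist.

## Ensemble metrics

Superposition is the optimal proper rotation (Kabsch via SVD, determinant
sign-corrected), solved on the fit selection and applied to all beads;
selections whose second singular value vanishes (collinear/coincident) are
rejected. RMSF and PCA align frames with a two-pass mean-structure fit
(fit to frame 0 → average → refit to the average) — standard practice,
deterministic, and within test tolerances of fully iterated alignment. PCA
eigendecomposes the dense 3N × 3N covariance (practical to a few thousand
selected beads; a rank-deficiency warning fires when frames < 3N).
Contacts are bead-centre pairs within a closed cutoff (default 0.6 nm, the
conventional coarse-grained contact distance), counted with a KD-tree and
verified against an O(N²) loop in the tests.

## WHAM

Window histograms are combined by the standard self-consistent iteration
(see README for the two equations), stopping when max_i |Δf_i| < 10⁻⁶
kJ/mol (default; 10⁵ iteration cap — non-convergence returns a flagged
profile rather than raising). Two discretisation choices matter:

- **Bin width 0.05 nm** (default, over the sampled span). Window σ is
  ≥ 0.05 nm at the force constants used here, so the profile is still
  oversampled, while per-bin counting noise (k_BT/√count) stays well below
  the recovery tolerances; the discretisation bias ~U″w²/24 is ≈ 0.004
  kJ/mol for the test surfaces — negligible against that noise.
- **Bin-averaged bias factors.** The bias enters as the log of the
  Boltzmann factor *averaged over each bin* (analytic via the Gaussian CDF,
  evaluated in log space), not the factor at the bin centre. In any
  window's tail the bias varies by more than k_BT across a single bin, and
  centre-evaluation leaves kJ/mol-scale systematic errors there; bin
  averaging removes them exactly for harmonic biases.

The PMF is −k_BT ln P, min-shifted to zero; empty bins inside the sampled
range are NaN sentinels and logged. Out-of-range samples are dropped and
counted. Window free energies are reported with f₀ pinned to zero.
Residual estimator error is dominated by a random walk in the f_i (each
window constrains only its neighbours through histogram overlap), which
tilts single realizations; the acceptance check for harmonic recovery
therefore takes the median RMS over three independent realizations at the
unchanged tolerance.

Diagnostics: adjacent-window overlap Σ_b min(p_b, q_b) with a 0.05 warning
floor; integrated autocorrelation time τ = 1 + 2Σρ(t) truncated at the
first negative ρ (FFT autocovariance; constant series → τ = 1 by
convention), giving effective sample sizes N/τ; windows may optionally be
thinned by ⌈τ⌉ before WHAM. Errors are a Bayesian bootstrap: each replicate
rescales every window's histogram by an i.i.d. unit-mean exponential weight
and re-solves (warm-started at the unweighted solution); the per-bin error
is the standard deviation of the min-shifted replicates, and unconverged
replicates are discarded and logged. The binding energy is the mean PMF
over a dissociated plateau (default: the last 1.0 nm of the profile).

The reaction coordinate is a 1D scalar throughout; which Cartesian axis it
came from is irrelevant to the estimator.

## Problem sizes and limitations

The test and acceptance workloads use 17 windows × 5,000 samples for PMF
recovery, 10⁵ samples for flatness/autocorrelation checks, 5,000–10,000
frames for RMSF/PCA recoveries, and 5,000-frame toy ensembles (50,000
configurations; 150,000 pooled over three runs) for accessibility — sizes
at which the closed-form tolerances are comfortably resolved on a single
CPU in minutes. Known limitations: spherical probes cannot capture an
anisotropic receptor's shape; nearest-obstruction distances default to bead
centres (an `obstruction_mode="residue"` option measures to residue centres
of mass instead); the toy generator's arms ignore excluded volume, so its binding
probabilities describe the geometry of independent cones, not a real
antibody; and no MBAR/umbrella-integration estimators are provided.
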
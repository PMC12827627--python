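"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators matter:

* a toy pentameric antibody — a rigid planar core ring with mobile arms
  whose orientations are redrawn each frame inside a cone about the
  outward radial direction, mimicking a rigid glycan-stabilised Fc core
  carrying ten flexible Fab arms;
* exact Boltzmann samples of umbrella-sampling windows from known 1D
  potentials under harmonic biases, so the free-energy machinery can be
  tested against closed-form truth instead of MD output.

A Gaussian-mode ensemble generator (known PCA spectrum) and a scalar AR(1)
series (known integrated autocorrelation time, used purely as a test
fixture) complete the set. All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DEFAULT_BEAD_RADIUS, BeadStructure, DomainMap, Ensemble, UmbrellaWindow

__all__ = [
    "ToyIgMParams",
    "PotentialSpec",
    "generate_toy_igm",
    "generate_umbrella_series",
    "generate_gaussian_ensemble",
    "ar1_series",
    "KB",
]

#: Boltzmann constant in kJ mol⁻¹ K⁻¹.
KB = 0.0083144621


@dataclass
class ToyIgMParams:
    """Geometry and sampling parameters for the toy pentameric antibody.

    Defaults reflect the rough dimensions of a pentameric IgM: an overall
    diameter near 30 nm, a planar core of radius ~8 nm, and ~9 nm Fab arms,
    two per subunit. ``hinge_cone_half_angle`` (degrees) bounds how far an
    arm may swing from the outward radial direction; 0 freezes the arms.
    """

    n_subunits: int = 5
    fabs_per_subunit: int = 2
    core_radius: float = 8.0
    arm_length: float = 9.0
    beads_per_arm: int = 10
    cdr_tip_beads: int = 2
    hinge_cone_half_angle: float = 40.0
    n_frames: int = 100
    frame_spacing: float = 1.0
    seed: int = 0
    core_beads_per_subunit: int = 12
    bead_radius: float = DEFAULT_BEAD_RADIUS

    def __post_init__(self) -> None:
        for name in ("n_subunits", "fabs_per_subunit", "beads_per_arm", "cdr_tip_beads",
                     "n_frames", "core_beads_per_subunit"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.hinge_cone_half_angle <= 90.0:
            raise ValueError("hinge_cone_half_angle must be within [0, 90] degrees")
        if self.core_radius <= 0 or self.arm_length <= 0:
            raise ValueError("core_radius and arm_length must be positive")
        if self.cdr_tip_beads > self.beads_per_arm:
            raise ValueError("cdr_tip_beads cannot exceed beads_per_arm")


@dataclass
class PotentialSpec:
    """A 1D potential U(x) used as ground truth for umbrella sampling.

    forms
        ``flat``: U = 0.
        ``harmonic``: U = ½ κ (x − c)², parameters ``{"kappa", "center"}``
        (κ in kJ mol⁻¹ nm⁻², center nm, default 0).
        ``double_well``: U = B ((x − c)² − w²)² / w⁴, parameters
        ``{"barrier", "center", "half_separation"}`` — minima at c ± w and
        a barrier of exactly B kJ/mol at x = c.
    """

    form: str = "flat"
    parameters: dict = field(default_factory=dict)
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if self.form not in ("flat", "harmonic", "double_well"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if self.form == "harmonic" and self.parameters.get("kappa", 1.0) <= 0:
            raise ValueError("harmonic stiffness kappa must be positive")
        if self.form == "double_well":
            if self.parameters.get("barrier", 1.0) <= 0:
                raise ValueError("double-well barrier must be positive")
            if self.parameters.get("half_separation", 1.0) <= 0:
                raise ValueError("double-well half_separation must be positive")

    def energy(self, x: np.ndarray) -> np.ndarray:
        """U(x) in kJ/mol."""
        x = np.asarray(x, dtype=float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            kappa = self.parameters["kappa"]
            c = self.parameters.get("center", 0.0)
            return 0.5 * kappa * (x - c) ** 2
        b = self.parameters["barrier"]
        c = self.parameters.get("center", 0.0)
        w = self.parameters["half_separation"]
        return b * ((x - c) ** 2 - w**2) ** 2 / w**4


# ---------------------------------------------------------------------------
# Toy pentameric antibody
# ---------------------------------------------------------------------------


def _rotations_z_to(dirs: np.ndarray) -> np.ndarray:
    """Batch of proper rotations mapping +z onto each unit vector (Rodrigues)."""
    dirs = np.asarray(dirs, dtype=float)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(np.tile(z, (len(dirs), 1)), dirs)  # (F, 3)
    c = dirs[:, 2]  # cos angle
    s2 = (v**2).sum(axis=1)  # sin² angle
    out = np.tile(np.eye(3), (len(dirs), 1, 1))
    ok = s2 > 1e-24
    vx = np.zeros((len(dirs), 3, 3))
    vx[:, 0, 1], vx[:, 0, 2] = -v[:, 2], v[:, 1]
    vx[:, 1, 0], vx[:, 1, 2] = v[:, 2], -v[:, 0]
    vx[:, 2, 0], vx[:, 2, 1] = -v[:, 1], v[:, 0]
    factor = np.where(ok, (1.0 - c) / np.where(ok, s2, 1.0), 0.0)
    out += vx + vx @ vx * factor[:, None, None]
    # antiparallel case: rotate by π about x
    flip = (~ok) & (c < 0)
    out[flip] = np.diag([1.0, -1.0, -1.0])
    return out


def _sample_cone(rng: np.random.Generator, axis: np.ndarray, half_angle_rad: float,
                 size: int) -> np.ndarray:
    """Directions uniform over the spherical cap of the given half-angle about axis."""
    if half_angle_rad == 0.0:
        return np.tile(axis, (size, 1))
    cos_t = rng.uniform(np.cos(half_angle_rad), 1.0, size)
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = rng.uniform(0.0, 2.0 * np.pi, size)
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    # rotate local +z onto axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    c = float(np.dot(z, axis))
    if s < 1e-12:
        return local if c > 0 else -local
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    return local @ rot.T


def generate_toy_igm(params: ToyIgMParams) -> tuple[Ensemble, DomainMap]:
    """Generate a toy pentamer ensemble: rigid planar core, mobile arms.

    The core is a ring of ``n_subunits`` straight segments in the z = 0
    plane, identical in every frame. Each subunit carries
    ``fabs_per_subunit`` arms hinged at its outer edge; per frame each arm
    axis is drawn independently and uniformly within a cone of
    ``hinge_cone_half_angle`` about the outward radial direction. The last
    ``cdr_tip_beads`` beads of arm *k* form the ``CDR_k`` selection.
    Deterministic given ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    arm_spacing = p.arm_length / p.beads_per_arm
    if arm_spacing <= 0:
        raise ValueError("arm geometry not satisfiable")

    chain_ids: list[str] = []
    residue_indices: list[int] = []
    bead_names: list[str] = []
    residue_names: list[str] = []
    core_coords: list[np.ndarray] = []
    domains: dict[str, list[int]] = {"Fc": []}
    hinges: list[tuple[np.ndarray, np.ndarray]] = []  # (hinge point, outward axis)

    def chain_label(i: int) -> str:
        # A..Z then AA.. — PDB chain ids stay single-char for <= 26 chains
        alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        return alphabet[i] if i < 26 else alphabet[i // 26 - 1] + alphabet[i % 26]

    bead_counter = 0
    for s in range(p.n_subunits):
        theta = 2.0 * np.pi * s / p.n_subunits
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        # core segment: beads along the tangent, centred on the ring
        half = (p.core_beads_per_subunit - 1) / 2.0
        seg_len = min(0.8 * 2 * np.pi * p.core_radius / p.n_subunits, p.core_radius)
        step = seg_len / max(p.core_beads_per_subunit - 1, 1)
        chain = chain_label(s)
        for b in range(p.core_beads_per_subunit):
            core_coords.append(p.core_radius * radial + (b - half) * step * tangent)
            chain_ids.append(chain)
            residue_indices.append(b + 1)
            residue_names.append("COR")
            bead_names.append("BB")
            domains["Fc"].append(bead_counter)
            bead_counter += 1
        # hinge points at the two ends of the segment, pushed slightly outward
        for a in range(p.fabs_per_subunit):
            sign = 1.0 if a % 2 == 0 else -1.0
            hinge = p.core_radius * radial + sign * (half * step + arm_spacing) * tangent
            hinges.append((hinge, radial))

    n_core = bead_counter
    fab_ids: list[str] = []
    cdr_of: dict[str, str] = {}
    for k, _ in enumerate(hinges, start=1):
        fab = f"Fab_{k}"
        cdr = f"CDR_{k}"
        fab_ids.append(fab)
        cdr_of[fab] = cdr
        chain = chain_label(p.n_subunits + k - 1)
        fab_idx, cdr_idx = [], []
        for b in range(p.beads_per_arm):
            chain_ids.append(chain)
            residue_indices.append(b + 1)
            residue_names.append("ARM")
            bead_names.append("BB")
            fab_idx.append(bead_counter)
            if b >= p.beads_per_arm - p.cdr_tip_beads:
                cdr_idx.append(bead_counter)
            bead_counter += 1
        domains[fab] = fab_idx
        domains[cdr] = cdr_idx

    n_total = bead_counter
    core_block = np.asarray(core_coords)
    frames = np.empty((p.n_frames, n_total, 3))
    frames[:, :n_core] = core_block
    half_angle = np.deg2rad(p.hinge_cone_half_angle)
    # rigid arm template in its local frame (+z along the arm axis): beads
    # trace a shallow helix so the arm has a 3D cross-section and a
    # well-defined orientation (a straight bead line would make
    # self-superposition degenerate and give the arm zero minimal width)
    b = np.arange(p.beads_per_arm)
    template = np.column_stack(
        [
            0.3 * np.cos(2.0 * np.pi * b / 3.0),
            0.3 * np.sin(2.0 * np.pi * b / 3.0),
            (b + 1) * arm_spacing,
        ]
    )
    offset = n_core
    for hinge, axis in hinges:
        dirs = _sample_cone(rng, axis, half_angle, p.n_frames)  # (F, 3)
        rots = _rotations_z_to(dirs)  # (F, 3, 3)
        frames[:, offset : offset + p.beads_per_arm] = hinge + np.einsum(
            "fij,bj->fbi", rots, template
        )
        offset += p.beads_per_arm

    topology = BeadStructure(
        positions=frames[0],
        radii=np.full(n_total, p.bead_radius),
        chain_ids=np.asarray(chain_ids),
        residue_indices=np.asarray(residue_indices),
        residue_names=np.asarray(residue_names),
        bead_names=np.asarray(bead_names),
    )
    ensemble = Ensemble(
        topology=topology, frames=frames, frame_spacing=p.frame_spacing, label="toy_igm"
    )
    domain_map = DomainMap(
        domains={k: np.asarray(v, dtype=int) for k, v in domains.items()},
        fab_ids=fab_ids,
        cdr_of=cdr_of,
    )
    return ensemble, domain_map


# ---------------------------------------------------------------------------
# Umbrella-window sampling
# ---------------------------------------------------------------------------


def generate_umbrella_series(
    true_potential: PotentialSpec,
    centers: Sequence[float],
    force_constant: float,
    n_samples: int,
    seed: int,
    sample_spacing: float = 1.0,
    min_acceptance: float = 0.01,
) -> list[UmbrellaWindow]:
    """Draw exact equilibrium samples for each umbrella window.

    Each window samples the density ∝ exp(−[U(x) + ½k(x − x₀)²] / k_BT).
    For flat or harmonic U this is an exact Gaussian draw (combined
    stiffness κ + k, mean (k·x₀ + κ·c)/(κ + k)); for the double well,
    rejection sampling against the bias-only Gaussian envelope with
    acceptance probability exp(−U/k_BT). Deterministic given ``seed``.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("at least one window center required")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("window centers must be strictly increasing")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    k = float(force_constant)
    kbt = KB * true_potential.temperature
    rng = np.random.default_rng(seed)
    windows: list[UmbrellaWindow] = []
    for x0 in centers:
        if true_potential.form in ("flat", "harmonic"):
            kappa = 0.0 if true_potential.form == "flat" else true_potential.parameters["kappa"]
            c = true_potential.parameters.get("center", 0.0)
            total = kappa + k
            mean = (k * x0 + kappa * c) / total
            sigma = np.sqrt(kbt / total)
            samples = rng.normal(mean, sigma, n_samples)
        else:
            samples = _rejection_sample(
                rng, true_potential, x0, k, kbt, n_samples, min_acceptance
            )
        windows.append(
            UmbrellaWindow(
                center=float(x0),
                force_constant=k,
                samples=samples,
                sample_spacing=sample_spacing,
            )
        )
    return windows


def _rejection_sample(rng, potential, x0, k, kbt, n_samples, min_acceptance):
    """Exact draw from density ∝ exp(−[U(x) + ½k(x−x₀)²]/k_BT) by rejection.

    The Gaussian envelope sits at the combined potential's minimum with a
    curvature softened by 30% so its tails dominate the target's local
    shape; the acceptance log-ratio is capped over a wide grid so the
    envelope provably bounds the target there.
    """

    def total(x):
        return potential.energy(x) + 0.5 * k * (x - x0) ** 2

    sigma_bias = np.sqrt(kbt / k)
    grid = x0 + sigma_bias * np.linspace(-12.0, 12.0, 4001)
    v = total(grid)
    i_min = int(np.argmin(v))
    x_star = grid[i_min]
    h = grid[1] - grid[0]
    curv = (v[min(i_min + 1, len(v) - 1)] - 2 * v[i_min] + v[max(i_min - 1, 0)]) / h**2
    k_env = max(0.7 * curv, 0.1 * k)
    sigma = np.sqrt(kbt / k_env)
    # log acceptance ratio: -(V - ½k_env(x-x*)²)/kbt, capped at its grid max
    log_ratio_grid = -(v - 0.5 * k_env * (grid - x_star) ** 2) / kbt
    log_m = log_ratio_grid.max()

    out = np.empty(n_samples)
    filled = 0
    drawn = accepted = 0
    while filled < n_samples:
        batch = max(4 * (n_samples - filled), 1000)
        x = rng.normal(x_star, sigma, batch)
        log_r = -(total(x) - 0.5 * k_env * (x - x_star) ** 2) / kbt - log_m
        keep = np.log(rng.uniform(size=batch)) < log_r
        drawn += batch
        accepted += int(keep.sum())
        take = min(int(keep.sum()), n_samples - filled)
        out[filled : filled + take] = x[keep][:take]
        filled += take
        if drawn >= 50_000 and accepted / drawn < min_acceptance:
            raise RuntimeError(
                f"rejection acceptance rate {accepted / drawn:.3g} below floor "
                f"{min_acceptance}; window at {x0} nm poorly matched to the potential"
            )
    return out


# ---------------------------------------------------------------------------
# Gaussian-mode ensembles and AR(1) fixture
# ---------------------------------------------------------------------------


def generate_gaussian_ensemble(
    mean_structure: BeadStructure,
    mode_vectors: np.ndarray,
    mode_variances: Sequence[float],
    n_frames: int,
    seed: int,
    frame_spacing: float = 1.0,
) -> Ensemble:
    """Frames = mean + Σₘ zₘ·vₘ with zₘ ~ N(0, σₘ²): a known PCA spectrum.

    ``mode_vectors`` is ``(n_modes, n_beads, 3)`` (or ``(n_modes, 3N)``),
    orthonormal as flattened 3N-vectors within 1e-8.
    """
    n_beads = mean_structure.n_beads
    modes = np.asarray(mode_vectors, dtype=float).reshape(-1, 3 * n_beads)
    variances = np.asarray(mode_variances, dtype=float)
    if len(variances) != len(modes):
        raise ValueError("one variance per mode vector required")
    if np.any(variances < 0):
        raise ValueError("mode variances must be non-negative")
    gram = modes @ modes.T
    if not np.allclose(gram, np.eye(len(modes)), atol=1e-8):
        raise ValueError("mode vectors must be orthonormal (tolerance 1e-8)")
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_frames, len(modes))) * np.sqrt(variances)[None, :]
    flat = mean_structure.positions.ravel()[None, :] + z @ modes
    return Ensemble(
        topology=mean_structure,
        frames=flat.reshape(n_frames, n_beads, 3),
        frame_spacing=frame_spacing,
        label="gaussian_modes",
    )


def ar1_series(phi: float, n: int, seed: int) -> np.ndarray:
    """Stationary AR(1) series with unit innovations: x_t = φ·x_{t−1} + ε_t.

    Test fixture for the integrated autocorrelation time, whose true value
    is (1 + φ)/(1 − φ).
    """
    if not -1.0 < phi < 1.0:
        raise ValueError("phi must lie in (-1, 1) for stationarity")
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    eps = rng.normal(size=n)
    eps[0] /= np.sqrt(1.0 - phi**2)  # stationary start
    return lfilter([1.0], [1.0, -phi], eps)
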
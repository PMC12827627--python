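"""Large-probe accessibility statistics for multivalent antibodies.

The central question: can a receptor-sized probe reach the antigen-binding
loops (CDRs) of each Fab arm, given the crowding of the other arms, the
core and the glycans? Three quantities answer it:

* the accessible surface area of a CDR selection traced with a large
  spherical probe (default 3.5 nm, half the maximum width of the receptor's
  binding domain);
* a per-configuration nearest-obstruction distance — from the CDR's centre
  of mass to the nearest bead of any other domain;
* the simultaneous-binding probability: the fraction of (frame, Fab)
  configurations whose nearest-obstruction distance clears a threshold
  (default 1.8 nm, the minimal width of the receptor's binding domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import BeadStructure, DomainMap, Ensemble

__all__ = [
    "ASAResult",
    "AccessibilityResult",
    "sphere_points",
    "compute_asa",
    "asa_timeseries",
    "domain_widths",
    "nearest_obstruction_distance",
    "binding_accessibility",
]

DEFAULT_PROBE_RADIUS = 3.5  # nm — half the receptor binding domain's maximum width
DEFAULT_THRESHOLD = 1.8  # nm — the receptor binding domain's minimal width
DEFAULT_SPHERE_POINTS = 960


@dataclass
class ASAResult:
    """Accessible surface area of a bead selection under a large probe."""

    probe_radius: float
    per_bead_area: np.ndarray  # nm², one per selected bead
    total_area: float  # nm²
    n_sphere_points: int


@dataclass
class AccessibilityResult:
    """Simultaneous-binding accessibility over pooled (frame, Fab) configurations.

    ``distances`` has shape ``(n_configurations,)`` — pooled over ensembles,
    frames and Fabs; ``fab_labels`` aligns each entry with its Fab name.
    A configuration is accessible iff its distance ≥ ``threshold`` (closed
    comparison: ties count as accessible).
    """

    distances: np.ndarray
    fab_labels: np.ndarray
    threshold: float
    per_fab_probability: dict
    overall_probability: float
    n_configurations: int


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of ``n`` quasi-uniform unit vectors."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z**2, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def compute_asa(
    structure: BeadStructure,
    selection: Sequence[int],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> ASAResult:
    """Shrake–Rupley-style accessible surface area with an arbitrary probe.

    For each selected bead i, ``n_sphere_points`` lattice points are placed
    on the sphere of radius rᵢ + R; a point is exposed iff it lies outside
    every other bead's (rⱼ + R)-sphere. Occluders are ALL beads in the
    structure, selected or not. Deterministic — the lattice uses no RNG.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection must be non-empty")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    if n_sphere_points < 32:
        raise ValueError("n_sphere_points must be >= 32")

    pos = structure.positions
    expanded = structure.radii + probe_radius
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(pos)
    max_expanded = expanded.max()

    per_bead = np.empty(selection.size)
    for out_i, i in enumerate(selection):
        rho = expanded[i]
        # candidate occluders: centres within rho + max expanded radius
        cand = tree.query_ball_point(pos[i], rho + max_expanded)
        cand = [j for j in cand if j != i and np.linalg.norm(pos[j] - pos[i]) < rho + expanded[j]]
        pts = pos[i] + rho * unit
        if cand:
            occ = pos[cand]
            occ_r = expanded[cand]
            d2 = ((pts[:, None, :] - occ[None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (occ_r**2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        per_bead[out_i] = frac * 4.0 * np.pi * rho**2
    return ASAResult(
        probe_radius=probe_radius,
        per_bead_area=per_bead,
        total_area=float(per_bead.sum()),
        n_sphere_points=n_sphere_points,
    )


def asa_timeseries(
    ensemble: Ensemble,
    domain_map: DomainMap,
    cdr_name: str,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_SPHERE_POINTS,
) -> np.ndarray:
    """Per-frame total ASA (nm²) of a named CDR selection, aligned to frame times."""
    if cdr_name not in domain_map:
        raise KeyError(f"unknown selection {cdr_name!r}")
    sel = domain_map[cdr_name]
    out = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        frame_struct = ensemble.topology.with_positions(ensemble.frames[f])
        out[f] = compute_asa(frame_struct, sel, probe_radius, n_sphere_points).total_area
    return out


def domain_widths(
    structure: BeadStructure, selection: Sequence[int]
) -> tuple[float, float]:
    """(max_width, min_width) of a selection, in nm.

    max_width is the largest pairwise centre distance. min_width is the
    smallest extent of the selection along the three principal axes of its
    coordinate covariance — a global "thickness", not a pairwise minimum.
    Halving these gives the probe radius and the clearance threshold used
    elsewhere.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size < 2:
        raise ValueError("selection must contain at least 2 beads")
    pts = structure.positions[selection]
    from scipy.spatial.distance import pdist

    max_width = float(pdist(pts).max())
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    _, vecs = np.linalg.eigh(cov)
    proj = centered @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    return max_width, float(extents.min())


def _obstruction_indices(
    domain_map: DomainMap, fab_name: str, exclusions: Iterable[str]
) -> np.ndarray:
    """Bead indices of all domains outside the exclusion set (host Fab always excluded)."""
    excluded = set(exclusions) | {fab_name}
    cdr_name = domain_map.cdr_of.get(fab_name)
    if cdr_name is not None:
        excluded.add(cdr_name)
    fab_beads = set(domain_map[fab_name].tolist())
    obst: set[int] = set()
    for name, idx in domain_map.domains.items():
        if name in excluded:
            continue
        obst.update(int(i) for i in idx if int(i) not in fab_beads)
    return np.fromiter(sorted(obst), dtype=int, count=len(obst))


def _residue_groups(topology: BeadStructure, indices: np.ndarray) -> list[np.ndarray]:
    """Partition a bead index set by (chain, residue)."""
    keys: dict[tuple, list[int]] = {}
    for i in indices:
        key = (str(topology.chain_ids[i]), int(topology.residue_indices[i]))
        keys.setdefault(key, []).append(int(i))
    return [np.asarray(v, dtype=int) for v in keys.values()]


def nearest_obstruction_distance(
    frame: np.ndarray,
    domain_map: DomainMap,
    fab_name: str,
    exclusions: Iterable[str] = (),
    obstruction_mode: str = "bead",
    topology: BeadStructure | None = None,
) -> float:
    """Distance (nm) from a Fab's CDR centre of mass to the nearest obstruction.

    The CDR centre of mass is the unweighted mean of its bead positions.
    Obstruction beads are every bead of every domain not in ``exclusions``;
    the host Fab (and therefore its CDR) is always excluded. Returns ``inf``
    when no obstruction beads exist.

    ``obstruction_mode="bead"`` (default) measures to the nearest bead
    centre; ``"residue"`` measures to the nearest residue centre of mass,
    which requires ``topology`` for the residue grouping.
    """
    if fab_name not in domain_map:
        raise KeyError(f"unknown Fab {fab_name!r}")
    cdr_name = domain_map.cdr_of.get(fab_name)
    if cdr_name is None:
        raise KeyError(f"Fab {fab_name!r} has no CDR link in the domain map")
    frame = np.asarray(frame, dtype=float)
    com = frame[domain_map[cdr_name]].mean(axis=0)
    obst = _obstruction_indices(domain_map, fab_name, exclusions)
    if obst.size == 0:
        return float("inf")
    if obstruction_mode == "bead":
        targets = frame[obst]
    elif obstruction_mode == "residue":
        if topology is None:
            raise ValueError("obstruction_mode='residue' requires a topology")
        targets = np.stack([frame[g].mean(axis=0) for g in _residue_groups(topology, obst)])
    else:
        raise ValueError(f"unknown obstruction_mode {obstruction_mode!r}")
    return float(np.sqrt(((targets - com) ** 2).sum(axis=1)).min())


def binding_accessibility(
    ensembles: Sequence[Ensemble] | Ensemble,
    domain_map: DomainMap,
    threshold: float = DEFAULT_THRESHOLD,
    exclude_glycans: bool = False,
    obstruction_mode: str = "bead",
) -> AccessibilityResult:
    """Simultaneous-binding probability pooled over every (frame, Fab) configuration.

    For each ensemble, frame and Fab, the nearest-obstruction distance is
    computed; a configuration counts as accessible iff distance ≥ threshold.
    Glycan domains (names starting with ``glycan``) obstruct by default;
    ``exclude_glycans=True`` drops them, for the reading in which only
    protein domains block the receptor. ``obstruction_mode`` selects bead
    centres (default) or residue centres of mass as the obstruction points.
    """
    if isinstance(ensembles, Ensemble):
        ensembles = [ensembles]
    if not domain_map.fab_ids:
        raise ValueError("domain map lists no Fab domains")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n_beads = ensembles[0].n_beads
    for ens in ensembles:
        if ens.n_beads != n_beads:
            raise ValueError("all ensembles must share the topology")

    exclusions: tuple[str, ...] = ()
    if exclude_glycans:
        exclusions = tuple(
            name for name in domain_map.domains if name.lower().startswith("glycan")
        )

    all_dists: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for ens in ensembles:
        frames = ens.frames
        for fab in domain_map.fab_ids:
            cdr_name = domain_map.cdr_of.get(fab)
            if cdr_name is None:
                raise KeyError(f"Fab {fab!r} has no CDR link in the domain map")
            coms = frames[:, domain_map[cdr_name]].mean(axis=1)  # (F, 3)
            obst = _obstruction_indices(domain_map, fab, exclusions)
            if obst.size:
                if obstruction_mode == "residue":
                    groups = _residue_groups(ens.topology, obst)
                    targets = np.stack(
                        [frames[:, g].mean(axis=1) for g in groups], axis=1
                    )  # (F, n_res, 3)
                elif obstruction_mode == "bead":
                    targets = frames[:, obst]
                else:
                    raise ValueError(f"unknown obstruction_mode {obstruction_mode!r}")
                diff = targets - coms[:, None, :]
                d = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
            else:
                d = np.full(ens.n_frames, np.inf)
            all_dists.append(d)
            all_labels.append(np.full(ens.n_frames, fab, dtype="U16"))

    distances = np.concatenate(all_dists)
    labels = np.concatenate(all_labels)
    accessible = distances >= threshold
    per_fab = {
        fab: float(accessible[labels == fab].mean()) for fab in domain_map.fab_ids
    }
    return AccessibilityResult(
        distances=distances,
        fab_labels=labels,
        threshold=threshold,
        per_fab_probability=per_fab,
        overall_probability=float(accessible.mean()),
        n_configurations=int(distances.size),
    )
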
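"""Core containers for bead-resolution structures, ensembles, domain maps
and umbrella-sampling windows.

All lengths are in nanometres, energies in kJ/mol, force constants in
kJ mol⁻¹ nm⁻², times in nanoseconds. File readers convert at the boundary
(PDB stores ångström; the readers multiply by 0.1 on the way in).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeadStructure",
    "Ensemble",
    "DomainMap",
    "UmbrellaWindow",
    "DEFAULT_BEAD_RADIUS",
]

#: Half of a typical 0.47 nm coarse-grained bead diameter.
DEFAULT_BEAD_RADIUS = 0.235


@dataclass
class BeadStructure:
    """A static bead-resolution structure.

    Parameters
    ----------
    positions
        ``(n_beads, 3)`` array of coordinates in nm.
    radii
        ``(n_beads,)`` array of bead radii in nm (all > 0).
    chain_ids, residue_indices, residue_names, bead_names
        Per-bead annotations. ``(chain_id, residue_index, bead_name)``
        must be unique within a structure.
    """

    positions: np.ndarray
    radii: np.ndarray
    chain_ids: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    bead_names: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U8")
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype="U8")
        self.bead_names = np.asarray(self.bead_names, dtype="U8")
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        if n == 0:
            raise ValueError("structure must contain at least one bead")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError("radii must be positive, one per bead")
        for name, arr in (
            ("chain_ids", self.chain_ids),
            ("residue_indices", self.residue_indices),
            ("residue_names", self.residue_names),
            ("bead_names", self.bead_names),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
        keys = set(zip(self.chain_ids.tolist(), self.residue_indices.tolist(), self.bead_names.tolist()))
        if len(keys) != n:
            raise ValueError("(chain_id, residue_index, bead_name) must be unique per bead")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def with_positions(self, positions: np.ndarray) -> "BeadStructure":
        """Copy of this structure with new coordinates (same topology)."""
        return BeadStructure(
            positions=np.asarray(positions, dtype=float),
            radii=self.radii.copy(),
            chain_ids=self.chain_ids.copy(),
            residue_indices=self.residue_indices.copy(),
            residue_names=self.residue_names.copy(),
            bead_names=self.bead_names.copy(),
        )


@dataclass
class Ensemble:
    """An ordered set of conformations over a fixed bead topology.

    ``frames`` is ``(n_frames, n_beads, 3)`` in nm; ``frame_spacing`` is the
    time between consecutive frames in ns. The topology's own coordinates
    are ignored.
    """

    topology: BeadStructure
    frames: np.ndarray
    frame_spacing: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_beads, 3)")
        if self.frames.shape[1] != self.topology.n_beads:
            raise ValueError(
                f"frames have {self.frames.shape[1]} beads but topology has "
                f"{self.topology.n_beads}"
            )
        if self.frames.shape[0] == 0:
            raise ValueError("ensemble must contain at least one frame")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ns, starting at 0."""
        return np.arange(self.n_frames) * self.frame_spacing


@dataclass
class DomainMap:
    """Named bead selections over a topology.

    ``domains`` maps a name (``"Fc"``, ``"Fab_3"``, ``"CDR_3"``, ...) to a
    sorted integer index array. ``fab_ids`` lists the Fab domain names in
    order; ``cdr_of`` links each Fab to its CDR selection name.
    """

    domains: dict
    fab_ids: list = field(default_factory=list)
    cdr_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.domains = {
            str(k): np.unique(np.asarray(v, dtype=int)) for k, v in self.domains.items()
        }
        for fab in self.fab_ids:
            if fab not in self.domains:
                raise ValueError(f"fab_ids entry {fab!r} is not a domain")
        for fab, cdr in self.cdr_of.items():
            if fab not in self.domains or cdr not in self.domains:
                raise ValueError(f"cdr_of link {fab!r} -> {cdr!r} names unknown domains")
            if not np.all(np.isin(self.domains[cdr], self.domains[fab])):
                raise ValueError(f"CDR {cdr!r} is not a subset of its Fab {fab!r}")

    def validate_against(self, topology: BeadStructure) -> None:
        n = topology.n_beads
        for name, idx in self.domains.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"domain {name!r} has indices outside [0, {n})")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.domains[name]

    def __contains__(self, name: str) -> bool:
        return name in self.domains


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling window along a 1D reaction coordinate.

    ``center`` (nm) and ``force_constant`` (kJ mol⁻¹ nm⁻²) define the
    harmonic bias w(x) = ½ k (x − center)²; ``samples`` are reaction
    coordinate values in nm recorded every ``sample_spacing`` ns.
    """

    center: float
    force_constant: float
    samples: np.ndarray
    sample_spacing: float = 1.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.samples.size == 0:
            raise ValueError("window must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def bias(self, x: np.ndarray) -> np.ndarray:
        """Bias energy w(x) in kJ/mol."""
        return 0.5 * self.force_constant * (np.asarray(x) - self.center) ** 2
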
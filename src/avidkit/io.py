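"""Readers and writers for structures, ensembles, domain maps and
umbrella-sampling window data.

PDB files store ångström; everything in memory is nm (exact ×0.1 / ×10
conversion at the boundary). Domain maps are YAML; umbrella manifests are
three-column text (window file path, bias center, force constant) and the
window files themselves two-column time/coordinate text in which comment
lines start with ``#`` or ``@`` — the dialect common pulling codes emit.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

from .core import DEFAULT_BEAD_RADIUS, BeadStructure, DomainMap, Ensemble, UmbrellaWindow

__all__ = [
    "read_structure",
    "write_structure",
    "read_ensemble",
    "write_ensemble",
    "read_xyz",
    "write_xyz",
    "load_domain_map",
    "write_domain_map",
    "read_umbrella_manifest",
    "write_umbrella_windows",
]

ANGSTROM_PER_NM = 10.0


def _structure_from_atom_array(
    atoms: AtomArray,
    radius_table: Mapping[str, float] | None,
    default_radius: float,
) -> BeadStructure:
    radius_table = radius_table or {}
    names = atoms.atom_name
    radii = np.array([radius_table.get(n, default_radius) for n in names], dtype=float)
    return BeadStructure(
        positions=atoms.coord / ANGSTROM_PER_NM,
        radii=radii,
        chain_ids=atoms.chain_id,
        residue_indices=atoms.res_id,
        residue_names=atoms.res_name,
        bead_names=names,
    )


def read_structure(
    path: str | os.PathLike,
    radius_table: Mapping[str, float] | None = None,
    default_radius: float = DEFAULT_BEAD_RADIUS,
) -> BeadStructure:
    """Read a bead structure from a PDB file (first model of a multi-model file).

    Radii are assigned from ``radius_table`` by bead name, falling back to
    ``default_radius`` (0.235 nm, half a standard CG bead diameter).
    """
    pdb = PDBFile.read(str(path))
    if pdb.get_model_count() < 1:
        raise ValueError(f"{path}: no models / atoms found")
    atoms = pdb.get_structure(model=1)
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: zero atoms")
    return _structure_from_atom_array(atoms, radius_table, default_radius)


def _atom_array_template(structure: BeadStructure) -> AtomArray:
    n = structure.n_beads
    atoms = AtomArray(n)
    atoms.chain_id = structure.chain_ids
    atoms.res_id = structure.residue_indices
    atoms.res_name = structure.residue_names
    atoms.atom_name = structure.bead_names
    atoms.element = np.full(n, "C", dtype="U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    return atoms


def write_structure(structure: BeadStructure, path: str | os.PathLike) -> None:
    """Write a structure as a single-model PDB (coordinates written in Å)."""
    atoms = _atom_array_template(structure)
    atoms.coord = structure.positions * ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_ensemble(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a multi-model PDB."""
    template = _atom_array_template(ensemble.topology)
    stack = AtomArrayStack(ensemble.n_frames, ensemble.n_beads)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = ensemble.frames * ANGSTROM_PER_NM
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble(
    paths: str | os.PathLike | Sequence[str | os.PathLike],
    frame_spacing: float = 1.0,
    label: str = "",
    radius_table: Mapping[str, float] | None = None,
    default_radius: float = DEFAULT_BEAD_RADIUS,
) -> Ensemble:
    """Read an ensemble from one multi-model PDB or an ordered series of files.

    The topology is taken from the first frame; every frame must have the
    same bead count. XYZ files (extension ``.xyz``) are accepted in a series.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    if len(paths) == 0:
        raise ValueError("no input files given")

    frames: list[np.ndarray] = []
    topology: BeadStructure | None = None
    for p in paths:
        p = Path(p)
        if p.suffix.lower() == ".xyz":
            struct = read_xyz(p, default_radius=default_radius)
            coords = [struct.positions]
        else:
            pdb = PDBFile.read(str(p))
            stack = pdb.get_structure(model=None)
            if stack.array_length() == 0:
                raise ValueError(f"{p}: zero atoms")
            struct = _structure_from_atom_array(stack[0], radius_table, default_radius)
            coords = [stack.coord[i] / ANGSTROM_PER_NM for i in range(stack.stack_depth())]
        if topology is None:
            topology = struct
        elif struct.n_beads != topology.n_beads:
            raise ValueError(
                f"{p}: bead count {struct.n_beads} does not match first frame "
                f"({topology.n_beads})"
            )
        frames.extend(coords)
    assert topology is not None
    return Ensemble(
        topology=topology,
        frames=np.stack(frames),
        frame_spacing=frame_spacing,
        label=label,
    )


def read_xyz(path: str | os.PathLike, default_radius: float = DEFAULT_BEAD_RADIUS) -> BeadStructure:
    """Read a single-frame XYZ file (coordinates in Å, converted to nm).

    XYZ carries no chain/residue annotation: beads land on chain ``A`` with
    residue index equal to bead index.
    """
    with open(path) as fh:
        header = fh.readline()
        try:
            n = int(header.strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed XYZ header") from exc
        fh.readline()  # comment
        names, coords = [], []
        for _ in range(n):
            parts = fh.readline().split()
            if len(parts) < 4:
                raise ValueError(f"{path}: truncated XYZ record")
            names.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
    coords_nm = np.asarray(coords) / ANGSTROM_PER_NM
    n = len(names)
    return BeadStructure(
        positions=coords_nm,
        radii=np.full(n, default_radius),
        chain_ids=np.full(n, "A"),
        residue_indices=np.arange(n),
        residue_names=np.full(n, "UNK"),
        bead_names=np.asarray(names),
    )


def write_xyz(structure: BeadStructure, path: str | os.PathLike, comment: str = "") -> None:
    """Write a structure as XYZ (coordinates in Å)."""
    with open(path, "w") as fh:
        fh.write(f"{structure.n_beads}\n{comment}\n")
        for name, pos in zip(structure.bead_names, structure.positions * ANGSTROM_PER_NM):
            fh.write(f"{name} {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f}\n")


# ---------------------------------------------------------------------------
# Domain maps
# ---------------------------------------------------------------------------


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise ValueError(f"duplicate key {key!r} in domain-map config")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping
)


def _resolve_selector(sel: Mapping, topology: BeadStructure) -> np.ndarray:
    if "indices" in sel:
        return np.asarray(sel["indices"], dtype=int)
    mask = np.ones(topology.n_beads, dtype=bool)
    if "chains" in sel:
        chains = [str(c) for c in sel["chains"]]
        mask &= np.isin(topology.chain_ids, chains)
    if "residues" in sel:
        lo, hi = sel["residues"]
        mask &= (topology.residue_indices >= int(lo)) & (topology.residue_indices <= int(hi))
    if "bead_names" in sel:
        mask &= np.isin(topology.bead_names, [str(b) for b in sel["bead_names"]])
    return np.flatnonzero(mask)


def load_domain_map(path: str | os.PathLike, topology: BeadStructure) -> DomainMap:
    """Load a YAML domain map and resolve every selection to bead indices.

    Config layout::

        domains:
          Fc:
            - {chains: [A, B]}
          Fab_1:
            - {chains: [F], residues: [1, 220]}
          CDR_1:
            - {chains: [F], residues: [210, 220]}
        fabs: [Fab_1]
        cdr_of: {Fab_1: CDR_1}

    Each domain is a list of selector mappings (keys ``chains``,
    ``residues: [lo, hi]``, ``bead_names``, or explicit ``indices``); the
    selection is the union over selectors. Resolution is deterministic and
    order-independent (indices are returned sorted).
    """
    with open(path) as fh:
        config = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(config, Mapping) or "domains" not in config:
        raise ValueError(f"{path}: config must contain a 'domains' mapping")
    domains: dict[str, np.ndarray] = {}
    for name, selectors in config["domains"].items():
        if isinstance(selectors, Mapping):
            selectors = [selectors]
        idx_parts = [_resolve_selector(sel, topology) for sel in selectors]
        idx = np.unique(np.concatenate(idx_parts)) if idx_parts else np.array([], dtype=int)
        if idx.size == 0:
            raise ValueError(f"{path}: selection {name!r} resolves to no beads")
        if idx.min() < 0 or idx.max() >= topology.n_beads:
            raise ValueError(f"{path}: selection {name!r} has out-of-range indices")
        domains[str(name)] = idx
    dmap = DomainMap(
        domains=domains,
        fab_ids=[str(f) for f in config.get("fabs", [])],
        cdr_of={str(k): str(v) for k, v in (config.get("cdr_of") or {}).items()},
    )
    dmap.validate_against(topology)
    return dmap


def write_domain_map(domain_map: DomainMap, path: str | os.PathLike) -> None:
    """Write a domain map as YAML with explicit bead indices."""
    config = {
        "domains": {
            name: [{"indices": idx.tolist()}] for name, idx in domain_map.domains.items()
        },
        "fabs": list(domain_map.fab_ids),
        "cdr_of": dict(domain_map.cdr_of),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Umbrella windows
# ---------------------------------------------------------------------------


def _read_window_file(path: Path) -> tuple[np.ndarray, float]:
    try:
        data = np.loadtxt(path, comments=["#", "@"], ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric sample data") from exc
    if data.size == 0:
        raise ValueError(f"{path}: empty window file")
    if data.shape[1] >= 2:
        times, samples = data[:, 0], data[:, 1]
        spacing = float(times[1] - times[0]) if len(times) > 1 else 1.0
    else:
        samples, spacing = data[:, 0], 1.0
    return samples, spacing if spacing > 0 else 1.0


def read_umbrella_manifest(path: str | os.PathLike) -> list[UmbrellaWindow]:
    """Read an umbrella manifest: one window per row ``path center force_constant``.

    Window file paths are resolved relative to the manifest's directory.
    Window files are two-column (time, coordinate) text; lines starting with
    ``#`` or ``@`` are skipped.
    """
    manifest_dir = Path(path).parent
    windows: list[UmbrellaWindow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'path center force_constant'")
            wpath = manifest_dir / parts[0]
            if not wpath.exists():
                raise FileNotFoundError(f"{path}:{lineno}: window file not found: {wpath}")
            samples, spacing = _read_window_file(wpath)
            windows.append(
                UmbrellaWindow(
                    center=float(parts[1]),
                    force_constant=float(parts[2]),
                    samples=samples,
                    sample_spacing=spacing,
                )
            )
    if not windows:
        raise ValueError(f"{path}: manifest lists no windows")
    return windows


def write_umbrella_windows(
    windows: Sequence[UmbrellaWindow],
    directory: str | os.PathLike,
    manifest_name: str = "manifest.txt",
) -> Path:
    """Write window sample files plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / manifest_name
    with open(manifest, "w") as mfh:
        mfh.write("# window_file  center_nm  force_constant_kJ_mol_nm2\n")
        for i, win in enumerate(windows):
            fname = f"window_{i:04d}.xvg"
            times = np.arange(win.n_samples) * win.sample_spacing
            with open(directory / fname, "w") as wfh:
                wfh.write("@ title \"reaction coordinate\"\n")
                wfh.write("# time_ns  coordinate_nm\n")
                for t, x in zip(times, win.samples):
                    wfh.write(f"{t:.6g} {x:.10g}\n")
            mfh.write(f"{fname} {win.center:.10g} {win.force_constant:.10g}\n")
    return manifest
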
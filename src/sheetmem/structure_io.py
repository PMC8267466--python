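"""Reading and writing standard coordinate formats (GRO, PDB, XYZ).

Thin wrappers over MDAnalysis.  Internally the package works in nm;
MDAnalysis exposes Angstrom, so positions are scaled by 10 on the way
out and 0.1 on the way in (this also covers the PDB Angstrom
convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["StructureFrame", "read_structure", "write_structure", "write_sheet"]

_FORMATS = {".gro": "GRO", ".pdb": "PDB", ".xyz": "XYZ"}


@dataclass
class StructureFrame:
    """A static structure: names, positions (nm) and box (nm) if present."""

    names: np.ndarray
    positions: np.ndarray
    box: np.ndarray | None
    resnames: np.ndarray | None = None


def _resolve_format(path, fmt):
    if fmt is not None:
        fmt = fmt.upper()
        if fmt not in _FORMATS.values():
            raise ValueError(f"unrecognised structure format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix not in _FORMATS:
        raise ValueError(f"cannot infer structure format from suffix {suffix!r}")
    return _FORMATS[suffix]


def read_structure(path, fmt: str | None = None) -> StructureFrame:
    """Read a single-frame GRO/PDB/XYZ structure into nm coordinates."""
    import MDAnalysis as mda

    fmt = _resolve_format(path, fmt)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(str(path), format=fmt, topology_format=fmt)
        positions = u.atoms.positions / 10.0  # A -> nm
        names = np.array(
            u.atoms.names if hasattr(u.atoms, "names") else [""] * len(u.atoms)
        )
        resnames = (
            np.array(u.atoms.resnames) if hasattr(u.atoms, "resnames") else None
        )
        box = None
        if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
            box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    except (ValueError, OSError, EOFError, IndexError) as exc:
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    return StructureFrame(names=names, positions=positions, box=box, resnames=resnames)


def write_structure(
    path,
    names,
    positions_nm,
    box_nm=None,
    resname: str = "MOL",
    fmt: str | None = None,
) -> None:
    """Write a single frame; GRO in nm, PDB/XYZ in Angstrom conventions."""
    import MDAnalysis as mda

    fmt = _resolve_format(path, fmt)
    names = list(names)
    n = len(names)
    u = mda.Universe.empty(n_atoms=n, n_residues=1, trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", [resname])
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("elements", [str(x)[:2] for x in names])
    u.atoms.positions = np.asarray(positions_nm, dtype=float) * 10.0
    if box_nm is not None:
        u.dimensions = [
            box_nm[0] * 10.0, box_nm[1] * 10.0, box_nm[2] * 10.0, 90.0, 90.0, 90.0,
        ]
    u.atoms.write(str(path))


def write_sheet(sheet, path, fmt: str | None = None) -> None:
    """Write a nanosheet's coordinates as PDB or GRO (residue MOS)."""
    box = None
    span = np.ptp(sheet.positions, axis=0) + 2.0
    box = np.maximum(span, 1.0)
    write_structure(
        path, list(sheet.elements), sheet.positions, box_nm=box, resname="MOS", fmt=fmt
    )
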
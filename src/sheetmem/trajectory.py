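"""Trajectory and frame containers plus the package's frame-stream format.

A trajectory stores ordered frames (time, positions, box) for one fixed
topology.  The box is periodic in x and y only; z is open (slab
geometry), so minimum-image conventions apply to the first two axes.

On disk a trajectory is either a concatenated-GRO text file (written via
MDAnalysis) or the package's documented binary stream:

    header: magic b"SMTRJ1", int32 n_atoms, float32 dt_hint,
            3x float32 box (nm)
    frame:  float32 time (ps), n_atoms x 3 float32 positions (nm)

The binary reader/writer round-trips exactly at float32 precision.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_MAGIC = b"SMTRJ1"

SHEET_KINDS = ("Mo", "S")


@dataclass
class Topology:
    """Per-atom labels shared by all frames of a trajectory.

    kinds: "Mo"/"S" for sheet atoms, "head"/"tail" for lipid beads,
    "water" for water oxygens.  lipid_id is -1 for non-lipid atoms;
    chain_pos is the bead's index along its lipid chain (-1 for heads
    and non-lipids).
    """

    kinds: np.ndarray
    lipid_id: np.ndarray
    leaflet: np.ndarray
    chain_pos: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.kinds)
        for name in ("lipid_id", "leaflet", "chain_pos", "masses"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name} has inconsistent length")

    @property
    def n_atoms(self) -> int:
        return len(self.kinds)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "kinds": list(map(str, self.kinds)),
                "lipid_id": [int(x) for x in self.lipid_id],
                "leaflet": list(map(str, self.leaflet)),
                "chain_pos": [int(x) for x in self.chain_pos],
                "masses": [float(x) for x in self.masses],
            }
        )

    @staticmethod
    def from_json(text: str) -> "Topology":
        import json

        d = json.loads(text)
        return Topology(
            kinds=np.array(d["kinds"]),
            lipid_id=np.array(d["lipid_id"], dtype=int),
            leaflet=np.array(d["leaflet"]),
            chain_pos=np.array(d["chain_pos"], dtype=int),
            masses=np.array(d["masses"], dtype=float),
        )

    @property
    def sheet_indices(self) -> np.ndarray:
        return np.flatnonzero(np.isin(self.kinds, SHEET_KINDS))

    @property
    def lipid_indices(self) -> np.ndarray:
        return np.flatnonzero(self.lipid_id >= 0)

    @property
    def water_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == "water")

    @property
    def head_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == "head")

    @property
    def tail_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == "tail")


@dataclass
class Frame:
    """One snapshot: positions (nm), box (nm, periodic in x,y), time (ps)."""

    positions: np.ndarray
    box: np.ndarray
    topology: Topology
    time: float = 0.0


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology."""

    topology: Topology
    times: np.ndarray  # (n_frames,), ps
    positions: np.ndarray  # (n_frames, n_atoms, 3), nm
    box: np.ndarray  # (3,), nm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions disagree on frame count")
        if self.positions.shape[1] != self.topology.n_atoms:
            raise ValueError("positions disagree with topology on atom count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Frame:
        return Frame(self.positions[i], self.box, self.topology, float(self.times[i]))

    def __iter__(self):
        return (self.frame(i) for i in range(self.n_frames))

    # ------------------------------------------------------------------
    # binary frame stream
    # ------------------------------------------------------------------
    def write_binary(self, path) -> None:
        dt_hint = float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<i", self.topology.n_atoms))
            fh.write(struct.pack("<f", dt_hint))
            fh.write(np.asarray(self.box, dtype="<f4").tobytes())
            for i in range(self.n_frames):
                fh.write(struct.pack("<f", float(self.times[i])))
                fh.write(np.ascontiguousarray(self.positions[i], dtype="<f4").tobytes())

    @staticmethod
    def read_binary(path, topology: Topology) -> "Trajectory":
        raw = Path(path).read_bytes()
        if raw[:6] != _MAGIC:
            raise ValueError(f"{path}: not a sheetmem trajectory stream")
        (n_atoms,) = struct.unpack_from("<i", raw, 6)
        if n_atoms != topology.n_atoms:
            raise ValueError(
                f"{path}: stream has {n_atoms} atoms, topology has {topology.n_atoms}"
            )
        box = np.frombuffer(raw, dtype="<f4", count=3, offset=14).astype(np.float32)
        off = 26
        frame_bytes = 4 + 12 * n_atoms
        body = raw[off:]
        if len(body) % frame_bytes:
            raise ValueError(f"{path}: truncated frame stream")
        n_frames = len(body) // frame_bytes
        times = np.empty(n_frames)
        pos = np.empty((n_frames, n_atoms, 3), dtype=np.float32)
        for i in range(n_frames):
            start = off + i * frame_bytes
            (times[i],) = struct.unpack_from("<f", raw, start)
            pos[i] = np.frombuffer(
                raw, dtype="<f4", count=3 * n_atoms, offset=start + 4
            ).reshape(n_atoms, 3)
        return Trajectory(topology, times, pos, box.astype(float))

    # ------------------------------------------------------------------
    # concatenated GRO frames (text), via MDAnalysis
    # ------------------------------------------------------------------
    def write_gro(self, path) -> None:
        import MDAnalysis as mda

        u = _as_universe(self.topology, self.positions[0], self.box)
        with open(path, "w") as out:
            tmp = Path(str(path) + ".frame.tmp.gro")
            try:
                for i in range(self.n_frames):
                    u.atoms.positions = self.positions[i] * 10.0  # nm -> A
                    u.trajectory.ts.data["time"] = float(self.times[i])
                    u.atoms.write(str(tmp))
                    out.write(tmp.read_text())
            finally:
                tmp.unlink(missing_ok=True)


_KIND_NAMES = {"Mo": ("MOS", "MO"), "S": ("MOS", "S"), "head": ("LIP", "H"),
               "tail": ("LIP", "T"), "water": ("SOL", "OW")}


def _as_universe(top: Topology, positions_nm: np.ndarray, box_nm: np.ndarray):
    import MDAnalysis as mda

    n = top.n_atoms
    # one residue per lipid; sheet and waters get their own residues
    resid_key = []
    for i in range(n):
        if top.lipid_id[i] >= 0:
            resid_key.append(("LIP", int(top.lipid_id[i])))
        elif top.kinds[i] in SHEET_KINDS:
            resid_key.append(("MOS", 0))
        else:
            resid_key.append(("SOL", i))
    uniq = {}
    res_index = np.empty(n, dtype=int)
    for i, key in enumerate(resid_key):
        res_index[i] = uniq.setdefault(key, len(uniq))
    u = mda.Universe.empty(
        n_atoms=n, n_residues=len(uniq), atom_resindex=res_index, trajectory=True
    )
    names = [_KIND_NAMES[k][1] for k in top.kinds]
    resnames = [""] * len(uniq)
    for i, key in enumerate(resid_key):
        resnames[res_index[i]] = key[0]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, len(uniq) + 1))
    u.add_TopologyAttr("masses", top.masses)
    u.atoms.positions = np.asarray(positions_nm) * 10.0
    u.dimensions = [box_nm[0] * 10, box_nm[1] * 10, box_nm[2] * 10, 90, 90, 90]
    return u
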
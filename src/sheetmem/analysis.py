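"""Per-trajectory statistics for the nanosheet-membrane system.

Implements the study's observables: sheet-lipid atom contacts (total and
head/tail split), bound surface waters, centre-of-mass insertion depth,
van der Waals / Coulomb interaction-energy decomposition, the lipid
chain order parameter S_chain = 0.5<3 cos^2 theta - 1>, membrane
thickness (global and local), local lipid selections, insertion-time
detection, and multi-trajectory tail-window summaries.

Distances honour the slab periodicity (minimum image in x,y; open z).
Neighbour searches go through a KD-tree over the 3x3 in-plane periodic
images; brute-force double loops in the test-suite serve as the
independent oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import DEFAULT_CUTOFF
from .membrane import pair_energy
from .nanosheet import SpeciesParams
from .trajectory import Frame, Trajectory

__all__ = [
    "ContactCriterion",
    "AnalysisSeries",
    "OrderParameterResult",
    "count_contacts",
    "split_head_tail_contacts",
    "count_bound_waters",
    "com_distance_z",
    "interaction_energy",
    "chain_order",
    "local_lipid_selection",
    "membrane_thickness",
    "insertion_time",
    "batch_summary",
    "series_over_trajectory",
]


@dataclass(frozen=True)
class ContactCriterion:
    """Atom-atom contact rule: centre distance strictly below cutoff."""

    cutoff: float = 0.5  # nm (the 5 A criterion)
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if not (self.cutoff > 0):
            raise ValueError("contact cutoff must be positive")


@dataclass
class AnalysisSeries:
    """Time-indexed scalar series with provenance parameters."""

    times: np.ndarray  # ps
    values: np.ndarray
    label: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")

    def tail_mean(self, window: float) -> float:
        """Mean over the final ``window`` ps of the series."""
        span = self.times[-1] - self.times[0]
        if window > span:
            raise ValueError(
                f"averaging window {window} ps exceeds series span {span} ps"
            )
        mask = self.times >= self.times[-1] - window
        return float(self.values[mask].mean())


@dataclass
class OrderParameterResult:
    """Chain order parameter with the per-chain tilt angles behind it."""

    s_chain: float
    angles: np.ndarray  # radians
    selection: str = "all"


# ----------------------------------------------------------------------
# neighbour machinery (KD-tree over in-plane periodic images)
# ----------------------------------------------------------------------
def _image_shifts(box):
    sx, sy = box[0], box[1]
    return np.array(
        [(ix * sx, iy * sy, 0.0) for ix in (-1, 0, 1) for iy in (-1, 0, 1)]
    )


def _min_dist_to_group(query: np.ndarray, group: np.ndarray, box, cutoff: float):
    """Per-query minimum distance to any group atom, inf beyond cutoff."""
    shifts = _image_shifts(box)
    tiled = (group[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tree = cKDTree(tiled)
    d, _ = tree.query(query, k=1, distance_upper_bound=cutoff * (1 + 1e-12))
    return d


def _pairs_within(a: np.ndarray, b: np.ndarray, box, cutoff: float):
    """(i, j, r) for all a-b pairs with minimum-image distance < cutoff."""
    shifts = _image_shifts(box)
    tiled = (a[None, :, :] + shifts[:, None, :]).reshape(-1, 3)
    tree_a = cKDTree(tiled)
    tree_b = cKDTree(b)
    pairs = tree_b.query_ball_tree(tree_a, r=cutoff)
    na = len(a)
    out_i, out_j, out_r = [], [], []
    for j, hits in enumerate(pairs):
        if not hits:
            continue
        hits = np.asarray(hits)
        d = np.linalg.norm(tiled[hits] - b[j], axis=1)
        keep = d < cutoff
        # the same a-atom can appear via several images; keep the nearest
        ai = hits[keep] % na
        dk = d[keep]
        order = np.argsort(dk)
        seen = {}
        for idx in order:
            if ai[idx] not in seen:
                seen[ai[idx]] = dk[idx]
        for i, r in seen.items():
            out_i.append(i)
            out_j.append(j)
            out_r.append(r)
    return np.array(out_i, int), np.array(out_j, int), np.array(out_r, float)


def _heavy_filter(frame: Frame, indices: np.ndarray, heavy_only: bool) -> np.ndarray:
    if not heavy_only:
        return indices
    kinds = frame.topology.kinds[indices]
    return indices[kinds != "H"]


# ----------------------------------------------------------------------
# contacts and hydration
# ----------------------------------------------------------------------
def count_contacts(
    frame: Frame,
    group_a: np.ndarray,
    group_b: np.ndarray,
    criterion: ContactCriterion = ContactCriterion(),
) -> int:
    """Number of group_b atoms with at least one group_a atom in contact."""
    group_a = np.asarray(group_a, int)
    group_b = np.asarray(group_b, int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("contact groups must be non-empty")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("contact groups must be disjoint")
    group_a = _heavy_filter(frame, group_a, criterion.heavy_only)
    group_b = _heavy_filter(frame, group_b, criterion.heavy_only)
    d = _min_dist_to_group(
        frame.positions[group_b], frame.positions[group_a], frame.box, criterion.cutoff
    )
    return int(np.sum(d < criterion.cutoff))


def split_head_tail_contacts(
    frame: Frame,
    sheet: np.ndarray,
    membrane: np.ndarray,
    criterion: ContactCriterion = ContactCriterion(),
) -> tuple[int, int]:
    """Sheet-lipid contacts partitioned by head/tail region label."""
    membrane = np.asarray(membrane, int)
    kinds = frame.topology.kinds[membrane]
    if not np.all(np.isin(kinds, ("head", "tail"))):
        raise ValueError("membrane group contains beads without head/tail labels")
    head = membrane[kinds == "head"]
    tail = membrane[kinds == "tail"]
    n_head = count_contacts(frame, sheet, head, criterion) if len(head) else 0
    n_tail = count_contacts(frame, sheet, tail, criterion) if len(tail) else 0
    return n_head, n_tail


def count_bound_waters(
    frame: Frame,
    sheet: np.ndarray,
    water_group: np.ndarray,
    cutoff: float = 0.35,
) -> int:
    """Waters whose oxygen lies within ``cutoff`` of any sheet atom.

    The sheet "surface" is the nearest atom centre; the 3.5 A criterion
    is inclusive (within), unlike the strict contact criterion.
    """
    water_group = np.asarray(water_group, int)
    if len(water_group) == 0:
        return 0
    d = _min_dist_to_group(
        frame.positions[water_group],
        frame.positions[np.asarray(sheet, int)],
        frame.box,
        cutoff,
    )
    return int(np.sum(d <= cutoff))


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------
def com_distance_z(frame: Frame, sheet: np.ndarray, membrane: np.ndarray) -> float:
    """|z_CoM(sheet) - z_CoM(membrane)|, mass weighted, nm."""
    sheet = np.asarray(sheet, int)
    membrane = np.asarray(membrane, int)
    if len(sheet) == 0 or len(membrane) == 0:
        raise ValueError("groups must be non-empty")
    m = frame.topology.masses
    z_s = np.average(frame.positions[sheet, 2], weights=m[sheet])
    z_m = np.average(frame.positions[membrane, 2], weights=m[membrane])
    return float(abs(z_s - z_m))


def interaction_energy(
    frame: Frame,
    sheet: np.ndarray,
    lipid_group: np.ndarray,
    species_of: dict[str, SpeciesParams],
    charges: np.ndarray | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> tuple[float, float]:
    """Pairwise (vdW, Coulomb) sheet-lipid energy within cutoff, kJ/mol.

    ``species_of`` maps each atom kind to its non-bonded parameters;
    ``charges`` optionally overrides per-atom charges (e.g. alternating
    head-bead partials).  Uses the simulator's cut-and-shifted LJ and
    truncated Coulomb so trajectory energies match the dynamics.
    """
    sheet = np.asarray(sheet, int)
    lipid_group = np.asarray(lipid_group, int)
    kinds = frame.topology.kinds
    for idx in np.concatenate([sheet, lipid_group]):
        if kinds[idx] not in species_of:
            raise KeyError(
                f"atom {idx} of kind {kinds[idx]!r} has no non-bonded parameters"
            )
    ii, jj, rr = _pairs_within(
        frame.positions[sheet], frame.positions[lipid_group], frame.box, cutoff
    )
    vdw = coul = 0.0
    for i, j, r in zip(ii, jj, rr):
        sp_a = species_of[kinds[sheet[i]]]
        sp_b = species_of[kinds[lipid_group[j]]]
        if charges is not None:
            sp_a = SpeciesParams(sp_a.element, sp_a.vdw, float(charges[sheet[i]]))
            sp_b = SpeciesParams(sp_b.element, sp_b.vdw, float(charges[lipid_group[j]]))
        v, c = pair_energy(r, sp_a, sp_b, cutoff)
        vdw += v
        coul += c
    return float(vdw), float(coul)


def chain_order(
    frames: Frame | Trajectory,
    membrane: np.ndarray | None = None,
    lipid_subset: np.ndarray | None = None,
    selection: str = "all",
) -> OrderParameterResult:
    """Lipid chain order parameter S_chain = 0.5<3 cos^2 theta - 1>.

    theta is the angle between the bilayer normal (z) and the chain
    vector from the first to the last chain bead of each lipid.  The
    mean runs over chains, and over frames for a trajectory.  S_chain
    is 1 for perfect alignment, -0.5 for chains perpendicular to the
    normal, and 0 for isotropically random orientations.
    """
    frame_list = [frames] if isinstance(frames, Frame) else list(frames)
    angles = []
    for frame in frame_list:
        top = frame.topology
        lipids = np.unique(top.lipid_id[top.lipid_id >= 0])
        if lipid_subset is not None:
            lipids = np.intersect1d(lipids, lipid_subset)
        for lid in lipids:
            chain = np.flatnonzero((top.lipid_id == lid) & (top.chain_pos >= 0))
            if len(chain) < 2:
                raise ValueError(f"lipid {lid} has fewer than 2 chain beads")
            order = chain[np.argsort(top.chain_pos[chain])]
            v = frame.positions[order[-1]] - frame.positions[order[0]]
            norm = np.linalg.norm(v)
            if norm == 0.0:
                warnings.warn(
                    f"lipid {lid}: zero-length chain vector, skipped", stacklevel=2
                )
                continue
            cos_t = np.clip(v[2] / norm, -1.0, 1.0)
            angles.append(np.arccos(cos_t))
    angles = np.asarray(angles)
    if angles.size == 0:
        raise ValueError("no usable chains in selection")
    s = float(np.mean(0.5 * (3.0 * np.cos(angles) ** 2 - 1.0)))
    return OrderParameterResult(s_chain=s, angles=angles, selection=selection)


def local_lipid_selection(
    frame: Frame, sheet: np.ndarray, radius: float = 1.0
) -> np.ndarray:
    """Lipid ids with any atom within ``radius`` of any sheet atom.

    Whole lipids are selected, never fragments.  The default 1.0 nm
    radius is the study's 10 A locality shell.
    """
    if not (radius > 0):
        raise ValueError("selection radius must be positive")
    top = frame.topology
    lipid_atoms = np.flatnonzero(top.lipid_id >= 0)
    if len(lipid_atoms) == 0:
        return np.array([], dtype=int)
    d = _min_dist_to_group(
        frame.positions[lipid_atoms],
        frame.positions[np.asarray(sheet, int)],
        frame.box,
        radius,
    )
    hit = top.lipid_id[lipid_atoms[d <= radius]]
    return np.unique(hit)


def membrane_thickness(
    frame: Frame, lipid_subset: np.ndarray | None = None
) -> float:
    """Inter-leaflet head-plane separation, nm.

    Mean z of upper-leaflet head beads minus mean z of lower-leaflet
    head beads, optionally restricted to a lipid subset (local
    thickness near the sheet).
    """
    top = frame.topology
    mask = top.kinds == "head"
    if lipid_subset is not None:
        mask &= np.isin(top.lipid_id, lipid_subset)
    out = []
    for leaf in ("upper", "lower"):
        sel = mask & (top.leaflet == leaf)
        if not sel.any():
            raise ValueError(f"no head beads in {leaf} leaflet (selection too small?)")
        out.append(frame.positions[sel, 2].mean())
    return float(out[0] - out[1])


def insertion_time(
    traj: Trajectory,
    sustain_window: float | None = None,
) -> float | None:
    """First time the sheet CoM drops below the proximal head plane.

    The crossing must be sustained: the CoM stays below the plane for at
    least ``sustain_window`` ps (default 5% of the trajectory length).
    Returns None if the sheet never (durably) inserts.
    """
    top = traj.topology
    sheet = top.sheet_indices
    heads_upper = np.flatnonzero((top.kinds == "head") & (top.leaflet == "upper"))
    if len(sheet) == 0 or len(heads_upper) == 0:
        raise ValueError("trajectory lacks sheet atoms or upper-leaflet heads")
    span = traj.times[-1] - traj.times[0]
    if sustain_window is None:
        sustain_window = 0.05 * span
    if span <= sustain_window:
        raise ValueError("trajectory shorter than the sustain window")
    m = top.masses[sheet]
    z_com = np.array(
        [np.average(traj.positions[i][sheet, 2], weights=m) for i in range(traj.n_frames)]
    )
    plane = np.array(
        [traj.positions[i][heads_upper, 2].mean() for i in range(traj.n_frames)]
    )
    below = z_com < plane
    for i in np.flatnonzero(below):
        t0 = traj.times[i]
        horizon = (traj.times >= t0) & (traj.times <= t0 + sustain_window)
        if below[horizon].all():
            return float(t0)
    return None


# ----------------------------------------------------------------------
# batch summaries
# ----------------------------------------------------------------------
def series_over_trajectory(traj: Trajectory, stat: str, **kwargs) -> AnalysisSeries:
    """Evaluate a named per-frame statistic over a whole trajectory."""
    top = traj.topology
    sheet = top.sheet_indices
    values = []
    for frame in traj:
        if stat == "contacts":
            values.append(
                count_contacts(
                    frame, sheet, top.lipid_indices,
                    kwargs.get("criterion", ContactCriterion()),
                )
            )
        elif stat == "bound_waters":
            values.append(
                count_bound_waters(
                    frame, sheet, top.water_indices, kwargs.get("cutoff", 0.35)
                )
            )
        elif stat == "com":
            values.append(com_distance_z(frame, sheet, top.lipid_indices))
        elif stat == "thickness":
            values.append(membrane_thickness(frame))
        elif stat == "schain":
            values.append(chain_order(frame).s_chain)
        elif stat == "schain_local":
            local = local_lipid_selection(frame, sheet, kwargs.get("radius", 1.0))
            if len(local) == 0:
                values.append(np.nan)
            else:
                values.append(chain_order(frame, lipid_subset=local).s_chain)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
    return AnalysisSeries(traj.times.copy(), np.array(values, float), stat, kwargs)


def batch_summary(
    series_by_trajectory: list[dict[str, AnalysisSeries]],
    averaging_window: float,
) -> pd.DataFrame:
    """Tail-window means per trajectory plus across-trajectory mean +/- SE.

    Mirrors the study's protocol of averaging the final stretch of each
    independent run and reporting the spread across replicas.
    """
    if not series_by_trajectory:
        raise ValueError("need at least one trajectory")
    rows = []
    for i, series_map in enumerate(series_by_trajectory):
        for name, series in series_map.items():
            rows.append(
                {
                    "trajectory": i,
                    "statistic": name,
                    "tail_mean": series.tail_mean(averaging_window),
                }
            )
    per_traj = pd.DataFrame(rows)
    agg = per_traj.groupby("statistic")["tail_mean"].agg(["mean", "sem", "count"])
    agg = agg.rename(columns={"sem": "se", "count": "n_trajectories"})
    return per_traj.merge(agg, on="statistic")
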
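"""Triangular MoS2 nanosheet geometry and fresh/aged force-field parameters.

A single 2H-MoS2 layer is a three-plane S-Mo-S sandwich: Mo centres on a
triangular lattice (in-plane constant ``a``), sulfur columns on the
displaced sublattice with one S above and one S below the Mo plane.  The
sheet studied here is an equilateral triangle cut from that lattice.

Surface aging (hydrocarbon contamination in ambient air) is represented
entirely by the Lennard-Jones well depth of the sulfur site, eps_S,
calibrated against the measured water contact angle (WCA): the fresh
surface (WCA ~69 deg) is more hydrophilic and has the deeper sulfur well,
the aged surface (WCA ~90 deg) the shallower one.  All other parameters
are identical between the two states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VdwParams",
    "SpeciesParams",
    "AgingState",
    "NanosheetModel",
    "DEFAULT_LATTICE_A",
    "DEFAULT_MO_S_OFFSET",
    "WCA_FRESH",
    "WCA_AGED",
    "EPS_S_FRESH",
    "EPS_S_AGED",
    "fresh_params",
    "aged_params",
    "build_triangular_nanosheet",
    "assign_aging_state",
    "eps_from_wca",
    "net_charge",
    "species_param_diff",
]

#: In-plane lattice constant of 2H-MoS2, nm.
DEFAULT_LATTICE_A = 0.316
#: Vertical Mo-S offset (half the S-S plane separation), nm.
DEFAULT_MO_S_OFFSET = 0.156

#: Water contact angle anchors (degrees) and the sulfur well depths
#: (kJ/mol) they calibrate to.
WCA_FRESH = 69.0
WCA_AGED = 90.0
EPS_S_FRESH = 1.6744
EPS_S_AGED = 1.0450

_SIGMA_MO = 0.2551
_EPS_MO = 0.5441
_Q_MO = 0.76
_SIGMA_S = 0.3550
_Q_S = -0.38


@dataclass(frozen=True)
class VdwParams:
    """Lennard-Jones parameters in CHARMM-like 4*eps[(s/r)^12-(s/r)^6] form."""

    sigma: float  # nm
    epsilon: float  # kJ/mol

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not (self.epsilon >= 0):
            raise ValueError(f"epsilon must be non-negative, got {self.epsilon}")


@dataclass(frozen=True)
class SpeciesParams:
    """Non-bonded parameters of one atomic species."""

    element: str  # "Mo" or "S"
    vdw: VdwParams
    charge: float  # e


@dataclass(frozen=True)
class AgingState:
    """Complete parameter set for one surface state (fresh or aged)."""

    label: str  # "fresh" or "aged"
    wca: float  # degrees
    species: dict[str, SpeciesParams] = field(compare=False)

    @property
    def eps_s(self) -> float:
        return self.species["S"].vdw.epsilon


def _make_state(label: str, wca: float, eps_s: float) -> AgingState:
    return AgingState(
        label=label,
        wca=wca,
        species={
            "Mo": SpeciesParams("Mo", VdwParams(_SIGMA_MO, _EPS_MO), _Q_MO),
            "S": SpeciesParams("S", VdwParams(_SIGMA_S, eps_s), _Q_S),
        },
    )


def fresh_params() -> AgingState:
    """Packaged parameter set for the freshly exfoliated surface."""
    return _make_state("fresh", WCA_FRESH, EPS_S_FRESH)


def aged_params() -> AgingState:
    """Packaged parameter set for the air-aged surface."""
    return _make_state("aged", WCA_AGED, EPS_S_AGED)


@dataclass(frozen=True)
class NanosheetModel:
    """A rigid triangular MoS2 sheet: atoms, geometry and parameter state."""

    elements: tuple[str, ...]
    positions: np.ndarray  # (n_atoms, 3), nm
    side_length: float  # nm
    aging: AgingState | None = None
    lattice_a: float = DEFAULT_LATTICE_A
    mo_s_offset: float = DEFAULT_MO_S_OFFSET

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    @property
    def masses(self) -> np.ndarray:
        """Atomic masses, g/mol (Mo 95.95, S 32.06)."""
        return np.where(np.asarray(self.elements) == "Mo", 95.95, 32.06)

    def translated(self, shift) -> "NanosheetModel":
        return replace(self, positions=self.positions + np.asarray(shift, float))


def _triangle_inward_normals(side: float):
    """Vertices and inward edge normals of the centred equilateral triangle.

    One vertex lies on the +y axis; the centroid is the origin.
    """
    r = side / math.sqrt(3.0)  # circumradius
    verts = np.array(
        [
            [0.0, r],
            [-side / 2.0, -r / 2.0],
            [side / 2.0, -r / 2.0],
        ]
    )
    normals = []
    offsets = []
    for i in range(3):
        p, q = verts[i], verts[(i + 1) % 3]
        edge = q - p
        n = np.array([-edge[1], edge[0]])
        n /= np.linalg.norm(n)
        if np.dot(n, -p) < 0:  # make it point inward (toward the centroid)
            n = -n
        normals.append(n)
        offsets.append(np.dot(n, p))
    return verts, np.array(normals), np.array(offsets)


def _points_in_triangle(xy: np.ndarray, side: float, tol: float = 1e-6) -> np.ndarray:
    _, normals, offsets = _triangle_inward_normals(side)
    d = xy @ normals.T - offsets  # signed inward distances per edge
    return np.all(d >= -tol, axis=1)


def build_triangular_nanosheet(
    side_length: float,
    lattice_a: float = DEFAULT_LATTICE_A,
    mo_s_offset: float = DEFAULT_MO_S_OFFSET,
) -> NanosheetModel:
    """Cut an equilateral-triangle MoS2 sheet from the 2H lattice.

    The sheet lies in the xy-plane (normal +z) with one vertex toward +y
    and is re-centred at the origin after the cut.  A non-stoichiometric
    cut is neutralised by trimming excess atoms of the over-represented
    species, farthest from the centroid first (ties broken by
    lexicographic position), until Mo:S = 1:2.

    Parameters
    ----------
    side_length : float
        Triangle side, nm.  Must be at least one lattice spacing.
    lattice_a : float
        In-plane lattice constant, nm.
    mo_s_offset : float
        Vertical offset of each sulfur plane from the Mo plane, nm.
    """
    if not np.isfinite(side_length) or side_length < lattice_a - 1e-12:
        raise ValueError(
            "degenerate geometry: side_length "
            f"{side_length!r} nm is smaller than one lattice spacing ({lattice_a} nm)"
        )
    a = lattice_a
    a1 = np.array([a, 0.0])
    a2 = np.array([a / 2.0, a * math.sqrt(3.0) / 2.0])
    # S-column sublattice offset (honeycomb B site), toward the +y vertex
    delta = np.array([0.0, a / math.sqrt(3.0)])

    nmax = int(math.ceil(side_length / a)) + 2
    n1, n2 = np.meshgrid(np.arange(-nmax, nmax + 1), np.arange(-nmax, nmax + 1))
    idx = np.column_stack([n1.ravel(), n2.ravel()])
    lattice = idx[:, :1] * a1 + idx[:, 1:] * a2

    mo_sel = _points_in_triangle(lattice, side_length)
    mo_idx = idx[mo_sel]
    mo_xy = lattice[mo_sel]
    # every S column coordinating an included Mo (each Mo has three S
    # neighbours at index offsets (0,0), (0,-1), (+1,-1) on the shifted
    # sublattice); edges come out S-rich and neutralisation trims S,
    # leaving the Mo corners - and hence the nominal extent - intact
    s_cols = {
        (i + di, j + dj)
        for i, j in map(tuple, mo_idx)
        for di, dj in ((0, 0), (0, -1), (1, -1))
    }
    s_idx = np.array(sorted(s_cols))
    s_xy = s_idx[:, :1] * a1 + s_idx[:, 1:] * a2 + delta

    elements: list[str] = []
    positions: list[tuple[float, float, float]] = []
    for x, y in sorted(map(tuple, mo_xy)):
        elements.append("Mo")
        positions.append((x, y, 0.0))
    for x, y in sorted(map(tuple, s_xy)):
        for z in (mo_s_offset, -mo_s_offset):
            elements.append("S")
            positions.append((x, y, z))

    if not elements or "Mo" not in elements:
        raise ValueError("degenerate geometry: cut contains no Mo atoms")

    elements_arr = np.array(elements)
    pos = np.array(positions, dtype=float)

    # neutralisation: trim the over-represented species until Mo:S = 1:2
    keep = np.ones(len(elements_arr), dtype=bool)

    def _counts():
        return int(np.sum(elements_arr[keep] == "Mo")), int(np.sum(elements_arr[keep] == "S"))

    n_mo, n_s = _counts()
    while n_s != 2 * n_mo:
        excess = "S" if n_s > 2 * n_mo else "Mo"
        idx = np.flatnonzero(keep & (elements_arr == excess))
        if idx.size == 0:
            raise ValueError("degenerate geometry: cannot neutralise cut")
        cen = pos[keep].mean(axis=0)
        r = np.linalg.norm(pos[idx] - cen, axis=1)
        far = idx[np.abs(r - r.max()) < 1e-12]
        order = np.lexsort((pos[far, 2], pos[far, 1], pos[far, 0]))
        keep[far[order[0]]] = False
        n_mo, n_s = _counts()

    elements_final = tuple(elements_arr[keep])
    pos_final = pos[keep]
    pos_final = pos_final - pos_final.mean(axis=0)

    return NanosheetModel(
        elements=elements_final,
        positions=pos_final,
        side_length=side_length,
        lattice_a=lattice_a,
        mo_s_offset=mo_s_offset,
    )


def assign_aging_state(sheet: NanosheetModel, label: str) -> NanosheetModel:
    """Attach the fresh or aged parameter set to a sheet (idempotent)."""
    if label == "fresh":
        state = fresh_params()
    elif label == "aged":
        state = aged_params()
    else:
        raise ValueError(f"unknown aging label {label!r}; expected 'fresh' or 'aged'")
    return replace(sheet, aging=state)


def eps_from_wca(wca: float) -> float:
    """Sulfur LJ well depth (kJ/mol) from the water contact angle (degrees).

    Linear interpolation through the two calibration anchors
    (69 deg, 1.6744 kJ/mol) and (90 deg, 1.0450 kJ/mol); strictly
    decreasing in the contact angle.  Values outside the bracket are
    extrapolated with a warning.
    """
    if not np.isfinite(wca):
        raise ValueError(f"water contact angle must be finite, got {wca!r}")
    if wca < WCA_FRESH or wca > WCA_AGED:
        warnings.warn(
            f"WCA {wca} deg is outside the calibration bracket "
            f"[{WCA_FRESH}, {WCA_AGED}]; extrapolating",
            stacklevel=2,
        )
    slope = (EPS_S_AGED - EPS_S_FRESH) / (WCA_AGED - WCA_FRESH)
    return EPS_S_FRESH + slope * (wca - WCA_FRESH)


def net_charge(sheet: NanosheetModel) -> float:
    """Total charge of the sheet in elementary charges."""
    state = sheet.aging if sheet.aging is not None else fresh_params()
    charges = np.array([state.species[el].charge for el in sheet.elements])
    return float(charges.sum())


def species_param_diff(a: AgingState, b: AgingState) -> list[str]:
    """Names of scalar parameters that differ between two states."""
    diffs = []
    for el in sorted(set(a.species) | set(b.species)):
        pa, pb = a.species[el], b.species[el]
        if pa.vdw.sigma != pb.vdw.sigma:
            diffs.append(f"{el}.sigma")
        if pa.vdw.epsilon != pb.vdw.epsilon:
            diffs.append(f"{el}.epsilon")
        if pa.charge != pb.charge:
            diffs.append(f"{el}.charge")
    return diffs
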
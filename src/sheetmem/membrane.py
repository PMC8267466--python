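"""Coarse stochastic model of a nanosheet interacting with a lipid bilayer.

This module is the package's synthetic-data stage.  It replaces atomistic
MD with two nested levels of description:

* an *implicit* membrane: a smooth one-dimensional potential along the
  bilayer normal with a hydrophobic tail well (depth proportional to the
  sulfur LJ well depth eps_S of the sheet's aging state), head-group
  barriers at the two interfaces, and an orientational term that favours
  edge-on (sheet normal perpendicular to the bilayer normal) insertion;

* an optional *bead-explicit* bilayer: two leaflets of head+chain bead
  lipids on a grid, harmonically tethered, which respond to the sheet
  through Lennard-Jones/Coulomb bead-atom forces so that contact,
  thickness and chain-order analyses have explicit particles to act on.

Dynamics are overdamped Langevin, fully reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import COULOMB_FACTOR, DEFAULT_CUTOFF, KB
from .nanosheet import NanosheetModel, SpeciesParams, VdwParams, assign_aging_state, build_triangular_nanosheet
from .trajectory import Frame, Topology, Trajectory

__all__ = [
    "ImplicitMembranePotential",
    "implicit_for_state",
    "SimState",
    "MembraneModel",
    "CoarseSystem",
    "SimOptions",
    "membrane_potential",
    "pair_energy",
    "langevin_step",
    "simulate",
    "build_coarse_membrane",
    "scripted_scenario",
    "orient_edge_on",
    "DEFAULT_BEAD_SPECIES",
    "WELL_DEPTH_PER_EPS",
]

#: Coarse-map proportionality between the implicit tail-well depth and
#: the sulfur LJ well depth of the sheet's aging state (dimensionless).
WELL_DEPTH_PER_EPS = 10.0

#: Pseudo-species for the membrane beads.  Head beads carry alternating
#: partial charges (zwitterionic pairs, net zero per leaflet); tails are
#: neutral and set the hydrophobic attraction, which through
#: Lorentz-Berthelot combining scales with sqrt(eps_S) of the sheet.
DEFAULT_BEAD_SPECIES = {
    "head": SpeciesParams("head", VdwParams(0.55, 0.40), 0.0),
    "tail": SpeciesParams("tail", VdwParams(0.50, 12.00), 0.0),
}

_HEAD_PARTIAL_CHARGE = 0.20
_BEAD_MASS = 100.0


# ----------------------------------------------------------------------
# implicit membrane
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ImplicitMembranePotential:
    """Smooth slab potential for the sheet centre of mass.

    The z profile is ``U_t*g(dz) + U_h*(b(dz) - b(0)*g(dz))`` with
    ``g = exp(-dz^4/(2 h^4))`` (a flat-bottomed well of depth U_t) and
    ``b = exp(-u^2/2)``, ``u = (dz^2-h^2)/(2 h w)`` (interface bumps of
    height ~U_h at |dz| = h).  The correction term makes
    ``U(z0, optimal tilt) = U_t`` exact.  The orientational term
    ``kappa*cos(tilt)^2*g(dz)`` penalises sheet-normal alignment with
    the membrane normal inside the slab, vanishing in bulk.
    """

    z0: float  # midplane, nm
    half_thickness: float = 2.0  # nm
    tail_well_depth: float = -16.744  # kJ/mol, negative = attractive
    head_barrier: float = 5.0  # kJ/mol
    interface_width: float = 0.3  # nm
    tilt_coupling: float = 10.0  # kJ/mol

    def _g(self, dz):
        h = self.half_thickness
        return np.exp(-(dz**4) / (2.0 * h**4))

    def _b(self, dz):
        h, w = self.half_thickness, self.interface_width
        u = (dz**2 - h**2) / (2.0 * h * w)
        return np.exp(-0.5 * u**2)

    def energy(self, z, tilt=np.pi / 2.0):
        """Potential energy (kJ/mol) at height z (nm) and tilt (rad).

        ``tilt`` is the angle between the sheet normal and the membrane
        normal; pi/2 (edge-on) is the in-membrane optimum.
        """
        dz = np.asarray(z, dtype=float) - self.z0
        g = self._g(dz)
        b = self._b(dz)
        b0 = self._b(0.0)
        u = self.tail_well_depth * g + self.head_barrier * (b - b0 * g)
        u = u + self.tilt_coupling * np.cos(tilt) ** 2 * g
        return u if u.shape else float(u)

    def dU_dz(self, z, tilt=np.pi / 2.0):
        dz = np.asarray(z, dtype=float) - self.z0
        h, w = self.half_thickness, self.interface_width
        g = self._g(dz)
        dg = g * (-2.0 * dz**3 / h**4)
        b = self._b(dz)
        u = (dz**2 - h**2) / (2.0 * h * w)
        db = b * (-u) * (dz / (h * w))
        b0 = self._b(0.0)
        out = (
            self.tail_well_depth * dg
            + self.head_barrier * (db - b0 * dg)
            + self.tilt_coupling * np.cos(tilt) ** 2 * dg
        )
        return out if out.shape else float(out)

    def dU_dtilt(self, z, tilt):
        dz = np.asarray(z, dtype=float) - self.z0
        return -self.tilt_coupling * math.sin(2.0 * tilt) * float(self._g(dz))

    # scalar fast paths (plain math, used by tight sampling loops)
    def energy_scalar(self, z: float, tilt: float = math.pi / 2.0) -> float:
        dz = z - self.z0
        h, w = self.half_thickness, self.interface_width
        g = math.exp(-(dz**4) / (2.0 * h**4))
        b = math.exp(-0.5 * ((dz * dz - h * h) / (2.0 * h * w)) ** 2)
        b0 = math.exp(-0.5 * (h / (2.0 * w)) ** 2)
        return (
            self.tail_well_depth * g
            + self.head_barrier * (b - b0 * g)
            + self.tilt_coupling * math.cos(tilt) ** 2 * g
        )

    def grad_scalar(self, z: float, tilt: float = math.pi / 2.0) -> float:
        dz = z - self.z0
        h, w = self.half_thickness, self.interface_width
        g = math.exp(-(dz**4) / (2.0 * h**4))
        dg = g * (-2.0 * dz**3 / h**4)
        u = (dz * dz - h * h) / (2.0 * h * w)
        b = math.exp(-0.5 * u * u)
        db = b * (-u) * (dz / (h * w))
        b0 = math.exp(-0.5 * (h / (2.0 * w)) ** 2)
        return (
            self.tail_well_depth * dg
            + self.head_barrier * (db - b0 * dg)
            + self.tilt_coupling * math.cos(tilt) ** 2 * dg
        )


def membrane_potential(z, tilt, params: ImplicitMembranePotential):
    """Functional form of :meth:`ImplicitMembranePotential.energy`."""
    return params.energy(z, tilt)


def implicit_for_state(
    aging_eps_s: float,
    z0: float,
    depth_per_eps: float = WELL_DEPTH_PER_EPS,
    **kwargs,
) -> ImplicitMembranePotential:
    """Implicit membrane whose tail well scales linearly with eps_S.

    An explicit ``tail_well_depth`` keyword overrides the eps_S scaling
    (e.g. 0.0 for a purely repulsive, barrier-only membrane).
    """
    depth = kwargs.pop("tail_well_depth", -depth_per_eps * aging_eps_s)
    return ImplicitMembranePotential(z0=z0, tail_well_depth=depth, **kwargs)


# ----------------------------------------------------------------------
# pair interactions
# ----------------------------------------------------------------------
def pair_energy(r, a: SpeciesParams, b: SpeciesParams, cutoff: float = DEFAULT_CUTOFF):
    """LJ (cut-and-shifted) and Coulomb (truncated) pair energies, kJ/mol.

    Lorentz-Berthelot combining: sigma arithmetic mean, epsilon
    geometric mean.  The LJ term is shifted so it vanishes continuously
    at the cutoff; the Coulomb term is plainly truncated.  Both are
    exactly zero for r >= cutoff.  Accepts scalar or array r.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("pair distance must be positive (r = 0 is singular)")
    sigma = 0.5 * (a.vdw.sigma + b.vdw.sigma)
    eps = math.sqrt(a.vdw.epsilon * b.vdw.epsilon)

    def _lj(rr):
        sr6 = (sigma / rr) ** 6
        return 4.0 * eps * (sr6 * sr6 - sr6)

    inside = r_arr < cutoff
    shift = _lj(cutoff) if np.isfinite(cutoff) else 0.0
    vdw = np.where(inside, _lj(np.where(inside, r_arr, 1.0)) - shift, 0.0)
    coul = np.where(inside, COULOMB_FACTOR * a.charge * b.charge / r_arr, 0.0)
    if r_arr.shape:
        return vdw, coul
    return float(vdw), float(coul)


def _lj_force_mag(r, sigma, eps, cutoff):
    """-dU/dr of the (unshifted-slope) LJ term, zero beyond cutoff."""
    sr6 = (sigma / r) ** 6
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return np.where(r < cutoff, f, 0.0)


# ----------------------------------------------------------------------
# Langevin dynamics
# ----------------------------------------------------------------------
@dataclass
class SimState:
    """Sheet rigid-body state: CoM position (nm), tilt (rad), time (ps)."""

    com: np.ndarray
    tilt: float = np.pi / 2.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)


def langevin_step(x, force, dt, temperature, gamma, rng):
    """One overdamped (Brownian) Euler-Maruyama update.

    x <- x + dt*force/gamma + N(0, 2*kB*T*dt/gamma).  ``gamma`` is the
    friction coefficient (kJ mol^-1 ps nm^-2, i.e. friction*mass in the
    Langevin sense); at T = 0 with zero force the state is unchanged.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    force = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(force)):
        raise FloatingPointError("non-finite force in langevin_step")
    x = np.asarray(x, dtype=float)
    noise = 0.0
    if temperature > 0:
        sigma = math.sqrt(2.0 * KB * temperature * dt / gamma)
        noise = sigma * rng.standard_normal(x.shape)
    return x + dt * force / gamma + noise


# ----------------------------------------------------------------------
# bead membrane
# ----------------------------------------------------------------------
@dataclass
class MembraneModel:
    """Bead-explicit bilayer: grid lipids with one head and a tail chain."""

    positions: np.ndarray  # (n_beads, 3), nm
    leaflet: np.ndarray  # "upper"/"lower"
    region: np.ndarray  # "head"/"tail"
    lipid_id: np.ndarray  # int
    chain_pos: np.ndarray  # -1 for head, 0..m-1 along the chain
    box: np.ndarray  # (3,), nm
    midplane: float  # nm
    normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    bead_species: dict = field(default_factory=lambda: dict(DEFAULT_BEAD_SPECIES))

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_lipids(self) -> int:
        return int(self.lipid_id.max()) + 1

    def head_charges(self) -> np.ndarray:
        """Alternating +/- head partial charges (net zero); tails neutral."""
        q = np.zeros(self.n_beads)
        heads = self.region == "head"
        sign = np.where(self.lipid_id % 2 == 0, 1.0, -1.0)
        q[heads] = _HEAD_PARTIAL_CHARGE * sign[heads]
        return q

    def topology(self) -> Topology:
        return Topology(
            kinds=self.region.copy(),
            lipid_id=self.lipid_id.copy(),
            leaflet=self.leaflet.copy(),
            chain_pos=self.chain_pos.copy(),
            masses=np.full(self.n_beads, _BEAD_MASS),
        )


def build_coarse_membrane(
    n_lipids_per_leaflet: int,
    spacing: float = 0.8,
    beads_per_chain: int = 3,
    head_offset: float = 2.0,
    midplane: float = 6.0,
    box_z: float = 12.0,
) -> MembraneModel:
    """Two planar leaflets of head+chain lipids on a square grid.

    Heads sit outermost at ``midplane +/- head_offset``; each chain runs
    from just below its head toward the midplane, perfectly aligned with
    the normal, so the initial chain order parameter is exactly 1.
    """
    if n_lipids_per_leaflet < 1:
        raise ValueError("need at least one lipid per leaflet")
    if beads_per_chain < 2:
        raise ValueError("chains need >= 2 beads to define a chain vector")
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    side = int(math.ceil(math.sqrt(n_lipids_per_leaflet)))
    box_xy = side * spacing
    chain_z = np.linspace(head_offset - 0.4, 0.4, beads_per_chain)

    pos, leaflet, region, lipid, chain = [], [], [], [], []
    lid = 0
    for leaf, sgn in (("upper", 1.0), ("lower", -1.0)):
        count = 0
        for i in range(side):
            for j in range(side):
                if count >= n_lipids_per_leaflet:
                    break
                x = (i + 0.5) * spacing
                y = (j + 0.5) * spacing
                pos.append((x, y, midplane + sgn * head_offset))
                leaflet.append(leaf)
                region.append("head")
                lipid.append(lid)
                chain.append(-1)
                for m, cz in enumerate(chain_z):
                    pos.append((x, y, midplane + sgn * cz))
                    leaflet.append(leaf)
                    region.append("tail")
                    lipid.append(lid)
                    chain.append(m)
                lid += 1
                count += 1
    return MembraneModel(
        positions=np.array(pos, dtype=float),
        leaflet=np.array(leaflet),
        region=np.array(region),
        lipid_id=np.array(lipid, dtype=int),
        chain_pos=np.array(chain, dtype=int),
        box=np.array([box_xy, box_xy, box_z]),
        midplane=midplane,
    )


# ----------------------------------------------------------------------
# assembled system + simulator
# ----------------------------------------------------------------------
def orient_edge_on(sheet: NanosheetModel, vertex: str = "down") -> NanosheetModel:
    """Rotate the sheet from the xy-plane into the xz-plane (edge-on).

    After the rotation the sheet normal lies along +y (perpendicular to
    the membrane normal z); the +y vertex points toward -z
    (``vertex="down"``, the insertion-ready pose) or +z (``"up"``).
    """
    s = {"down": -1.0, "up": 1.0}[vertex]
    rot = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -s], [0.0, s, 0.0]])
    return replace(sheet, positions=sheet.positions @ rot.T)


@dataclass
class SimOptions:
    dt: float = 0.02  # ps
    temperature: float = 300.0  # K
    gamma_sheet: float = 50.0  # kJ mol^-1 ps nm^-2
    gamma_bead: float = 20.0
    tether_k_head: float = 100.0  # kJ mol^-1 nm^-2, keeps leaflet structure
    tether_k_tail: float = 100.0
    cutoff: float = DEFAULT_CUTOFF
    sheet_mobile: bool = True
    beads_mobile: bool = True
    repulsive_beads: bool = False  # WCA-style truncation of bead-sheet LJ


@dataclass
class CoarseSystem:
    """Rigid sheet + implicit membrane, optionally with explicit beads."""

    sheet: NanosheetModel  # oriented and placed in absolute coordinates
    implicit: ImplicitMembranePotential
    membrane: MembraneModel | None = None
    box: np.ndarray = field(default_factory=lambda: np.array([8.0, 8.0, 12.0]))
    options: SimOptions = field(default_factory=SimOptions)

    def topology(self) -> Topology:
        sheet_kinds = np.array(self.sheet.elements)
        n_s = len(sheet_kinds)
        parts = [
            Topology(
                kinds=sheet_kinds,
                lipid_id=np.full(n_s, -1),
                leaflet=np.array([""] * n_s),
                chain_pos=np.full(n_s, -1),
                masses=self.sheet.masses,
            )
        ]
        if self.membrane is not None:
            parts.append(self.membrane.topology())
        return Topology(
            kinds=np.concatenate([p.kinds for p in parts]),
            lipid_id=np.concatenate([p.lipid_id for p in parts]),
            leaflet=np.concatenate([p.leaflet for p in parts]),
            chain_pos=np.concatenate([p.chain_pos for p in parts]),
            masses=np.concatenate([p.masses for p in parts]),
        )

    def initial_positions(self) -> np.ndarray:
        if self.membrane is None:
            return self.sheet.positions.copy()
        return np.vstack([self.sheet.positions, self.membrane.positions])


def make_system(
    side_length: float = 2.89,
    aging: str = "fresh",
    n_lipids_per_leaflet: int = 36,
    start_distance: float = 4.2,
    depth_per_eps: float = WELL_DEPTH_PER_EPS,
    with_beads: bool = True,
    options: SimOptions | None = None,
    vertex: str = "down",
    **implicit_kwargs,
) -> CoarseSystem:
    """Assemble the reference system: sheet above the bilayer, edge-on."""
    membrane = build_coarse_membrane(n_lipids_per_leaflet) if with_beads else None
    midplane = membrane.midplane if membrane is not None else 6.0
    box = (
        membrane.box.copy()
        if membrane is not None
        else np.array([8.0, 8.0, 12.0])
    )
    sheet = assign_aging_state(build_triangular_nanosheet(side_length), aging)
    sheet = orient_edge_on(sheet, vertex)
    center = np.array([box[0] / 2.0, box[1] / 2.0, midplane + start_distance])
    sheet = sheet.translated(center)
    implicit = implicit_for_state(
        sheet.aging.eps_s, z0=midplane, depth_per_eps=depth_per_eps, **implicit_kwargs
    )
    return CoarseSystem(
        sheet=sheet,
        implicit=implicit,
        membrane=membrane,
        box=box,
        options=options or SimOptions(),
    )


def _min_image_xy(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    disp = disp.copy()
    for ax in (0, 1):
        disp[..., ax] -= box[ax] * np.round(disp[..., ax] / box[ax])
    return disp


class _BeadSheetForceField:
    """Precomputed bead-atom pair parameters for the rigid sheet."""

    def __init__(self, membrane, sheet, cutoff, repulsive_only):
        bead_sp = [membrane.bead_species[r] for r in membrane.region]
        atom_sp = [sheet.aging.species[e] for e in sheet.elements]
        sig_b = np.array([s.vdw.sigma for s in bead_sp])
        sig_a = np.array([s.vdw.sigma for s in atom_sp])
        eps_b = np.array([s.vdw.epsilon for s in bead_sp])
        eps_a = np.array([s.vdw.epsilon for s in atom_sp])
        self.sigma = 0.5 * (sig_b[:, None] + sig_a[None, :])
        self.eps = np.sqrt(eps_b[:, None] * eps_a[None, :])
        q_b = membrane.head_charges()
        q_a = np.array([s.charge for s in atom_sp])
        self.qq = COULOMB_FACTOR * q_b[:, None] * q_a[None, :]
        self.cutoff = cutoff
        if repulsive_only:
            self.rc = np.minimum(cutoff, 2 ** (1.0 / 6.0) * self.sigma)
            self.qq = np.zeros_like(self.qq)
        else:
            self.rc = np.full_like(self.sigma, cutoff)

    def forces(self, bead_pos, sheet_pos, box):
        """Forces on beads from the sheet atoms (kJ mol^-1 nm^-1).

        Distances are clamped at 0.8*sigma (soft core) so transient
        overlaps during insertion cannot produce divergent forces.
        """
        disp = _min_image_xy(bead_pos[:, None, :] - sheet_pos[None, :, :], box)
        r_true = np.maximum(np.linalg.norm(disp, axis=-1), 1e-6)
        r = np.maximum(r_true, 0.8 * self.sigma)
        sr6 = (self.sigma / r) ** 6
        fmag = 24.0 * self.eps * (2.0 * sr6 * sr6 - sr6) / r
        np.putmask(fmag, r >= self.rc, 0.0)
        if self.qq.any():
            fmag += np.where(r < self.cutoff, self.qq / (r * r), 0.0)
        return np.einsum("bs,bsk->bk", fmag / r_true, disp)


def simulate(
    system: CoarseSystem,
    n_steps: int,
    report_interval: int,
    seed: int,
) -> Trajectory:
    """Run the coarse overdamped dynamics and record a trajectory.

    The sheet moves rigidly along z in the implicit membrane potential
    (its aging state already encoded in the well depth); beads, when
    present and mobile, feel their tethers plus bead-sheet pair forces.
    Returns ``n_steps // report_interval`` frames plus the initial one.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    opts = system.options
    rng = np.random.default_rng(seed)
    top = system.topology()
    pos = system.initial_positions()
    n_sheet = len(system.sheet.elements)

    # reject overlapping starts
    if system.membrane is not None:
        d = _min_image_xy(pos[:n_sheet, None, :] - pos[None, n_sheet:, :], system.box)
        if np.min(np.linalg.norm(d, axis=-1)) < 0.05:
            raise ValueError("overlapping initial particles (sheet/bead distance < 0.05 nm)")

    bead_ref = pos[n_sheet:].copy()
    if system.membrane is not None:
        tether_k = np.where(
            system.membrane.region == "head", opts.tether_k_head, opts.tether_k_tail
        )
    ff = (
        _BeadSheetForceField(
            system.membrane, system.sheet, opts.cutoff, opts.repulsive_beads
        )
        if system.membrane is not None
        else None
    )
    z_lo, z_hi = 0.3, system.box[2] - 0.3  # reflecting walls, open z

    frames = [pos.copy()]
    times = [0.0]
    z_com = float(np.average(pos[:n_sheet, 2], weights=system.sheet.masses))
    for step in range(1, n_steps + 1):
        if opts.sheet_mobile:
            fz = -system.implicit.dU_dz(z_com)
            new_z = float(
                langevin_step(
                    np.array(z_com), np.array(fz), opts.dt, opts.temperature,
                    opts.gamma_sheet, rng,
                )
            )
            if new_z < z_lo:
                new_z = 2 * z_lo - new_z
            elif new_z > z_hi:
                new_z = 2 * z_hi - new_z
            pos[:n_sheet, 2] += new_z - z_com
            z_com = new_z
        if system.membrane is not None and opts.beads_mobile:
            bead_pos = pos[n_sheet:]
            f = -tether_k[:, None] * (bead_pos - bead_ref)
            f += ff.forces(bead_pos, pos[:n_sheet], system.box)
            pos[n_sheet:] = langevin_step(
                bead_pos, f, opts.dt, opts.temperature, opts.gamma_bead, rng
            )
        if step % report_interval == 0:
            frames.append(pos.copy())
            times.append(step * opts.dt)

    return Trajectory(
        topology=top,
        times=np.array(times),
        positions=np.array(frames),
        box=system.box.copy(),
        metadata={
            "seed": seed,
            "temperature": opts.temperature,
            "dt": opts.dt,
            "aging": system.sheet.aging.label if system.sheet.aging else None,
            "n_steps": n_steps,
            "report_interval": report_interval,
        },
    )


# ----------------------------------------------------------------------
# scripted scenarios with embedded ground truth
# ----------------------------------------------------------------------
_SCENARIOS = ("approach", "preorganize_insert", "direct_insert", "no_insert")


def _scenario_path(name: str, n_frames: int, rng) -> np.ndarray:
    """Sheet CoM height above the midplane (nm) per frame."""
    t = np.linspace(0.0, 1.0, n_frames)
    wobble = 0.03 * rng.standard_normal(n_frames)
    if name == "approach":
        z = 4.2 - 1.6 * np.minimum(t / 0.8, 1.0)
    elif name == "no_insert":
        z = np.where(t < 0.4, 4.2 - 1.4 * t / 0.4, 2.8 + 0.1 * np.sin(12 * t))
    elif name == "direct_insert":
        z = np.where(t < 0.4, 4.2 - (4.2 - 0.6) * t / 0.4, 0.6)
    elif name == "preorganize_insert":
        z = np.empty(n_frames)
        for i, ti in enumerate(t):
            if ti < 0.25:
                z[i] = 4.2 - (4.2 - 3.7) * ti / 0.25
            elif ti < 0.55:
                z[i] = 3.7  # adhered, preorganising on the surface
            elif ti < 0.8:
                z[i] = 3.7 - (3.7 - 0.5) * (ti - 0.55) / 0.25
            else:
                z[i] = 0.5
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {_SCENARIOS}")
    return z + wobble


def scripted_scenario(
    name: str,
    seed: int = 0,
    n_frames: int = 120,
    frame_dt: float = 10.0,
    side_length: float = 2.89,
    n_lipids_per_leaflet: int = 36,
    n_waters: int = 85,
    contact_cutoff: float = 0.5,
    water_cutoff: float = 0.35,
):
    """Deterministic kinematic trajectory with machine-readable truth.

    The sheet follows a prescribed CoM path over a static bead bilayer;
    bound surface waters ride rigidly with the sheet until they detach
    (monotonically, as insertion deepens) to the bulk.  Returns
    ``(Trajectory, truth)`` where ``truth`` holds the true insertion
    time, per-frame sheet-lipid contact counts and bound-water counts,
    computed here by direct distance loops independent of the analysis
    module.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {_SCENARIOS}")
    rng = np.random.default_rng(seed)
    membrane = build_coarse_membrane(n_lipids_per_leaflet)
    box = membrane.box
    sheet = orient_edge_on(
        assign_aging_state(build_triangular_nanosheet(side_length), "fresh")
    )
    center_xy = np.array([box[0] / 2.0, box[1] / 2.0, 0.0])

    z_path = _scenario_path(name, n_frames, rng)
    head_plane = 2.0  # proximal (upper) head plane height above midplane

    # waters start bound to the sheet surface: offset along the sheet
    # normal (+/- y after edge-on orientation) from randomly chosen atoms
    host = rng.integers(0, sheet.n_atoms, size=n_waters)
    side = np.where(rng.random(n_waters) < 0.5, 1.0, -1.0)
    offset = np.zeros((n_waters, 3))
    offset[:, 1] = side * 0.28
    # detachment: waters leave (deepest threshold first) as the sheet descends
    detach_z = np.linspace(1.9, 0.4, n_waters)
    rng.shuffle(detach_z)
    bulk_pos = np.column_stack(
        [
            rng.uniform(0.2, box[0] - 0.2, n_waters),
            rng.uniform(0.2, box[1] - 0.2, n_waters),
            rng.uniform(box[2] - 1.2, box[2] - 0.2, n_waters),
        ]
    )

    n_sheet = sheet.n_atoms
    n_beads = membrane.n_beads
    all_pos = np.empty((n_frames, n_sheet + n_beads + n_waters, 3))
    contacts = np.zeros(n_frames, dtype=int)
    waters = np.zeros(n_frames, dtype=int)
    detached = np.zeros(n_waters, dtype=bool)
    insertion_frame = None
    for i in range(n_frames):
        com = center_xy + np.array([0.0, 0.0, membrane.midplane + z_path[i]])
        spos = sheet.positions + com
        detached |= z_path[i] < detach_z  # monotone: never re-attach
        wpos = np.where(
            detached[:, None], bulk_pos, spos[host] + offset
        )
        all_pos[i, :n_sheet] = spos
        all_pos[i, n_sheet : n_sheet + n_beads] = membrane.positions
        all_pos[i, n_sheet + n_beads :] = wpos

        # ground truth by direct double loops (vectorised per frame)
        disp = _min_image_xy(
            membrane.positions[:, None, :] - spos[None, :, :], box
        )
        dmin = np.linalg.norm(disp, axis=-1).min(axis=1)
        contacts[i] = int(np.sum(dmin < contact_cutoff))
        wdisp = _min_image_xy(wpos[:, None, :] - spos[None, :, :], box)
        wmin = np.linalg.norm(wdisp, axis=-1).min(axis=1)
        waters[i] = int(np.sum(wmin <= water_cutoff))
        if insertion_frame is None and z_path[i] < head_plane:
            if np.all(z_path[i:] < head_plane):
                insertion_frame = i

    times = np.arange(n_frames) * frame_dt
    top_parts = sheet.elements
    kinds = np.concatenate(
        [np.array(top_parts), membrane.region, np.array(["water"] * n_waters)]
    )
    topology = Topology(
        kinds=kinds,
        lipid_id=np.concatenate(
            [np.full(n_sheet, -1), membrane.lipid_id, np.full(n_waters, -1)]
        ),
        leaflet=np.concatenate(
            [np.array([""] * n_sheet), membrane.leaflet, np.array([""] * n_waters)]
        ),
        chain_pos=np.concatenate(
            [np.full(n_sheet, -1), membrane.chain_pos, np.full(n_waters, -1)]
        ),
        masses=np.concatenate(
            [sheet.masses, np.full(n_beads, _BEAD_MASS), np.full(n_waters, 18.02)]
        ),
    )
    traj = Trajectory(
        topology=topology,
        times=times,
        positions=all_pos,
        box=box.copy(),
        metadata={"scenario": name, "seed": seed, "frame_dt": frame_dt},
    )
    truth = {
        "insertion_time": (
            None if insertion_frame is None else float(times[insertion_frame])
        ),
        "insertion_frame": insertion_frame,
        "contacts": contacts,
        "bound_waters": waters,
        "com_height": z_path.copy(),
        "head_plane": head_plane,
    }
    return traj, truth
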
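"""End-to-end orchestration: build -> simulate -> analyze -> umbrella -> WHAM.

Produces a deterministic artifact directory:

    structures/    sheet and membrane coordinates (GRO/PDB)
    trajectories/  coarse trajectory (binary stream + topology JSON)
    windows/       per-window (time, d) samples as plain text
    pmf/           PMF profile TSV and the located minimum
    analysis/      per-frame statistic series as TSV, summary CSV
    manifest.json  config echo, named seeds, sha256 of every output

Completed stages (detected by their outputs) are reused on rerun.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import series_over_trajectory
from .config import RunConfig
from .membrane import SimOptions, implicit_for_state, make_system, simulate
from .nanosheet import (
    assign_aging_state,
    build_triangular_nanosheet,
    eps_from_wca,
)
from .structure_io import write_sheet, write_structure
from .trajectory import Topology, Trajectory
from .umbrella import (
    ReactionCoordinateSampler,
    UmbrellaWindow,
    generate_windows,
    pmf_minimum,
    run_window,
    wham,
)

__all__ = ["pipeline_run", "derive_seed", "write_pmf_tsv", "umbrella_campaign"]


def derive_seed(seed: int, stream: str) -> int:
    """Deterministic named seed stream below 2^31."""
    return (seed * 2654435761 + zlib.crc32(stream.encode())) % (2**31 - 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_pmf_tsv(profile, path) -> None:
    se = profile.se if profile.se is not None else np.full_like(profile.pmf, np.nan)
    df = pd.DataFrame(
        {"z": profile.z, "pmf": profile.pmf, "se": se, "counts": profile.counts}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def umbrella_campaign(cfg: RunConfig, seed: int, sheet_state) -> list[UmbrellaWindow]:
    """Run the full window ladder over the implicit membrane potential."""
    implicit = implicit_for_state(
        sheet_state.eps_s, z0=0.0, depth_per_eps=cfg.simulator.depth_per_eps
    )
    sampler = ReactionCoordinateSampler(
        gradient=implicit.grad_scalar,
        gamma=cfg.simulator.gamma_sheet,
        temperature=cfg.simulator.temperature,
    )
    ladder = generate_windows(cfg.umbrella.d_min, cfg.umbrella.d_max, cfg.umbrella.spacing)
    windows = []
    for i, d0 in enumerate(ladder):
        w = UmbrellaWindow(d0=d0, k=cfg.umbrella.k)
        windows.append(
            run_window(
                sampler,
                w,
                seed=derive_seed(seed, f"umbrella:{i}"),
                n_samples=cfg.umbrella.n_samples,
                equil_steps=cfg.umbrella.equil_steps,
                thin=cfg.umbrella.thin,
            )
        )
    return windows


def pipeline_run(cfg: RunConfig, out_dir=None) -> Path:
    """Run the whole pipeline; returns the artifact directory."""
    cfg.validate()
    root = Path(out_dir if out_dir is not None else cfg.out_dir)
    dirs = {
        name: root / name
        for name in ("structures", "trajectories", "windows", "pmf", "analysis")
    }
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    seeds = {
        "simulate": derive_seed(cfg.seed, "simulate"),
        "umbrella": derive_seed(cfg.seed, "umbrella"),
        "bootstrap": derive_seed(cfg.seed, "bootstrap"),
    }

    # stage 1: structures
    sheet_gro = dirs["structures"] / "sheet.gro"
    sheet = build_triangular_nanosheet(
        cfg.sheet.side_length, cfg.lattice.a, cfg.lattice.mo_s_offset
    )
    sheet = assign_aging_state(sheet, cfg.sheet.aging)
    if cfg.sheet.wca is not None:
        # informational: the eps implied by a custom contact angle
        _ = eps_from_wca(cfg.sheet.wca)
    if not sheet_gro.exists():
        write_sheet(sheet, sheet_gro)
        write_sheet(sheet, dirs["structures"] / "sheet.pdb")

    # stage 2: coarse dynamic run with the bead membrane
    traj_bin = dirs["trajectories"] / "run.trj"
    top_json = dirs["trajectories"] / "topology.json"
    system = make_system(
        side_length=cfg.sheet.side_length,
        aging=cfg.sheet.aging,
        n_lipids_per_leaflet=cfg.simulator.n_lipids_per_leaflet,
        start_distance=cfg.simulator.start_distance,
        depth_per_eps=cfg.simulator.depth_per_eps,
        options=SimOptions(
            dt=cfg.simulator.dt,
            temperature=cfg.simulator.temperature,
            gamma_sheet=cfg.simulator.gamma_sheet,
            gamma_bead=cfg.simulator.gamma_bead,
            cutoff=cfg.simulator.cutoff,
        ),
    )
    if traj_bin.exists() and top_json.exists():
        traj = Trajectory.read_binary(traj_bin, Topology.from_json(top_json.read_text()))
    else:
        traj = simulate(
            system, cfg.simulator.n_steps, cfg.simulator.report_interval,
            seed=seeds["simulate"],
        )
        traj.write_binary(traj_bin)
        top_json.write_text(traj.topology.to_json())
        write_structure(
            dirs["structures"] / "membrane.gro",
            ["H" if k == "head" else "T" for k in system.membrane.region],
            system.membrane.positions,
            box_nm=system.membrane.box,
            resname="LIP",
        )

    # stage 3: analysis series
    for stat in ("contacts", "com", "thickness", "schain"):
        out = dirs["analysis"] / f"{stat}.tsv"
        if out.exists():
            continue
        series = series_over_trajectory(traj, stat)
        pd.DataFrame({"time": series.times, "value": series.values}).to_csv(
            out, sep="\t", index=False, float_format="%.6f"
        )

    # stage 4: umbrella + WHAM on the implicit membrane
    pmf_tsv = dirs["pmf"] / "pmf.tsv"
    if not pmf_tsv.exists():
        windows = umbrella_campaign(cfg, seeds["umbrella"], sheet.aging)
        for i, w in enumerate(windows):
            if w.samples is None:
                continue
            np.savetxt(
                dirs["windows"] / f"window_{i:03d}.txt",
                np.column_stack([w.times, w.samples]),
                header=f"d0={w.d0} k={w.k} seed={w.seed}  columns: time(ps) d(nm)",
                fmt="%.6f",
            )
        profile = wham(
            windows,
            temperature=cfg.simulator.temperature,
            n_bins=cfg.wham.n_bins,
            tol=cfg.wham.tol,
            max_iter=cfg.wham.max_iter,
            bootstrap=cfg.wham.bootstrap,
            seed=seeds["bootstrap"],
        )
        write_pmf_tsv(profile, pmf_tsv)
        mn = pmf_minimum(profile)
        (dirs["pmf"] / "minimum.json").write_text(
            json.dumps(
                {"z_min": mn.z, "depth": mn.depth, "degenerate": mn.degenerate},
                indent=2,
            )
        )

    outputs = {}
    for d in dirs.values():
        for p in sorted(d.rglob("*")):
            if p.is_file():
                outputs[str(p.relative_to(root))] = _sha256(p)
    manifest = {
        "package": "sheetmem",
        "version": __version__,
        "config": cfg.to_dict(),
        "seeds": seeds,
        "outputs": outputs,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return root
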
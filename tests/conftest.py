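"""Shared fixtures: expensive simulation products are session-scoped."""

import numpy as np
import pytest

from sheetmem.membrane import SimOptions, make_system, simulate
from sheetmem.umbrella import ReactionCoordinateSampler, UmbrellaWindow, run_window, wham


@pytest.fixture(scope="session")
def small_sheet():
    from sheetmem.nanosheet import assign_aging_state, build_triangular_nanosheet

    return assign_aging_state(build_triangular_nanosheet(1.6), "fresh")


@pytest.fixture(scope="session")
def small_membrane():
    from sheetmem.membrane import build_coarse_membrane

    return build_coarse_membrane(16, spacing=0.8, beads_per_chain=3)


def random_frame(rng, n_a=12, n_b=30, box=(4.0, 4.0, 8.0)):
    """A random two-group frame for brute-force oracle comparisons."""
    from sheetmem.trajectory import Frame, Topology

    n = n_a + n_b
    pos = np.column_stack(
        [
            rng.uniform(0, box[0], n),
            rng.uniform(0, box[1], n),
            rng.uniform(2.0, 6.0, n),
        ]
    )
    kinds = np.array(["S"] * n_a + ["tail"] * n_b)
    # group_b atoms are beads of two-bead "lipids" with head/tail labels
    kinds[n_a::2] = "head"
    lipid = np.full(n, -1)
    lipid[n_a:] = np.arange(n_b) // 2
    leaflet = np.array([""] * n)
    leaflet[n_a:] = np.where(np.arange(n_b) % 2 == 0, "upper", "lower")
    chain = np.full(n, -1)
    top = Topology(
        kinds=kinds,
        lipid_id=lipid,
        leaflet=leaflet,
        chain_pos=chain,
        masses=np.ones(n),
    )
    return Frame(pos, np.asarray(box, float), top)


def brute_min_dist(frame, group_a, group_b):
    """Python-loop minimum-image distances: the O(N^2) oracle."""
    box = frame.box
    out = np.empty(len(group_b))
    for jj, j in enumerate(group_b):
        best = np.inf
        for i in group_a:
            d = frame.positions[j] - frame.positions[i]
            dx = d[0] - box[0] * round(d[0] / box[0])
            dy = d[1] - box[1] * round(d[1] / box[1])
            r = (dx * dx + dy * dy + d[2] * d[2]) ** 0.5
            best = min(best, r)
        out[jj] = best
    return out


@pytest.fixture(scope="session")
def ordering_runs():
    """Five seed-paired fresh/aged coarse runs with the bead membrane."""
    runs = []
    for seed in range(5):
        pair = {}
        for aging in ("fresh", "aged"):
            system = make_system(
                side_length=1.6, aging=aging, n_lipids_per_leaflet=36
            )
            pair[aging] = simulate(system, 8000, 200, seed=100 + seed)
        runs.append(pair)
    return runs


@pytest.fixture(scope="session")
def doublewell_pmf():
    """Umbrella ladder + WHAM over an analytic double well a(z^2-b^2)^2."""
    b = 0.8
    a = 6.0 / b**4

    sampler = ReactionCoordinateSampler(
        gradient=lambda z: 4 * a * z * (z * z - b * b), gamma=50.0
    )
    from sheetmem.umbrella import generate_windows

    windows = [
        run_window(
            sampler,
            UmbrellaWindow(d0=d0, k=500.0),
            seed=300 + i,
            n_samples=5000,
            equil_steps=3000,
            thin=80,
        )
        for i, d0 in enumerate(generate_windows(-1.2, 1.2, 0.1))
    ]
    profile = wham(windows, n_bins=100, bootstrap=20, seed=1)
    return {"a": a, "b": b, "windows": windows, "profile": profile}


@pytest.fixture(scope="session")
def harmonic_pmf():
    """Single unbiased window sampling U = 0.5*kappa*z^2, inverted by WHAM."""
    kappa = 10.0
    sampler = ReactionCoordinateSampler(gradient=lambda z: kappa * z, gamma=50.0)
    times, d = sampler.sample(
        40000, 0.0, seed=7, bias_k=0.0, dt=0.1, equil_steps=3000, thin=60
    )
    window = UmbrellaWindow(d0=0.0, k=1e-12, samples=d, times=times)
    profile = wham([window], n_bins=80, bootstrap=20, seed=2)
    return {"kappa": kappa, "profile": profile}
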
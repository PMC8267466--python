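"""Umbrella sampling along the insertion coordinate and a WHAM solver.

The reaction coordinate d is the signed sheet-membrane centre-of-mass
separation along the bilayer normal (positive on the bulk-water side).
Each window restrains d to a reference d0 with the harmonic force
F = k*(d - d0) (the paper convention), i.e. bias energy
U_bias = 0.5*k*(d - d0)^2.  The biased window histograms are combined
into one unbiased potential of mean force by self-consistent WHAM
iteration over the window free-energy shifts f_i.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kt

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "PMFMinimum",
    "ReactionCoordinateSampler",
    "generate_windows",
    "restraint_force",
    "bias_energy",
    "run_window",
    "wham",
    "pmf_minimum",
    "pmf_difference",
    "DEFAULT_FORCE_CONSTANT",
    "DEFAULT_WINDOW_SPACING",
]

#: Harmonic restraint force constant, kJ mol^-1 nm^-2.
DEFAULT_FORCE_CONSTANT = 2000.0
#: Window ladder spacing, nm.
DEFAULT_WINDOW_SPACING = 0.1


@dataclass
class UmbrellaWindow:
    """One biased window: reference d0 (nm), force constant k, samples."""

    d0: float
    k: float
    samples: np.ndarray | None = None
    times: np.ndarray | None = None
    equil_time: float = 0.0
    prod_time: float = 0.0
    seed: int | None = None
    failed: bool = False

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"force constant must be positive, got {self.k}")

    @property
    def n_samples(self) -> int:
        return 0 if self.samples is None else len(self.samples)


@dataclass
class PMFProfile:
    """Gridded free-energy curve with bootstrap uncertainty."""

    z: np.ndarray  # bin centres, nm
    pmf: np.ndarray  # kJ/mol, bulk region averaged to zero
    counts: np.ndarray  # raw samples per bin (all windows)
    se: np.ndarray | None  # bootstrap standard error per bin
    f: np.ndarray  # converged window shifts, kJ/mol
    iterations: int
    residual: float
    converged: bool
    temperature: float
    bulk_mask: np.ndarray | None = None

    @property
    def bin_width(self) -> float:
        return float(self.z[1] - self.z[0]) if len(self.z) > 1 else 0.0


@dataclass(frozen=True)
class PMFMinimum:
    z: float
    depth: float  # kJ/mol below the bulk reference (positive for a well)
    degenerate: bool = False


def generate_windows(d_min: float, d_max: float, spacing: float) -> list[float]:
    """Inclusive arithmetic window ladder with exact decimal spacing.

    The ladder is evaluated in exact rational arithmetic from the
    decimal representations of the inputs, so there is no floating-point
    drift; the span must be an integer multiple of the spacing.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if d_max <= d_min:
        raise ValueError("d_max must exceed d_min")
    lo, hi, sp = (Fraction(repr(float(v))) for v in (d_min, d_max, spacing))
    n = round((hi - lo) / sp)
    rem = (hi - lo) - n * sp
    if abs(rem) > Fraction(1, 10**9):
        raise ValueError(
            f"window span {d_max}-{d_min} is not an integer multiple of "
            f"spacing {spacing} (remainder {float(rem)} nm)"
        )
    return [float(lo + i * sp) for i in range(int(n) + 1)]


def restraint_force(d, d0, k=DEFAULT_FORCE_CONSTANT):
    """Restraint force F = k*(d - d0), kJ mol^-1 nm^-1."""
    return k * (np.asarray(d, dtype=float) - d0) if np.ndim(d) else k * (d - d0)


def bias_energy(d, d0, k=DEFAULT_FORCE_CONSTANT):
    """Harmonic bias energy 0.5*k*(d - d0)^2 consistent with the force."""
    dd = np.asarray(d, dtype=float) - d0 if np.ndim(d) else d - d0
    return 0.5 * k * dd**2


@dataclass
class ReactionCoordinateSampler:
    """Overdamped Langevin sampler of a one-dimensional coordinate.

    ``gradient`` is dU/dd of the unbiased potential (kJ mol^-1 nm^-1);
    the harmonic window bias is added internally.  The integration step
    is chosen as ``stability * gamma / k_eff`` unless given, keeping the
    Euler-Maruyama discretisation bias on sampled variances ~ stability/2.
    """

    gradient: "callable"
    gamma: float = 50.0  # kJ mol^-1 ps nm^-2
    temperature: float = DEFAULT_TEMPERATURE
    stability: float = 0.02

    def timestep(self, bias_k: float, curvature: float = 0.0) -> float:
        k_eff = max(bias_k + curvature, 1e-3)
        return self.stability * self.gamma / k_eff

    def sample(
        self,
        n_samples: int,
        d_init: float,
        seed: int,
        bias_k: float = 0.0,
        bias_d0: float = 0.0,
        dt: float | None = None,
        equil_steps: int = 2000,
        thin: int = 10,
    ):
        """Return (times, samples) of d from the biased dynamics."""
        if dt is None:
            dt = self.timestep(bias_k)
        kT = kt(self.temperature)
        sig = math.sqrt(2.0 * kT * dt / self.gamma)
        n_steps = equil_steps + n_samples * thin
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(n_steps) * sig
        grad = self.gradient
        inv_gamma = dt / self.gamma
        d = float(d_init)
        out = np.empty(n_samples)
        j = 0
        for i in range(n_steps):
            f = -grad(d) - bias_k * (d - bias_d0)
            d += f * inv_gamma + noise[i]
            if i >= equil_steps and (i - equil_steps) % thin == thin - 1:
                out[j] = d
                j += 1
        times = (equil_steps + (np.arange(n_samples) + 1) * thin) * dt
        return times, out


def run_window(
    sampler: ReactionCoordinateSampler,
    window: UmbrellaWindow,
    seed: int,
    n_samples: int = 2000,
    equil_steps: int = 2000,
    thin: int = 60,
    dt: float | None = None,
) -> UmbrellaWindow:
    """Sample one umbrella window; equilibration is discarded.

    A window whose dynamics diverge is returned flagged ``failed``
    rather than dropped.
    """
    try:
        times, samples = sampler.sample(
            n_samples,
            d_init=window.d0,
            seed=seed,
            bias_k=window.k,
            bias_d0=window.d0,
            dt=dt,
            equil_steps=equil_steps,
            thin=thin,
        )
        if not np.all(np.isfinite(samples)):
            raise FloatingPointError("non-finite reaction-coordinate samples")
    except FloatingPointError:
        return replace(window, failed=True, seed=seed)
    dt_used = dt if dt is not None else sampler.timestep(window.k)
    return replace(
        window,
        samples=samples,
        times=times,
        equil_time=equil_steps * dt_used,
        prod_time=n_samples * thin * dt_used,
        seed=seed,
        failed=False,
    )


def _window_histograms(windows, edges):
    n = np.vstack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    return n.astype(float)


def wham(
    windows: list[UmbrellaWindow],
    temperature: float = DEFAULT_TEMPERATURE,
    n_bins: int = 200,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bootstrap: int = 50,
    seed: int = 0,
    bin_range: tuple[float, float] | None = None,
    bulk_fraction: float = 0.1,
) -> PMFProfile:
    """Self-consistent WHAM over the window free-energy shifts.

    Iterates p_j = sum_i n_ij / sum_i N_i exp(beta(f_i - U_ij)),
    f_i = -kT log sum_j p_j exp(-beta U_ij) until max|df_i| < tol.
    The PMF -kT log p is shifted so the bulk reference region (bins in
    the outermost ``bulk_fraction`` of the sampled range, large-d side)
    averages zero.  Bootstrap resampling within windows gives per-bin
    standard errors.
    """
    live = [w for w in windows if not w.failed and w.n_samples > 0]
    if not live:
        raise ValueError("no usable windows (all empty or failed)")
    kT = kt(temperature)
    beta = 1.0 / kT
    all_samples = np.concatenate([w.samples for w in live])
    if bin_range is None:
        bin_range = (float(all_samples.min()), float(all_samples.max()))
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    z = 0.5 * (edges[:-1] + edges[1:])

    n_ij = _window_histograms(live, edges)
    _check_overlap(live, n_ij)
    counts = n_ij.sum(axis=0)

    u_ij = np.array([bias_energy(z, w.d0, w.k) for w in live])  # (n_win, n_bins)
    n_i = n_ij.sum(axis=1)

    c_ij = np.exp(-beta * u_ij)  # distant bins underflow harmlessly to 0

    def solve(nij, f_init=None):
        f = np.zeros(len(live)) if f_init is None else f_init.copy()
        m_j = nij.sum(axis=0)
        occupied = m_j > 0
        nn_i = nij.sum(axis=1)
        a_i = np.exp(beta * f)  # a_i = exp(beta f_i) = 1/Z_i
        it = 0
        resid = np.inf
        tiny = np.finfo(float).tiny
        for it in range(1, max_iter + 1):
            den = (nn_i * a_i) @ c_ij
            p = np.where(occupied, m_j / np.maximum(den, tiny), 0.0)
            p /= p.sum()
            z_i = c_ij @ p
            f_new = -kT * np.log(np.maximum(z_i, tiny))
            f_new -= f_new[0]
            resid = float(np.max(np.abs(f_new - f)))
            f = f_new
            a_i = np.exp(beta * f)
            if resid < tol:
                break
        with np.errstate(divide="ignore"):
            pmf = np.where(occupied, -kT * np.log(np.maximum(p, tiny)), np.nan)
        return pmf, f, it, resid

    pmf, f, iterations, residual = solve(n_ij)
    converged = residual < tol

    finite = np.isfinite(pmf)
    span = bin_range[1] - bin_range[0]
    bulk = finite & (z >= bin_range[1] - bulk_fraction * span)
    if not bulk.any():
        bulk = finite
    shift = float(np.mean(pmf[bulk]))
    pmf = pmf - shift

    se = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        # moving-block bootstrap: window samples are autocorrelated, so
        # resample contiguous blocks sized by the integrated
        # autocorrelation time estimated from the lag-1 coefficient
        blocks = []
        for w in live:
            s = w.samples
            rho = 0.0
            if w.n_samples > 10 and s.std() > 0:
                rho = float(np.clip(np.corrcoef(s[:-1], s[1:])[0, 1], 0.0, 0.99))
            blocks.append(max(1, int(np.ceil((1 + rho) / (1 - rho)))))
        curves = []
        for _ in range(bootstrap):
            boot = []
            for w, blk in zip(live, blocks):
                n = w.n_samples
                if blk == 1:
                    resampled = rng.choice(w.samples, size=n, replace=True)
                else:
                    starts = rng.integers(0, max(n - blk, 1), size=n // blk + 1)
                    resampled = np.concatenate(
                        [w.samples[s0 : s0 + blk] for s0 in starts]
                    )[:n]
                boot.append(replace(w, samples=resampled))
            nb = _window_histograms(boot, edges)
            # guard: a resample may empty a bin; solve handles -inf mass
            pmf_b, _, _, _ = solve(nb, f_init=f)
            fb = np.isfinite(pmf_b)
            bulk_b = fb & bulk
            if bulk_b.any():
                pmf_b = pmf_b - np.mean(pmf_b[bulk_b])
            curves.append(pmf_b)
        curves = np.array(curves)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = np.nanstd(curves, axis=0, ddof=1)

    if not converged:
        warnings.warn(
            f"WHAM did not converge: residual {residual:.3g} after "
            f"{iterations} iterations",
            stacklevel=2,
        )
    return PMFProfile(
        z=z,
        pmf=pmf,
        counts=counts,
        se=se,
        f=f,
        iterations=iterations,
        residual=residual,
        converged=converged,
        temperature=temperature,
        bulk_mask=bulk,
    )


def _check_overlap(windows, n_ij) -> None:
    if len(windows) < 2:
        return
    order = np.argsort([w.d0 for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        shared = float(np.minimum(n_ij[a], n_ij[b]).sum())
        if shared == 0:
            raise ValueError(
                "no histogram overlap between adjacent windows at "
                f"d0 = {windows[a].d0} and {windows[b].d0} nm"
            )
        if shared < 10:
            warnings.warn(
                f"windows at d0 = {windows[a].d0} and {windows[b].d0} nm "
                f"share only {int(shared)} samples in common bins",
                stacklevel=3,
            )


def pmf_minimum(profile: PMFProfile) -> PMFMinimum:
    """Location and depth of the PMF minimum (parabolically refined).

    Depth is measured relative to the bulk reference (PMF zero); ties go
    to the smaller reaction-coordinate value.  A profile whose total
    variation is indistinguishable from its bootstrap noise is flagged
    degenerate.
    """
    finite = np.isfinite(profile.pmf)
    # ignore barely-visited bins at the sampled-range edges, whose PMF
    # values are dominated by shot noise
    well_sampled = finite & (profile.counts >= 5)
    if well_sampled.sum() >= 3:
        finite = well_sampled
    if finite.sum() < 3:
        raise ValueError("PMF profile has fewer than 3 finite bins")
    z = profile.z[finite]
    p = profile.pmf[finite]
    i = int(np.argmin(p))  # first minimum -> smaller z on ties
    z_min, p_min = float(z[i]), float(p[i])
    # refine by a least-squares parabola over a small window around the
    # raw minimum (more noise-tolerant than a three-point fit)
    lo, hi = max(i - 3, 0), min(i + 4, len(p))
    if hi - lo >= 3:
        c2, c1, c0 = np.polyfit(z[lo:hi] - z[i], p[lo:hi], 2)
        if c2 > 0:
            dz = -c1 / (2 * c2)
            if abs(dz) <= z[hi - 1] - z[i] + 1e-12 and abs(dz) <= z[i] - z[lo] + 1e-12:
                z_min = float(z[i] + dz)
                p_min = float(c0 - c1**2 / (4 * c2))
    # degenerate = indistinguishable from flat given per-bin uncertainty
    degenerate = False
    if profile.se is not None:
        se = profile.se[finite]
        ok = np.isfinite(se) & (se > 0)
        if ok.any():
            degenerate = bool(np.all(np.abs(p[ok] - p[ok].mean()) < 3.0 * se[ok]))
    return PMFMinimum(z=z_min, depth=-p_min, degenerate=degenerate)


def pmf_difference(profile_a: PMFProfile, profile_b: PMFProfile):
    """Well-depth difference depth(A) - depth(B) with propagated error.

    Profiles on different grids are re-binned (linear interpolation)
    onto the common overlap; disjoint grids are an error.
    """
    lo = max(profile_a.z.min(), profile_b.z.min())
    hi = min(profile_a.z.max(), profile_b.z.max())
    if hi <= lo:
        raise ValueError("PMF profiles have disjoint reaction-coordinate grids")
    depth_a = pmf_minimum(profile_a).depth
    depth_b = pmf_minimum(profile_b).depth

    def _min_se(profile):
        if profile.se is None:
            return 0.0
        finite = np.isfinite(profile.pmf)
        i = int(np.nanargmin(np.where(finite, profile.pmf, np.nan)))
        s = profile.se[i]
        return float(s) if np.isfinite(s) else 0.0

    err = math.hypot(_min_se(profile_a), _min_se(profile_b))
    return depth_a - depth_b, err
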
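"""Sedimentation-velocity simulation (Lamm equation) and c(s) distribution fitting.

The forward model solves the Lamm equation in a sector-shaped cell with a
conservative Crank–Nicolson finite-volume scheme (zero flux at meniscus and
base).  c(s) analysis regresses the scan matrix onto unit-signal
single-species basis solutions — with diffusion tied to s through a global
frictional ratio f/f0 via the Svedberg relation — using Tikhonov-regularized
non-negative least squares, as in the standard c(s) framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.optimize
from scipy.signal import find_peaks

KB = 1.380649e-16  # erg/K
RPM_TO_RAD = 2.0 * np.pi / 60.0
S_UNIT = 1e-13  # Svedberg in seconds

WATER_20C_DENSITY = 0.99823  # g/mL
WATER_20C_VISCOSITY = 1.002  # cP


@dataclass
class SolventParams:
    density: float = WATER_20C_DENSITY  # g/mL
    viscosity: float = WATER_20C_VISCOSITY  # cP
    vbar: float = 0.73  # mL/g
    temperature_c: float = 20.0

    def __post_init__(self) -> None:
        if abs(1.0 - self.vbar * self.density) < 1e-9:
            raise ValueError("neutral buoyancy: 1 - vbar*rho = 0")


@dataclass
class ExperimentDesign:
    meniscus_cm: float = 6.0
    base_cm: float = 7.2
    n_radii: int = 200
    n_scans: int = 30
    duration_s: float = 3.0 * 3600.0
    rpm: float = 50000.0

    def __post_init__(self) -> None:
        if self.meniscus_cm >= self.base_cm:
            raise ValueError("meniscus must be < base")

    @property
    def omega(self) -> float:
        return self.rpm * RPM_TO_RAD

    @property
    def radii(self) -> np.ndarray:
        return np.linspace(self.meniscus_cm, self.base_cm, self.n_radii)

    @property
    def scan_times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration_s, self.n_scans + 1)[1:]


@dataclass
class SVExperiment:
    radii: np.ndarray  # cm, ascending
    times: np.ndarray  # s, ascending
    omega: float  # rad/s
    absorbance: np.ndarray  # (n_scans, n_radii)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must ascend")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must ascend")
        if self.absorbance.shape != (len(self.times), len(self.radii)):
            raise ValueError("absorbance must be (scans, radii)")


@dataclass
class CsDistribution:
    s_grid: np.ndarray  # Svedberg
    cs: np.ndarray  # signal per S, >= 0
    alpha: float
    ff0: float
    peaks: list[tuple[float, float]] = field(default_factory=list)  # (s, height)
    rmsd: float = np.nan

    def total_signal(self) -> float:
        return float(np.trapezoid(self.cs, self.s_grid))


def diffusion_from_s(
    s_svedberg: float, ff0: float, solvent: SolventParams
) -> float:
    """D(s) from the Svedberg relation with a global frictional ratio (cm²/s).

    D = kT·√2/(18π) · ((1−v̄ρ)/(v̄·s))^½ · (η·f/f0)^(−3/2), CGS units.
    """
    s = s_svedberg * S_UNIT
    t_k = solvent.temperature_c + 273.15
    eta_poise = solvent.viscosity * 0.01
    buoy = 1.0 - solvent.vbar * solvent.density
    if buoy <= 0:
        raise ValueError("negative or zero buoyancy term")
    return float(
        KB * t_k * np.sqrt(2.0) / (18.0 * np.pi)
        * np.sqrt(buoy / (solvent.vbar * s))
        * (eta_poise * ff0) ** -1.5
    )


def _lamm_matrices(
    radii: np.ndarray, s_cgs: float, d_cgs: float, omega: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Crank–Nicolson banded matrices for the sector-cell Lamm operator.

    Conservative finite-volume discretization with Scharfetter–Gummel
    (exponential-fitting) face fluxes, zero flux at meniscus and base: the
    outward face flux is J = (D/Δr)·[B(−Pe)·c_i − B(Pe)·c_{i+1}] with
    Pe = w·Δr/D and B(x) = x/(eˣ−1), which reduces to central differencing
    at small Péclet and to upwinding at large.  Returns (lhs_banded,
    rhs_dense) for scipy.linalg.solve_banded.
    """

    def bern(x: float) -> float:
        if abs(x) < 1e-10:
            return 1.0 - 0.5 * x
        return x / np.expm1(x)

    n = len(radii)
    dr = radii[1] - radii[0]
    op = np.zeros((n, n))
    for i in range(n - 1):
        rf = 0.5 * (radii[i] + radii[i + 1])
        w = s_cgs * omega**2 * rf  # outward advection speed at the face
        pe = w * dr / d_cgs
        a_lo = rf * (d_cgs / dr) * bern(-pe)  # multiplies c_i (outflow side)
        a_hi = rf * (d_cgs / dr) * bern(pe)  # multiplies c_{i+1}
        # face flux J = a_lo*c_i - a_hi*c_{i+1}; leaves cell i, enters cell i+1
        op[i, i] += -a_lo / (radii[i] * dr)
        op[i, i + 1] += a_hi / (radii[i] * dr)
        op[i + 1, i] += a_lo / (radii[i + 1] * dr)
        op[i + 1, i + 1] += -a_hi / (radii[i + 1] * dr)
    lhs = np.eye(n) - 0.5 * dt * op
    rhs = np.eye(n) + 0.5 * dt * op
    ab = np.zeros((3, n))
    ab[0, 1:] = np.diag(lhs, 1)
    ab[1, :] = np.diag(lhs)
    ab[2, :-1] = np.diag(lhs, -1)
    return ab, rhs


def solve_lamm(
    radii: np.ndarray,
    times: np.ndarray,
    omega: float,
    s_svedberg: float,
    d_cm2s: float,
    c0: float = 1.0,
    dt_internal: float = 20.0,
    peclet_limit: float = 20.0,
) -> np.ndarray:
    """Concentration profiles c(r, t) for one species, uniform initial loading.

    Raises if the cell Péclet number s·ω²·r·Δr/D exceeds ``peclet_limit``:
    exponential fitting keeps the scheme positive, but the boundary shape
    degrades on a grid that coarse — refine the radial grid instead.
    """
    s_cgs = s_svedberg * S_UNIT
    dr = radii[1] - radii[0]
    peclet = s_cgs * omega**2 * radii[-1] * dr / d_cm2s
    if peclet > peclet_limit:
        raise ValueError(
            f"cell Péclet {peclet:.2f} > {peclet_limit}: refine the radial grid"
        )
    ab, rhs = _lamm_matrices(radii, s_cgs, d_cm2s, omega, dt_internal)
    c = np.full(len(radii), c0)
    out = np.empty((len(times), len(radii)))
    t_now = 0.0
    for k, t_target in enumerate(times):
        while t_now < t_target - 1e-9:
            step = min(dt_internal, t_target - t_now)
            if abs(step - dt_internal) > 1e-9:
                ab_s, rhs_s = _lamm_matrices(radii, s_cgs, d_cm2s, omega, step)
                c = scipy.linalg.solve_banded((1, 1), ab_s, rhs_s @ c)
            else:
                c = scipy.linalg.solve_banded((1, 1), ab, rhs @ c)
            t_now += step
        out[k] = c
    return out


def sector_integral(radii: np.ndarray, profile: np.ndarray) -> float:
    """Sector-weighted total signal Σ c·r·Δr (sector area ∝ r).

    Uses the finite-volume cell sum, under which the solver conserves signal
    exactly while both boundary fluxes are zero.
    """
    dr = radii[1] - radii[0]
    return float(np.sum(profile * radii) * dr)


def simulate_sv(
    species: list[tuple[float, float, float]],  # (s in S, D in cm²/s, signal)
    design: ExperimentDesign | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt_internal: float = 20.0,
) -> SVExperiment:
    """Forward-simulate a multi-species sedimentation-velocity experiment."""
    design = design or ExperimentDesign()
    for s, d, sig in species:
        if s <= 0 or d <= 0 or sig <= 0:
            raise ValueError("species s, D, signal must all be > 0")
    radii, times, omega = design.radii, design.scan_times, design.omega
    total = np.zeros((len(times), len(radii)))
    for s, d, sig in species:
        total += sig * solve_lamm(radii, times, omega, s, d, dt_internal=dt_internal)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        total = total + rng.normal(0.0, noise_sd, size=total.shape)
    return SVExperiment(radii, times, omega, total, noise_sd)


def write_scans(e: SVExperiment, path: str | Path) -> None:
    """Scan matrix as delimited text: first column radius, one column per scan."""
    with open(path, "w") as fh:
        fh.write("radius_cm\t" + "\t".join(f"{t:.1f}" for t in e.times) + "\n")
        for i, r in enumerate(e.radii):
            fh.write(
                f"{r:.5f}\t" + "\t".join(f"{v:.6f}" for v in e.absorbance[:, i]) + "\n"
            )


def read_scans(path: str | Path, omega: float) -> SVExperiment:
    with open(path) as fh:
        header = fh.readline().split("\t")
    times = np.array([float(x) for x in header[1:]])
    data = np.loadtxt(path, skiprows=1)
    return SVExperiment(data[:, 0], times, omega, data[:, 1:].T)


def fit_cs(
    e: SVExperiment,
    s_grid: np.ndarray,
    ff0: float = 1.2,
    alpha: float = 0.1,
    solvent: SolventParams | None = None,
    dt_internal: float = 20.0,
    peak_rel_height: float = 0.05,
) -> CsDistribution:
    """Fit a regularized continuous c(s) distribution to the scan matrix.

    Builds unit-signal Lamm basis solutions on the s grid (D(s) from the
    global f/f0), then solves a Tikhonov-regularized NNLS on the flattened
    scan matrix.  Peaks are local maxima above ``peak_rel_height`` of the
    distribution maximum, refined parabolically.
    """
    solvent = solvent or SolventParams()
    s_grid = np.asarray(s_grid, dtype=float)
    if len(s_grid) < 3:
        raise ValueError("s grid too small: basis under-determined")
    n_obs = e.absorbance.size
    basis = np.empty((n_obs, len(s_grid)))
    for j, s in enumerate(s_grid):
        d = diffusion_from_s(float(s), ff0, solvent)
        prof = solve_lamm(
            e.radii, e.times, e.omega, float(s), d, dt_internal=dt_internal
        )
        basis[:, j] = prof.ravel()
    b = e.absorbance.ravel()

    m = len(s_grid)
    d2 = np.zeros((m - 2, m))
    for i in range(m - 2):
        d2[i, i : i + 3] = (1.0, -2.0, 1.0)
    reg_scale = np.linalg.norm(basis) / max(np.linalg.norm(d2), 1e-12)
    a = np.vstack([basis, alpha * reg_scale * d2])
    rhs = np.concatenate([b, np.zeros(m - 2)])
    coeffs, _ = scipy.optimize.nnls(a, rhs)

    ds = np.gradient(s_grid)
    cs = coeffs / ds  # signal per Svedberg
    resid = basis @ coeffs - b
    rmsd = float(np.sqrt(np.mean(resid**2)))

    peaks = []
    if cs.max() > 0:
        idx, _ = find_peaks(cs, height=peak_rel_height * cs.max())
        for p in idx:
            if 0 < p < len(cs) - 1:
                y0, y1, y2 = cs[p - 1 : p + 2]
                denom = y0 - 2 * y1 + y2
                shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
                sp = s_grid[p] + shift * (s_grid[min(p + 1, m - 1)] - s_grid[p])
            else:
                sp = s_grid[p]
            peaks.append((float(sp), float(cs[p])))
    return CsDistribution(
        s_grid=s_grid, cs=cs, alpha=alpha, ff0=ff0, peaks=peaks, rmsd=rmsd
    )


def standardize_s(
    s_obs: float,
    p: SolventParams,
    ref_density: float = WATER_20C_DENSITY,
    ref_viscosity: float = WATER_20C_VISCOSITY,
) -> float:
    """Standardize an observed sedimentation coefficient to water at 20 °C.

    s20,w = s_obs · (η_b/η_20,w) · (1 − v̄ρ_20,w)/(1 − v̄ρ_b).
    """
    buoy_b = 1.0 - p.vbar * p.density
    if abs(buoy_b) < 1e-12:
        raise ValueError("neutral buoyancy in experimental buffer")
    buoy_ref = 1.0 - p.vbar * ref_density
    return float(s_obs * (p.viscosity / ref_viscosity) * (buoy_ref / buoy_b))
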
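"""Native-MS charge-envelope simulation and mass deconvolution.

An intact complex of neutral mass M electrosprayed in positive mode yields
peaks at m/z = (M + z·m_p)/z for consecutive charge states z.  Deconvolution
assigns charges from adjacent-peak spacings and forms consensus masses by
clustering the per-peak estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PROTON_MASS = 1.00728  # Da, charge carrier in positive mode


class AmbiguityError(ValueError):
    """A single peak cannot determine charge and mass."""


class NoSolutionError(ValueError):
    """No self-consistent charge assignment in the search range."""


@dataclass
class ChargeEnvelope:
    mz: np.ndarray  # Thomson, > 0
    intensity: np.ndarray  # >= 0
    charges: np.ndarray | None = None  # optional known annotations

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.mz) < 1:
            raise ValueError("envelope needs at least one peak")
        if np.any(self.mz <= 0):
            raise ValueError("m/z must be > 0")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class MassSolution:
    mass: float  # Da
    charge_range: tuple[int, int]
    n_peaks: int
    mass_sd: float  # Da, spread of per-peak estimates
    peak_residuals: np.ndarray = field(default_factory=lambda: np.array([]))  # Th

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be > 0")
        if self.n_peaks < 2:
            raise ValueError("a solution needs >= 2 supporting peaks")


def read_peaklist(path: str | Path) -> ChargeEnvelope:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return ChargeEnvelope(data[:, 0], data[:, 1])


def write_peaklist(e: ChargeEnvelope, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mz intensity\n")
        for mz, inten in zip(e.mz, e.intensity):
            fh.write(f"{mz:.5f} {inten:.6e}\n")


def simulate_envelope(
    mass: float,
    charges: range | list[int],
    z_center: float | None = None,
    z_width: float = 3.0,
    mz_noise_sd: float = 0.0,
    seed: int | None = None,
    proton_mass: float = PROTON_MASS,
) -> ChargeEnvelope:
    """Simulate an ESI envelope: one peak per charge state, Gaussian z-profile."""
    if mass <= 0:
        raise ValueError("mass must be > 0")
    charges = np.array(sorted(charges), dtype=int)
    if len(charges) == 0:
        raise ValueError("charges must be non-empty")
    rng = np.random.default_rng(seed)
    if z_center is None:
        z_center = float(charges.mean())
    mz = (mass + charges * proton_mass) / charges
    if mz_noise_sd > 0:
        mz = mz + rng.normal(0.0, mz_noise_sd, size=len(mz))
    intensity = np.exp(-0.5 * ((charges - z_center) / z_width) ** 2)
    order = np.argsort(mz)
    return ChargeEnvelope(mz[order], intensity[order], charges[order])


def deconvolve(
    e: ChargeEnvelope,
    z_min: int = 1,
    z_max: int = 100,
    proton_mass: float = PROTON_MASS,
    cluster_rel_width: float = 2e-4,
) -> list[MassSolution]:
    """Consensus charge-state assignment from adjacent-peak spacings.

    For adjacent peaks x₁ > x₂ of the same species carrying consecutive
    charges, z(x₁) = round((x₂ − m_p)/(x₁ − x₂)).  Per-peak masses
    M = z·(x − m_p) are clustered (width = cluster_rel_width × mass) and
    clusters are ranked by supporting-peak count, then residual.
    """
    if len(e) < 2:
        raise AmbiguityError("a single peak cannot be deconvolved")
    mz = np.sort(e.mz)[::-1]  # descending
    estimates: list[tuple[float, int, float]] = []  # (mass, z, mz)
    for x1, x2 in zip(mz[:-1], mz[1:]):
        gap = x1 - x2
        if gap <= 0:
            continue
        z = int(round((x2 - proton_mass) / gap))
        if not z_min <= z <= z_max:
            continue
        estimates.append((z * (x1 - proton_mass), z, x1))
        estimates.append(((z + 1) * (x2 - proton_mass), z + 1, x2))
    if not estimates:
        raise NoSolutionError("no adjacent-pair charge in search range")

    estimates.sort(key=lambda t: t[0])
    clusters: list[list[tuple[float, int, float]]] = []
    for est in estimates:
        if clusters and abs(est[0] - np.mean([x[0] for x in clusters[-1]])) <= (
            cluster_rel_width * est[0]
        ):
            clusters[-1].append(est)
        else:
            clusters.append([est])

    solutions = []
    for cl in clusters:
        # one estimate per distinct peak (a peak can appear in two pairs)
        by_peak: dict[float, tuple[float, int, float]] = {}
        for est in cl:
            by_peak[est[2]] = est
        if len(by_peak) < 2:
            continue
        masses = np.array([v[0] for v in by_peak.values()])
        zs = np.array([v[1] for v in by_peak.values()])
        mass = float(masses.mean())
        residuals = np.array(
            [x - (mass + z * proton_mass) / z for (_, z, x) in by_peak.values()]
        )
        solutions.append(
            MassSolution(
                mass=mass,
                charge_range=(int(zs.min()), int(zs.max())),
                n_peaks=len(by_peak),
                mass_sd=float(masses.std()),
                peak_residuals=residuals,
            )
        )
    if not solutions:
        raise NoSolutionError("no cluster with >= 2 supporting peaks")
    solutions.sort(key=lambda s: (-s.n_peaks, float(np.abs(s.peak_residuals).mean())))
    return solutions


def species_report(
    solutions: list[MassSolution], monomer_mass: float
) -> list[dict]:
    """Annotate each solution with its oligomer number and ppm deviation."""
    if monomer_mass <= 0:
        raise ValueError("monomer mass must be > 0")
    out = []
    for s in solutions:
        n = max(1, int(round(s.mass / monomer_mass)))
        expected = n * monomer_mass
        ppm = (s.mass - expected) / expected * 1e6
        out.append(
            {
                "mass": s.mass,
                "n_mer": n,
                "ppm_deviation": ppm,
                "n_peaks": s.n_peaks,
                "charge_range": s.charge_range,
            }
        )
    return out
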
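"""SAXS analysis and C4-symmetric restrained rigid-body tetramer modeling.

Curve analysis: self-consistent Guinier fitting, regularized indirect
Fourier transform P(r) with Dmax estimation, Debye-formula model scattering
and χ fitting.  Assembly modeling: a single protomer pose (three rotation
angles + radial offset from the four-fold axis) parameterizes an exact
C4 tetramer, optimized by seeded simulated annealing against a target curve
under homotypic inter-protomer distance restraints and a clash penalty,
with an optional harmonic local refinement stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.optimize
from scipy.spatial.transform import Rotation

from .struct_io import CalphaModel


class NoGuinierRegionError(ValueError):
    pass


class UnboundedDmaxError(ValueError):
    pass


@dataclass
class SAXSCurve:
    q: np.ndarray  # Å^-1, strictly ascending, > 0
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (np.all(self.q > 0) and np.all(np.diff(self.q) > 0)):
            raise ValueError("q must be positive and strictly ascending")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be > 0")
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise ValueError("q, I, sigma must have equal length")

    def __len__(self) -> int:
        return len(self.q)


def read_curve(path: str | Path) -> SAXSCurve:
    """Read a 3-column (q, I, sigma) whitespace-delimited text curve."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("expected 3 columns: q, I, sigma")
    return SAXSCurve(data[:, 0], data[:, 1], data[:, 2])


def write_curve(c: SAXSCurve, path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for q, i, s in zip(c.q, c.intensity, c.sigma):
            fh.write(f"{q:.6e} {i:.6e} {s:.6e}\n")


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_window: tuple[float, float]
    n_points: int
    qmax_rg: float
    residual_rms: float

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValueError("Rg must be > 0")


def guinier_fit(c: SAXSCurve, qrg_limit: float = 1.3, min_points: int = 5) -> GuinierFit:
    """Self-consistent Guinier fit: ln I vs q² over the largest low-q window
    with qmax·Rg ≤ limit.

    Weighted linear least squares (weights from σ propagated to ln I);
    Rg = sqrt(−3·slope), I0 = exp(intercept).
    """
    pos = c.intensity > 0
    q, inten, sig = c.q[pos], c.intensity[pos], c.sigma[pos]
    if len(q) < min_points:
        raise NoGuinierRegionError("too few positive-intensity points")
    y = np.log(inten)
    w = inten / sig  # d(lnI) = dI/I

    best: GuinierFit | None = None
    for n in range(len(q), min_points - 1, -1):
        x = q[:n] ** 2
        slope, intercept = np.polyfit(x, y[:n], 1, w=w[:n])
        if slope >= 0:
            continue
        rg = float(np.sqrt(-3.0 * slope))
        if q[n - 1] * rg <= qrg_limit:
            resid = y[:n] - (slope * x + intercept)
            best = GuinierFit(
                rg=rg,
                i0=float(np.exp(intercept)),
                q_window=(float(q[0]), float(q[n - 1])),
                n_points=n,
                qmax_rg=float(q[n - 1] * rg),
                residual_rms=float(np.sqrt(np.mean(resid**2))),
            )
            break
    if best is None:
        raise NoGuinierRegionError("no self-consistent Guinier window found")
    return best


@dataclass
class PofR:
    r: np.ndarray  # 0 … Dmax grid
    p: np.ndarray  # P(r) >= 0, P(0) = P(Dmax) = 0
    dmax: float
    rg: float  # real-space radius of gyration
    alpha: float
    back_fit: SAXSCurve | None = None
    back_chi: float = np.nan

    def peak(self) -> float:
        return float(self.p.max())


def _ift_kernel(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """K[k, j] = Δr · sin(q_k r_j)/(q_k r_j); constants absorbed by scale."""
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(qr > 0, np.sin(qr) / qr, 1.0)
    return k * dr


def pofr_transform(
    c: SAXSCurve, dmax: float, alpha: float = 1.0, n_r: int = 101
) -> PofR:
    """Regularized indirect Fourier transform of a scattering curve.

    Solves  min ‖(I − K·P)/σ‖² + α‖D²P‖²  with P ≥ 0 and P pinned to zero at
    r = 0 and r = Dmax, on a fixed r grid; reports real-space Rg and the
    back-transformed curve with its residual χ.
    """
    if dmax <= 0:
        raise ValueError("dmax must be > 0")
    if alpha <= 0:
        raise ValueError("ill-conditioned at alpha = 0; pass alpha > 0")
    r = np.linspace(0.0, dmax, n_r)
    kernel = _ift_kernel(c.q, r)
    # endpoint constraint: drop first and last columns (P=0 there)
    inner = slice(1, n_r - 1)
    a_data = kernel[:, inner] / c.sigma[:, None]
    b_data = c.intensity / c.sigma
    # second-difference smoother over the inner grid
    m = n_r - 2
    d2 = np.zeros((m, m))
    for i in range(m):
        d2[i, i] = -2.0
        if i > 0:
            d2[i, i - 1] = 1.0
        if i < m - 1:
            d2[i, i + 1] = 1.0
    scale = np.median(np.abs(a_data)) * np.sqrt(len(c)) / max(m, 1)
    a = np.vstack([a_data, np.sqrt(alpha) * scale * d2])
    b = np.concatenate([b_data, np.zeros(m)])
    p_inner, _ = scipy.optimize.nnls(a, b)
    p = np.zeros(n_r)
    p[inner] = p_inner

    if p.sum() <= 0:
        raise ValueError("degenerate P(r): all-zero solution")
    rg = float(np.sqrt((p * r**2).sum() / (2.0 * p.sum())))
    back_i = kernel @ p
    chi = float(
        np.sqrt(np.sum(((c.intensity - back_i) / c.sigma) ** 2) / (len(c) - 1))
    )
    back = SAXSCurve(c.q, back_i, c.sigma)
    return PofR(r=r, p=p, dmax=dmax, rg=rg, alpha=alpha, back_fit=back, back_chi=chi)


def estimate_dmax(
    c: SAXSCurve,
    scan: np.ndarray | tuple[float, float, int],
    alpha: float = 1.0,
    tail_fraction: float = 0.01,
    chi_slack: float = 0.05,
    min_signal_to_noise: float = 3.0,
) -> float:
    """Scan candidate Dmax values; pick the smallest that closes P(r).

    Criteria: the last P(r) bin before Dmax is ≤ ``tail_fraction`` of the
    peak AND the back-fit residual is within ``chi_slack`` of its minimum
    over the scan.  Candidates whose back-transformed I(0) falls below
    ``min_signal_to_noise`` × median σ are discarded as signal-free (this is
    how a pure-noise curve is rejected).
    """
    if isinstance(scan, tuple):
        scan = np.linspace(*scan)
    noise_floor = min_signal_to_noise * float(np.median(c.sigma))
    results = []
    for d in scan:
        try:
            pr = pofr_transform(c, float(d), alpha=alpha)
        except ValueError:
            results.append((d, np.inf, np.inf))
            continue
        i0_back = float(pr.p.sum() * (pr.r[1] - pr.r[0]))
        if i0_back < noise_floor:
            results.append((d, np.inf, np.inf))
            continue
        tail = pr.p[-2] / pr.peak() if pr.peak() > 0 else np.inf
        results.append((d, tail, pr.back_chi))
    chis = np.array([r[2] for r in results])
    if not np.isfinite(chis).any():
        raise UnboundedDmaxError("no candidate Dmax produced a valid P(r)")
    chi_min = np.nanmin(chis[np.isfinite(chis)])
    for d, tail, chi in results:
        if tail <= tail_fraction and np.isfinite(chi) and chi <= chi_min * (1 + chi_slack):
            return float(d)
    raise UnboundedDmaxError("Dmax criteria never met over the scan range")


def debye_scatter(
    coords: np.ndarray,
    q: np.ndarray,
    form_factors: np.ndarray | None = None,
) -> SAXSCurve:
    """Debye-formula scattering of a bead model: I(q) = Σ fᵢfⱼ sin(qrᵢⱼ)/(qrᵢⱼ).

    σ is set to 1% of I (floor 1e-6·I(0)) so the result is a valid curve;
    callers modeling noise should overwrite it.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    q = np.asarray(q, dtype=float)
    n = len(coords)
    if n < 1:
        raise ValueError("need at least one bead")
    f = np.ones(n) if form_factors is None else np.asarray(form_factors, dtype=float)
    i0 = float(f.sum() ** 2)
    if n == 1:
        inten = np.full(len(q), f[0] ** 2)
    else:
        iu, ju = np.triu_indices(n, k=1)
        rij = np.linalg.norm(coords[iu] - coords[ju], axis=1)
        ff = f[iu] * f[ju]
        qr = np.outer(q, rij)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr > 0, np.sin(qr) / qr, 1.0)
        inten = (f**2).sum() + 2.0 * (sinc * ff).sum(axis=1)
    sigma = np.maximum(0.01 * np.abs(inten), 1e-6 * max(i0, 1.0))
    return SAXSCurve(q, inten, sigma)


def _debye_binned(
    coords: np.ndarray, q: np.ndarray, bin_width: float = 0.2
) -> np.ndarray:
    """Fast Debye intensity via pair-distance histogramming (unit form factors).

    Exact up to the distance quantization (relative error ≈ (q·Δ/2)²/6,
    <1e-4 at q = 0.25 Å⁻¹ and Δ = 0.2 Å); used inside fitting loops.
    """
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    rij = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    bins = np.round(rij / bin_width).astype(np.int64)
    counts = np.bincount(bins)
    r_centers = np.arange(len(counts)) * bin_width
    qr = np.outer(q, r_centers[counts > 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / qr, 1.0)
    return n + 2.0 * (sinc * counts[counts > 0]).sum(axis=1)


def coordinate_rg(coords: np.ndarray, weights: np.ndarray | None = None) -> float:
    coords = np.asarray(coords, dtype=float)
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, float)
    c = (coords * w[:, None]).sum(0) / w.sum()
    return float(np.sqrt((w * ((coords - c) ** 2).sum(1)).sum() / w.sum()))


def chi_fit(model: SAXSCurve, data: SAXSCurve) -> tuple[float, float]:
    """χ between a model curve and data with the optimal scale factor.

    The model is evaluated on (interpolated to) the data grid; the scale c
    minimizing Σ((I_d − c·I_m)/σ)² has the closed form
    c = Σ(I_d·I_m/σ²)/Σ(I_m²/σ²).
    """
    if len(data) < 2:
        raise ValueError("need at least 2 data points")
    im = np.interp(data.q, model.q, model.intensity)
    w = 1.0 / data.sigma**2
    scale = float((w * data.intensity * im).sum() / (w * im * im).sum())
    resid = (data.intensity - scale * im) / data.sigma
    chi = float(np.sqrt((resid**2).sum() / (len(data) - 1)))
    return chi, scale


# ---------------------------------------------------------------------------
# C4 rigid-body modeling
# ---------------------------------------------------------------------------

@dataclass
class RestraintSpec:
    """Homotypic inter-protomer restraints for tetramer modeling."""

    residues: tuple[int, ...] = (157, 173, 305)
    upper_bound: float = 35.0  # rigid-body stage: flat-bottom max distance
    harmonic_target: float = 30.0  # refinement stage
    force_constant: float = 10.0  # energy / Å² (paper units ambiguous)


@dataclass
class TetramerModel:
    protomer: CalphaModel
    pose: np.ndarray  # (4,): rotvec (3) + radial offset ρ (Å)
    chains: list[CalphaModel] = field(default_factory=list)
    chi: float = np.nan
    scale: float = np.nan
    restraint_distances: dict[int, float] = field(default_factory=dict)
    restraint_energy: float = np.nan
    objective_trace: list[float] = field(default_factory=list)
    seed: int | None = None


def _posed_protomer(protomer: CalphaModel, pose: np.ndarray) -> np.ndarray:
    """Protomer centered, rotated by the pose rotvec, shifted ρ along +x."""
    rot = Rotation.from_rotvec(pose[:3]).as_matrix()
    centered = protomer.coords - protomer.coords.mean(axis=0)
    return centered @ rot.T + np.array([pose[3], 0.0, 0.0])


_C4_ROTS = [
    Rotation.from_euler("z", 90.0 * k, degrees=True).as_matrix() for k in range(4)
]


def assemble_c4(protomer: CalphaModel, pose: np.ndarray) -> list[CalphaModel]:
    """Replicate the posed protomer by exact 90° rotations about z."""
    pose = np.asarray(pose, dtype=float)
    base = _posed_protomer(protomer, pose)
    chains = []
    for k, rz in enumerate(_C4_ROTS):
        chain = protomer.copy()
        chain.coords = base @ rz.T
        chain.chain_ids = np.array([chr(ord("A") + k)] * len(protomer), dtype=object)
        chains.append(chain)
    return chains


def _assembly_coords(chains: list[CalphaModel]) -> np.ndarray:
    return np.vstack([c.coords for c in chains])


def _restraint_distances(
    chains: list[CalphaModel], residues: tuple[int, ...]
) -> dict[int, float]:
    """Min homotypic distance to a neighboring protomer (equal for all pairs by symmetry)."""
    idx = {int(r): i for i, r in enumerate(chains[0].res_ids)}
    out = {}
    for res in residues:
        if res not in idx:
            raise ValueError(f"restraint residue {res} not in protomer")
        a = chains[0].coords[idx[res]]
        b = chains[1].coords[idx[res]]  # adjacent protomer (90°)
        out[res] = float(np.linalg.norm(a - b))
    return out


def _clash_penalty(chains: list[CalphaModel], cutoff: float = 3.0) -> float:
    """Quadratic penalty on inter-protomer Cα approaches below cutoff."""
    a = chains[0].coords
    pen = 0.0
    for other in chains[1:]:
        d = np.linalg.norm(a[:, None, :] - other.coords[None, :, :], axis=-1)
        close = d[d < cutoff]
        pen += float(((cutoff - close) ** 2).sum())
    return pen * 4.0 / 2.0  # all ordered pairs relative to one protomer, halved


def tetramer_objective(
    protomer: CalphaModel,
    pose: np.ndarray,
    data: SAXSCurve,
    restraints: RestraintSpec,
    w_restraint: float = 10.0,
    w_clash: float = 1.0,
) -> tuple[float, float, float, dict[int, float]]:
    """Return (objective, χ, scale, restraint distances) for a pose."""
    chains = assemble_c4(protomer, pose)
    coords = _assembly_coords(chains)
    inten = _debye_binned(coords, data.q)
    model_curve = SAXSCurve(data.q, inten, np.maximum(0.01 * np.abs(inten), 1e-12))
    chi, scale = chi_fit(model_curve, data)
    dists = _restraint_distances(chains, restraints.residues)
    pen = sum(
        max(0.0, d - restraints.upper_bound) ** 2 for d in dists.values()
    )
    clash = _clash_penalty(chains)
    obj = chi**2 + w_restraint * pen + w_clash * clash
    return obj, chi, scale, dists


def rigid_body_fit(
    protomer: CalphaModel,
    data: SAXSCurve,
    restraints: RestraintSpec | None = None,
    seed: int = 0,
    t0: float = 2.0,
    tf: float = 0.01,
    steps: int = 400,
    rho_init: float | None = None,
    w_restraint: float = 10.0,
    w_clash: float = 1.0,
    polish: bool = True,
) -> TetramerModel:
    """Simulated-annealing search over (rotation, ρ) for a C4 tetramer.

    Geometric cooling from t0 to tf; proposals are small random rotations
    (≤ 5°) and ρ steps (≤ 2 Å).  An optional Nelder–Mead polish descends
    from the annealing optimum.  Deterministic given the seed.
    """
    restraints = restraints or RestraintSpec()
    rng = np.random.default_rng(seed)
    if rho_init is None:
        # start beyond the protomer radius so copies do not overlap
        rad = np.linalg.norm(
            protomer.coords - protomer.coords.mean(axis=0), axis=1
        ).max()
        rho_init = float(rad) + 5.0
    pose = np.array([0.0, 0.0, 0.0, rho_init])
    obj, chi, scale, dists = tetramer_objective(
        protomer, pose, data, restraints, w_restraint, w_clash
    )
    best_pose, best = pose.copy(), (obj, chi, scale, dists)
    trace = [obj]
    cooling = (tf / t0) ** (1.0 / max(steps - 1, 1))
    temp = t0
    n_accept = 0
    for _ in range(steps):
        prop = pose.copy()
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(0.0, 5.0))
        r_new = Rotation.from_rotvec(axis * angle) * Rotation.from_rotvec(prop[:3])
        prop[:3] = r_new.as_rotvec()
        prop[3] = max(0.0, prop[3] + rng.uniform(-2.0, 2.0))
        o2, c2, s2, d2 = tetramer_objective(
            protomer, prop, data, restraints, w_restraint, w_clash
        )
        if o2 < obj or rng.random() < np.exp(-(o2 - obj) / temp):
            pose, obj, chi, scale, dists = prop, o2, c2, s2, d2
            n_accept += 1
            if obj < best[0]:
                best_pose, best = pose.copy(), (obj, chi, scale, dists)
        trace.append(obj)
        temp *= cooling
    if n_accept == 0:
        import warnings

        warnings.warn("annealing stalled: no proposal accepted; returning best-so-far")
    if polish:
        res = scipy.optimize.minimize(
            lambda p: tetramer_objective(
                protomer, p, data, restraints, w_restraint, w_clash
            )[0],
            best_pose,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 300},
        )
        if res.fun < best[0]:
            best_pose = res.x
            best = tetramer_objective(
                protomer, best_pose, data, restraints, w_restraint, w_clash
            )
            trace.append(best[0])
    obj, chi, scale, dists = best
    chains = assemble_c4(protomer, best_pose)
    energy = restraints.force_constant * sum(
        (d - restraints.harmonic_target) ** 2 for d in dists.values()
    )
    return TetramerModel(
        protomer=protomer,
        pose=best_pose,
        chains=chains,
        chi=chi,
        scale=scale,
        restraint_distances=dists,
        restraint_energy=energy,
        objective_trace=trace,
        seed=seed,
    )


def refine_restrained(
    t: TetramerModel,
    spec: RestraintSpec | None = None,
    w_clash: float = 1.0,
) -> TetramerModel:
    """Local pose optimization under harmonic wells k(d − target)² + clash.

    Symmetry is preserved exactly (only the protomer pose moves); restraint
    energies are reported before and after in the objective trace.
    """
    spec = spec or (RestraintSpec() if not t.restraint_distances else RestraintSpec(
        residues=tuple(t.restraint_distances)
    ))

    def objective(pose):
        chains = assemble_c4(t.protomer, pose)
        dists = _restraint_distances(chains, spec.residues)
        e = spec.force_constant * sum(
            (d - spec.harmonic_target) ** 2 for d in dists.values()
        )
        return e + w_clash * _clash_penalty(chains)

    e_before = objective(t.pose)
    res = scipy.optimize.minimize(
        objective, t.pose, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
    )
    pose = res.x if res.fun <= e_before else t.pose
    chains = assemble_c4(t.protomer, pose)
    dists = _restraint_distances(chains, spec.residues)
    energy = spec.force_constant * sum(
        (d - spec.harmonic_target) ** 2 for d in dists.values()
    )
    return TetramerModel(
        protomer=t.protomer,
        pose=np.asarray(pose, dtype=float),
        chains=chains,
        chi=t.chi,
        scale=t.scale,
        restraint_distances=dists,
        restraint_energy=energy,
        objective_trace=[e_before, float(min(res.fun, e_before))],
        seed=t.seed,
    )
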
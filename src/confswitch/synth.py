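"""Seeded synthetic-data generators for every pipeline input.

Every generator draws randomness from a single spec-level seed through
``numpy.random.SeedSequence`` child spawning (one child per named stream),
and scenario emitters serialize the latent ground truth as a key-value
sidecar next to each artifact so downstream tests compare against recorded
truth, never re-derived values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from . import auc, binding, nativems, saxs
from .struct_io import CalphaModel
from .xlms import DEFAULT_BOUNDS

HELIX_RADIUS = 2.3  # Å, Cα helix radius
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)
CA_BOND = 3.8  # Å, sequential Cα spacing


@dataclass
class GeneratorSpec:
    seed: int
    scenario: str
    ground_truth: dict = field(default_factory=dict)

    def stream(self, name: str) -> np.random.Generator:
        """Deterministic child generator for a named randomness stream."""
        import zlib

        child = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(zlib.crc32(name.encode()),)
        )
        return np.random.default_rng(child)


def write_sidecar(path: str | Path, truth: dict) -> None:
    """Serialize ground truth as sorted key-value text next to an artifact."""
    with open(path, "w") as fh:
        for k in sorted(truth):
            fh.write(f"{k}\t{json.dumps(truth[k])}\n")


def read_sidecar(path: str | Path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            k, v = line.rstrip("\n").split("\t", 1)
            out[k] = json.loads(v)
    return out


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _helix(n: int, z0: float = 0.0, phase: float = 0.0) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(phase + HELIX_TWIST * i),
            HELIX_RADIUS * np.sin(phase + HELIX_TWIST * i),
            z0 + HELIX_RISE * i,
        ]
    )


def _arc_linker(a: np.ndarray, b: np.ndarray, n_link: int) -> np.ndarray:
    """Linker Cα positions between anchors a and b with bonds as close to
    3.8 Å as geometry allows.

    If the anchor gap fits within (n_link+1) bonds of 3.8 Å, the linker lies
    on a circular arc whose equal sub-chords are exactly 3.8 Å; otherwise
    the bonds stretch uniformly along the straight line (documented
    limitation of short linkers across wide gaps).
    """
    m = n_link + 1  # number of bonds
    chord = float(np.linalg.norm(b - a))
    ts = np.arange(1, n_link + 1) / m
    if chord >= m * CA_BOND - 1e-9:
        return a + np.outer(ts, b - a)  # stretched straight linker

    # solve sin(phi) / sin(phi/m) = chord / 3.8 for the half-arc angle phi
    target = chord / CA_BOND

    def f(phi):
        return np.sin(phi) / np.sin(phi / m) - target

    phi = scipy.optimize.brentq(f, 1e-9, np.pi - 1e-9)
    radius = chord / (2.0 * np.sin(phi))
    u = (b - a) / chord
    # perpendicular bulge direction
    trial = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 0.0, 1.0])
    v = trial - np.dot(trial, u) * u
    v /= np.linalg.norm(v)
    mid = 0.5 * (a + b)
    center = mid - v * radius * np.cos(phi)
    # angles of a and b around the center in the (u, v) plane
    pts = []
    ang_a = np.arctan2(np.dot(a - center, u), np.dot(a - center, v))
    ang_b = np.arctan2(np.dot(b - center, u), np.dot(b - center, v))
    for t in ts:
        ang = ang_a + t * (ang_b - ang_a)
        pts.append(center + radius * (np.sin(ang) * u + np.cos(ang) * v))
    return np.array(pts)


def _hairpin_lobe(n: int, turn_res: int = 3, helix_sep: float = 6.0) -> np.ndarray:
    """Compact antiparallel two-helix hairpin of n residues (torsionally stiff)."""
    n1 = (n - turn_res) // 2
    n2 = n - turn_res - n1
    h1 = _helix(n1)
    ztop = h1[-1, 2]
    i = np.arange(n2)
    h2 = np.column_stack(
        [
            helix_sep + HELIX_RADIUS * np.cos(np.pi + HELIX_TWIST * i),
            HELIX_RADIUS * np.sin(np.pi + HELIX_TWIST * i),
            ztop - HELIX_RISE * i,
        ]
    )
    turn = _arc_linker(h1[-1], h2[0], turn_res)
    return np.vstack([h1, turn, h2])


def make_two_domain_toy(
    n_a: int = 30,
    n_b: int = 30,
    linker_length: int = 5,
    separation: float = 25.0,
    seed: int = 0,
    labels: tuple[str, str, str] = ("A", "linker", "B"),
    res_start: int = 1,
    jitter: float = 0.02,
) -> CalphaModel:
    """Two idealized helical-bundle lobes joined by a linker, lobes a set
    distance apart.

    Each lobe is an antiparallel two-helix hairpin; the minimum inter-lobe
    Cα distance equals ``separation`` (by direct placement); lobe-internal
    sequential distances are ideal-helix 3.8 Å with a tiny seeded jitter.
    """
    if n_a < 10 or n_b < 10:
        raise ValueError("lobes need >= 10 residues")
    if separation < 2 * HELIX_RADIUS:
        raise ValueError(
            f"separation {separation} < sum of lobe radii {2 * HELIX_RADIUS}"
        )
    rng = np.random.default_rng(seed)
    lobe_a = _hairpin_lobe(n_a)
    lobe_b_local = _hairpin_lobe(n_b)
    # lobe B anchored by its first residue, placed beyond lobe A along +x
    lobe_b_local = lobe_b_local - lobe_b_local[0] + lobe_a[-1]

    def min_dist(dx: float) -> float:
        b = lobe_b_local + np.array([dx, 0.0, 0.0])
        d = np.linalg.norm(lobe_a[:, None, :] - b[None, :, :], axis=-1)
        return float(d.min())

    lo, hi = 1e-3, separation + 4 * HELIX_RADIUS + 1.0
    dx = scipy.optimize.brentq(lambda x: min_dist(x) - separation, lo, hi)
    lobe_b = lobe_b_local + np.array([dx, 0.0, 0.0])

    linker = (
        _arc_linker(lobe_a[-1], lobe_b[0], linker_length)
        if linker_length > 0
        else np.empty((0, 3))
    )
    coords = np.vstack([lobe_a, linker, lobe_b])
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    n_total = len(coords)
    domains = (
        [labels[0]] * n_a + [labels[1]] * linker_length + [labels[2]] * n_b
    )
    return CalphaModel(
        coords,
        np.array(["A"] * n_total, dtype=object),
        np.arange(res_start, res_start + n_total),
        np.array(domains, dtype=object),
    )


def make_compact_protomer(
    n: int = 60, seed: int = 0, label: str = "body", jitter: float = 0.02
) -> CalphaModel:
    """A compact antiparallel two-helix hairpin protomer for assembly fixtures."""
    if n < 10:
        raise ValueError("protomer needs >= 10 residues")
    rng = np.random.default_rng(seed)
    coords = _hairpin_lobe(n)
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    return CalphaModel(
        coords,
        np.array(["A"] * n, dtype=object),
        np.arange(1, n + 1),
        np.array([label] * n, dtype=object),
    )


# ---------------------------------------------------------------------------
# crosslinks
# ---------------------------------------------------------------------------

_AMINE = "KSTY"
_ACID = "DE"


def make_crosslink_set(
    assembly: CalphaModel | Sequence[CalphaModel],
    n_links: int,
    satisfied_fraction: float,
    linker_mix: Sequence[str] = ("DMTMM", "DSS", "BS3"),
    seed: int = 0,
    homotypic_only: bool = False,
    margin: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample chemistry-valid residue pairs hitting a target satisfied fraction.

    Returns (crosslink table, ground-truth table with true distances and
    verdicts).  Satisfied links have min-assignment distance ≤ bound −
    ``margin``·0; violated links exceed the bound.  Raises if the geometry
    cannot supply the requested split.
    """
    if not 0.0 <= satisfied_fraction <= 1.0:
        raise ValueError("satisfied fraction must be in [0, 1]")
    protomers = [assembly] if isinstance(assembly, CalphaModel) else list(assembly)
    rng = np.random.default_rng(seed)
    res_ids = protomers[0].res_ids
    coords = [p.coords for p in protomers]
    n_prot = len(protomers)
    n_res = len(res_ids)

    def min_assignment_distance(ia: int, ib: int, homotypic: bool) -> float:
        best = np.inf
        for pa in range(n_prot):
            for pb in range(n_prot):
                if homotypic and pa == pb:
                    continue
                d = float(np.linalg.norm(coords[pa][ia] - coords[pb][ib]))
                best = min(best, d)
        return best

    n_sat = int(round(satisfied_fraction * n_links))
    rows, truth = [], []
    # enumerate candidate pairs in random order, bucketing by verdict
    pairs = [
        (i, j)
        for i in range(n_res)
        for j in range(i if homotypic_only else i, n_res)
        if not homotypic_only or i == j
    ]
    rng.shuffle(pairs)
    for ia, ib in pairs:
        if len(rows) >= n_links:
            break
        need_sat = sum(1 for t in truth if t["satisfied"]) < n_sat
        linker = str(rng.choice(list(linker_mix)))
        bound = DEFAULT_BOUNDS[linker]
        homotypic = ia == ib
        if homotypic and n_prot == 1:
            continue
        d = min_assignment_distance(ia, ib, homotypic)
        satisfied = d <= bound
        if satisfied != need_sat:
            continue
        if linker == "DMTMM":
            if homotypic:
                continue  # K-K is not a DMTMM pair
            aa_a, aa_b = "K", str(rng.choice(list(_ACID)))
        elif homotypic:
            aa_a = aa_b = str(rng.choice(list(_AMINE)))
        else:
            aa_a = str(rng.choice(list(_AMINE)))
            aa_b = str(rng.choice(list(_AMINE)))
        rows.append(
            {
                "residueA": f"{aa_a}{res_ids[ia]}",
                "residueB": f"{aa_b}{res_ids[ib]}",
                "linker": linker,
                "score": float(np.round(rng.uniform(50, 200), 1)),
                "count": int(rng.integers(1, 10)),
            }
        )
        truth.append(
            {
                "residueA": rows[-1]["residueA"],
                "residueB": rows[-1]["residueB"],
                "linker": linker,
                "true_distance": d,
                "satisfied": bool(satisfied),
            }
        )
    n_got_sat = sum(1 for t in truth if t["satisfied"])
    if len(rows) < n_links or n_got_sat != n_sat:
        raise ValueError(
            "geometry cannot supply the requested satisfied/violated split"
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# HDX
# ---------------------------------------------------------------------------

_HDX_ALPHABET = "ACDEFGHIKLMNQRSTVWY"  # no proline: keeps site counting simple


def make_hdx_table(
    true_profile: dict[int, float],
    mean_length: int = 10,
    overlap: int = 4,
    replicates: int = 3,
    noise_sd: float = 0.0,
    time_s: float = 300.0,
    exclude_prefix: int = 2,
    state: str = "A",
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Tile a true per-residue uptake profile with overlapping peptides.

    Peptide deuteration = mean of the true residue values over
    start+exclude_prefix … end, plus Gaussian noise per replicate.  Returns
    the peptide table and a ground-truth dict.
    """
    residues = sorted(true_profile)
    if residues != list(range(residues[0], residues[-1] + 1)):
        raise ValueError("true profile must cover contiguous residues")
    rng = np.random.default_rng(seed)
    first, last = residues[0], residues[-1]
    rows = []
    start = first
    step = max(1, mean_length - overlap)
    while start <= last:
        end = min(start + mean_length - 1, last)
        if end - start + 1 < exclude_prefix + 1:
            break
        seq = "".join(rng.choice(list(_HDX_ALPHABET)) for _ in range(end - start + 1))
        true_val = float(
            np.mean([true_profile[r] for r in range(start + exclude_prefix, end + 1)])
        )
        for rep in range(1, replicates + 1):
            val = true_val + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append(
                {
                    "sequence": seq,
                    "start": start,
                    "end": end,
                    "time_s": time_s,
                    "replicate": rep,
                    "state": state,
                    "percent_D": float(np.clip(val, 0.0, 110.0)),
                }
            )
        if end == last:
            break
        start += step
    truth = {
        "true_profile": {str(k): v for k, v in true_profile.items()},
        "exclude_prefix": exclude_prefix,
        "noise_sd": noise_sd,
        "time_s": time_s,
        "state": state,
        "seed": seed,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# delegated simulators with ground-truth bookkeeping
# ---------------------------------------------------------------------------

def make_saxs_curve(
    coords: np.ndarray,
    q: np.ndarray,
    rel_noise: float = 0.0,
    seed: int = 0,
) -> tuple[saxs.SAXSCurve, dict]:
    """Debye scattering of a bead model with multiplicative Gaussian noise."""
    clean = saxs.debye_scatter(coords, q)
    rng = np.random.default_rng(seed)
    if rel_noise > 0:
        sigma = rel_noise * clean.intensity
        inten = clean.intensity + rng.normal(0.0, 1.0, len(q)) * sigma
        curve = saxs.SAXSCurve(q, inten, np.maximum(sigma, 1e-12))
    else:
        curve = clean
    truth = {
        "rg": saxs.coordinate_rg(coords),
        "n_beads": int(len(np.atleast_2d(coords))),
        "rel_noise": rel_noise,
        "seed": seed,
    }
    return curve, truth


def make_envelope(
    mass: float,
    charges: range | list[int],
    mz_noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> tuple[nativems.ChargeEnvelope, dict]:
    env = nativems.simulate_envelope(
        mass, charges, mz_noise_sd=mz_noise_sd, seed=seed, **kwargs
    )
    truth = {
        "mass": mass,
        "charges": [int(z) for z in sorted(charges)],
        "mz_noise_sd": mz_noise_sd,
        "seed": seed,
    }
    return env, truth


def make_titration(
    kd_uM: float,
    delta_tm_max: float = 4.0,
    concentrations_uM: Sequence[float] = (0, 6.25, 12.5, 25, 50, 100, 200, 400),
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[binding.TitrationSeries, dict]:
    """Single-site ΔTm titration with per-replicate Gaussian noise."""
    rng = np.random.default_rng(seed)
    conc = np.asarray(sorted(concentrations_uM), dtype=float)
    reps = np.empty((replicates, len(conc)))
    for k in range(replicates):
        vals = delta_tm_max * conc / (kd_uM + conc)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, len(conc))
        vals[conc == 0.0] = 0.0  # ΔTm is defined relative to this condition
        reps[k] = vals
    mean = reps.mean(axis=0)
    mean[conc == 0.0] = 0.0
    sd = reps.std(axis=0, ddof=1) if replicates > 1 else None
    series = binding.TitrationSeries(conc, mean, sd)
    truth = {
        "kd_uM": kd_uM,
        "delta_tm_max": delta_tm_max,
        "noise_sd": noise_sd,
        "replicates": replicates,
        "seed": seed,
    }
    return series, truth


def make_sv(
    species_s: Sequence[float],
    signals: Sequence[float],
    ff0: float = 1.2,
    design: auc.ExperimentDesign | None = None,
    solvent: auc.SolventParams | None = None,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> tuple[auc.SVExperiment, dict]:
    """Two-(or N-)species Lamm-equation scan series with Gaussian noise."""
    design = design or auc.ExperimentDesign()
    solvent = solvent or auc.SolventParams()
    species = [
        (float(s), auc.diffusion_from_s(float(s), ff0, solvent), float(sig))
        for s, sig in zip(species_s, signals)
    ]
    exp = auc.simulate_sv(species, design, noise_sd=noise_sd, seed=seed)
    truth = {
        "species_s": [float(s) for s in species_s],
        "signals": [float(s) for s in signals],
        "ff0": ff0,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return exp, truth


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def scenario_tetramer_recovery(
    out_dir: str | Path, seed: int = 0
) -> GeneratorSpec:
    """Emit a full C4 tetramer-recovery scenario: protomer, target curve,
    restraint spec, and the latent truth pose."""
    from .saxs import RestraintSpec, assemble_c4, debye_scatter
    from .struct_io import write_assembly_pdb, calpha_to_structure, write_structure

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = GeneratorSpec(seed=seed, scenario="tetramer-recovery")
    rng = spec.stream("pose")
    protomer = make_compact_protomer(n=60, seed=seed)
    rho_true = 22.0 + float(rng.uniform(-2.0, 2.0))
    rotvec_true = rng.normal(0.0, 0.3, size=3)
    pose_true = np.array([*rotvec_true, rho_true])
    chains = assemble_c4(protomer, pose_true)
    coords = np.vstack([c.coords for c in chains])
    q = np.linspace(0.008, 0.25, 60)
    curve, curve_truth = make_saxs_curve(
        coords, q, rel_noise=0.02, seed=int(spec.stream("saxs").integers(2**31))
    )
    restraints = RestraintSpec(residues=(10, 30, 50))
    from .saxs import _restraint_distances

    true_dists = _restraint_distances(chains, restraints.residues)

    write_structure(calpha_to_structure(protomer), out_dir / "protomer.pdb")
    write_assembly_pdb(chains, out_dir / "true_assembly.pdb")
    saxs.write_curve(curve, out_dir / "target.dat", header="synthetic C4 target")
    spec.ground_truth = {
        "pose_rotvec": [float(x) for x in rotvec_true],
        "pose_rho": float(rho_true),
        "restraint_residues": list(restraints.residues),
        "restraint_distances": {str(k): v for k, v in true_dists.items()},
        "assembly_rg": curve_truth["rg"],
        "seed": seed,
    }
    write_sidecar(out_dir / "truth.tsv", spec.ground_truth)
    return spec


SCENARIOS = {
    "tetramer-recovery": scenario_tetramer_recovery,
}
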
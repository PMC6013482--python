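"""Anisotropic elastic-network normal modes and eigenvector-tracked domain closure.

The network is a Cα-only anisotropic network model (ANM): every Cα pair
within the cutoff is joined by a Hookean spring of uniform constant γ.  The
closure procedure repeatedly displaces the model along the non-rigid mode
that best overlaps the starting low-frequency eigenvector, relaxing chain
geometry after each step, until the two named domains come into contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .struct_io import CalphaModel, min_interdomain_distance

RIGID_TOL = 1e-8  # rigid modes must fall below RIGID_TOL * largest eigenvalue


class DisconnectedNetworkError(ValueError):
    """The spring network splits into >1 component at the given cutoff."""

    def __init__(self, n_components: int, labels: np.ndarray):
        self.n_components = n_components
        self.component_labels = labels
        sizes = np.bincount(labels)
        super().__init__(
            f"elastic network disconnected: {n_components} components "
            f"with sizes {sizes.tolist()}"
        )


class StalledTrajectoryError(RuntimeError):
    """No candidate mode reduces the inter-domain distance at iteration 0."""


@dataclass
class ENModel:
    """Assembled ANM: source model, parameters, and the 3N×3N Hessian."""

    source: CalphaModel
    cutoff: float
    gamma: float
    hessian: np.ndarray


@dataclass
class ModeSet:
    """Non-rigid normal modes, ascending by eigenvalue, unit-norm eigenvectors."""

    eigenvalues: np.ndarray  # (m,)
    eigenvectors: np.ndarray  # (3N, m), columns unit-norm, orthonormal
    n_rigid_discarded: int


@dataclass
class IterationRecord:
    iteration: int
    mode_index: int
    overlap: float
    amplitude: float
    min_distance: float


@dataclass
class TrackingResult:
    records: list[IterationRecord]
    final_model: CalphaModel
    converged: bool
    trajectory: list[np.ndarray] = field(default_factory=list)

    def log_text(self) -> str:
        lines = ["iteration\tmode\toverlap\tamplitude\tmin_distance"]
        for r in self.records:
            lines.append(
                f"{r.iteration}\t{r.mode_index}\t{r.overlap:.6f}"
                f"\t{r.amplitude:.4f}\t{r.min_distance:.4f}"
            )
        return "\n".join(lines) + "\n"


def _check_connected(coords: np.ndarray, cutoff: float) -> None:
    d = squareform(pdist(coords))
    adj = (d <= cutoff) & ~np.eye(len(coords), dtype=bool)
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        raise DisconnectedNetworkError(n_comp, labels)


def build_enm(m: CalphaModel, cutoff: float = 15.0, gamma: float = 1.0) -> ENModel:
    """Assemble the ANM Hessian from pairwise superelements within the cutoff.

    For a pair (i, j) at separation vector d the 3×3 superelement is
    −γ d dᵀ / |d|²; diagonal blocks accumulate the negatives, giving a
    translationally invariant, positive semi-definite Hessian.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    coords = m.coords
    n = len(coords)
    _check_connected(coords, cutoff)
    hessian = np.zeros((3 * n, 3 * n))
    dmat = squareform(pdist(coords))
    ii, jj = np.where(np.triu(dmat <= cutoff, k=1))
    for i, j in zip(ii, jj):
        dvec = coords[j] - coords[i]
        block = -gamma * np.outer(dvec, dvec) / dmat[i, j] ** 2
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return ENModel(source=m, cutoff=cutoff, gamma=gamma, hessian=hessian)


def normal_modes(
    e: ENModel, n_modes: int | None = None, rigid_tol: float = RIGID_TOL
) -> ModeSet:
    """Diagonalize the Hessian and strip the six rigid-body modes.

    A seventh eigenvalue below the rigid tolerance normally means the
    network fell apart; the spring graph is re-checked to distinguish true
    disconnection (raised) from a soft internal mechanism of a connected
    network (kept, with a warning) — thin linkers produce the latter.
    """
    if not np.all(np.isfinite(e.hessian)):
        raise ValueError("Hessian contains non-finite entries")
    evals, evecs = scipy.linalg.eigh(e.hessian)
    scale = float(evals[-1])
    rigid_cut = rigid_tol * scale
    if np.any(evals[:6] > rigid_cut):
        raise ValueError(
            "fewer than 6 rigid modes found; Hessian is not a valid connected ANM"
        )
    if len(evals) > 6 and evals[6] <= rigid_cut:
        try:
            _check_connected(e.source.coords, e.cutoff)
        except DisconnectedNetworkError:
            raise
        else:
            import warnings

            warnings.warn(
                "near-zero non-rigid eigenvalue on a connected network: "
                "soft internal mechanism retained"
            )
    evals, evecs = evals[6:], evecs[:, 6:]
    if n_modes is not None:
        evals, evecs = evals[:n_modes], evecs[:, :n_modes]
    evecs = evecs / np.linalg.norm(evecs, axis=0, keepdims=True)
    return ModeSet(eigenvalues=evals, eigenvectors=evecs, n_rigid_discarded=6)


def mode_overlap(v1: np.ndarray, v2: np.ndarray) -> float:
    """Absolute cosine similarity between two mode vectors (sign-free)."""
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.shape != v2.shape:
        raise ValueError("mode vectors must have equal dimension")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no overlap")
    return float(abs(v1 @ v2) / (n1 * n2))


def _chain_bonds(m: CalphaModel) -> np.ndarray:
    """Index pairs of sequential Cα bonds (same chain, consecutive order)."""
    pairs = []
    for i in range(len(m) - 1):
        if m.chain_ids[i] == m.chain_ids[i + 1]:
            pairs.append((i, i + 1))
    return np.array(pairs, dtype=int)


def _relax(
    coords: np.ndarray,
    bonds: np.ndarray,
    ref_lengths: np.ndarray,
    clash_cutoff: float = 4.0,
    max_steps: int = 200,
    step: float = 0.05,
    diverge_patience: int = 10,
) -> tuple[np.ndarray, float]:
    """Gradient descent on Σ(d_bond − d⁰)² + quadratic soft-sphere repulsion.

    Returns the relaxed coordinates and the maximum per-residue drift.
    Raises on sustained energy increase (divergence).
    """
    x = coords.copy()
    start = coords.copy()

    def energy_grad(x):
        g = np.zeros_like(x)
        en = 0.0
        dv = x[bonds[:, 1]] - x[bonds[:, 0]]
        dl = np.linalg.norm(dv, axis=1)
        dl = np.maximum(dl, 1e-12)
        delta = dl - ref_lengths
        en += float((delta**2).sum())
        f = (2 * delta / dl)[:, None] * dv
        np.add.at(g, bonds[:, 0], -f)
        np.add.at(g, bonds[:, 1], f)
        # soft-sphere repulsion between non-bonded pairs closer than cutoff
        d = squareform(pdist(x))
        np.fill_diagonal(d, np.inf)
        for a, b in bonds:
            d[a, b] = d[b, a] = np.inf
        ii, jj = np.where(np.triu(d < clash_cutoff))
        if len(ii):
            dv2 = x[jj] - x[ii]
            dl2 = np.maximum(np.linalg.norm(dv2, axis=1), 1e-12)
            pen = clash_cutoff - dl2
            en += float((pen**2).sum())
            f2 = (-2 * pen / dl2)[:, None] * dv2
            np.add.at(g, ii, -f2)
            np.add.at(g, jj, f2)
        return en, g

    prev_en, _ = energy_grad(x)
    bad = 0
    for _ in range(max_steps):
        en, g = energy_grad(x)
        if en > prev_en + 1e-12:
            bad += 1
            if bad > diverge_patience:
                raise RuntimeError("relaxation diverged: energy increasing")
        else:
            bad = 0
        prev_en = en
        gmax = np.abs(g).max()
        if gmax < 1e-6:
            break
        x = x - step * g / max(1.0, gmax)  # normalized step, <= `step` Å/coord
    drift = float(np.linalg.norm(x - start, axis=1).max())
    return x, drift


def displace_and_relax(
    m: CalphaModel,
    mode: np.ndarray,
    amplitude: float,
    topology: CalphaModel,
) -> tuple[CalphaModel, float]:
    """Move coordinates by amplitude × mode, then restore chain geometry.

    The relaxation pseudo-energy preserves the sequential Cα–Cα distances of
    the topology reference and penalizes non-bonded approaches below 4 Å.
    Returns (relaxed model, max per-residue relaxation drift in Å).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    mode = np.asarray(mode, dtype=float).reshape(len(m), 3)
    new = m.copy()
    new.coords = m.coords + amplitude * mode
    if amplitude == 0:
        return new, 0.0
    bonds = _chain_bonds(topology)
    ref = np.linalg.norm(
        topology.coords[bonds[:, 1]] - topology.coords[bonds[:, 0]], axis=1
    )
    new.coords, drift = _relax(new.coords, bonds, ref)
    return new, drift


def _centroid_distance(m: CalphaModel, label_a: str, label_b: str) -> float:
    ca = m.coords[m.domain_mask(label_a)].mean(axis=0)
    cb = m.coords[m.domain_mask(label_b)].mean(axis=0)
    return float(np.linalg.norm(ca - cb))


def _scaled_amplitude(mode: np.ndarray, max_step: float) -> float:
    per_res = np.linalg.norm(mode.reshape(-1, 3), axis=1).max()
    return max_step / per_res


def track_closure(
    start: CalphaModel,
    label_a: str,
    label_b: str,
    cutoff: float = 15.0,
    gamma: float = 1.0,
    max_step: float = 0.5,
    contact_threshold: float = 8.0,
    max_iterations: int = 500,
    n_candidate_modes: int = 10,
    keep_trajectory: bool = False,
) -> TrackingResult:
    """Iterative eigenvector tracking that closes domain A onto domain B.

    Iteration 0 picks the lowest-frequency non-rigid mode whose displacement
    (with the sign that shrinks the domain-centroid distance) reduces the
    minimum inter-domain Cα distance; its eigenvector becomes the reference.
    Subsequent iterations recompute the modes on the relaxed geometry and
    follow the mode with the largest overlap with the reference, until the
    domains are in contact or the iteration budget is exhausted.
    """
    model = start.copy()
    d0 = min_interdomain_distance(model, label_a, label_b)
    if d0 <= contact_threshold:
        rec = IterationRecord(0, -1, 1.0, 0.0, d0)
        return TrackingResult([rec], model, True, [model.coords.copy()])

    records: list[IterationRecord] = []
    trajectory: list[np.ndarray] = [model.coords.copy()] if keep_trajectory else []
    reference: np.ndarray | None = None
    current_d = d0
    converged = False

    for it in range(max_iterations):
        modes = normal_modes(build_enm(model, cutoff, gamma))
        if reference is None:
            chosen = None
            for k in range(min(n_candidate_modes, modes.eigenvectors.shape[1])):
                vec = modes.eigenvectors[:, k]
                cand, dist = _try_step(
                    model, vec, max_step, label_a, label_b, start
                )
                if cand is not None and dist < current_d:
                    chosen = (k, vec, cand, dist)
                    break
            if chosen is None:
                raise StalledTrajectoryError(
                    "no low-frequency mode reduces the inter-domain distance"
                )
            k, vec, cand, dist = chosen
            reference = vec.copy()
            overlap = 1.0  # by construction at iteration 0
        else:
            # follow the mode with the largest overlap with the reference;
            # if its step would increase the distance, fall back through the
            # next-best-overlap modes so the non-increase invariant holds
            overlaps = np.abs(reference @ modes.eigenvectors)
            order = np.argsort(overlaps)[::-1][:n_candidate_modes]
            cand = None
            for k in order:
                vec = modes.eigenvectors[:, int(k)]
                overlap = float(overlaps[int(k)])
                cand, dist = _try_step(
                    model, vec, max_step, label_a, label_b, start
                )
                if cand is not None and dist <= current_d:
                    k = int(k)
                    break
                cand = None
            if cand is None:
                break  # cannot make progress; report non-convergence
        model = cand
        current_d = dist
        records.append(
            IterationRecord(it, k, overlap, _scaled_amplitude(vec, max_step), dist)
        )
        if keep_trajectory:
            trajectory.append(model.coords.copy())
        if current_d <= contact_threshold:
            converged = True
            break

    return TrackingResult(records, model, converged, trajectory)


def _try_step(
    model: CalphaModel,
    vec: np.ndarray,
    max_step: float,
    label_a: str,
    label_b: str,
    topology: CalphaModel,
) -> tuple[CalphaModel | None, float]:
    """Displace along ±vec (sign shrinking the centroid distance) and relax."""
    amp = _scaled_amplitude(vec, max_step)
    mode3 = vec.reshape(-1, 3)
    best: tuple[CalphaModel | None, float] = (None, np.inf)
    signs = []
    for s in (+1.0, -1.0):
        tm = model.copy()
        tm.coords = model.coords + s * amp * mode3
        signs.append((s, _centroid_distance(tm, label_a, label_b)))
    signs.sort(key=lambda t: t[1])  # centroid-shrinking sign first
    for s, _cdist in signs:
        try:
            cand, _ = displace_and_relax(model, s * vec, amp, topology)
        except RuntimeError:
            continue
        dist = min_interdomain_distance(cand, label_a, label_b)
        if dist < best[1]:
            best = (cand, dist)
        if best[0] is not None and dist < min_interdomain_distance(
            model, label_a, label_b
        ):
            break  # preferred sign already makes progress
    return best
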
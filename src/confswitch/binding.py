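"""Thermal-shift assay analysis: melt-curve Tm extraction and ΔTm → Kd fitting.

Melting transitions are located at maxima of the smoothed first derivative
of the fluorescence melt curve; ligand-induced stabilization ΔTm([L]) is fit
with a single-site saturation model ΔTm = ΔTm_max·[L]/(Kd + [L]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.signal import find_peaks, savgol_filter


class NoTransitionError(ValueError):
    pass


@dataclass
class MeltCurve:
    temperature: np.ndarray  # °C, ascending
    fluorescence: np.ndarray
    replicate: int = 1
    ligand_uM: float = 0.0

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.temperature) < 10:
            raise ValueError("melt curve needs >= 10 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature grid must be ascending")


@dataclass
class TitrationSeries:
    concentrations_uM: np.ndarray  # includes 0
    delta_tm: np.ndarray  # °C, ΔTm(0) = 0 by construction
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.delta_tm = np.asarray(self.delta_tm, dtype=float)
        if 0.0 not in self.concentrations_uM:
            raise ValueError("titration must include the 0-ligand condition")
        zero = self.concentrations_uM == 0.0
        if np.any(np.abs(self.delta_tm[zero]) > 1e-9):
            raise ValueError("ΔTm at [L]=0 must be 0 by construction")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


@dataclass
class KdFit:
    kd_uM: float
    delta_tm_max: float
    kd_se: float
    delta_tm_max_se: float
    residual_norm: float
    reliable: bool

    def __post_init__(self) -> None:
        if self.kd_uM <= 0:
            raise ValueError("Kd must be > 0")


def extract_tm(
    m: MeltCurve,
    window: int = 5,
    polyorder: int = 2,
    prominence_frac: float = 0.05,
) -> list[float]:
    """Locate melting transitions at maxima of the smoothed dF/dT.

    Returns transition temperatures ascending; the first is the canonical
    Tm (used for ΔTm when several transitions are present).
    """
    smoothed = savgol_filter(m.fluorescence, window, polyorder)
    dfdt = np.gradient(smoothed, m.temperature)
    span = float(np.ptp(m.fluorescence))
    floor = 1e-9 * max(span, abs(m.fluorescence).max(), 1e-30)
    if dfdt.max() <= floor:
        raise NoTransitionError("no rising region in melt curve")
    peaks, _ = find_peaks(dfdt, prominence=prominence_frac * dfdt.max())
    if len(peaks) == 0:
        raise NoTransitionError("no derivative maximum above prominence threshold")
    # parabolic refinement of each peak position
    tms = []
    for p in peaks:
        if 0 < p < len(dfdt) - 1:
            y0, y1, y2 = dfdt[p - 1 : p + 2]
            denom = y0 - 2 * y1 + y2
            shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            dt = m.temperature[p + 1] - m.temperature[p]
            tms.append(float(m.temperature[p] + shift * dt))
        else:
            tms.append(float(m.temperature[p]))
    return sorted(tms)


def sigmoid_tm(m: MeltCurve) -> float:
    """Alternative Tm: midpoint of a Boltzmann sigmoid fit to the main transition."""
    t, f = m.temperature, m.fluorescence
    f0, f1 = float(f.min()), float(f.max())
    guess = [f0, f1 - f0, float(t[np.argmax(np.gradient(f, t))]), 2.0]

    def model(x, base, amp, tm, width):
        return base + amp / (1.0 + np.exp(-(x - tm) / width))

    popt, _ = scipy.optimize.curve_fit(model, t, f, p0=guess, maxfev=10000)
    return float(popt[2])


def build_titration(
    curves: list[MeltCurve], **extract_kwargs
) -> TitrationSeries:
    """Assemble a ΔTm titration from melt curves at varied ligand concentration.

    Replicates per concentration are averaged; the canonical (first)
    transition defines Tm; ΔTm = Tm([L]) − Tm(0).
    """
    by_conc: dict[float, list[float]] = {}
    for c in curves:
        tm = extract_tm(c, **extract_kwargs)[0]
        by_conc.setdefault(c.ligand_uM, []).append(tm)
    if 0.0 not in by_conc:
        raise ValueError("titration requires a 0-ligand condition")
    tm0 = float(np.mean(by_conc[0.0]))
    concs = np.array(sorted(by_conc))
    dtm = np.array([np.mean(by_conc[c]) - tm0 for c in concs])
    dtm[concs == 0.0] = 0.0
    sd = np.array(
        [np.std(by_conc[c], ddof=1) if len(by_conc[c]) > 1 else np.nan for c in concs]
    )
    return TitrationSeries(concs, dtm, sd)


def fit_kd(t: TitrationSeries) -> KdFit:
    """Weighted least-squares fit of ΔTm([L]) = ΔTm_max·[L]/(Kd + [L]).

    Standard errors come from the fit covariance; a fit with Kd SE > Kd (or
    a vanishing ΔTm_max) is flagged unreliable but still returned.
    """
    nonzero = t.concentrations_uM > 0
    if len(np.unique(t.concentrations_uM[nonzero])) < 4:
        raise ValueError("need >= 4 distinct nonzero concentrations")
    conc, dtm = t.concentrations_uM, t.delta_tm
    # weight by the pooled replicate SD: per-point small-sample SDs are too
    # noisy to serve as individual weights and destabilize the fit
    sigma = None
    if t.sd is not None:
        finite = t.sd[np.isfinite(t.sd) & (t.sd > 0)]
        if len(finite):
            sigma = np.full(len(conc), float(np.sqrt(np.mean(finite**2))))

    def model(L, dtm_max, kd):
        return dtm_max * L / (kd + L)

    dtm_guess = float(dtm.max()) if dtm.max() > 0 else 1.0
    kd_guess = float(np.median(conc[nonzero]))
    try:
        popt, pcov = scipy.optimize.curve_fit(
            model, conc, dtm, p0=[dtm_guess, kd_guess],
            sigma=sigma, absolute_sigma=sigma is not None,
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise ValueError(f"Kd fit failed to converge: {exc}") from exc
    dtm_max, kd = popt
    se = np.sqrt(np.diag(pcov))
    resid = dtm - model(conc, *popt)
    reliable = bool(se[1] < kd and abs(dtm_max) > 10 * max(se[0], 1e-12))
    return KdFit(
        kd_uM=float(kd),
        delta_tm_max=float(dtm_max),
        kd_se=float(se[1]),
        delta_tm_max_se=float(se[0]),
        residual_norm=float(np.linalg.norm(resid)),
        reliable=reliable,
    )
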
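"""Per-residue HDX-MS profiling from peptide-level deuteration tables.

Peptide deuteration (% of theoretical maximum) is spread over the residues
each peptide covers — minus an excluded N-terminal prefix that suffers rapid
back exchange — replicate-averaged first, then averaged across overlapping
peptides per residue.  Differential profiles subtract one state from
another wherever both are covered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class HDXPeptideRecord:
    sequence: str
    start: int
    end: int
    time_s: float
    replicate: int
    percent_d: float
    state: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("end < start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("sequence length does not match residue span")
        if not 0.0 <= self.percent_d <= 110.0:
            raise ValueError("deuteration outside [0, 110] %")


@dataclass
class ResidueExchangeProfile:
    """Per-residue deuteration at one time point."""

    time_s: float
    residues: np.ndarray  # (R,) residue numbers with coverage > 0
    mean: np.ndarray  # (R,) mean % deuteration
    sem: np.ndarray  # (R,) SEM across replicates; NaN where n_rep < 2
    coverage: np.ndarray  # (R,) number of covering peptides
    exclude_prefix: int = 2
    state: str = ""

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(m) for r, m in zip(self.residues, self.mean)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "mean_percent_d": self.mean,
                "sem_percent_d": self.sem,
                "coverage": self.coverage,
            }
        )


@dataclass
class DifferentialProfile:
    """Δ deuteration (state A − state B) per residue at one time point."""

    time_s: float
    residues: np.ndarray  # residues covered in BOTH states
    delta: np.ndarray
    state_a: str = "A"
    state_b: str = "B"

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(d) for r, d in zip(self.residues, self.delta)}


@dataclass
class RejectedRow:
    index: int
    reason: str


def load_peptides(path: str | Path) -> tuple[list[HDXPeptideRecord], list[RejectedRow]]:
    """Load a peptide table (sequence, start, end, time_s, replicate, percent_D[, state]).

    Invalid rows (span mismatch, out-of-range deuteration) are rejected with
    a reason rather than aborting the load.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sequence", "start", "end", "time_s", "replicate", "percent_D"}
    if not required.issubset(df.columns):
        raise ValueError(f"peptide table must have columns {sorted(required)}")
    records: list[HDXPeptideRecord] = []
    rejected: list[RejectedRow] = []
    for i, row in df.iterrows():
        try:
            records.append(
                HDXPeptideRecord(
                    sequence=str(row["sequence"]).strip(),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    time_s=float(row["time_s"]),
                    replicate=int(row["replicate"]),
                    percent_d=float(row["percent_D"]),
                    state=str(row["state"]) if "state" in df.columns else "",
                )
            )
        except (ValueError, TypeError) as exc:
            rejected.append(RejectedRow(i, str(exc)))
    return records, rejected


def theoretical_max_sites(sequence: str) -> int:
    """Exchangeable backbone amides: length − 1 − prolines after position 1."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - AA_LETTERS
    if bad:
        raise ValueError(f"non-amino-acid letters {sorted(bad)}")
    return len(seq) - 1 - seq[1:].count("P")


def per_residue_profile(
    records: Iterable[HDXPeptideRecord],
    time_s: float,
    exclude_prefix: int = 2,
    state: str | None = None,
) -> ResidueExchangeProfile:
    """Aggregate peptide deuteration into a per-residue profile.

    Each peptide contributes its (replicate-averaged) deuteration to residues
    start+exclude_prefix … end; the per-residue mean is the unweighted mean
    over contributing peptides and the SEM is propagated across replicates.
    """
    if exclude_prefix < 0:
        raise ValueError("exclude_prefix must be >= 0")
    recs = [r for r in records if r.time_s == time_s]
    if state is not None:
        recs = [r for r in recs if r.state == state]

    # replicate-first averaging: group replicates of the same peptide
    groups: dict[tuple[str, int, int], list[float]] = {}
    for r in recs:
        groups.setdefault((r.sequence, r.start, r.end), []).append(r.percent_d)

    acc: dict[int, list[tuple[float, float, int]]] = {}  # residue -> (mean, var, n)
    for (seq, start, end), vals in groups.items():
        vals_arr = np.asarray(vals, dtype=float)
        pmean = float(vals_arr.mean())
        n = len(vals_arr)
        pvar = float(vals_arr.var(ddof=1)) if n >= 2 else np.nan
        first = start + exclude_prefix
        for res in range(first, end + 1):
            acc.setdefault(res, []).append((pmean, pvar, n))

    if not acc:
        warnings.warn("no residue is covered after prefix exclusion")
        return ResidueExchangeProfile(
            time_s, np.array([], dtype=int), np.array([]), np.array([]),
            np.array([], dtype=int), exclude_prefix, state or "",
        )

    residues = np.array(sorted(acc), dtype=int)
    mean = np.empty(len(residues))
    sem = np.empty(len(residues))
    coverage = np.empty(len(residues), dtype=int)
    for i, res in enumerate(residues):
        entries = acc[int(res)]
        means = np.array([e[0] for e in entries])
        mean[i] = means.mean()
        coverage[i] = len(entries)
        # SEM across replicates: propagate peptide replicate variances
        vars_ = np.array([e[1] for e in entries])
        ns = np.array([e[2] for e in entries])
        if np.all(ns >= 2):
            # variance of the mean-of-peptide-means
            sem[i] = float(np.sqrt(np.sum(vars_ / ns)) / len(entries))
        else:
            sem[i] = np.nan
    return ResidueExchangeProfile(
        time_s, residues, mean, sem, coverage, exclude_prefix, state or ""
    )


def differential(
    profile_a: ResidueExchangeProfile, profile_b: ResidueExchangeProfile
) -> DifferentialProfile:
    """Δ = A − B on residues covered in both states; undefined elsewhere."""
    if profile_a.time_s != profile_b.time_s:
        raise ValueError("profiles must share the time point")
    a, b = profile_a.as_dict(), profile_b.as_dict()
    common = sorted(set(a) & set(b))
    if not common:
        warnings.warn("profiles have disjoint coverage; empty differential")
    residues = np.array(common, dtype=int)
    delta = np.array([a[r] - b[r] for r in common])
    return DifferentialProfile(
        profile_a.time_s, residues, delta,
        profile_a.state or "A", profile_b.state or "B",
    )
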
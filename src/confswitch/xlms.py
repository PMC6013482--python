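"""Chemical crosslink restraints: parsing, distance mapping, satisfaction scoring.

Crosslinks are residue-pair restraints with linker-specific Cα–Cα upper
bounds (DMTMM zero-length coupling: 30 Å; DSS/BS3 amine-reactive spacers:
35 Å).  Mapping onto a monomer or a multi-protomer assembly reports, per
link, the minimal distance over all chain assignments and a satisfaction
verdict against the bound (inclusive comparison).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .struct_io import CalphaModel

LINKERS = ("DMTMM", "DSS", "BS3")
DEFAULT_BOUNDS = {"DMTMM": 30.0, "DSS": 35.0, "BS3": 35.0}

# reaction-site chemistry per linker
_AMINE_SITES = set("KSTY")  # DSS/BS3: lysines, serines, threonines, tyrosines
_ACID_SITES = set("DE")  # DMTMM acidic side
_RES_TOKEN = re.compile(r"^([A-Z])(\d+)$")


@dataclass(frozen=True)
class Crosslink:
    """One identified crosslink between two residues (chain-agnostic)."""

    res_a: int
    aa_a: str
    res_b: int
    aa_b: str
    linker: str
    score: float | None = None
    count: int | None = None

    @property
    def homotypic(self) -> bool:
        return self.res_a == self.res_b and self.aa_a == self.aa_b


@dataclass
class LinkerBounds:
    bounds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        for k, v in self.bounds.items():
            if v <= 0:
                raise ValueError(f"bound for {k} must be > 0")

    def __getitem__(self, linker: str) -> float:
        return self.bounds[linker]


@dataclass
class LinkRecord:
    """Mapping result for one crosslink."""

    link: Crosslink
    min_distance: float | None
    assignment: tuple[int, int] | None  # (protomer index A, protomer index B)
    satisfied: bool
    ambiguity_count: int
    error: str | None = None


@dataclass
class CrosslinkReport:
    records: list[LinkRecord]

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "residueA": f"{r.link.aa_a}{r.link.res_a}",
                    "residueB": f"{r.link.aa_b}{r.link.res_b}",
                    "linker": r.link.linker,
                    "min_distance": r.min_distance,
                    "protomerA": None if r.assignment is None else r.assignment[0],
                    "protomerB": None if r.assignment is None else r.assignment[1],
                    "satisfied": r.satisfied,
                    "ambiguity_count": r.ambiguity_count,
                    "error": r.error,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RejectReport:
    rows: list[tuple[int, str, str]] = field(default_factory=list)  # (line, row, reason)


def _chemistry_valid(aa_a: str, aa_b: str, linker: str) -> bool:
    if linker == "DMTMM":
        return (aa_a == "K" and aa_b in _ACID_SITES) or (
            aa_b == "K" and aa_a in _ACID_SITES
        )
    return aa_a in _AMINE_SITES and aa_b in _AMINE_SITES


def _parse_residue(token: str) -> tuple[str, int]:
    m = _RES_TOKEN.match(token.strip())
    if not m:
        raise ValueError(f"malformed residue token {token!r}")
    return m.group(1), int(m.group(2))


def parse_crosslinks(
    path: str | Path,
) -> tuple[list[Crosslink], RejectReport]:
    """Parse a delimited crosslink table (residueA, residueB, linker[, score, count]).

    Rows violating residue-chemistry invariants are collected into the reject
    report; an unknown linker token is a hard error.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"residueA", "residueB", "linker"}
    if not required.issubset(df.columns):
        raise ValueError(f"crosslink table must have columns {sorted(required)}")
    links: list[Crosslink] = []
    rejects = RejectReport()
    for i, row in df.iterrows():
        linker = str(row["linker"]).strip().upper().replace("³", "3")
        if linker not in LINKERS:
            raise ValueError(f"unknown linker token {row['linker']!r} at row {i}")
        try:
            aa_a, res_a = _parse_residue(str(row["residueA"]))
            aa_b, res_b = _parse_residue(str(row["residueB"]))
        except ValueError as exc:
            rejects.rows.append((i, str(row.to_dict()), str(exc)))
            continue
        if not _chemistry_valid(aa_a, aa_b, linker):
            rejects.rows.append(
                (i, str(row.to_dict()), f"{aa_a}-{aa_b} not reactive for {linker}")
            )
            continue
        score = float(row["score"]) if "score" in df.columns and pd.notna(row.get("score")) else None
        count = int(row["count"]) if "count" in df.columns and pd.notna(row.get("count")) else None
        links.append(Crosslink(res_a, aa_a, res_b, aa_b, linker, score, count))
    return links, rejects


def map_distances(
    links: Iterable[Crosslink],
    assembly: Sequence[CalphaModel] | CalphaModel,
    bounds: LinkerBounds | None = None,
) -> CrosslinkReport:
    """Map each link onto the assembly: minimal Cα–Cα distance over assignments.

    Every protomer pair is considered: both residues on the same protomer
    (intra) or on two different protomers (inter).  Homotypic links (same
    residue on both sides) only admit inter-protomer assignments.  The
    satisfied flag compares the minimal distance to the linker bound
    (inclusive); the ambiguity count is the number of unordered assignments
    within the bound.
    """
    if isinstance(assembly, CalphaModel):
        assembly = [assembly]
    bounds = bounds or LinkerBounds()
    protomer_index = [
        {int(r): i for i, r in enumerate(p.res_ids)} for p in assembly
    ]
    n_prot = len(assembly)
    records: list[LinkRecord] = []
    for link in links:
        missing = [
            p for p, idx in enumerate(protomer_index)
            if link.res_a not in idx or link.res_b not in idx
        ]
        if missing:
            records.append(
                LinkRecord(
                    link, None, None, False, 0,
                    error=f"residue not resolvable in protomer(s) {missing}",
                )
            )
            continue
        bound = bounds[link.linker]
        best = (np.inf, None)
        n_within = 0
        seen: set[frozenset] = set()
        for pa in range(n_prot):
            for pb in range(n_prot):
                if link.homotypic and pa == pb:
                    continue
                key = frozenset(((pa, link.res_a), (pb, link.res_b)))
                if key in seen:
                    continue
                seen.add(key)
                ca = assembly[pa].coords[protomer_index[pa][link.res_a]]
                cb = assembly[pb].coords[protomer_index[pb][link.res_b]]
                d = float(np.linalg.norm(ca - cb))
                if d <= bound:
                    n_within += 1
                if d < best[0]:
                    best = (d, (pa, pb))
        if best[1] is None:
            records.append(
                LinkRecord(link, None, None, False, 0, error="no valid assignment")
            )
            continue
        records.append(
            LinkRecord(
                link,
                min_distance=best[0],
                assignment=best[1],
                satisfied=best[0] <= bound,
                ambiguity_count=n_within,
            )
        )
    return CrosslinkReport(records)


def classify_intersubunit(
    links: Iterable[Crosslink],
) -> dict[str, list[Crosslink]]:
    """Partition links into unambiguous-inter (homotypic) and ambiguous.

    Only like-to-like links (the same residue crosslinked to itself) must
    bridge two protomers; every other link could be intra- or inter-subunit.
    """
    out: dict[str, list[Crosslink]] = {"unambiguous-inter": [], "ambiguous": []}
    for link in links:
        key = "unambiguous-inter" if link.homotypic else "ambiguous"
        out[key].append(link)
    return out


def satisfaction_score(
    report: CrosslinkReport, weights: Sequence[float] | None = None
) -> float:
    """(Weighted) fraction of satisfied links in [0, 1]."""
    if len(report) == 0:
        raise ValueError("empty crosslink report")
    if weights is None:
        weights = [1.0] * len(report)
    weights = np.asarray(list(weights), dtype=float)
    if len(weights) != len(report):
        raise ValueError("weights length must match report length")
    sat = np.array([r.satisfied for r in report.records], dtype=float)
    return float((weights * sat).sum() / weights.sum())
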
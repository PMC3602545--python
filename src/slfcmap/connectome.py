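"""Collated structural-connectivity (SC) reports and the directed SC graph.

The SC substrate is a table of per-report rows in the style of a collated
rat connectome database: source region, target region, a qualitative
projection strength on a linear 1–7 scale (1 = very strong … 7 = very
weak, plus a 'fibers of passage' code for axons merely passing through),
and a laterality flag.  Before any network analysis the reports are
filtered — 'very weak' (code 7), 'fibers of passage', and contralateral
reports are removed — and multiple surviving reports on one directed pair
are aggregated into a single edge.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParseError

FIBERS_OF_PASSAGE = "fibers_of_passage"
VERY_WEAK_CODE = 7

#: word → code lookup for the ten qualitative strengths used by collated
#: connectome databases.  The linear 1–7 encoding is standard; the exact
#: word-to-number assignment below is this package's documented convention
#: and is editable by passing a replacement mapping to read_sc_table.
STRENGTH_WORDS: dict[str, int | str] = {
    "very strong": 1,
    "strong": 2,
    "moderate to strong": 3,
    "moderate": 4,
    "weak to moderate": 5,
    "weak": 6,
    "light": 6,
    "very weak": 7,
    "present": 4,           # strength not stated by the collated source
    "fibers of passage": FIBERS_OF_PASSAGE,
}

REQUIRED_COLUMNS = ("source", "target", "strength_code", "laterality")


@dataclass(frozen=True)
class SCReport:
    """One collated connectivity report (one table row)."""

    source: str
    target: str
    strength: int | str          # 1..7 or 'fibers_of_passage'
    laterality: str = "ipsi"     # 'ipsi' | 'contra'
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("region names must be non-empty")
        ok = self.strength == FIBERS_OF_PASSAGE or (
            isinstance(self.strength, (int, np.integer))
            and 1 <= self.strength <= 7)
        if not ok:
            raise ValueError(f"invalid strength {self.strength!r}")
        if self.laterality not in ("ipsi", "contra"):
            raise ValueError(f"invalid laterality {self.laterality!r}")


def _parse_strength(value, words: dict) -> int | str:
    if isinstance(value, str):
        text = value.strip().lower().replace("_", " ")
        if text in ("fibers of passage",):
            return FIBERS_OF_PASSAGE
        if text in words:
            return words[text]
        try:
            value = int(text)
        except ValueError:
            raise ValueError(f"unknown strength label {value!r}")
    code = int(value)
    if not 1 <= code <= 7:
        raise ValueError(f"strength code {code} outside 1..7")
    return code


def read_sc_table(source: str | Path | io.IOBase | pd.DataFrame,
                  strength_words: dict | None = None) -> list[SCReport]:
    """Parse a TSV of connectivity reports into :class:`SCReport` rows.

    Strength entries may be numeric codes 1–7, the word vocabulary in
    :data:`STRENGTH_WORDS`, or 'fibers_of_passage'.  Malformed rows raise
    :class:`ParseError` citing the (1-based, data) row number.
    """
    words = STRENGTH_WORDS if strength_words is None else strength_words
    if isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source, sep="\t", dtype=str,
                            keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    reports = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        try:
            reports.append(SCReport(
                source=str(row.source).strip(),
                target=str(row.target).strip(),
                strength=_parse_strength(row.strength_code, words),
                laterality=str(row.laterality).strip().lower(),
                annotation=str(getattr(row, "reference_note", "") or
                               getattr(row, "annotation", ""))))
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}", row=i) from exc
    return reports


def write_sc_table(reports: Iterable[SCReport], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([{
        "source": r.source, "target": r.target,
        "strength_code": r.strength, "laterality": r.laterality,
        "reference_note": r.annotation,
    } for r in reports]).to_csv(path, sep="\t", index=False)
    return path


def filter_reports(reports: Sequence[SCReport]) -> list[SCReport]:
    """Drop 'very weak' (code 7), 'fibers of passage', and contralateral
    reports; order is preserved.  Idempotent."""
    return [r for r in reports
            if r.strength != FIBERS_OF_PASSAGE
            and r.strength != VERY_WEAK_CODE
            and r.laterality == "ipsi"]


def build_graph(reports: Sequence[SCReport],
                aggregate: str = "strongest") -> nx.DiGraph:
    """Aggregate reports into a directed graph, one edge per ordered pair.

    ``aggregate='strongest'`` keeps the minimum strength code (strongest
    projection) across reports on the same pair; ``'median'`` takes the
    median code rounded to an integer.  Each edge carries its contributing
    reports as provenance and a ``bidirectional`` flag is set on both
    members of reciprocal pairs.
    """
    if aggregate not in ("strongest", "median"):
        raise ValueError("aggregate must be 'strongest' or 'median'")
    graph = nx.DiGraph()
    for r in reports:
        if r.strength == FIBERS_OF_PASSAGE:
            raise ValueError("build_graph expects filtered reports "
                             "(found 'fibers of passage')")
        graph.add_node(r.source)
        graph.add_node(r.target)
        if graph.has_edge(r.source, r.target):
            graph[r.source][r.target]["reports"].append(r)
        else:
            graph.add_edge(r.source, r.target, reports=[r])
    for u, v, attrs in graph.edges(data=True):
        codes = sorted(int(r.strength) for r in attrs["reports"])
        if aggregate == "strongest":
            attrs["strength"] = codes[0]
        else:
            attrs["strength"] = int(round(float(np.median(codes))))
        attrs["n_reports"] = len(codes)
        attrs["bidirectional"] = graph.has_edge(v, u)
    return graph


@dataclass(frozen=True)
class Neighborhood:
    """Partition of a region's structural neighbours by edge direction."""

    region: str
    afferent: frozenset[str]       # send input to the region only
    efferent: frozenset[str]       # receive output from the region only
    bidirectional: frozenset[str]

    @property
    def all_neighbors(self) -> frozenset[str]:
        return self.afferent | self.efferent | self.bidirectional

    def direction_of(self, partner: str) -> str:
        if partner in self.bidirectional:
            return "bidirectional"
        if partner in self.afferent:
            return "partner_to_seed"
        if partner in self.efferent:
            return "seed_to_partner"
        raise KeyError(f"{partner!r} is not a structural neighbour "
                       f"of {self.region!r}")


def neighborhood(graph: nx.DiGraph, region: str) -> Neighborhood:
    """Split a region's neighbours into exclusively-afferent,
    exclusively-efferent, and bidirectional sets."""
    if region not in graph:
        raise LookupError(f"region {region!r} not in the SC graph")
    preds = set(graph.predecessors(region)) - {region}
    succs = set(graph.successors(region)) - {region}
    both = preds & succs
    return Neighborhood(region=region,
                        afferent=frozenset(preds - both),
                        efferent=frozenset(succs - both),
                        bidirectional=frozenset(both))


def export_edgelist(graph: nx.DiGraph, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"source": u, "target": v, "strength": d["strength"],
             "n_reports": d["n_reports"],
             "bidirectional": d["bidirectional"]}
            for u, v, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "strength", "n_reports",
                                "bidirectional"]).to_csv(
        path, sep="\t", index=False)
    return path
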
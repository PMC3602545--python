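"""Structurally linked functional connectivity (SLFC).

SLFC restricts the seed's functional-connectivity (FC) result to region
pairs with a direct structural projection: each surviving edge inherits its
directionality (afferent / efferent / bidirectional) from the structural
graph and its sign (positive or negative correlation) from the FC map.
Both networks are binarized before the intersection; strength codes and
peak statistics ride along as annotations only.

Edges are labelled with compact motifs read seed-first, e.g.
``PrL[-]←La`` (negative FC over an afferent projection from La) or
``PrL[+]←→MD`` (positive FC over a reciprocal connection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Neighborhood
from .mapping import ClusterSet, clusters_to_regions

ARROWS = {"partner_to_seed": "←",        # ←
          "seed_to_partner": "→",        # →
          "bidirectional": "←→"}    # ←→


# ---------------------------------------------------------------------------
# FC region table
# ---------------------------------------------------------------------------

def fc_region_table(clusters: ClusterSet, atlas,
                    subgroup: tuple | None = None,
                    min_overlap_frac: float = 0.10) -> pd.DataFrame:
    """Region-level summary of a thresholded seed-correlation map.

    One row per atlas region: sign ∈ {+1, −1, 0} (0 = no significant
    cluster overlap), peak |t| and overlap voxel count of the dominant
    cluster.  When clusters of both signs overlap one region, the larger
    overlap wins and a warning is emitted (within-region sign conflicts
    have no principled resolution at region granularity).
    """
    overlaps = clusters_to_regions(clusters, atlas,
                                   min_overlap_frac=min_overlap_frac)
    rows = []
    for name in atlas.region_names:
        sub = overlaps[overlaps["region"] == name]
        if sub.empty:
            rows.append({"region": name, "sign": 0, "peak_abs_stat": np.nan,
                         "overlap_voxels": 0})
            continue
        by_sign = sub.groupby("sign")["overlap_voxels"].sum()
        if len(by_sign) > 1:
            warnings.warn(f"region {name!r} overlaps clusters of both "
                          "signs; reporting the larger overlap",
                          stacklevel=2)
        sign = int(by_sign.idxmax())
        dom = sub[sub["sign"] == sign]
        rows.append({"region": name, "sign": sign,
                     "peak_abs_stat": float(dom["peak_stat"].abs().max()),
                     "overlap_voxels": int(dom["overlap_voxels"].sum())})
    table = pd.DataFrame(rows)
    table["subgroup"] = [subgroup] * len(table)
    return table


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SLFCEdge:
    """One SLFC edge: SC direction + FC sign between seed and partner."""

    seed: str
    partner: str
    direction: str               # 'partner_to_seed'|'seed_to_partner'|'bidirectional'
    fc_sign: int                 # +1 | -1
    sc_strength: int
    peak_abs_stat: float = float("nan")
    overlap_voxels: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ARROWS:
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.fc_sign not in (+1, -1):
            raise ValueError("fc_sign must be +1 or -1")


@dataclass
class IntersectResult:
    """SLFC edges plus the FC regions that did not make it and why."""

    edges: list[SLFCEdge]
    fc_without_sc: list[str] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)

    def partners(self) -> set[str]:
        return {e.partner for e in self.edges}

    def edge_for(self, partner: str) -> SLFCEdge:
        for e in self.edges:
            if e.partner == partner:
                return e
        raise KeyError(partner)


def _edge_strength(graph: nx.DiGraph, seed: str, partner: str,
                   direction: str) -> int:
    codes = []
    if direction in ("partner_to_seed", "bidirectional"):
        codes.append(graph[partner][seed]["strength"])
    if direction in ("seed_to_partner", "bidirectional"):
        codes.append(graph[seed][partner]["strength"])
    return int(min(codes))


def intersect(fc_table: pd.DataFrame, sc_neighborhood: Neighborhood,
              sc_graph: nx.DiGraph) -> IntersectResult:
    """Binarized intersection of the FC region table with the seed's
    structural neighbourhood.

    Every functionally connected region is classified exactly once: an
    SLFC edge (structural neighbour of the seed), FC-without-SC (a known
    region with no direct projection — a candidate false-positive or
    indirect connection), or unresolved (a name absent from the SC
    nomenclature, reported rather than silently dropped).  Structural
    neighbours with no FC are omitted.
    """
    seed = sc_neighborhood.region
    edges, without_sc, unresolved = [], [], []
    for row in fc_table.itertuples(index=False):
        if row.sign == 0 or row.region == seed:
            continue
        if row.region not in sc_graph:
            unresolved.append(row.region)
        elif row.region in sc_neighborhood.all_neighbors:
            direction = sc_neighborhood.direction_of(row.region)
            edges.append(SLFCEdge(
                seed=seed, partner=row.region, direction=direction,
                fc_sign=int(row.sign),
                sc_strength=_edge_strength(sc_graph, seed, row.region,
                                           direction),
                peak_abs_stat=float(getattr(row, "peak_abs_stat",
                                            float("nan"))),
                overlap_voxels=int(getattr(row, "overlap_voxels", 0))))
        else:
            without_sc.append(row.region)
    return IntersectResult(edges=edges, fc_without_sc=without_sc,
                           unresolved=unresolved)


def motif_label(edge: SLFCEdge) -> str:
    """Canonical seed-first motif, e.g. ``PrL[-]←La`` or ``PrL[+]←→MD``."""
    sign = "+" if edge.fc_sign > 0 else "-"
    return f"{edge.seed}[{sign}]{ARROWS[edge.direction]}{edge.partner}"


# ---------------------------------------------------------------------------
# condition comparison
# ---------------------------------------------------------------------------

def compare_conditions(a: Sequence[SLFCEdge], b: Sequence[SLFCEdge]
                       ) -> pd.DataFrame:
    """Classify each partner region's SLFC edge between two conditions.

    Classes: ``unchanged`` (present in both with the same FC sign),
    ``sign-flip`` (present in both, sign reversed), ``lost`` (in A only),
    ``gained`` (in B only).  Returns one row per partner with the signs and
    motifs in each condition.
    """
    seeds = {e.seed for e in list(a) + list(b)}
    if len(seeds) > 1:
        raise ValueError(f"conditions use different seeds: {sorted(seeds)}")
    ea = {e.partner: e for e in a}
    eb = {e.partner: e for e in b}
    rows = []
    for partner in sorted(set(ea) | set(eb)):
        in_a, in_b = partner in ea, partner in eb
        if in_a and in_b:
            change = ("unchanged" if ea[partner].fc_sign == eb[partner].fc_sign
                      else "sign-flip")
        else:
            change = "lost" if in_a else "gained"
        rows.append({
            "partner": partner,
            "change": change,
            "sign_a": ea[partner].fc_sign if in_a else 0,
            "sign_b": eb[partner].fc_sign if in_b else 0,
            "motif_a": motif_label(ea[partner]) if in_a else "",
            "motif_b": motif_label(eb[partner]) if in_b else "",
        })
    return pd.DataFrame(rows, columns=["partner", "change", "sign_a",
                                       "sign_b", "motif_a", "motif_b"])


def change_counts(changes: pd.DataFrame) -> dict[str, int]:
    counts = {c: 0 for c in ("unchanged", "sign-flip", "lost", "gained")}
    if len(changes):
        counts.update(changes["change"].value_counts().to_dict())
    return counts


def write_edges(edges: Sequence[SLFCEdge], path: str | Path,
                header_lines: Sequence[str] = ()) -> Path:
    """Edge-list TSV (seed, partner, direction, fc_sign, sc_strength,
    motif), optionally preceded by provenance comment lines."""
    path = Path(path)
    table = pd.DataFrame([{
        "seed": e.seed, "partner": e.partner, "direction": e.direction,
        "fc_sign": e.fc_sign, "sc_strength": e.sc_strength,
        "peak_abs_stat": e.peak_abs_stat,
        "overlap_voxels": e.overlap_voxels,
        "motif": motif_label(e),
    } for e in edges], columns=["seed", "partner", "direction", "fc_sign",
                                "sc_strength", "peak_abs_stat",
                                "overlap_voxels", "motif"])
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        table.to_csv(fh, sep="\t", index=False)
    return path


def export_graphml(edges: Sequence[SLFCEdge], path: str | Path) -> Path:
    graph = nx.DiGraph()
    for e in edges:
        graph.add_edge(*((e.partner, e.seed)
                         if e.direction == "partner_to_seed"
                         else (e.seed, e.partner)),
                       fc_sign=e.fc_sign, sc_strength=e.sc_strength,
                       bidirectional=e.direction == "bidirectional",
                       motif=motif_label(e))
    nx.write_graphml(graph, path)
    return Path(path)
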
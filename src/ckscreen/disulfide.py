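"""Scaffold-based disulfide-bond mapping.

Given a query-to-template threading alignment, every pair of query cysteines
is tested for disulfide-bond feasibility using only the template's Cα/Cβ
geometry at the aligned positions — no model building. A pair is possible
when three criteria all hold (inclusive bounds):

i.   distance: d(Cα1, Cα2) <= 10 Å and d(Cβ1, Cβ2) <= 9 Å,
ii.  orientation: d(Cβ1, Cβ2) - d(Cα1, Cα2) <= 1 Å (the side chains must not
     point away from each other),
iii. separation: the cysteines are at least 3 residues apart in the query.

A cysteine aligned to a gap or unresolved template residue borrows the
nearest resolved template neighbors on the left and right as candidate
anchors. The number of mappable bonds (diS) is the size of a maximum set of
vertex-disjoint possible pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CysPairAssessment",
    "DisulfideMap",
    "DisulfideParams",
    "anchor_cysteines",
    "check_pair",
    "enumerate_bonds",
    "map_disulfides",
]


@dataclass(frozen=True)
class DisulfideParams:
    d_ca_max: float = 10.0
    d_cb_max: float = 9.0
    d_diff_max: float = 1.0
    min_sep: int = 3
    anchor_mode: str = "any"  # "any": pair passes if any anchor combo passes
    max_cys: int = 20


@dataclass
class CysPairAssessment:
    """Geometric assessment of one query cysteine pair (1-based indices i < j)."""

    i: int
    j: int
    anchors_i: tuple  # ((template_pos_0based, flagged), ...)
    anchors_j: tuple
    d_ca: float
    d_cb: float
    crit_distance: bool
    crit_orientation: bool
    crit_separation: bool
    possible: bool

    def __post_init__(self):
        if self.possible and not (
            self.crit_distance and self.crit_orientation and self.crit_separation
        ):
            raise ValueError("possible pair must satisfy all three criteria")


@dataclass
class DisulfideMap:
    """All pairwise assessments plus the maximal disjoint bond pairing."""

    assessments: list
    bond_count: int
    chosen_pairing: list  # [(i, j), ...] 1-based cysteine positions
    cys_positions: list = field(default_factory=list)
    unanchored: list = field(default_factory=list)

    def summary_line(self, query_id: str = "", template_name: str = "") -> str:
        return f"{query_id}\t{template_name}\tdiS={self.bond_count}"


def cysteine_positions(seq: str) -> list:
    return [i + 1 for i, aa in enumerate(seq) if aa == "C"]


def anchor_cysteines(alignment, template, query) -> dict:
    """Template anchor positions for each query cysteine.

    A cysteine aligned to a resolved template residue anchors there
    (unflagged). A cysteine falling in an alignment gap (or aligned to an
    unresolved residue) yields up to two flagged candidate anchors: the
    nearest resolved template position left and right of the gap. A cysteine
    with no resolved neighbor on either side is unanchorable and excluded
    with a warning.

    Returns {cys_position_1based: [(template_pos_0based, flagged), ...]}.
    """
    seq = getattr(query, "residues", query)
    pairs = alignment.pairs if hasattr(alignment, "pairs") else list(alignment)
    q2t = dict(pairs)
    resolved = template.resolved
    anchors = {}
    sorted_q = sorted(q2t)
    for cys in cysteine_positions(seq):
        q0 = cys - 1
        tp = q2t.get(q0)
        if tp is not None and resolved[tp]:
            anchors[cys] = [(int(tp), False)]
            continue
        # nearest aligned query neighbors left/right, then their (resolved)
        # template positions
        cand = []
        left = [q for q in sorted_q if q < q0 and resolved[q2t[q]]]
        right = [q for q in sorted_q if q > q0 and resolved[q2t[q]]]
        if left:
            cand.append((int(q2t[left[-1]]), True))
        if right:
            tp_r = int(q2t[right[0]])
            if not cand or cand[0][0] != tp_r:
                cand.append((tp_r, True))
        if not cand:
            warnings.warn(f"cysteine {cys} has no resolved anchor; excluded")
            continue
        anchors[cys] = cand
    return anchors


def check_pair(
    anchors_a,
    anchors_b,
    i: int,
    j: int,
    template,
    params: DisulfideParams = DisulfideParams(),
) -> CysPairAssessment:
    """Assess one cysteine pair against the three geometric criteria.

    Every anchor combination (a, b) with distinct template positions is
    measured on the template's Cα/Cβ coordinates (virtual Cβ acceptable). In
    the default permissive mode the pair is possible if any combination
    passes criteria i and ii (and the sequence-separation criterion iii
    holds); the recorded distances are those of the best (minimum d_cb)
    passing combination, else of the minimum-d_cb combination overall. In
    strict mode every combination must pass.
    """
    if i > j:
        i, j = j, i
        anchors_a, anchors_b = anchors_b, anchors_a
    combos = []
    for (pa, fa) in anchors_a:
        for (pb, fb) in anchors_b:
            if pa == pb:
                continue
            for p, who in ((pa, "A"), (pb, "B")):
                if np.any(np.isnan(template.ca[p])) or np.any(np.isnan(template.cb[p])):
                    raise ValueError(
                        f"anchor {who} at template position {p + 1} lacks coordinates"
                    )
            d_ca = float(np.linalg.norm(template.ca[pa] - template.ca[pb]))
            d_cb = float(np.linalg.norm(template.cb[pa] - template.cb[pb]))
            geom_ok = (
                d_ca <= params.d_ca_max
                and d_cb <= params.d_cb_max
                and (d_cb - d_ca) <= params.d_diff_max
            )
            combos.append((d_ca, d_cb, geom_ok))
    sep_ok = (j - i) >= params.min_sep
    if not combos:
        return CysPairAssessment(
            i=i, j=j, anchors_i=tuple(anchors_a), anchors_j=tuple(anchors_b),
            d_ca=float("nan"), d_cb=float("nan"),
            crit_distance=False, crit_orientation=False,
            crit_separation=sep_ok, possible=False,
        )
    if params.anchor_mode == "strict":
        geom_pass = all(ok for _, _, ok in combos)
    else:
        geom_pass = any(ok for _, _, ok in combos)
    passing = [c for c in combos if c[2]]
    pick_from = passing if (geom_pass and passing) else combos
    d_ca, d_cb, _ = min(pick_from, key=lambda c: c[1])
    crit_distance = d_ca <= params.d_ca_max and d_cb <= params.d_cb_max
    crit_orientation = (d_cb - d_ca) <= params.d_diff_max
    return CysPairAssessment(
        i=i, j=j, anchors_i=tuple(anchors_a), anchors_j=tuple(anchors_b),
        d_ca=d_ca, d_cb=d_cb,
        crit_distance=crit_distance,
        crit_orientation=crit_orientation,
        crit_separation=sep_ok,
        possible=geom_pass and sep_ok,
    )


def _max_matching(vertices, edges):
    """Exact maximum-cardinality matching with deterministic lexicographically
    smallest tie-break. ``edges`` is a set of (i, j) with i < j."""
    vertices = sorted(vertices)
    adj = {v: sorted(u for (a, b) in edges for v2, u in ((a, b), (b, a)) if v2 == v)
           for v in vertices}

    best = {"size": 0, "pairing": ()}

    def rec(idx, used, current):
        # upper-bound prune
        remaining = sum(1 for v in vertices[idx:] if v not in used)
        if len(current) + remaining // 2 < best["size"]:
            return
        if idx == len(vertices):
            key = tuple(sorted(current))
            if len(current) > best["size"] or (
                len(current) == best["size"]
                and (not best["pairing"] or key < best["pairing"])
            ):
                best["size"] = len(current)
                best["pairing"] = key
            return
        v = vertices[idx]
        if v in used:
            rec(idx + 1, used, current)
            return
        for u in adj[v]:
            if u > v and u not in used:
                used.add(v)
                used.add(u)
                current.append((v, u))
                rec(idx + 1, used, current)
                current.pop()
                used.discard(v)
                used.discard(u)
        rec(idx + 1, used, current)

    rec(0, set(), [])
    return best["size"], list(best["pairing"])


def enumerate_bonds(assessments, max_cys: int = 20) -> DisulfideMap:
    """Build the disulfide map: bond_count is the size of a maximum set of
    pairwise-disjoint possible pairs (exact search, guarded at ``max_cys``
    cysteines); the chosen pairing is the lexicographically smallest maximum
    matching."""
    vertices = sorted({a.i for a in assessments} | {a.j for a in assessments})
    if len(vertices) > max_cys:
        raise ValueError(
            f"{len(vertices)} cysteines exceeds the exact-search guard "
            f"({max_cys}); raise max_cys in the configuration to proceed"
        )
    edges = {(a.i, a.j) for a in assessments if a.possible}
    size, pairing = _max_matching(vertices, edges)
    return DisulfideMap(
        assessments=list(assessments),
        bond_count=size,
        chosen_pairing=pairing,
        cys_positions=vertices,
    )


def map_disulfides(
    query,
    template,
    alignment,
    params: DisulfideParams = DisulfideParams(),
) -> DisulfideMap:
    """Full scaffold-based mapping for one query/template alignment."""
    seq = getattr(query, "residues", query)
    anchors = anchor_cysteines(alignment, template, seq)
    positions = cysteine_positions(seq)
    anchored = [p for p in positions if p in anchors]
    assessments = []
    for a_idx in range(len(anchored)):
        for b_idx in range(a_idx + 1, len(anchored)):
            i, j = anchored[a_idx], anchored[b_idx]
            assessments.append(
                check_pair(anchors[i], anchors[j], i, j, template, params)
            )
    dmap = enumerate_bonds(assessments, max_cys=params.max_cys)
    dmap.cys_positions = positions
    dmap.unanchored = [p for p in positions if p not in anchors]
    return dmap


def write_report(dmap: DisulfideMap, path, query_id: str = "", template_name: str = ""):
    """TSV report: one row per assessed pair plus a summary line."""
    chosen = set(map(tuple, dmap.chosen_pairing))
    with open(path, "w") as fh:
        fh.write(
            "query\ttemplate\ti\tj\td_ca\td_cb\tcrit_distance\tcrit_orientation"
            "\tcrit_separation\tpossible\tin_chosen_pairing\n"
        )
        for a in dmap.assessments:
            fh.write(
                f"{query_id}\t{template_name}\t{a.i}\t{a.j}\t{a.d_ca:.2f}\t"
                f"{a.d_cb:.2f}\t{int(a.crit_distance)}\t{int(a.crit_orientation)}\t"
                f"{int(a.crit_separation)}\t{int(a.possible)}\t"
                f"{int((a.i, a.j) in chosen)}\n"
            )
        fh.write("# " + dmap.summary_line(query_id, template_name) + "\n")
    return path
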
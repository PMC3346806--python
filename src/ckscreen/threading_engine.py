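"""Knowledge-based threading: potentials, alignment, scoring, ranking.

The engine pulls a query sequence through template backbones and scores the
fit with knowledge-based potentials of mean force:

* a residue-residue pair potential over Cβ-Cβ distance bins,
  ``E(a,b,d) = -ln[ K (N(a,b,d) + pc) / (N_ref(d) + pc K) ]``, derived from
  training structures with a minimum sequence separation, pseudocount
  regularized and symmetric in (a, b);
* a burial potential over Cβ-neighbor-count bands (residue-solvent term).

Alignment uses the frozen approximation: a query residue placed at template
position i interacts with the template's *native* residues at i's contact
partners. The per-position profile scores feed an affine-gap dynamic program,
global in the template (full fold coverage is required downstream) and
semi-global in the query.

Significance is measured by shuffle z-scores (permute the query, realign,
compare energies), and hits are ranked by a composite threading index::

    Thx = scale * (w_pair * z_pair + w_surf * z_surf + w_seq * S_seq) / len(query)

where S_seq is a substitution-matrix similarity over the aligned pairs. The
absolute Thx scale is specific to this engine; the family cutoff is re-derived
by calibrating on a designated known remote homolog rather than carried over
from any other threading package.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is expected to be present
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "AA_ORDER",
    "PairPotential",
    "BurialPotential",
    "ThreadingAlignment",
    "ThreadingHit",
    "derive_potentials",
    "align_sequence_to_structure",
    "zscores",
    "compute_thx",
    "rank_templates",
    "percent_identity",
    "calibrate_cutoff",
    "seed_for",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# dense 20x20 copy in AA_ORDER
_BLOSUM = np.zeros((20, 20))
for _i, _a in enumerate(AA_ORDER):
    for _j, _b in enumerate(AA_ORDER):
        _BLOSUM[_i, _j] = _BLOSUM62[_a][_b]

BURIAL_BAND_EDGES = (3, 6, 9)  # neighbor-count bands 0-2, 3-5, 6-8, 9+
BURIAL_RADIUS = 10.0


def seed_for(seed: int, *tokens) -> int:
    """Stable sub-seed derivation (below 2**31) from a master seed and tokens."""
    text = ":".join([str(seed)] + [str(t) for t in tokens])
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def aa_indices(sequence: str) -> np.ndarray:
    """Map a one-letter sequence to 0..19 indices; X and unknowns become -1
    (they carry no energy and zero similarity)."""
    return np.array([_AA_INDEX.get(aa, -1) for aa in sequence], dtype=np.int64)


@dataclass
class PairPotential:
    """Distance-binned residue-residue potential of mean force."""

    energy: np.ndarray  # (20, 20, n_bins)
    bin_edges: np.ndarray  # (n_bins + 1,)
    min_separation: int
    pseudocount: float
    reference_state: str = "distance-conditioned pair-type frequency"

    def __post_init__(self):
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("pair potential has non-finite entries")
        if not np.allclose(self.energy, np.swapaxes(self.energy, 0, 1)):
            raise ValueError("pair potential not symmetric in residue types")

    @property
    def n_bins(self) -> int:
        return self.energy.shape[2]

    @property
    def max_distance(self) -> float:
        return float(self.bin_edges[-1])

    def to_json_dict(self) -> dict:
        return {
            "energy": self.energy.tolist(),
            "bin_edges": self.bin_edges.tolist(),
            "min_separation": self.min_separation,
            "pseudocount": self.pseudocount,
            "reference_state": self.reference_state,
            "aa_order": AA_ORDER,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PairPotential":
        return cls(
            energy=np.asarray(d["energy"], dtype=float),
            bin_edges=np.asarray(d["bin_edges"], dtype=float),
            min_separation=int(d["min_separation"]),
            pseudocount=float(d["pseudocount"]),
            reference_state=d.get("reference_state", ""),
        )


@dataclass
class BurialPotential:
    """Residue-type burial potential over Cβ-neighbor-count bands."""

    energy: np.ndarray  # (20, n_bands)
    band_edges: tuple = BURIAL_BAND_EDGES
    radius: float = BURIAL_RADIUS

    def __post_init__(self):
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("burial potential has non-finite entries")

    def band(self, neighbor_count: int) -> int:
        for b, edge in enumerate(self.band_edges):
            if neighbor_count < edge:
                return b
        return len(self.band_edges)

    def to_json_dict(self) -> dict:
        return {
            "energy": self.energy.tolist(),
            "band_edges": list(self.band_edges),
            "radius": self.radius,
            "aa_order": AA_ORDER,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "BurialPotential":
        return cls(
            energy=np.asarray(d["energy"], dtype=float),
            band_edges=tuple(d["band_edges"]),
            radius=float(d["radius"]),
        )


@dataclass
class Potentials:
    pair: PairPotential
    burial: BurialPotential


def _template_geometry(template, max_distance, min_separation):
    """Resolved indices, Cβ distance matrix and contact lists for a template."""
    idx = template.resolved_indices()
    cb = template.cb[idx]
    diff = cb[:, None, :] - cb[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    sep = np.abs(idx[:, None] - idx[None, :])
    contacts = (dist <= max_distance) & (sep >= min_separation)
    return idx, dist, contacts


def derive_potentials(
    training_templates,
    bin_edges=None,
    min_separation: int = 4,
    pseudocount: float = 1.0,
) -> Potentials:
    """Derive pair and burial potentials from training structures.

    Pair counts accumulate over Cβ-Cβ distances of resolved residue pairs at
    sequence separation >= ``min_separation``; burial counts over the number
    of Cβ neighbors within 10 Å. Both tables are converted to mean-force
    energies against a distance-(resp. band-)conditioned uniform reference,
    so uniformly distributed contacts give energies of zero everywhere.
    """
    if bin_edges is None:
        bin_edges = np.arange(0.0, 16.0)  # 0-15 A in 1 A steps
    bin_edges = np.asarray(bin_edges, dtype=float)
    n_bins = len(bin_edges) - 1
    n_bands = len(BURIAL_BAND_EDGES) + 1

    pair_counts = np.zeros((20, 20, n_bins))
    burial_counts = np.zeros((20, n_bands))
    total_contacts = 0
    templates = list(training_templates)
    if not templates:
        raise ValueError("no training templates supplied")
    burial_helper = BurialPotential(energy=np.zeros((20, n_bands)))

    for tpl in templates:
        idx, dist, _ = _template_geometry(tpl, bin_edges[-1], min_separation)
        aa = aa_indices(tpl.sequence)[idx]
        m = len(idx)
        for p in range(m):
            if aa[p] < 0:
                continue
            # burial: neighbors within radius, any separation
            ncount = int(np.sum(dist[p] <= BURIAL_RADIUS)) - 1
            burial_counts[aa[p], burial_helper.band(ncount)] += 1
            for q in range(p + 1, m):
                if aa[q] < 0:
                    continue
                if abs(int(idx[q]) - int(idx[p])) < min_separation:
                    continue
                d = dist[p, q]
                if d >= bin_edges[-1] or d < bin_edges[0]:
                    continue
                b = int(np.searchsorted(bin_edges, d, side="right")) - 1
                pair_counts[aa[p], aa[q], b] += 1
                pair_counts[aa[q], aa[p], b] += 1
                total_contacts += 1
    if total_contacts == 0:
        raise ValueError("no contacts found in training set")

    k_pair = 400.0  # ordered residue-type pairs (counts are symmetrized)
    n_ref = pair_counts.sum(axis=(0, 1))  # per distance bin
    pair_energy = -np.log(
        k_pair * (pair_counts + pseudocount) / (n_ref + pseudocount * k_pair)
    )

    k_bur = 20.0
    bur_ref = burial_counts.sum(axis=0)
    burial_energy = -np.log(
        k_bur * (burial_counts + pseudocount) / (bur_ref + pseudocount * k_bur)
    )

    return Potentials(
        pair=PairPotential(
            energy=pair_energy,
            bin_edges=bin_edges,
            min_separation=min_separation,
            pseudocount=pseudocount,
        ),
        burial=BurialPotential(energy=burial_energy),
    )


class TemplateProfile:
    """Frozen-approximation profile of one template under given potentials.

    ``pair_energy[a, j]`` is the pair energy a query residue of type ``a``
    accrues at resolved template slot ``j`` against the template's native
    contact partners; ``burial_energy[a, j]`` the burial term. Slots follow
    the template's resolved residues in chain order.
    """

    def __init__(self, template, potentials: Potentials):
        self.template = template
        pp, bp = potentials.pair, potentials.burial
        idx, dist, contacts = _template_geometry(
            template, pp.max_distance, pp.min_separation
        )
        self.resolved_idx = idx
        m = len(idx)
        native = aa_indices(template.sequence)[idx]
        self.native_aa = native

        pair_energy = np.zeros((20, m))
        burial_energy = np.zeros((20, m))
        for j in range(m):
            ncount = int(np.sum(dist[j] <= bp.radius)) - 1
            band = bp.band(ncount)
            burial_energy[:, j] = bp.energy[:, band]
            partners = np.flatnonzero(contacts[j])
            for q in partners:
                if native[q] < 0:
                    continue
                b = int(np.searchsorted(pp.bin_edges, dist[j, q], side="right")) - 1
                b = min(max(b, 0), pp.n_bins - 1)
                pair_energy[:, j] += pp.energy[:, native[q], b]
        self.pair_energy = pair_energy
        self.burial_energy = burial_energy
        # half weight on pair term when summing a single side of the
        # interaction during alignment scoring (each contact is shared)
        self.match_score = -(0.5 * pair_energy + burial_energy)


@dataclass
class ThreadingAlignment:
    """A query-to-template alignment with its scores."""

    pairs: list  # ordered (query_pos, template_pos), 0-based, template chain numbering
    pl: int
    fl: int
    gaps: list  # (length, "query" | "template")
    raw_pair_energy: float
    raw_burial_energy: float
    seq_similarity: float
    percent_id: float
    score: float
    z_pair: Optional[float] = None
    z_surf: Optional[float] = None
    thx: Optional[float] = None
    degenerate: bool = False

    def query_to_template(self) -> dict:
        return dict(self.pairs)


@dataclass
class ThreadingHit:
    """A ranked threading result for one template."""

    template: object
    alignment: ThreadingAlignment
    rank: int = 0
    confidence: Optional[str] = None  # "HC" | "FP"
    sse_covered: Optional[bool] = None
    gap_ok: Optional[bool] = None
    fcov_ok: Optional[bool] = None
    domain_coverage: dict = field(default_factory=dict)  # family -> %Cov

    @property
    def thx(self):
        return self.alignment.thx


@njit(cache=False)
def _affine_dp(S, gap_open_col, gap_extend_col, gap_open, gap_extend):  # pragma: no cover - numba kernel
    """Affine-gap DP, global in template (columns), semi-global in query
    (rows; leading/trailing query residues free). Returns DP matrices and
    traceback pointers.

    ``gap_open_col``/``gap_extend_col`` give per-column penalties (gaps are
    disfavored inside secondary-structure elements, so they route through
    loops); ``gap_open``/``gap_extend`` are the uniform query-insertion
    penalties scaled per opening column. Pointer codes: 0 diagonal (match),
    1 up (template gap: query residue skipped), 2 left (query gap: template
    slot skipped).
    """
    q, m = S.shape
    NEG = -1e18
    M = np.full((q + 1, m + 1), NEG)
    Ix = np.full((q + 1, m + 1), NEG)  # gap in template side (query insertion)
    Iy = np.full((q + 1, m + 1), NEG)  # gap in query side (template deletion)
    ptr_m = np.zeros((q + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((q + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((q + 1, m + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, q + 1):
        Ix[i, 0] = 0.0  # leading query residues free (semi-global)
        ptr_x[i, 0] = 1
    acc = 0.0
    for j in range(1, m + 1):
        acc += gap_extend_col[j - 1] if j > 1 else gap_open_col[j - 1]
        Iy[0, j] = -acc
        ptr_y[0, j] = 2

    for i in range(1, q + 1):
        for j in range(1, m + 1):
            # match
            best = M[i - 1, j - 1]
            p = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[i - 1, j - 1]
            ptr_m[i, j] = p
            # gap in template (consume query residue i); opening cost depends
            # on the flanking template column
            col_factor = gap_open_col[j - 1] / gap_open if gap_open > 0 else 1.0
            open_x = M[i - 1, j] - gap_open * col_factor
            ext_x = Ix[i - 1, j] - gap_extend
            if open_x >= ext_x:
                Ix[i, j] = open_x
                ptr_x[i, j] = 0
            else:
                Ix[i, j] = ext_x
                ptr_x[i, j] = 1
            # gap in query (consume template slot j)
            open_y = M[i, j - 1] - gap_open_col[j - 1]
            ext_y = Iy[i, j - 1] - gap_extend_col[j - 1]
            if open_y >= ext_y:
                Iy[i, j] = open_y
                ptr_y[i, j] = 0
            else:
                Iy[i, j] = ext_y
                ptr_y[i, j] = 2
    return M, Ix, Iy, ptr_m, ptr_x, ptr_y


def _traceback(M, Ix, Iy, ptr_m, ptr_x, ptr_y, q, m):
    """Find the best end state at j = m with free trailing query residues and
    trace back to collect (query, slot) match pairs."""
    # end: any i, j = m; trailing query rows free only through Ix chain at j=m
    # with zero cost, so compare M/Iy at each i plus free tail.
    best_score, best_i, best_state = -np.inf, q, 0
    for i in range(q + 1):
        for state, mat in ((0, M), (2, Iy)):
            if mat[i, m] > best_score:
                best_score, best_i, best_state = mat[i, m], i, state
    pairs = []
    i, j, state = best_i, m, best_state
    while i > 0 or j > 0:
        if state == 0:  # in M
            if i == 0 and j == 0:
                break
            pairs.append((i - 1, j - 1))
            state = ptr_m[i, j]
            i, j = i - 1, j - 1
        elif state == 1:  # in Ix
            if j == 0 and i > 0:
                i -= 1  # free leading query residues
                continue
            state = ptr_x[i, j]
            i -= 1
        else:  # in Iy
            state = ptr_y[i, j]
            j -= 1
        if i == 0 and j == 0 and state == 0:
            break
    pairs.reverse()
    return best_score, pairs


def _collect_gaps(pairs, q_len, m):
    """Gap runs: template-side gaps (unmatched slots, incl. terminal — the
    template must be fully covered) and internal query-side gaps."""
    gaps = []
    matched_slots = [tp for _, tp in pairs]
    matched_q = [qp for qp, _ in pairs]
    prev = -1
    for slot in matched_slots + [m]:
        run = slot - prev - 1
        if run > 0:
            gaps.append((run, "template"))
        prev = slot
    for a, b in zip(matched_q, matched_q[1:]):
        run = b - a - 1
        if run > 0:
            gaps.append((run, "query"))
    return gaps


def align_sequence_to_structure(
    query: str,
    template,
    potentials: Potentials,
    gap_open: float = 4.0,
    gap_extend: float = 0.4,
    seq_weight: float = 0.2,
    sse_gap_factor: float = 4.0,
    profile: Optional[TemplateProfile] = None,
) -> ThreadingAlignment:
    """Thread ``query`` onto ``template`` and return the scored alignment.

    The match score combines the frozen-approximation energy profile with a
    small substitution-similarity term (weight ``seq_weight``). Gap penalties
    are position-specific: opening or extending a gap at a template position
    inside a helix or strand costs ``sse_gap_factor`` times more than in a
    loop, so insertions and deletions route through loop regions. Unresolved
    template residues carry no energy and are skipped at zero cost (alignment
    slots cover resolved residues only).
    """
    seq = getattr(query, "residues", query)
    if len(seq) == 0:
        raise ValueError("empty query")
    if len(seq) < 10:
        raise ValueError("query shorter than 10 residues")
    prof = profile or TemplateProfile(template, potentials)
    q_idx = aa_indices(seq)
    m = len(prof.resolved_idx)

    S = np.zeros((len(seq), m))
    valid = q_idx >= 0
    S[valid] = prof.match_score[q_idx[valid]]
    nat_valid = prof.native_aa >= 0
    blos = np.zeros((len(seq), m))
    both = np.outer(valid, nat_valid)
    blos[both] = _BLOSUM[
        np.repeat(q_idx[valid], nat_valid.sum()),
        np.tile(prof.native_aa[nat_valid], valid.sum()),
    ]
    S = S + seq_weight * blos

    in_sse = np.array(
        [template.sse[p] in ("H", "E") for p in prof.resolved_idx], dtype=float
    )
    factor = 1.0 + (sse_gap_factor - 1.0) * in_sse
    gap_open_col = gap_open * factor
    gap_extend_col = gap_extend * factor
    M, Ix, Iy, pm, px, py = _affine_dp(
        S, gap_open_col, gap_extend_col, float(gap_open), float(gap_extend)
    )
    score, slot_pairs = _traceback(M, Ix, Iy, pm, px, py, len(seq), m)

    pairs = [(qp, int(prof.resolved_idx[sp])) for qp, sp in slot_pairs]
    raw_pair = 0.0
    raw_burial = 0.0
    sim = 0.0
    matches = 0
    for (qp, sp) in slot_pairs:
        a = q_idx[qp]
        if a >= 0:
            raw_pair += 0.5 * prof.pair_energy[a, sp]
            raw_burial += prof.burial_energy[a, sp]
            if prof.native_aa[sp] >= 0:
                sim += _BLOSUM[a, prof.native_aa[sp]]
                if a == prof.native_aa[sp]:
                    matches += 1
    pl = len(pairs)
    pid = 100.0 * matches / pl if pl else 0.0
    return ThreadingAlignment(
        pairs=pairs,
        pl=pl,
        fl=template.fl,
        gaps=_collect_gaps(slot_pairs, len(seq), m),
        raw_pair_energy=raw_pair,
        raw_burial_energy=raw_burial,
        seq_similarity=sim / 10.0,
        percent_id=pid,
        score=float(score),
    )


def zscores(
    query,
    template,
    potentials: Potentials,
    n_shuffles: int = 100,
    seed: int = 0,
    profile: Optional[TemplateProfile] = None,
    alignment: Optional[ThreadingAlignment] = None,
):
    """Shuffle z-scores for the pair and burial energies.

    The query sequence is permuted ``n_shuffles`` times; each permutation is
    realigned and its raw energies collected. ``z = (mean_shuffled - E_native)
    / sd`` so that better-than-random (lower energy) is positive. A zero
    spread yields z = 0 with a degenerate flag.
    """
    seq = getattr(query, "residues", query)
    prof = profile or TemplateProfile(template, potentials)
    native = alignment or align_sequence_to_structure(
        seq, template, potentials, profile=prof
    )
    rng = np.random.default_rng(seed)
    chars = np.array(list(seq))
    pair_e = np.empty(n_shuffles)
    burial_e = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuf = "".join(rng.permutation(chars))
        aln = align_sequence_to_structure(shuf, template, potentials, profile=prof)
        pair_e[s] = aln.raw_pair_energy
        burial_e[s] = aln.raw_burial_energy

    degenerate = False

    def z(native_e, samples):
        nonlocal degenerate
        sd = float(np.std(samples))
        if sd < 1e-12:
            degenerate = True
            return 0.0
        return float((np.mean(samples) - native_e) / sd)

    z_pair = z(native.raw_pair_energy, pair_e)
    z_surf = z(native.raw_burial_energy, burial_e)
    native.z_pair, native.z_surf = z_pair, z_surf
    native.degenerate = degenerate
    return z_pair, z_surf, native


def compute_thx(
    alignment: ThreadingAlignment,
    query_length: int,
    w_pair: float = 1.0,
    w_surf: float = 1.0,
    w_seq: float = 1.0,
    scale: float = 100.0,
) -> float:
    """Composite threading index, normalized by query length."""
    if query_length == 0:
        raise ValueError("query_length must be positive")
    if alignment.z_pair is None or alignment.z_surf is None:
        raise ValueError("z-scores not computed; run zscores() first")
    thx = (
        scale
        * (w_pair * alignment.z_pair + w_surf * alignment.z_surf
           + w_seq * alignment.seq_similarity)
        / query_length
    )
    alignment.thx = thx
    return thx


def percent_identity(alignment: ThreadingAlignment, query, template) -> float:
    """100 x identical aligned pairs / pl."""
    seq = getattr(query, "residues", query)
    if alignment.pl == 0:
        raise ValueError("empty alignment")
    matches = sum(
        1 for qp, tp in alignment.pairs if seq[qp] == template.sequence[tp]
    )
    return 100.0 * matches / alignment.pl


def rank_templates(
    query,
    library,
    potentials: Potentials,
    seed: int = 0,
    n_shuffles: int = 100,
    thx_weights=(1.0, 1.0, 1.0),
    scale: float = 100.0,
) -> list:
    """Thread ``query`` against every library template and rank by Thx
    (descending; ties by z_pair then template id). The per-template shuffle
    seed derives from (seed, template id), so the ranking is invariant to
    library ordering."""
    seq = getattr(query, "residues", query)
    hits = []
    for tpl in library:
        prof = TemplateProfile(tpl, potentials)
        aln = align_sequence_to_structure(seq, tpl, potentials, profile=prof)
        zscores(
            seq, tpl, potentials,
            n_shuffles=n_shuffles,
            seed=seed_for(seed, tpl.name),
            profile=prof,
            alignment=aln,
        )
        compute_thx(
            aln, len(seq),
            w_pair=thx_weights[0], w_surf=thx_weights[1], w_seq=thx_weights[2],
            scale=scale,
        )
        hits.append(ThreadingHit(template=tpl, alignment=aln))
    hits.sort(key=lambda h: (-h.alignment.thx, -h.alignment.z_pair, h.template.name))
    for r, hit in enumerate(hits, start=1):
        hit.rank = r
    return hits


def calibrate_cutoff(
    known_homolog,
    library,
    potentials: Potentials,
    seed: int = 0,
    n_shuffles: int = 100,
) -> float:
    """Re-derive the family Thx cutoff by threading a designated known remote
    homolog against the family library (the analogue of calibrating on the
    most remote confirmed family member). Returns the Thx of its best
    high-confidence hit."""
    from ckscreen.screening import classify_hit

    hits = rank_templates(known_homolog, library, potentials,
                          seed=seed, n_shuffles=n_shuffles)
    for hit in hits:
        classify_hit(hit)
        if hit.confidence == "HC":
            return float(hit.alignment.thx)
    # fall back to the top hit if no HC hit exists
    return float(hits[0].alignment.thx)
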
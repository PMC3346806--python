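"""Candidate-model quality statistics.

Once a candidate has been threaded into the chemokine scaffold and a model
built externally, its packing is judged the way reference chemokine models
are: per-residue contact energies under the knowledge-based pair potential,
a rigid-body structural superposition onto the reference, the coefficient of
determination (R²) between the paired contact-energy profiles, and secondary
structure fractions for comparison against spectroscopic estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from ckscreen.foldlib import sse_elements

__all__ = [
    "EnergyProfile",
    "Correspondence",
    "contact_energy_profile",
    "superpose",
    "contact_energy_r2",
    "sse_fractions",
]


@dataclass
class EnergyProfile:
    """Per-residue contact energies, one entry per resolved residue."""

    values: np.ndarray        # (n_resolved,)
    positions: np.ndarray     # chain positions (0-based) of each entry

    def __post_init__(self):
        if len(self.values) != len(self.positions):
            raise ValueError("values/positions length mismatch")

    @property
    def total(self) -> float:
        return float(np.sum(self.values))

    def by_position(self) -> dict:
        return {int(p): float(v) for p, v in zip(self.positions, self.values)}


@dataclass
class Correspondence:
    """Structurally corresponding positions from rigid-body superposition."""

    pairs: list   # (pos_in_A, pos_in_B), 0-based chain positions, increasing
    rmsd: float

    def __post_init__(self):
        if self.rmsd < 0:
            raise ValueError("negative RMSD")
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ValueError("correspondence not strictly increasing")


def contact_energy_profile(structure, pair_potential, cutoff: float = 10.0,
                           min_sep: int = 4) -> EnergyProfile:
    """Per-residue contact energy: half the sum of pair energies over Cβ
    contacts within ``cutoff`` at sequence separation >= ``min_sep``."""
    from ckscreen.threading_engine import aa_indices

    idx = structure.resolved_indices()
    cb = structure.cb[idx]
    aa = aa_indices(structure.sequence)[idx]
    m = len(idx)
    diff = cb[:, None, :] - cb[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    sep = np.abs(idx[:, None] - idx[None, :])
    edges = pair_potential.bin_edges
    values = np.zeros(m)
    for p in range(m):
        if aa[p] < 0:
            continue
        for q in range(m):
            if q == p or aa[q] < 0 or sep[p, q] < min_sep or dist[p, q] > cutoff:
                continue
            b = int(np.searchsorted(edges, dist[p, q], side="right")) - 1
            b = min(max(b, 0), pair_potential.n_bins - 1)
            values[p] += 0.5 * pair_potential.energy[aa[p], aa[q], b]
    return EnergyProfile(values=values, positions=idx)


def _kabsch_rmsd(xa: np.ndarray, xb: np.ndarray):
    """Least-squares rigid superposition of xb onto xa: returns (rmsd, fn)
    where fn transforms arbitrary B-frame coordinates."""
    ca_ = xa.mean(axis=0)
    cb_ = xb.mean(axis=0)
    rot, rssd = Rotation.align_vectors(xa - ca_, xb - cb_)
    rmsd = rssd / np.sqrt(len(xa))

    def transform(x):
        return rot.apply(x - cb_) + ca_

    return float(rmsd), transform


def _monotone_pairs(da: np.ndarray, cutoff: float):
    """Maximum set of strictly increasing (i, j) pairs with distance <= cutoff
    (LCS-style DP over the candidate distance matrix)."""
    na, nb = da.shape
    dp = np.zeros((na + 1, nb + 1), dtype=np.int32)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            best = max(dp[i - 1, j], dp[i, j - 1])
            if da[i - 1, j - 1] <= cutoff:
                best = max(best, dp[i - 1, j - 1] + 1)
            dp[i, j] = best
    pairs = []
    i, j = na, nb
    while i > 0 and j > 0:
        if da[i - 1, j - 1] <= cutoff and dp[i, j] == dp[i - 1, j - 1] + 1:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif dp[i - 1, j] >= dp[i, j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def superpose(struct_a, struct_b, pair_cutoff: float = 5.0,
              max_iter: int = 50, tol: float = 1e-4) -> Correspondence:
    """Iterative closest-correspondence rigid superposition on Cα.

    Seeds the correspondence from an in-order pairing of same-type secondary
    structure elements, then alternates least-squares superposition with
    re-pairing of positions within ``pair_cutoff`` Å (kept sequential on both
    chains) until the RMSD converges.
    """
    for s in (struct_a, struct_b):
        if s.fl < 20:
            raise ValueError("structures must have >= 20 resolved residues")
    elems_a = sse_elements(struct_a)
    elems_b = sse_elements(struct_b)
    seed_pairs = []
    used_b = 0
    for label, sa, ea in elems_a:
        for k in range(used_b, len(elems_b)):
            lb, sb, eb = elems_b[k]
            if lb == label:
                span = min(ea - sa, eb - sb) + 1
                seed_pairs.extend((sa + t, sb + t) for t in range(span))
                used_b = k + 1
                break
    if not seed_pairs:
        raise ValueError(
            "no secondary-structure element pairing between the structures; "
            "supply a manual correspondence"
        )
    seed_pairs = [
        (a, b) for a, b in seed_pairs
        if struct_a.resolved[a] and struct_b.resolved[b]
    ]

    idx_a = struct_a.resolved_indices()
    idx_b = struct_b.resolved_indices()
    ca_a = struct_a.ca[idx_a]
    ca_b = struct_b.ca[idx_b]
    pos_a = {int(p): k for k, p in enumerate(idx_a)}
    pos_b = {int(p): k for k, p in enumerate(idx_b)}

    pairs = [(pos_a[a], pos_b[b]) for a, b in seed_pairs]
    prev_rmsd = np.inf
    rmsd = np.inf
    for _ in range(max_iter):
        xa = ca_a[[p for p, _ in pairs]]
        xb = ca_b[[q for _, q in pairs]]
        rmsd, transform = _kabsch_rmsd(xa, xb)
        moved_b = transform(ca_b)
        diff = ca_a[:, None, :] - moved_b[None, :, :]
        dmat = np.sqrt((diff ** 2).sum(axis=2))
        new_pairs = _monotone_pairs(dmat, pair_cutoff)
        if new_pairs == pairs and abs(prev_rmsd - rmsd) < tol:
            break
        prev_rmsd = rmsd
        if not new_pairs:
            break
        pairs = new_pairs
    xa = ca_a[[p for p, _ in pairs]]
    xb = ca_b[[q for _, q in pairs]]
    rmsd, _ = _kabsch_rmsd(xa, xb)
    chain_pairs = [(int(idx_a[p]), int(idx_b[q])) for p, q in pairs]
    return Correspondence(pairs=chain_pairs, rmsd=rmsd)


def contact_energy_r2(profile_a: EnergyProfile, profile_b: EnergyProfile,
                      correspondence: Correspondence) -> float:
    """Squared Pearson correlation of contact energies over structurally
    corresponding residues (gap positions do not enter)."""
    by_a = profile_a.by_position()
    by_b = profile_b.by_position()
    xs, ys = [], []
    for a, b in correspondence.pairs:
        if a in by_a and b in by_b:
            xs.append(by_a[a])
            ys.append(by_b[b])
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} corresponding energy pairs (< 3)")
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if np.std(xs) < 1e-12 or np.std(ys) < 1e-12:
        raise ValueError("zero variance in a contact-energy profile")
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r * r


def sse_fractions(structure, turn_distance: float = 7.0) -> dict:
    """Helix / strand / turn / unordered fractions of the resolved residues.

    Turns are 4-residue coil stretches whose Cα(i)-Cα(i+3) distance is below
    ``turn_distance``. Returns percentages and residue counts; percentages
    sum to 100 up to rounding.
    """
    idx = structure.resolved_indices()
    labels = structure.sse
    n = len(idx)
    is_turn = np.zeros(structure.n_residues, dtype=bool)
    for i in range(structure.n_residues - 3):
        window = range(i, i + 4)
        if all(structure.resolved[k] and labels[k] == "C" for k in window):
            d = np.linalg.norm(structure.ca[i] - structure.ca[i + 3])
            if d < turn_distance:
                is_turn[i : i + 4] = True
    counts = {"helix": 0, "strand": 0, "turn": 0, "unordered": 0}
    for k in idx:
        if labels[k] == "H":
            counts["helix"] += 1
        elif labels[k] == "E":
            counts["strand"] += 1
        elif is_turn[k]:
            counts["turn"] += 1
        else:
            counts["unordered"] += 1
    return {
        "percent": {k: 100.0 * v / n for k, v in counts.items()},
        "counts": counts,
        "n_resolved": n,
    }
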
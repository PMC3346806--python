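"""Template structures and fold libraries.

Two libraries drive the screen: a chemokine-only library (every template with
a SCOP d.9 — IL8-like — domain) used as the family's 3D descriptor, and a
redundancy-reduced all-fold library used for control threading across fold
space. Templates are single PDB/mmCIF chains reduced to the geometry the
threading engine and disulfide mapper consume: per-residue identity, Cα and
Cβ coordinates (virtual Cβ reconstructed with ideal tetrahedral geometry when
unobserved, including glycine), resolved flags, secondary-structure labels and
SCOP domain ranges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "TemplateStructure",
    "FoldLibrary",
    "parse_structure_chain",
    "virtual_cbeta",
    "assign_sse",
    "read_scop_map",
    "build_chemokine_library",
    "build_foldspace_library",
    "global_identity",
    "scop_domain_coverage",
]

# Ideal-geometry constants for the N/CA/C -> CB reconstruction. The linear
# combination of the two backbone bond vectors and their cross product places
# CB at ~1.53 A from CA with tetrahedral angles.
_CB_A, _CB_B, _CB_C = -0.58273431, 0.56802827, -0.54067466


@dataclass
class TemplateStructure:
    """One polymer chain reduced to threading/mapping geometry.

    Arrays are index-aligned over all polymer residues of the chain; positions
    are 0-based internally (operations exposing residue numbers use 1-based).
    """

    pdb_id: str
    chain_id: str
    sequence: str                      # one-letter codes, X for unknowns
    resolved: np.ndarray               # bool, has a CA coordinate
    ca: np.ndarray                     # (n, 3) float, NaN where unresolved
    cb: np.ndarray                     # (n, 3) float, NaN where unresolved
    cb_virtual: np.ndarray             # bool, CB reconstructed (incl. Gly)
    sse: np.ndarray = None             # unicode 'H'/'E'/'C'
    scop_domains: list = field(default_factory=list)  # (family_id, start, end) 1-based

    def __post_init__(self):
        n = len(self.sequence)
        if self.sse is None:
            self.sse = np.full(n, "C", dtype="<U1")
        for arr, name in ((self.resolved, "resolved"), (self.sse, "sse")):
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
        if self.fl < 1:
            raise ValueError(f"{self.pdb_id}_{self.chain_id}: no resolved residues")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def fl(self) -> int:
        """Template fold length: number of resolved residues."""
        return int(np.count_nonzero(self.resolved))

    @property
    def key(self):
        return (self.pdb_id, self.chain_id)

    @property
    def name(self) -> str:
        return f"{self.pdb_id}_{self.chain_id}"

    def resolved_indices(self) -> np.ndarray:
        return np.flatnonzero(self.resolved)


@dataclass
class FoldLibrary:
    """A named collection of unique template chains."""

    name: str
    kind: str  # "chemokine" | "fold_space"
    templates: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        keys = [t.key for t in self.templates]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (pdb_id, chain_id) in library")

    def __len__(self):
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def get(self, name: str):
        for t in self.templates:
            if t.name == name:
                return t
        raise KeyError(name)

    def manifest(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "n_templates": len(self.templates),
            "templates": [
                {"pdb_id": t.pdb_id, "chain": t.chain_id, "fl": t.fl,
                 "scop": [d[0] for d in t.scop_domains]}
                for t in self.templates
            ],
            "provenance": self.provenance,
        }

    def write_manifest(self, path):
        Path(path).write_text(json.dumps(self.manifest(), indent=2))


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Reconstruct CB from backbone N, CA, C with ideal tetrahedral geometry
    (CA-CB bond ~1.53 A)."""
    b = ca - n
    c_vec = c - ca
    a = np.cross(c_vec, b)  # handedness: CB on the si face of the backbone
    return _CB_A * a + _CB_B * b + _CB_C * c_vec + ca


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is None:
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() and code != " " else "X"


def parse_structure_chain(path, chain_id: str) -> TemplateStructure:
    """Parse one chain of a PDB or mmCIF file into a :class:`TemplateStructure`.

    Altlocs resolve to the highest-occupancy conformer; NMR ensembles take
    model 1. Residues without a CA are marked unresolved; missing CBs
    (including glycine) are reconstructed from N/CA/C where available.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model)
        raise KeyError(
            f"chain {chain_id!r} not found in {path}; available chains: {available}"
        )

    seq, resolved, cas, cbs, virt = [], [], [], [], []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and not info.is_amino_acid():
            continue  # waters, ligands
        seq.append(_one_letter(res.name))

        def best_atom(name):
            best = None
            for atom in res:
                if atom.name == name and (best is None or atom.occ > best.occ):
                    best = atom
            return best

        atoms = {nm: best_atom(nm) for nm in ("N", "CA", "C", "CB")}
        ca_at = atoms["CA"]
        if ca_at is None:
            resolved.append(False)
            cas.append([np.nan] * 3)
            cbs.append([np.nan] * 3)
            virt.append(False)
            continue
        resolved.append(True)
        ca_xyz = np.array([ca_at.pos.x, ca_at.pos.y, ca_at.pos.z])
        cas.append(ca_xyz)
        cb_at = atoms["CB"]
        if cb_at is not None:
            cbs.append([cb_at.pos.x, cb_at.pos.y, cb_at.pos.z])
            virt.append(False)
        elif atoms["N"] is not None and atoms["C"] is not None:
            n_xyz = np.array([atoms["N"].pos.x, atoms["N"].pos.y, atoms["N"].pos.z])
            c_xyz = np.array([atoms["C"].pos.x, atoms["C"].pos.y, atoms["C"].pos.z])
            cbs.append(virtual_cbeta(n_xyz, ca_xyz, c_xyz))
            virt.append(True)
        else:
            # CA-only residue: fall back to CA as the interaction center
            cbs.append(ca_xyz)
            virt.append(True)

    pdb_id = (st.name or Path(path).stem).lower()[:4]
    tpl = TemplateStructure(
        pdb_id=pdb_id,
        chain_id=chain_id,
        sequence="".join(seq),
        resolved=np.array(resolved, dtype=bool),
        ca=np.asarray(cas, dtype=float),
        cb=np.asarray(cbs, dtype=float),
        cb_virtual=np.array(virt, dtype=bool),
    )
    assign_sse(tpl)
    return tpl


# Canonical CA-geometry signatures (A). An ideal alpha-helix has
# d(i,i+3) ~ 5.3 and d(i,i+4) ~ 6.2; extended strands have d(i,i+2) >~ 6.3 and
# pair with a partner strand at CA-CA ~ 4.5-5.5.
_HELIX_D13 = (4.6, 6.0)
_HELIX_D14 = (5.2, 7.0)
_EXT_D2 = 6.3
_PAIR_DIST = 5.5
_MIN_ELEMENT = 3


def assign_sse(template: TemplateStructure, external_labels=None) -> TemplateStructure:
    """Assign H/E/C labels from CA geometry (in place; also returns template).

    ``external_labels`` may supply a per-residue label sequence (1-based dict
    or full string) overriding the built-in assignment. Chains with fewer than
    5 resolved residues are labelled all-coil.
    """
    n = template.n_residues
    labels = np.full(n, "C", dtype="<U1")
    if external_labels is not None:
        if isinstance(external_labels, str):
            if len(external_labels) != n:
                raise ValueError("external SSE label length mismatch")
            labels[:] = list(external_labels)
        else:
            for pos, lab in external_labels.items():
                labels[pos - 1] = lab
        template.sse = labels
        return template

    idx = template.resolved_indices()
    if len(idx) < 5:
        template.sse = labels
        return template
    ca = template.ca

    def d(i, j):
        return float(np.linalg.norm(ca[i] - ca[j]))

    resolved = template.resolved
    helix = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if not all(resolved[i : i + 5]):
            continue
        if (
            _HELIX_D13[0] <= d(i, i + 3) <= _HELIX_D13[1]
            and _HELIX_D14[0] <= d(i, i + 4) <= _HELIX_D14[1]
        ):
            helix[i : i + 5] = True

    # extension candidates
    ext = np.zeros(n, dtype=bool)
    for i in range(1, n - 1):
        if resolved[i - 1] and resolved[i] and resolved[i + 1]:
            if d(i - 1, i + 1) >= _EXT_D2:
                ext[i] = True
    # strand requires a partner strand within pairing distance
    strand = np.zeros(n, dtype=bool)
    cand = np.flatnonzero(ext & ~helix)
    for ii, i in enumerate(cand):
        for j in cand[ii + 1 :]:
            if j - i >= 4 and d(i, j) <= _PAIR_DIST:
                strand[i] = strand[j] = True

    labels[helix] = "H"
    labels[strand & ~helix] = "E"

    # enforce minimum element length
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in "HE" and j - i < _MIN_ELEMENT:
            labels[i:j] = "C"
        i = j
    template.sse = labels
    return template


def sse_elements(template: TemplateStructure, min_length: int = 3):
    """Contiguous H/E elements of at least ``min_length`` residues, as
    (label, start, end) with 0-based inclusive bounds."""
    out = []
    labels = template.sse
    i, n = 0, template.n_residues
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        if labels[i] in "HE" and j - i >= min_length:
            out.append((str(labels[i]), i, j - 1))
        i = j
    return out


def read_scop_map(path) -> dict:
    """Read a SCOP mapping TSV (pdb_id, chain, scop_family, start, end) into
    {(pdb_id, chain): [(family, start, end), ...]} with 1-based ranges."""
    mapping = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns")
            key = (cols[0].lower(), cols[1])
            mapping.setdefault(key, []).append((cols[2], int(cols[3]), int(cols[4])))
    return mapping


def build_chemokine_library(templates, scop_map, fold_prefix="d.9") -> FoldLibrary:
    """Keep templates carrying at least one SCOP domain under the IL8-like
    chemokine fold (d.9). Templates without any SCOP mapping are excluded with
    a warning."""
    kept, unmapped = [], 0
    for tpl in templates:
        domains = scop_map.get(tpl.key)
        if not domains:
            unmapped += 1
            warnings.warn(f"template {tpl.name} has no SCOP mapping; excluded")
            continue
        tpl.scop_domains = list(domains)
        if any(fam.startswith(fold_prefix) for fam, _, _ in domains):
            kept.append(tpl)
    return FoldLibrary(
        name="chemokine",
        kind="chemokine",
        templates=kept,
        provenance={"fold_prefix": fold_prefix, "n_input": len(list(templates)),
                    "n_unmapped": unmapped},
    )


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity under a global match-maximizing alignment
    (match=1, mismatch=0, no gap penalty), normalized by the shorter
    sequence length (terminal overhangs do not dilute identity)."""
    la, lb = len(seq_a), len(seq_b)
    if la == 0 or lb == 0:
        return 0.0
    # LCS-style DP on match counts
    dp = np.zeros((la + 1, lb + 1), dtype=np.int32)
    for i in range(1, la + 1):
        ai = seq_a[i - 1]
        row, prev = dp[i], dp[i - 1]
        for j in range(1, lb + 1):
            m = prev[j - 1] + (1 if ai == seq_b[j - 1] else 0)
            row[j] = max(m, prev[j], row[j - 1])
    matches = int(dp[la, lb])
    return 100.0 * matches / min(la, lb)


def build_foldspace_library(templates, identity_cutoff: float = 95.0) -> FoldLibrary:
    """Greedy redundancy reduction at ``identity_cutoff`` percent identity.

    Templates are sorted by fold length descending (ties by (pdb_id, chain));
    a template is admitted iff its global identity to every admitted
    representative is below the cutoff. Deterministic and invariant to input
    order."""
    pool = sorted(templates, key=lambda t: (-t.fl, t.pdb_id, t.chain_id))
    admitted = []
    for tpl in pool:
        if all(
            global_identity(tpl.sequence, rep.sequence) < identity_cutoff
            for rep in admitted
        ):
            admitted.append(tpl)
    return FoldLibrary(
        name="fold_space",
        kind="fold_space",
        templates=admitted,
        provenance={"identity_cutoff": identity_cutoff, "n_input": len(pool)},
    )


def scop_domain_coverage(alignment_pairs, domain_range) -> float:
    """%Cov: percentage of a SCOP domain's positions aligned to a query residue.

    ``alignment_pairs`` is an iterable of (query_pos, template_pos) with
    0-based template positions; ``domain_range`` is (start, end) 1-based
    inclusive in template numbering."""
    start, end = domain_range
    length = end - start + 1
    if length <= 0:
        raise ValueError("empty SCOP domain range")
    covered = sum(1 for _, tp in alignment_pairs if start - 1 <= tp <= end - 1)
    return 100.0 * covered / length
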
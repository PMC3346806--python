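"""Seeded synthetic fixtures: toy templates, homologs, decoy cohorts.

The screening pipeline is exercised end to end without downloads by
generating idealized template structures (secondary-structure elements laid
out as parallel/antiparallel segments with connecting loops), sequences
mutated away from a template to a target identity, and cohorts of decoy
sequences with companion predictor and homology-hit files in the same
formats the pipeline consumes.

Toy backbones are Cα traces with synthetic Cβ directions; only Cα/Cβ
geometry and SSE labels matter downstream, so no attempt is made at physical
plausibility beyond that. Planted disulfide pairs are positioned to satisfy
exactly the intended subset of the three geometric bond criteria, and every
emitted fixture is validated against a direct recomputation of those
criteria before it is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ckscreen.disulfide import DisulfideParams, check_pair
from ckscreen.foldlib import FoldLibrary, TemplateStructure
from ckscreen.seqio import SequenceRecord
from ckscreen.threading_engine import AA_ORDER, _BLOSUM, _AA_INDEX

__all__ = [
    "FixtureSpec",
    "make_toy_template",
    "make_chemokine_fixture",
    "make_toy_foldspace",
    "make_homolog",
    "make_decoy_cohort",
]

# amino-acid background frequencies (approximate vertebrate proteome)
_BG_AA = "ALGVESIKRDTPNQFYMHCW"
_BG_P = np.array(
    [8.3, 9.7, 7.0, 6.9, 6.8, 6.6, 5.9, 5.8, 5.5, 5.4,
     5.4, 4.7, 4.1, 4.0, 3.9, 2.9, 2.4, 2.6, 1.4, 1.1]
)
_BG_P = _BG_P / _BG_P.sum()

_VERDICTS = ("all_pass", "fail_distance", "fail_orientation", "fail_separation")

_RISE = {"H": 1.5, "E": 3.3, "C": 3.0}
_LATERAL = {"H": 10.0, "E": 4.8, "C": 7.0}


@dataclass
class FixtureSpec:
    """Declarative description of a toy template."""

    seed: int
    sse_layout: list  # [(label, length), ...] labels in {H, E, C}
    planted_disulfides: list = field(default_factory=list)  # (i, j, verdict)
    name: str = "toy"
    scop_family: str = ""

    @property
    def n_residues(self) -> int:
        return sum(length for _, length in self.sse_layout)

    def __post_init__(self):
        n = self.n_residues
        labels = self.labels()
        for i, j, verdict in self.planted_disulfides:
            if not (1 <= i < j <= n):
                raise ValueError(f"planted pair ({i}, {j}) out of bounds")
            if verdict not in _VERDICTS:
                raise ValueError(f"unknown verdict {verdict!r}")
            if labels[i - 1] != "C" or labels[j - 1] != "C":
                raise ValueError(
                    f"planted cysteines must sit in coil segments; "
                    f"({i}, {j}) violates the layout"
                )

    def labels(self) -> str:
        return "".join(label * length for label, length in self.sse_layout)


def _helix_coords(length: int, rng) -> np.ndarray:
    """Ideal alpha-helix Cα trace along +x (radius 2.3 Å, rise 1.5 Å,
    100 degrees per residue)."""
    t = np.arange(length)
    ang = np.deg2rad(100.0 * t)
    return np.column_stack([1.5 * t, 2.3 * np.cos(ang), 2.3 * np.sin(ang)])


def _strand_coords(length: int, rng) -> np.ndarray:
    """Extended strand along +x with a small pleat."""
    t = np.arange(length)
    return np.column_stack([3.3 * t, 0.5 * (-1.0) ** t, np.zeros(length)])


def _coil_coords(length: int, rng) -> np.ndarray:
    """A meandering connector with ~3.6 Å steps."""
    steps = rng.normal(size=(length, 3))
    steps[:, 0] += 0.8  # drift forward
    steps /= np.linalg.norm(steps, axis=1, keepdims=True) / 3.6
    return np.cumsum(steps, axis=0)


def make_toy_template(spec: FixtureSpec,
                      params: DisulfideParams = DisulfideParams()
                      ) -> TemplateStructure:
    """Build a deterministic toy template from a :class:`FixtureSpec`.

    Elements are stacked with element-type lateral offsets (consecutive
    strands land at sheet-pairing distance, so strand detection and contact
    formation work), alternating direction for antiparallel topology. Planted
    disulfide pairs are then positioned to meet exactly their intended
    criteria and verified by direct recomputation; a fixture whose intended
    verdicts cannot be realized raises at build time.
    """
    rng = np.random.default_rng(spec.seed)
    labels = spec.labels()
    n = spec.n_residues
    ca = np.zeros((n, 3))
    cursor = 0
    y_off = 0.0
    direction = 1.0
    for k, (label, length) in enumerate(spec.sse_layout):
        if label == "H":
            seg = _helix_coords(length, rng)
        elif label == "E":
            seg = _strand_coords(length, rng)
        else:
            seg = _coil_coords(length, rng)
        seg = seg * np.array([direction, 1.0, 1.0])
        if label in "HE":
            y_off += _LATERAL[label]
            direction *= -1.0
        start = ca[cursor - 1] if cursor else np.zeros(3)
        offset = start + np.array([direction * 2.0, 0.0, 0.0])
        seg = seg - seg[0] + offset + np.array([0.0, (y_off if label in "HE" else y_off * 0.5), 0.0])
        ca[cursor : cursor + length] = seg
        cursor += length

    # synthetic Cβ: unit vector away from the centroid
    centroid = ca.mean(axis=0)
    out_dir = ca - centroid
    norms = np.linalg.norm(out_dir, axis=1, keepdims=True)
    norms[norms < 1e-9] = 1.0
    cb = ca + 1.53 * out_dir / norms

    # sequence: background draw, no stray cysteines
    seq = list(rng.choice(list(_BG_AA), size=n, p=_BG_P))
    for p in range(n):
        if seq[p] == "C":
            seq[p] = "S"

    # plant disulfide geometry
    for i, j, verdict in spec.planted_disulfides:
        a, b = i - 1, j - 1
        seq[a] = seq[b] = "C"
        e = rng.normal(size=3)
        e /= np.linalg.norm(e)
        if verdict in ("all_pass", "fail_separation"):
            d_ca = 5.5
            ca[b] = ca[a] + d_ca * e
            cb[a] = ca[a] + 1.53 * e
            cb[b] = ca[b] - 1.53 * e
        elif verdict == "fail_distance":
            d_ca = 14.0
            ca[b] = ca[a] + d_ca * e
            cb[a] = ca[a] + 1.53 * e
            cb[b] = ca[b] - 1.53 * e
        elif verdict == "fail_orientation":
            d_ca = 5.0
            ca[b] = ca[a] + d_ca * e
            cb[a] = ca[a] - 1.53 * e  # side chains point apart
            cb[b] = ca[b] + 1.53 * e

    tpl = TemplateStructure(
        pdb_id=spec.name[:4].lower().ljust(4, "0"),
        chain_id="A",
        sequence="".join(seq),
        resolved=np.ones(n, dtype=bool),
        ca=ca,
        cb=cb,
        cb_virtual=np.ones(n, dtype=bool),
        sse=np.array(list(labels), dtype="<U1"),
    )
    if spec.scop_family:
        tpl.scop_domains = [(spec.scop_family, 1, n)]

    # build-time oracle: recompute each planted pair's criteria directly
    for i, j, verdict in spec.planted_disulfides:
        a = check_pair([(i - 1, False)], [(j - 1, False)], i, j, tpl, params)
        expected = {
            "all_pass": (True, True, True),
            "fail_distance": (False, True, True),
            "fail_orientation": (True, False, True),
            "fail_separation": (True, True, False),
        }[verdict]
        got = (a.crit_distance, a.crit_orientation, a.crit_separation)
        if got != expected:
            raise ValueError(
                f"fixture {spec.name}: planted pair ({i}, {j}) intended "
                f"{verdict} but realized criteria {got}"
            )
    return tpl


def make_chemokine_fixture(seed: int = 0, name: str = "ckfx") -> TemplateStructure:
    """A 70-residue chemokine-like toy fold: three strands packed against a
    C-terminal helix, six cysteines planted as three compatible disulfide
    pairs in the loop regions."""
    spec = FixtureSpec(
        seed=seed,
        sse_layout=[("C", 6), ("E", 8), ("C", 4), ("E", 8), ("C", 4),
                    ("E", 8), ("C", 5), ("H", 14), ("C", 13)],
        planted_disulfides=[(2, 60, "all_pass"), (4, 28, "all_pass"),
                            (16, 40, "all_pass")],
        name=name,
        scop_family="d.9.1.1",
    )
    return make_toy_template(spec)


_FOLDSPACE_SPECS = [
    dict(name="ckfx", scop_family="d.9.1.1", layout=None),  # chemokine fixture
    dict(name="hbdl", scop_family="a.60.1.2",
         layout=[("C", 4), ("H", 14), ("C", 4), ("H", 14), ("C", 4), ("H", 14), ("C", 4)]),
    dict(name="sndw", scop_family="b.1.1.1",
         layout=[("C", 4), ("E", 7), ("C", 3), ("E", 7), ("C", 3), ("E", 7),
                 ("C", 3), ("E", 7), ("C", 4)]),
    dict(name="toxn", scop_family="g.3.7.2",
         layout=[("C", 5), ("E", 6), ("C", 4), ("E", 6), ("C", 6)]),
    dict(name="abrl", scop_family="c.2.1.1",
         layout=[("C", 4), ("E", 6), ("C", 3), ("H", 12), ("C", 3), ("E", 6),
                 ("C", 3), ("H", 12), ("C", 4)]),
    dict(name="hhpn", scop_family="a.1.1.1",
         layout=[("C", 5), ("H", 16), ("C", 5), ("H", 16), ("C", 5)]),
]


def make_toy_foldspace(seed: int = 0):
    """A mixed toy fold-space library (chemokine fixture + 5 geometrically
    distinct folds) and its SCOP mapping."""
    templates = []
    scop_map = {}
    for k, entry in enumerate(_FOLDSPACE_SPECS):
        sub_seed = seed * 1000 + k
        if entry["layout"] is None:
            tpl = make_chemokine_fixture(seed=sub_seed, name=entry["name"])
        else:
            tpl = make_toy_template(
                FixtureSpec(seed=sub_seed, sse_layout=entry["layout"],
                            name=entry["name"],
                            scop_family=entry["scop_family"])
            )
        templates.append(tpl)
        scop_map[tpl.key] = list(tpl.scop_domains)
    library = FoldLibrary(name="toy_fold_space", kind="fold_space",
                          templates=templates,
                          provenance={"seed": seed, "synthetic": True})
    return library, scop_map


def make_homolog(template, target_identity: float, preserve_cys: bool = True,
                 seed: int = 0) -> str:
    """Mutate the template's native sequence to a target percent identity.

    Cysteines are preserved (and never introduced) when ``preserve_cys``;
    substitutions are drawn with BLOSUM-weighted probabilities. The realized
    identity is exact to within rounding of the mutation count."""
    if not (0 < target_identity <= 100):
        raise ValueError("target identity must be in (0, 100]")
    rng = np.random.default_rng(seed)
    seq = list(template.sequence)
    n = len(seq)
    mutable = [p for p in range(n)
               if not (preserve_cys and seq[p] == "C") and seq[p] in _AA_INDEX]
    n_mut = int(round(n * (1.0 - target_identity / 100.0)))
    if n_mut > len(mutable):
        raise ValueError(
            f"target identity {target_identity}% unreachable with "
            f"{len(mutable)} mutable positions"
        )
    chosen = rng.choice(len(mutable), size=n_mut, replace=False)
    for c in chosen:
        p = mutable[c]
        a = _AA_INDEX[seq[p]]
        weights = np.exp(_BLOSUM[a] / 2.0)
        weights[a] = 0.0
        if preserve_cys:
            weights[_AA_INDEX["C"]] = 0.0
        weights /= weights.sum()
        seq[p] = AA_ORDER[rng.choice(20, p=weights)]
    return "".join(seq)


def make_decoy_cohort(
    n: int,
    length_range=(55, 120),
    cys_range=(2, 8),
    seed: int = 0,
    sp_fraction: float = 0.2,
    tm_fraction: float = 0.1,
    annotated_fraction: float = 0.1,
    out_dir=None,
):
    """Generate ``n`` decoy records plus companion predictor/hit fixtures.

    Returns ``(records, sp_predictions, tm_predictions, homology_hits)`` in
    the in-memory form the pipeline consumes; when ``out_dir`` is given the
    same content is also written as FASTA / TSV files (byte-identical for a
    given seed)."""
    from ckscreen.seqio import SignalPeptidePrediction, write_fasta

    rng = np.random.default_rng(seed)
    records = []
    sp_preds = {}
    tm_preds = {}
    hom_hits = {}
    for k in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        n_cys = int(rng.integers(cys_range[0], cys_range[1] + 1))
        seq = list(rng.choice(list(_BG_AA), size=length, p=_BG_P))
        for p in range(length):
            if seq[p] == "C":
                seq[p] = "S"
        cys_pos = rng.choice(length, size=min(n_cys, length), replace=False)
        for p in cys_pos:
            seq[p] = "C"
        rec_id = f"tr|D{k:04d}X|D{k:04d}X_HUMAN"
        rec = SequenceRecord(
            id=rec_id,
            residues="".join(seq),
            accession=f"D{k:04d}X",
            description="Putative uncharacterized protein (hypothetical)",
        )
        records.append(rec)
        if rng.random() < sp_fraction:
            cpos = int(rng.integers(16, 31))
            sp_preds[rec_id] = (
                SignalPeptidePrediction(True, cpos, 0.9, "methodA"),
                SignalPeptidePrediction(True, cpos + int(rng.integers(0, 3)),
                                        0.8, "methodB"),
            )
        if rng.random() < tm_fraction and length >= 80:
            s = int(rng.integers(30, length - 40))
            tm_preds[rec_id] = ([(s, s + 20)], [(s + 1, s + 21)])
        if rng.random() < annotated_fraction:
            from ckscreen.seqio import HomologyHit
            hom_hits[rec_id] = [
                HomologyHit(rec_id, "1abc_A", 55.0, 80, 1e-20)
            ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "decoys.fasta")
        with open(out_dir / "sp_predictions.tsv", "w") as fh:
            for rid, (a, b) in sorted(sp_preds.items()):
                fh.write(f"{rid}\t{a.cleavage_pos}\t{a.score:.2f}\n")
                fh.write(f"{rid}\t{b.cleavage_pos}\t{b.score:.2f}\n")
        with open(out_dir / "tm_predictions.tsv", "w") as fh:
            for rid, (a, b) in sorted(tm_preds.items()):
                pos_a = ",".join(f"{s}-{e}" for s, e in a)
                pos_b = ",".join(f"{s}-{e}" for s, e in b)
                fh.write(f"{rid}\t{pos_a}\t1.0\n{rid}\t{pos_b}\t1.0\n")
        with open(out_dir / "homology_hits.tsv", "w") as fh:
            for rid, hits in sorted(hom_hits.items()):
                for h in hits:
                    fh.write(
                        f"{h.query_id}\t{h.subject_id}\t{h.percent_similarity}\t"
                        f"{h.alignment_length}\t0\t0\t1\t{h.alignment_length}\t1\t"
                        f"{h.alignment_length}\t{h.evalue}\t100.0\n"
                    )
    return records, sp_preds, tm_preds, hom_hits
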
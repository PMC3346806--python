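"""Candidate sequence I/O and the pre-filter cascade.

Uncharacterized proteins enter the screen as FASTA records with UniProt-style
headers. Before any threading is attempted, candidates pass a cascade of cheap
sequence-level filters: description-keyword selection, cysteine-count and
length thresholds (a functional IL8-like chemokine fold needs at least one
disulfide bond and a minimal domain size), rejection of sequences that are
already structurally annotated (strong hits against the PDB), and removal of
predicted signal peptides and transmembrane segments, which are not part of
the chemokine fold. Signal-peptide and transmembrane predictions come from
external tools; this module only builds consensus regions from two methods'
outputs and excises them.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Region",
    "HomologyHit",
    "SignalPeptidePrediction",
    "read_fasta",
    "write_fasta",
    "keyword_filter",
    "cys_length_filter",
    "parse_homology_hits",
    "annotation_filter",
    "consensus_signal_peptide",
    "consensus_transmembrane",
    "apply_region_removal",
    "DEFAULT_KEYWORDS",
]

DEFAULT_KEYWORDS = frozenset(
    {"unknown", "orf", "hypothetical", "uncharacterized", "putative"}
)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Non-standard one-letter codes: selenocysteine and pyrrolysine are mapped to
# their canonical analogs; ambiguity codes collapse to X and are excluded from
# cysteine counting and mass computation.
_RESIDUE_MAP = {"U": "C", "O": "K", "B": "X", "Z": "X", "J": "X"}

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([A-Z0-9-]+)\|\S+")


@dataclass(frozen=True)
class Region:
    """A predicted signal-peptide or transmembrane segment (1-based, inclusive)."""

    start: int
    end: int
    kind: str  # "signal_peptide" | "transmembrane"
    confidence: str  # "high" | "medium" | "low"
    method_scores: tuple = ()

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region bounds [{self.start}, {self.end}]")
        if self.kind not in ("signal_peptide", "transmembrane", "discarded_segment"):
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.confidence not in ("high", "medium", "low"):
            raise ValueError(f"unknown confidence {self.confidence!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SequenceRecord:
    """A candidate protein sequence with provenance and trim history.

    ``parent_start`` is the 1-based position of ``residues[0]`` in the
    original, untrimmed parent sequence; ``trim_log`` records the regions
    removed so far, in parent coordinates.
    """

    id: str
    residues: str
    accession: str = ""
    description: str = ""
    parent_start: int = 1
    trim_log: list = field(default_factory=list)
    substitutions: list = field(default_factory=list)  # (pos, original, mapped)

    def __post_init__(self):
        if self.parent_start < 1:
            raise ValueError("parent_start must be >= 1")
        bad = set(self.residues) - set(STANDARD_AA + "X")
        if bad:
            raise ValueError(f"non-sanitized residues {sorted(bad)} in {self.id}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_cys(self) -> int:
        return self.residues.count("C")


class HomologyHit(NamedTuple):
    """One row of a tabular homology search (PDB annotation check)."""

    query_id: str
    subject_id: str
    percent_similarity: float
    alignment_length: int
    evalue: float


class SignalPeptidePrediction(NamedTuple):
    """Output of one external signal-peptide predictor."""

    has_sp: bool
    cleavage_pos: int = 0  # 1-based last residue of the signal peptide
    score: float = 0.0
    method: str = ""


def _sanitize(seq: str, record_id: str):
    out = []
    subs = []
    for pos, aa in enumerate(seq.upper(), start=1):
        if aa in ("*", "-", "."):
            continue
        mapped = _RESIDUE_MAP.get(aa, aa)
        if mapped not in STANDARD_AA + "X":
            mapped = "X"
        if mapped != aa:
            subs.append((pos, aa, mapped))
        out.append(mapped)
    return "".join(out), subs


def read_fasta(path) -> list[SequenceRecord]:
    """Read candidate sequences; extract accessions from UniProt-style headers.

    Headers of the form ``sp|ACC|NAME`` or ``tr|ACC|NAME`` yield the accession;
    otherwise the first whitespace token is the id and the accession is empty.
    An empty file yields an empty list.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _UNIPROT_HEADER.match(rec.id)
        accession = m.group(1) if m else ""
        residues, subs = _sanitize(str(rec.seq), rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                accession=accession,
                description=rec.description.partition(" ")[2].strip(),
                substitutions=subs,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path, header_extra: str = ""):
    """Write records back out (survivor lists between pipeline stages)."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            extra = f" {header_extra}" if header_extra else ""
            fh.write(f">{rec.id}{desc}{extra}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")
    return path


def keyword_filter(records, keywords=DEFAULT_KEYWORDS) -> list[SequenceRecord]:
    """Keep records whose description contains >=1 keyword (whole word,
    case-insensitive). Mirrors the selection of 'unknown'/'orf'/'hypothetical'/
    'uncharacterized'/'putative' labelled entries."""
    pats = [re.compile(rf"\b{re.escape(k)}\b", re.IGNORECASE) for k in keywords]
    return [r for r in records if any(p.search(r.description) for p in pats)]


def cys_length_filter(record: SequenceRecord, min_cys: int = 2, min_len: int = 55):
    """Pass iff the record has >= min_cys cysteines and >= min_len residues.

    Returns ``(passed, reason)``; reason names the failing criterion (length is
    reported first when both fail).
    """
    if len(record) < min_len:
        return False, f"length {len(record)} < {min_len}"
    if record.n_cys < min_cys:
        return False, f"cysteines {record.n_cys} < {min_cys}"
    return True, None


def parse_homology_hits(path) -> list[HomologyHit]:
    """Parse a 12-column tab-separated homology hit file (outfmt-6 dialect:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore). A row with the wrong column count raises, naming the
    line number."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(cols)}"
                )
            hits.append(
                HomologyHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_similarity=float(cols[2]),
                    alignment_length=int(cols[3]),
                    evalue=float(cols[10]),
                )
            )
    return hits


def annotation_filter(
    record: SequenceRecord,
    hits: Sequence[HomologyHit],
    min_len: int = 50,
    max_eval: float = 0.0005,
    min_sim: float = 30.0,
):
    """Discard a candidate that is already structurally annotated.

    A record is discarded iff some hit has alignment length > ``min_len``,
    e-value <= ``max_eval`` and similarity > ``min_sim`` (all strict/inclusive
    as written). Returns ``(keep, triggering_hit)``.
    """
    for hit in hits:
        if (
            hit.alignment_length > min_len
            and hit.evalue <= max_eval
            and hit.percent_similarity > min_sim
        ):
            return False, hit
    return True, None


def consensus_signal_peptide(
    predA: SignalPeptidePrediction, predB: SignalPeptidePrediction
):
    """Combine two signal-peptide predictions into one consensus region.

    Both methods agree within 3 residues on the cleavage site -> high
    confidence, region ends at the smaller cleavage position (the conservative
    trim). Both predict but disagree by more -> medium. Exactly one predicts ->
    low. Neither -> None.
    """
    for p in (predA, predB):
        if p.has_sp and p.cleavage_pos <= 0:
            raise ValueError(f"cleavage_pos must be positive, got {p.cleavage_pos}")
    scores = tuple(
        (p.method or name, p.score)
        for name, p in (("A", predA), ("B", predB))
        if p.has_sp
    )
    if predA.has_sp and predB.has_sp:
        end = min(predA.cleavage_pos, predB.cleavage_pos)
        conf = "high" if abs(predA.cleavage_pos - predB.cleavage_pos) <= 3 else "medium"
        return Region(1, end, "signal_peptide", conf, scores)
    if predA.has_sp or predB.has_sp:
        end = predA.cleavage_pos if predA.has_sp else predB.cleavage_pos
        return Region(1, end, "signal_peptide", "low", scores)
    return None


def _merge_intervals(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def _tm_confidence(length: int) -> str:
    # 94% of TM helices are 17-25 residues long; band the consensus length.
    if 17 <= length <= 25:
        return "high"
    if 12 <= length < 17 or 25 < length <= 35:
        return "medium"
    return "low"


def consensus_transmembrane(predA, predB) -> list[Region]:
    """Intersect two methods' transmembrane interval lists into consensus
    regions; confidence follows the biologically expected helix length
    (17-25 residues high, 12-35 medium, otherwise low). Overlapping intervals
    within one prediction are merged first."""
    a = _merge_intervals(predA)
    b = _merge_intervals(predB)
    regions = []
    for sa, ea in a:
        for sb, eb in b:
            s, e = max(sa, sb), min(ea, eb)
            if s <= e:
                regions.append(
                    Region(s, e, "transmembrane", _tm_confidence(e - s + 1))
                )
    return regions


def removable(region: Region) -> bool:
    """Trimming policy: signal peptides only at high confidence; transmembrane
    segments at high or medium confidence."""
    if region.kind == "signal_peptide":
        return region.confidence == "high"
    return region.confidence in ("high", "medium")


def apply_region_removal(record: SequenceRecord, regions: Sequence[Region]):
    """Excise qualifying regions and keep the longest remaining segment.

    Regions are given in the record's local coordinates. Only regions passing
    the trimming policy (see :func:`removable`) are excised. After excision the
    longest remaining contiguous segment becomes the new record (ties broken
    toward the C-terminal segment, where the chemokine domain typically sits);
    ``parent_start`` and ``trim_log`` are updated in parent coordinates.
    """
    n = len(record)
    to_remove = []
    for reg in regions:
        if reg.end > n:
            raise ValueError(
                f"region [{reg.start},{reg.end}] outside sequence of length {n}"
            )
        if removable(reg):
            to_remove.append(reg)
    if not to_remove:
        return record

    removed_mask = [False] * n
    for reg in to_remove:
        for i in range(reg.start - 1, reg.end):
            removed_mask[i] = True

    # contiguous kept segments in local 1-based coordinates
    segments = []
    start = None
    for i in range(n):
        if not removed_mask[i]:
            if start is None:
                start = i + 1
        elif start is not None:
            segments.append((start, i))
            start = None
    if start is not None:
        segments.append((start, n))
    if not segments:
        raise ValueError(f"all residues of {record.id} removed by trimming")

    # longest segment; ties toward the C-terminal one
    best = max(segments, key=lambda seg: (seg[1] - seg[0], seg[0]))

    offset = record.parent_start - 1  # local -> parent shift
    new_log = list(record.trim_log)
    for reg in to_remove:
        new_log.append(replace(reg, start=reg.start + offset, end=reg.end + offset))
    for seg in segments:
        if seg != best:
            new_log.append(
                Region(seg[0] + offset, seg[1] + offset, "discarded_segment", "low")
            )
    return replace(
        record,
        residues=record.residues[best[0] - 1 : best[1]],
        parent_start=best[0] + offset,
        trim_log=new_log,
    )
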
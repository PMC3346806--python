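"""Hit classification and the staged candidate-selection logic.

A threading hit is high confidence (HC) only when the query plausibly covers
the whole template fold:

* fold coverage: 0.6 <= fl/pl <= 1.3 (inclusive),
* gaps: no alignment gap longer than 10 residues,
* secondary structure: every template SSE element is covered by the
  alignment (at most one unaligned position tolerated at each element edge).

The screen then runs in two stages mirroring a family-profile search followed
by a fold-space control: stage 3 keeps queries whose best HC chemokine hit
clears the calibrated Thx cutoff *and* supports at least one mappable
disulfide bond; stage 4 threads survivors against a redundancy-reduced
all-fold library, collapses hits to the best template per SCOP domain
(domains under 70% coverage dropped), and keeps queries whose chemokine
(d.9) domain ranks first or second among the top-20 high-confidence domains.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ckscreen.disulfide import DisulfideParams, map_disulfides
from ckscreen.foldlib import scop_domain_coverage, sse_elements
from ckscreen.seqio import cys_length_filter, keyword_filter, annotation_filter
from ckscreen.threading_engine import rank_templates, seed_for

__all__ = [
    "ScreenReport",
    "classify_hit",
    "chemokine_profile_screen",
    "take_top",
    "foldspace_screen",
    "run_pipeline",
]


@dataclass
class Decision:
    query_id: str
    stage: str
    verdict: str  # "kept" | "dropped"
    reason: str
    values: dict = field(default_factory=dict)


@dataclass
class ScreenReport:
    """Per-stage counts and per-query decisions with machine-readable reasons."""

    stage_counts: list = field(default_factory=list)  # (stage, n_in, n_out)
    decisions: list = field(default_factory=list)

    def add_stage(self, stage: str, n_in: int, n_out: int):
        if n_out > n_in:
            raise ValueError(f"stage {stage}: output {n_out} exceeds input {n_in}")
        self.stage_counts.append((stage, n_in, n_out))

    def record(self, query_id, stage, verdict, reason, **values):
        self.decisions.append(Decision(query_id, stage, verdict, reason, values))

    def counts_monotone(self) -> bool:
        outs = [n_out for _, _, n_out in self.stage_counts]
        ins = [n_in for _, n_in, _ in self.stage_counts]
        return all(o <= i for i, o in zip(ins, outs)) and all(
            ins[k + 1] <= outs[k] for k in range(len(outs) - 1)
        )

    def to_dict(self) -> dict:
        return {
            "stage_counts": [
                {"stage": s, "in": i, "out": o} for s, i, o in self.stage_counts
            ],
            "decisions": [
                {
                    "query": d.query_id,
                    "stage": d.stage,
                    "verdict": d.verdict,
                    "reason": d.reason,
                    "values": d.values,
                }
                for d in self.decisions
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def write(self, path):
        Path(path).write_text(self.to_json(indent=2))


def classify_hit(hit, ratio_lo: float = 0.6, ratio_hi: float = 1.3,
                 max_gap: int = 10, edge_slack: int = 1):
    """Set the HC/FP confidence flags on a threading hit (returns the hit).

    ``fcov_ok``: ratio_lo <= fl/pl <= ratio_hi, inclusive. ``gap_ok``: no gap
    run longer than ``max_gap``. ``sse_covered``: every template SSE element
    (length >= 3) fully aligned, allowing ``edge_slack`` unaligned positions
    at each element edge.
    """
    aln = hit.alignment
    if aln.pl == 0:
        raise ValueError("alignment has no aligned pairs")
    ratio = aln.fl / aln.pl
    hit.fcov_ok = ratio_lo <= ratio <= ratio_hi
    hit.gap_ok = all(length <= max_gap for length, _ in aln.gaps)

    aligned = {tp for _, tp in aln.pairs}
    tpl = hit.template
    covered = True
    for label, start, end in sse_elements(tpl, min_length=3):
        required = [
            p for p in range(start + edge_slack, end - edge_slack + 1)
            if tpl.resolved[p]
        ]
        if any(p not in aligned for p in required):
            covered = False
            break
    hit.sse_covered = covered
    hit.confidence = "HC" if (hit.fcov_ok and hit.gap_ok and hit.sse_covered) else "FP"
    return hit


@dataclass
class ProfileScreenResult:
    passed: bool
    reason: str
    best_hit: Optional[object] = None
    disulfide_map: Optional[object] = None

    @property
    def thx(self):
        return self.best_hit.alignment.thx if self.best_hit else None


def chemokine_profile_screen(
    query,
    chemokine_library,
    potentials,
    thx_cutoff: float,
    min_bonds: int = 1,
    seed: int = 0,
    n_shuffles: int = 100,
    disulfide_params: DisulfideParams = DisulfideParams(),
) -> ProfileScreenResult:
    """Stage-3 decision: best HC chemokine hit above the calibrated Thx cutoff
    and a disulfide map with at least ``min_bonds`` mappable bonds."""
    if len(chemokine_library) == 0:
        raise ValueError("empty chemokine library")
    seq = getattr(query, "residues", query)
    hits = rank_templates(seq, chemokine_library, potentials,
                          seed=seed, n_shuffles=n_shuffles)
    for hit in hits:
        classify_hit(hit)
    hc = [h for h in hits if h.confidence == "HC"]
    if not hc:
        return ProfileScreenResult(False, "no high-confidence chemokine hit")
    best = hc[0]
    if best.alignment.thx < thx_cutoff:
        return ProfileScreenResult(
            False, f"Thx {best.alignment.thx:.2f} below cutoff {thx_cutoff:.2f}",
            best_hit=best,
        )
    dmap = map_disulfides(seq, best.template, best.alignment, disulfide_params)
    if dmap.bond_count < min_bonds:
        return ProfileScreenResult(
            False, f"only {dmap.bond_count} mappable disulfide bonds "
                   f"(minimum {min_bonds})",
            best_hit=best, disulfide_map=dmap,
        )
    return ProfileScreenResult(True, "pass", best_hit=best, disulfide_map=dmap)


def take_top(scored_queries, n: int = 70, key=None):
    """Top ``n`` queries by score (default: best Thx), deterministic tie-break
    by query id. ``scored_queries`` maps record -> score or is a list of
    (record, score)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if isinstance(scored_queries, dict):
        items = list(scored_queries.items())
    elif key is not None:
        items = [(rec, key(rec)) for rec in scored_queries]
    else:
        items = list(scored_queries)
    items.sort(key=lambda rs: (-rs[1], getattr(rs[0], "id", str(rs[0]))))
    return [rec for rec, _ in items[:n]]


@dataclass
class FoldspaceScreenResult:
    passed: bool
    reason: str
    domain_ranking: list = field(default_factory=list)
    # (rank, scop_family, hit) over collapsed HC domains

    @property
    def chemokine_rank(self):
        for rank, family, _ in self.domain_ranking:
            if family.startswith("d.9"):
                return rank
        return None


def foldspace_screen(
    query,
    foldspace_library,
    potentials,
    min_cov: float = 70.0,
    top_domains: int = 20,
    max_ck_rank: int = 2,
    seed: int = 0,
    n_shuffles: int = 100,
    fold_prefix: str = "d.9",
) -> FoldspaceScreenResult:
    """Stage-4 control: rank all folds, collapse to the best hit per SCOP
    domain (coverage >= ``min_cov``), and pass iff a chemokine-fold domain is
    ranked 1 or 2 among the top ``top_domains`` high-confidence domains."""
    seq = getattr(query, "residues", query)
    hits = rank_templates(seq, foldspace_library, potentials,
                          seed=seed, n_shuffles=n_shuffles)
    best_per_domain = {}
    for hit in hits:
        classify_hit(hit)
        for family, start, end in hit.template.scop_domains:
            cov = scop_domain_coverage(hit.alignment.pairs, (start, end))
            hit.domain_coverage[family] = cov
            if cov < min_cov:
                continue
            prev = best_per_domain.get(family)
            if prev is None or hit.alignment.thx > prev.alignment.thx:
                best_per_domain[family] = hit
    ranked = sorted(
        best_per_domain.items(),
        key=lambda kv: (-kv[1].alignment.thx, kv[0]),
    )
    hc_ranked = [
        (family, hit) for family, hit in ranked if hit.confidence == "HC"
    ][:top_domains]
    ranking = [(r, family, hit) for r, (family, hit) in enumerate(hc_ranked, start=1)]
    if not ranking:
        return FoldspaceScreenResult(False, "no high-confidence hits", ranking)
    for rank, family, _ in ranking:
        if family.startswith(fold_prefix) and rank <= max_ck_rank:
            return FoldspaceScreenResult(True, f"chemokine domain at rank {rank}",
                                         ranking)
    result = FoldspaceScreenResult(False, "chemokine domain not in top ranks",
                                   ranking)
    ck = result.chemokine_rank
    if ck is not None:
        result.reason = f"chemokine domain at rank {ck} > {max_ck_rank}"
    return result


def run_pipeline(config) -> ScreenReport:
    """Execute the four automated screening stages on a configured cohort.

    ``config`` is a :class:`ckscreen.config.RunConfig` (or any object with the
    same attributes) whose input records, predictor outputs, homology hits and
    libraries have been loaded. Produces a :class:`ScreenReport` and, when an
    output directory is configured, per-stage survivor FASTA files.
    """
    from ckscreen.seqio import (
        apply_region_removal, consensus_signal_peptide, consensus_transmembrane,
        write_fasta,
    )

    report = ScreenReport()
    records = list(config.records)
    out_dir = Path(config.output_dir) if getattr(config, "output_dir", None) else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # Stage 1: keyword selection + initial cysteine requirement
    n_in = len(records)
    selected = keyword_filter(records, config.keywords)
    stage1 = []
    for rec in selected:
        if rec.n_cys >= config.min_cys:
            stage1.append(rec)
            report.record(rec.id, "1_extraction", "kept", "keyword+cysteine")
        else:
            report.record(rec.id, "1_extraction", "dropped",
                          f"cysteines {rec.n_cys} < {config.min_cys}")
    for rec in records:
        if rec not in selected:
            report.record(rec.id, "1_extraction", "dropped", "no keyword match")
    report.add_stage("1_extraction", n_in, len(stage1))

    # Stage 2: annotation check, SP/TM trimming, cysteine/length re-check
    stage2 = []
    for rec in stage1:
        keep, hit = annotation_filter(
            rec, config.homology_hits.get(rec.id, []),
            min_len=config.annot_min_len, max_eval=config.annot_max_eval,
            min_sim=config.annot_min_sim,
        )
        if not keep:
            report.record(rec.id, "2_prefilter", "dropped",
                          "structurally annotated",
                          subject=hit.subject_id, evalue=hit.evalue)
            continue
        regions = []
        sp = config.sp_predictions.get(rec.id)
        if sp:
            reg = consensus_signal_peptide(*sp)
            if reg:
                regions.append(reg)
        tm = config.tm_predictions.get(rec.id)
        if tm:
            regions.extend(consensus_transmembrane(*tm))
        trimmed = apply_region_removal(rec, regions) if regions else rec
        ok, reason = cys_length_filter(trimmed, config.min_cys, config.min_len)
        if not ok:
            report.record(rec.id, "2_prefilter", "dropped", reason)
            continue
        report.record(rec.id, "2_prefilter", "kept", "pass")
        stage2.append(trimmed)
    report.add_stage("2_prefilter", len(stage1), len(stage2))
    if out_dir:
        write_fasta(stage2, out_dir / "stage2_survivors.fasta")

    # Stage 3: chemokine 3D family profile
    stage3 = []
    scores = []
    for rec in stage2:
        res = chemokine_profile_screen(
            rec, config.chemokine_library, config.potentials,
            thx_cutoff=config.thx_cutoff, min_bonds=config.min_bonds,
            seed=seed_for(config.seed, "profile", rec.id),
            n_shuffles=config.n_shuffles,
            disulfide_params=config.disulfide_params,
        )
        if res.passed:
            report.record(rec.id, "3_profile", "kept", "pass",
                          thx=res.thx, diS=res.disulfide_map.bond_count)
            stage3.append(rec)
            scores.append((rec, res.thx))
        else:
            report.record(rec.id, "3_profile", "dropped", res.reason)
    report.add_stage("3_profile", len(stage2), len(stage3))
    if out_dir:
        write_fasta(stage3, out_dir / "stage3_survivors.fasta")

    # top-n cut before the fold-space control
    top = take_top(scores, n=config.top_n)
    report.add_stage("3b_top_n", len(stage3), len(top))

    # Stage 4: fold-space control
    stage4 = []
    for rec in top:
        res = foldspace_screen(
            rec, config.foldspace_library, config.potentials,
            min_cov=config.min_cov, top_domains=config.top_domains,
            max_ck_rank=config.max_ck_rank,
            seed=seed_for(config.seed, "foldspace", rec.id),
            n_shuffles=config.n_shuffles,
        )
        if res.passed:
            report.record(rec.id, "4_foldspace", "kept", res.reason,
                          ck_rank=res.chemokine_rank)
            stage4.append(rec)
        else:
            report.record(rec.id, "4_foldspace", "dropped", res.reason)
    report.add_stage("4_foldspace", len(top), len(stage4))
    if out_dir:
        write_fasta(stage4, out_dir / "stage4_survivors.fasta")
        report.write(out_dir / "screen_report.json")
    return report
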
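"""Run configuration: every screening threshold in one place.

Defaults are the screen's canonical operating point: candidate selection
needs >= 2 cysteines and >= 55 residues; the structural-annotation check
discards BLAST hits longer than 50 residues at e-value <= 5e-4 and
similarity > 30%; high-confidence threading requires 0.6 <= fl/pl <= 1.3,
no gap over 10 residues and full SSE coverage; the fold-space control keeps
SCOP domains at >= 70% coverage, considers the top 20 and demands the
chemokine fold at rank 1-2; disulfide feasibility uses d_Cα <= 10 Å,
d_Cβ <= 9 Å, d_Cβ - d_Cα <= 1 Å and sequence separation >= 3.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import yaml

from ckscreen.disulfide import DisulfideParams
from ckscreen.seqio import DEFAULT_KEYWORDS

__all__ = ["RunConfig"]

_THRESHOLD_FIELDS = (
    "min_cys", "min_len", "annot_min_len", "annot_max_eval", "annot_min_sim",
    "ratio_lo", "ratio_hi", "max_gap", "min_cov", "top_domains", "max_ck_rank",
    "thx_cutoff", "min_bonds", "top_n", "n_shuffles", "seed",
)


@dataclass
class RunConfig:
    # inputs (in-memory objects; the CLI populates them from files)
    records: list = field(default_factory=list)
    homology_hits: dict = field(default_factory=dict)   # query_id -> [HomologyHit]
    sp_predictions: dict = field(default_factory=dict)  # query_id -> (predA, predB)
    tm_predictions: dict = field(default_factory=dict)  # query_id -> (intervalsA, intervalsB)
    chemokine_library: object = None
    foldspace_library: object = None
    potentials: object = None
    output_dir: str = ""

    # thresholds (defaults = the screen's canonical operating point)
    keywords: frozenset = DEFAULT_KEYWORDS
    min_cys: int = 2
    min_len: int = 55
    annot_min_len: int = 50
    annot_max_eval: float = 0.0005
    annot_min_sim: float = 30.0
    ratio_lo: float = 0.6
    ratio_hi: float = 1.3
    max_gap: int = 10
    min_cov: float = 70.0
    top_domains: int = 20
    max_ck_rank: int = 2
    thx_cutoff: float = 0.0     # re-derived by calibration per library
    min_bonds: int = 1
    top_n: int = 70
    disulfide_params: DisulfideParams = field(default_factory=DisulfideParams)
    n_shuffles: int = 100
    seed: int = 0

    def thresholds(self) -> dict:
        d = {k: getattr(self, k) for k in _THRESHOLD_FIELDS}
        d["keywords"] = sorted(self.keywords)
        d["disulfide"] = asdict(self.disulfide_params)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.thresholds(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        cfg = cls()
        ds = data.pop("disulfide", None)
        if ds:
            cfg.disulfide_params = DisulfideParams(**ds)
        kw = data.pop("keywords", None)
        if kw:
            cfg.keywords = frozenset(kw)
        for k, v in data.items():
            if k not in _THRESHOLD_FIELDS:
                raise ValueError(f"unknown configuration field {k!r}")
            setattr(cfg, k, v)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def provenance_header(self, stage: str) -> str:
        return (f"# ckscreen stage={stage} config={self.config_hash()} "
                f"seed={self.seed}\n")

    def validate(self):
        errors = []
        if self.min_cys < 1:
            errors.append("min_cys must be >= 1")
        if self.min_len < 1:
            errors.append("min_len must be >= 1")
        if not (0 < self.ratio_lo <= self.ratio_hi):
            errors.append("require 0 < ratio_lo <= ratio_hi")
        if self.top_n <= 0:
            errors.append("top_n must be positive")
        if self.max_ck_rank < 1:
            errors.append("max_ck_rank must be >= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
        return self
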
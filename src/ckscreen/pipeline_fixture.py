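"""Assemble a complete synthetic screening run (cohort + libraries + cutoff).

This is the standard harness for end-to-end runs without downloads: a decoy
cohort with planted homologs of the chemokine fixture fold, a two-template
chemokine library, the mixed toy fold-space library, potentials trained on
the fold-space templates, and a Thx cutoff calibrated on a designated remote
homolog (mutated to 30% identity — deliberately more remote than the 40%
homologs the screen is expected to recover, mirroring how a family cutoff is
anchored at the most remote confirmed member).
"""

from __future__ import annotations

from ckscreen.config import RunConfig
from ckscreen.foldlib import FoldLibrary
from ckscreen.fixtures import (
    make_chemokine_fixture, make_decoy_cohort, make_homolog, make_toy_foldspace,
)
from ckscreen.seqio import SequenceRecord
from ckscreen.threading_engine import calibrate_cutoff, derive_potentials, seed_for

__all__ = ["build_fixture_config", "homolog_record"]

CALIBRATION_IDENTITY = 30.0
HOMOLOG_IDENTITY = 40.0


def homolog_record(template, identity: float, seed: int, tag: str) -> SequenceRecord:
    seq = make_homolog(template, identity, preserve_cys=True, seed=seed)
    return SequenceRecord(
        id=f"tr|H{tag}|H{tag}_HUMAN",
        residues=seq,
        accession=f"H{tag}",
        description="Uncharacterized protein (hypothetical)",
    )


def build_fixture_config(cfg: RunConfig = None, n_decoys: int = 100,
                         n_homologs: int = 5,
                         homolog_identity: float = HOMOLOG_IDENTITY) -> RunConfig:
    """Populate ``cfg`` (or a default RunConfig) with the synthetic study:
    libraries, potentials, calibrated cutoff, and a cohort of decoys plus
    planted chemokine-fold homologs."""
    cfg = cfg or RunConfig()
    seed = cfg.seed

    foldspace, scop_map = make_toy_foldspace(seed=seed_for(seed, "foldspace"))
    ck_templates = [
        t for t in foldspace
        if any(fam.startswith("d.9") for fam, _, _ in t.scop_domains)
    ]
    # a second, independently generated chemokine-fold template for the
    # family library (same architecture, different seed/sequence)
    ck2 = make_chemokine_fixture(seed=seed_for(seed, "ck2"), name="ckfy")
    chemokine_library = FoldLibrary(
        name="toy_chemokine", kind="chemokine",
        templates=ck_templates + [ck2],
        provenance={"synthetic": True},
    )
    potentials = derive_potentials(list(foldspace))

    records, sp_preds, tm_preds, hom_hits = make_decoy_cohort(
        n_decoys, seed=seed_for(seed, "decoys"),
    )
    ck_parent = ck_templates[0]
    for k in range(n_homologs):
        records.append(
            homolog_record(ck_parent, homolog_identity,
                           seed=seed_for(seed, "homolog", k), tag=f"{k:04d}")
        )

    calibrant = homolog_record(ck_parent, CALIBRATION_IDENTITY,
                               seed=seed_for(seed, "calibrant"), tag="CAL0")
    cutoff = calibrate_cutoff(
        calibrant.residues, chemokine_library, potentials,
        seed=seed_for(seed, "calibration"), n_shuffles=cfg.n_shuffles,
    )

    cfg.records = records
    cfg.homology_hits = hom_hits
    cfg.sp_predictions = sp_preds
    cfg.tm_predictions = tm_preds
    cfg.chemokine_library = chemokine_library
    cfg.foldspace_library = foldspace
    cfg.potentials = potentials
    cfg.thx_cutoff = cutoff
    return cfg
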
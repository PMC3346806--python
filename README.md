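# ckscreen

Proteome-scale screening for **remote structural homologs of the IL8-like
chemokine fold** (SCOP fold d.9): three antiparallel β-strands packed against
a C-terminal α-helix, stabilized by intramolecular disulfide bonds.

Chemokines are small secreted immune-signalling proteins. New family members
keep being missed by sequence-based annotation because remote homologs can
share the fold while showing almost no sequence similarity and carrying
non-canonical cysteine patterns. `ckscreen` finds such candidates with a 3D
family profile: fold-recognition (threading) scoring combined with an
automatic, scaffold-based test of whether a candidate's cysteines could form
disulfide bonds in the template geometry.

## The method

Candidates flow through four automated stages:

1. **Extraction** — uncharacterized entries (description keywords such as
   *hypothetical*, *uncharacterized*, *putative*) with ≥ 2 cysteines.
2. **Pre-filtering** — discard sequences already structurally annotated
   (homology hit vs. the PDB with alignment length > 50, e-value ≤ 5·10⁻⁴ and
   similarity > 30%); trim consensus signal peptides (high confidence) and
   transmembrane segments (high/medium confidence); re-require ≥ 2 cysteines
   and ≥ 55 residues.
3. **Family-profile screen** — thread each candidate against a chemokine-fold
   template library and rank by the threading index

   `Thx = 100 · (z_pair + z_surf + S_seq) / L_query`

   where `z_pair` and `z_surf` are shuffle z-scores of the knowledge-based
   residue–residue and burial energies of the alignment and `S_seq` is a
   substitution-matrix similarity. A hit is **high confidence (HC)** only if
   it covers the whole template fold: `0.6 ≤ fl/pl ≤ 1.3` (template fold
   length over alignment path length), no alignment gap over 10 residues,
   and every secondary-structure element covered. A candidate passes if its
   best HC hit clears a family cutoff calibrated on a designated remote
   homolog *and* at least one disulfide bond is mappable onto the scaffold:
   a query cysteine pair is bond-capable when, at the aligned template
   positions, `d(Cα,Cα) ≤ 10 Å`, `d(Cβ,Cβ) ≤ 9 Å`,
   `d(Cβ,Cβ) − d(Cα,Cα) ≤ 1 Å`, and the cysteines are ≥ 3 residues apart;
   the number of bonds (diS) is a maximum disjoint pairing of capable pairs.
4. **Fold-space control** — thread survivors against a redundancy-reduced
   all-fold library; collapse hits to the best template per SCOP domain
   (domains < 70% covered are dropped) and keep a candidate only if a
   chemokine (d.9) domain ranks 1st or 2nd among the top-20 HC domains.

Supporting analyses: per-residue contact energies and their R² against a
reference structure over a rigid-body structural correspondence, secondary
structure fractions, disulfide-corrected monoisotopic masses with isotope
envelopes (each bond removes two hydrogens, −2.0156501 Da), and chemokine
motif scanning (GAG attachment, RGD, N-glycosylation sequons).

## Worked example

Sequence-level features of a candidate:

```python
from ckscreen.features import monoisotopic_mass, scan_motifs, cysteine_stats

seq = "MKVLACLLPSGACDSFRSGGAQNVTKECAARGDVLQCEW"
st = cysteine_stats(seq)
print("cysteines:", st.count, "at", st.positions)
for h in scan_motifs(seq):
    print(f"motif {h.name}: {h.matched} at {h.start}-{h.end}")
for n in (0, 1, 2):
    print(f"monoisotopic mass with {n} disulfide bond(s): "
          f"{monoisotopic_mass(seq, n).mass:.4f} Da")
```

```
cysteines: 4 at (6, 13, 28, 37)
motif GAG_attachment: SGA at 10-12
motif GAG_attachment: RSGG at 17-20
motif N_glycosylation: NVT at 23-25
motif RGD: RGD at 31-33
monoisotopic mass with 0 disulfide bond(s): 4112.9363 Da
monoisotopic mass with 1 disulfide bond(s): 4110.9206 Da
monoisotopic mass with 2 disulfide bond(s): 4108.9050 Da
```

The four cysteines could support up to two disulfide bonds; each formed bond
lowers the monoisotopic mass by exactly 2 × 1.0078250 Da, which is how a
measured deconvoluted mass counts the bonds actually formed. The GAG
(glycosaminoglycan) attachment and RGD hits are the sequence features that
commonly corroborate a chemokine-like annotation.

A full synthetic screen from the shell (10 decoys plus 2 planted
chemokine-fold homologs at 40% identity):

```bash
ckscreen run-all --n-decoys 10 --n-homologs 2 --seed 5 --out-dir run
```

```
1_extraction: 12 -> 12
2_prefilter: 12 -> 9
3_profile: 9 -> 2
3b_top_n: 2 -> 2
4_foldspace: 2 -> 2
report hash 3735f8b61454f02d5a37208a1c617901f746f319a4e3c13526a23a543cdab4c0
```

The two stage-4 survivors are exactly the two planted homologs: the profile
stage rejects all decoys (sub-cutoff Thx or no mappable disulfide) and the
fold-space control confirms the survivors prefer the chemokine fold over all
other architectures in the library. The report hash is stable under rerun
with the same seed. Per-stage survivor FASTA files and a JSON
`screen_report.json` with machine-readable decisions land in `run/`.

## Layout

- `ckscreen.seqio` — FASTA I/O, keyword/cysteine/length filters, annotation
  check, consensus signal-peptide and transmembrane trimming
- `ckscreen.foldlib` — PDB/mmCIF chain parsing, virtual Cβ, secondary
  structure assignment, chemokine and fold-space libraries, SCOP coverage
- `ckscreen.threading_engine` — knowledge-based potentials, frozen-approximation
  alignment, shuffle z-scores, Thx, ranking, cutoff calibration
- `ckscreen.disulfide` — scaffold-based disulfide mapping and bond counting
- `ckscreen.screening` — HC/FP classification, the two screening stages,
  the four-stage pipeline
- `ckscreen.evaluation` — contact-energy profiles, superposition, R²,
  secondary-structure fractions
- `ckscreen.features` — masses, isotope envelopes, motifs, cysteine stats
- `ckscreen.fixtures` / `ckscreen.pipeline_fixture` — seeded synthetic
  templates, homologs and decoy cohorts
- `ckscreen.cli` — `ckscreen` command-line entry point
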
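# External worked-example inputs

The worked-example checks in `tests/test_acceptance.py::TestWorkedExample`
and the corresponding entries in `scripts/acceptance.py` evaluate two real
uncharacterized human proteins and one real chemokine template. These inputs
are not redistributed with the package; place them here to enable those
checks:

| file           | content                                  | source                                            |
|----------------|------------------------------------------|---------------------------------------------------|
| `Q1T7F1.fasta` | UniProt entry Q1T7F1 (B42, 81 aa)         | https://rest.uniprot.org/uniprotkb/Q1T7F1.fasta   |
| `Q71RG6.fasta` | UniProt entry Q71RG6 (N73, 208 aa)        | https://rest.uniprot.org/uniprotkb/Q71RG6.fasta   |
| `1ZXT.pdb`     | PDB entry 1ZXT (vMIP-I, X-ray, 1.7 Å)     | https://files.rcsb.org/download/1ZXT.pdb          |

Without these files the worked-example checks fail with a message pointing
here; all synthetic-fixture checks are independent of them.
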
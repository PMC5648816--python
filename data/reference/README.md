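# Reference inputs (not redistributed)

The tests in `tests/test_acceptance.py::TestPublishedData` validate the
pipeline against published MycG / CYP101A1 data.  Those inputs are not
bundled; place them here to run the checks:

| file                  | content                                                          | source |
|-----------------------|------------------------------------------------------------------|--------|
| `mycg_bound_5uhu.pdb` | M-IV-bound MycG solution structure (first model)                 | PDB 5UHU |
| `mycg_free_rep2.pdb`  | substrate-free MycG representative conformer REP2, solvent removed | journal supplement |
| `cyp101a1_2l8m.pdb`   | camphor-bound CYP101A1 solution structure (first model)          | PDB 2L8M |
| `rdcs_pf1.tbl`        | refined pf1 RDC list, reformatted to `medium residue atom_pair observed_hz` | journal supplement |
| `rdcs_c12e5.tbl`      | refined C12E5 RDC list, same format                              | journal supplement |
| `violations.tbl`      | persistently violating records, same format                      | journal supplement |
| `correspondence.tsv`  | CYP101A1/MycG residue pairs from the published structural alignment | derived from the alignment figure |
| `cyp101a1.fasta`      | CYP101A1 (P450cam) sequence                                      | UniProt P00183 |
| `mycg.fasta`          | MycG sequence                                                    | UniProt |

Without these files the corresponding tests fail with a message naming the
missing input; all other tests are self-contained.
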
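# External reference inputs (not redistributed)

The repeat-scanner reproduction (acceptance criterion on the two reference
proteins) needs inputs that cannot be shipped with this repository and are
not reachable from an offline environment:

- `Q9C0D5.fasta` — canonical TANC1 sequence (UniProt, 1,861 residues)
- `Q9HCD6.fasta` — canonical TANC2 sequence (UniProt, 1,990 residues)
- `regions.tsv`  — annotated repeat-domain boundaries, columns
  `accession  region  start  end` with `ANK` and `TPR` rows for `Q9C0D5`
  (e.g. from an InterProScan run or UniProt feature annotations)

Fetch them with network access, e.g.:

    curl -o Q9C0D5.fasta https://rest.uniprot.org/uniprotkb/Q9C0D5.fasta
    curl -o Q9HCD6.fasta https://rest.uniprot.org/uniprotkb/Q9HCD6.fasta

With these files in place, `tests/test_acceptance.py::TestCriterion2RepeatReproduction`
runs against the real records and `scripts/acceptance.py` reports the `t12`
sequence-length target.
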
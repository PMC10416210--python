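# External inputs (not redistributed)

The acceptance checks that reproduce printed metrics of the deposited
triangular-origami crystal structure read the following files from this
directory. They are not shipped with the package and must be obtained from
the PDB / the publication's supplementary material:

- `8P4Y.cif` (or `8P4Y.pdb`) — the deposited entry, e.g.
  `https://files.rcsb.org/download/8P4Y.cif`
- `8P4Y_segments.yaml` — residue ranges of the six CC segments (P1, GCN-a,
  P4, P2, GCN-b, P3) and their dimer pairing, curated from the deposited
  coordinates. Schema:

  ```yaml
  segments:
    P1:    {chain: A, first: <n>, last: <n>, cc_name: P1,  heptad_start: a}
    GCN-a: {chain: A, first: <n>, last: <n>, cc_name: GCN, heptad_start: a}
    # ... P4, P2, GCN-b, P3
  dimers:
    - [P1, P2, parallel]
    - [P3, P4, parallel]
    - [GCN-a, GCN-b, parallel]
  ```

  Known anchors from the published description: P1 contains residues 11,
  23, 26 and 30; P4 contains 69, 73, 91 and 95; the GSG linker at 99–101
  precedes P2 (Ser100/Gly101 join the P2 helix); the second GCN segment
  contains 149, 150 and 158.

- `tri4shbgcn.fasta` — the full designed chain sequence (published in the
  supplementary material of the source study).

Without these files the corresponding tests in `tests/test_acceptance.py`
fail with a message pointing here; all other tests are self-contained.
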
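# Deposited coordinate files

The regression tests and analyses that run against the deposited FtsA
crystal structures expect the public mmCIF files here, lower-case:

    data/accessions/7q6f.cif   # VmFtsA 1-396 double filament
    data/accessions/7q6i.cif   # VmFtsA 1-396 / VmFtsN 1-29 co-crystal

Download them from the public PDB archive (e.g.
`https://files.rcsb.org/download/7Q6F.cif`).  They are not redistributed
with the package; without them the corresponding tests fail with a
message pointing here, and the synthetic-data suite runs unaffected.
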
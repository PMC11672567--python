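# Down-sampled crystal structure fixtures

This directory holds plain-text, per-chain atom CSVs for the deposited Fab
crystal structures (PDB 6FOE, imalumab/BaxB01; PDB 9FQO, C0083), trimmed to
the variable domains, plus Kabat numbering maps. They are produced by

    python scripts/fetch_structures.py

which requires network access to RCSB and is run once; nothing in the
library or the default test run downloads anything. The integration tests
that compare computed SASA/hydrophobicity values against the deposited
entries fail with an explanatory message until these files exist.
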
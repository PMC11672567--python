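"""Fetch the deposited Fab crystal structures and down-sample them to Fv fixtures.

Downloads PDB entries 6FOE (imalumab/BaxB01 Fab, two copies in the
asymmetric unit) and 9FQO (C0083 Fab) from RCSB, trims each chain to the
variable domain plus a short pad, and writes:

* one compact atom CSV per chain under data/structures/ (plain text,
  coordinates to 0.01 Å) loadable with
  :func:`abdev.structure.read_compact_chain_csv`;
* a Kabat numbering map CSV per entry (the deposits use Kabat author
  numbering, which the script verifies against sequence anchors before
  writing).

Run once, from the repository root, with network access:

    python scripts/fetch_structures.py

The library and the default test run never download anything themselves;
only the integration tests against the deposited entries consume these
files.
"""

from __future__ import annotations

import sys
import tempfile
import urllib.request
from pathlib import Path

import pandas as pd

from abdev.structure import kabat_region, read_structure, write_compact_chain_csv

OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "structures"

# chain roles and residue ranges kept (variable domain + pad for burial context)
ENTRIES = {
    "6foe": {
        "heavy": ["A", "H"],
        "light": ["B", "L"],
        # sequence anchors in Kabat author numbering: (chain, resnum, one-letter)
        "anchors": [("H", 97, "W"), ("L", 93, "W"), ("L", 30, "M"), ("H", 99, "Y")],
    },
    "9fqo": {
        "heavy": ["A", "H"],
        "light": ["B", "L"],
        "anchors": [("H", 97, "Y"), ("L", 93, "F"), ("H", 99, "Y"), ("L", 49, "Y")],
    },
}
KEEP_MAX = {"heavy": 122, "light": 112}


def fetch(entry: str) -> Path:
    url = f"https://files.rcsb.org/download/{entry.upper()}.pdb"
    dest = Path(tempfile.gettempdir()) / f"{entry}.pdb"
    print(f"downloading {url}")
    urllib.request.urlretrieve(url, dest)
    return dest


def process(entry: str, spec: dict) -> None:
    pdb_path = fetch(entry)
    st = read_structure(pdb_path, drop_waters=True, drop_hetero=True, drop_hydrogens=True)
    roles: dict[str, str] = {}
    for role in ("heavy", "light"):
        for cid in spec[role]:
            if cid in st.chain_ids():
                roles[cid] = role
    if not roles:
        sys.exit(f"{entry}: none of the expected chains {spec['heavy'] + spec['light']} "
                 f"found (file has {st.chain_ids()}); adjust ENTRIES")

    for chain_id, resnum, aa in spec["anchors"]:
        if chain_id not in roles:
            continue
        found = None
        for res in st.chain(chain_id):
            if res.key.seq_number == resnum and not res.key.insertion_code:
                found = res.key.aa
                break
        if found != aa:
            sys.exit(f"{entry}: anchor {chain_id}:{resnum} expected {aa}, found {found}; "
                     "the deposit does not use the expected Kabat author numbering")

    OUT_DIR.mkdir(parents=True, exist_ok=True)
    numbering_rows = []
    for chain_id, role in roles.items():
        chain = st.chain(chain_id)
        chain.residues = [r for r in chain.residues if r.key.seq_number <= KEEP_MAX[role]]
        out = OUT_DIR / f"{entry}_{chain_id}.csv"
        write_compact_chain_csv(st, chain_id, out)
        print(f"wrote {out} ({len(chain.residues)} residues)")
        prefix = "H" if role == "heavy" else "L"
        for res in chain.residues:
            num, icode = res.key.seq_number, res.key.insertion_code
            numbering_rows.append({
                "chain": chain_id, "resnum": num, "icode": icode, "aa": res.key.aa,
                "scheme_label": f"{chain_id}:{prefix}{num}{icode}",
                "region": kabat_region(role, num),
            })
    map_path = OUT_DIR / f"{entry}_numbering.csv"
    pd.DataFrame(numbering_rows).to_csv(map_path, index=False)
    print(f"wrote {map_path}")


def main() -> None:
    for entry, spec in ENTRIES.items():
        process(entry, spec)
    print("done; integration tests against the deposited entries are now enabled")


if __name__ == "__main__":
    main()
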
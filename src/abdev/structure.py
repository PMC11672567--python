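"""Atomic structure model for antibody developability analysis.

A deliberately small hierarchy — chains of residues of atoms — carrying
exactly what the downstream stages need: coordinates, elements, van der
Waals radii, occupancies and B-factors, plus optional antibody numbering
(scheme label such as ``H97`` and a CDR/framework region label).

Parsing of PDB and mmCIF files is delegated to :mod:`gemmi`; writing uses
our own fixed-width PDB emitter so that synthetic fixtures and round-trips
are format-conformant and byte-stable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "Residue",
    "Chain",
    "AtomicStructure",
    "NumberingMap",
    "StructureError",
    "read_structure",
    "write_pdb",
    "extract_chain_sequence",
    "apply_numbering",
    "load_numbering_csv",
    "kabat_region",
    "vdw_radius_for_element",
    "REGION_VOCABULARY",
]

REGION_VOCABULARY = frozenset(
    {"FR1", "FR2", "FR3", "FR4", "CDR1", "CDR2", "CDR3", "constant", "other"}
)

WATER_NAMES = frozenset({"HOH", "WAT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for unparseable files, empty structures, or lookup failures."""


def _load_data(name: str) -> dict:
    with resources.files("abdev.data").joinpath(name).open() as fh:
        return json.load(fh)


_VDW = _load_data("vdw_radii.json")
_KABAT = _load_data("kabat_regions.json")
_ALIASES = _load_data("modified_residues.json")["aliases"]


def vdw_radius_for_element(element: str, name: str = "", default: float | None = None) -> float:
    """Van der Waals radius (Å) for an element symbol.

    Unknown symbols fall back to name-based inference (first letter of the
    atom name that is alphabetic) and finally to the configured default.
    """
    radii = _VDW["radii"]
    sym = element.strip().upper()
    if sym in radii:
        return radii[sym]
    for ch in name.strip():
        if ch.isalpha():
            if ch.upper() in radii:
                return radii[ch.upper()]
            break
    return default if default is not None else _VDW["default"]


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray          # shape (3,), Å
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    vdw_radius: float = 0.0     # Å, assigned at read/build time

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue: chain, author sequence number, insertion code, one-letter aa."""
    chain_id: str
    seq_number: int
    insertion_code: str = ""
    aa: str = "X"

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.aa}{self.seq_number}{self.insertion_code}"


@dataclass
class Residue:
    key: ResidueKey
    name: str                   # 3-letter PDB residue name
    atoms: list[AtomRecord] = field(default_factory=list)
    scheme_label: str | None = None   # e.g. Kabat "H97"
    region: str = "other"
    is_hetero: bool = False

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def atom(self, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.key}: no atom named {name!r}")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class AtomicStructure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    source_format: str = "PDB"

    # -- traversal ---------------------------------------------------------
    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def iter_residues(self) -> Iterator[Residue]:
        for chain in self.chains:
            yield from chain.residues

    def iter_atoms(self) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.iter_residues():
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"structure {self.id}: no chain {chain_id!r}")

    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def residue(self, key: ResidueKey) -> Residue:
        for res in self.chain(key.chain_id).residues:
            if res.key == key:
                return res
        raise StructureError(f"structure {self.id}: no residue {key}")

    def find_residue(self, chain_id: str, seq_number: int, insertion_code: str = "") -> Residue:
        for res in self.chain(chain_id).residues:
            k = res.key
            if k.seq_number == seq_number and k.insertion_code == insertion_code:
                return res
        raise StructureError(
            f"structure {self.id}: no residue {chain_id}:{seq_number}{insertion_code}"
        )

    def subset(self, chain_ids: Iterable[str]) -> "AtomicStructure":
        """A new structure containing only the named chains (atoms shared, not copied)."""
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chain_ids()]
        if missing:
            raise StructureError(f"structure {self.id}: no chain(s) {missing}")
        return AtomicStructure(
            id=f"{self.id}[{','.join(wanted)}]",
            chains=[c for c in self.chains if c.chain_id in wanted],
            source_format=self.source_format,
        )

    def coords(self) -> np.ndarray:
        return np.array([a.coords for _, a in self.iter_atoms()])

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for res in self.iter_residues():
            ident = (res.key.chain_id, res.key.seq_number, res.key.insertion_code)
            if ident in seen:
                raise StructureError(f"duplicate residue identity {ident}")
            seen.add(ident)
            if not res.atoms:
                raise StructureError(f"residue {res.key} has no atoms")


# ---------------------------------------------------------------------------
# Numbering
# ---------------------------------------------------------------------------

@dataclass
class NumberingMap:
    """Mapping from residue identity to (scheme label, region).

    Keys are ``(chain_id, seq_number, insertion_code)`` triples in author
    numbering; values carry the scheme label (e.g. Kabat ``"H97"``) and a
    region drawn from :data:`REGION_VOCABULARY`.
    """
    entries: dict[tuple[str, int, str], tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, (label, region) in self.entries.items():
            if region not in REGION_VOCABULARY:
                raise StructureError(f"numbering entry {key}: unknown region {region!r}")

    def __len__(self) -> int:
        return len(self.entries)


def load_numbering_csv(path: str | Path) -> NumberingMap:
    """Read a numbering map from CSV with columns chain,resnum,icode,aa,scheme_label,region."""
    df = pd.read_csv(path, dtype={"chain": str, "icode": str, "scheme_label": str}, keep_default_na=False)
    required = {"chain", "resnum", "icode", "aa", "scheme_label", "region"}
    if not required.issubset(df.columns):
        raise StructureError(f"numbering CSV {path}: missing columns {sorted(required - set(df.columns))}")
    entries = {}
    for row in df.itertuples(index=False):
        entries[(str(row.chain), int(row.resnum), str(row.icode))] = (
            str(row.scheme_label), str(row.region))
    return NumberingMap(entries)


def kabat_region(chain_type: str, kabat_number: int) -> str:
    """Region (CDR/FR/constant) of a Kabat position on a heavy or light chain.

    ``chain_type`` is ``"heavy"`` or ``"light"``; insertion codes share the
    region of their parent number.
    """
    table = _KABAT[chain_type]
    for region, (lo, hi) in table.items():
        if lo <= kabat_number <= hi:
            return region
    return "constant" if kabat_number > table["FR4"][1] else "other"


def apply_numbering(structure: AtomicStructure, numbering: NumberingMap,
                    strict: bool = True) -> AtomicStructure:
    """Annotate residues in place with scheme labels and regions.

    Residues absent from the map keep ``region="other"``. In strict mode a
    map entry that matches no residue raises; in lenient mode it is ignored.
    Coordinates and atom counts are never modified.
    """
    index = {
        (r.key.chain_id, r.key.seq_number, r.key.insertion_code): r
        for r in structure.iter_residues()
    }
    seen_labels: set[str] = set()
    for key, (label, region) in numbering.entries.items():
        res = index.get(key)
        if res is None:
            if strict:
                raise StructureError(f"numbering key {key} not present in structure {structure.id}")
            continue
        if label in seen_labels:
            raise StructureError(f"numbering maps two residues to scheme label {label!r}")
        seen_labels.add(label)
        res.scheme_label = label
        res.region = region
    return structure


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _one_letter(resname: str, use_aliases: bool) -> str:
    if resname in THREE_TO_ONE:
        return THREE_TO_ONE[resname]
    if use_aliases and resname in _ALIASES:
        return _ALIASES[resname]
    return "X"


def _select_altloc(atoms: list[AtomRecord], policy: str) -> list[AtomRecord]:
    if policy not in ("highest_occupancy", "first", "all"):
        raise StructureError(f"unknown altloc policy {policy!r}")
    if policy == "all":
        return atoms
    by_name: dict[str, list[AtomRecord]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept: list[AtomRecord] = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
        elif policy == "first":
            kept.append(group[0])
        else:
            # highest occupancy; ties broken by altloc identifier ('A' first)
            kept.append(sorted(group, key=lambda a: (-a.occupancy, a.altloc or "~"))[0])
    kept.sort(key=lambda a: a.serial)
    return kept


def read_structure(
    path: str | Path,
    format: str | None = None,
    *,
    drop_waters: bool = True,
    drop_hetero: bool = True,
    drop_hydrogens: bool = True,
    altloc_policy: str = "highest_occupancy",
    use_modified_aliases: bool = True,
    radius_overrides: Mapping[str, float] | None = None,
) -> AtomicStructure:
    """Parse a PDB or mmCIF file into an :class:`AtomicStructure`.

    Filters are applied in order waters → hetero → hydrogens → altlocs, and
    van der Waals radii are assigned from the pinned element table (with
    optional per-element overrides). Raises :class:`StructureError` on
    unparseable input or when nothing survives filtering.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = (format or ("mmCIF" if path.suffix.lower() in (".cif", ".mmcif") else "PDB")).upper()
    try:
        if fmt == "MMCIF":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    if not len(st):
        raise StructureError(f"{path}: no models")
    model = st[0]

    out = AtomicStructure(id=st.name or path.stem, source_format="mmCIF" if fmt == "MMCIF" else "PDB")
    overrides = {k.upper(): v for k, v in (radius_overrides or {}).items()}
    for ch in model:
        chain = Chain(chain_id=ch.name)
        for res in ch:
            resname = res.name.strip().upper()
            if drop_waters and resname in WATER_NAMES:
                continue
            is_het = res.het_flag == "H" and resname not in WATER_NAMES
            if drop_hetero and is_het and resname not in _ALIASES:
                continue
            atoms: list[AtomRecord] = []
            for at in res:
                element = at.element.name.upper() if at.element else ""
                if drop_hydrogens and element in ("H", "D"):
                    continue
                radius = overrides.get(element) if element in overrides else None
                if radius is None:
                    radius = vdw_radius_for_element(element, at.name)
                atoms.append(AtomRecord(
                    serial=at.serial,
                    name=at.name,
                    element=element,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    altloc=at.altloc if at.altloc != "\x00" else "",
                    b_factor=at.b_iso,
                    vdw_radius=radius,
                ))
            atoms = _select_altloc(atoms, altloc_policy)
            if not atoms:
                continue
            key = ResidueKey(
                chain_id=ch.name,
                seq_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                aa=_one_letter(resname, use_modified_aliases),
            )
            chain.residues.append(Residue(key=key, name=resname, atoms=atoms,
                                          is_hetero=(res.het_flag == "H")))
        if chain.residues:
            out.chains.append(chain)
    if out.n_atoms == 0:
        raise StructureError(f"{path}: empty structure after filtering")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_pdb(structure: AtomicStructure, path: str | Path) -> None:
    """Write fixed-width PDB ATOM/HETATM records with populated element columns."""
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                record = "HETATM" if res.is_hetero else "ATOM  "
                name = atom.name
                # standard alignment: 1-char element names start in column 14
                padded = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:>5d} {padded}{'':1s}{res.name:<3s} "
                    f"{chain.chain_id[:1]:1s}{res.key.seq_number:>4d}{res.key.insertion_code or '':1s}   "
                    f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{atom.occupancy:>6.2f}{atom.b_factor:>6.2f}"
                    f"          {atom.element:>2s}  "
                )
        lines.append(f"TER   {serial + 1:>5d}      {chain.residues[-1].name:<3s} "
                     f"{chain.chain_id[:1]:1s}{chain.residues[-1].key.seq_number:>4d}"
                     f"{chain.residues[-1].key.insertion_code or '':1s}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Compact chain CSV (down-sampled crystal structures, one file per chain)
# ---------------------------------------------------------------------------

_COMPACT_COLUMNS = ["chain", "resnum", "icode", "resname", "atom", "element", "x", "y", "z", "b"]


def write_compact_chain_csv(structure: AtomicStructure, chain_id: str, path: str | Path) -> None:
    """Write one chain as a compact atom CSV (coordinates to 0.01 Å).

    This plain-text format exists to keep down-sampled crystal structures
    small and diff-friendly; it preserves exactly what the pipeline needs
    (identity, element, coordinates, B-factor).
    """
    rows = []
    for res in structure.chain(chain_id):
        for atom in res.atoms:
            rows.append({
                "chain": chain_id, "resnum": res.key.seq_number,
                "icode": res.key.insertion_code, "resname": res.name,
                "atom": atom.name, "element": atom.element,
                "x": f"{atom.coords[0]:.2f}", "y": f"{atom.coords[1]:.2f}",
                "z": f"{atom.coords[2]:.2f}", "b": f"{atom.b_factor:.2f}",
            })
    pd.DataFrame(rows, columns=_COMPACT_COLUMNS).to_csv(path, index=False)


def read_compact_chain_csv(paths: Iterable[str | Path], structure_id: str) -> AtomicStructure:
    """Assemble a structure from per-chain compact CSVs (see the writer above)."""
    out = AtomicStructure(id=structure_id, source_format="PDB")
    serial = 0
    for path in paths:
        df = pd.read_csv(path, keep_default_na=False, dtype={"chain": str, "icode": str})
        chain: Chain | None = None
        residue: Residue | None = None
        for row in df.itertuples(index=False):
            if chain is None or chain.chain_id != str(row.chain):
                chain = Chain(chain_id=str(row.chain))
                out.chains.append(chain)
                residue = None
            ident = (int(row.resnum), str(row.icode))
            if residue is None or (residue.key.seq_number, residue.key.insertion_code) != ident:
                resname = str(row.resname).upper()
                key = ResidueKey(chain_id=chain.chain_id, seq_number=ident[0],
                                 insertion_code=ident[1], aa=_one_letter(resname, True))
                residue = Residue(key=key, name=resname)
                chain.residues.append(residue)
            serial += 1
            element = str(row.element).upper()
            residue.atoms.append(AtomRecord(
                serial=serial, name=str(row.atom), element=element,
                coords=np.array([float(row.x), float(row.y), float(row.z)]),
                b_factor=float(row.b),
                vdw_radius=vdw_radius_for_element(element, str(row.atom)),
            ))
    if out.n_atoms == 0:
        raise StructureError(f"no atoms read for {structure_id}")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def extract_chain_sequence(structure: AtomicStructure, chain_id: str) -> str:
    """One-letter sequence of a chain, in residue order; non-standard residues are 'X'."""
    chain = structure.chain(chain_id)
    if not chain.residues:
        raise StructureError(f"chain {chain_id} is empty")
    return "".join(res.key.aa for res in chain.residues)
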
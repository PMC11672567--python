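"""Inter-group contact detection and hydrophobic interface summaries.

Antibody Fabs frequently self-associate through hydrophobic surface
patches; in a crystal containing two Fab copies the contact residues and
the solvent-accessible area they bury against the partner quantify such a
pocket. Groups are arbitrary chain sets, so the same machinery analyses
any inter-molecular interface present in the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .hydrophobicity import HydrophobicityProfile
from .sasa import SasaParams, SasaResult, compute_sasa
from .structure import AtomicStructure, ResidueKey

__all__ = [
    "ContactRecord",
    "InterfaceSummary",
    "find_intergroup_contacts",
    "buried_sasa",
    "summarize_interface",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactRecord:
    residue_a: ResidueKey
    residue_b: ResidueKey
    min_atom_distance: float          # Å
    n_atom_pairs_within_cutoff: int


@dataclass
class InterfaceSummary:
    contact_residues_a: list[ResidueKey]
    contact_residues_b: list[ResidueKey]
    hydrophobic_fraction: float | None
    h_cutoff: float
    buried_by_residue: dict[ResidueKey, float] = field(default_factory=dict)
    top_residues: list[tuple[ResidueKey, float]] = field(default_factory=list)


def _check_groups(structure: AtomicStructure, group_a, group_b) -> tuple[list[str], list[str]]:
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be nonempty")
    if set(ga) & set(gb):
        raise ValueError(f"groups overlap: {sorted(set(ga) & set(gb))}")
    for cid in ga + gb:
        structure.chain(cid)  # raises on unknown chain
    return ga, gb


def _group_atoms(structure: AtomicStructure, chain_ids: list[str]):
    keys, coords = [], []
    for cid in chain_ids:
        for res in structure.chain(cid):
            for atom in res.atoms:
                keys.append(res.key)
                coords.append(atom.coords)
    return keys, np.asarray(coords)


def find_intergroup_contacts(structure: AtomicStructure, group_a, group_b,
                             cutoff: float = 4.5) -> list[ContactRecord]:
    """All residue pairs with any heavy-atom pair within ``cutoff`` Å.

    Exhaustive over residue pairs between the two chain groups; output is
    ordered by (chain, residue number) of the group-A residue. Swapping the
    groups mirrors every record.
    """
    ga, gb = _check_groups(structure, group_a, group_b)
    keys_a, xyz_a = _group_atoms(structure, ga)
    keys_b, xyz_b = _group_atoms(structure, gb)
    tree_a, tree_b = cKDTree(xyz_a), cKDTree(xyz_b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    agg: dict[tuple[ResidueKey, ResidueKey], list[float]] = {}
    for ia, hits in enumerate(pairs):
        for ib in hits:
            d = float(np.linalg.norm(xyz_a[ia] - xyz_b[ib]))
            agg.setdefault((keys_a[ia], keys_b[ib]), []).append(d)
    records = [
        ContactRecord(residue_a=ka, residue_b=kb,
                      min_atom_distance=min(ds), n_atom_pairs_within_cutoff=len(ds))
        for (ka, kb), ds in agg.items()
    ]
    records.sort(key=lambda r: (r.residue_a, r.residue_b))
    return records


def buried_sasa(structure: AtomicStructure, group_a, group_b,
                params: SasaParams | None = None) -> dict[ResidueKey, float]:
    """Per-residue SASA buried on complex formation.

    buried(r) = SASA(r | own group alone) − SASA(r | both groups together).
    Small negative differences (quadrature jitter) are clamped to zero and
    logged.
    """
    ga, gb = _check_groups(structure, group_a, group_b)
    params = params or SasaParams()
    complex_sasa = compute_sasa(structure.subset(ga + gb), params)
    buried: dict[ResidueKey, float] = {}
    for grp in (ga, gb):
        alone = compute_sasa(structure.subset(grp), params)
        for key, area in alone.per_residue.items():
            delta = area - complex_sasa.per_residue[key]
            if delta < 0:
                log.info("clamping negative buried area %.3f at %s", delta, key)
                delta = 0.0
            buried[key] = delta
    return buried


def summarize_interface(contacts: list[ContactRecord],
                        profile: HydrophobicityProfile,
                        h_cutoff: float = 0.72,
                        buried: dict[ResidueKey, float] | None = None,
                        top_k: int = 10) -> InterfaceSummary:
    """Summarize contact residues and their hydrophobic character.

    ``hydrophobic_fraction`` is the fraction of unique contact residues
    whose scale value is at least ``h_cutoff`` (default 0.72: F, W, Y, L, I,
    V and M qualify on the Black–Mould scale); ``None`` when there are no
    contacts. When buried areas are supplied, residues are ranked by
    buried_area × h.
    """
    residues_a = sorted({c.residue_a for c in contacts})
    residues_b = sorted({c.residue_b for c in contacts})
    all_contact = residues_a + residues_b
    h_by_key = {r.key: r.h for r in profile.residues}
    if all_contact:
        hydrophobic = [k for k in all_contact if h_by_key.get(k, 0.0) >= h_cutoff]
        fraction = len(hydrophobic) / len(all_contact)
    else:
        fraction = None
    top: list[tuple[ResidueKey, float]] = []
    if buried:
        ranked = sorted(
            ((k, buried.get(k, 0.0) * h_by_key.get(k, 0.0)) for k in all_contact),
            key=lambda kv: -kv[1])
        top = ranked[:top_k]
    return InterfaceSummary(
        contact_residues_a=residues_a,
        contact_residues_b=residues_b,
        hydrophobic_fraction=fraction,
        h_cutoff=h_cutoff,
        buried_by_residue=buried or {},
        top_residues=top,
    )
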
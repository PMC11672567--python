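"""Rigid-body superposition (Kabsch) and normalized B-factor analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import AtomicStructure

__all__ = [
    "SuperpositionResult",
    "NormalizedBfactors",
    "kabsch_superpose",
    "pair_atoms",
    "normalize_bfactors",
    "residue_bfactors",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    rmsd: float                 # Å
    rotation: np.ndarray        # 3×3 proper orthonormal
    translation: np.ndarray     # 3-vector, Å
    n_atoms_paired: int


@dataclass
class NormalizedBfactors:
    z: np.ndarray               # dimensionless
    mu: float                   # Å²
    sigma: float                # Å²


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of B onto A.

    Solves for the proper rotation R and translation t minimizing
    ``|| (B R^T + t) − A ||``; reflections are excluded by correcting the
    sign of the smallest singular vector. RMSD is reported after applying
    the optimal transform.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be N×3, got {A.shape} and {B.shape}")
    n = len(A)
    if n < 3:
        raise ValueError(f"need at least 3 paired atoms, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    if np.linalg.matrix_rank(np.vstack([A0, B0])) < 2:
        raise ValueError("degenerate (collinear) coordinates")
    H = B0.T @ A0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    B_fit = (R @ B0.T).T
    rmsd = float(np.sqrt(np.mean(np.sum((B_fit - A0) ** 2, axis=1))))
    translation = ca - R @ cb
    return SuperpositionResult(rmsd=rmsd, rotation=R, translation=translation, n_atoms_paired=n)


def pair_atoms(structure_a: AtomicStructure, structure_b: AtomicStructure,
               policy: str = "ca",
               label_map: dict[str, str] | None = None,
               ) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Paired coordinate arrays for two structures, matched by scheme label.

    ``policy`` selects atoms per residue: ``"ca"`` (C-alpha only),
    ``"backbone"`` (N, CA, C, O) or ``"all"`` (atoms shared by name).
    ``label_map`` maps labels of A to labels of B (identity by default).
    Residues with insertion codes pair only through their (identical)
    labels, which carry the code. Returns (coords_a, coords_b, paired
    labels, unpaired labels report).
    """
    if policy not in ("ca", "backbone", "all"):
        raise ValueError(f"unknown pairing policy {policy!r}")
    res_a = {r.scheme_label: r for r in structure_a.iter_residues() if r.scheme_label}
    res_b = {r.scheme_label: r for r in structure_b.iter_residues() if r.scheme_label}
    if label_map is None:
        label_map = {lbl: lbl for lbl in res_a}
    coords_a, coords_b, paired = [], [], []
    unpaired = sorted(set(res_a) - set(label_map)) + sorted(set(res_b) - set(label_map.values()))
    for la, lb in label_map.items():
        ra, rb = res_a.get(la), res_b.get(lb)
        if ra is None or rb is None:
            unpaired.append(la)
            continue
        if policy == "ca":
            names = ["CA"]
        elif policy == "backbone":
            names = list(BACKBONE_ATOMS)
        else:
            names = sorted({a.name for a in ra.atoms} & {a.name for a in rb.atoms})
        got_any = False
        for name in names:
            atoms_a = [a for a in ra.atoms if a.name == name]
            atoms_b = [a for a in rb.atoms if a.name == name]
            if atoms_a and atoms_b:
                coords_a.append(atoms_a[0].coords)
                coords_b.append(atoms_b[0].coords)
                got_any = True
        if got_any:
            paired.append(la)
        else:
            unpaired.append(la)
    if not coords_a:
        raise ValueError("no atoms paired between the two structures")
    return np.asarray(coords_a), np.asarray(coords_b), paired, unpaired


def normalize_bfactors(values, population: bool = True) -> NormalizedBfactors:
    """Z-score normalization of B-factors: z = (b − μ)/σ.

    Uses the population standard deviation by default (``population=False``
    switches to the n−1 sample convention). Constant or single-value input
    is degenerate and raises.
    """
    b = np.asarray(list(values), dtype=float)
    if b.size < 2:
        raise ValueError(f"need at least 2 B-factors, got {b.size}")
    mu = float(b.mean())
    sigma = float(b.std(ddof=0 if population else 1))
    if sigma == 0:
        raise ValueError("constant B-factors: sigma is zero")
    return NormalizedBfactors(z=(b - mu) / sigma, mu=mu, sigma=sigma)


def residue_bfactors(structure: AtomicStructure, chain_ids=None) -> dict:
    """Mean atomic B-factor per residue, optionally restricted to chains."""
    out = {}
    for res in structure.iter_residues():
        if chain_ids is not None and res.key.chain_id not in chain_ids:
            continue
        out[res.key] = float(np.mean([a.b_factor for a in res.atoms]))
    return out
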
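"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator returns a :class:`FixtureBundle` holding in-memory objects,
a ``truth`` dict recording every planted parameter (analytic areas, motif
positions, true EC50/Hill, true λmax, the true calibration line), and can
write the corresponding artifact files (PDB / FASTA / CSV plus
``truth.json``). Generators are seed-deterministic: the same seed yields
byte-identical files.

The toy structures are small sphere packings whose SASA is known in closed
form (isolated sphere, two intersecting spheres) or by construction (a
fully caged atom); they stand in for real crystal structures when testing
the geometry pipeline without downloads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .liabilities import MotifRuleSet, scan_motifs
from .sasa import analytic_sphere_sasa, golden_spiral_points, two_sphere_sasa
from .structure import AtomicStructure, AtomRecord, Chain, Residue, ResidueKey, write_pdb

__all__ = [
    "FixtureBundle",
    "make_toy_structure",
    "make_liability_sequence",
    "make_assay_fixtures",
]

# Background alphabet for planted sequences: excludes N, D, S, E and L so no
# deamidation / glycosylation / proteolysis / isomerization motif can arise
# from background residues alone or across a plant boundary.
BACKGROUND_ALPHABET = "ACFGHIKMPQRTVWY"

PLANT_MOTIFS = {
    "deamidation": "SNG",
    "glycosylation": "NAT",
    "proteolysis": "DP",
    "isomerization": "DS",
}


@dataclass
class FixtureBundle:
    kind: str
    truth: dict
    structure: AtomicStructure | None = None
    sequence: str | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write artifact files plus truth.json; byte-stable for a fixed seed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files: dict[str, Path] = {}
        if self.structure is not None:
            p = out / f"{self.kind}.pdb"
            write_pdb(self.structure, p)
            files["structure"] = p
        if self.sequence is not None:
            p = out / f"{self.kind}.fasta"
            p.write_text(f">{self.kind}\n{self.sequence}\n")
            files["sequence"] = p
        for name, df in self.tables.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.6f")
            files[name] = p
        truth_path = out / "truth.json"
        truth_path.write_text(json.dumps(self.truth, sort_keys=True, indent=2) + "\n")
        files["truth"] = truth_path
        return files


def _make_structure(atoms: list[tuple[np.ndarray, float]], struct_id: str) -> AtomicStructure:
    """One chain, one dummy residue per atom; radii set directly on the atoms."""
    chain = Chain(chain_id="A")
    for i, (coords, radius) in enumerate(atoms, start=1):
        key = ResidueKey(chain_id="A", seq_number=i, insertion_code="", aa="X")
        atom = AtomRecord(serial=i, name="X1", element="C", coords=coords,
                          occupancy=1.0, b_factor=0.0, vdw_radius=radius)
        chain.residues.append(Residue(key=key, name="UNK", atoms=[atom]))
    return AtomicStructure(id=struct_id, chains=[chain])


def make_toy_structure(kind: str, seed: int = 0, *, r_vdw: float = 1.9,
                       distance: float = 3.3, n_atoms: int = 10,
                       probe: float = 1.4) -> FixtureBundle:
    """Toy sphere packings with analytic or constructed SASA truth.

    Kinds: ``single_atom`` (closed-form area), ``two_sphere`` (spherical-cap
    closed form at centre distance ``distance``), ``cage`` (a central atom
    completely enclosed by an icosahedral shell: true area 0, coverage
    verified numerically at build time), ``random_cluster`` (``n_atoms``
    random atoms, no analytic truth).
    """
    rng = np.random.default_rng(seed)
    if kind == "single_atom":
        structure = _make_structure([(np.zeros(3), r_vdw)], "single_atom")
        truth = {
            "kind": kind, "seed": seed, "probe": probe, "r_vdw": r_vdw,
            "true_area_per_atom": [analytic_sphere_sasa(r_vdw, probe)],
        }
    elif kind == "two_sphere":
        if not 0 < distance < 2 * (r_vdw + probe):
            raise ValueError(
                f"distance must be in (0, {2 * (r_vdw + probe)}) for partial overlap")
        area = two_sphere_sasa(r_vdw, probe, distance)
        structure = _make_structure(
            [(np.zeros(3), r_vdw), (np.array([distance, 0.0, 0.0]), r_vdw)], "two_sphere")
        truth = {
            "kind": kind, "seed": seed, "probe": probe, "r_vdw": r_vdw,
            "distance": distance,
            "true_area_per_atom": [area, area],
            "true_buried_per_atom": analytic_sphere_sasa(r_vdw, probe) - area,
        }
    elif kind == "cage":
        # central atom enclosed by 12 large atoms on icosahedron vertices
        r_center, r_shell, shell_dist = r_vdw, 3.0, 4.0
        phi = (1 + math.sqrt(5)) / 2
        verts = []
        for a in (-1.0, 1.0):
            for b_ in (-phi, phi):
                verts.extend([(0.0, a, b_), (a, b_, 0.0), (b_, 0.0, a)])
        verts = np.array(verts)
        verts = shell_dist * verts / np.linalg.norm(verts[0])
        atoms = [(np.zeros(3), r_center)] + [(v, r_shell) for v in verts]
        # verify total coverage of the central expanded sphere
        pts = (r_center + probe) * golden_spiral_points(2000)
        d = np.linalg.norm(pts[:, None, :] - verts[None, :, :], axis=-1)
        if not np.all(d.min(axis=1) < r_shell + probe):
            raise ValueError("cage construction failed to enclose the central atom")
        structure = _make_structure(atoms, "cage")
        truth = {
            "kind": kind, "seed": seed, "probe": probe,
            "true_area_center_atom": 0.0,
            "r_center": r_center, "r_shell": r_shell, "shell_distance": shell_dist,
        }
    elif kind == "random_cluster":
        coords = rng.uniform(-4.0, 4.0, size=(n_atoms, 3)).round(3)
        radii = rng.uniform(1.5, 2.0, size=n_atoms).round(2)
        structure = _make_structure(list(zip(coords, radii)), f"random_cluster_{seed}")
        truth = {
            "kind": kind, "seed": seed, "probe": probe, "n_atoms": n_atoms,
            "radii": radii.tolist(),
        }
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")
    return FixtureBundle(kind=kind, truth=truth, structure=structure)


def make_liability_sequence(length: int, planted: list[tuple[str, int]],
                            seed: int = 0) -> FixtureBundle:
    """A random sequence with motif liabilities planted at known positions.

    ``planted`` is a list of ``(kind, 1-based position)``. The background
    alphabet avoids every motif-forming residue, and the two positions after
    each plant are forced to alanine, so the only scanner hits are exactly
    the planted ones — which is asserted at build time with the motif
    scanner's independent brute-force contract.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(BACKGROUND_ALPHABET), size=length))
    occupied: list[tuple[int, int]] = []   # [start0, end0) including safety pad
    truth_hits = []
    for kind, pos in sorted(planted, key=lambda kp: kp[1]):
        if kind not in PLANT_MOTIFS:
            raise ValueError(f"unknown liability kind {kind!r}")
        motif = PLANT_MOTIFS[kind]
        start0 = pos - 1
        end0 = start0 + len(motif)
        if start0 < 0 or end0 > length:
            raise ValueError(f"plant {kind}@{pos} does not fit in length {length}")
        for s, e in occupied:
            if start0 < e and s < end0 + 2:
                raise ValueError(f"plant {kind}@{pos} conflicts with another plant")
        seq[start0:end0] = list(motif)
        for pad in (end0, end0 + 1):       # guard against boundary motifs
            if pad < length:
                seq[pad] = "A"
        occupied.append((start0, end0 + 2))
        truth_hits.append({"kind": kind, "position": pos, "matched_text": motif})
    sequence = "".join(seq)
    found = [(h.kind, h.position, h.matched_text) for h in scan_motifs(sequence, MotifRuleSet())]
    expected = sorted((h["kind"], h["position"], h["matched_text"]) for h in truth_hits)
    if sorted(found) != expected:
        raise AssertionError(f"fixture self-check failed: planted {expected}, scanner saw {found}")
    truth = {"kind": "liability_sequence", "seed": seed, "length": length,
             "planted_hits": truth_hits}
    return FixtureBundle(kind="liability_sequence", truth=truth, sequence=sequence)


def make_assay_fixtures(kind: str, params: dict | None = None,
                        noise: float = 0.0, seed: int = 0) -> FixtureBundle:
    """Synthetic assay data with recorded truth.

    Kinds and their parameters (defaults in parentheses):

    * ``acsins`` — quadratic plasmon peak on the 480–580 nm grid at 2 nm
      steps: ``lambda_max`` (530.0 nm), curvature ``a`` (−0.001, must be
      negative), ``peak_height`` (0.5 AU); additive Gaussian noise of SD
      ``noise`` AU.
    * ``binding`` — 4PL curve: ``bottom`` (0.05), ``top`` (2.0), ``ec50``
      (200.0 pM), ``hill`` (1.0), ``n_concentrations`` (12) log-spaced over
      ``ec50`` × [1e-2, 1e2]; multiplicative log-normal noise with
      ``sigma = noise`` (e.g. 0.02 for ~2%).
    * ``sec`` — protein standards (670, 158, 44, 17, 1.35 kDa) placed on a
      true line ``log10(MW) = slope·V + intercept`` (slope −0.30,
      intercept 5.23); Gaussian retention jitter of SD ``noise`` mL.
    * ``bfactor`` — ``n`` (50) Gaussian B-factors with ``mu`` (20.0) and
      ``sigma`` (8.0) Å².
    """
    p = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "acsins":
        lam, a, height = p.get("lambda_max", 530.0), p.get("a", -0.001), p.get("peak_height", 0.5)
        if a >= 0:
            raise ValueError("curvature a must be negative for a plasmon peak")
        x = np.arange(480.0, 580.0 + 1e-9, 2.0)
        y = height + a * (x - lam) ** 2
        if noise > 0:
            y = y + rng.normal(0.0, noise, size=len(x))
        df = pd.DataFrame({"wavelength_nm": x, "absorbance": y})
        truth = {"kind": kind, "seed": seed, "noise_sd": noise,
                 "lambda_max": lam, "a": a,
                 "b": -2 * a * lam, "c": height + a * lam ** 2}
        return FixtureBundle(kind=kind, truth=truth, tables={"spectrum": df})
    if kind == "binding":
        bottom, top = p.get("bottom", 0.05), p.get("top", 2.0)
        ec50, hill = p.get("ec50", 200.0), p.get("hill", 1.0)
        n = p.get("n_concentrations", 12)
        if ec50 <= 0:
            raise ValueError("ec50 must be positive")
        conc = np.logspace(math.log10(ec50) - 2, math.log10(ec50) + 2, n)
        y = bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)
        if noise > 0:
            y = y * np.exp(rng.normal(0.0, noise, size=n))
        df = pd.DataFrame({"concentration_pM": conc, "response": y})
        truth = {"kind": kind, "seed": seed, "noise_sigma": noise,
                 "bottom": bottom, "top": top, "ec50": ec50, "hill": hill}
        return FixtureBundle(kind=kind, truth=truth, tables={"binding": df})
    if kind == "sec":
        slope, intercept = p.get("slope", -0.30), p.get("intercept", 5.23)
        mws = p.get("standards_kda", [670.0, 158.0, 44.0, 17.0, 1.35])
        if slope >= 0:
            raise ValueError("slope must be negative")
        vols = (np.log10(mws) - intercept) / slope
        if noise > 0:
            vols = vols + rng.normal(0.0, noise, size=len(vols))
        df = pd.DataFrame({"mw_kda": mws, "retention_ml": vols})
        truth = {"kind": kind, "seed": seed, "noise_sd": noise,
                 "slope": slope, "intercept": intercept, "standards_kda": list(mws)}
        return FixtureBundle(kind=kind, truth=truth, tables={"sec_standards": df})
    if kind == "bfactor":
        n, mu, sigma = p.get("n", 50), p.get("mu", 20.0), p.get("sigma", 8.0)
        values = rng.normal(mu, sigma, size=n)
        df = pd.DataFrame({"b_factor": values})
        truth = {"kind": kind, "seed": seed, "n": n, "mu": mu, "sigma": sigma}
        return FixtureBundle(kind=kind, truth=truth, tables={"bfactors": df})
    raise ValueError(f"unknown assay fixture kind {kind!r}")
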
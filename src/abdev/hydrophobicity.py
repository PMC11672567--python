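"""SASA-weighted hydrophobicity profiles, hotspot classes, and profile deltas.

The per-residue hydrophobicity score is the product of a residue's
solvent-accessible surface area with its entry on a normalized
hydrophobicity scale (default: Black & Mould, Phe = 1.0, Arg = 0.0):

    score_r = SASA_r * h_aa          [Å² · index units]

Scores are aggregated over CDR/framework regions and whole chains, residues
are classed as elevated/moderate hotspots against configurable thresholds,
and two structures' profiles can be differenced position-by-position via
their shared scheme labels (e.g. Kabat ``H99``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .sasa import SasaResult
from .structure import AtomicStructure, ResidueKey

__all__ = [
    "HydrophobicityScale",
    "ResidueScore",
    "HydrophobicityProfile",
    "HotspotReport",
    "ProfileDelta",
    "load_scale",
    "score_profile",
    "aggregate_regions",
    "classify_hotspots",
    "diff_profiles",
    "mean_profile_by_label",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class HydrophobicityScale:
    name: str
    index: Mapping[str, float]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.index)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        if not all(np.isfinite(v) for v in self.index.values()):
            raise ValueError(f"scale {self.name!r} has non-finite entries")

    def __getitem__(self, aa: str) -> float:
        return self.index[aa]

    def __contains__(self, aa: str) -> bool:
        return aa in self.index


def load_scale(name: str = "black_mould") -> HydrophobicityScale:
    """Load a shipped hydrophobicity scale by name."""
    with resources.files("abdev.data").joinpath(f"{name}.json").open() as fh:
        raw = json.load(fh)
    meta = {k: v for k, v in raw.items() if k != "index"}
    return HydrophobicityScale(name=raw["name"], index=raw["index"], metadata=meta)


@dataclass
class ResidueScore:
    key: ResidueKey
    sasa: float           # Å²
    h: float              # scale index
    score: float          # sasa * h
    region: str = "other"
    scheme_label: str | None = None


@dataclass
class HydrophobicityProfile:
    scale_name: str
    residues: list[ResidueScore]
    skipped: list[ResidueKey] = field(default_factory=list)

    @property
    def per_residue(self) -> dict[ResidueKey, float]:
        return {r.key: r.score for r in self.residues}

    def by_label(self) -> dict[str, ResidueScore]:
        return {r.scheme_label: r for r in self.residues if r.scheme_label}

    def total_per_chain(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for r in self.residues:
            totals[r.key.chain_id] = totals.get(r.key.chain_id, 0.0) + r.score
        return totals


@dataclass
class HotspotReport:
    elevated: list[ResidueKey]
    moderate: list[ResidueKey]
    thresholds: tuple[float, float]


@dataclass
class ProfileDelta:
    """Per-position differences b − a, paired by scheme label."""
    delta_sasa: dict[str, float]
    delta_score: dict[str, float]
    unpaired_a: list[str]
    unpaired_b: list[str]


def score_profile(sasa: SasaResult, structure: AtomicStructure,
                  scale: HydrophobicityScale | None = None,
                  *, strict: bool = False) -> HydrophobicityProfile:
    """Score every residue of ``structure`` with ``score = SASA × h_aa``.

    Residues with unknown amino acid ('X') are skipped and logged; in strict
    mode a residue whose code is missing from the scale raises instead.
    """
    scale = scale or load_scale()
    residues: list[ResidueScore] = []
    skipped: list[ResidueKey] = []
    for res in structure.iter_residues():
        aa = res.key.aa
        if aa not in scale:
            if strict and aa != "X":
                raise KeyError(f"scale {scale.name!r} has no entry for {aa!r} ({res.key})")
            log.info("skipping residue %s: no scale entry for %r", res.key, aa)
            skipped.append(res.key)
            continue
        area = sasa.per_residue.get(res.key, 0.0)
        h = scale[aa]
        residues.append(ResidueScore(
            key=res.key, sasa=area, h=h, score=area * h,
            region=res.region, scheme_label=res.scheme_label,
        ))
    return HydrophobicityProfile(scale_name=scale.name, residues=residues, skipped=skipped)


def aggregate_regions(profile: HydrophobicityProfile) -> dict[tuple[str, str], float]:
    """Exact sums of residue scores per (chain, region).

    Residues without a CDR/FR annotation fall into the ``(chain, "other")``
    remainder bucket, so per-chain totals equal the sum over their regions.
    """
    sums: dict[tuple[str, str], float] = {}
    for r in profile.residues:
        k = (r.key.chain_id, r.region)
        sums[k] = sums.get(k, 0.0) + r.score
    return sums


def classify_hotspots(profile: HydrophobicityProfile,
                      thresholds: tuple[float, float] = (100.0, 50.0)) -> HotspotReport:
    """Classify residues as elevated (score ≥ t_elevated) or moderate
    (t_moderate ≤ score < t_elevated) hydrophobicity hotspots."""
    t_elevated, t_moderate = thresholds
    if not t_elevated > t_moderate > 0:
        raise ValueError(f"thresholds must satisfy t_elevated > t_moderate > 0, got {thresholds}")
    elevated = sorted((r.key for r in profile.residues if r.score >= t_elevated))
    moderate = sorted((r.key for r in profile.residues
                       if t_moderate <= r.score < t_elevated))
    return HotspotReport(elevated=elevated, moderate=moderate, thresholds=thresholds)


def diff_profiles(profile_a: HydrophobicityProfile, profile_b: HydrophobicityProfile,
                  pairing: Mapping[str, str] | None = None) -> ProfileDelta:
    """Per-position deltas (b − a) of SASA and score, paired by scheme label.

    ``pairing`` maps labels of *a* to labels of *b*; by default identical
    labels pair with each other. Labels present on one side only are listed
    as unpaired.
    """
    a_by = profile_a.by_label()
    b_by = profile_b.by_label()
    if pairing is None:
        pairing = {lbl: lbl for lbl in a_by if lbl in b_by}
    targets = list(pairing.values())
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate pairing target label")
    delta_sasa: dict[str, float] = {}
    delta_score: dict[str, float] = {}
    for la, lb in pairing.items():
        if la in a_by and lb in b_by:
            delta_sasa[la] = b_by[lb].sasa - a_by[la].sasa
            delta_score[la] = b_by[lb].score - a_by[la].score
    paired_a = {la for la in pairing if la in a_by and pairing[la] in b_by}
    paired_b = {pairing[la] for la in paired_a}
    return ProfileDelta(
        delta_sasa=delta_sasa,
        delta_score=delta_score,
        unpaired_a=sorted(set(a_by) - paired_a),
        unpaired_b=sorted(set(b_by) - paired_b),
    )


def mean_profile_by_label(profiles: list[HydrophobicityProfile]) -> dict[str, tuple[float, float]]:
    """Mean ± SD of scores across structure copies, keyed by scheme label.

    Used for multi-copy crystal structures where the same Fv occurs more
    than once in the asymmetric unit; labels missing from a copy are
    averaged over the copies that carry them.
    """
    values: dict[str, list[float]] = {}
    for p in profiles:
        for lbl, r in p.by_label().items():
            values.setdefault(lbl, []).append(r.score)
    return {lbl: (float(np.mean(v)), float(np.std(v))) for lbl, v in values.items()}
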
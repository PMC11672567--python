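"""Sequence and structure liability scanning.

Three screens used in antibody developability triage:

* post-translational-modification motifs — asparagine deamidation trimers
  (SNG, ENN, LNG, LNN), the N-linked glycosylation sequon N-X-[S/T] with
  X ≠ P, the DP proteolysis dipeptide, and aspartate isomerization
  dipeptides (DS, DN, DQ, DK, DL);
* solvent-exposed oxidation-prone residues — Met and Trp whose relative
  SASA (residue SASA over the Gly-X-Gly maximum for that amino acid)
  exceeds a threshold;
* rare framework residues — framework positions whose observed amino acid
  is uncommon in a germline position-frequency table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .sasa import SasaResult
from .structure import AtomicStructure

__all__ = [
    "MotifRuleSet",
    "LiabilityHit",
    "GermlineFrequencyTable",
    "scan_motifs",
    "flag_exposed_oxidation_sites",
    "flag_rare_framework_residues",
    "load_max_sasa_table",
    "load_germline_csv",
]

log = logging.getLogger(__name__)

VALID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_KIND_ORDER = {
    "deamidation": 0, "glycosylation": 1, "proteolysis": 2,
    "isomerization": 3, "oxidation_exposed": 4, "rare_framework": 5,
}


@dataclass(frozen=True)
class MotifRuleSet:
    deamidation: tuple[str, ...] = ("SNG", "ENN", "LNG", "LNN")
    proteolysis: tuple[str, ...] = ("DP",)
    isomerization: tuple[str, ...] = ("DS", "DN", "DQ", "DK", "DL")
    # glycosylation is the positional rule N-X-[S/T], X != P; held as a rule
    # object rather than literal strings
    glycosylation_first: str = "N"
    glycosylation_third: tuple[str, ...] = ("S", "T")
    glycosylation_excluded_middle: tuple[str, ...] = ("P",)

    def matches_glycosylation(self, window: str) -> bool:
        return (len(window) == 3
                and window[0] == self.glycosylation_first
                and window[2] in self.glycosylation_third
                and window[1] not in self.glycosylation_excluded_middle)


@dataclass(frozen=True)
class LiabilityHit:
    kind: str
    position: int            # 1-based start within the scanned sequence
    matched_text: str
    context: str             # ±3 residues around the match
    scheme_label: str | None = None
    detail: str = ""

    def sort_key(self) -> tuple[int, int]:
        return (self.position, _KIND_ORDER.get(self.kind, 99))


def _context(sequence: str, start0: int, length: int) -> str:
    return sequence[max(0, start0 - 3): start0 + length + 3]


def scan_motifs(sequence: str, rules: MotifRuleSet | None = None) -> list[LiabilityHit]:
    """Scan a one-letter sequence for all PTM motif occurrences.

    Reports every occurrence, including overlapping ones, ordered by
    position then kind. Raises on characters outside the 20 standard codes
    plus 'X'.
    """
    rules = rules or MotifRuleSet()
    for i, ch in enumerate(sequence):
        if ch not in VALID_ALPHABET:
            raise ValueError(f"illegal character {ch!r} at position {i + 1}")
    hits: list[LiabilityHit] = []
    n = len(sequence)
    for i in range(n):
        tri = sequence[i:i + 3]
        di = sequence[i:i + 2]
        if len(tri) == 3:
            if tri in rules.deamidation:
                hits.append(LiabilityHit("deamidation", i + 1, tri, _context(sequence, i, 3)))
            if rules.matches_glycosylation(tri):
                hits.append(LiabilityHit("glycosylation", i + 1, tri, _context(sequence, i, 3)))
        if len(di) == 2:
            if di in rules.proteolysis:
                hits.append(LiabilityHit("proteolysis", i + 1, di, _context(sequence, i, 2)))
            if di in rules.isomerization:
                hits.append(LiabilityHit("isomerization", i + 1, di, _context(sequence, i, 2)))
    hits.sort(key=LiabilityHit.sort_key)
    return hits


def load_max_sasa_table() -> dict[str, float]:
    """Pinned per-residue maximal SASA (Å², Gly-X-Gly tripeptide reference)."""
    with resources.files("abdev.data").joinpath("max_sasa.json").open() as fh:
        return json.load(fh)["max_sasa"]


def flag_exposed_oxidation_sites(structure: AtomicStructure, sasa: SasaResult,
                                 rel_exposure_threshold: float = 0.2,
                                 max_sasa: Mapping[str, float] | None = None,
                                 ) -> list[LiabilityHit]:
    """Flag Met/Trp residues whose relative exposure reaches the threshold.

    Relative exposure is residue SASA divided by the pinned maximal SASA of
    the amino acid; oxidation risk for Met and Trp is driven by exposure,
    not by sequence context.
    """
    if not 0 < rel_exposure_threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {rel_exposure_threshold}")
    max_sasa = max_sasa or load_max_sasa_table()
    hits: list[LiabilityHit] = []
    position = 0
    for res in structure.iter_residues():
        position += 1
        aa = res.key.aa
        if aa not in ("M", "W"):
            continue
        if aa not in max_sasa:
            raise KeyError(f"no maximal-SASA reference for {aa!r}")
        area = sasa.per_residue.get(res.key, 0.0)
        rel = area / max_sasa[aa]
        if rel >= rel_exposure_threshold:
            hits.append(LiabilityHit(
                kind="oxidation_exposed", position=position, matched_text=aa,
                context=str(res.key), scheme_label=res.scheme_label,
                detail=f"relative SASA {rel:.2f} (area {area:.1f} A^2)",
            ))
    return hits


@dataclass
class GermlineFrequencyTable:
    """Observed amino-acid frequencies per scheme position in a reference repertoire."""
    frequencies: dict[str, dict[str, float]]   # scheme_label -> {aa: frequency}
    source: str = ""

    def __post_init__(self) -> None:
        for label, freqs in self.frequencies.items():
            for aa, f in freqs.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"frequency {f} for {label}:{aa} outside [0, 1]")
            if sum(freqs.values()) > 1.0 + 1e-6:
                raise ValueError(f"frequencies at {label} sum to more than 1")

    def frequency(self, label: str, aa: str) -> float | None:
        if label not in self.frequencies:
            return None
        return self.frequencies[label].get(aa, 0.0)


def load_germline_csv(path: str | Path, source: str = "") -> GermlineFrequencyTable:
    """Read a germline table from CSV with columns scheme_label,aa,frequency."""
    df = pd.read_csv(path, dtype={"scheme_label": str, "aa": str})
    freqs: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        freqs.setdefault(str(row.scheme_label), {})[str(row.aa)] = float(row.frequency)
    return GermlineFrequencyTable(frequencies=freqs, source=source or str(path))


def flag_rare_framework_residues(labeled_sequence: list[tuple[str, str, str]],
                                 table: GermlineFrequencyTable,
                                 freq_threshold: float = 0.02) -> list[LiabilityHit]:
    """Flag framework positions carrying a germline-rare amino acid.

    ``labeled_sequence`` is a list of ``(scheme_label, aa, region)`` tuples;
    CDR positions are never flagged, and positions missing from the table
    produce a warning, not an error.
    """
    hits: list[LiabilityHit] = []
    for pos0, (label, aa, region) in enumerate(labeled_sequence):
        if region.startswith("CDR"):
            continue
        if not region.startswith("FR"):
            continue
        freq = table.frequency(label, aa)
        if freq is None:
            log.warning("no germline frequencies for position %s; skipping", label)
            continue
        if freq < freq_threshold:
            hits.append(LiabilityHit(
                kind="rare_framework", position=pos0 + 1, matched_text=aa,
                context=label, scheme_label=label,
                detail=f"frequency {freq:.4f} < {freq_threshold}",
            ))
    return hits
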
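"""End-to-end developability screen over structures, sequences and assay data.

``run_screen`` wires the pipeline stages in a fixed order — parse → SASA →
hydrophobicity profile → hotspots → sequence/structure liabilities →
interface → structure comparison → assay analytics — degrades gracefully
when an optional input is absent (a sequence-only screen simply marks the
structure sections absent), and emits a JSON-serializable report in which
every number comes from a module output and every parameter is echoed
verbatim.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .assays import (BindingCurve, SecCalibration, Spectrum, acsins_lambda_max,
                     acsins_shift, fit_4pl, relative_potency, sec_mw_estimate)
from .compare import kabsch_superpose, normalize_bfactors, pair_atoms, residue_bfactors
from .hydrophobicity import (aggregate_regions, classify_hotspots, diff_profiles,
                             load_scale, score_profile)
from .interface import buried_sasa, find_intergroup_contacts, summarize_interface
from .liabilities import (flag_exposed_oxidation_sites, flag_rare_framework_residues,
                          load_germline_csv, scan_motifs)
from .sasa import SasaParams, compute_sasa
from .structure import apply_numbering, extract_chain_sequence, load_numbering_csv, read_structure

__all__ = ["DEFAULT_PARAMS", "load_config", "run_screen", "render_text"]

log = logging.getLogger(__name__)

DEFAULT_PARAMS: dict = {
    "probe_radius": 1.4,
    "n_sphere_points": 960,
    "hotspot_thresholds": [100.0, 50.0],
    "exposure_threshold": 0.2,
    "rare_frequency_threshold": 0.02,
    "contact_cutoff": 4.5,
    "h_cutoff": 0.72,
    "scale": "black_mould",
    "acsins_window": [500.0, 560.0],
    "pairing_policy": "ca",
}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON screen configuration and validate its shape."""
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict) or "inputs" not in config:
        raise ValueError(f"config {path}: expected a mapping with an 'inputs' section")
    unknown = set(config) - {"inputs", "params", "candidate"}
    if unknown:
        raise ValueError(f"config {path}: unknown top-level keys {sorted(unknown)}")
    for key, value in config["inputs"].items():
        if isinstance(value, str) and not Path(value).exists():
            raise ValueError(f"config {path}: input file {value!r} ({key}) does not exist")
    return config


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _key_str(key) -> str:
    return str(key)


def _load_structure(inputs: dict, which: str, params: dict):
    path = inputs.get(which)
    if path is None:
        return None
    st = read_structure(path)
    numbering = inputs.get(f"{which}_numbering")
    if numbering:
        apply_numbering(st, load_numbering_csv(numbering), strict=False)
    return st


def run_screen(config: dict | str | Path) -> dict:
    """Run the full developability screen described by ``config``.

    The config has an ``inputs`` section (paths: ``structure``,
    ``structure_numbering``, ``reference_structure``,
    ``reference_structure_numbering``, ``fasta``, ``germline_table``,
    ``binding_csv``, ``binding_reference_csv``, ``spectrum_csv``,
    ``spectrum_control_csv``, ``sec_standards_csv`` plus scalar
    ``sec_retention_ml``, and ``interface_groups`` as two chain lists) and a
    ``params`` section overriding :data:`DEFAULT_PARAMS`. Missing optional
    inputs skip their stage and are recorded under ``stages``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    inputs = config.get("inputs", {})
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    report: dict = {
        "candidate": config.get("candidate", "unnamed"),
        "provenance": {
            "tool_version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "parameters": params,
            "input_hashes": {k: _sha256(v) for k, v in inputs.items()
                             if isinstance(v, str) and Path(v).exists()},
        },
        "stages": {},
    }
    stages = report["stages"]
    sasa_params = SasaParams(probe_radius=params["probe_radius"],
                             n_sphere_points=params["n_sphere_points"])
    scale = load_scale(params["scale"])

    structure = _load_structure(inputs, "structure", params)
    profile = None
    if structure is None:
        stages["structure"] = "absent"
    else:
        stages["structure"] = "ok"
        sasa = compute_sasa(structure, sasa_params)
        profile = score_profile(sasa, structure, scale)
        regions = aggregate_regions(profile)
        hotspots = classify_hotspots(profile, tuple(params["hotspot_thresholds"]))
        report["hydrophobicity"] = {
            "total_per_chain": profile.total_per_chain(),
            "region_scores": {f"{c}:{r}": v for (c, r), v in sorted(regions.items())},
            "per_residue": {_key_str(r.key): round(r.score, 3) for r in profile.residues},
            "hotspots": {
                "elevated": [_key_str(k) for k in hotspots.elevated],
                "moderate": [_key_str(k) for k in hotspots.moderate],
                "thresholds": list(hotspots.thresholds),
            },
        }
        oxidation = flag_exposed_oxidation_sites(structure, sasa,
                                                 params["exposure_threshold"])
        report.setdefault("liabilities", {})["oxidation_exposed"] = [
            {"residue": h.context, "detail": h.detail} for h in oxidation]

        groups = inputs.get("interface_groups")
        if groups:
            group_a, group_b = groups
            contacts = find_intergroup_contacts(structure, group_a, group_b,
                                                params["contact_cutoff"])
            buried = buried_sasa(structure, group_a, group_b, sasa_params)
            summary = summarize_interface(contacts, profile, params["h_cutoff"], buried)
            report["interface"] = {
                "n_contacts": len(contacts),
                "contact_residues_a": [_key_str(k) for k in summary.contact_residues_a],
                "contact_residues_b": [_key_str(k) for k in summary.contact_residues_b],
                "hydrophobic_fraction": summary.hydrophobic_fraction,
                "top_residues": [[_key_str(k), round(v, 2)] for k, v in summary.top_residues],
            }
            stages["interface"] = "ok"
        else:
            stages["interface"] = "absent"

    # sequence liabilities: explicit FASTA, else chains of the structure
    sequences: dict[str, str] = {}
    if inputs.get("fasta"):
        for record in SeqIO.parse(inputs["fasta"], "fasta"):
            sequences[record.id] = str(record.seq).upper()
    elif structure is not None:
        for cid in structure.chain_ids():
            sequences[cid] = extract_chain_sequence(structure, cid)
    if sequences:
        motif_hits = {
            name: [{"kind": h.kind, "position": h.position, "motif": h.matched_text,
                    "context": h.context} for h in scan_motifs(seq)]
            for name, seq in sequences.items()
        }
        report.setdefault("liabilities", {})["motifs"] = motif_hits
        stages["sequence"] = "ok"
    else:
        stages["sequence"] = "absent"

    if inputs.get("germline_table") and structure is not None:
        table = load_germline_csv(inputs["germline_table"])
        labeled = [(r.scheme_label, r.key.aa, r.region)
                   for r in structure.iter_residues() if r.scheme_label]
        rare = flag_rare_framework_residues(labeled, table,
                                            params["rare_frequency_threshold"])
        report["liabilities"]["rare_framework"] = [
            {"label": h.scheme_label, "aa": h.matched_text, "detail": h.detail}
            for h in rare]
        stages["rare_framework"] = "ok"
    else:
        stages["rare_framework"] = "absent"

    # immunogenicity is an external prediction; the slot is pass-through only
    report.setdefault("liabilities", {})["immunogenicity"] = inputs.get(
        "immunogenicity_epitopes", None)

    reference = _load_structure(inputs, "reference_structure", params)
    if reference is not None and structure is not None:
        ref_sasa = compute_sasa(reference, sasa_params)
        ref_profile = score_profile(ref_sasa, reference, scale)
        delta = diff_profiles(ref_profile, profile)
        coords_a, coords_b, paired, unpaired = pair_atoms(
            reference, structure, policy=params["pairing_policy"])
        sup = kabsch_superpose(coords_a, coords_b)
        try:
            zb = normalize_bfactors(list(residue_bfactors(structure).values()))
            bfac = {"mu": zb.mu, "sigma": zb.sigma}
        except ValueError:
            bfac = None
        report["comparison"] = {
            "rmsd_A": sup.rmsd,
            "n_atoms_paired": sup.n_atoms_paired,
            "pairing_policy": params["pairing_policy"],
            "unpaired_labels": unpaired,
            "delta_sasa": {k: round(v, 3) for k, v in sorted(delta.delta_sasa.items())},
            "delta_score": {k: round(v, 3) for k, v in sorted(delta.delta_score.items())},
            "normalized_bfactors": bfac,
        }
        stages["comparison"] = "ok"
    else:
        stages["comparison"] = "absent"

    assay_section: dict = {}
    if inputs.get("binding_csv"):
        curve = _read_binding(inputs["binding_csv"])
        fit = fit_4pl(curve)
        assay_section["binding"] = {
            "ec50_pM": fit.ec50, "hill": fit.hill, "bottom": fit.bottom,
            "top": fit.top, "converged": fit.converged,
        }
        if inputs.get("binding_reference_csv"):
            ref_fit = fit_4pl(_read_binding(inputs["binding_reference_csv"]))
            assay_section["binding"]["relative_potency_pct"] = relative_potency(
                ref_fit.ec50, fit.ec50)
    if inputs.get("spectrum_csv"):
        fit = acsins_lambda_max(_read_spectrum(inputs["spectrum_csv"]),
                                tuple(params["acsins_window"]))
        assay_section["acsins"] = {"lambda_max_nm": fit.lambda_max, "valid": fit.valid}
        if inputs.get("spectrum_control_csv"):
            control = acsins_lambda_max(_read_spectrum(inputs["spectrum_control_csv"]),
                                        tuple(params["acsins_window"]))
            assay_section["acsins"]["delta_lambda_max_nm"] = acsins_shift(fit, control)
    if inputs.get("sec_standards_csv"):
        import pandas as pd
        df = pd.read_csv(inputs["sec_standards_csv"])
        calib = SecCalibration(list(zip(df["mw_kda"], df["retention_ml"])))
        assay_section["sec"] = {"slope": calib.slope, "intercept": calib.intercept}
        if inputs.get("sec_retention_ml") is not None:
            assay_section["sec"]["mw_kda"] = sec_mw_estimate(
                float(inputs["sec_retention_ml"]), calib)
    if assay_section:
        report["assays"] = assay_section
        stages["assays"] = "ok"
    else:
        stages["assays"] = "absent"
    return report


def _read_binding(path: str | Path) -> BindingCurve:
    import pandas as pd
    df = pd.read_csv(path)
    return BindingCurve(df["concentration_pM"].to_numpy(), df["response"].to_numpy())


def _read_spectrum(path: str | Path) -> Spectrum:
    import pandas as pd
    df = pd.read_csv(path)
    return Spectrum(df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy())


def render_text(report: dict) -> str:
    """Human-readable summary of a screen report."""
    lines = [f"Developability screen — candidate {report['candidate']}"]
    stages = report.get("stages", {})
    lines.append("stages: " + ", ".join(f"{k}={v}" for k, v in stages.items()))
    hydro = report.get("hydrophobicity")
    if hydro:
        lines.append("chain totals: " + ", ".join(
            f"{c}: {v:.1f}" for c, v in hydro["total_per_chain"].items()))
        hs = hydro["hotspots"]
        lines.append(f"hotspots elevated: {', '.join(hs['elevated']) or 'none'}")
        lines.append(f"hotspots moderate: {', '.join(hs['moderate']) or 'none'}")
    liab = report.get("liabilities", {})
    if "motifs" in liab:
        n = sum(len(v) for v in liab["motifs"].values())
        lines.append(f"motif hits: {n}")
    if "oxidation_exposed" in liab:
        lines.append("exposed Met/Trp: " + (", ".join(
            h["residue"] for h in liab["oxidation_exposed"]) or "none"))
    if "comparison" in report:
        lines.append(f"RMSD vs reference: {report['comparison']['rmsd_A']:.3f} A "
                     f"({report['comparison']['n_atoms_paired']} atoms)")
    if "assays" in report:
        for name, values in report["assays"].items():
            lines.append(f"{name}: " + ", ".join(
                f"{k}={v}" for k, v in values.items()))
    return "\n".join(lines)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
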
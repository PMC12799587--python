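"""Plate-data I/O and results serialization.

Plate CSV dialect (one row per well):

    plate_id    plate identifier; one plate holds one dilution series
    well        A1..H12 style well id, unique within a plate
    assay       binding_saturation | binding_competition | functional
    design      functional | shift_control | shift_blocked | dip |
                stephenson_control | stephenson_combined | binding
    cell_line   cell-line label
    compound    analyte compound id (or 'radioligand' for saturation)
    role        test | total | nsb | basal | positive | reference
    conc_M      final in-well concentration, molar (test/saturation-nsb rows)
    replicate   1-based replicate index
    signal      raw reader signal
    fixed_reference / fixed_reference_conc_M      dip designs
    fixed_antagonist / fixed_antagonist_conc_M    shift / combined designs
    radioligand_conc_M / radioligand_logKd        binding plates

Files carry final in-well concentrations (the dilution arithmetic is the
data producer's job).  Unicode minus signs and micro signs are normalized
on read.  Results are emitted as TSVs plus a JSON summary and a plain-text
audit log.
"""
from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import ConcentrationSeries
from .pipeline import StudyResults
from .synthetic import Experiment, StudyBundle

__all__ = [
    "PlateRecord",
    "COLUMNS",
    "parse_concentration",
    "series_to_records",
    "write_plate_csv",
    "read_plate_csv",
    "bundle_to_series",
    "bundle_from_series",
    "write_ground_truth",
    "write_results",
]

COLUMNS = [
    "plate_id", "well", "assay", "design", "cell_line", "compound", "role",
    "conc_M", "replicate", "signal",
    "fixed_reference", "fixed_reference_conc_M",
    "fixed_antagonist", "fixed_antagonist_conc_M",
    "radioligand_conc_M", "radioligand_logKd",
]

_ROLES = {"test", "total", "nsb", "basal", "positive", "reference"}

_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9, "pm": 1e-12}


@dataclass
class PlateRecord:
    """One well of one plate in the documented CSV dialect."""

    plate_id: str
    well: str
    assay: str
    design: str
    cell_line: str
    compound: str
    role: str
    conc_M: Optional[float]
    replicate: int
    signal: float
    fixed_reference: Optional[str] = None
    fixed_reference_conc_M: Optional[float] = None
    fixed_antagonist: Optional[str] = None
    fixed_antagonist_conc_M: Optional[float] = None
    radioligand_conc_M: Optional[float] = None
    radioligand_logKd: Optional[float] = None


def parse_concentration(text: str) -> float:
    """Parse '10 nM' / '1.5e-8 M' / '3 uM' (micro sign accepted) to molar."""
    cleaned = str(text).strip().replace("−", "-").replace("µ", "u").replace("μ", "u")
    m = re.fullmatch(r"([-+0-9.eE]+)\s*([pnum]?[Mm])?", cleaned)
    if not m:
        raise ValueError(f"cannot parse concentration {text!r}")
    value = float(m.group(1))
    unit = (m.group(2) or "M").lower()
    return value * _UNITS[unit]


def _well_name(index: int) -> str:
    return f"{chr(ord('A') + index // 12)}{index % 12 + 1}"


def series_to_records(series: ConcentrationSeries, plate_id: str,
                      design: str = "functional") -> List[PlateRecord]:
    meta = series.meta
    fr = meta.get("fixed_reference")
    fa = meta.get("fixed_antagonist")
    common = dict(
        plate_id=plate_id,
        assay=meta.get("assay", "functional"),
        design=design,
        cell_line=meta.get("cell_line", ""),
        compound=series.compound_id,
        fixed_reference=fr[0] if fr else None,
        fixed_reference_conc_M=fr[1] if fr else None,
        fixed_antagonist=fa[0] if fa else None,
        fixed_antagonist_conc_M=fa[1] if fa else None,
        radioligand_conc_M=meta.get("radioligand_conc"),
        radioligand_logKd=meta.get("radioligand_logKd"),
    )
    records: List[PlateRecord] = []
    idx = 0
    for i, c in enumerate(series.conc):
        for r in range(series.n_replicates):
            records.append(PlateRecord(well=_well_name(idx), role="test", conc_M=float(c),
                                       replicate=r + 1, signal=float(series.signal[i, r]),
                                       **common))
            idx += 1
    for role_name, key in (("total", "total"), ("nsb", "nonspecific"), ("basal", "basal"),
                           ("positive", "positive"), ("reference", "reference")):
        if key not in series.controls:
            continue
        readings = np.asarray(series.controls[key], dtype=float)
        if readings.ndim == 2:  # per-concentration nonspecific wells (saturation)
            for i, c in enumerate(series.conc):
                for r in range(readings.shape[1]):
                    records.append(PlateRecord(well=_well_name(idx), role=role_name,
                                               conc_M=float(c), replicate=r + 1,
                                               signal=float(readings[i, r]), **common))
                    idx += 1
        else:
            for r, v in enumerate(readings):
                records.append(PlateRecord(well=_well_name(idx), role=role_name, conc_M=None,
                                           replicate=r + 1, signal=float(v), **common))
                idx += 1
    return records


def write_plate_csv(series_list, path, designs: Optional[List[str]] = None) -> None:
    """Write series to the plate CSV dialect, one plate per series."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS)
        writer.writeheader()
        for i, series in enumerate(series_list):
            design = designs[i] if designs else "functional"
            for rec in series_to_records(series, plate_id=f"P{i + 1:03d}", design=design):
                row = {k: getattr(rec, k) for k in COLUMNS}
                for k, v in row.items():
                    if isinstance(v, float):
                        row[k] = np.format_float_scientific(v, unique=True) \
                            if k.endswith("_M") else repr(v)
                writer.writerow(row)


def read_plate_csv(path) -> List[ConcentrationSeries]:
    """Read the plate CSV dialect back into ConcentrationSeries, one per plate.

    Malformed rows are rejected with their line numbers; duplicated wells
    within a plate and non-numeric signals are errors.
    """
    path = Path(path)
    text = path.read_text().replace("−", "-").replace("µ", "u").replace("μ", "u")
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames is None or not set(COLUMNS) <= set(reader.fieldnames):
        missing = set(COLUMNS) - set(reader.fieldnames or [])
        raise ValueError(f"{path.name}: missing required columns {sorted(missing)}")
    plates: Dict[str, List[dict]] = {}
    seen: set = set()
    for lineno, row in enumerate(reader, start=2):
        key = (row["plate_id"], row["well"])
        if key in seen:
            raise ValueError(f"{path.name}:{lineno}: duplicate well {row['well']!r} "
                             f"on plate {row['plate_id']!r}")
        seen.add(key)
        if row["role"] not in _ROLES:
            raise ValueError(f"{path.name}:{lineno}: unknown role {row['role']!r}")
        try:
            row["signal"] = float(row["signal"])
        except ValueError:
            raise ValueError(f"{path.name}:{lineno}: non-numeric signal {row['signal']!r}") from None
        plates.setdefault(row["plate_id"], []).append(row)

    out: List[ConcentrationSeries] = []
    for plate_id in plates:
        rows = plates[plate_id]
        first = rows[0]

        def opt_float(v):
            return None if v in ("", None) else float(v)

        meta = {
            "assay": first["assay"],
            "design": first["design"],
            "cell_line": first["cell_line"],
            "fixed_reference": (first["fixed_reference"], float(first["fixed_reference_conc_M"]))
            if first["fixed_reference"] else None,
            "fixed_antagonist": (first["fixed_antagonist"], float(first["fixed_antagonist_conc_M"]))
            if first["fixed_antagonist"] else None,
        }
        for k_csv, k_meta in (("radioligand_conc_M", "radioligand_conc"),
                              ("radioligand_logKd", "radioligand_logKd")):
            v = opt_float(first[k_csv])
            if v is not None:
                meta[k_meta] = v

        def matrix(selected):
            by_conc: Dict[float, Dict[int, float]] = {}
            for r in selected:
                by_conc.setdefault(float(r["conc_M"]), {})[int(r["replicate"])] = r["signal"]
            concs = sorted(by_conc)
            n_rep = max(len(v) for v in by_conc.values())
            mat = np.full((len(concs), n_rep), np.nan)
            for i, c in enumerate(concs):
                for rep, sig in by_conc[c].items():
                    mat[i, rep - 1] = sig
            return np.array(concs), mat

        conc, signal = matrix([r for r in rows if r["role"] == "test"])
        controls = {}
        for role, key in (("total", "total"), ("nsb", "nonspecific"), ("basal", "basal"),
                          ("positive", "positive"), ("reference", "reference")):
            sel = [r for r in rows if r["role"] == role]
            if not sel:
                continue
            if any(r["conc_M"] not in ("", None) for r in sel):
                _, controls[key] = matrix(sel)
            else:
                controls[key] = np.array([r["signal"] for r in sel])
        out.append(ConcentrationSeries(compound_id=first["compound"], conc=conc,
                                       signal=signal, controls=controls, meta=meta))
    return out


# ---------------------------------------------------------------------------
# bundle <-> flat series

def bundle_to_series(bundle: StudyBundle) -> Tuple[List[ConcentrationSeries], List[str]]:
    """Flatten a study bundle to (series, design) pairs for CSV export."""
    series, designs = [], []
    for exp in bundle.experiments:
        if exp.kind in ("binding_saturation", "binding_competition"):
            series.append(exp.series)
            designs.append("binding")
        elif exp.kind in ("functional", "dip"):
            series.append(exp.series)
            designs.append("functional" if exp.kind == "functional" else "dip")
        elif exp.kind == "shift":
            series.append(exp.control)
            designs.append("shift_control")
            for _, s in exp.blocked:
                series.append(s)
                designs.append("shift_blocked")
        elif exp.kind == "stephenson":
            series.append(exp.control)
            designs.append("stephenson_control")
            series.append(exp.series)
            designs.append("stephenson_combined")
    return series, designs


def bundle_from_series(series_list: List[ConcentrationSeries]) -> StudyBundle:
    """Reconstruct the experiment roster from plate series (CSV route)."""
    exps: List[Experiment] = []
    shift_groups: Dict[Tuple[str, str, str], Dict] = {}
    steph: Dict[str, Dict] = {}
    for s in series_list:
        design = s.meta.get("design", "functional")
        line = s.meta.get("cell_line", "")
        if s.meta.get("assay") == "binding_saturation":
            exps.append(Experiment("binding_saturation", line, s.compound_id, series=s))
        elif s.meta.get("assay") == "binding_competition":
            exps.append(Experiment("binding_competition", line, s.compound_id, series=s))
        elif design == "dip":
            exps.append(Experiment("dip", line, s.compound_id, series=s))
        elif design in ("shift_control", "shift_blocked"):
            fa = s.meta.get("fixed_antagonist")
            ant = fa[0] if fa else s.meta.get("shift_antagonist")
            key = (line, s.compound_id, ant)
            if design == "shift_control":
                # control carries no antagonist; match it to every group of
                # this agonist/line lacking a control
                for (l2, ag2, _), grp in shift_groups.items():
                    if l2 == line and ag2 == s.compound_id and grp.get("control") is None:
                        grp["control"] = s
                shift_groups.setdefault((line, s.compound_id, None), {}) \
                    .setdefault("controls", []).append(s)
            else:
                grp = shift_groups.setdefault(key, {"control": None, "blocked": []})
                grp.setdefault("blocked", []).append((fa[1], s))
        elif design == "stephenson_control":
            steph.setdefault(line, {})["control"] = s
        elif design == "stephenson_combined":
            fa = s.meta.get("fixed_antagonist")
            steph.setdefault(line, {}).update(combined=s, partial=fa[0], P=fa[1])
        else:
            exps.append(Experiment("functional", line, s.compound_id, series=s))
    # attach controls to shift groups
    controls = {}
    for key, grp in list(shift_groups.items()):
        if key[2] is None:
            for s in grp.get("controls", []):
                controls[(key[0], key[1])] = s
            del shift_groups[key]
    for (line, agonist, ant), grp in shift_groups.items():
        ctrl = grp.get("control") or controls.get((line, agonist))
        if ctrl is None:
            raise ValueError(f"shift experiment {agonist}/{ant} in {line} lacks a control curve")
        blocked = sorted(grp["blocked"], key=lambda t: t[0])
        exps.append(Experiment("shift", line, agonist, control=ctrl, blocked=blocked,
                               antagonist_id=ant))
    for line, grp in steph.items():
        if "combined" in grp and "control" in grp:
            exps.append(Experiment("stephenson", line, grp["control"].compound_id,
                                   series=grp["combined"], control=grp["control"],
                                   partial_agonist=grp["partial"], P=grp["P"]))
    return StudyBundle(seed=-1, ground_truth={}, ground_truth_mutant={}, configs={},
                       experiments=exps, table_outcomes={}, expected_letters={})


def write_ground_truth(bundle: StudyBundle, path) -> None:
    """Flat key-value dump of the generative parameters, for recovery tests."""
    lines = [f"seed = {bundle.seed}"]
    for label, truth in (("", bundle.ground_truth), ("mutant.", bundle.ground_truth_mutant)):
        for cpd, gt in truth.items():
            prefix = f"{label}{cpd}"
            lines.append(f"{prefix}.mode = {gt.mode}")
            for f_ in ("logKd_cce", "logKd_sce", "efficacy_cce", "efficacy_sce"):
                v = getattr(gt, f_)
                if v is not None:
                    lines.append(f"{prefix}.{f_} = {v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# results emission

def affinity_frame(results: StudyResults) -> pd.DataFrame:
    rows = []
    for est in results.affinities:
        rows.append({
            "compound": est.compound_id, "cell_line": est.cell_line,
            "method": est.method,
            "logKd": None if est.is_censored else est.logKd,
            "se": est.se, "n": est.n,
            "censored": str(est.censored) if est.is_censored else "",
            "conformation": est.context.get("conformation", ""),
        })
    return pd.DataFrame(rows).sort_values(["compound", "cell_line", "method"],
                                          ignore_index=True)


def fits_frame(results: StudyResults) -> pd.DataFrame:
    rows = []
    for (cpd, line), choice in sorted({**results.functional_choices,
                                       **results.dip_choices}.items()):
        row = {"compound": cpd, "cell_line": line, "model": choice.chosen,
               "p_model": choice.p_value}
        fit = choice.candidates.get(choice.chosen)
        if choice.chosen == "one_site":
            fit = choice.candidates.get("one_site")
            if fit is not None:
                row.update(logEC50=fit.logEC50, Emax_pct=fit.Emax_pct)
        elif choice.chosen == "two_site":
            row.update(logEC1_50=fit.logEC1_50, logEC2_50=fit.logEC2_50,
                       site1_pct=fit.site1_pct, Emax_pct=fit.total_Emax_pct)
        elif choice.chosen == "dip":
            row.update(logIC50=fit.logIC50, logEC50=fit.logEC50, Smax_pct=fit.Smax_pct)
        rows.append(row)
    return pd.DataFrame(rows)


def classification_frame(results: StudyResults) -> pd.DataFrame:
    rows = []
    for cpd, profile in sorted(results.profiles.items()):
        rows.append({
            "compound": cpd,
            "A": profile.A.call, "B": profile.B.call,
            "C": profile.C.call, "D": profile.D.call,
            "A_gap": profile.numbers.get("A_gap"),
            "B_gap": profile.numbers.get("B_gap"),
            "evidence": profile.letters,
            "classification": results.classifications.get(cpd),
        })
    return pd.DataFrame(rows)


def write_results(results: StudyResults, out_dir) -> Dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("affinities", affinity_frame(results)),
                        ("fits", fits_frame(results)),
                        ("classification", classification_frame(results))):
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.6g")
        paths[name] = p
    audit = out / "audit.txt"
    audit.write_text("\n".join(results.audit) + "\n")
    paths["audit"] = audit
    summary = {
        "classifications": results.classifications,
        "evidence": {c: p.letters for c, p in results.profiles.items()},
        "loss_of_evidence": {c: {"lost": r.lost, "sce_lost": r.sce_lost}
                             for c, r in results.loss_reports.items()},
    }
    sp = out / "summary.json"
    sp.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    paths["summary"] = sp
    return paths
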
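"""End-to-end analysis driver.

Takes a :class:`~scepharm.synthetic.StudyBundle` (or the equivalent set of
plate series read from CSV), refits every experiment with the binding,
functional and shift analyses, applies the evidence rubric per cell line,
pools evidence across lines, classifies every compound, and builds the
wild-type vs mutant loss-of-evidence contrast where contrast lines exist.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

from .antagonism import ShiftExperiment, gaddum_kd, schild_fit, stephenson_kd
from .binding import competition_to_affinity, fit_competition, fit_saturation
from .core import AffinityEstimate
from .evidence import (
    CompoundLineData,
    EvidenceProfile,
    LossOfEvidenceReport,
    Thresholds,
    classify_compound,
    compare_lines,
    evaluate_evidence,
    pool_profiles,
)
from .functional import ModelChoice, fit_one_site, normalize_plate, select_cr_model
from .synthetic import REFERENCE_AGONIST, REFERENCE_ANTAGONIST, Experiment, StudyBundle

__all__ = ["StudyResults", "analyze_bundle"]


@dataclass
class StudyResults:
    thresholds: Thresholds
    affinities: List[AffinityEstimate] = field(default_factory=list)
    functional_choices: Dict[Tuple[str, str], ModelChoice] = field(default_factory=dict)
    dip_choices: Dict[Tuple[str, str], ModelChoice] = field(default_factory=dict)
    shift_estimates: Dict[Tuple[str, str, str], AffinityEstimate] = field(default_factory=dict)
    saturation_fits: Dict[str, object] = field(default_factory=dict)
    line_profiles: Dict[Tuple[str, str], EvidenceProfile] = field(default_factory=dict)
    profiles: Dict[str, EvidenceProfile] = field(default_factory=dict)
    classifications: Dict[str, str] = field(default_factory=dict)
    loss_reports: Dict[str, LossOfEvidenceReport] = field(default_factory=dict)
    audit: List[str] = field(default_factory=list)


def _fit_shift(exp: Experiment, results: StudyResults) -> AffinityEstimate:
    """Refit an antagonist-shift experiment and estimate the antagonist KD.

    Three or more antagonist concentrations go through Schild regression;
    fewer through Gaddum single-shift analysis (several concentrations
    combined as the mean of per-concentration log KDs).
    """
    ctrl_fit = fit_one_site(normalize_plate(exp.control))
    blocked_fits = [(b, fit_one_site(normalize_plate(s))) for b, s in exp.blocked]
    shift_exp = ShiftExperiment(
        agonist_fit_control=ctrl_fit,
        agonist_fits_blocked=blocked_fits,
        antagonist_id=exp.antagonist_id,
        agonist_id=exp.compound_id,
        cell_line=exp.cell_line,
    )
    conformation = "cce" if exp.compound_id == REFERENCE_AGONIST else "sce"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # parallel-shift deviations logged in the audit instead
        if len(blocked_fits) >= 3:
            sf = schild_fit(shift_exp)
            est = AffinityEstimate(
                logKd=sf.intercept_logKd, method="schild", se=sf.se_slope,
                n=sf.n_points, compound_id=exp.antagonist_id, cell_line=exp.cell_line,
                context={"agonist": exp.compound_id, "conformation": conformation,
                         "slope": sf.slope, "competitive": sf.competitive},
            )
            results.audit.append(
                f"schild {exp.antagonist_id} vs {exp.compound_id} [{exp.cell_line}]: "
                f"slope {sf.slope:.3f} +/- {sf.se_slope:.3f}, logKd {sf.intercept_logKd:.2f}"
            )
        else:
            est = gaddum_kd(shift_exp)
            est.context["conformation"] = conformation
            shown = f"logKd {est.logKd:.2f}" if not est.is_censored else f"censored {est.censored}"
            results.audit.append(
                f"gaddum {exp.antagonist_id} vs {exp.compound_id} [{exp.cell_line}]: {shown}"
            )
    return est


def analyze_bundle(bundle: StudyBundle, thresholds: Thresholds = Thresholds()) -> StudyResults:
    """Run the full pipeline on a simulated (or reconstructed) study."""
    results = StudyResults(thresholds=thresholds)
    th = thresholds

    for exp in bundle.experiments:
        if exp.kind == "binding_saturation":
            sat = fit_saturation(exp.series)
            results.saturation_fits[exp.cell_line] = sat
            results.affinities.append(AffinityEstimate(
                logKd=sat.logKd, method="saturation", se=sat.se_logKd,
                n=sat.n_points, compound_id=exp.compound_id, cell_line=exp.cell_line,
            ))
        elif exp.kind == "binding_competition":
            comp = fit_competition(exp.series)
            est = competition_to_affinity(
                comp,
                exp.series.meta["radioligand_conc"],
                10.0 ** exp.series.meta["radioligand_logKd"],
                compound_id=exp.compound_id, cell_line=exp.cell_line,
            )
            results.affinities.append(est)
        elif exp.kind == "functional":
            curve = normalize_plate(exp.series)
            results.functional_choices[(exp.compound_id, exp.cell_line)] = select_cr_model(
                curve, alpha=th.alpha)
        elif exp.kind == "dip":
            curve = normalize_plate(exp.series)
            results.dip_choices[(exp.compound_id, exp.cell_line)] = select_cr_model(
                curve, alpha=th.alpha)
        elif exp.kind == "shift":
            est = _fit_shift(exp, results)
            results.shift_estimates[(exp.antagonist_id, exp.compound_id, exp.cell_line)] = est
            results.affinities.append(est)
        elif exp.kind == "stephenson":
            ctrl_fit = fit_one_site(normalize_plate(exp.control))
            combined = normalize_plate(exp.series)
            combined.meta.setdefault("fixed_partial_agonist", exp.partial_agonist)
            est = stephenson_kd(ctrl_fit, combined, exp.P)
            est.compound_id = exp.partial_agonist
            est.cell_line = exp.cell_line
            est.context["conformation"] = "cce"
            results.affinities.append(est)
            results.audit.append(
                f"stephenson {exp.partial_agonist} [{exp.cell_line}]: logKd {est.logKd:.2f}"
            )
        else:
            raise ValueError(f"unknown experiment kind {exp.kind!r}")

    # assemble per-compound, per-line rubric inputs
    by_line: Dict[Tuple[str, str], CompoundLineData] = {}
    compounds = set(bundle.ground_truth) | set(bundle.ground_truth_mutant)
    lines = list(bundle.configs)
    for exp in bundle.experiments:
        compounds.add(exp.compound_id)
        if exp.antagonist_id:
            compounds.add(exp.antagonist_id)
        if exp.partial_agonist:
            compounds.add(exp.partial_agonist)
        if exp.cell_line not in lines:
            lines.append(exp.cell_line)
    compounds.discard("radioligand")
    def background(line: str) -> str:
        return bundle.line_backgrounds.get(line, line)

    for cpd in sorted(compounds):
        for line in lines:
            data = CompoundLineData(compound_id=cpd, cell_line=line)
            # affinities transfer between lines expressing the same receptor
            data.affinities = [e for e in results.affinities
                               if e.compound_id == cpd
                               and background(e.cell_line) == background(line)]
            data.functional_choice = results.functional_choices.get((cpd, line))
            data.antagonist_vs_self = results.shift_estimates.get(
                (REFERENCE_ANTAGONIST, cpd, line))
            data.antagonist_vs_reference = results.shift_estimates.get(
                (REFERENCE_ANTAGONIST, REFERENCE_AGONIST, line))
            data.dip_choice = results.dip_choices.get((cpd, line))
            if (data.affinities or data.functional_choice is not None
                    or data.dip_choice is not None):
                by_line[(cpd, line)] = data
                results.line_profiles[(cpd, line)] = evaluate_evidence(data, th)

    # pooled classification over the stable (non-contrast) lines
    pool_lines = [l for l in lines if l not in bundle.contrast_lines]
    for cpd in sorted(compounds):
        profs = [results.line_profiles[(cpd, l)] for l in pool_lines
                 if (cpd, l) in results.line_profiles]
        if not profs:
            continue
        pooled = pool_profiles(profs)
        results.profiles[cpd] = pooled
        try:
            results.classifications[cpd] = classify_compound(pooled)
        except ValueError as err:
            results.classifications[cpd] = "contradictory"
            results.audit.append(f"CONTRADICTION {cpd}: {err}")
            continue
        results.audit.append(
            f"classify {cpd}: {results.classifications[cpd]} "
            f"[evidence {pooled.letters or '-'}]"
        )

    # wild-type vs mutant loss-of-evidence contrast
    if len(bundle.contrast_lines) == 2:
        first, second = bundle.contrast_lines
        for cpd in bundle.contrast_compounds:
            p1 = results.line_profiles.get((cpd, first))
            p2 = results.line_profiles.get((cpd, second))
            if p1 is None or p2 is None:
                continue
            report = compare_lines(p1, p2)
            results.loss_reports[cpd] = report
            results.audit.append(
                f"contrast {cpd}: lost {''.join(report.lost) or '-'} "
                f"({report.first_classification} -> {report.second_classification})"
            )
    return results
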
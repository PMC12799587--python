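"""The four-criterion evidence rubric for secondary-conformation activation.

A ligand's agonism is attributed to the secondary conformation ensemble
(SCE) rather than the classical catecholamine conformation (CCE) when:

A. its functional EC50 sits substantially (>= 10-fold by default) above its
   CCE KD — binding half the receptors produces no response, yet much
   higher concentrations stimulate;
B. a reference CCE antagonist needs substantially higher concentrations to
   inhibit the ligand's response than to inhibit a reference CCE agonist
   (the apparent antagonist KD worsens by >= 10-fold);
C. the ligand's concentration-response curve is biphasic (two-site model
   selected), first component readily antagonized, second resistant;
D. against a fixed reference agonist the ligand first inhibits (high-
   affinity CCE occupancy) and then stimulates, producing a dip.

Each call carries the numbers it was made from; classification follows a
fixed decision order over the pooled calls.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core import AffinityEstimate
from .functional import ModelChoice, OneSiteFit, TwoSiteFit

__all__ = [
    "Thresholds",
    "EvidenceCall",
    "CompoundLineData",
    "EvidenceProfile",
    "LossOfEvidenceReport",
    "evaluate_evidence",
    "pool_profiles",
    "classify_compound",
    "compare_lines",
    "CLASSIFICATIONS",
]

CLASSIFICATIONS = (
    "no_interaction",
    "neutral_antagonist",
    "cce_agonist",
    "sce_agonist",
    "biphasic_agonist",
)

POSITIVE, NEGATIVE, INDETERMINATE = "positive", "negative", "indeterminate"


@dataclass(frozen=True)
class Thresholds:
    """Configurable rubric thresholds (log10 units unless noted).

    ``a_gap_log`` / ``b_gap_log``: what counts as "substantially higher".
    The observed positive cases sit at gaps >= 1.9 and the negative ones at
    <= 0.8, so 1.0 separates them with margin on both sides.
    ``min_agonist_emax_pct``: smallest fitted maximum (percent isoprenaline)
    accepted as real agonism rather than noise.  ``se_multiplier``: a gap
    must also exceed this many pooled SEs to be called.
    """

    a_gap_log: float = 1.0
    b_gap_log: float = 1.0
    min_agonist_emax_pct: float = 10.0
    se_multiplier: float = 2.0
    alpha: float = 0.05
    dr_tolerance: float = 1.2
    # affinities no better than this (log10 molar) do not count as receptor
    # interaction -- the same >= -5 region that defines a non-binder
    interaction_floor_log: float = -5.0


@dataclass
class EvidenceCall:
    call: str  # positive | negative | indeterminate
    gap: Optional[float] = None
    detail: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.call == POSITIVE


@dataclass
class CompoundLineData:
    """Everything the rubric needs about one compound in one cell line."""

    compound_id: str
    cell_line: str
    affinities: List[AffinityEstimate] = field(default_factory=list)
    functional_choice: Optional[ModelChoice] = None  # compound-alone curve
    antagonist_vs_self: Optional[AffinityEstimate] = None  # reference antagonist vs this compound's response
    antagonist_vs_reference: Optional[AffinityEstimate] = None  # same antagonist vs reference agonist
    dip_choice: Optional[ModelChoice] = None  # compound vs fixed reference agonist


@dataclass
class EvidenceProfile:
    compound_id: str
    cell_line: str
    A: EvidenceCall
    B: EvidenceCall
    C: EvidenceCall
    D: EvidenceCall
    has_agonism: bool
    affinity_present: bool
    affinity_observed: bool  # any affinity record at all, censored or not
    classification: Optional[str] = None
    numbers: dict = field(default_factory=dict)

    @property
    def letters(self) -> str:
        return "".join(l for l, c in zip("ABCD", (self.A, self.B, self.C, self.D)) if c)


@dataclass
class LossOfEvidenceReport:
    compound_id: str
    lost: List[str]
    gained: List[str]
    first_classification: str
    second_classification: str
    sce_lost: bool


def _best_cce_affinity(affinities: List[AffinityEstimate],
                       floor: float = -5.0) -> Optional[AffinityEstimate]:
    """Most reliable CCE affinity: functional (Stephenson/Gaddum/Schild) over binding."""
    functional, bound = [], []
    for est in affinities:
        if est.is_censored or est.context.get("conformation") == "sce" \
                or est.logKd >= floor:
            continue
        if est.method in ("stephenson", "gaddum", "schild"):
            functional.append(est)
        else:
            bound.append(est)
    pool = functional or bound
    return pool[0] if pool else None


def _primary_ec50(choice: ModelChoice, min_emax: float):
    """EC50 (and SE, top) of the agonist curve; first component if two-site."""
    if choice.chosen == "one_site":
        fit: OneSiteFit = choice.candidates["one_site"]
        if fit.Emax_pct < min_emax or not fit.identifiable:
            return None
        # an EC50 within 0.6 log of the top tested concentration never
        # reached half its own plateau: the "maximum" is extrapolation,
        # not an observed agonist response
        top = choice.diagnostics.get("log_conc_max")
        if top is not None and fit.logEC50 > top - 0.6:
            return None
        return fit.logEC50, fit.se_logEC50, fit.Emax_pct
    if choice.chosen == "two_site":
        fit2: TwoSiteFit = choice.candidates["two_site"]
        if fit2.total_Emax_pct < min_emax:
            return None
        return fit2.logEC1_50, 0.0, fit2.total_Emax_pct
    return None


def evaluate_evidence(data: CompoundLineData, thresholds: Thresholds = Thresholds()) -> EvidenceProfile:
    """Apply criteria A-D to one compound in one cell line.

    Missing or censored inputs yield indeterminate calls, never negatives:
    in particular D is indeterminate (not negative) when no fixed-reference
    experiment was run.
    """
    th = thresholds
    numbers: dict = {}

    ec = None if data.functional_choice is None else _primary_ec50(
        data.functional_choice, th.min_agonist_emax_pct)
    has_agonism = ec is not None
    kd = _best_cce_affinity(data.affinities, floor=th.interaction_floor_log)
    affinity_present = any(not e.is_censored and e.logKd < th.interaction_floor_log
                           for e in data.affinities)
    affinity_observed = bool(data.affinities)

    # A: EC50 substantially above the CCE KD.  An EC50 within 0.6 log of the
    # top tested concentration has no defined plateau and cannot support a
    # call either way.
    top = None
    if data.functional_choice is not None:
        top = data.functional_choice.diagnostics.get("log_conc_max")
    if ec is None or kd is None:
        a = EvidenceCall(INDETERMINATE)
    elif top is not None and ec[0] > top - 0.6:
        a = EvidenceCall(INDETERMINATE,
                         detail={"reason": "EC50 too close to the top tested concentration",
                                 "logEC50": ec[0], "log_conc_max": top})
    else:
        log_ec50, se_ec, _ = ec
        gap = log_ec50 - kd.logKd
        pooled_se = float(np.hypot(se_ec or 0.0, kd.se or 0.0))
        ok = gap >= th.a_gap_log and gap > th.se_multiplier * pooled_se
        a = EvidenceCall(POSITIVE if ok else NEGATIVE, gap=gap,
                         detail={"logEC50": log_ec50, "logKd_cce": kd.logKd,
                                 "kd_method": kd.method, "pooled_se": pooled_se})
        numbers["A_gap"] = gap

    # B: reference antagonist KD worsens against this compound's response
    vs_self, vs_ref = data.antagonist_vs_self, data.antagonist_vs_reference
    if vs_self is None or vs_ref is None or vs_ref.is_censored:
        b = EvidenceCall(INDETERMINATE)
    elif vs_self.is_censored:
        if vs_self.censored.direction == ">" and (vs_self.censored.bound - vs_ref.logKd) >= th.b_gap_log:
            b = EvidenceCall(POSITIVE, gap=vs_self.censored.bound - vs_ref.logKd,
                             detail={"censored": str(vs_self.censored)})
        else:
            b = EvidenceCall(INDETERMINATE)
    else:
        gap = vs_self.logKd - vs_ref.logKd
        pooled_se = float(np.hypot(vs_self.se or 0.0, vs_ref.se or 0.0))
        ok = gap >= th.b_gap_log and gap > th.se_multiplier * pooled_se
        b = EvidenceCall(POSITIVE if ok else NEGATIVE, gap=gap,
                         detail={"kd_vs_self": vs_self.logKd, "kd_vs_reference": vs_ref.logKd,
                                 "pooled_se": pooled_se})
        numbers["B_gap"] = gap

    # C: biphasic concentration-response curve
    if data.functional_choice is None:
        c = EvidenceCall(INDETERMINATE)
    else:
        chosen = data.functional_choice.chosen
        c = EvidenceCall(POSITIVE if chosen == "two_site" else NEGATIVE,
                         detail={"model": chosen,
                                 "p_value": data.functional_choice.p_value})

    # D: dip against a fixed reference agonist
    if data.dip_choice is None:
        d = EvidenceCall(INDETERMINATE)
    else:
        dip_fit = data.dip_choice.candidates.get("dip")
        d = EvidenceCall(POSITIVE if data.dip_choice.chosen == "dip" else NEGATIVE,
                         detail={"model": data.dip_choice.chosen,
                                 "logIC50": getattr(dip_fit, "logIC50", None),
                                 "logEC50": getattr(dip_fit, "logEC50", None)})

    return EvidenceProfile(
        compound_id=data.compound_id, cell_line=data.cell_line,
        A=a, B=b, C=c, D=d,
        has_agonism=has_agonism,
        affinity_present=affinity_present,
        affinity_observed=affinity_observed,
        numbers=numbers,
    )


def _pool_call(calls: List[EvidenceCall]) -> EvidenceCall:
    for call in calls:
        if call.call == POSITIVE:
            return call
    negatives = [c for c in calls if c.call == NEGATIVE]
    if negatives:
        return negatives[0]
    return EvidenceCall(INDETERMINATE)


def pool_profiles(profiles: List[EvidenceProfile]) -> EvidenceProfile:
    """Accumulate evidence across cell lines: a criterion positive anywhere
    is positive overall (low- and high-expression lines reveal different
    phenomena), negative only if tested and negative everywhere."""
    if not profiles:
        raise ValueError("nothing to pool")
    ids = {p.compound_id for p in profiles}
    if len(ids) != 1:
        raise ValueError(f"cannot pool different compounds: {sorted(ids)}")
    return EvidenceProfile(
        compound_id=profiles[0].compound_id,
        cell_line="pooled",
        A=_pool_call([p.A for p in profiles]),
        B=_pool_call([p.B for p in profiles]),
        C=_pool_call([p.C for p in profiles]),
        D=_pool_call([p.D for p in profiles]),
        has_agonism=any(p.has_agonism for p in profiles),
        affinity_present=any(p.affinity_present for p in profiles),
        affinity_observed=any(p.affinity_observed for p in profiles),
        numbers={k: v for p in profiles for k, v in p.numbers.items()},
    )


def classify_compound(profile: EvidenceProfile) -> str:
    """Fixed decision order over the pooled evidence.

    no_interaction (no quantifiable affinity anywhere, no agonism) ->
    neutral_antagonist (binds, no agonism) -> biphasic_agonist (C) ->
    sce_agonist (A with B, or D, or A with B untestable) -> cce_agonist.
    """
    if not profile.affinity_present and profile.has_agonism and profile.affinity_observed:
        # affinity was measured, censored everywhere, yet the compound fits
        # an agonist curve: flag for audit rather than classify
        raise ValueError(
            f"{profile.compound_id}: fitted agonist curve but every measured affinity "
            "is censored; profile contradictory"
        )
    if not profile.affinity_present and not profile.has_agonism:
        profile.classification = "no_interaction"
    elif not profile.has_agonism:
        profile.classification = "neutral_antagonist"
    elif profile.C:
        profile.classification = "biphasic_agonist"
    elif (profile.A and profile.B) or profile.D or \
            (profile.A and profile.B.call == INDETERMINATE):
        profile.classification = "sce_agonist"
    else:
        profile.classification = "cce_agonist"
    return profile.classification


def compare_lines(profile_first: EvidenceProfile, profile_second: EvidenceProfile) -> LossOfEvidenceReport:
    """Per-criterion contrast between two receptor backgrounds (e.g. wild
    type vs the TM4 triple mutant): which positive calls disappear.

    ``sce_lost`` flags the loss-of-evidence pattern: at least one criterion
    positive in the first background turns negative in the second while the
    compound keeps a CCE-type classification there.
    """
    if profile_first.compound_id != profile_second.compound_id:
        raise ValueError(
            f"mismatched compounds: {profile_first.compound_id} vs {profile_second.compound_id}"
        )
    lost, gained = [], []
    for letter in "ABCD":
        first: EvidenceCall = getattr(profile_first, letter)
        second: EvidenceCall = getattr(profile_second, letter)
        if first.call == POSITIVE and second.call == NEGATIVE:
            lost.append(letter)
        if first.call == NEGATIVE and second.call == POSITIVE:
            gained.append(letter)
    cls1 = profile_first.classification or classify_compound(profile_first)
    cls2 = profile_second.classification or classify_compound(profile_second)
    sce_lost = bool(lost) and cls2 in ("cce_agonist", "neutral_antagonist")
    return LossOfEvidenceReport(
        compound_id=profile_first.compound_id,
        lost=lost, gained=gained,
        first_classification=cls1, second_classification=cls2,
        sce_lost=sce_lost,
    )
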
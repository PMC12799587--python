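"""Affinity estimation from agonist curve shifts.

Gaddum single-shift analysis, Schild regression over several antagonist
concentrations, and Stephenson's null method for the affinity of a partial
agonist, plus the log ratio of a ligand's affinities for the two receptor
conformations.

Gaddum:     DR = 1 + [B]/KD          (DR = EC50 shift caused by antagonist B)
Schild:     log(DR - 1) = log[B] - log KD    (slope 1 <=> simple competition)
Stephenson: KD = Y*[P]/(1 - Y),  Y = (A2 - A1)/A3
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
from scipy import optimize, stats

from .core import AffinityEstimate, Censor
from .functional import LOG_BOUNDS, NormalizedCurve, OneSiteFit, one_site_response

__all__ = [
    "ShiftExperiment",
    "SchildFit",
    "StephensonInputs",
    "ParallelShiftWarning",
    "gaddum_kd",
    "schild_fit",
    "stephenson_kd",
    "stephenson_from_points",
    "conformation_ratio",
]


class ParallelShiftWarning(UserWarning):
    """Blocked-curve maximum differs from control beyond tolerance."""


@dataclass
class ShiftExperiment:
    """An agonist curve alone and in the presence of fixed antagonist levels."""

    agonist_fit_control: OneSiteFit
    agonist_fits_blocked: List[Tuple[float, OneSiteFit]]  # (antagonist molar, fit)
    antagonist_id: str
    agonist_id: str
    cell_line: str = ""

    def __post_init__(self) -> None:
        concs = [b for b, _ in self.agonist_fits_blocked]
        if any(b <= 0 for b in concs):
            raise ValueError("antagonist concentrations must be positive")
        if len(set(concs)) != len(concs):
            raise ValueError("antagonist concentrations must be distinct")

    def dose_ratios(self) -> List[Tuple[float, float]]:
        """(antagonist conc, DR) per blocked curve; DR depends only on EC50s."""
        ec_c = self.agonist_fit_control.logEC50
        return [(b, 10.0 ** (fit.logEC50 - ec_c)) for b, fit in self.agonist_fits_blocked]


@dataclass
class SchildFit:
    slope: float
    se_slope: float
    intercept_logKd: float
    n_points: int
    r_squared: float
    competitive: bool = True


@dataclass
class StephensonInputs:
    """Matched-response concentrations for one Stephenson read-out.

    [P]: fixed partial-agonist concentration.  A1: full-agonist concentration
    matching the partial agonist's own plateau; A2: full-agonist concentration
    at a chosen higher response; A3: full-agonist concentration producing that
    same response in the presence of the partial agonist.
    """

    P: float
    A1: float
    A2: float
    A3: float

    @property
    def Y(self) -> float:
        y = (self.A2 - self.A1) / self.A3
        if not 0.0 < y < 1.0:
            raise ValueError(f"Y = (A2-A1)/A3 must lie in (0,1), got {y:.3g}")
        return y

    @property
    def kd(self) -> float:
        y = self.Y
        return y * self.P / (1.0 - y)


def stephenson_from_points(P: float, A1: float, A2: float, A3: float) -> float:
    """KD (molar) from one matched-response quadruple."""
    return StephensonInputs(P=P, A1=A1, A2=A2, A3=A3).kd


def _check_parallel(exp: ShiftExperiment, tol_pct: float) -> None:
    e0 = exp.agonist_fit_control.Emax_pct
    for b, fit in exp.agonist_fits_blocked:
        if abs(fit.Emax_pct - e0) > tol_pct:
            warnings.warn(
                f"{exp.antagonist_id} at {b:.3g} M changes {exp.agonist_id} Emax "
                f"({e0:.1f} -> {fit.Emax_pct:.1f}%); parallel-shift assumption suspect",
                ParallelShiftWarning,
                stacklevel=3,
            )


def gaddum_kd(
    experiment: ShiftExperiment,
    dr_tolerance: float = 1.2,
    emax_tol_pct: float = 15.0,
    se_multiplier: float = 2.0,
) -> AffinityEstimate:
    """Antagonist KD from EC50 dose ratios, one per blocked curve.

    KD = [B]/(DR - 1); several antagonist concentrations are combined as the
    mean of the per-concentration log KDs.  A shift below ``dr_tolerance``,
    or one not exceeding ``se_multiplier`` pooled EC50 standard errors,
    carries no information at triplicate noise and yields the censored
    "no shift at [B]" estimate instead of an extrapolated point value.
    """
    if not experiment.agonist_fits_blocked:
        raise ValueError("need at least one blocked curve")
    _check_parallel(experiment, emax_tol_pct)
    logs, ses = [], []
    top_b = max(b for b, _ in experiment.agonist_fits_blocked)
    ctrl = experiment.agonist_fit_control
    for (b, dr), (_, fit) in zip(experiment.dose_ratios(),
                                 experiment.agonist_fits_blocked):
        shift_log = fit.logEC50 - ctrl.logEC50
        se_shift = float(np.hypot(fit.se_logEC50 or 0.0, ctrl.se_logEC50 or 0.0))
        if dr >= dr_tolerance and shift_log > se_multiplier * se_shift:
            logs.append(np.log10(b / (dr - 1.0)))
            # d logKd / d logDR = -DR/(DR-1)
            ses.append(se_shift * dr / (dr - 1.0))
    if not logs:
        return AffinityEstimate(
            logKd=float("nan"), method="gaddum", n=len(experiment.agonist_fits_blocked),
            censored=Censor(">", float(np.log10(top_b))),
            compound_id=experiment.antagonist_id, cell_line=experiment.cell_line,
            context={"agonist": experiment.agonist_id, "no_shift_at": top_b},
        )
    if len(logs) > 1:
        se = float(max(np.std(logs, ddof=1) / np.sqrt(len(logs)),
                       np.sqrt(np.mean(np.square(ses))) / np.sqrt(len(logs))))
    else:
        se = float(ses[0])
    return AffinityEstimate(
        logKd=float(np.mean(logs)), method="gaddum", se=se, n=len(logs),
        compound_id=experiment.antagonist_id, cell_line=experiment.cell_line,
        context={"agonist": experiment.agonist_id},
    )


def schild_fit(experiment: ShiftExperiment) -> SchildFit:
    """Ordinary least-squares Schild line through (log[B], log(DR-1)).

    The fitted x-intercept gives log KD; ``competitive`` is set when the
    slope's 95% interval covers 1.  Points with DR <= 1 carry no shift
    information and are excluded with a warning.
    """
    pts = []
    for b, dr in experiment.dose_ratios():
        if dr > 1.0:
            pts.append((np.log10(b), np.log10(dr - 1.0)))
        else:
            warnings.warn(
                f"DR <= 1 at {b:.3g} M {experiment.antagonist_id}; point excluded from Schild plot",
                UserWarning, stacklevel=2,
            )
    if len(pts) < 3:
        raise ValueError("Schild regression needs >= 3 antagonist concentrations with DR > 1")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    reg = stats.linregress(x, y)
    log_kd = -reg.intercept / reg.slope  # x-intercept
    se = float(reg.stderr) if np.isfinite(reg.stderr) else 0.0
    competitive = abs(reg.slope - 1.0) <= 1.96 * se if se > 0 else np.isclose(reg.slope, 1.0)
    return SchildFit(
        slope=float(reg.slope), se_slope=se, intercept_logKd=float(log_kd),
        n_points=len(pts), r_squared=float(reg.rvalue**2), competitive=bool(competitive),
    )


def _fit_offset_one_site(curve: NormalizedCurve):
    """Fit plateau + Emax*A/(A+EC50) to a combined (full + fixed partial agonist) curve."""
    conc = np.repeat(curve.conc, curve.n_replicates)
    y = curve.response.ravel()

    def residuals(p):
        s0, emax, log_ec50 = p
        return s0 + one_site_response(conc, emax, log_ec50) - y

    lo, hi = np.log10(curve.conc[0]), np.log10(curve.conc[-1])
    s0_guess = float(np.mean(curve.response[0]))
    top = float(np.mean(curve.response[-1]))
    best = None
    for g in np.linspace(lo, hi, 5):
        res = optimize.least_squares(
            residuals, [s0_guess, max(top - s0_guess, 1.0), g],
            bounds=([-50.0, 0.0, LOG_BOUNDS[0]], [250.0, 250.0, LOG_BOUNDS[1]]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    s0, emax, log_ec50 = best.x
    return float(s0), float(emax), float(log_ec50)


def stephenson_kd(
    control_curve: OneSiteFit,
    combined_curve: NormalizedCurve,
    P: float,
    n_levels: int = 5,
    plateau_margin_pct: float = 5.0,
    top_fraction: float = 0.9,
) -> AffinityEstimate:
    """Partial-agonist KD by Stephenson's matched-response method.

    The full-agonist control curve and the combined (full agonist + fixed
    partial agonist [P]) curve are compared at ``n_levels`` evenly spaced
    response levels between (partial-agonist plateau + ``plateau_margin_pct``)
    and ``top_fraction`` of the control maximum.  A1, A2 are read off the
    fitted control curve and A3 off the fitted combined curve by inverse
    interpolation; per-level KDs are averaged in log space with their spread
    as the SE.
    """
    if P <= 0:
        raise ValueError("partial agonist concentration must be positive")
    plateau, emax_c, log_ec_c = _fit_offset_one_site(combined_curve)
    if plateau <= 0:
        raise ValueError("partial agonist produces no plateau; Stephenson's method not applicable")
    if plateau >= control_curve.Emax_pct:
        raise ValueError("plateau reaches the full agonist maximum; not a partial agonist here")

    lo = plateau + plateau_margin_pct
    hi = top_fraction * control_curve.Emax_pct
    if hi <= lo:
        raise ValueError("no response level between the plateau and the control maximum")
    levels = np.linspace(lo, hi, n_levels)
    a1 = control_curve.inverse(plateau)
    log_kds = []
    for level in levels:
        a2 = control_curve.inverse(level)
        # invert plateau + emax*A/(A+ec50) = level
        frac = (level - plateau) / emax_c
        if not 0.0 < frac < 1.0:
            continue
        a3 = 10.0 ** log_ec_c * frac / (1.0 - frac)
        try:
            log_kds.append(np.log10(stephenson_from_points(P, a1, a2, a3)))
        except ValueError:
            continue
    if not log_kds:
        raise ValueError("no response level satisfied the Stephenson preconditions")
    se = float(np.std(log_kds, ddof=1)) if len(log_kds) > 1 else None
    return AffinityEstimate(
        logKd=float(np.mean(log_kds)), method="stephenson", se=se, n=len(log_kds),
        compound_id=combined_curve.meta.get("fixed_partial_agonist"),
        cell_line=combined_curve.meta.get("cell_line"),
        context={"P": P, "plateau_pct": plateau},
    )


def conformation_ratio(
    kd_cce: AffinityEstimate, kd_sce: AffinityEstimate
) -> Union[float, Censor]:
    """Log10 ratio of SCE over CCE affinity (positive: CCE-preferring ligand).

    With a censored SCE affinity ("no shift at 10 uM") the ratio becomes a
    one-sided bound, as in the "> 3" table entries.
    """
    if kd_cce.is_censored and kd_sce.is_censored:
        raise ValueError("both affinities censored; ratio undefined")
    if kd_sce.is_censored:
        return Censor(">", kd_sce.censored.bound - kd_cce.logKd)
    if kd_cce.is_censored:
        return Censor("<", kd_sce.logKd - kd_cce.censored.bound)
    return float(kd_sce.logKd - kd_cce.logKd)
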
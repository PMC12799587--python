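"""Radioligand binding analysis.

Saturation binding (one-site hyperbola), competition binding on the
percent-of-specific scale, the Cheng-Prusoff IC50 -> KD correction, and
between-subtype selectivity ratios.

Model equations
---------------
Saturation:   SB(A)   = Bmax * A / (A + KD)
Competition:  %uninhibited(A) = 100 - 100 * A / (A + IC50) + NS
Cheng-Prusoff: KD = IC50 / (1 + [L] / KD_L)

where A is the competing/radio-ligand concentration, [L] the free
radioligand concentration and KD_L the radioligand's own affinity.  All
concentration parameters are optimized on the log10 scale inside the box
[-13, -2] so that standard errors are meaningful on the scale the results
are reported on.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .core import AffinityEstimate, Censor, ConcentrationSeries

__all__ = [
    "SaturationFit",
    "CompetitionFit",
    "saturation_sb",
    "competition_pct",
    "fit_saturation",
    "fit_competition",
    "cheng_prusoff",
    "inverse_cheng_prusoff",
    "selectivity_ratio",
    "specific_binding_pct",
]

LOG_BOUNDS = (-13.0, -2.0)


def saturation_sb(conc: np.ndarray, bmax: float, log_kd: float) -> np.ndarray:
    """Specific binding of the radioligand at concentration ``conc`` (molar)."""
    conc = np.asarray(conc, dtype=float)
    kd = 10.0 ** log_kd
    return bmax * conc / (conc + kd)


def competition_pct(conc: np.ndarray, log_ic50: float, ns: float = 0.0) -> np.ndarray:
    """Percent uninhibited specific binding at competitor concentration ``conc``."""
    conc = np.asarray(conc, dtype=float)
    ic50 = 10.0 ** log_ic50
    return 100.0 - 100.0 * conc / (conc + ic50) + ns


@dataclass
class SaturationFit:
    Bmax: float
    logKd: float
    se_logKd: float
    rss: float
    n_points: int

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return saturation_sb(conc, self.Bmax, self.logKd)


@dataclass
class CompetitionFit:
    logIC50: float
    se_logIC50: float
    ns_level: float
    rss: float
    n_points: int
    censored: Optional[Censor] = None

    @property
    def is_censored(self) -> bool:
        return self.censored is not None

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return competition_pct(conc, self.logIC50, self.ns_level)


def _se_from_jacobian(res: optimize.OptimizeResult, n_points: int) -> np.ndarray:
    """Parameter SEs from the Gauss-Newton curvature at the optimum."""
    n_par = res.x.size
    dof = max(n_points - n_par, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
    return se


def specific_binding_pct(data: ConcentrationSeries) -> np.ndarray:
    """Per-well specific binding as percent of the plate's specific window.

    Computed per plate as (well - mean nonspecific) normalized to percent of
    (mean total - mean nonspecific).
    """
    total = data.control("total")
    nsb = data.control("nonspecific")
    window = float(np.mean(total)) - float(np.mean(nsb))
    if window <= 0:
        raise ValueError("no specific-binding window: mean total <= mean nonspecific")
    return 100.0 * (data.signal - float(np.mean(nsb))) / window


def fit_saturation(data: ConcentrationSeries) -> SaturationFit:
    """Fit the one-site saturation hyperbola to specific binding.

    ``data.signal`` holds total-binding wells over the radioligand dilution
    series; ``data.controls['nonspecific']`` the matched propranolol-blocked
    wells (matrix of the same shape, or a 1-D per-concentration vector).
    """
    if np.unique(data.conc).size < 4:
        raise ValueError("saturation fit needs at least 4 distinct radioligand concentrations")
    nsb = data.control("nonspecific")
    nsb = np.atleast_2d(nsb)
    if nsb.shape[0] == 1 and data.conc.size > 1:
        raise ValueError("saturation fit needs per-concentration nonspecific wells")
    specific = data.signal - nsb.mean(axis=1, keepdims=True)
    if not np.any(specific > 0):
        raise ValueError("specific binding is non-positive at every concentration")

    y = specific.ravel()
    conc = np.repeat(data.conc, data.n_replicates)

    def residuals(p):
        bmax, log_kd = p
        return saturation_sb(conc, bmax, log_kd) - y

    b0 = max(float(np.max(specific.mean(axis=1))), 1e-6)
    starts = [
        (b0, float(np.log10(np.median(data.conc)))),
        (1.5 * b0, float(np.log10(data.conc[0]))),
        (1.1 * b0, float(np.log10(data.conc[-1]))),
    ]
    best = None
    for p0 in starts:
        res = optimize.least_squares(
            residuals, p0, bounds=([0.0, LOG_BOUNDS[0]], [np.inf, LOG_BOUNDS[1]]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    se = _se_from_jacobian(best, y.size)
    return SaturationFit(
        Bmax=float(best.x[0]),
        logKd=float(best.x[1]),
        se_logKd=float(se[1]),
        rss=float(2.0 * best.cost),
        n_points=int(y.size),
    )


def fit_competition(data: ConcentrationSeries, censor_threshold: float = 50.0) -> CompetitionFit:
    """Fit the competition curve on the percent-specific-binding scale.

    If no concentration inhibits at least ``censor_threshold`` percent of
    specific binding, a censored fit is returned with the one-sided bound
    ``logIC50 > log10(top concentration)`` and no point estimate, matching
    the "IC50 > -4" / "no binding to 100 uM" reporting convention.
    """
    span = np.log10(data.conc[-1]) - np.log10(data.conc[0])
    if span < 3.0:
        raise ValueError("competition series must span at least 3 log units")
    pct = specific_binding_pct(data)

    mean_curve = pct.mean(axis=1)
    if float(mean_curve.min()) > 100.0 - censor_threshold:
        return CompetitionFit(
            logIC50=float("nan"),
            se_logIC50=float("nan"),
            ns_level=float("nan"),
            rss=float("nan"),
            n_points=int(pct.size),
            censored=Censor(">", float(np.log10(data.conc[-1]))),
        )

    y = pct.ravel()
    conc = np.repeat(data.conc, data.n_replicates)

    def residuals(p):
        log_ic50, ns = p
        return competition_pct(conc, log_ic50, ns) - y

    # start near the concentration where the mean curve crosses 50%
    idx = int(np.argmin(np.abs(mean_curve - 50.0)))
    starts = [
        (float(np.log10(data.conc[idx])), 0.0),
        (float(np.log10(np.median(data.conc))), 0.0),
    ]
    best = None
    for p0 in starts:
        res = optimize.least_squares(
            residuals, p0, bounds=([LOG_BOUNDS[0], 0.0], [LOG_BOUNDS[1], 100.0]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    se = _se_from_jacobian(best, y.size)
    return CompetitionFit(
        logIC50=float(best.x[0]),
        se_logIC50=float(se[0]),
        ns_level=float(best.x[1]),
        rss=float(2.0 * best.cost),
        n_points=int(y.size),
    )


def cheng_prusoff(
    ic50: float,
    radioligand_conc: float,
    radioligand_kd: float,
    *,
    se_log: Optional[float] = None,
    n: int = 1,
    censored: Optional[Censor] = None,
    compound_id: Optional[str] = None,
    cell_line: Optional[str] = None,
) -> AffinityEstimate:
    """Correct a competition IC50 (molar) to a KD for the competing ligand.

    KD = IC50 / (1 + [L]/KD_L).  Censoring propagates: a bound on the IC50
    becomes the correspondingly corrected bound on the KD, same direction.
    """
    if radioligand_conc <= 0 or radioligand_kd <= 0:
        raise ValueError("radioligand concentration and KD must be positive")
    shift = np.log10(1.0 + radioligand_conc / radioligand_kd)
    if censored is not None:
        return AffinityEstimate(
            logKd=float("nan"),
            method="competition_cheng_prusoff",
            se=None,
            n=n,
            censored=Censor(censored.direction, censored.bound - shift),
            compound_id=compound_id,
            cell_line=cell_line,
        )
    if ic50 <= 0:
        raise ValueError("IC50 must be positive")
    return AffinityEstimate(
        logKd=float(np.log10(ic50) - shift),
        method="competition_cheng_prusoff",
        se=se_log,
        n=n,
        compound_id=compound_id,
        cell_line=cell_line,
    )


def competition_to_affinity(
    fit: CompetitionFit,
    radioligand_conc: float,
    radioligand_kd: float,
    *,
    n: int = 1,
    compound_id: Optional[str] = None,
    cell_line: Optional[str] = None,
) -> AffinityEstimate:
    """Cheng-Prusoff correction applied to a fitted competition curve."""
    ic50 = float("nan") if fit.is_censored else 10.0 ** fit.logIC50
    return cheng_prusoff(
        ic50,
        radioligand_conc,
        radioligand_kd,
        se_log=None if fit.is_censored else fit.se_logIC50,
        n=n,
        censored=fit.censored,
        compound_id=compound_id,
        cell_line=cell_line,
    )


def inverse_cheng_prusoff(kd: float, radioligand_conc: float, radioligand_kd: float) -> float:
    """IC50 (molar) a competitor of affinity ``kd`` shows at the given radioligand level."""
    if min(kd, radioligand_conc, radioligand_kd) <= 0:
        raise ValueError("all inputs must be positive")
    return kd * (1.0 + radioligand_conc / radioligand_kd)


def selectivity_ratio(log_kd_a: float, log_kd_b: float) -> float:
    """Fold selectivity as the ratio of linear KDs, a over b.

    For Table-1 style beta2-selectivity pass (logKd at beta1, logKd at
    beta2): a value > 1 means higher affinity (lower KD) at receptor b.
    """
    for v in (log_kd_a, log_kd_b):
        if not np.isfinite(v):
            raise ValueError("selectivity requires point estimates, not censored bounds")
    return 10.0 ** (log_kd_a - log_kd_b)
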
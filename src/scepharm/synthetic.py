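"""Two-conformation assay simulator.

Generates radioligand-binding and reporter-gene plates with the statistical
structure the analysis pipeline assumes, from a declared ground truth: each
compound carries an affinity and an intrinsic efficacy for the catecholamine
conformation ensemble (CCE) and, where applicable, for the secondary
conformation ensemble (SCE).

Occupancy of a conformation is turned into an observable curve through a
single receptor-reserve scalar per cell line (``receptor_expression``, R):

    tau  = R * e / (1 - e)              (amplified efficacy)
    Emax = 100 * tau / (1 + tau)        (% of the isoprenaline maximum)
    EC50 = KD / (1 + tau)

so raising expression makes a partial agonist's maximum proportionately
greater and left-shifts its EC50, and the observable curve stays an exact
unit-slope hyperbola.  A compound active at both conformations produces the
exact two-site stimulatory mixture of its per-conformation components; a
compound measured against a fixed reference agonist produces the composite
inhibit-then-stimulate ("dip") curve with the inhibitory IC50 set by the
Gaddum-shifted CCE KD.  Replicate noise is additive Gaussian with SD given
as a fraction of the positive-control window.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import ConcentrationSeries

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "Experiment",
    "StudyBundle",
    "MODES",
    "functional_components",
    "expected_functional_pct",
    "simulate_binding_plate",
    "simulate_functional_curve",
    "make_study_fixture",
    "REFERENCE_AGONIST",
    "REFERENCE_ANTAGONIST",
]

MODES = ("neutral", "cce_agonist", "sce_agonist", "biphasic", "nonbinder")

REFERENCE_AGONIST = "cimaterol"
REFERENCE_ANTAGONIST = "CGP20712A"

# raw reader units for synthetic plates
_FUNC_BASAL = 250.0
_FUNC_WINDOW = 2000.0
_BIND_NS = 400.0
_BIND_WINDOW = 2600.0
_SAT_BMAX = 1000.0
_SAT_NS_FRACTION = 0.2  # nonspecific at the top radioligand concentration, vs Bmax

DEFAULT_FUNCTIONAL_GRID = tuple(10.0 ** np.arange(-11.0, -4.75, 0.5))  # 1e-11 .. 1e-5 M
# compound-alone panel curves run to 100 uM so that low-potency secondary
# components (EC50 near 2 uM) reach a defined plateau
STUDY_FUNCTIONAL_GRID = tuple(10.0 ** np.arange(-11.0, -3.75, 0.5))    # 1e-11 .. 1e-4 M
SHIFT_GRID = tuple(10.0 ** np.arange(-10.0, -3.75, 0.5))               # 1e-10 .. 1e-4 M
BINDING_GRID = tuple(10.0 ** np.arange(-10.0, -3.75, 0.5))
SATURATION_GRID = tuple(np.geomspace(8e-12, 8.911e-9, 10))


@dataclass(frozen=True)
class GroundTruth:
    """A compound's generative parameters at the two conformations."""

    compound_id: str
    mode: str
    logKd_cce: Optional[float] = None
    logKd_sce: Optional[float] = None
    efficacy_cce: float = 0.0
    efficacy_sce: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        for kd in (self.logKd_cce, self.logKd_sce):
            if kd is not None and not -12.0 <= kd <= -3.0:
                raise ValueError(f"logKd {kd} outside [-12, -3]")
        for e in (self.efficacy_cce, self.efficacy_sce):
            if not 0.0 <= e <= 0.999:
                raise ValueError("efficacies must lie in [0, 0.999]")
        if self.mode == "nonbinder":
            if self.efficacy_cce or self.efficacy_sce:
                raise ValueError("nonbinder must have zero efficacy at both conformations")
            for kd in (self.logKd_cce, self.logKd_sce):
                if kd is not None and kd < -5.0:
                    raise ValueError("nonbinder affinity must be absent or >= -5")
        if self.mode == "biphasic":
            if self.logKd_sce is None or self.logKd_cce is None:
                raise ValueError("biphasic compounds need both affinities")
            if not self.logKd_sce > self.logKd_cce:
                raise ValueError("biphasic compounds have lower affinity at the SCE "
                                 "(logKd_sce > logKd_cce)")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell line's assay conditions."""

    ground_truth: Tuple[GroundTruth, ...]
    radioligand_conc: float = 0.71e-9
    radioligand_logKd: float = -9.38  # 0.42 nM
    receptor_expression: float = 1.0
    noise_sd: float = 0.05
    n_replicates: int = 3
    seed: int = 0
    concentration_grid: Tuple[float, ...] = DEFAULT_FUNCTIONAL_GRID
    cell_line: str = "line"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ground_truth", tuple(self.ground_truth))
        object.__setattr__(self, "concentration_grid", tuple(self.concentration_grid))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.receptor_expression <= 0:
            raise ValueError("receptor_expression must be positive")
        grid = np.asarray(self.concentration_grid)
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("concentration_grid must be positive and strictly increasing")

    def truth_for(self, compound_id: str) -> GroundTruth:
        for gt in self.ground_truth:
            if gt.compound_id == compound_id:
                return gt
        raise KeyError(f"compound {compound_id!r} not in ground truth")


def _rng(config: SimulationConfig, label: str) -> np.random.Generator:
    """Deterministic per-experiment stream: same (config, seed, label) -> same draws."""
    tag = zlib.crc32(f"{config.cell_line}|{label}".encode()) & 0x7FFFFFFF
    return np.random.default_rng([config.seed & 0x7FFFFFFF, tag])


# ---------------------------------------------------------------------------
# forward model

# curve components smaller than this fraction of the assay window are below
# what triplicate plates resolve (half the default noise SD) and are not
# emitted: a low-expression line shows a genuinely monophasic curve even if
# the compound has a trace of efficacy at the other conformation
COMPONENT_RESOLUTION_PCT = 2.5


def functional_components(gt: GroundTruth, receptor_expression: float):
    """Per-conformation (Emax_pct, logEC50) components of a compound's curve.

    Sub-resolution components are dropped and the remainder capped jointly
    so the summed maximum never exceeds the system maximum (100% of
    isoprenaline).
    """
    comps = []
    for kd, eff, conf in ((gt.logKd_cce, gt.efficacy_cce, "cce"),
                          (gt.logKd_sce, gt.efficacy_sce, "sce")):
        if kd is None or eff <= 0.0:
            continue
        tau = receptor_expression * eff / (1.0 - eff)
        emax = 100.0 * tau / (1.0 + tau)
        if emax < COMPONENT_RESOLUTION_PCT:
            continue
        comps.append({"conformation": conf, "emax": emax,
                      "log_ec50": kd - np.log10(1.0 + tau)})
    total = sum(c["emax"] for c in comps)
    if total > 100.0:
        for c in comps:
            c["emax"] *= 100.0 / total
    return comps


def expected_functional_pct(
    config: SimulationConfig,
    compound: str,
    conc: np.ndarray,
    fixed_reference: Optional[Tuple[str, float]] = None,
    fixed_antagonist: Optional[Tuple[str, float]] = None,
) -> np.ndarray:
    """Noiseless expected response (percent isoprenaline) over ``conc``."""
    gt = config.truth_for(compound)
    R = config.receptor_expression
    conc = np.asarray(conc, dtype=float)
    comps = functional_components(gt, R)

    shift = {"cce": 0.0, "sce": 0.0}
    offset = 0.0
    if fixed_antagonist is not None:
        ant_id, b = fixed_antagonist
        if b <= 0:
            raise ValueError("antagonist concentration must be positive")
        ant = config.truth_for(ant_id)
        if ant.logKd_cce is None and ant.mode != "nonbinder":
            raise ValueError(f"{ant_id} has no CCE affinity; cannot act as fixed antagonist")
        if ant.logKd_cce is not None:
            shift["cce"] = np.log10(1.0 + b / 10.0 ** ant.logKd_cce)
        if ant.logKd_sce is not None:
            shift["sce"] = np.log10(1.0 + b / 10.0 ** ant.logKd_sce)
        # a fixed partial agonist contributes its own constant response
        for c in functional_components(ant, R):
            ec = 10.0 ** c["log_ec50"]
            offset += c["emax"] * b / (b + ec)

    if fixed_reference is None:
        resp = np.full(conc.shape, 0.0)
        for c in comps:
            ec = 10.0 ** (c["log_ec50"] + shift[c["conformation"]])
            resp = resp + c["emax"] * conc / (conc + ec)
        return resp + offset

    # dip design: compound titrated against a fixed reference agonist
    ref_id, r_conc = fixed_reference
    ref = config.truth_for(ref_id)
    ref_comps = functional_components(ref, R)
    if not ref_comps:
        raise ValueError(f"fixed reference {ref_id!r} has no agonism")
    control = sum(c["emax"] * r_conc / (r_conc + 10.0 ** c["log_ec50"]) for c in ref_comps)
    resp = np.full(conc.shape, control)
    if gt.logKd_cce is not None:
        # competitive displacement of the reference: IC50 is the compound's
        # CCE KD Gaddum-shifted by the reference occupancy
        ref_ec50 = 10.0 ** ref_comps[0]["log_ec50"]
        ic50 = 10.0 ** gt.logKd_cce * (1.0 + r_conc / ref_ec50)
        resp = control * (1.0 - conc / (conc + ic50))
    for c in comps:
        ec = 10.0 ** c["log_ec50"]
        resp = resp + c["emax"] * conc / (conc + ec)
    return resp


# ---------------------------------------------------------------------------
# plate simulators

def simulate_functional_curve(
    config: SimulationConfig,
    compound: str,
    fixed_reference: Optional[Tuple[str, float]] = None,
    fixed_antagonist: Optional[Tuple[str, float]] = None,
    grid: Optional[Tuple[float, ...]] = None,
    label: str = "",
) -> ConcentrationSeries:
    """One reporter-gene plate: compound dilution series in triplicate plus
    basal, positive-control (10 uM isoprenaline) and, for dip designs,
    reference-alone control wells.  Raw reader units."""
    conc = np.asarray(grid if grid is not None else config.concentration_grid, dtype=float)
    pct = expected_functional_pct(config, compound, conc, fixed_reference, fixed_antagonist)
    rng = _rng(config, f"func|{compound}|{fixed_reference}|{fixed_antagonist}|{label}")
    sd = config.noise_sd * _FUNC_WINDOW

    def raw(p, shape):
        return np.clip(_FUNC_BASAL + np.asarray(p) * _FUNC_WINDOW / 100.0
                       + rng.normal(0.0, sd, shape), 0.0, None)

    signal = raw(pct[:, None], (conc.size, config.n_replicates))
    controls = {
        "basal": raw(0.0, 6),
        "positive": raw(100.0, 6),
    }
    meta = {
        "assay": "functional",
        "cell_line": config.cell_line,
        "fixed_reference": fixed_reference,
        "fixed_antagonist": fixed_antagonist,
    }
    if fixed_reference is not None:
        ref_pct = expected_functional_pct(config, fixed_reference[0],
                                          np.array([fixed_reference[1]]))[0]
        controls["reference"] = raw(ref_pct, 6)
    return ConcentrationSeries(compound_id=compound, conc=conc, signal=signal,
                               controls=controls, meta=meta)


def simulate_binding_plate(
    config: SimulationConfig,
    compound: Optional[str] = None,
    mode: str = "competition",
    label: str = "",
) -> ConcentrationSeries:
    """One radioligand whole-cell binding plate.

    Competition mode: the compound's dilution series against a fixed free
    radioligand concentration; noiseless specific binding at competitor
    concentration c is 100*(1 - c/(c + IC50)) with IC50 from the inverse
    Cheng-Prusoff relation on the CCE KD (only the high-affinity
    catecholamine conformation is detected by the radioligand).
    Saturation mode: the radioligand's own dilution series with matched
    nonspecific (propranolol-blocked) wells.
    """
    if config.radioligand_conc <= 0:
        raise ValueError("radioligand concentration must be positive")
    if mode == "saturation":
        conc = np.asarray(SATURATION_GRID, dtype=float)
        kd = 10.0 ** config.radioligand_logKd
        sb = _SAT_BMAX * conc / (conc + kd)
        ns = _SAT_NS_FRACTION * _SAT_BMAX * conc / conc[-1]
        rng = _rng(config, f"bind|saturation|{label}")
        sd = config.noise_sd * _SAT_BMAX
        shape = (conc.size, config.n_replicates)
        signal = np.clip(sb[:, None] + ns[:, None] + rng.normal(0.0, sd, shape), 0.0, None)
        nsb = np.clip(ns[:, None] + rng.normal(0.0, sd, shape), 0.0, None)
        return ConcentrationSeries(
            compound_id="radioligand", conc=conc, signal=signal,
            controls={"nonspecific": nsb},
            meta={"assay": "binding_saturation", "cell_line": config.cell_line,
                  "radioligand_logKd": config.radioligand_logKd},
        )
    if mode != "competition":
        raise ValueError(f"unknown binding mode {mode!r}")
    if compound is None:
        raise ValueError("competition mode needs a compound")
    gt = config.truth_for(compound)
    conc = np.asarray(BINDING_GRID, dtype=float)
    if gt.logKd_cce is None:
        frac = np.ones_like(conc)  # no displacement up to the top concentration
    else:
        ic50 = 10.0 ** gt.logKd_cce * (1.0 + config.radioligand_conc / 10.0 ** config.radioligand_logKd)
        frac = 1.0 - conc / (conc + ic50)
    rng = _rng(config, f"bind|competition|{compound}|{label}")
    sd = config.noise_sd * _BIND_WINDOW

    def raw(p, shape):
        return np.clip(_BIND_NS + np.asarray(p) * _BIND_WINDOW
                       + rng.normal(0.0, sd, shape), 0.0, None)

    signal = raw(frac[:, None], (conc.size, config.n_replicates))
    controls = {"total": raw(1.0, 6), "nonspecific": raw(0.0, 6)}
    return ConcentrationSeries(
        compound_id=compound, conc=conc, signal=signal, controls=controls,
        meta={"assay": "binding_competition", "cell_line": config.cell_line,
              "radioligand_conc": config.radioligand_conc,
              "radioligand_logKd": config.radioligand_logKd},
    )


# ---------------------------------------------------------------------------
# the study fixture

@dataclass
class Experiment:
    """One simulated experiment with everything the pipeline needs to refit it."""

    kind: str  # binding_saturation | binding_competition | functional | shift | dip | stephenson
    cell_line: str
    compound_id: str  # the analyte (for shifts: the agonist whose curve is shifted)
    series: Optional[ConcentrationSeries] = None
    control: Optional[ConcentrationSeries] = None
    blocked: List[Tuple[float, ConcentrationSeries]] = field(default_factory=list)
    antagonist_id: Optional[str] = None
    partial_agonist: Optional[str] = None
    P: Optional[float] = None


@dataclass
class StudyBundle:
    """A deterministic multi-compound, multi-line study."""

    seed: int
    ground_truth: Dict[str, GroundTruth]
    ground_truth_mutant: Dict[str, GroundTruth]
    configs: Dict[str, SimulationConfig]
    experiments: List[Experiment]
    table_outcomes: Dict[str, str]       # expected classification per compound
    expected_letters: Dict[str, str]     # expected pooled evidence letters
    contrast_lines: Tuple[str, str] = ("b1wt", "b1mut")
    contrast_compounds: Tuple[str, ...] = ()
    expected_loss: Dict[str, Tuple[str, ...]] = field(default_factory=dict)
    # receptor background per cell line: affinity estimates transfer between
    # lines expressing the same receptor (a KD is a receptor property)
    line_backgrounds: Dict[str, str] = field(default_factory=dict)


def _study_ground_truth() -> List[GroundTruth]:
    """The compound panel: affinities from binding/shift tables, efficacies
    from inverting the reserve transform at the line that characterizes each
    component best."""
    g = GroundTruth
    return [
        g("cimaterol", "cce_agonist", logKd_cce=-6.43, efficacy_cce=0.97),
        g("CGP12177", "sce_agonist", logKd_cce=-9.77, logKd_sce=-7.20, efficacy_sce=0.542),
        g("CGP20712A", "neutral", logKd_cce=-9.47, logKd_sce=-7.37),
        g("alprenolol", "biphasic", logKd_cce=-8.20, efficacy_cce=0.036,
          logKd_sce=-6.30, efficacy_sce=0.024),
        g("bucindolol", "biphasic", logKd_cce=-9.24, efficacy_cce=0.2,
          logKd_sce=-7.16, efficacy_sce=0.178),
        g("oxprenolol", "biphasic", logKd_cce=-8.06, efficacy_cce=0.075,
          logKd_sce=-5.55, efficacy_sce=0.023),
        g("pindolol", "biphasic", logKd_cce=-8.71, efficacy_cce=0.066,
          logKd_sce=-5.80, efficacy_sce=0.02),
        g("VL01", "sce_agonist", logKd_cce=-10.19, logKd_sce=-6.68, efficacy_sce=0.197),
        g("VL03", "neutral", logKd_cce=-8.91, logKd_sce=-6.38),
        g("VL04", "biphasic", logKd_cce=-9.12, efficacy_cce=0.0195,
          logKd_sce=-6.00, efficacy_sce=0.237),
        g("VL05", "cce_agonist", logKd_cce=-8.00, efficacy_cce=0.097),
        g("VL06", "cce_agonist", logKd_cce=-5.95, efficacy_cce=0.074),
        g("VL07", "sce_agonist", logKd_cce=-8.21, logKd_sce=-6.42, efficacy_sce=0.0243),
        g("VL08", "nonbinder"),
        g("VL09", "biphasic", logKd_cce=-9.03, efficacy_cce=0.024,
          logKd_sce=-6.77, efficacy_sce=0.239),
        g("VL10", "cce_agonist", logKd_cce=-6.73, efficacy_cce=0.122),
        g("VL11", "nonbinder"),
        g("VL12", "nonbinder"),
        g("VL13", "nonbinder"),
    ]


def _mutant_ground_truth() -> List[GroundTruth]:
    """TM4 triple-mutant background: the secondary conformation is gone;
    former SCE agonists appear as conventional weak CCE partial agonists."""
    g = GroundTruth
    return [
        g("cimaterol", "cce_agonist", logKd_cce=-6.43, efficacy_cce=0.97),
        g("CGP20712A", "neutral", logKd_cce=-9.47),
        g("CGP12177", "cce_agonist", logKd_cce=-9.57, efficacy_cce=0.0373),
        g("VL01", "cce_agonist", logKd_cce=-9.56, efficacy_cce=0.0419),
        g("VL04", "cce_agonist", logKd_cce=-8.76, efficacy_cce=0.0351),
        g("VL09", "cce_agonist", logKd_cce=-8.61, efficacy_cce=0.0524),
    ]


TABLE_OUTCOMES: Dict[str, str] = {
    "alprenolol": "biphasic_agonist",
    "bucindolol": "biphasic_agonist",
    "CGP12177": "sce_agonist",
    "cimaterol": "cce_agonist",
    "oxprenolol": "biphasic_agonist",
    "pindolol": "biphasic_agonist",
    "CGP20712A": "neutral_antagonist",
    "VL01": "sce_agonist",
    "VL03": "neutral_antagonist",
    "VL04": "biphasic_agonist",
    "VL05": "cce_agonist",
    "VL06": "cce_agonist",
    "VL07": "sce_agonist",
    "VL08": "no_interaction",
    "VL09": "biphasic_agonist",
    "VL10": "cce_agonist",
    "VL11": "no_interaction",
    "VL12": "no_interaction",
    "VL13": "no_interaction",
}

EXPECTED_LETTERS: Dict[str, str] = {
    "alprenolol": "C", "bucindolol": "C", "CGP12177": "ABD", "cimaterol": "",
    "oxprenolol": "C", "pindolol": "C", "CGP20712A": "", "VL01": "ABD",
    "VL03": "", "VL04": "ABCD", "VL05": "", "VL06": "", "VL07": "A",
    "VL08": "", "VL09": "ABCD", "VL10": "", "VL11": "", "VL12": "", "VL13": "",
}


def make_study_fixture(seed: int) -> StudyBundle:
    """Deterministic whole-study bundle: the full compound panel in a
    low-expression (luciferase-type) and a high-expression (SPAP-type) line,
    plus wild-type and TM4-triple-mutant mixed-population lines for the
    loss-of-evidence contrast.  Bit-identical across calls at a fixed seed.
    """
    truth = _study_ground_truth()
    mut_truth = _mutant_ground_truth()
    base = dict(ground_truth=tuple(truth), noise_sd=0.05, n_replicates=3, seed=seed)
    configs: Dict[str, SimulationConfig] = {
        # radioligand KD: 0.15 nM (luciferase line), 0.42 nM (SPAP line),
        # 0.17 nM (wild-type mixed populations)
        "b1luc": SimulationConfig(**base, receptor_expression=1.0,
                                  radioligand_logKd=-9.82, cell_line="b1luc"),
        "b1spap": SimulationConfig(**base, receptor_expression=14.5,
                                   radioligand_logKd=-9.38, cell_line="b1spap"),
        "b1wt": SimulationConfig(**base, receptor_expression=10.0,
                                 radioligand_logKd=-9.77, cell_line="b1wt"),
        "b1mut": SimulationConfig(ground_truth=tuple(mut_truth), noise_sd=0.05,
                                  n_replicates=3, seed=seed, receptor_expression=10.0,
                                  radioligand_logKd=-9.57, cell_line="b1mut"),
    }
    exps: List[Experiment] = []
    panel = [gt.compound_id for gt in truth]

    # --- binding ---------------------------------------------------------
    exps.append(Experiment("binding_saturation", "b1spap", "radioligand",
                           series=simulate_binding_plate(configs["b1spap"], mode="saturation")))
    exps.append(Experiment("binding_saturation", "b1wt", "radioligand",
                           series=simulate_binding_plate(configs["b1wt"], mode="saturation")))
    for cpd in panel:
        exps.append(Experiment("binding_competition", "b1spap", cpd,
                               series=simulate_binding_plate(configs["b1spap"], cpd)))
    for cpd in ("CGP12177", "VL01", "VL04", "VL09"):
        for line in ("b1wt", "b1mut"):
            exps.append(Experiment("binding_competition", line, cpd,
                                   series=simulate_binding_plate(configs[line], cpd)))

    # --- compound-alone functional curves --------------------------------
    for cpd in panel:
        for line in ("b1luc", "b1spap"):
            exps.append(Experiment("functional", line, cpd,
                                   series=simulate_functional_curve(
                                       configs[line], cpd, grid=STUDY_FUNCTIONAL_GRID)))
    for cpd in ("cimaterol", "CGP12177", "VL01", "VL04", "VL09"):
        for line in ("b1wt", "b1mut"):
            exps.append(Experiment("functional", line, cpd,
                                   series=simulate_functional_curve(
                                       configs[line], cpd, grid=STUDY_FUNCTIONAL_GRID)))

    # --- antagonist shift experiments ------------------------------------
    def shift(line: str, agonist: str, antagonist: str, ant_concs) -> Experiment:
        cfg = configs[line]
        ctrl = simulate_functional_curve(cfg, agonist, grid=SHIFT_GRID,
                                         label=f"shift-ctrl|{antagonist}")
        blocked = [
            (b, simulate_functional_curve(cfg, agonist, fixed_antagonist=(antagonist, b),
                                          grid=SHIFT_GRID, label="shift-blocked"))
            for b in ant_concs
        ]
        return Experiment("shift", line, agonist, control=ctrl, blocked=blocked,
                          antagonist_id=antagonist)

    ref_ant = REFERENCE_ANTAGONIST
    # reference-antagonist vs reference-agonist baselines, all lines
    for line in ("b1luc", "b1spap", "b1wt", "b1mut"):
        exps.append(shift(line, "cimaterol", ref_ant, [10e-9]))
    # reference antagonist vs each agonist's own response (criterion B designs)
    exps.append(shift("b1luc", "CGP12177", ref_ant, [1e-6]))
    exps.append(shift("b1spap", "CGP12177", ref_ant, [1e-6]))
    exps.append(shift("b1wt", "CGP12177", ref_ant, [1e-6]))
    exps.append(shift("b1mut", "CGP12177", ref_ant, [10e-9]))
    exps.append(shift("b1luc", "VL01", ref_ant, [1e-6]))
    exps.append(shift("b1wt", "VL01", ref_ant, [1e-6]))
    exps.append(shift("b1mut", "VL01", ref_ant, [100e-9]))
    exps.append(shift("b1luc", "VL04", ref_ant, [1e-6]))
    exps.append(shift("b1luc", "VL09", ref_ant, [1e-6]))
    exps.append(shift("b1spap", "VL05", ref_ant, [10e-9]))
    exps.append(shift("b1spap", "VL06", ref_ant, [10e-9]))
    exps.append(shift("b1spap", "VL10", ref_ant, [10e-9]))
    # test compounds acting as antagonists (conformation affinities)
    exps.append(shift("b1luc", "cimaterol", "VL03", [10e-9, 100e-9, 1e-6]))  # Schild design
    exps.append(shift("b1luc", "CGP12177", "VL03", [10e-6]))
    for cpd in ("VL08", "VL11", "VL12", "VL13"):
        exps.append(shift("b1luc", "cimaterol", cpd, [10e-6]))
        exps.append(shift("b1luc", "CGP12177", cpd, [10e-6]))

    # --- dip designs: compound vs fixed reference agonist ----------------
    for cpd in ("CGP12177", "VL01", "VL03", "VL04", "VL05", "VL09", "VL10", "VL13"):
        exps.append(Experiment(
            "dip", "b1luc", cpd,
            series=simulate_functional_curve(configs["b1luc"], cpd,
                                             fixed_reference=(REFERENCE_AGONIST, 30e-9)),
        ))

    # --- Stephenson design: reference agonist +/- fixed partial agonist --
    cfg = configs["b1luc"]
    steph_ctrl = simulate_functional_curve(cfg, REFERENCE_AGONIST, label="steph-ctrl")
    combined = simulate_functional_curve(cfg, REFERENCE_AGONIST,
                                         fixed_antagonist=("CGP12177", 10e-9),
                                         label="steph-combined")
    combined.meta["fixed_partial_agonist"] = "CGP12177"
    exps.append(Experiment("stephenson", "b1luc", REFERENCE_AGONIST,
                           series=combined, control=steph_ctrl,
                           partial_agonist="CGP12177", P=10e-9))

    return StudyBundle(
        seed=seed,
        ground_truth={gt.compound_id: gt for gt in truth},
        ground_truth_mutant={gt.compound_id: gt for gt in mut_truth},
        configs=configs,
        experiments=exps,
        table_outcomes=dict(TABLE_OUTCOMES),
        expected_letters=dict(EXPECTED_LETTERS),
        contrast_lines=("b1wt", "b1mut"),
        contrast_compounds=("CGP12177", "VL01", "VL04", "VL09"),
        expected_loss={"CGP12177": ("A", "B"), "VL01": ("A", "B"),
                       "VL04": ("C",), "VL09": ("C",)},
        line_backgrounds={"b1luc": "wt", "b1spap": "wt", "b1wt": "wt", "b1mut": "mut"},
    )
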
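"""Core containers shared by every assay-analysis stage.

Concentrations are stored in molar and reported in log10 molar throughout,
matching the convention of pharmacology tables (log KD, log EC50).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ConcentrationSeries",
    "AffinityEstimate",
    "Censor",
    "log_molar_to_nM",
]


def log_molar_to_nM(log_kd: float) -> float:
    """Convert a log10-molar affinity/potency to nanomolar."""
    return 10.0 ** log_kd * 1e9


@dataclass(frozen=True)
class Censor:
    """One-sided bound for an unquantifiable affinity.

    ``direction`` is ">" (e.g. "IC50 > -4", no inhibition up to the top
    concentration) or "<" (affinity better than the lowest tested
    concentration).  ``bound`` is in log10 molar.
    """

    direction: str
    bound: float

    def __post_init__(self) -> None:
        if self.direction not in (">", "<"):
            raise ValueError(f"censor direction must be '>' or '<', got {self.direction!r}")

    def __str__(self) -> str:  # e.g. "> -4.0"
        return f"{self.direction} {self.bound:g}"


@dataclass
class ConcentrationSeries:
    """One compound's dilution series on a plate, with replicate wells.

    Parameters
    ----------
    compound_id:
        Ligand identifier.
    conc:
        Final in-well concentrations, molar, strictly increasing.
    signal:
        Raw reader signal, shape ``(n_conc, n_replicates)``.
    controls:
        Plate control wells; keys among ``total``, ``nonspecific``,
        ``basal``, ``positive`` (1-D arrays of readings).  Saturation-binding
        series carry a per-concentration ``nonspecific`` matrix shaped like
        ``signal`` instead.
    meta:
        Assay context: ``assay`` (binding_saturation / binding_competition /
        functional), ``cell_line``, ``radioligand_conc``/``radioligand_logKd``
        for binding, ``fixed_reference``/``fixed_antagonist`` as
        ``(compound_id, molar)`` tuples for functional designs.
    """

    compound_id: str
    conc: np.ndarray
    signal: np.ndarray
    controls: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != self.conc.size:
            raise ValueError(
                f"signal rows ({self.signal.shape[0]}) must match concentrations ({self.conc.size})"
            )
        if self.conc.size and (np.any(self.conc <= 0) or np.any(np.diff(self.conc) <= 0)):
            raise ValueError("concentrations must be positive and strictly increasing")

    @property
    def n_replicates(self) -> int:
        return self.signal.shape[1]

    def control(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.controls[name], dtype=float)
        except KeyError:
            raise KeyError(f"series for {self.compound_id!r} lacks {name!r} control wells") from None


@dataclass
class AffinityEstimate:
    """A log10 KD with provenance.

    ``method`` records how the estimate was obtained: ``saturation``,
    ``competition_cheng_prusoff``, ``gaddum``, ``schild`` or ``stephenson``.
    Censored estimates (``censored`` set) carry no point value: ``logKd`` is
    ``nan`` and the bound lives in the :class:`Censor`.
    """

    logKd: float
    method: str
    se: Optional[float] = None
    n: int = 1
    censored: Optional[Censor] = None
    compound_id: Optional[str] = None
    cell_line: Optional[str] = None
    context: dict = field(default_factory=dict)

    _METHODS = {"saturation", "competition_cheng_prusoff", "gaddum", "schild", "stephenson"}

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unknown affinity method {self.method!r}")
        if self.censored is not None and np.isfinite(self.logKd):
            raise ValueError("censored estimates must not carry a point value")

    @property
    def is_censored(self) -> bool:
        return self.censored is not None
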
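"""Temperature-dependence utilities and the packaged reference table.

Hydration free energies compared across temperatures are conveniently
expressed in units of kT (per-temperature normalization).  The
temperature dependence itself follows the standard excess-thermodynamics
form

    dG(T) = dG(T0) + (Cex - Sex(T0)) (T - T0) - Cex T ln(T/T0),

parameterized by the excess entropy Sex at the reference temperature T0
and a temperature-independent excess heat capacity Cex.  For fixed T0
the model is linear in (dG(T0), Cex - Sex, Cex), so the fit is an exact
linear least-squares problem; note that over narrow temperature ranges
the ``-T ln(T/T0)`` regressor is nearly collinear with ``T - T0`` and
the fit is badly conditioned - a warning reports the condition number.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .fep_estimator import ThermoState

__all__ = [
    "ThermoFitPar",
    "to_kt",
    "from_kt",
    "rmsd_vs_reference",
    "fit_eq3",
    "eq3_curve",
    "load_reference",
]


@dataclass(frozen=True)
class ThermoFitPar:
    """Fitted excess-thermodynamics parameters at reference temperature T0."""

    dG_T0: float  # kJ/mol
    S_ex: float  # kJ/(mol K)
    C_ex: float  # kJ/(mol K)
    T0: float  # K

    def __post_init__(self) -> None:
        if not (self.T0 > 0.0):
            raise ValueError("T0 must be > 0")


def to_kt(dG: float, ts: ThermoState) -> float:
    """Energy in units of kT at the state's temperature."""
    return dG / ts.kT


def from_kt(x: float, ts: ThermoState) -> float:
    """Inverse of :func:`to_kt`."""
    return x * ts.kT


def rmsd_vs_reference(model: np.ndarray, ref: np.ndarray) -> float:
    """Root mean squared deviation between two matched series."""
    model = np.asarray(model, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if model.shape != ref.shape or model.size == 0:
        raise ValueError("series must be nonempty and of matching shape")
    return float(np.sqrt(np.mean((model - ref) ** 2)))


def _design(T: np.ndarray, T0: float) -> np.ndarray:
    return np.column_stack([np.ones_like(T), T - T0, -T * np.log(T / T0)])


def fit_eq3(data, T0: float) -> ThermoFitPar:
    """Least-squares fit of the excess-thermodynamics temperature model.

    ``data`` is a sequence of (T, dG) pairs with at least three distinct
    temperatures.  Emits a conditioning warning when the design matrix is
    nearly singular (narrow temperature windows).
    """
    arr = np.asarray(list(data), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be (T, dG) pairs")
    T, dg = arr[:, 0], arr[:, 1]
    if np.unique(T).size < 3:
        raise ValueError("need at least three distinct temperatures")
    X = _design(T, T0)
    coef, _, _, sv = np.linalg.lstsq(X, dg, rcond=None)
    cond = sv[0] / sv[-1] if sv[-1] > 0 else math.inf
    if cond > 1e4:
        warnings.warn(
            f"ill-conditioned temperature fit (condition number {cond:.2e}); "
            "widen the temperature range",
            stacklevel=2,
        )
    dg_t0, b, c_ex = coef  # b = C_ex - S_ex(T0)
    return ThermoFitPar(dG_T0=float(dg_t0), S_ex=float(c_ex - b), C_ex=float(c_ex), T0=T0)


def eq3_curve(par: ThermoFitPar, T) -> np.ndarray:
    """Evaluate the fitted temperature model on a temperature grid."""
    T = np.asarray(T, dtype=float)
    return (
        par.dG_T0
        + (par.C_ex - par.S_ex) * (T - par.T0)
        - par.C_ex * T * np.log(T / par.T0)
    )


# ---------------------------------------------------------------------------
# packaged reference data
# ---------------------------------------------------------------------------

_REFERENCE = {
    "table1_spce": (
        "table1_spce.csv",
        "sha256:1aec767573ce403afe5156f7124f0fc097cb09a9aa2f54599f7722239eca3c9f",
    ),
    "table2_epsilon": (
        "table2_epsilon.csv",
        "sha256:3b39ba4592d554e7359b63a991e999f4014c64b1c18adecb19fbd90b699a5d1d",
    ),
}


def load_reference(name: str = "table1_spce") -> pd.DataFrame:
    """Load a packaged reference table, verifying its checksum.

    ``table1_spce``: per-alkane hydration decomposition (12 linear
    alkanes, C1-C6, C8, C10, C12, C14, C16, C18) for the SPC/E water
    model; ``table2_epsilon``: original and updated alkane-water well
    depths for all water models.
    """
    if name not in _REFERENCE:
        raise KeyError(f"unknown reference table {name!r}")
    fname, pinned = _REFERENCE[name]
    text = (resources.files("hydralk.data.reference") / fname).read_text()
    digest = "sha256:" + hashlib.sha256(text.encode()).hexdigest()
    if digest != pinned:
        raise RuntimeError(
            f"reference fixture {fname} failed integrity check: {digest} != {pinned}"
        )
    return pd.read_csv(StringIO(text), comment="#")
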
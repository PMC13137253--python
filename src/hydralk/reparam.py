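"""Cavity-decomposition reparameterization of alkane-water well depths.

The hydration free energy of an alkane decomposes as

    dG_hyd = dG_cavity + dH_att,

where dG_cavity is the free energy of opening a solute-shaped cavity in
water and dH_att the (negative) alkane-water attraction enthalpy.  Given
experimental dG_hyd and cavity values, the experimental attraction
enthalpy follows by subtraction; comparing it with the simulated model
value for a series of alkanes yields a single global scale factor s on
the alkane-water Lennard-Jones well depth epsilon (dH_att is linear in
epsilon when the local solvent structure is assumed unchanged by the
small perturbation).  Scaled well depths then predict hydration free
energies directly, without re-simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forcefield import PairPar

__all__ = [
    "HydrationRecord",
    "ScaleFit",
    "attraction_from_decomposition",
    "update_epsilon",
    "fit_global_scale",
    "apply_scale",
    "predict_hydration",
    "build_reparam_table",
    "records_from_frame",
]


@dataclass
class HydrationRecord:
    """One alkane's hydration decomposition entries (kJ/mol).

    ``dg_hyd_exp``/``dg_cavity`` are inputs; ``dg_hyd_model`` and
    ``dh_att_model`` come from simulations with the original parameters;
    the remaining fields are derived (``None`` until filled).
    """

    n_carbons: int
    dg_hyd_exp: float
    dg_cavity: float
    dg_hyd_model: float | None = None
    dh_att_model: float | None = None
    dh_att_exp: float | None = None
    dh_att_updated: float | None = None
    dg_pred: float | None = None

    def __post_init__(self) -> None:
        if not (self.dg_cavity > 0.0):
            raise ValueError("dg_cavity must be positive")
        for name in ("dh_att_model", "dh_att_exp", "dh_att_updated"):
            v = getattr(self, name)
            if v is not None and v > 0.0:
                raise ValueError(f"{name} must be <= 0, got {v}")


@dataclass
class ScaleFit:
    """Fitted global well-depth scale ``s`` with the per-alkane ratios."""

    s: float
    ratios: list[float] = field(default_factory=list)
    method: str = "mean_ratio"

    def __post_init__(self) -> None:
        if not (self.s > 0.0):
            raise ValueError("scale s must be positive")


def attraction_from_decomposition(dg_hyd: float, dg_cavity: float) -> float:
    """Attraction enthalpy by decomposition: ``dG_hyd - dG_cavity``."""
    if not (math.isfinite(dg_hyd) and math.isfinite(dg_cavity)):
        raise ValueError("inputs must be finite")
    return dg_hyd - dg_cavity


def update_epsilon(eps: float, dh_target: float, dh_model: float) -> float:
    """Rescale a well depth by the target/model attraction-enthalpy ratio."""
    if dh_model == 0.0:
        raise ValueError("dh_model must be nonzero")
    if dh_target * dh_model <= 0.0:
        raise ValueError("dh_target and dh_model must share sign")
    return eps * dh_target / dh_model


def fit_global_scale(
    records: list[HydrationRecord], method: str = "mean_ratio"
) -> ScaleFit:
    """Fit the global well-depth scale from per-alkane enthalpy ratios.

    ``mean_ratio`` (default) is the unweighted mean of
    ``dh_att_exp / dh_att_model``; ``weighted_ls`` is the least-squares
    slope ``sum(dh_exp * dh_model) / sum(dh_model^2)``, which weights
    longer alkanes more heavily.
    """
    pairs = [
        (r.dh_att_exp, r.dh_att_model)
        for r in records
        if r.dh_att_exp is not None and r.dh_att_model is not None
    ]
    if not pairs:
        raise ValueError("need at least one record with dh_att_exp and dh_att_model")
    exp = np.array([p[0] for p in pairs])
    mod = np.array([p[1] for p in pairs])
    ratios = exp / mod
    if np.any(ratios <= 0.0):
        raise ValueError("all dh_att_exp/dh_att_model ratios must be positive")
    if method == "mean_ratio":
        s = float(ratios.mean())
    elif method == "weighted_ls":
        s = float(np.dot(exp, mod) / np.dot(mod, mod))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScaleFit(s=s, ratios=[float(x) for x in ratios], method=method)


def apply_scale(
    fit: ScaleFit,
    pairs: list[PairPar],
    records: list[HydrationRecord],
) -> tuple[list[PairPar], list[HydrationRecord]]:
    """Apply a fitted scale: multiply pair epsilons and model enthalpies by s.

    Records without a model enthalpy are passed through untouched (never
    imputed).  Returns new objects; inputs are not mutated.
    """
    scaled_pairs = [p.scaled(fit.s) for p in pairs]
    out_records = []
    for r in records:
        upd = None if r.dh_att_model is None else fit.s * r.dh_att_model
        out_records.append(
            HydrationRecord(
                n_carbons=r.n_carbons,
                dg_hyd_exp=r.dg_hyd_exp,
                dg_cavity=r.dg_cavity,
                dg_hyd_model=r.dg_hyd_model,
                dh_att_model=r.dh_att_model,
                dh_att_exp=r.dh_att_exp,
                dh_att_updated=upd,
                dg_pred=None if upd is None else r.dg_cavity + upd,
            )
        )
    return scaled_pairs, out_records


def predict_hydration(dg_cavity: float, dh_att_updated: float) -> float:
    """Predicted hydration free energy: cavity term plus updated attraction."""
    if not (math.isfinite(dg_cavity) and math.isfinite(dh_att_updated)):
        raise ValueError("inputs must be finite")
    return dg_cavity + dh_att_updated


def records_from_frame(df: pd.DataFrame) -> list[HydrationRecord]:
    """Build records from a table with columns n_carbons, dg_hyd_exp,
    dg_cavity and optionally dg_hyd_model, dh_att_model."""
    for col in ("n_carbons", "dg_hyd_exp", "dg_cavity"):
        if col not in df.columns:
            raise KeyError(f"missing required column {col!r}")

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    out = []
    for _, row in df.iterrows():
        out.append(
            HydrationRecord(
                n_carbons=int(row["n_carbons"]),
                dg_hyd_exp=float(row["dg_hyd_exp"]),
                dg_cavity=float(row["dg_cavity"]),
                dg_hyd_model=_opt(row, "dg_hyd_model"),
                dh_att_model=_opt(row, "dh_att_model"),
            )
        )
    return out


def build_reparam_table(
    records: list[HydrationRecord],
    pairs: dict[str, PairPar] | None = None,
    method: str = "mean_ratio",
) -> tuple[pd.DataFrame, ScaleFit, pd.DataFrame | None]:
    """End-to-end reparameterization report.

    Fills ``dh_att_exp`` from the decomposition, fits the global scale,
    fills ``dh_att_updated`` and ``dg_pred``, and (when a named pair
    table is given) returns the updated epsilon table alongside.

    Returns ``(per-alkane DataFrame, ScaleFit, epsilon DataFrame or None)``.
    """
    if not records:
        raise ValueError("no records given")
    filled = []
    for r in records:
        dh_exp = attraction_from_decomposition(r.dg_hyd_exp, r.dg_cavity)
        filled.append(
            HydrationRecord(
                n_carbons=r.n_carbons,
                dg_hyd_exp=r.dg_hyd_exp,
                dg_cavity=r.dg_cavity,
                dg_hyd_model=r.dg_hyd_model,
                dh_att_model=r.dh_att_model,
                dh_att_exp=dh_exp,
            )
        )
    fit = fit_global_scale(filled, method=method)
    pair_list = list(pairs.values()) if pairs else []
    scaled_pairs, out_records = apply_scale(fit, pair_list, filled)

    table = pd.DataFrame(
        {
            "n_carbons": [r.n_carbons for r in out_records],
            "dg_hyd_exp": [r.dg_hyd_exp for r in out_records],
            "dg_hyd_model": [r.dg_hyd_model for r in out_records],
            "dg_cavity": [r.dg_cavity for r in out_records],
            "dh_att_exp": [r.dh_att_exp for r in out_records],
            "dh_att_model": [r.dh_att_model for r in out_records],
            "dh_att_updated": [r.dh_att_updated for r in out_records],
            "dg_pred": [r.dg_pred for r in out_records],
        }
    )
    eps_table = None
    if pairs:
        eps_table = pd.DataFrame(
            {
                "pair": list(pairs.keys()),
                "eps_original": [p.epsilon for p in pairs.values()],
                "eps_updated": [p.epsilon for p in scaled_pairs],
            }
        )
    return table, fit, eps_table
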
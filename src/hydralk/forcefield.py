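"""Lennard-Jones site/pair parameters, mixing rules and pair potentials.

Units throughout the package: energies in kJ/mol, lengths in nm,
temperatures in K.  The Boltzmann constant is pinned to
``KB = 0.0083144621`` kJ/(mol K) so that epsilon/k_B values quoted in
Kelvin (TraPPE-UA convention) convert reproducibly.

The module covers the interaction forms needed for alchemical hydration
free-energy work on united-atom alkanes in water:

* plain Lennard-Jones, :func:`lj_energy`;
* the soft-core coupling form, :func:`softcore_energy`, which is finite
  at zero separation for any coupling strength below one;
* the cutoff-shifted potential, :func:`shifted_energy`;
* the analytic long-range (tail) correction, :func:`tail_correction`.

The tail correction follows the solute-solvent convention used by the
correction integrals in :mod:`hydralk.shift_corrections`: the default
``prefactor="half"`` carries a 2*pi*r^2 weight in the underlying integral
(8*pi*eps*sigma^3 in the closed form); ``prefactor="full"`` uses the
standard 4*pi*r^2 pair-counting convention, i.e. exactly twice the value.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "KB",
    "SitePar",
    "PairPar",
    "SoftCorePar",
    "CutoffSpec",
    "AlkaneSpec",
    "lorentz_berthelot",
    "lj_energy",
    "softcore_energy",
    "shifted_energy",
    "tail_correction",
    "load_sites",
    "alkane_cross_pairs",
]

#: Boltzmann constant, kJ/(mol K)
KB = 0.0083144621


@dataclass(frozen=True)
class SitePar:
    """A single Lennard-Jones interaction site.

    Parameters
    ----------
    name : str
        Site label (``CH4``, ``CH3``, ``CH2`` or ``O-<water model>``).
    epsilon : float
        Well depth, kJ/mol.  Must be >= 0.
    sigma : float
        Diameter, nm.  Must be > 0.
    """

    name: str
    epsilon: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("site name must be nonempty")
        if not (self.epsilon >= 0.0):
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class PairPar:
    """Mixed-pair Lennard-Jones parameters (epsilon kJ/mol, sigma nm)."""

    epsilon: float
    sigma: float
    origin: str = "explicit"

    def __post_init__(self) -> None:
        if not (self.epsilon >= 0.0):
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if not (self.sigma > 0.0):
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def scaled(self, s: float) -> "PairPar":
        """Return a copy with the well depth multiplied by ``s``."""
        return PairPar(self.epsilon * s, self.sigma, origin=f"{self.origin}*{s:g}")


@dataclass(frozen=True)
class SoftCorePar:
    """Soft-core constants: ``alpha`` (dimensionless) and lambda exponent ``n_exp``."""

    alpha: float = 0.5
    n_exp: int = 2

    def __post_init__(self) -> None:
        if not (self.alpha > 0.0):
            raise ValueError("alpha must be > 0")
        if self.n_exp < 1 or int(self.n_exp) != self.n_exp:
            raise ValueError("n_exp must be an integer >= 1")


@dataclass(frozen=True)
class CutoffSpec:
    """Spherical cutoff ``rc`` (nm) with independent shift/tail flags."""

    rc: float
    shifted: bool = False
    tail_corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.rc > 0.0):
            raise ValueError("rc must be > 0")


@dataclass(frozen=True)
class AlkaneSpec:
    """United-atom composition of a linear alkane.

    Methane is a single CH4 site; every longer chain is two CH3 ends plus
    ``n_carbons - 2`` CH2 middles.
    """

    n_carbons: int
    n_CH4: int = field(default=-1)
    n_CH3: int = field(default=-1)
    n_CH2: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be >= 1")
        expected = (1, 0, 0) if self.n_carbons == 1 else (0, 2, self.n_carbons - 2)
        # -1 sentinels mean "derive from n_carbons"
        counts = tuple(
            e if c == -1 else c
            for c, e in zip((self.n_CH4, self.n_CH3, self.n_CH2), expected)
        )
        if counts != expected:
            raise ValueError(
                f"site counts {counts} inconsistent with n_carbons={self.n_carbons}"
            )
        object.__setattr__(self, "n_CH4", counts[0])
        object.__setattr__(self, "n_CH3", counts[1])
        object.__setattr__(self, "n_CH2", counts[2])

    @property
    def site_labels(self) -> list[str]:
        """Site type per united atom, end-to-end along the chain."""
        if self.n_carbons == 1:
            return ["CH4"]
        return ["CH3"] + ["CH2"] * (self.n_carbons - 2) + ["CH3"]


def lorentz_berthelot(a: SitePar, b: SitePar) -> PairPar:
    """Lorentz-Berthelot mixing: arithmetic mean sigma, geometric mean epsilon."""
    return PairPar(
        epsilon=math.sqrt(a.epsilon * b.epsilon),
        sigma=0.5 * (a.sigma + b.sigma),
        origin="LB",
    )


def lj_energy(r, p: PairPar):
    """Plain Lennard-Jones energy ``4 eps [(sigma/r)^12 - (sigma/r)^6]``.

    ``r`` may be a scalar or array of separations (nm); ``r <= 0`` is rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("separation r must be > 0")
    x6 = (p.sigma / r) ** 6
    out = 4.0 * p.epsilon * (x6 * x6 - x6)
    return out if out.ndim else float(out)


def softcore_energy(lam: float, r, p: PairPar, sc: SoftCorePar = SoftCorePar()):
    """Soft-core Lennard-Jones coupling energy.

    ``lam^n * 4 eps [ (alpha (1-lam)^2 + (r/sigma)^6)^-2
                     - (alpha (1-lam)^2 + (r/sigma)^6)^-1 ]``

    Finite at ``r = 0`` for ``lam < 1``; collapses to :func:`lj_energy` at
    ``lam = 1`` and vanishes identically at ``lam = 0``.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0):
        raise ValueError("separation r must be >= 0")
    a = sc.alpha * (1.0 - lam) ** 2 + (r / p.sigma) ** 6
    with np.errstate(divide="ignore"):
        inv = 1.0 / a
    out = lam**sc.n_exp * 4.0 * p.epsilon * (inv * inv - inv)
    # lam = 0 must be exactly zero even where 1/a diverges (r=0, alpha term 0)
    out = np.where(np.isfinite(out), out, 0.0) if lam == 0.0 else out
    return out if out.ndim else float(out)


def shifted_energy(r, p: PairPar, cut: CutoffSpec):
    """Cutoff-shifted Lennard-Jones: ``u(r) - u(rc)`` inside, zero beyond."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ValueError("separation r must be > 0")
    u_rc = lj_energy(cut.rc, p)
    out = np.where(r <= cut.rc, 4.0 * p.epsilon * ((p.sigma / r) ** 12 - (p.sigma / r) ** 6) - u_rc, 0.0)
    return out if out.ndim else float(out)


def tail_correction(
    n_sites: int, rho: float, p: PairPar, rc: float, prefactor: str = "half"
) -> float:
    """Long-range (tail) energy beyond the cutoff, uniform-fluid assumption.

    ``N rho 8 pi eps sigma^3 [ sigma^9/(9 rc^9) - sigma^3/(3 rc^3) ]`` for the
    default ``prefactor="half"``; twice that for ``prefactor="full"``
    (standard 4*pi*r^2 solute-solvent pair counting).  Negative for
    ``rc >> sigma`` (the neglected interactions are attractive).
    """
    if not (rc > 0.0):
        raise ValueError("rc must be > 0")
    if rc <= p.sigma:
        raise ValueError(f"rc={rc} must exceed sigma={p.sigma}")
    fac = {"half": 1.0, "full": 2.0}[prefactor]
    s3 = p.sigma**3
    return (
        fac
        * n_sites
        * rho
        * 8.0
        * math.pi
        * p.epsilon
        * s3
        * (p.sigma**9 / (9.0 * rc**9) - s3 / (3.0 * rc**3))
    )


# ---------------------------------------------------------------------------
# parameter file loading
# ---------------------------------------------------------------------------

_BUILTIN = {
    "trappe_ua": "trappe_ua.toml",
    "spce": "spce.toml",
    "opc3": "opc3.toml",
    "tip4p2005": "tip4p2005.toml",
    "opc": "opc.toml",
    "hh_alkane": "hh_alkane.toml",
}


def load_sites(
    source: str | Path, sigma_defaults: dict[str, float] | None = None
) -> dict[str, SitePar]:
    """Load LJ sites from a TOML parameter file.

    ``source`` is either a builtin model key (``trappe_ua``, ``spce``,
    ``opc3``, ``tip4p2005``, ``opc``, ``hh_alkane``) or a filesystem path.
    Each ``[[site]]`` block needs ``name``, ``sigma_nm`` and one of
    ``epsilon_kJmol`` / ``epsilon_over_kB_K``.  Files may omit
    ``sigma_nm`` (the HH-alkane file ships well depths only); such sites
    must then be completed through ``sigma_defaults`` or they raise.
    """
    if isinstance(source, str) and source in _BUILTIN:
        res = resources.files("hydralk.data.forcefields") / _BUILTIN[source]
        raw = tomllib.loads(res.read_text())
    else:
        raw = tomllib.loads(Path(source).read_text())
    sigma_defaults = sigma_defaults or {}
    sites: dict[str, SitePar] = {}
    for blk in raw.get("site", []):
        name = blk["name"]
        if "epsilon_kJmol" in blk:
            eps = float(blk["epsilon_kJmol"])
        elif "epsilon_over_kB_K" in blk:
            eps = float(blk["epsilon_over_kB_K"]) * KB
        else:
            raise KeyError(f"site {name!r}: need epsilon_kJmol or epsilon_over_kB_K")
        sigma = blk.get("sigma_nm", sigma_defaults.get(name))
        if sigma is None:
            raise KeyError(
                f"site {name!r} has no sigma_nm and no sigma_defaults entry"
            )
        sites[name] = SitePar(name, eps, float(sigma))
    return sites


def alkane_cross_pairs(
    alkane: AlkaneSpec,
    alkane_sites: dict[str, SitePar],
    water_site: SitePar,
) -> list[PairPar]:
    """Per-united-atom alkane-water cross pairs (Lorentz-Berthelot)."""
    return [
        lorentz_berthelot(alkane_sites[label], water_site)
        for label in alkane.site_labels
    ]
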
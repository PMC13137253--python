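"""Free-energy perturbation over a lambda-window schedule.

The free energy of coupling a solute to its solvent is accumulated over
adjacent coupling windows as

    dG = -kB T sum_i ln( <V exp(-(U(lam_{i+1}) - U(lam_i)) / kB T)>_{lam_i}
                         / <V>_{lam_i} ),

the isothermal-isobaric exponential-averaging estimator.  With constant
volume (NVT sampling) the volume weights cancel and the expression
reduces to the plain Zwanzig average.  Every exponential average is
evaluated through a log-sum-exp so that large energy gaps cannot
overflow.

A forward pass (lambda 0 -> 1, decoupled -> fully coupled) yields the
hydration free energy; a reverse pass retraces 1 -> 0, and the signed sum
of the two totals (the hysteresis) is the closure diagnostic.  Replicate
runs are summarized by mean and sample standard deviation, mirroring the
three-independent-simulations protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .forcefield import KB

__all__ = [
    "ThermoState",
    "LambdaSchedule",
    "WindowSamples",
    "FepResult",
    "make_lambda_schedule",
    "window_increment",
    "window_increment_se",
    "accumulate",
    "hysteresis",
    "replicate_stats",
    "write_windows_tsv",
    "read_windows_tsv",
]


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state point: T (K), P (bar), and kB (kJ/(mol K))."""

    T: float
    P: float = 1.0
    kB: float = KB

    def __post_init__(self) -> None:
        if not (self.T > 0.0):
            raise ValueError("T must be > 0")

    @property
    def kT(self) -> float:
        return self.kB * self.T


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered lambda values from 0 to 1 with uniform spacing ``delta``."""

    values: tuple[float, ...]
    delta: float

    def __post_init__(self) -> None:
        v = self.values
        if v[0] != 0.0 or v[-1] != 1.0:
            raise ValueError("schedule must start at 0 and end at 1")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.values) - 1


def make_lambda_schedule(delta: float) -> LambdaSchedule:
    """Uniform schedule covering [0, 1] in ``round(1/delta)`` windows.

    ``delta`` must divide 1 to within 1e-9 (e.g. 0.025 -> 40 windows);
    otherwise the windows could not land exactly on lambda = 1.
    """
    if not (0.0 < delta <= 1.0):
        raise ValueError("delta must lie in (0, 1]")
    n = 1.0 / delta
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"1/delta = {n} is not an integer; pick delta = 1/k, e.g. 0.025 or 0.05"
        )
    n = int(round(n))
    values = tuple(i / n for i in range(n + 1))
    return LambdaSchedule(values=values, delta=1.0 / n)


@dataclass
class WindowSamples:
    """Per-window samples: energy gaps ``dU = U(lam_j) - U(lam_i)`` (kJ/mol)
    and box volumes ``V`` (nm^3), both recorded at configurations sampled
    in the ``lam_i`` ensemble."""

    lam_i: float
    lam_j: float
    dU: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.dU = np.asarray(self.dU, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.dU.size == 0 or self.dU.shape != self.V.shape:
            raise ValueError("dU and V must be nonempty arrays of equal length")
        if np.any(self.V <= 0.0):
            raise ValueError("volumes must be positive")


@dataclass
class FepResult:
    """Accumulated FEP total with per-window increments (kJ/mol)."""

    per_window: list[float]
    total: float
    direction: str
    temperature: float
    se: float | None = None
    per_window_se: list[float] = field(default_factory=list)


def window_increment(w: WindowSamples, ts: ThermoState) -> float:
    """Single-window increment ``-kT ln(<V e^{-dU/kT}> / <V>)``.

    Stabilized: with log-weights ``ln V - dU/kT`` the exponentials are
    shifted by their maximum inside :func:`scipy.special.logsumexp`, so
    arbitrarily large gaps cannot overflow.
    """
    kT = ts.kT
    log_v = np.log(w.V)
    num = logsumexp(log_v - w.dU / kT)
    den = logsumexp(log_v)
    return float(-kT * (num - den))


def window_increment_se(w: WindowSamples, ts: ThermoState, n_blocks: int = 10) -> float:
    """Block-averaged standard error of one window increment.

    The samples are split into ``n_blocks`` contiguous blocks (absorbing
    serial correlation at the block scale), the increment is evaluated on
    each block, and the standard error of the block mean is returned.
    """
    n = w.dU.size
    n_blocks = max(2, min(n_blocks, n))
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    vals = []
    for a, b in zip(edges, edges[1:]):
        if b > a:
            vals.append(window_increment(WindowSamples(w.lam_i, w.lam_j, w.dU[a:b], w.V[a:b]), ts))
    vals = np.asarray(vals)
    return float(vals.std(ddof=1) / math.sqrt(len(vals)))


def _direction(windows: list[WindowSamples]) -> str:
    if all(w.lam_j > w.lam_i for w in windows):
        return "forward"
    if all(w.lam_j < w.lam_i for w in windows):
        return "reverse"
    raise ValueError("windows mix forward and reverse gaps")


def accumulate(
    windows: list[WindowSamples], ts: ThermoState, with_se: bool = False
) -> FepResult:
    """Sum window increments over an adjacent, gap-free window chain."""
    if not windows:
        raise ValueError("no windows given")
    direction = _direction(windows)
    for a, b in zip(windows, windows[1:]):
        if not math.isclose(a.lam_j, b.lam_i, abs_tol=1e-12):
            raise ValueError(
                f"lambda coverage broken between {a.lam_j} and {b.lam_i}"
            )
    ends = (windows[0].lam_i, windows[-1].lam_j)
    expected = (0.0, 1.0) if direction == "forward" else (1.0, 0.0)
    if not all(math.isclose(x, y, abs_tol=1e-12) for x, y in zip(ends, expected)):
        raise ValueError(f"window chain covers {ends}, expected {expected}")
    per = [window_increment(w, ts) for w in windows]
    per_se = [window_increment_se(w, ts) for w in windows] if with_se else []
    se = math.sqrt(sum(s * s for s in per_se)) if per_se else None
    return FepResult(
        per_window=per,
        total=float(sum(per)),
        direction=direction,
        temperature=ts.T,
        se=se,
        per_window_se=per_se,
    )


def hysteresis(fwd: FepResult, rev: FepResult) -> float:
    """Signed closure error of a forward/reverse pair: ``fwd.total + rev.total``."""
    if fwd.direction == rev.direction:
        raise ValueError("need one forward and one reverse result")
    if not math.isclose(fwd.temperature, rev.temperature):
        raise ValueError("forward and reverse runs are at different temperatures")
    return fwd.total + rev.total


def replicate_stats(totals: list[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) over replicate totals."""
    if len(totals) < 2:
        raise ValueError("need at least two replicates")
    arr = np.asarray(totals, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


# ---------------------------------------------------------------------------
# TSV serialization (lam_i, lam_j, dU_kJmol, V_nm3) so externally produced
# window samples can feed the estimator
# ---------------------------------------------------------------------------

def write_windows_tsv(windows: list[WindowSamples], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lam_i\tlam_j\tdU_kJmol\tV_nm3\n")
        for w in windows:
            for du, v in zip(w.dU, w.V):
                fh.write(f"{w.lam_i:.10g}\t{w.lam_j:.10g}\t{du:.10g}\t{v:.10g}\n")


def read_windows_tsv(path: str | Path) -> list[WindowSamples]:
    data = np.loadtxt(path, skiprows=1)
    data = np.atleast_2d(data)
    windows = []
    # group rows by (lam_i, lam_j), preserving file order of first appearance
    seen: list[tuple[float, float]] = []
    for row in data:
        key = (row[0], row[1])
        if key not in seen:
            seen.append(key)
    for lam_i, lam_j in seen:
        mask = (data[:, 0] == lam_i) & (data[:, 1] == lam_j)
        windows.append(
            WindowSamples(lam_i, lam_j, data[mask, 2].copy(), data[mask, 3].copy())
        )
    return windows
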
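"""Minimal ODE model of the proximal BCR phosphorylation cascade.

The model tracks the phosphorylated fractions of three proteins in series —
pCD79a (X), pSYK (Y) and pPLCg2 (Z) — each treated as a covalent
modification cycle with Michaelis–Menten phosphorylation and
dephosphorylation.  Extracellular H2O2 (S) oxidises and thereby inactivates
the protein tyrosine phosphatases; the active-phosphatase fraction is a
decreasing Hill function

    P(S) = 1 / (1 + (S / k_ros)**H_ros),

which scales every dephosphorylation term.  Each phosphorylated protein
acts as the kinase of the next; SYK additionally carries a positive
feedback term.  With totals scaled to 1 the system is

    dX/dt = k_f (X_T - X)/(K_M1 + X_T - X) - k_r P X/(K_M2 + X)
    dY/dt = k_f X (Y_T - Y)/(K_M3 + Y_T - Y)
            + k_cat (Y_T - Y)/(k_pos + Y_T - Y) [* Y, optional]
            - k_r P Y/(K_M4 + Y)
    dZ/dt = k_f Y (Z_T - Z)/(K_M5 + Z_T - Z) - k_r P Z/(K_M6 + Z)

Cell-to-cell variability enters through per-cell lognormal draws of the
Michaelis constants and of k_ros; the successively smaller K_M1 > K_M3 >
K_M5 defaults propagate and sharpen sensitivity down the cascade.
Concentrations are dimensionless model units numerically identified with
experimental mM.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .patterns import InputPattern, concentration_at

__all__ = [
    "PROTEINS",
    "ModelParameters",
    "CellParameters",
    "PopulationTrajectories",
    "phosphatase_activity",
    "cascade_derivatives",
    "simulate_cell",
    "sample_population",
    "simulate_population",
    "steady_state",
    "percent_on",
    "ec50_percent",
    "interp_crossing",
    "rate_sweep",
]

#: Cascade order: readouts of the three phospho-channels.
PROTEINS = ("pCD79a", "pSYK", "pPLCg2")

_VARIED = ("K_M1", "K_M2", "K_M3", "K_M4", "K_M5", "K_M6", "k_ros")


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the cascade (defaults: the reference set).

    Rates are per minute, Michaelis constants and ``k_ros`` in mM-equivalent
    model units, protein totals scaled to 1.  ``s_x50`` sets the
    cell-to-cell variability scale of the lognormal parameter draws.
    """

    k_f: float = 1.0
    k_r: float = 10.0
    K_M1: float = 2.0
    K_M2: float = 1.0
    K_M3: float = 0.5
    K_M4: float = 1.0
    K_M5: float = 0.125
    K_M6: float = 1.0
    k_cat: float = 1.0
    k_pos: float = 1.0
    k_ros: float = 0.5
    H_ros: float = 1.0
    X_T: float = 1.0
    Y_T: float = 1.0
    Z_T: float = 1.0
    s_x50: float = 1.25
    feedback_includes_yp: bool = False

    def __post_init__(self) -> None:
        for name in ("k_f", "k_r", "k_cat", "k_pos", "k_ros", *(f"K_M{i}" for i in range(1, 7))):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("X_T", "Y_T", "Z_T"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.H_ros < 1:
            raise ValueError("H_ros must be >= 1")
        if self.s_x50 < 0:
            raise ValueError("s_x50 must be >= 0")

    @property
    def totals(self) -> np.ndarray:
        return np.array([self.X_T, self.Y_T, self.Z_T])

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)

    def to_yaml(self, path=None):
        import yaml

        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def from_yaml(cls, path) -> "ModelParameters":
        import yaml

        if hasattr(path, "read"):
            d = yaml.safe_load(path)
        else:
            with open(path) as fh:
                d = yaml.safe_load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class CellParameters:
    """Per-cell parameter draws; array fields have one entry per cell."""

    base: ModelParameters
    K_M1: np.ndarray
    K_M2: np.ndarray
    K_M3: np.ndarray
    K_M4: np.ndarray
    K_M5: np.ndarray
    K_M6: np.ndarray
    k_ros: np.ndarray

    def __post_init__(self) -> None:
        for name in _VARIED:
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, arr)
            if np.any(arr <= 0):
                raise ValueError(f"per-cell {name} draws must be > 0")
        ns = {len(getattr(self, name)) for name in _VARIED}
        if len(ns) != 1:
            raise ValueError("per-cell parameter arrays must share one length")

    @property
    def n_cells(self) -> int:
        return len(self.K_M1)

    @classmethod
    def homogeneous(cls, params: ModelParameters, n: int = 1) -> "CellParameters":
        return cls(base=params, **{k: np.full(n, getattr(params, k)) for k in _VARIED})

    def subset(self, idx) -> "CellParameters":
        return CellParameters(base=self.base, **{k: getattr(self, k)[idx] for k in _VARIED})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: getattr(self, k) for k in _VARIED})


def phosphatase_activity(S, k_ros, H_ros=1.0):
    """Active-phosphatase fraction P(S) = 1 / (1 + (S/k_ros)**H_ros)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("H2O2 concentration must be >= 0")
    out = 1.0 / (1.0 + (S / np.asarray(k_ros, dtype=float)) ** H_ros)
    return float(out) if out.ndim == 0 else out


def cascade_derivatives(state, S, cell: CellParameters, *, check_bounds: bool = True):
    """Right-hand side of the cascade ODEs.

    ``state`` has shape (3,) or (n_cells, 3) with columns (X_p, Y_p, Z_p);
    the return value has the same shape.
    """
    p = cell.base
    st = np.asarray(state, dtype=float)
    scalar = st.ndim == 1
    st = np.atleast_2d(st)
    totals = p.totals
    if check_bounds:
        tol = 1e-6
        if np.any(st < -tol) or np.any(st > totals + tol):
            raise ValueError("state outside [0, totals]")
    # protect Michaelis denominators against tiny solver excursions
    X, Y, Z = (np.clip(st[:, i], 0.0, totals[i]) for i in range(3))
    P = phosphatase_activity(S, cell.k_ros, p.H_ros)
    fX = p.X_T - X
    fY = p.Y_T - Y
    fZ = p.Z_T - Z
    dX = p.k_f * fX / (cell.K_M1 + fX) - p.k_r * P * X / (cell.K_M2 + X)
    fb = p.k_cat * fY / (p.k_pos + fY)
    if p.feedback_includes_yp:
        fb = fb * Y
    dY = p.k_f * X * fY / (cell.K_M3 + fY) + fb - p.k_r * P * Y / (cell.K_M4 + Y)
    dZ = p.k_f * Y * fZ / (cell.K_M5 + fZ) - p.k_r * P * Z / (cell.K_M6 + Z)
    out = np.stack([dX, dY, dZ], axis=1)
    return out[0] if scalar else out


@dataclass
class PopulationTrajectories:
    """Per-cell time courses of the three phospho-levels.

    ``levels`` has shape (n_cells, n_times, 3) in cascade order
    (pCD79a, pSYK, pPLCg2).
    """

    time_min: np.ndarray
    levels: np.ndarray
    cells: CellParameters
    pattern: InputPattern
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.levels.shape[0]

    @property
    def params(self) -> ModelParameters:
        return self.cells.base

    def protein(self, name: str) -> np.ndarray:
        """(n_cells, n_times) levels of one protein."""
        return self.levels[:, :, PROTEINS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (cell_id, time_min, protein, level) export."""
        n, m, _ = self.levels.shape
        recs = {
            "cell_id": np.repeat(np.arange(n), m * 3),
            "time_min": np.tile(np.repeat(self.time_min, 3), n),
            "protein": np.tile(list(PROTEINS), n * m),
            "level": self.levels.reshape(-1),
        }
        return pd.DataFrame(recs)


def _integrate(cells, pattern, t_grid, rtol, atol, method):
    """Integrate all cells jointly as one stacked system."""
    n = cells.n_cells
    totals = cells.base.totals
    if t_grid[-1] == t_grid[0]:
        # pre-stimulus state only: everything unphosphorylated
        return np.zeros((n, len(t_grid), 3))

    def rhs(t, y):
        st = y.reshape(n, 3)
        return cascade_derivatives(st, concentration_at(pattern, t), cells, check_bounds=False).reshape(-1)

    # split at the pattern's kinks so the adaptive solver never steps
    # across a discontinuity or corner of S(t)
    breaks = sorted({float(t_grid[0]), float(t_grid[-1])}
                    | {b for b in (pattern.t0, pattern.end_time) if t_grid[0] < b < t_grid[-1]})
    y = np.zeros(3 * n)
    pieces = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        mask = (t_grid >= a) & (t_grid <= b) if not pieces else (t_grid > a) & (t_grid <= b)
        t_eval = t_grid[mask]
        sol = solve_ivp(
            rhs, (a, b), y, method=method, rtol=rtol, atol=atol,
            t_eval=t_eval if len(t_eval) else None, dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed on [{a}, {b}]: {sol.message}")
        if len(t_eval):
            pieces.append(sol.y.T.reshape(-1, n, 3))
        y = sol.y[:, -1] if sol.y.shape[1] else y
    levels = np.concatenate(pieces, axis=0) if pieces else np.zeros((0, n, 3))
    levels = np.clip(levels.transpose(1, 0, 2), 0.0, totals)
    return levels


def simulate_cell(
    cell: CellParameters,
    pattern: InputPattern,
    t_grid,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
) -> PopulationTrajectories:
    """Integrate one cell (or a pre-built cell set) from the unphosphorylated
    state under the given input pattern, evaluated on ``t_grid`` (min)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid[0] != 0:
        raise ValueError("t_grid must start at 0 (pre-stimulus state)")
    levels = _integrate(cell, pattern, t_grid, rtol, atol, method)
    return PopulationTrajectories(time_min=t_grid, levels=levels, cells=cell, pattern=pattern)


def lognormal_draws(rng, mean, variance, size):
    """Lognormal draws with the given *arithmetic* mean and variance."""
    if variance == 0:
        return np.full(size, float(mean))
    sigma2 = np.log1p(variance / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def sample_population(params: ModelParameters, n: int, seed=None) -> CellParameters:
    """Draw ``n`` cells' Michaelis constants and k_ros.

    Each varied parameter is drawn independently from a lognormal with
    arithmetic mean ``m`` (the reference value) and arithmetic variance
    ``m * s_x50**2``, moment-matched to the underlying normal.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {}
    for name in _VARIED:
        m = getattr(params, name)
        draws[name] = lognormal_draws(rng, m, m * params.s_x50**2, n)
    return CellParameters(base=params, **draws)


def simulate_population(
    params: ModelParameters,
    pattern: InputPattern,
    n: int,
    t_grid,
    seed=None,
    *,
    cells: CellParameters | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    method: str = "RK45",
) -> PopulationTrajectories:
    """Simulate a heterogeneous population under one input pattern.

    Pass ``cells`` to reuse an existing draw (e.g. across patterns of a
    rate sweep); otherwise ``n`` cells are drawn with ``seed``.
    """
    if cells is None:
        cells = sample_population(params, n, seed)
    traj = simulate_cell(cells, pattern, t_grid, rtol=rtol, atol=atol, method=method)
    traj.seed = seed
    return traj


def steady_state(cell: CellParameters, S: float, *, xtol: float = 1e-12) -> np.ndarray:
    """Algebraic steady state of the cascade at constant stimulus ``S``.

    Solves the three balance equations sequentially by bracketing root
    finding (X feeds Y feeds Z); independent of the ODE integrator and used
    as its oracle.  Returns shape (n_cells, 3).
    """
    p = cell.base
    P = phosphatase_activity(S, cell.k_ros, p.H_ros)
    P = np.broadcast_to(np.atleast_1d(P), (cell.n_cells,))
    out = np.zeros((cell.n_cells, 3))
    for i in range(cell.n_cells):
        def fx(x):
            return (p.k_f * (p.X_T - x) / (cell.K_M1[i] + p.X_T - x)
                    - p.k_r * P[i] * x / (cell.K_M2[i] + x))

        x = brentq(fx, 0.0, p.X_T, xtol=xtol) if fx(p.X_T) < 0 else p.X_T

        def fy(y):
            fb = p.k_cat * (p.Y_T - y) / (p.k_pos + p.Y_T - y)
            if p.feedback_includes_yp:
                fb *= y
            return (p.k_f * x * (p.Y_T - y) / (cell.K_M3[i] + p.Y_T - y) + fb
                    - p.k_r * P[i] * y / (cell.K_M4[i] + y))

        y = brentq(fy, 0.0, p.Y_T, xtol=xtol) if fy(p.Y_T) < 0 else p.Y_T

        def fz(z):
            return (p.k_f * y * (p.Z_T - z) / (cell.K_M5[i] + p.Z_T - z)
                    - p.k_r * P[i] * z / (cell.K_M6[i] + z))

        z = brentq(fz, 0.0, p.Z_T, xtol=xtol) if fz(p.Z_T) < 0 else p.Z_T
        out[i] = (x, y, z)
    return out


def percent_on(traj: PopulationTrajectories, activation_fraction: float = 0.3) -> pd.DataFrame:
    """Percentage of cells whose phospho-level exceeds a fraction of its total.

    A cell counts as ON for a protein at a time point iff its level is
    strictly above ``activation_fraction`` of that protein's total.
    Returns a frame indexed by time with one column per protein.
    """
    if not 0 < activation_fraction < 1:
        raise ValueError("activation_fraction must lie in (0, 1)")
    if traj.n_cells == 0:
        raise ValueError("empty population")
    thr = activation_fraction * traj.params.totals
    pct = 100.0 * np.mean(traj.levels > thr, axis=0)  # (n_times, 3)
    return pd.DataFrame(pct, index=pd.Index(traj.time_min, name="time_min"), columns=list(PROTEINS))


def interp_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float:
    """First linear-interpolated crossing of ``y`` above ``level`` along x.

    Returns NaN when the level is never reached.  ``x`` must be
    non-decreasing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be non-decreasing")
    above = y >= level
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(x[0])
    x0, x1, y0, y1 = x[i - 1], x[i], y[i - 1], y[i]
    if y1 == y0:
        return float(x1)
    return float(x0 + (level - y0) * (x1 - x0) / (y1 - y0))


def ec50_percent(
    traj: PopulationTrajectories,
    pattern: InputPattern | None = None,
    activation_fraction: float = 0.3,
) -> dict:
    """Concentration reached during a gradient when 50% of cells are ON.

    Maps each sampled time within the gradient window to the concentration
    reached, then linearly interpolates the %ON-vs-concentration curve to
    its 50% crossing.  Returns ``{protein: concentration}`` with NaN where
    50% is never reached during the gradient.
    """
    pattern = pattern or traj.pattern
    if not pattern.is_gradient:
        raise ValueError("EC50% is defined for gradient patterns only")
    pct = percent_on(traj, activation_fraction)
    in_window = (traj.time_min >= pattern.t0) & (traj.time_min <= pattern.end_time)
    t = traj.time_min[in_window]
    conc = concentration_at(pattern, t)
    if np.any(np.diff(conc) < 0):
        raise ValueError("concentration mapping must be non-decreasing")
    return {
        prot: interp_crossing(conc, pct[prot].to_numpy()[in_window], 50.0)
        for prot in PROTEINS
    }


def rate_sweep(
    params: ModelParameters,
    rates,
    c_final: float = 10.0,
    n: int = 1000,
    seed=None,
    *,
    n_conc: int = 81,
    activation_fraction: float = 0.3,
    cells: CellParameters | None = None,
) -> pd.DataFrame:
    """EC50% of each protein across linear-gradient rates.

    Each rate ``r`` defines a linear gradient of duration ``c_final / r``;
    the same population draw is reused across rates (variance reduction).
    Returns a tidy frame (rate, protein, ec50_percent); NaN marks rates for
    which 50% ON is never reached during the gradient.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("gradient rates must be > 0")
    if cells is None:
        cells = sample_population(params, n, seed)
    rows = []
    for r in rates:
        T = c_final / r
        pattern = InputPattern("linear", c_max=c_final, T=T)
        t_grid = np.linspace(0.0, T, n_conc)
        traj = simulate_population(params, pattern, n, t_grid, cells=cells)
        ec = ec50_percent(traj, pattern, activation_fraction)
        for prot in PROTEINS:
            rows.append({"rate": r, "protein": prot, "ec50_percent": ec[prot]})
    return pd.DataFrame(rows)
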
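"""Dynamic H2O2 input patterns and pump dosing schedules.

An :class:`InputPattern` describes the extracellular H2O2 concentration a
cell suspension experiences over time: an instantaneous step, a linear ramp,
a cubic ("exponential") ramp with accelerating rate, or no stimulus at all.
Concentrations are expressed in model units numerically identified with
experimental mM; time is in minutes.  H2O2 degradation is taken as
negligible on the experimental time scale, so every pattern holds its
plateau concentration once the gradient has finished.

A :class:`PumpSchedule` realises a pattern in a stirred vessel by dosing
concentrated stock: the mass balance

    d(C*V)/dt = q(t) * c_stock,    dV/dt = q(t)

is inverted per time step to obtain the piecewise-constant flow rate q(t)
that reproduces the target profile, with sample withdrawals treated as
instantaneous, concentration-preserving volume losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputPattern",
    "PumpSchedule",
    "concentration_at",
    "rate_at",
    "mean_rate",
    "cumulative_exposure",
    "time_to_reach",
    "pump_schedule",
    "simulate_schedule",
    "parse_pattern",
]

_KINDS = ("step", "linear", "exponential", "constant-zero")
_GRADIENT_KINDS = ("linear", "exponential")


@dataclass(frozen=True)
class InputPattern:
    """A non-decreasing H2O2 concentration time course.

    Parameters
    ----------
    kind:
        ``"step"``, ``"linear"``, ``"exponential"`` or ``"constant-zero"``.
        The exponential ramp is cubic in time, ``c_max * ((t - t0)/T)**3``,
        so its rate increases throughout the gradient.
    c_max:
        Plateau concentration (mM-equivalent model units).
    T:
        Gradient duration in minutes (ignored for step / constant-zero).
    t0:
        Onset time in minutes (default 0).
    """

    kind: str
    c_max: float = 0.0
    T: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}; expected one of {_KINDS}")
        if self.c_max < 0:
            raise ValueError("c_max must be >= 0")
        if self.kind in _GRADIENT_KINDS and self.T <= 0:
            raise ValueError("gradient duration T must be > 0")
        if self.t0 < 0:
            raise ValueError("onset time t0 must be >= 0")

    # -- accessors ---------------------------------------------------------

    @property
    def is_gradient(self) -> bool:
        return self.kind in _GRADIENT_KINDS

    @property
    def end_time(self) -> float:
        """Time at which the pattern reaches (and holds) its plateau."""
        return self.t0 + self.T if self.is_gradient else self.t0

    def concentration(self, t):
        return concentration_at(self, t)

    def rate(self, t):
        return rate_at(self, t)

    def mean_rate(self) -> float:
        return mean_rate(self)

    def cumulative_exposure(self, t):
        return cumulative_exposure(self, t)

    def time_to_reach(self, c: float) -> float:
        return time_to_reach(self, c)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {"kind": self.kind, "c_max": self.c_max, "T": self.T, "t0": self.t0}

    @classmethod
    def from_dict(cls, d: dict) -> "InputPattern":
        return cls(
            kind=d["kind"],
            c_max=float(d.get("c_max", 0.0)),
            T=float(d.get("T", 1.0)),
            t0=float(d.get("t0", 0.0)),
        )


def parse_pattern(spec: str) -> InputPattern:
    """Parse a compact ``kind:c_max[:T[:t0]]`` pattern string.

    ``"linear:10:20"`` is a 20-min linear gradient to 10 mM;
    ``"step:25"`` a step to 25 mM; ``"zero"`` the unstimulated control.
    """
    parts = spec.split(":")
    kind = parts[0]
    if kind in ("zero", "constant-zero"):
        return InputPattern("constant-zero")
    if kind == "step":
        if len(parts) < 2:
            raise ValueError("step pattern needs a concentration, e.g. 'step:10'")
        t0 = float(parts[2]) if len(parts) > 2 else 0.0
        return InputPattern("step", c_max=float(parts[1]), t0=t0)
    if kind in _GRADIENT_KINDS:
        if len(parts) < 3:
            raise ValueError(f"{kind} pattern needs c_max and duration, e.g. '{kind}:10:60'")
        t0 = float(parts[3]) if len(parts) > 3 else 0.0
        return InputPattern(kind, c_max=float(parts[1]), T=float(parts[2]), t0=t0)
    raise ValueError(f"cannot parse pattern spec {spec!r}")


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def concentration_at(pattern: InputPattern, t):
    """Concentration at time ``t`` (min); scalar in, scalar out."""
    tt = _check_time(t)
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)
    c = np.zeros_like(tt)
    if pattern.kind == "constant-zero":
        pass
    elif pattern.kind == "step":
        c[tt >= pattern.t0] = pattern.c_max
    else:
        u = np.clip((tt - pattern.t0) / pattern.T, 0.0, 1.0)
        if pattern.kind == "linear":
            c = pattern.c_max * u
        else:  # exponential (cubic) ramp
            c = pattern.c_max * u**3
    return float(c[0]) if scalar else c


def rate_at(pattern: InputPattern, t):
    """Time derivative of the concentration (mM/min); 0 outside the ramp."""
    tt = _check_time(t)
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)
    r = np.zeros_like(tt)
    if pattern.is_gradient:
        u = (tt - pattern.t0) / pattern.T
        inside = (u >= 0) & (u <= 1)
        if pattern.kind == "linear":
            r[inside] = pattern.c_max / pattern.T
        else:
            r[inside] = 3.0 * pattern.c_max * u[inside] ** 2 / pattern.T
    return float(r[0]) if scalar else r


def mean_rate(pattern: InputPattern) -> float:
    """Average rate of increase ``c_max / T`` over the gradient window."""
    if not pattern.is_gradient:
        raise ValueError(f"mean rate is undefined for {pattern.kind!r} patterns")
    return pattern.c_max / pattern.T


def cumulative_exposure(pattern: InputPattern, t):
    """Exact integral of the concentration from 0 to ``t`` (mM * min)."""
    tt = _check_time(t)
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)
    e = np.zeros_like(tt)
    if pattern.kind == "constant-zero":
        pass
    elif pattern.kind == "step":
        e = pattern.c_max * np.clip(tt - pattern.t0, 0.0, None)
    else:
        T, cm = pattern.T, pattern.c_max
        dt_in = np.clip(tt - pattern.t0, 0.0, T)
        dt_post = np.clip(tt - pattern.t0 - T, 0.0, None)
        if pattern.kind == "linear":
            e = cm * dt_in**2 / (2.0 * T) + cm * dt_post
        else:
            e = cm * dt_in**4 / (4.0 * T**3) + cm * dt_post
    return float(e[0]) if scalar else e


def time_to_reach(pattern: InputPattern, c: float) -> float:
    """Earliest time at which the pattern reaches concentration ``c``."""
    if c < 0 or c > pattern.c_max:
        raise ValueError(f"concentration {c} outside [0, c_max={pattern.c_max}]")
    if c == 0:
        return 0.0
    if pattern.kind == "constant-zero":
        raise ValueError("constant-zero pattern never reaches a positive concentration")
    if pattern.kind == "step":
        return pattern.t0
    u = c / pattern.c_max
    if pattern.kind == "exponential":
        u = u ** (1.0 / 3.0)
    return pattern.t0 + pattern.T * u


# ---------------------------------------------------------------------------
# Pump schedules
# ---------------------------------------------------------------------------


@dataclass
class PumpSchedule:
    """Piecewise-constant dosing schedule realising a target pattern.

    ``time_min`` holds the grid edges (length m+1); ``flow`` the constant
    flow on each interval (volume/min, length m); ``volume`` the vessel
    volume at the grid edges after any withdrawal at that instant.
    """

    pattern: InputPattern
    c_stock: float
    time_min: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    samples: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": np.round(self.time_min[:-1] * 60.0, 6),
                "flow_mL_per_min": self.flow,
                "volume_mL": self.volume[:-1],
            }
        )


def pump_schedule(
    pattern: InputPattern,
    V0: float,
    c_stock: float,
    samples: list | None = None,
    dt: float = 1.0 / 60.0,
    t_end: float | None = None,
) -> PumpSchedule:
    """Compute the dosing flow profile that realises ``pattern`` in a vessel.

    Parameters
    ----------
    V0:
        Initial vessel volume (same volume unit as the sample volumes,
        conventionally mL).
    c_stock:
        Stock concentration; must exceed ``pattern.c_max``.
    samples:
        Optional ``(time_min, volume)`` withdrawal events.  Withdrawals are
        instantaneous and leave the concentration unchanged.
    dt:
        Grid step in minutes (default 1 s).

    The flow on each interval is the exact mass-balance inversion

        q_i = V_i * (C*_{i+1} - C_i) / (dt * (c_stock - C*_{i+1})),

    so the forward simulation lands on the target concentration at every
    grid point.  Decreasing targets (q < 0) are infeasible and rejected.
    """
    samples = sorted(samples or [], key=lambda s: s[0])
    if V0 <= 0:
        raise ValueError("initial volume must be > 0")
    if c_stock <= pattern.c_max:
        raise ValueError("stock concentration must exceed the target c_max")
    total_withdrawn = sum(v for _, v in samples)
    if total_withdrawn >= V0:
        raise ValueError("sampled volume exceeds the initial vessel volume")

    if t_end is None:
        t_end = max(pattern.end_time, max((t for t, _ in samples), default=0.0))
    t_end = max(t_end, dt)
    n = int(np.ceil(t_end / dt - 1e-9))
    grid = np.arange(n + 1) * dt
    # snap withdrawals to the nearest grid point
    withdraw = np.zeros(n + 1)
    for t_s, v_s in samples:
        withdraw[int(round(t_s / dt))] += v_s

    flow = np.zeros(n)
    volume = np.zeros(n + 1)
    V = V0 - withdraw[0]
    volume[0] = V
    C = 0.0  # vessel starts clean; a step at t0=0 is dosed over the first interval
    for i in range(n):
        c_target = concentration_at(pattern, grid[i + 1])
        q = V * (c_target - C) / (dt * (c_stock - c_target))
        if q < -1e-9 * max(1.0, V):
            raise ValueError(
                f"target concentration decreases at t={grid[i + 1]:.4f} min; "
                "a dosing-only schedule cannot realise it"
            )
        q = max(q, 0.0)
        flow[i] = q
        V = V + q * dt - withdraw[i + 1]
        if V <= 0:
            raise ValueError(f"vessel volume exhausted at t={grid[i + 1]:.4f} min")
        C = c_target
        volume[i + 1] = V
    return PumpSchedule(
        pattern=pattern,
        c_stock=c_stock,
        time_min=grid,
        flow=flow,
        volume=volume,
        samples=samples,
    )


def simulate_schedule(schedule: PumpSchedule, V0: float) -> np.ndarray:
    """Forward mass-balance simulation of a schedule.

    Returns the vessel concentration at each grid point; independent of the
    inversion in :func:`pump_schedule`, this integrates the dosing mass
    balance from scratch and serves as its oracle.
    """
    grid = schedule.time_min
    withdraw = np.zeros(len(grid))
    for t_s, v_s in schedule.samples:
        dt = grid[1] - grid[0] if len(grid) > 1 else 1.0
        withdraw[int(round(t_s / dt))] += v_s

    conc = np.zeros(len(grid))
    V = V0 - withdraw[0]
    mass = 0.0  # dissolved H2O2 amount (conc * volume)
    for i in range(len(grid) - 1):
        dt = grid[i + 1] - grid[i]
        q = schedule.flow[i]
        added = q * dt
        mass += added * schedule.c_stock
        V += added
        c_new = mass / V
        # withdrawal removes proportional mass, concentration unchanged
        if withdraw[i + 1] > 0:
            mass -= c_new * withdraw[i + 1]
            V -= withdraw[i + 1]
        conc[i + 1] = c_new
    return conc
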
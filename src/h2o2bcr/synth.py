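"""Synthetic flow-cytometry experiments with known ground truth.

The generator drives the cascade ODE model through a measurement model to
produce event tables indistinguishable in structure from real phospho-flow
exports: scatter and viability channels with debris, doublet and dead
subpopulations (so gating is exercised), and three phospho channels whose
signal is an affine map of the simulated phospho-level times multiplicative
lognormal noise,

    F = (alpha + beta * level) * exp(noise_sd * N(0, 1)).

The affine-plus-lognormal form reproduces the log-scale unimodal/bimodal
density shapes of real data and the way small shifts can vanish into the
autofluorescence background.  Every generated experiment carries a
:class:`GroundTruth` — generating parameters, per-cell draws, true
phospho-levels and true %ON per sample — sufficient to recompute each
downstream estimate exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cytometry import PHOSPHO_CHANNELS, EventTable
from .model import (
    PROTEINS,
    ModelParameters,
    sample_population,
    simulate_population,
)
from .patterns import InputPattern, concentration_at, time_to_reach

__all__ = [
    "MeasurementModel",
    "GroundTruth",
    "generate_static_experiment",
    "generate_gradient_experiment",
    "make_fixture_suite",
]


@dataclass(frozen=True)
class MeasurementModel:
    """Affine-plus-lognormal map from phospho-levels to channel intensities.

    ``alpha`` is the per-channel autofluorescence offset in cascade order
    (pCD79a, pSYK, pPLCg2), ``beta`` the gain (intensity per unit scaled
    phospho-level), ``noise_log_sd`` the log-sd of the multiplicative
    measurement noise.  The default offsets are calibrated against the
    model's basal (unstimulated) level distributions so that the control
    sample's 97.5th-percentile ON threshold corresponds to the 30%-of-
    maximum activation criterion used on the model side; channels with a
    lower basal phospho-level (pPLCg2) need a larger offset for the two
    conventions to coincide.  Junk-event fractions and the
    scatter/viability locations of each subpopulation are chosen so the
    default gate chain separates them.
    """

    alpha: tuple = (290.0, 255.0, 460.0)
    beta: float = 1000.0
    noise_log_sd: float = 0.25
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.03
    dead_fraction: float = 0.02
    # (location, sd) per scatter channel for intact single cells
    fsc_a: tuple = (1.1e5, 2.0e4)
    ssc_a: tuple = (5.0e4, 1.2e4)
    fsc_w: tuple = (6.5e4, 6.0e3)
    viability_live: tuple = (3.0e2, 0.45)   # lognormal: (median, log-sd)
    viability_dead: tuple = (8.0e3, 0.35)

    def __post_init__(self) -> None:
        if np.isscalar(self.alpha):
            object.__setattr__(self, "alpha", (float(self.alpha),) * 3)
        else:
            object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        fr = (self.debris_fraction, self.doublet_fraction, self.dead_fraction)
        if any(f < 0 or f > 1 for f in fr) or sum(fr) >= 1:
            raise ValueError("junk fractions must lie in [0, 1] and sum to < 1")
        if self.beta <= 0:
            raise ValueError("gain beta must be > 0")

    def to_dict(self) -> dict:
        return {
            "alpha": list(self.alpha), "beta": self.beta, "noise_log_sd": self.noise_log_sd,
            "debris_fraction": self.debris_fraction,
            "doublet_fraction": self.doublet_fraction,
            "dead_fraction": self.dead_fraction,
            "fsc_a": list(self.fsc_a), "ssc_a": list(self.ssc_a),
            "fsc_w": list(self.fsc_w),
            "viability_live": list(self.viability_live),
            "viability_dead": list(self.viability_dead),
        }


@dataclass
class GroundTruth:
    """Everything needed to recompute downstream estimates exactly."""

    params: ModelParameters
    measurement: MeasurementModel
    seed: int
    activation_fraction: float = 0.3
    #: per-replicate per-cell parameter draws, replicate -> DataFrame
    cells: dict = field(default_factory=dict)
    #: one record per sample: metadata, true %ON and true mean level per protein
    samples: list = field(default_factory=list)

    def true_percent_on(self, sample_id: str) -> dict:
        for rec in self.samples:
            if rec["sample_id"] == sample_id:
                return {p: rec[f"true_pct_on_{p}"] for p in PROTEINS}
        raise KeyError(sample_id)

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "measurement": self.measurement.to_dict(),
            "seed": self.seed,
            "activation_fraction": self.activation_fraction,
            "cells": {rep: df.to_dict(orient="list") for rep, df in self.cells.items()},
            "samples": self.samples,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        gt = cls(
            params=ModelParameters.from_dict(d["params"]),
            measurement=MeasurementModel(
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["measurement"].items()}
            ),
            seed=d["seed"],
            activation_fraction=d["activation_fraction"],
        )
        gt.cells = {rep: pd.DataFrame(v) for rep, v in d["cells"].items()}
        gt.samples = d["samples"]
        return gt


def _measure_phospho(levels_row, meas: MeasurementModel, rng, n: int) -> dict:
    """Map one sample's per-event phospho-levels to channel intensities."""
    out = {}
    for j, (prot, ch) in enumerate(PHOSPHO_CHANNELS.items()):
        clean = meas.alpha[j] + meas.beta * levels_row[:, j]
        noise = np.exp(meas.noise_log_sd * rng.standard_normal(n)) if meas.noise_log_sd > 0 else 1.0
        out[ch] = clean * noise
    return out


def _scatter_live(meas: MeasurementModel, rng, n: int) -> dict:
    fsc_a = rng.normal(*meas.fsc_a, size=n).clip(min=1.0)
    return {
        "FSC_A": fsc_a,
        "FSC_H": (fsc_a * rng.normal(0.95, 0.05, size=n)).clip(min=1.0),
        "FSC_W": rng.normal(*meas.fsc_w, size=n).clip(min=1.0),
        "SSC_A": rng.normal(*meas.ssc_a, size=n).clip(min=1.0),
        "viability": meas.viability_live[0] * np.exp(
            meas.viability_live[1] * rng.standard_normal(n)
        ),
    }


def _junk_events(meas: MeasurementModel, rng, kind: str, n: int,
                 donor_levels: np.ndarray) -> pd.DataFrame:
    """Debris, doublet or dead events with scatter signatures the gates catch."""
    cols = _scatter_live(meas, rng, n)
    if kind == "debris":
        cols["FSC_A"] = rng.normal(1.2e4, 5e3, size=n).clip(min=1.0)
        cols["FSC_H"] = (cols["FSC_A"] * rng.normal(0.95, 0.05, size=n)).clip(min=1.0)
        cols["SSC_A"] = rng.normal(4e3, 1.5e3, size=n).clip(min=1.0)
        levels = np.zeros((n, 3))
    elif kind == "doublet":
        cols["FSC_W"] = rng.normal(1.25e5, 8e3, size=n).clip(min=1.0)
        cols["FSC_A"] = (cols["FSC_A"] * 1.8).clip(min=1.0)
        idx = rng.integers(0, len(donor_levels), size=(n, 2))
        levels = donor_levels[idx[:, 0]] + donor_levels[idx[:, 1]]
    elif kind == "dead":
        cols["viability"] = meas.viability_dead[0] * np.exp(
            meas.viability_dead[1] * rng.standard_normal(n)
        )
        idx = rng.integers(0, len(donor_levels), size=n)
        levels = donor_levels[idx]
    else:  # pragma: no cover
        raise ValueError(kind)
    cols.update(_measure_phospho(levels, meas, rng, n))
    return pd.DataFrame(cols)


def _make_sample(sample_id, meta, levels_pop, meas, rng, n_events,
                 activation_fraction, totals):
    """Assemble one sample's events plus its ground-truth record."""
    n_cells = len(levels_pop)
    n_debris = int(round(n_events * meas.debris_fraction))
    n_doublet = int(round(n_events * meas.doublet_fraction))
    n_dead = int(round(n_events * meas.dead_fraction))
    n_live = n_events - n_debris - n_doublet - n_dead

    idx = rng.integers(0, n_cells, size=n_live)
    live_levels = levels_pop[idx]
    live = _scatter_live(meas, rng, n_live)
    live.update(_measure_phospho(live_levels, meas, rng, n_live))
    parts = [pd.DataFrame(live)]
    for kind, n_k in (("debris", n_debris), ("doublet", n_doublet), ("dead", n_dead)):
        if n_k > 0:
            parts.append(_junk_events(meas, rng, kind, n_k, levels_pop))
    ev = pd.concat(parts, ignore_index=True)
    ev = ev.iloc[rng.permutation(len(ev))].reset_index(drop=True)
    ev.insert(0, "sample_id", sample_id)

    rec = dict(meta, sample_id=sample_id, n_events=int(n_events))
    for j, prot in enumerate(PROTEINS):
        thr = activation_fraction * totals[j]
        rec[f"true_pct_on_{prot}"] = float(100.0 * np.mean(levels_pop[:, j] > thr))
        rec[f"true_mean_level_{prot}"] = float(levels_pop[:, j].mean())
    return ev, rec


def generate_static_experiment(
    params: ModelParameters,
    doses,
    times,
    n_events: int = 10_000,
    meas: MeasurementModel | None = None,
    seed: int = 0,
    *,
    n_cells: int = 1000,
    replicates: int = 1,
    condition: str = "static",
    activation_fraction: float = 0.3,
):
    """Simulate a static step-dose experiment and measure it.

    For every (replicate, dose) a fresh model population is simulated; each
    (dose, time) sample resamples ``n_events`` events from that population
    through the measurement model, with debris/doublet/dead events injected
    at the configured fractions.  Returns ``(EventTable, GroundTruth)``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    meas = meas or MeasurementModel()
    doses = [float(d) for d in doses]
    times = sorted(float(t) for t in times)
    if times and times[0] < 0:
        raise ValueError("times must be >= 0")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(params=params, measurement=meas, seed=seed,
                        activation_fraction=activation_fraction)
    t_grid = np.unique(np.r_[0.0, times])
    frames = []
    for r in range(1, replicates + 1):
        rep = f"R{r}"
        cells = sample_population(params, n_cells, seed=rng.integers(2**31))
        truth.cells[rep] = cells.to_frame()
        for dose in doses:
            pattern = (InputPattern("step", c_max=dose) if dose > 0
                       else InputPattern("constant-zero"))
            traj = simulate_population(params, pattern, n_cells, t_grid, cells=cells)
            for t in times:
                ti = int(np.flatnonzero(t_grid == t)[0])
                sample_id = f"{condition}_{rep}_d{dose:g}_t{t:g}"
                meta = {"condition": condition, "replicate": rep,
                        "time_min": t, "conc_mM": dose}
                ev, rec = _make_sample(sample_id, meta, traj.levels[:, ti, :], meas,
                                       rng, n_events, activation_fraction, params.totals)
                frames.append(_attach_meta(ev, meta))
                truth.samples.append(rec)
    return EventTable(pd.concat(frames, ignore_index=True)), truth


def generate_gradient_experiment(
    params: ModelParameters,
    pattern: InputPattern,
    sample_concentrations,
    n_events: int = 10_000,
    meas: MeasurementModel | None = None,
    seed: int = 0,
    *,
    n_cells: int = 1000,
    replicates: int = 1,
    condition: str = "gradient",
    activation_fraction: float = 0.3,
    sample_times=None,
):
    """Simulate sampling a gradient run when target concentrations are reached.

    Each requested concentration maps to the time the pattern first reaches
    it; the population trajectory is sampled at those times through the
    same measurement model as the static generator.  For step patterns
    (which reach every concentration at once) pass ``sample_times``
    instead; concentrations are then derived from the pattern.
    """
    meas = meas or MeasurementModel()
    if sample_times is not None:
        times = sorted(float(t) for t in sample_times)
        concs = [concentration_at(pattern, t) for t in times]
    else:
        if pattern.kind == "step":
            raise ValueError("a step pattern reaches every concentration at its onset; "
                             "pass sample_times instead of sample_concentrations")
        concs = [float(c) for c in sample_concentrations]
        for c in concs:
            if c < 0 or c > pattern.c_max:
                raise ValueError(f"sample concentration {c} outside [0, c_max={pattern.c_max}]")
        times = [time_to_reach(pattern, c) for c in concs]
    rng = np.random.default_rng(seed)
    truth = GroundTruth(params=params, measurement=meas, seed=seed,
                        activation_fraction=activation_fraction)
    t_grid = np.unique(np.r_[0.0, times])
    frames = []
    for r in range(1, replicates + 1):
        rep = f"R{r}"
        cells = sample_population(params, n_cells, seed=rng.integers(2**31))
        truth.cells[rep] = cells.to_frame()
        traj = simulate_population(params, pattern, n_cells, t_grid, cells=cells)
        for c, t in zip(concs, times):
            if n_events < 1:
                warnings.warn(f"zero events requested; omitting sample at {c} mM", stacklevel=2)
                continue
            ti = int(np.flatnonzero(t_grid == t)[0])
            sample_id = (f"{condition}_{rep}_t{t:g}" if sample_times is not None
                         else f"{condition}_{rep}_c{c:g}")
            meta = {"condition": condition, "replicate": rep,
                    "time_min": t, "conc_mM": c}
            ev, rec = _make_sample(sample_id, meta, traj.levels[:, ti, :], meas,
                                   rng, n_events, activation_fraction, params.totals)
            frames.append(_attach_meta(ev, meta))
            truth.samples.append(rec)
    if not frames:
        raise ValueError("no samples generated")
    return EventTable(pd.concat(frames, ignore_index=True)), truth


def _attach_meta(ev: pd.DataFrame, meta: dict) -> pd.DataFrame:
    for k, v in meta.items():
        ev[k] = v
    return ev


def make_fixture_suite(out_dir, seed: int = 0, *, n_events: int = 10_000,
                       n_cells: int = 1000) -> dict:
    """Write the canonical fixture set used by the test suite.

    One static experiment (7 doses x 4 times x 3 replicates) and three
    gradient experiments (step, 20-min linear, 60-min linear to 10 mM,
    sampled at the standard 9 concentrations), each as events CSV +
    samplesheet CSV + ground-truth JSON.  Deterministic under ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = ModelParameters()
    written = {}

    ev, gt = generate_static_experiment(
        params, doses=[0, 0.25, 1, 2.5, 5, 10, 20], times=[0, 5, 10, 25],
        n_events=n_events, seed=seed, n_cells=n_cells, replicates=3,
    )
    written["static"] = _write_experiment(out / "static", ev, gt)

    grad_specs = {
        "step": InputPattern("step", c_max=10.0),
        "linear20": InputPattern("linear", c_max=10.0, T=20.0),
        "linear60": InputPattern("linear", c_max=10.0, T=60.0),
    }
    concs = [0, 1.25, 2.5, 3.75, 5, 6.25, 7.5, 8.75, 10]
    for i, (name, pattern) in enumerate(grad_specs.items(), start=1):
        if pattern.kind == "step":
            # a step reaches every concentration at t0; sample over time instead
            evg, gtg = generate_static_experiment(
                params, doses=[10.0], times=[0, 2, 5, 10, 20, 60],
                n_events=n_events, seed=seed + i, n_cells=n_cells,
                replicates=1, condition=name,
            )
        else:
            evg, gtg = generate_gradient_experiment(
                params, pattern, concs, n_events=n_events, seed=seed + i,
                n_cells=n_cells, replicates=1, condition=name,
            )
        written[name] = _write_experiment(out / name, evg, gtg)
    return written


def _write_experiment(folder: Path, ev: EventTable, gt: GroundTruth) -> dict:
    folder.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": folder / "events.csv",
        "samplesheet": folder / "samplesheet.csv",
        "ground_truth": folder / "ground_truth.json",
    }
    ev.to_csv(paths["events"], paths["samplesheet"])
    gt.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
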
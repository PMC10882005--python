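"""Single-cell phospho-flow analytics: gating, thresholds, %ON and MFI.

Events arrive as a CSV with one row per event (scatter, viability and three
phospho channels) plus a samplesheet keyed by ``sample_id`` carrying the
condition, time, concentration reached and replicate.  The pipeline mirrors
standard phospho-flow practice:

1. sequential rectangular gating — debris removal (FSC-A vs SSC-A),
   singlet selection (FSC-H vs FSC-W), live-cell selection (viability
   channel low: dead/apoptotic cells stain high for cleaved
   caspase-3/PARP);
2. per-sample QC: samples with fewer than 5000 gated events are dropped;
3. ON thresholds: the 97.5th percentile of the matching unstimulated
   control (time 0 / concentration 0), computed per condition and
   replicate; an event is ON when strictly above the threshold;
4. summaries: %ON and median fluorescence intensity (MFI) per channel,
   fold change of MFI against the control, dose–response tables and
   gradient response curves (vs time, concentration reached, and
   cumulative exposure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import patterns as pat
from .model import PROTEINS, interp_crossing

__all__ = [
    "CHANNELS",
    "PHOSPHO_CHANNELS",
    "META_COLUMNS",
    "EventTable",
    "RectGate",
    "GatingConfig",
    "SampleSummary",
    "read_events",
    "apply_gates",
    "qc_filter",
    "compute_on_threshold",
    "percent_on_experimental",
    "median_fluorescence",
    "fold_change",
    "control_thresholds",
    "summarise_samples",
    "build_dose_response",
    "gradient_response_curves",
]

#: Channel name for each phospho readout, in cascade order.
PHOSPHO_CHANNELS = {"pCD79a": "ch_pCD79a", "pSYK": "ch_pSYK", "pPLCg2": "ch_pPLCg2"}
CHANNELS = ("FSC_A", "FSC_H", "FSC_W", "SSC_A", "viability", *PHOSPHO_CHANNELS.values())
META_COLUMNS = ("sample_id", "condition", "time_min", "conc_mM", "replicate")


@dataclass
class EventTable:
    """Per-event fluorescence values joined with sample metadata."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", *CHANNELS) if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table is missing required channels/columns: {missing}")
        vals = self.data[list(CHANNELS)].to_numpy()
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals).all(axis=1))[0])
            raise ValueError(f"non-finite channel value at event row {bad}")

    def __len__(self) -> int:
        return len(self.data)

    def sample(self, sample_id) -> pd.DataFrame:
        return self.data[self.data["sample_id"] == sample_id]

    @property
    def sample_ids(self):
        return self.data["sample_id"].unique()

    def to_csv(self, events_path, samplesheet_path=None) -> None:
        ev_cols = ["sample_id", *CHANNELS]
        self.data[ev_cols].to_csv(events_path, index=False)
        if samplesheet_path is not None:
            self.samplesheet().to_csv(samplesheet_path, index=False)

    def samplesheet(self) -> pd.DataFrame:
        meta = [c for c in META_COLUMNS if c in self.data.columns]
        return self.data[meta].drop_duplicates("sample_id").reset_index(drop=True)


def read_events(path, samplesheet=None, *, format: str = "csv",
                channel_map: dict | None = None) -> EventTable:
    """Read an event CSV and join sample metadata from a samplesheet.

    ``channel_map`` renames instrument channel labels onto the canonical
    names.  FCS ingestion is not implemented; export events to CSV first.
    """
    if format == "fcs":
        raise NotImplementedError("FCS ingestion is not supported; export events to CSV")
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    df = pd.read_csv(path)
    if channel_map:
        df = df.rename(columns=channel_map)
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing channel columns {missing}")
    bad = ~np.isfinite(df[list(CHANNELS)].to_numpy()).all(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in np.flatnonzero(bad)[:5]]  # +2: header + 1-indexing
        raise ValueError(f"{path}: malformed/non-finite channel values at lines {lines}")
    if samplesheet is not None:
        sheet = samplesheet if isinstance(samplesheet, pd.DataFrame) else pd.read_csv(samplesheet)
        missing_meta = [c for c in META_COLUMNS if c not in sheet.columns]
        if missing_meta:
            raise ValueError(f"samplesheet is missing columns {missing_meta}")
        unknown = set(df["sample_id"]) - set(sheet["sample_id"])
        if unknown:
            raise ValueError(f"events reference samples absent from samplesheet: {sorted(unknown)[:5]}")
        df = df.merge(sheet, on="sample_id", how="left", validate="many_to_one")
    return EventTable(df)


# ---------------------------------------------------------------------------
# Gating
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RectGate:
    """Keep events inside a rectangle in two channels."""

    name: str
    x_channel: str
    y_channel: str
    x_low: float = -np.inf
    x_high: float = np.inf
    y_low: float = -np.inf
    y_high: float = np.inf

    def __post_init__(self) -> None:
        if self.x_low > self.x_high or self.y_low > self.y_high:
            raise ValueError(f"gate {self.name!r}: bounds must satisfy low <= high")

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        x = df[self.x_channel].to_numpy()
        y = df[self.y_channel].to_numpy()
        return (x >= self.x_low) & (x <= self.x_high) & (y >= self.y_low) & (y <= self.y_high)


@dataclass
class GatingConfig:
    """Ordered gate chain (debris -> singlets -> live by default)."""

    gates: list = field(default_factory=list)

    @classmethod
    def default(cls) -> "GatingConfig":
        """Defaults matched to the synthetic measurement model's populations."""
        return cls(gates=[
            RectGate("debris", "FSC_A", "SSC_A", x_low=3e4, x_high=2.6e5, y_low=8e3, y_high=2.2e5),
            RectGate("singlets", "FSC_H", "FSC_W", x_low=1e4, y_low=4e4, y_high=9.5e4),
            RectGate("live", "FSC_A", "viability", y_low=0.0, y_high=1.5e3),
        ])

    @classmethod
    def from_yaml(cls, path) -> "GatingConfig":
        import yaml

        with open(path) as fh:
            spec = yaml.safe_load(fh)
        gates = [RectGate(**g) for g in spec["gates"]]
        return cls(gates=gates)

    def to_yaml(self, path) -> None:
        import yaml

        spec = {"gates": [vars(g) for g in self.gates]}
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


def apply_gates(events: EventTable, config: GatingConfig):
    """Run the sequential gate chain.

    Returns ``(gated_events, report)`` where ``report`` is a per-sample,
    per-stage event-count frame (columns: sample_id, stage, n_in, n_out).
    """
    df = events.data
    for g in config.gates:
        for ch in (g.x_channel, g.y_channel):
            if ch not in df.columns:
                raise ValueError(f"gate {g.name!r} references missing channel {ch!r}")
    rows = []
    kept = df
    for g in config.gates:
        mask = g.mask(kept) if len(kept) else np.zeros(0, dtype=bool)
        nxt = kept[mask]
        n_in = kept.groupby("sample_id").size() if len(kept) else pd.Series(dtype=int)
        n_out = nxt.groupby("sample_id").size() if len(nxt) else pd.Series(dtype=int)
        for sid in events.sample_ids:
            rows.append({
                "sample_id": sid, "stage": g.name,
                "n_in": int(n_in.get(sid, 0)), "n_out": int(n_out.get(sid, 0)),
            })
        kept = nxt
    report = pd.DataFrame(rows, columns=["sample_id", "stage", "n_in", "n_out"])
    return EventTable(kept.reset_index(drop=True)), report


# ---------------------------------------------------------------------------
# Thresholds and summaries
# ---------------------------------------------------------------------------


def compute_on_threshold(control_values, q: float = 0.975) -> float:
    """ON threshold: empirical quantile of the unstimulated control.

    Uses the linear-interpolation quantile convention; an event is called
    ON when strictly above the returned value, so the control itself
    scores ~(1-q) ON by construction.
    """
    vals = np.asarray(control_values, dtype=float)
    if vals.ndim == 2 or isinstance(control_values, pd.DataFrame):
        raise ValueError("pass a single channel's values")
    if len(vals) == 0:
        raise ValueError("control sample is empty")
    if len(vals) < 100:
        warnings.warn(f"only {len(vals)} control events; the {q:.3f} quantile is unstable",
                      stacklevel=2)
    return float(np.quantile(vals, q, method="linear"))


def percent_on_experimental(values, threshold: float) -> float:
    """100 * fraction of events strictly above the threshold (NaN if empty)."""
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0:
        return float("nan")
    return float(100.0 * np.mean(vals > threshold))


def median_fluorescence(values) -> float:
    """Median fluorescence intensity (MFI) of one channel."""
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0:
        return float("nan")
    return float(np.median(vals))


def fold_change(mfi: float, control_mfi: float) -> float:
    """MFI ratio against the matched unstimulated control."""
    if control_mfi == 0:
        raise ZeroDivisionError("control MFI is zero; fold change undefined")
    return float(mfi / control_mfi)


@dataclass
class SampleSummary:
    """Per-sample gated counts, MFI and %ON per phospho channel."""

    sample_id: str
    condition: str
    time_min: float
    conc_mM: float
    replicate: str
    n_gated: int
    mfi: dict
    pct_on: dict
    qc_pass: bool = True

    def to_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id, "condition": self.condition,
            "time_min": self.time_min, "conc_mM": self.conc_mM,
            "replicate": self.replicate, "n_gated": self.n_gated, "qc_pass": self.qc_pass,
        }
        for prot in PROTEINS:
            d[f"mfi_{prot}"] = self.mfi.get(prot, np.nan)
            d[f"pct_on_{prot}"] = self.pct_on.get(prot, np.nan)
        return d


def qc_filter(samples, min_events: int = 5000):
    """Drop samples with fewer than ``min_events`` gated events (strict <)."""
    out = []
    for s in samples:
        n = s.n_gated if isinstance(s, SampleSummary) else s
        if isinstance(s, SampleSummary):
            s.qc_pass = n >= min_events
            if s.qc_pass:
                out.append(s)
        elif n >= min_events:
            out.append(s)
    return out


def _is_control(meta_row) -> bool:
    return float(meta_row["conc_mM"]) == 0.0 or float(meta_row["time_min"]) == 0.0


def control_thresholds(gated: EventTable, q: float = 0.975) -> pd.DataFrame:
    """97.5th-percentile ON thresholds from each condition's control sample.

    The control is the unstimulated sample (concentration 0 or time 0) of
    the same condition and replicate; one threshold per phospho channel.
    """
    sheet = gated.samplesheet()
    rows = []
    for (cond, rep), grp in sheet.groupby(["condition", "replicate"], sort=False):
        ctrl = grp[[_is_control(r) for _, r in grp.iterrows()]]
        if ctrl.empty:
            raise ValueError(f"no control (time 0 / 0 mM) sample for condition={cond!r}, "
                             f"replicate={rep!r}")
        ctrl_events = gated.data[gated.data["sample_id"].isin(ctrl["sample_id"])]
        row = {"condition": cond, "replicate": rep}
        for prot, ch in PHOSPHO_CHANNELS.items():
            row[prot] = compute_on_threshold(ctrl_events[ch].to_numpy(), q)
        rows.append(row)
    return pd.DataFrame(rows)


def summarise_samples(
    gated: EventTable,
    thresholds: pd.DataFrame | None = None,
    *,
    q: float = 0.975,
    min_events: int = 5000,
) -> list:
    """Per-sample %ON and MFI against condition-matched control thresholds.

    Returns :class:`SampleSummary` objects for samples passing the
    ``min_events`` QC filter.
    """
    if thresholds is None:
        thresholds = control_thresholds(gated, q)
    thr = thresholds.set_index(["condition", "replicate"])
    sheet = gated.samplesheet()
    summaries = []
    for _, meta in sheet.iterrows():
        ev = gated.sample(meta["sample_id"])
        t = thr.loc[(meta["condition"], meta["replicate"])]
        mfi = {prot: median_fluorescence(ev[ch]) for prot, ch in PHOSPHO_CHANNELS.items()}
        pct = {prot: percent_on_experimental(ev[ch], t[prot])
               for prot, ch in PHOSPHO_CHANNELS.items()}
        summaries.append(SampleSummary(
            sample_id=meta["sample_id"], condition=meta["condition"],
            time_min=float(meta["time_min"]), conc_mM=float(meta["conc_mM"]),
            replicate=meta["replicate"], n_gated=len(ev), mfi=mfi, pct_on=pct,
        ))
    return qc_filter(summaries, min_events)


def summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def build_dose_response(
    gated: EventTable,
    time_min: float,
    *,
    thresholds: pd.DataFrame | None = None,
    q: float = 0.975,
    min_events: int = 5000,
) -> pd.DataFrame:
    """Tidy dose–response table from static samples at one time point.

    One row per (replicate, protein, dose) with %ON and the fold change of
    MFI against the replicate's 0 mM control; feeds
    :func:`h2o2bcr.analysis.fit_hill`.
    """
    sheet = gated.samplesheet()
    at_t = sheet[sheet["time_min"].astype(float) == float(time_min)]
    if at_t.empty:
        raise ValueError(f"no samples at time {time_min} min")
    summaries = summarise_samples(
        EventTable(gated.data[gated.data["sample_id"].isin(at_t["sample_id"])]),
        thresholds, q=q, min_events=min_events,
    )
    rows = []
    for (cond, rep), group in _group_by_condition(summaries):
        controls = [s for s in group if s.conc_mM == 0.0]
        if not controls:
            raise ValueError(f"replicate {rep!r} of condition {cond!r} lacks a 0 mM control")
        ctrl = controls[0]
        for s in sorted(group, key=lambda s: s.conc_mM):
            for prot in PROTEINS:
                rows.append({
                    "condition": cond, "replicate": rep, "protein": prot,
                    "dose_mM": s.conc_mM,
                    "pct_on": s.pct_on[prot],
                    "fold_change_mfi": fold_change(s.mfi[prot], ctrl.mfi[prot]),
                    "n_gated": s.n_gated,
                })
    return pd.DataFrame(rows)


def _group_by_condition(summaries):
    keys = sorted({(s.condition, s.replicate) for s in summaries})
    for key in keys:
        yield key, [s for s in summaries if (s.condition, s.replicate) == key]


def gradient_response_curves(
    gated: EventTable,
    pattern: "pat.InputPattern",
    *,
    thresholds: pd.DataFrame | None = None,
    q: float = 0.975,
    min_events: int = 5000,
    time_tol: float = 1e-6,
) -> pd.DataFrame:
    """%ON along a gradient vs time, concentration reached and exposure.

    Samples must fall inside the gradient window [t0, t0+T]; each gets the
    concentration reached and the cumulative exposure implied by the
    pattern.  The per-protein EC50% (concentration at the 50% ON crossing)
    is attached as frame metadata ``.attrs['ec50_percent']``.
    """
    summaries = summarise_samples(gated, thresholds, q=q, min_events=min_events)
    rows = []
    for s in summaries:
        t = s.time_min
        if t < -time_tol or t > pattern.end_time + time_tol:
            raise ValueError(f"sample {s.sample_id!r} at t={t} min lies outside the "
                             f"pattern window [0, {pattern.end_time}]")
        conc = pat.concentration_at(pattern, max(t, 0.0))
        expo = pat.cumulative_exposure(pattern, max(t, 0.0))
        for prot in PROTEINS:
            rows.append({
                "condition": s.condition, "replicate": s.replicate, "protein": prot,
                "time_min": t, "conc_mM": conc, "cumulative_exposure": expo,
                "pct_on": s.pct_on[prot],
            })
    curves = pd.DataFrame(rows).sort_values(["protein", "replicate", "time_min"])
    ec50 = {}
    for prot, grp in curves.groupby("protein"):
        mean_curve = grp.groupby("conc_mM")["pct_on"].mean().reset_index()
        ec50[prot] = interp_crossing(
            mean_curve["conc_mM"].to_numpy(), mean_curve["pct_on"].to_numpy(), 50.0
        )
    curves.attrs["ec50_percent"] = ec50
    return curves.reset_index(drop=True)
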
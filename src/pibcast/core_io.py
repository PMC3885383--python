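"""Readers/writers, configuration and cohort summaries.

Conventions used throughout the package:

* time is measured in seconds from the start of the record (``t0`` defines
  time zero) and every interval is half-open ``[start, end)``;
* signals are stored channels x samples in microvolts;
* a single per-sample boolean validity mask is shared by all channels
  (telemetry dropouts affect the whole montage).

Two on-disk signal formats are supported: EDF (read via :mod:`mne`, written
by a minimal 16-bit EDF writer) and a "container" format — a raw float32
``.dat`` matrix plus a ``.json`` sidecar — which is far more practical for
months-long synthetic records than EDF's one-second record structure.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pibcast")

__all__ = [
    "IEEGRecord",
    "SeizureCatalog",
    "CohortSummary",
    "RunConfig",
    "read_edf",
    "write_edf",
    "read_container",
    "write_container",
    "read_seizure_catalog",
    "write_seizure_catalog",
    "summarize_cohort",
    "setup_logging",
    "substreams",
]


def setup_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; ``verbose`` enables DEBUG."""
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)


def substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    """Derive named independent random generators from one master seed.

    All randomness in a run flows from a single integer seed through
    :class:`numpy.random.SeedSequence` children, one per named stage, so
    that e.g. adding Monte-Carlo draws to the chance predictor never
    perturbs the simulated data.
    """
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class IEEGRecord:
    """A continuous multichannel iEEG record.

    Parameters
    ----------
    channel_ids
        One label per channel.
    fs
        Sampling rate in Hz.
    samples
        ``(n_channels, n_samples)`` array of signal values in microvolts.
    valid_mask
        Per-sample boolean; ``False`` marks telemetry dropouts / invalid data.
    t0
        Absolute start time of the record in seconds (defines time 0).
    """

    channel_ids: list[str]
    fs: float
    samples: np.ndarray
    valid_mask: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_ids)} channel ids but {self.samples.shape[0]} signal rows"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.shape[1], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.samples.shape[1],):
            raise ValueError("valid_mask must have one entry per sample")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs


@dataclass
class SeizureCatalog:
    """Ordered seizure onset/offset times, optionally with lead flags.

    A *lead* seizure is one preceded by at least a configured gap
    (default 4 h) with no other seizure; flags are filled by
    :func:`pibcast.labeling_cv.find_lead_seizures`.
    """

    onsets: np.ndarray
    offsets: np.ndarray
    lead_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.onsets.shape != self.offsets.shape:
            raise ValueError("onsets and offsets must have equal length")
        order = np.argsort(self.onsets, kind="stable")
        self.onsets = self.onsets[order]
        self.offsets = self.offsets[order]
        if self.lead_flags is not None:
            self.lead_flags = np.asarray(self.lead_flags, dtype=bool)[order]
        if np.any(self.offsets <= self.onsets):
            bad = int(np.flatnonzero(self.offsets <= self.onsets)[0])
            raise ValueError(f"event {bad}: offset must exceed onset")
        if len(self.onsets) > 1 and np.any(self.onsets[1:] < self.offsets[:-1]):
            bad = int(np.flatnonzero(self.onsets[1:] < self.offsets[:-1])[0])
            raise ValueError(f"events {bad} and {bad + 1} overlap")

    @classmethod
    def from_events(cls, events, lead_flags=None) -> "SeizureCatalog":
        events = list(events)
        onsets = [e[0] for e in events]
        offsets = [e[1] for e in events]
        return cls(np.array(onsets, dtype=float), np.array(offsets, dtype=float), lead_flags)

    def __len__(self) -> int:
        return len(self.onsets)

    @property
    def n_events(self) -> int:
        return len(self.onsets)


@dataclass
class CohortSummary:
    """Per-subject recording statistics with totals and mean +/- sample std."""

    per_subject: list[tuple]
    totals: tuple
    means: tuple
    stds: tuple  # entries are None when undefined (single subject)


@dataclass
class RunConfig:
    """Configuration for a full forecasting run.

    Defaults mirror the reference analysis: 1-minute feature blocks,
    90-minute pre-ictal windows and warning persistence, 5-minute forecast
    horizon, 4-hour lead-seizure gap, 10-fold contiguous cross-validation
    with 10 forward-selected features, and a grid of target time-in-warning
    proportions from 0.1 to 0.5.
    """

    band_edges: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.1, 4.0), (4.0, 8.0), (8.0, 12.0),
                                 (12.0, 30.0), (30.0, 70.0), (70.0, 180.0)]
    )
    block_len: float = 60.0
    preictal_len: float = 5400.0
    persistence: float = 5400.0
    horizon: float = 300.0
    min_lead_gap: float = 14400.0
    tiw_grid: list[float] = field(
        default_factory=lambda: [0.1, 0.15, 0.2, 0.3, 0.35, 0.4, 0.5]
    )
    n_folds: int = 10
    n_features: int = 10
    n_inner_folds: int = 5
    n_mc: int = 1000
    ridge: float = 1e-4
    seed: int = 0
    ictal_as_interictal: bool = False
    analysis_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.horizon < self.persistence:
            raise ValueError("require 0 < horizon < persistence")
        if any(not 0 < t < 1 for t in self.tiw_grid):
            raise ValueError("tiw_grid values must lie in (0, 1)")
        for lo, hi in self.band_edges:
            if lo >= hi:
                raise ValueError(f"band edge {lo} >= {hi}")
        edges = [e for pair in self.band_edges for e in pair]
        if edges != sorted(edges):
            raise ValueError("band edges must be non-decreasing")
        if self.block_len <= 0 or self.preictal_len <= 0:
            raise ValueError("block_len and preictal_len must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band_edges" in raw:
            raw["band_edges"] = [tuple(map(float, pair)) for pair in raw["band_edges"]]
        if "analysis_window" in raw and raw["analysis_window"] is not None:
            raw["analysis_window"] = tuple(map(float, raw["analysis_window"]))
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["band_edges"] = [list(pair) for pair in data["band_edges"]]
        if data["analysis_window"] is not None:
            data["analysis_window"] = list(data["analysis_window"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

_EDF_HEADER = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, record: IEEGRecord, patient_id: str = "X",
              recording_id: str = "pibcast") -> None:
    """Write an :class:`IEEGRecord` as plain 16-bit EDF.

    The sampling rate must be a whole number of samples per one-second data
    record; trailing samples beyond the last whole second are dropped (EDF
    stores fixed-length records). Validity information is not representable
    in plain EDF; use the container format when the mask matters.
    """
    fs = record.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_records = record.n_samples // spr
    if n_records == 0:
        raise ValueError("record shorter than one EDF data record (1 s)")
    ns = record.n_channels
    data = record.samples[:, : n_records * spr]

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmins[flat] -= 1.0
    pmaxs[flat] += 1.0

    header_bytes = _EDF_HEADER * (1 + ns)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(patient_id, 80))
        fh.write(_pad(recording_id, 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))

        for ch in record.channel_ids:
            fh.write(_pad(ch, 16))
        for _ in range(ns):
            fh.write(_pad("", 80))
        for _ in range(ns):
            fh.write(_pad("uV", 8))
        for p in pmins:
            fh.write(_pad(f"{p:.8g}"[:8], 8))
        for p in pmaxs:
            fh.write(_pad(f"{p:.8g}"[:8], 8))
        for _ in range(ns):
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in range(ns):
            fh.write(_pad(str(_DIG_MAX), 8))
        for _ in range(ns):
            fh.write(_pad("", 80))
        for _ in range(ns):
            fh.write(_pad(str(spr), 8))
        for _ in range(ns):
            fh.write(_pad("", 32))

        scale = (_DIG_MAX - _DIG_MIN) / (pmaxs - pmins)
        for r in range(n_records):
            chunk = data[:, r * spr : (r + 1) * spr]
            dig = np.rint((chunk - pmins[:, None]) * scale[:, None] + _DIG_MIN)
            fh.write(dig.astype("<i2").tobytes())


def read_edf(path) -> IEEGRecord:
    """Read an EDF/EDF+ file into an :class:`IEEGRecord`.

    Channels must share one sampling rate. Annotations whose description
    starts with ``bad`` (case-insensitive) are marked invalid in the mask;
    everything else is considered valid.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sfreqs = {int(round(raw.info["sfreq"]))}
    if len(sfreqs) != 1:
        raise ValueError("unsupported EDF: channels with unequal sampling rates")
    fs = float(raw.info["sfreq"])
    samples = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned channels
    n = samples.shape[1]
    mask = np.ones(n, dtype=bool)
    for ann in raw.annotations:
        if str(ann["description"]).lower().startswith("bad"):
            a = int(math.floor(ann["onset"] * fs))
            b = int(math.ceil((ann["onset"] + ann["duration"]) * fs))
            mask[max(a, 0) : min(b, n)] = False
    return IEEGRecord(list(raw.ch_names), fs, samples, mask, t0=0.0)


# ---------------------------------------------------------------------------
# native container (float32 .dat + .json sidecar)
# ---------------------------------------------------------------------------


def write_container(base_path, record: IEEGRecord) -> None:
    """Write ``<base>.dat`` (float32 channels x samples) + ``<base>.json``."""
    base = Path(base_path)
    invalid = _mask_to_runs(~record.valid_mask)
    meta = {
        "channel_ids": record.channel_ids,
        "fs": record.fs,
        "t0": record.t0,
        "n_channels": record.n_channels,
        "n_samples": record.n_samples,
        "dtype": "float32",
        "invalid_runs": invalid,
    }
    record.samples.astype(np.float32).tofile(base.with_suffix(".dat"))
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_container(base_path) -> IEEGRecord:
    base = Path(base_path)
    sidecar = base.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"no container sidecar: {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    data = np.fromfile(base.with_suffix(".dat"), dtype=meta["dtype"])
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    mask = np.ones(meta["n_samples"], dtype=bool)
    for a, b in meta["invalid_runs"]:
        mask[a:b] = False
    return IEEGRecord(meta["channel_ids"], meta["fs"], data, mask, t0=meta["t0"])


def _mask_to_runs(mask: np.ndarray) -> list[list[int]]:
    """Return [start, end) index runs where the boolean mask is True."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [[int(a), int(b)] for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# seizure catalogs
# ---------------------------------------------------------------------------


def read_seizure_catalog(path) -> SeizureCatalog:
    """Read a CSV with columns ``onset_s, offset_s`` into a catalog.

    Rows may appear in any order; malformed rows are rejected with their
    (1-based, header-exclusive) row number.
    """
    df = pd.read_csv(path)
    missing = {"onset_s", "offset_s"} - set(df.columns)
    if missing:
        raise ValueError(f"catalog missing required columns: {sorted(missing)}")
    for i, row in df.iterrows():
        if not np.isfinite(row["onset_s"]) or not np.isfinite(row["offset_s"]):
            raise ValueError(f"catalog row {i + 1}: non-numeric onset/offset")
        if row["offset_s"] <= row["onset_s"]:
            raise ValueError(
                f"catalog row {i + 1}: offset {row['offset_s']} <= onset {row['onset_s']}"
            )
    try:
        return SeizureCatalog(df["onset_s"].to_numpy(), df["offset_s"].to_numpy())
    except ValueError as exc:  # overlapping events, after sorting
        raise ValueError(f"invalid catalog {path}: {exc}") from exc


def write_seizure_catalog(path, catalog: SeizureCatalog) -> None:
    df = pd.DataFrame({"onset_s": catalog.onsets, "offset_s": catalog.offsets})
    if catalog.lead_flags is not None:
        df["lead"] = catalog.lead_flags.astype(int)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


def summarize_cohort(per_subject: list[tuple]) -> CohortSummary:
    """Summarize per-subject (duration_days, n_seizures, n_lead) rows.

    Totals are exact sums; means and standard deviations use the sample
    (n-1) convention. With a single subject the std is undefined and
    reported as ``None`` rather than 0.
    """
    if len(per_subject) == 0:
        raise ValueError("need at least one subject")
    arr = np.asarray(per_subject, dtype=float)
    if arr.ndim != 2:
        raise ValueError("per_subject must be a list of equal-length tuples")
    totals = tuple(arr.sum(axis=0))
    means = tuple(arr.mean(axis=0))
    if arr.shape[0] < 2:
        stds = tuple(None for _ in range(arr.shape[1]))
    else:
        stds = tuple(arr.std(axis=0, ddof=1))
    return CohortSummary([tuple(r) for r in per_subject], totals, means, stds)
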
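"""Power-in-band (PIB) feature extraction.

A record is average-referenced, partitioned into non-overlapping fixed-length
blocks (1 minute by default), and each fully-valid block is Fourier
transformed per channel. Periodogram power at every positive frequency bin in
[0.1, 180) Hz is assigned to the band whose half-open ``[lo, hi)`` interval
contains it and summed, yielding one power-in-band value per (channel, band).

Normalization: PIB values are in signal-variance units (microvolts squared);
the sum of all retained bins equals the variance of the mean-removed block
(Parseval), so the six band powers of a channel sum to the channel's
0.1-180 Hz variance exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import IEEGRecord, RunConfig

logger = logging.getLogger("pibcast")

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "FeatureMatrix",
    "average_reference",
    "partition_blocks",
    "compute_pib",
    "extract_features",
]

# block label codes (filled by labeling_cv)
UNLABELED = -1
INTERICTAL = 0
PREICTAL = 1
ICTAL_EXCLUDED = 2


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [lo_hz, hi_hz)."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self):
        if self.lo_hz >= self.hi_hz:
            raise ValueError(f"band {self.name}: lo {self.lo_hz} >= hi {self.hi_hz}")


#: The six canonical bands; shared edges belong to the upper band.
DEFAULT_BANDS = [
    BandDefinition("delta", 0.1, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma_low", 30.0, 70.0),
    BandDefinition("gamma_high", 70.0, 180.0),
]


@dataclass
class FeatureMatrix:
    """Per-block PIB feature vectors with validity, labels and folds.

    ``X`` is blocks x (n_channels * n_bands), ordered channel-major
    (channel 1 bands delta..gamma_high, then channel 2, ...). Invalid blocks
    carry NaN rows. ``labels`` and ``fold`` start unassigned (-1) and are
    filled by :mod:`pibcast.labeling_cv`.
    """

    block_start_s: np.ndarray
    X: np.ndarray
    feature_names: list[str]
    valid: np.ndarray
    block_len: float
    labels: np.ndarray = field(default=None)
    fold: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.block_start_s)
        if self.X.shape[0] != n or len(self.valid) != n:
            raise ValueError("inconsistent FeatureMatrix row counts")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if self.labels is None:
            self.labels = np.full(n, UNLABELED, dtype=np.int8)
        if self.fold is None:
            self.fold = np.full(n, -1, dtype=np.int32)

    @property
    def n_blocks(self) -> int:
        return len(self.block_start_s)

    @property
    def span(self) -> float:
        """Time covered by the block grid, [0, last block end)."""
        if self.n_blocks == 0:
            return 0.0
        return float(self.block_start_s[-1] + self.block_len)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "block_start_s", self.block_start_s)
        df.insert(1, "valid", self.valid.astype(int))
        df.insert(2, "label", self.labels)
        df.insert(3, "fold", self.fold)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, block_len: float) -> "FeatureMatrix":
        meta = ["block_start_s", "valid", "label", "fold"]
        names = [c for c in df.columns if c not in meta]
        return cls(
            block_start_s=df["block_start_s"].to_numpy(float),
            X=df[names].to_numpy(float),
            feature_names=names,
            valid=df["valid"].to_numpy(bool),
            block_len=block_len,
            labels=df["label"].to_numpy(np.int8),
            fold=df["fold"].to_numpy(np.int32),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, block_len: float = 60.0) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path), block_len)


def feature_names(n_channels: int, bands=DEFAULT_BANDS,
                  channel_ids: list[str] | None = None) -> list[str]:
    """Channel-major, band-minor feature column names (``ch1_delta`` ...)."""
    if channel_ids is None:
        channel_ids = [f"ch{i + 1}" for i in range(n_channels)]
    return [f"{ch}_{b.name}" for ch in channel_ids for b in bands]


def bands_from_config(config: RunConfig) -> list[BandDefinition]:
    if list(config.band_edges) == [(b.lo_hz, b.hi_hz) for b in DEFAULT_BANDS]:
        return DEFAULT_BANDS
    return [BandDefinition(f"band{i + 1}", lo, hi)
            for i, (lo, hi) in enumerate(config.band_edges)]


def average_reference(record: IEEGRecord) -> IEEGRecord:
    """Subtract the instantaneous across-channel mean from every sample."""
    if record.n_channels < 2:
        raise ValueError("average reference requires at least 2 channels")
    referenced = record.samples - record.samples.mean(axis=0, keepdims=True)
    return IEEGRecord(list(record.channel_ids), record.fs, referenced,
                      record.valid_mask.copy(), record.t0)


def partition_blocks(record: IEEGRecord, block_len: float):
    """Split a record into consecutive half-open blocks [k*L, (k+1)*L).

    Returns ``(block_start_s, block_valid)``. A block is valid iff all of
    its samples are valid; the trailing partial block is dropped.
    """
    spb = block_len * record.fs
    if abs(spb - round(spb)) > 1e-9:
        raise ValueError("block_len * fs must be an integer sample count")
    spb = int(round(spb))
    n_blocks = record.n_samples // spb
    starts = np.arange(n_blocks) * block_len
    mask = record.valid_mask[: n_blocks * spb].reshape(n_blocks, spb)
    return starts, mask.all(axis=1)


def _band_bin_masks(n: int, fs: float, bands) -> list[np.ndarray]:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    nyq = fs / 2.0
    masks = []
    for b in bands:
        hi = b.hi_hz
        if hi > nyq:
            logger.warning("band %s upper edge %.1f Hz above Nyquist %.1f Hz; clipped",
                           b.name, b.hi_hz, nyq)
            hi = nyq
        masks.append((freqs >= b.lo_hz) & (freqs < hi))
    return masks


def _periodogram_power(blocks: np.ndarray) -> np.ndarray:
    """Per-bin power of mean-removed blocks, normalized so that the sum of
    all positive-frequency bins equals the block variance (Parseval)."""
    n = blocks.shape[-1]
    x = blocks - blocks.mean(axis=-1, keepdims=True)
    spec = np.fft.rfft(x, axis=-1)
    power = (np.abs(spec) ** 2) * (2.0 / n**2)
    power[..., 0] = 0.0
    if n % 2 == 0:
        power[..., -1] *= 0.5  # Nyquist bin is not doubled
    return power


def compute_pib(block: np.ndarray, fs: float, bands=DEFAULT_BANDS) -> np.ndarray:
    """Power-in-band values for one fully-valid single-channel block."""
    block = np.asarray(block, dtype=float)
    if block.ndim != 1:
        raise ValueError("compute_pib expects a 1-D single-channel block")
    if not np.all(np.isfinite(block)):
        raise ValueError("block contains invalid (non-finite) samples")
    power = _periodogram_power(block[None, :])[0]
    masks = _band_bin_masks(len(block), fs, bands)
    return np.array([power[m].sum() for m in masks])


def extract_features(record: IEEGRecord, config: RunConfig | None = None,
                     bands=None, block_len: float | None = None) -> FeatureMatrix:
    """Full feature pipeline: average reference -> blocks -> per-channel PIB.

    Invalid blocks carry NaN feature rows and ``valid=False``; they receive
    no labels, folds, or risks downstream.
    """
    if config is None:
        config = RunConfig()
    if bands is None:
        bands = bands_from_config(config)
    if block_len is None:
        block_len = config.block_len

    ref = average_reference(record)
    starts, valid = partition_blocks(ref, block_len)
    if not valid.any():
        raise ValueError("record contains zero valid blocks")
    spb = int(round(block_len * record.fs))
    n_blocks = len(starts)
    names = feature_names(record.n_channels, bands, record.channel_ids)
    X = np.full((n_blocks, len(names)), np.nan)

    masks = _band_bin_masks(spb, record.fs, bands)
    band_mat = np.stack([m.astype(float) for m in masks])  # (n_bands, n_bins)
    vidx = np.flatnonzero(valid)
    for c in range(record.n_channels):
        blocks = ref.samples[c, : n_blocks * spb].reshape(n_blocks, spb)[vidx]
        power = _periodogram_power(blocks)  # (n_valid, n_bins)
        pib = power @ band_mat.T  # (n_valid, n_bands)
        X[vidx, c * len(bands) : (c + 1) * len(bands)] = pib
    return FeatureMatrix(starts, X, names, valid, block_len)
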
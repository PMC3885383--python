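"""Block labeling, lead-seizure identification, and contiguous CV folds.

Labels: a block is *pre-ictal* iff its start lies in ``[onset - L, onset)``
for any seizure (L = 90 min by default); blocks overlapping a seizure's
``[onset, offset)`` span are *ictal* and excluded from training and testing
(set ``ictal_as_interictal=True`` to fold them into the inter-ictal class
instead); every other valid block is *inter-ictal*. Pre-ictal windows of
clustered seizures simply union.

Folds: the record is divided into k contiguous sub-records balanced on
valid-block count (sizes differ by at most one valid block), so test data is
always a single time-contiguous stretch — the blocked scheme that prevents
temporal leakage in serially-correlated recordings.
"""

from __future__ import annotations

import numpy as np

from .core_io import SeizureCatalog
from .features import (FeatureMatrix, ICTAL_EXCLUDED, INTERICTAL, PREICTAL,
                       UNLABELED)

__all__ = ["label_blocks", "find_lead_seizures", "make_folds",
           "INTERICTAL", "PREICTAL", "ICTAL_EXCLUDED", "UNLABELED"]


def label_blocks(fm: FeatureMatrix, catalog: SeizureCatalog,
                 preictal_len: float = 5400.0,
                 ictal_as_interictal: bool = False) -> FeatureMatrix:
    """Attach pre-ictal / inter-ictal / ictal labels to valid blocks.

    Returns the same matrix with ``labels`` filled in place (invalid blocks
    stay unlabeled). Idempotent and independent of catalog row order.
    """
    labels = np.full(fm.n_blocks, UNLABELED, dtype=np.int8)
    t = fm.block_start_s
    valid = fm.valid

    labels[valid] = INTERICTAL
    onsets = catalog.onsets
    if len(onsets):
        # pre-ictal: some onset lies in (t, t + preictal_len]
        hi = np.searchsorted(onsets, t + preictal_len, side="right")
        lo = np.searchsorted(onsets, t, side="right")
        pre = (hi > lo) & valid
        labels[pre] = PREICTAL
        if not ictal_as_interictal:
            # ictal: block [t, t+block_len) overlaps some [onset, offset)
            for on, off in zip(catalog.onsets, catalog.offsets):
                ictal = (t < off) & (t + fm.block_len > on) & valid
                labels[ictal] = ICTAL_EXCLUDED
    fm.labels = labels
    return fm


def find_lead_seizures(catalog: SeizureCatalog,
                       min_gap: float = 14400.0) -> SeizureCatalog:
    """Flag lead seizures: events with no other onset in the preceding gap.

    Event i is lead iff no other event's onset lies in
    ``[onset_i - min_gap, onset_i)``; the first event is always lead.
    """
    onsets = catalog.onsets
    flags = np.ones(len(onsets), dtype=bool)
    if len(onsets) > 1:
        flags[1:] = (onsets[1:] - onsets[:-1]) >= min_gap
    return SeizureCatalog(onsets.copy(), catalog.offsets.copy(), flags)


def make_folds(fm: FeatureMatrix, k: int) -> np.ndarray:
    """Assign valid blocks to k contiguous folds balanced on block count.

    Returns a per-block fold array (0..k-1 for valid blocks, -1 otherwise)
    and stores it on the matrix. Fold ids form contiguous runs in time;
    valid-block counts differ by at most one.
    """
    vidx = np.flatnonzero(fm.valid)
    if k < 1:
        raise ValueError("need k >= 1 folds")
    if len(vidx) < k:
        raise ValueError(f"only {len(vidx)} valid blocks for {k} folds")
    fold = np.full(fm.n_blocks, -1, dtype=np.int32)
    for f, chunk in enumerate(np.array_split(vidx, k)):
        fold[chunk] = f
    fm.fold = fold
    return fold
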
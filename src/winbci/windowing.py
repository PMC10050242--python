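"""Window-sequence and pointwise dataset construction plus random splits.

The sequence dataset feeds the recurrent classifiers: for every labelled
EO/EC segment of the power series, windows of ``n_w`` power samples end
at the segment's last sample and slide backwards by ``hop`` until the
segment start, so each sequence lies entirely inside a single state and
contains no masked samples. The pointwise dataset feeds the classical
classifiers: one (P_O1, P_O2, label) row per unmasked EO/EC power
sample, with no further transformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .features import PowerSeries

__all__ = [
    "SequenceDataset",
    "PointDataset",
    "make_sequences",
    "make_points",
    "split_train_val",
]

CLASS_LABELS = ("EO", "EC")


@dataclass
class SequenceDataset:
    """Labelled window sequences.

    sequences
        ``(n_s, n_w, 2)`` array of (P_O1, P_O2) power rows.
    labels
        ``(n_s,)`` array of 'EO'/'EC'.
    provenance
        ``(n_s, 3)`` int/float array of (subject, segment index, window
        end time in seconds) identifying each sequence uniquely.
    """

    sequences: np.ndarray
    labels: np.ndarray
    window_s: float
    hop: int
    fs_power: float
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.provenance is None:
            self.provenance = np.zeros((len(self.labels), 3))
        if not (len(self.sequences) == len(self.labels) == len(self.provenance)):
            raise ValueError("sequence/label/provenance lengths differ")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_w(self) -> int:
        return self.sequences.shape[1] if len(self.sequences) else 0

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(self.sequences[idx], self.labels[idx],
                               self.window_s, self.hop, self.fs_power,
                               self.provenance[idx])


@dataclass
class PointDataset:
    """Single-time-point features: (P_O1, P_O2) rows with EO/EC labels."""

    features: np.ndarray      # (N, 2)
    labels: np.ndarray        # (N,)

    def __post_init__(self) -> None:
        if len(self.features) != len(self.labels):
            raise ValueError("feature/label lengths differ")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "PointDataset":
        return PointDataset(self.features[idx], self.labels[idx])


def _segments(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of identical labels; returns (start, stop_exclusive, label)."""
    out = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        out.append((i, j, str(labels[i])))
        i = j
    return out


def sequence_count(segment_len: int, n_w: int, hop: int) -> int:
    """Number of windows of ``n_w`` samples sliding back by ``hop`` from the
    last sample of a segment of ``segment_len`` samples."""
    if segment_len < n_w:
        return 0
    return (segment_len - n_w) // hop + 1


def make_sequences(
    ps: PowerSeries, window_s: float, hop: int = 1, subject: int = 0
) -> SequenceDataset:
    """Build the window-sequence dataset from a power series.

    Windows never cross state boundaries or masked samples: runs are
    maximal stretches of a single EO/EC label, and within each run the
    windows end at the run's last sample, sliding backwards by ``hop``.
    """
    if hop < 1:
        raise ValueError("hop must be >= 1")
    n_w = int(round(window_s * ps.fs_power))
    if n_w < 1:
        raise ValueError("window shorter than one power sample")
    stack = np.column_stack([ps.p_o1, ps.p_o2])
    seqs, labs, prov = [], [], []
    any_class_segment = False
    for i0, i1, lab in _segments(ps.labels):
        if lab not in CLASS_LABELS:
            continue
        any_class_segment = True
        seg_len = i1 - i0
        for m in range(sequence_count(seg_len, n_w, hop)):
            end = i1 - m * hop           # exclusive
            seqs.append(stack[end - n_w:end])
            labs.append(lab)
            prov.append((subject, i0, ps.times[end - 1]))
    if not seqs:
        if any_class_segment:
            raise ValueError("window exceeds trial length: no segment fits "
                             f"a {window_s} s window")
        raise ValueError("power series contains no EO/EC segments")
    return SequenceDataset(
        np.stack(seqs), np.array(labs, dtype="<U2"), float(window_s), hop,
        ps.fs_power, np.array(prov, dtype=float),
    )


def make_points(ps: PowerSeries) -> PointDataset:
    """One row per unmasked EO/EC power sample, values copied bit-exactly."""
    keep = np.isin(ps.labels, CLASS_LABELS)
    feats = np.column_stack([ps.p_o1[keep], ps.p_o2[keep]])
    return PointDataset(feats, ps.labels[keep].astype("<U2"))


def split_train_val(ds, fraction: float = 0.75, seed: int = 0):
    """Class-stratified random split into (train, val); deterministic under
    ``seed``. ``fraction`` is the training share and must leave both sides
    non-empty."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"split fraction must be in (0, 1), got {fraction}")
    labels = ds.labels
    present = set(np.unique(labels))
    missing = [c for c in CLASS_LABELS if c not in present]
    if missing:
        raise ValueError(f"cannot stratify: class(es) {missing} absent")
    idx = np.arange(len(labels))
    train_idx, val_idx = train_test_split(
        idx, train_size=fraction, random_state=seed % (2**32),
        stratify=labels, shuffle=True,
    )
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(val_idx))
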
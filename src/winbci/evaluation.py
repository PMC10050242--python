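"""Metrics, repeated-split evaluation, the window study and streaming tests.

The positive class is eyes closed (EC) throughout. Per-subject
evaluation repeats the random 75/25 split J times; cohort aggregation
takes the mean of per-subject means and the sample (n-1) standard
deviation across subjects. Window lengths are compared with the Friedman
rank test over subjects and post-hoc pairwise Wilcoxon signed-rank
tests (raw p values, no multiplicity correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifiers import (
    ClassifierSpec,
    LSTMModel,
    predict,
    train_lstm,
    train_pointwise,
    train_rnn,
)
from .core_io import RunConfig
from .features import PowerSeries
from .windowing import make_points, make_sequences, split_train_val

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "WindowStudyResult",
    "StreamResult",
    "confusion",
    "metrics",
    "repeated_eval",
    "aggregate",
    "friedman",
    "wilcoxon_pairwise",
    "window_study",
    "stream_classify",
]

POSITIVE = "EC"
NEGATIVE = "EO"


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with EC as the positive class."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def P(self) -> int:
        return self.TP + self.FN

    @property
    def N(self) -> int:
        return self.TN + self.FP


@dataclass
class MetricSet:
    """ACC / SEN / SPE in [0,1]; MCC in [-1,1] or None when its
    denominator vanishes (never silently 0)."""

    acc: float
    sen: float | None
    spe: float | None
    mcc: float | None

    def as_tuple(self):
        return (self.acc, self.sen, self.spe, self.mcc)


def confusion(true_labels, pred_labels) -> ConfusionMatrix:
    t = np.asarray(true_labels)
    p = np.asarray(pred_labels)
    if t.shape != p.shape:
        raise ValueError("label arrays must have equal length")
    known = {POSITIVE, NEGATIVE}
    bad = set(np.unique(np.concatenate([t, p]))) - known if t.size else set()
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    return ConfusionMatrix(
        TP=int(((t == POSITIVE) & (p == POSITIVE)).sum()),
        FP=int(((t == NEGATIVE) & (p == POSITIVE)).sum()),
        TN=int(((t == NEGATIVE) & (p == NEGATIVE)).sum()),
        FN=int(((t == POSITIVE) & (p == NEGATIVE)).sum()),
    )


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, sensitivity, specificity and Matthews correlation from a
    confusion matrix."""
    total = cm.P + cm.N
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.TP + cm.TN) / total
    sen = cm.TP / cm.P if cm.P > 0 else None
    spe = cm.TN / cm.N if cm.N > 0 else None
    denom = (cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    mcc = ((cm.TP * cm.TN - cm.FP * cm.FN) / np.sqrt(denom)) if denom > 0 else None
    return MetricSet(acc=acc, sen=sen, spe=spe, mcc=mcc)


def _subsample_per_class(ds, cap: int, rng: np.random.Generator):
    if cap <= 0:
        return ds
    keep, changed = [], False
    for c in np.unique(ds.labels):
        idx = np.flatnonzero(ds.labels == c)
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
            changed = True
        keep.append(idx)
    if not changed:
        return ds
    return ds.subset(np.sort(np.concatenate(keep)))


def _fit_and_score(train_ds, val_ds, spec, cfg: RunConfig, seed: int) -> MetricSet:
    if spec.family == "LSTM":
        model = train_lstm(
            train_ds, n_layers=cfg.lstm_layers, n_cells=cfg.lstm_cells,
            epochs=cfg.lstm_epochs, lr=cfg.lstm_lr, batch_size=cfg.lstm_batch,
            seed=seed,
        )
    elif spec.family == "RNN":
        model = train_rnn(train_ds, delay_s=float(spec.option), seed=seed)
    else:
        model = train_pointwise(train_ds, spec, seed=seed)
    pred = predict(model, val_ds)
    return metrics(confusion(val_ds.labels, pred))


def repeated_eval(
    ps: PowerSeries,
    window_s: float | None,
    spec: ClassifierSpec,
    J: int = 20,
    seed: int = 0,
    cfg: RunConfig | None = None,
    subject: int = 0,
) -> list[MetricSet]:
    """J independent split/train/validate cycles for one subject.

    ``window_s`` selects the sequence dataset (LSTM/RNN); pointwise
    families use the single-time-point dataset and ignore it. Class
    caps from ``cfg`` bound the per-split training/validation sizes.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    cfg = cfg or RunConfig()
    sequence_family = spec.family in ("LSTM", "RNN")
    if sequence_family:
        if window_s is None:
            raise ValueError("sequence classifiers need a window length")
        ds = make_sequences(ps, window_s, cfg.hop, subject=subject)
    else:
        ds = make_points(ps)
    out: list[MetricSet] = []
    root = np.random.SeedSequence((seed & 0x7FFFFFFF, subject, 911))
    for j, child in enumerate(root.spawn(J)):
        rng = np.random.default_rng(child)
        split_seed = int(rng.integers(0, 2**31 - 1))
        train_ds, val_ds = split_train_val(ds, cfg.split_fraction, split_seed)
        if sequence_family:
            train_ds = _subsample_per_class(train_ds, cfg.max_train_per_class, rng)
            val_ds = _subsample_per_class(val_ds, cfg.max_val_per_class, rng)
        else:
            train_ds = _subsample_per_class(train_ds, cfg.max_points_per_class, rng)
            val_ds = _subsample_per_class(val_ds, cfg.max_points_per_class, rng)
        out.append(_fit_and_score(train_ds, val_ds, spec, cfg, split_seed))
    return out


def aggregate(per_subject: np.ndarray) -> tuple[float, float]:
    """Cohort mean and sd of an I x J metric table: mean of per-subject
    means; sample (n-1) sd of the per-subject means. I >= 2 required for
    the sd."""
    m = np.asarray(per_subject, float)
    if m.ndim != 2:
        raise ValueError("expected an I x J table")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 subjects for the n-1 sd")
    subject_means = np.nanmean(m, axis=1)
    return float(subject_means.mean()), float(subject_means.std(ddof=1))


def _friedman_statistic(m: np.ndarray) -> float:
    """Friedman chi-square with average ranks and the standard tie
    correction."""
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    R = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * (R ** 2).sum() - 3.0 * n * (k + 1)
    ties = sum(
        float((c ** 3 - c).sum())
        for c in (np.unique(row, return_counts=True)[1] for row in m)
    )
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0:
        return 0.0
    return float(chisq / correction)


#: below this block count the chi-square approximation is replaced by a
#: within-row permutation null (the approximation is off by several
#: hundredths of a p unit for small cohorts)
_FRIEDMAN_EXACT_MAX_N = 10
_FRIEDMAN_PERMUTATIONS = 200_000


def friedman(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across columns (window lengths) with subjects as
    blocks; average-rank tie handling.

    The p value comes from the chi-square distribution with ``k-1``
    degrees of freedom for ``n > 10`` blocks, and from a seeded
    within-row permutation null (200k draws, deterministic) for small
    cohorts, where the chi-square approximation is unreliable. A matrix
    with no within-row variation anywhere returns ``(0.0, 1.0)``.
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 windows")
    if np.all(m == m[:, :1]):
        return 0.0, 1.0
    n, k = m.shape
    stat = _friedman_statistic(m)
    if n > _FRIEDMAN_EXACT_MAX_N:
        return stat, float(stats.chi2.sf(stat, k - 1))
    # permutation null: shuffle within every row; ranks are permuted with
    # the values, and the tie correction is permutation-invariant, so the
    # statistic can be recomputed from permuted row ranks
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rng = np.random.default_rng(18520707)      # fixed: p must be a function
    B = _FRIEDMAN_PERMUTATIONS                 # of the data only
    order = np.argsort(rng.random((B, n, k)), axis=2)
    permuted = np.take_along_axis(
        np.broadcast_to(ranks, (B, n, k)), order, axis=2)
    R = permuted.sum(axis=1)                   # (B, k) column rank sums
    chisq = 12.0 / (n * k * (k + 1)) * (R ** 2).sum(axis=1) \
        - 3.0 * n * (k + 1)
    obs = 12.0 / (n * k * (k + 1)) * (ranks.sum(axis=0) ** 2).sum() \
        - 3.0 * n * (k + 1)
    p = float((chisq >= obs - 1e-12).mean())
    return stat, p


def wilcoxon_pairwise(
    matrix: np.ndarray, zero_method: str = "wilcox"
) -> np.ndarray:
    """Two-sided Wilcoxon signed-rank p for every window pair.

    Returns a full symmetric k x k matrix with 1.0 on the diagonal
    (upper triangle is the canonical half). Exact distribution for
    n <= 25 without zero differences, normal approximation otherwise;
    zero differences dropped by default (``zero_method='pratt'`` keeps
    them)."""
    m = np.asarray(matrix, float)
    k = m.shape[1]
    out = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d = m[:, a] - m[:, b]
            if np.all(d == 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(
                    m[:, a], m[:, b], zero_method=zero_method,
                    alternative="two-sided", method="auto",
                ).pvalue)
            out[a, b] = out[b, a] = p
    return out


@dataclass
class WindowStudyResult:
    """Per-window cohort aggregates plus the nonparametric comparisons."""

    windows_s: tuple[float, ...]
    table: pd.DataFrame            # rows: window; cols: metric mean/sd
    accuracy: np.ndarray           # subjects x windows per-subject mean ACC
    friedman_stat: float
    friedman_p: float
    wilcoxon_p: np.ndarray | None  # k x k, None for a single window
    per_subject: dict = field(default_factory=dict)

    def wilcoxon_frame(self) -> pd.DataFrame | None:
        if self.wilcoxon_p is None:
            return None
        labels = [f"{w:g}s" for w in self.windows_s]
        return pd.DataFrame(self.wilcoxon_p, index=labels, columns=labels)


def window_study(
    cohort_ps: list[PowerSeries],
    windows_s,
    spec: ClassifierSpec,
    cfg: RunConfig | None = None,
    J: int = 5,
    seed: int = 0,
) -> WindowStudyResult:
    """Run ``repeated_eval`` for every subject and window, aggregate the
    four metrics, and compare windows with Friedman + pairwise Wilcoxon
    on the per-subject mean accuracies."""
    cfg = cfg or RunConfig()
    windows_s = tuple(float(w) for w in windows_s)
    if not windows_s:
        raise ValueError("need at least one window length")
    I = len(cohort_ps)
    acc = np.zeros((I, len(windows_s)))
    rows = []
    metric_names = ("accuracy", "sensitivity", "specificity", "mcc")
    per_subject: dict[float, np.ndarray] = {}
    for wi, w in enumerate(windows_s):
        table_ij = np.full((I, J, 4), np.nan)
        for i, ps in enumerate(cohort_ps):
            msets = repeated_eval(ps, w, spec, J=J, seed=seed, cfg=cfg, subject=i)
            for j, ms in enumerate(msets):
                table_ij[i, j] = [
                    v if v is not None else np.nan for v in ms.as_tuple()
                ]
        per_subject[w] = table_ij
        acc[:, wi] = np.nanmean(table_ij[:, :, 0], axis=1)
        row = {"window_s": w}
        for mi, name in enumerate(metric_names):
            mean, sd = aggregate(table_ij[:, :, mi])
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
        rows.append(row)
    table = pd.DataFrame(rows).set_index("window_s")
    if len(windows_s) >= 2 and I >= 2:
        stat, p = friedman(acc)
        wil = wilcoxon_pairwise(acc)
    else:
        stat, p, wil = 0.0, 1.0, None
    return WindowStudyResult(windows_s, table, acc, stat, p, wil, per_subject)


def classifier_roster_study(
    cohort_ps: list[PowerSeries],
    specs,
    cfg: RunConfig | None = None,
    J: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate a roster of classifier options (pointwise families, plus
    RNN entries given as ``RNN:<delay_s>``) with the same repeated-split
    protocol; returns a summary table and the per-spec accuracy
    matrices (subjects x J)."""
    cfg = cfg or RunConfig()
    specs = [ClassifierSpec.parse(s) if isinstance(s, str) else s for s in specs]
    rows = []
    acc_by_spec: dict[str, np.ndarray] = {}
    rnn_window = max(cfg.windows_s) if cfg.windows_s else 10.0
    for spec in specs:
        I = len(cohort_ps)
        table_ij = np.full((I, J, 4), np.nan)
        for i, ps in enumerate(cohort_ps):
            window = rnn_window if spec.family == "RNN" else None
            msets = repeated_eval(ps, window, spec, J=J, seed=seed, cfg=cfg,
                                  subject=i)
            for j, ms in enumerate(msets):
                table_ij[i, j] = [v if v is not None else np.nan
                                  for v in ms.as_tuple()]
        acc_by_spec[str(spec)] = np.nanmean(table_ij[:, :, 0], axis=1)
        row = {"classifier": str(spec)}
        for mi, name in enumerate(("accuracy", "sensitivity", "specificity",
                                   "mcc")):
            mean, sd = aggregate(table_ij[:, :, mi])
            row[f"{name}_mean"] = mean
            row[f"{name}_sd"] = sd
        rows.append(row)
    return pd.DataFrame(rows).set_index("classifier"), acc_by_spec


# ---------------------------------------------------------------------------
# Streaming simulator


@dataclass
class StreamResult:
    """Per-sample predicted timeline and per-transition detection delays."""

    times: np.ndarray              # window-end times
    predicted: np.ndarray          # '<U2'
    true_states: np.ndarray        # '<U6' at the same times
    transitions: list[dict]        # {'time', 'from', 'to', 'delay_s' or None}
    accuracy: float

    def delays(self, to_state: str | None = None) -> list[float]:
        """Detected delays in seconds, optionally only for transitions into
        ``to_state``."""
        return [tr["delay_s"] for tr in self.transitions
                if tr["delay_s"] is not None
                and (to_state is None or tr["to"] == to_state)]


def stream_classify(
    ps: PowerSeries,
    model,
    window_s: float,
    hold_s: float = 1.0,
) -> StreamResult:
    """Online-style classification: at every power sample, classify the
    window ending there (mixed-state windows included, as a deployed
    system would see them).

    For each true transition, the detection delay is the time until the
    prediction first switches to the new state and holds it for
    ``hold_s``; transitions never matched before the next true
    transition are reported as missed (delay ``None``).
    """
    n_w = int(round(window_s * ps.fs_power))
    n = len(ps.p_o1)
    if n_w >= n:
        raise ValueError("window exceeds the stream length")
    stack = np.column_stack([ps.p_o1, ps.p_o2])
    windows = np.lib.stride_tricks.sliding_window_view(stack, (n_w, 2))[:, 0]
    preds = []
    chunk = 512
    for s in range(0, len(windows), chunk):
        preds.append(predict(model, np.ascontiguousarray(windows[s:s + chunk])))
    predicted = np.concatenate(preds)
    times = ps.times[n_w - 1:]
    true_states = ps.labels[n_w - 1:]

    evaluable = np.isin(true_states, ("EO", "EC"))
    accuracy = float((predicted[evaluable] == true_states[evaluable]).mean()) \
        if evaluable.any() else float("nan")

    hold_n = max(int(round(hold_s * ps.fs_power)), 1)
    transitions: list[dict] = []
    # true transitions from the full label timeline (EO/EC only)
    lab = ps.labels
    change = [i for i in range(1, n)
              if lab[i] != lab[i - 1]
              and lab[i] in ("EO", "EC") and lab[i - 1] in ("EO", "EC")]
    for ci, i0 in enumerate(change):
        t0 = ps.times[i0]
        new = str(lab[i0])
        t_stop = ps.times[change[ci + 1]] if ci + 1 < len(change) else np.inf
        delay = None
        # search predictions at window-end times in [t0, next transition)
        j0 = np.searchsorted(times, t0)
        for j in range(j0, len(times)):
            if times[j] >= t_stop:
                break
            if predicted[j] == new and np.all(predicted[j:j + hold_n] == new):
                delay = float(times[j] - t0)
                break
        transitions.append({"time": float(t0), "from": str(lab[i0 - 1]),
                            "to": new, "delay_s": delay})
    return StreamResult(times, predicted, true_states, transitions, accuracy)
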
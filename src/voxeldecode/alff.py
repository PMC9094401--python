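"""Wavelet-ALFF: the univariate per-band amplitude baseline.

Wavelet-ALFF measures a voxel's fluctuation amplitude within one frequency
band as the time-mean absolute CWT coefficient at that band (an RMS variant
is available; the two are monotone-equivalent for the comparisons made here).
Across subjects it supports a paired t-test between the two task states, and
as a decoder each sample's band amplitude is itself the decision score — the
training data are used only to orient the score's sign, matching the
baseline's univariate character.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_auc_score

from .wavelet import Scalogram

__all__ = [
    "TStat",
    "DegenerateStatisticError",
    "wavelet_alff",
    "alff_table",
    "paired_t",
    "alff_decode_scores",
]


class DegenerateStatisticError(ValueError):
    """Raised when a statistic is undefined (e.g. zero-variance differences)."""


@dataclass
class TStat:
    """A paired t-test result."""

    t_value: float
    df: int
    p_value: float

    @property
    def abs_t(self) -> float:
        return abs(self.t_value)


def wavelet_alff(scalogram: Scalogram, band_index: int, method: str = "mean_abs") -> float:
    """Amplitude of one scalogram band: time-mean |coefficient| (or RMS)."""
    coefs = scalogram.coefficients
    if not 0 <= band_index < coefs.shape[0]:
        raise IndexError(f"band_index {band_index} out of range [0, {coefs.shape[0]})")
    row = coefs[band_index]
    if row.size == 0:
        raise ValueError("empty coefficient row")
    if method == "mean_abs":
        return float(np.mean(np.abs(row)))
    if method == "rms":
        return float(np.sqrt(np.mean(row**2)))
    raise ValueError(f"unknown wavelet-ALFF method {method!r}")


def alff_table(scalograms: list[Scalogram], method: str = "mean_abs") -> pd.DataFrame:
    """Tabulate wavelet-ALFF for every (series, band) pair.

    Returns a DataFrame with columns subject_id, state_label, voxel_id,
    band_index, alff_value — one record per (subject, state, voxel, band).
    """
    records = []
    for sg in scalograms:
        for band in range(sg.n_bands):
            records.append(
                {
                    "subject_id": sg.subject_id,
                    "state_label": sg.state_label,
                    "voxel_id": sg.voxel_id,
                    "band_index": band,
                    "alff_value": wavelet_alff(sg, band, method=method),
                }
            )
    return pd.DataFrame.from_records(records)


def paired_t(values_a: np.ndarray, values_b: np.ndarray) -> TStat:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)) with d = a - b, df = n - 1.

    Pairs are matched by position (here: by subject, SI vs VG of the same
    subject).  Zero-variance differences leave the statistic undefined and
    raise :class:`DegenerateStatisticError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t requires equal-length 1D vectors")
    if a.size < 2:
        raise ValueError("paired_t requires n >= 2 pairs")
    d = a - b
    if np.std(d, ddof=1) < 1e-300:
        raise DegenerateStatisticError("zero variance of paired differences")
    res = scipy.stats.ttest_rel(a, b)
    return TStat(t_value=float(res.statistic), df=a.size - 1, p_value=float(res.pvalue))


def alff_decode_scores(
    train_values: np.ndarray,
    train_labels: np.ndarray,
    test_values: np.ndarray,
    positive_label: str = "SI",
) -> np.ndarray:
    """Univariate decision scores for test samples from their ALFF values.

    The score of a test sample is its own ALFF value, sign-oriented so that
    the class ranking higher in the *training* ALFF values scores higher
    (orientation by the training AUC, a rank statistic, so the test AUC is
    invariant to any strictly increasing transform of the ALFF values).
    """
    train_values = np.asarray(train_values, dtype=float)
    train_labels = np.asarray(train_labels)
    test_values = np.asarray(test_values, dtype=float)
    pos = train_labels == positive_label
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present in the training records")
    train_auc = roc_auc_score(pos, train_values)
    sign = 1.0 if train_auc >= 0.5 else -1.0
    return sign * test_values
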
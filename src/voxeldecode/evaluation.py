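"""AUC scoring, AUC<->|T| calibration, and method-comparison summaries.

The decoding metric throughout is the AUC: the probability that a random
positive (SI) sample is scored above a random negative (VG) sample, computed
in the Mann-Whitney formulation with midrank tie handling.  Because the
univariate baseline admits a paired t-test, an ordinary least-squares line
fitted between per-model |T| values and AUCs translates a t-significance
level into an AUC "efficiency" threshold (0.61 in the reference analysis,
mapped from |T| = 4.08); models above the threshold count as efficient.
Comparison summaries count efficient models per method, their overlap, how
often the CNN beats the baseline among them, and the rank of the raw-series
model among all per-band models of a voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "CalibrationModel",
    "ComparisonSummary",
    "auc",
    "fit_calibration",
    "t_for_auc",
    "auc_threshold_for_t",
    "p_value_for_t",
    "summarize_comparison",
    "rank_models",
    "DEFAULT_AUC_THRESHOLD",
    "REFERENCE_T_THRESHOLD",
]

# AUC efficiency cutoff of the reference analysis, and the paired-|T| level it
# was mapped from; re-derive with auc_threshold_for_t on your own calibration.
DEFAULT_AUC_THRESHOLD = 0.61
REFERENCE_T_THRESHOLD = 4.08


def auc(scores, labels, positive_label="SI") -> float:
    """Probability a random positive outranks a random negative (midrank ties)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive_label
    if not y.any() or y.all():
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, scores))


@dataclass
class CalibrationModel:
    """OLS linear map |T| = slope * AUC + intercept with fit quality."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def fit_calibration(auc_values, abs_t_values) -> CalibrationModel:
    """Fit |T| = slope * AUC + intercept by ordinary least squares."""
    x = np.asarray(auc_values, dtype=float)
    y = np.asarray(abs_t_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("calibration requires two equal-length vectors, n >= 2")
    if np.ptp(x) < 1e-300:
        raise ValueError("constant AUC predictor; calibration undefined")
    res = scipy.stats.linregress(x, y)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=x.size,
    )


def t_for_auc(model: CalibrationModel, auc_value: float) -> float:
    """Forward map: the |T| the calibration assigns to an AUC."""
    return model.slope * auc_value + model.intercept


def auc_threshold_for_t(model: CalibrationModel, t_threshold: float) -> float:
    """Inverse map: the AUC at which the calibration line crosses |T|."""
    if abs(model.slope) < 1e-300:
        raise ValueError("zero slope: AUC threshold undefined")
    return (t_threshold - model.intercept) / model.slope


def p_value_for_t(abs_t: float, df: int) -> float:
    """Two-sided p for a |T| under the t distribution with ``df`` degrees of freedom."""
    return float(2.0 * scipy.stats.t.sf(abs(abs_t), df))


@dataclass
class ComparisonSummary:
    """Counts and fractions comparing CNN vs baseline decoders at a threshold.

    Fractions are ``None`` when their denominator is empty.  ``per_band_counts``
    maps method name to {band_label: efficient-model count}.
    """

    n_pairs: int
    auc_threshold: float
    n_efficient_cnn: int
    n_efficient_alff: int
    n_efficient_both: int
    n_efficient_either: int
    frac_cnn_higher_within_both: float | None
    frac_cnn_higher_within_either: float | None
    per_band_counts: dict = field(default_factory=dict)
    mean_rank_original: float | None = None

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "auc_threshold": self.auc_threshold,
            "n_efficient_cnn": self.n_efficient_cnn,
            "n_efficient_alff": self.n_efficient_alff,
            "n_efficient_both": self.n_efficient_both,
            "n_efficient_either": self.n_efficient_either,
            "frac_cnn_higher_within_both": self.frac_cnn_higher_within_both,
            "frac_cnn_higher_within_either": self.frac_cnn_higher_within_either,
            "per_band_counts": self.per_band_counts,
            "mean_rank_original": self.mean_rank_original,
        }


def _pair_key(result) -> tuple:
    return (result.voxel_id, result.band_label)


def summarize_comparison(cnn_results, alff_results, auc_threshold: float = DEFAULT_AUC_THRESHOLD) -> ComparisonSummary:
    """Pair CNN and baseline results by (voxel, band) and tally efficiency.

    "Efficient" means AUC strictly above the threshold.  Within the efficient
    sets, "CNN higher" counts strict inequalities only (ties favor neither).
    """
    if not 0.5 < auc_threshold < 1.0:
        raise ValueError("auc_threshold must lie in (0.5, 1)")
    cnn = {_pair_key(r): r for r in cnn_results}
    alff = {_pair_key(r): r for r in alff_results}
    unpaired = sorted(set(cnn) ^ set(alff))
    if unpaired:
        raise ValueError(f"unpaired (voxel, band) records: {unpaired[:10]}")
    keys = sorted(cnn)
    eff_c = {k for k in keys if cnn[k].auc_mean > auc_threshold}
    eff_a = {k for k in keys if alff[k].auc_mean > auc_threshold}
    both = eff_c & eff_a
    either = eff_c | eff_a
    higher_in_both = sum(1 for k in both if cnn[k].auc_mean > alff[k].auc_mean)
    higher_in_either = sum(1 for k in either if cnn[k].auc_mean > alff[k].auc_mean)
    per_band: dict[str, dict] = {"cnn": {}, "alff": {}}
    for k in eff_c:
        per_band["cnn"][k[1]] = per_band["cnn"].get(k[1], 0) + 1
    for k in eff_a:
        per_band["alff"][k[1]] = per_band["alff"].get(k[1], 0) + 1
    return ComparisonSummary(
        n_pairs=len(keys),
        auc_threshold=auc_threshold,
        n_efficient_cnn=len(eff_c),
        n_efficient_alff=len(eff_a),
        n_efficient_both=len(both),
        n_efficient_either=len(either),
        frac_cnn_higher_within_both=(higher_in_both / len(both)) if both else None,
        frac_cnn_higher_within_either=(higher_in_either / len(either)) if either else None,
        per_band_counts=per_band,
    )


def rank_models(results, original_label: str = "original", n_expected: int = 33):
    """Rank each voxel's models by AUC and locate the raw-series model.

    Rank 1 is the highest AUC within a voxel; ties get the average rank.
    Returns ``(per_voxel_rank, mean_rank)`` where ``per_voxel_rank`` maps
    voxel_id to the rank of the ``original`` (raw-series) model.  Every voxel
    must contribute exactly ``n_expected`` results (bands + original).
    """
    by_voxel: dict[str, list] = {}
    for r in results:
        by_voxel.setdefault(r.voxel_id, []).append(r)
    per_voxel_rank: dict[str, float] = {}
    for voxel, group in by_voxel.items():
        if len(group) != n_expected:
            raise ValueError(
                f"voxel {voxel!r} has {len(group)} results, expected {n_expected}"
            )
        aucs = np.array([g.auc_mean for g in group])
        # rankdata ranks ascending; invert so the best AUC gets rank 1
        ranks = scipy.stats.rankdata(-aucs, method="average")
        originals = [i for i, g in enumerate(group) if g.band_label == original_label]
        if len(originals) != 1:
            raise ValueError(f"voxel {voxel!r}: expected exactly one {original_label!r} model")
        per_voxel_rank[voxel] = float(ranks[originals[0]])
    mean_rank = float(np.mean(list(per_voxel_rank.values())))
    return per_voxel_rank, mean_rank
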
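"""Phenotype calls and summary analyses over functional score tables.

A mutation is called lambda-sensitive when F_lambda >= t_lambda, Mal+ when
F_malt >= t_malt, and jointly functional when (F_lambda + F_malt)/2 >=
t_joint; a score exactly at a threshold counts as the functional side.
The module also provides the Gaussian-intersection threshold estimate, the
two-sample Kolmogorov-Smirnov comparison of score distributions, the
Mal+/Mal- ratio curve over a grid of lambda thresholds, and per-residue
score aggregation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import NONSENSE, SYNONYMOUS


@dataclasses.dataclass
class ThresholdConfig:
    """Score thresholds for phenotype calls.

    ``t_lambda`` defaults to the anchor midpoint 0.5; 0.35 is the refined
    option that removes partially resistant mutations.
    """

    t_lambda: float = 0.5
    t_malt: float = 0.5
    t_joint: float = 0.5

    def __post_init__(self) -> None:
        for name in ("t_lambda", "t_malt", "t_joint"):
            value = getattr(self, name)
            if not (-1.0 < value < 2.0):
                raise ValueError(f"{name}={value} outside the sane interval (-1, 2)")


LAMBDA_SENSITIVE = "sensitive"
LAMBDA_RESISTANT = "resistant"
MAL_PLUS = "Mal+"
MAL_MINUS = "Mal-"
FUNCTIONAL = "functional"
NONFUNCTIONAL = "nonfunctional"


def call_phenotypes(
    scores_lambda: pd.DataFrame,
    scores_malt: pd.DataFrame,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Threshold mean scores into per-mutation phenotype calls.

    Tables are indexed by mutation key and carry ``F_mean``.  Mutations
    present in only one table get that single-trait call, with the other
    call and the joint call reported as NA.
    """
    cfg = cfg or ThresholdConfig()
    index = scores_lambda.index.union(scores_malt.index)
    f_lambda = scores_lambda["F_mean"].reindex(index)
    f_malt = scores_malt["F_mean"].reindex(index)
    out = pd.DataFrame(index=index)
    out["F_lambda"] = f_lambda
    out["F_malt"] = f_malt
    out["lambda_call"] = pd.Series(
        np.where(f_lambda >= cfg.t_lambda, LAMBDA_SENSITIVE, LAMBDA_RESISTANT),
        index=index,
    ).where(f_lambda.notna())
    out["malt_call"] = pd.Series(
        np.where(f_malt >= cfg.t_malt, MAL_PLUS, MAL_MINUS), index=index
    ).where(f_malt.notna())
    joint = (f_lambda + f_malt) / 2
    out["joint_call"] = pd.Series(
        np.where(joint >= cfg.t_joint, FUNCTIONAL, NONFUNCTIONAL), index=index
    ).where(joint.notna())
    meta = pd.concat(
        [
            df[[c for c in ("effect_class", "residue") if c in df.columns]]
            for df in (scores_lambda, scores_malt)
        ]
    )
    meta = meta[~meta.index.duplicated()]
    return out.join(meta.reindex(index))


def gaussian_intersection_threshold(
    class_a: np.ndarray | pd.Series, class_b: np.ndarray | pd.Series
) -> float:
    """Density crossing of moment-matched Gaussians fit to two score classes.

    Each class is summarised by its sample mean and standard deviation; the
    returned threshold is the root of the pdf-equality equation lying
    between the two means (the midpoint in the equal-variance case).  The
    result is symmetric in its arguments.
    """
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError(
            "each class needs >= 2 distinct values; with zero variance fall "
            "back to the midpoint of the class means explicitly"
        )
    m1, s1 = a.mean(), a.std(ddof=1)
    m2, s2 = b.mean(), b.std(ddof=1)
    if np.isclose(s1, s2):
        return float((m1 + m2) / 2)
    # N(m1,s1) pdf == N(m2,s2) pdf  <=>  quadratic in x.
    qa = 1 / (2 * s2**2) - 1 / (2 * s1**2)
    qb = m1 / s1**2 - m2 / s2**2
    qc = m2**2 / (2 * s2**2) - m1**2 / (2 * s1**2) + math.log(s2 / s1)
    roots = np.roots([qa, qb, qc])
    roots = roots[np.isreal(roots)].real
    lo, hi = min(m1, m2), max(m1, m2)
    between = [r for r in roots if lo <= r <= hi]
    if between:
        return float(between[0])
    # No crossing strictly between the means (strongly nested densities):
    # return the root closest to the midpoint.
    return float(roots[np.argmin(np.abs(roots - (lo + hi) / 2))])


def ks_compare(
    class_a: np.ndarray | pd.Series, class_b: np.ndarray | pd.Series
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(class_a, dtype=float)
    b = np.asarray(class_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("KS comparison requires non-empty samples")
    result = stats.ks_2samp(a, b, method="asymp")
    return float(result.statistic), float(result.pvalue)


def mal_ratio_curve(
    calls: pd.DataFrame,
    thresholds: np.ndarray | list[float],
    t_malt: float = 0.5,
) -> pd.DataFrame:
    """Mal+/Mal- ratio among missense mutations below each lambda threshold.

    Only missense mutations with both scores present are counted; the
    restriction uses strict ``F_lambda < t``.  An undefined ratio
    (no Mal- mutations) is reported as NA alongside the counts.
    """
    missense = calls[
        (calls["effect_class"] == "missense")
        & calls["F_lambda"].notna()
        & calls["F_malt"].notna()
    ]
    rows = []
    for t in thresholds:
        below = missense[missense["F_lambda"] < t]
        n_plus = int((below["F_malt"] >= t_malt).sum())
        n_minus = int((below["F_malt"] < t_malt).sum())
        ratio = n_plus / n_minus if n_minus else np.nan
        rows.append((float(t), n_plus, n_minus, ratio))
    return pd.DataFrame(
        rows, columns=["threshold", "n_mal_plus", "n_mal_minus", "ratio"]
    )


def per_residue_summary(scores: pd.DataFrame) -> pd.DataFrame:
    """Mean of per-mutation mean scores at each residue, with the number of
    scored mutations."""
    if "residue" not in scores.columns:
        raise ValueError("scores table lacks a residue column")
    grouped = scores.groupby("residue")["F_mean"]
    out = pd.DataFrame(
        {"mean_F": grouped.mean(), "n_mutations": grouped.size().astype(int)}
    )
    return out.reset_index()


def classification_accuracy(calls: pd.DataFrame) -> float:
    """Fraction of synonymous mutations called functional plus nonsense
    mutations called nonfunctional, over the union of the two classes."""
    anchors = calls[
        calls["effect_class"].isin([SYNONYMOUS, NONSENSE])
        & calls["joint_call"].notna()
    ]
    if anchors.empty:
        raise ValueError("no synonymous or nonsense mutations with joint calls")
    correct = np.where(
        anchors["effect_class"] == SYNONYMOUS,
        anchors["joint_call"] == FUNCTIONAL,
        anchors["joint_call"] == NONFUNCTIONAL,
    )
    return float(np.mean(correct))
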
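"""Validation statistics linking alignment distance to human coding.

The validation question is directional: if the alignment distance
captures gesture form similarity, it should decrease as the number of
form features human coders rate as similar (the overlap count, 0-4)
increases. The module provides the overlap count, ordinal-to-binary
recoding, Spearman rank correlation with a permutation or t-based
p-value, and a fixed-effects (dyad/item de-meaned) slope approximating a
varying-intercept mixed model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .timeseries import FEATURES, SimilarityAnnotation

#: largest n for which the permutation p-value enumerates all n! orderings
_EXACT_PERMUTATION_MAX_N = 8
_MC_PERMUTATIONS = 5000


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    method: str

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")


def binarize_rating(score: int) -> int:
    """Recode an ordinal 0-5 similarity rating to binary: 4-5 are
    similar (1), 0-3 are not (0)."""
    if score not in range(6):
        raise ValueError(f"ordinal rating must be in 0..5, got {score!r}")
    return 1 if score >= 4 else 0


def binarize_annotation(ann: SimilarityAnnotation) -> SimilarityAnnotation:
    """Binary version of an annotation (identity if already binary)."""
    if ann.scale == "binary":
        return ann
    return SimilarityAnnotation(
        ratings={f: binarize_rating(v) for f, v in ann.ratings.items()},
        scale="binary",
        handedness_match=ann.handedness_match,
    )


def overlap_count(annotation: SimilarityAnnotation) -> int:
    """Number of the four form features rated similar (0-4).

    Handedness is excluded: the distance is already computed on
    gesturing hands only. Ordinal annotations are binarized first.
    """
    ann = binarize_annotation(annotation)
    return int(sum(ann.ratings[f] for f in FEATURES))


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("Spearman rho undefined for a constant input vector")
    return float(rx @ ry) / denom


def spearman(
    x, y, rng: np.random.Generator | None = None
) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks. The p-value uses the
    t approximation for n > 20; otherwise a permutation test — exhaustive
    enumeration of all n! orderings up to n = 8, seeded Monte Carlo
    permutations above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if n > 20:
        # t approximation on rho with n - 2 degrees of freedom
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
        return CorrelationResult(rho=rho, n=n, p_value=min(p, 1.0),
                                 method="t_approximation")

    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    if denom == 0:
        raise ValueError("Spearman rho undefined for a constant input vector")
    if n <= _EXACT_PERMUTATION_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        rng = rng or np.random.default_rng(0)
        idx = np.argsort(rng.random((_MC_PERMUTATIONS, n)), axis=1)
        rhos = (ry_c[idx] @ rx_c) / denom
        # add-one correction: the observed ordering counts as one draw
        p = (1.0 + float(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))) / (
            _MC_PERMUTATIONS + 1
        )
    return CorrelationResult(rho=rho, n=n, p_value=p, method="permutation")


def demeaned_slope(
    distance, overlap, dyad_ids, item_ids
) -> tuple[float, float]:
    """Slope of distance on overlap net of dyad and item means.

    A fixed-effects approximation to a varying-intercept mixed model:
    OLS of distance on overlap with dyad and item intercepts (numerically
    identical to the two-way within transformation), reported with HC1
    robust standard errors. Returns ``(slope, standard_error)``.
    """
    distance = np.asarray(distance, dtype=float)
    overlap = np.asarray(overlap, dtype=float)
    if np.ptp(overlap) == 0:
        raise ValueError("slope undefined: overlap is constant")
    frame = pd.DataFrame(
        {
            "distance": distance,
            "overlap": overlap,
            "dyad": pd.Categorical(dyad_ids),
            "item": pd.Categorical(item_ids),
        }
    )
    X = pd.get_dummies(
        frame[["overlap", "dyad", "item"]], drop_first=True, dtype=float
    )
    X = sm.add_constant(X)
    fit = sm.OLS(frame["distance"], X).fit(cov_type="HC1")
    return float(fit.params["overlap"]), float(fit.bse["overlap"])


def validate_corpus(
    distance_table: pd.DataFrame,
    annotations: dict[str, SimilarityAnnotation],
) -> dict:
    """End-to-end validation report for one corpus.

    Joins per-pair distances with annotations and reports the Spearman
    correlation between distance and overlap count, per-feature distance
    summaries (similar vs not), the dyad/item de-meaned slope, and the
    incongruent pairs worth qualitative inspection: top-quartile
    distances with overlap >= 3 and bottom-quartile distances with
    overlap <= 1.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    table = distance_table.set_index("pair_id")
    pair_ids = [p for p in table.index if p in annotations]
    if len(pair_ids) < 3:
        raise ValueError("need at least 3 annotated pairs")
    dist = table.loc[pair_ids, "pair_distance"].to_numpy(dtype=float)
    binary = {p: binarize_annotation(annotations[p]) for p in pair_ids}
    overlap = np.array([overlap_count(binary[p]) for p in pair_ids])

    corr = spearman(dist, overlap)
    report: dict = {
        "n_pairs": len(pair_ids),
        "spearman_rho": corr.rho,
        "spearman_p": corr.p_value,
        "spearman_method": corr.method,
    }

    per_feature = {}
    for feat in FEATURES:
        flags = np.array([binary[p].ratings[feat] for p in pair_ids])
        per_feature[feat] = {
            "mean_distance_similar": float(dist[flags == 1].mean())
            if (flags == 1).any() else float("nan"),
            "mean_distance_not_similar": float(dist[flags == 0].mean())
            if (flags == 0).any() else float("nan"),
        }
    report["per_feature"] = per_feature

    if {"dyad", "item"}.issubset(table.columns) and np.ptp(overlap) > 0:
        slope, se = demeaned_slope(
            dist,
            overlap,
            table.loc[pair_ids, "dyad"],
            table.loc[pair_ids, "item"],
        )
        report["demeaned_slope"] = slope
        report["demeaned_slope_se"] = se
        report["slope_note"] = (
            "fixed-effects (dyad/item de-meaned) approximation to a "
            "varying-intercept mixed model"
        )

    q1, q3 = np.quantile(dist, [0.25, 0.75])
    report["incongruent_pairs"] = {
        "high_distance_high_similarity": [
            p for p, d, o in zip(pair_ids, dist, overlap)
            if d >= q3 and o >= 3
        ],
        "low_distance_low_similarity": [
            p for p, d, o in zip(pair_ids, dist, overlap)
            if d <= q1 and o <= 1
        ],
    }
    return report
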
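"""Chi-merge binning, weight-of-evidence encoding and scorecard ranking.

Predicted properties are turned into a single candidate score the way
credit scorecards are built: each feature is discretized by bottom-up
chi-square merging (adjacent intervals with the smallest 2x2 chi-square
statistic are merged until every adjacent pair exceeds the significance
threshold), each bin is encoded by its weight of evidence
woe_i = ln(py_i / pn_i) (the bin's share of positives over its share of
negatives), a logistic regression on the WOE-encoded features supplies
coefficients beta_i and intercept a, and the per-feature points are

    points_i = (woe_i * beta_i + a / n) * factor + offset / n

summed over the n features to the compound's score. With the default
factor = 20 / ln 2 and offset = 600, 20 points double the odds of being a
good candidate and higher scores are better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.linear_model import LogisticRegression

DEFAULT_FACTOR = 20.0 / np.log(2.0)
DEFAULT_OFFSET = 600.0

#: which call counts as "favorable" per ADMET endpoint (1 = positive label
#: is desirable, 0 = positive label is a liability such as hERG blockade
#: or micronucleus genotoxicity)
FAVORABLE_DIRECTION = {"caco2": 1, "cyp3a4": 1, "herg": 0, "hob": 1, "mn": 0}


def chi2_pair(table: np.ndarray) -> float:
    """Chi-square statistic sum_ij (A_ij - E_ij)^2 / E_ij of a 2x2 table.

    E_ij = row_i * col_j / total. A table with a zero marginal is
    degenerate: the statistic is reported as 0 so the merge is forced.
    """
    A = np.asarray(table, dtype=float)
    if A.shape != (2, 2):
        raise ValueError("chi2_pair expects a 2x2 count table")
    rows, cols, total = A.sum(axis=1), A.sum(axis=0), A.sum()
    if total == 0 or np.any(rows == 0) or np.any(cols == 0):
        return 0.0
    E = np.outer(rows, cols) / total
    return float(((A - E) ** 2 / E).sum())


def chi2_threshold(significance: float = 0.05, df: int = 1) -> float:
    """Critical value for the merge stopping rule (default 3.841)."""
    return float(chi2_dist.ppf(1.0 - significance, df))


@dataclass
class BinningResult:
    """Bins of one feature with per-class counts and WOE values.

    ``bin_edges`` are the interior cut points; bin i covers
    (edges[i-1], edges[i]] with open ends at the extremes.
    """

    feature_name: str
    bin_edges: np.ndarray  # interior cut points, length n_bins - 1
    counts: np.ndarray  # (n_bins, 2): negatives, positives per bin
    woe: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index for each value (searchsorted over the cut points)."""
        return np.searchsorted(self.bin_edges, np.asarray(values, float), side="left")


def chimerge_bins(
    values: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
    max_bins: int = 20,
    min_bins: int = 2,
    feature_name: str = "feature",
    significance: float = 0.05,
) -> BinningResult:
    """Bottom-up chi-square discretization of one feature.

    Initial intervals sit at the unique values (capped at ``max_bins``
    quantile bins); the adjacent pair with the smallest chi-square merges
    (ties: lowest index first) until every pair reaches ``threshold`` or
    only ``min_bins`` remain. Degenerate pairs (zero marginal) always merge
    first.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if threshold is None:
        threshold = chi2_threshold(significance)
    uniques = np.unique(values)
    if len(uniques) == 1:
        warnings.warn(f"constant feature {feature_name!r}: single bin")
        counts = np.array([[np.sum(labels == 0), np.sum(labels == 1)]], dtype=float)
        return BinningResult(feature_name, np.array([]), counts)
    if len(uniques) > max_bins:
        qs = np.quantile(values, np.linspace(0, 1, max_bins + 1)[1:-1])
        cuts = np.unique(qs)
    else:
        cuts = (uniques[:-1] + uniques[1:]) / 2.0
    idx = np.searchsorted(cuts, values, side="left")
    n_bins = len(cuts) + 1
    counts = np.zeros((n_bins, 2))
    for b, y in zip(idx, labels):
        counts[b, y] += 1
    cuts = list(cuts)
    while counts.shape[0] > min_bins:
        stats = [chi2_pair(counts[i : i + 2]) for i in range(counts.shape[0] - 1)]
        best = int(np.argmin(stats))  # ties: lowest index
        if stats[best] >= threshold:
            break
        counts = np.vstack(
            [counts[:best], counts[best] + counts[best + 1], counts[best + 2 :]]
        )
        del cuts[best]
    return BinningResult(feature_name, np.asarray(cuts), counts)


def woe_values(binning: BinningResult) -> np.ndarray:
    """Weight of evidence ln(py_i / pn_i) per bin, with 0.5-count smoothing.

    py_i (pn_i) is the bin's share of all positives (negatives); when any
    cell of a bin is empty, 0.5 is added to both of that bin's cells and
    the shares are renormalized so they still sum to one.
    """
    counts = binning.counts.astype(float).copy()
    empty = (counts == 0).any(axis=1)
    counts[empty] += 0.5
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("a class is entirely absent; WOE undefined")
    shares = counts / totals
    woe = np.log(shares[:, 1] / shares[:, 0])
    binning.woe = woe
    return woe


@dataclass
class Scorecard:
    """Per-feature binning, WOE tables, logistic coefficients and the
    affine points scale. ``score`` of a compound is exactly the sum of its
    per-feature points."""

    binnings: dict[str, BinningResult]
    coefficients: dict[str, float]
    intercept: float
    factor: float = DEFAULT_FACTOR
    offset: float = DEFAULT_OFFSET
    regularized: bool = False

    @property
    def n_features(self) -> int:
        return len(self.binnings)

    def feature_points(self, name: str) -> np.ndarray:
        """Points for each bin of one feature."""
        binning = self.binnings[name]
        woe = binning.woe if binning.woe is not None else woe_values(binning)
        n = self.n_features
        return (woe * self.coefficients[name] + self.intercept / n) * self.factor + self.offset / n

    def score_frame(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-feature points and total score for each row of raw features."""
        out = {}
        for name in self.binnings:
            bins = self.binnings[name].assign(features[name].to_numpy())
            out[f"points_{name}"] = self.feature_points(name)[bins]
        frame = pd.DataFrame(out, index=features.index)
        frame["score"] = frame.sum(axis=1)
        return frame

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# factor={self.factor!r} offset={self.offset!r} "
                     f"intercept={self.intercept!r}\n")
            fh.write("feature\tbin\tupper_edge\twoe\tbeta\tpoints\n")
            for name, binning in self.binnings.items():
                points = self.feature_points(name)
                edges = list(binning.bin_edges) + [np.inf]
                for b in range(binning.n_bins):
                    fh.write(
                        f"{name}\t{b}\t{edges[b]!r}\t{binning.woe[b]!r}\t"
                        f"{self.coefficients[name]!r}\t{points[b]!r}\n"
                    )


def fit_scorecard(
    woe_features: pd.DataFrame,
    target: np.ndarray,
    binnings: dict[str, BinningResult],
    factor: float = DEFAULT_FACTOR,
    offset: float = DEFAULT_OFFSET,
) -> Scorecard:
    """Logistic regression on WOE-encoded features -> scorecard.

    A separable fit (diverging coefficients) falls back to a ridge-penalized
    refit with a warning; ``regularized`` records that this happened.
    """
    target = np.asarray(target).astype(int)
    X = woe_features.to_numpy(dtype=float)
    model = LogisticRegression(C=1e6, max_iter=5000)
    model.fit(X, target)
    regularized = False
    if np.abs(model.coef_).max() > 30:
        warnings.warn("separable scorecard fit; refitting with ridge penalty")
        model = LogisticRegression(C=1.0, max_iter=5000)
        model.fit(X, target)
        regularized = True
    coefficients = dict(zip(woe_features.columns, model.coef_.ravel()))
    return Scorecard(
        binnings=binnings,
        coefficients=coefficients,
        intercept=float(model.intercept_[0]),
        factor=factor,
        offset=offset,
        regularized=regularized,
    )


@dataclass
class RankedList:
    """Compounds ordered by nonincreasing score, ties by compound id."""

    entries: pd.DataFrame  # columns: compound_id, score, rank, points_*
    tie_break: str = "compound_id"


def good_candidate_target(
    predictions: pd.DataFrame,
    activity_quantile: float = 0.7,
    min_favorable: int = 4,
    favorable: dict[str, int] = FAVORABLE_DIRECTION,
) -> np.ndarray:
    """Binary training target for the scorecard regression.

    A compound is a "good candidate" when its predicted pIC50 exceeds the
    set's ``activity_quantile`` quantile and at least ``min_favorable`` of
    its five ADMET calls point in the favorable direction.
    """
    cut = predictions["pIC50_pred"].quantile(activity_quantile)
    n_fav = sum(
        (predictions[f"{t}_call"].to_numpy(int) == fav).astype(int)
        for t, fav in favorable.items()
    )
    return ((predictions["pIC50_pred"] > cut) & (n_fav >= min_favorable)).to_numpy(int)


def build_scorecard(
    predictions: pd.DataFrame,
    target: np.ndarray | None = None,
    significance: float = 0.05,
    factor: float = DEFAULT_FACTOR,
    offset: float = DEFAULT_OFFSET,
    activity_quantile: float = 0.7,
    min_favorable: int = 4,
) -> Scorecard:
    """Bin the predicted activity and ADMET calls, encode, and fit.

    ``predictions`` needs a ``pIC50_pred`` column and ``<task>_call``
    columns; ``target`` defaults to :func:`good_candidate_target`.
    """
    if target is None:
        target = good_candidate_target(
            predictions, activity_quantile=activity_quantile,
            min_favorable=min_favorable,
        )
    features = scorecard_features(predictions)
    binnings: dict[str, BinningResult] = {}
    encoded = {}
    for name in features.columns:
        binning = chimerge_bins(
            features[name].to_numpy(), target, significance=significance,
            feature_name=name,
        )
        woe = woe_values(binning)
        binnings[name] = binning
        encoded[name] = woe[binning.assign(features[name].to_numpy())]
    return fit_scorecard(pd.DataFrame(encoded, index=features.index), target,
                         binnings, factor=factor, offset=offset)


def scorecard_features(predictions: pd.DataFrame) -> pd.DataFrame:
    """The raw scorecard inputs: predicted pIC50 plus the five ADMET calls."""
    cols = {"pIC50_pred": predictions["pIC50_pred"]}
    for task in FAVORABLE_DIRECTION:
        cols[f"{task}_call"] = predictions[f"{task}_call"].astype(float)
    return pd.DataFrame(cols, index=predictions.index)


def rank_candidates(scorecard: Scorecard, predictions: pd.DataFrame) -> RankedList:
    """Score every compound and emit the ranked list (ties by compound id)."""
    features = scorecard_features(predictions)
    points = scorecard.score_frame(features)
    frame = pd.concat(
        [predictions[["compound_id"]].reset_index(drop=True),
         points.reset_index(drop=True)], axis=1
    )
    frame = frame.sort_values(
        ["score", "compound_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame.insert(1, "rank", np.arange(1, len(frame) + 1))
    return RankedList(entries=frame)
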
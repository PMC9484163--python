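"""Chi-merge binning, WOE encoding and scorecard ranking."""

import numpy as np
import pandas as pd
import pytest

from molscreen import ranker
from molscreen.ranker import (
    BinningResult,
    build_scorecard,
    chi2_pair,
    chi2_threshold,
    chimerge_bins,
    fit_scorecard,
    good_candidate_target,
    rank_candidates,
    woe_values,
)


class TestChi2:
    def test_homogeneous_table_is_zero(self):
        assert chi2_pair([[10, 10], [10, 10]]) == 0.0

    def test_perfect_separation_value(self):
        # E = 10 everywhere; four cells of (+-10)^2 / 10
        assert chi2_pair([[20, 0], [0, 20]]) == pytest.approx(40.0)

    def test_symmetry_under_interval_swap(self, rng):
        for _ in range(10):
            table = rng.integers(1, 30, size=(2, 2))
            assert chi2_pair(table) == pytest.approx(chi2_pair(table[::-1]))

    def test_zero_marginal_reports_degenerate_zero(self):
        assert chi2_pair([[0, 0], [5, 7]]) == 0.0

    def test_threshold_default_significance(self):
        assert chi2_threshold() == pytest.approx(3.841, abs=1e-3)


def exhaustive_chimerge(values, labels, threshold):
    """Independent merge-order simulation on unique-value bins."""
    uniq = np.unique(values)
    cuts = list((uniq[:-1] + uniq[1:]) / 2)
    counts = []
    edges = [-np.inf] + cuts + [np.inf]
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (values > lo) & (values <= hi) if lo != -np.inf else (values <= hi)
        counts.append([np.sum(labels[sel] == 0), np.sum(labels[sel] == 1)])
    counts = np.array(counts, float)
    while len(counts) > 2:
        stats = [chi2_pair(counts[i : i + 2]) for i in range(len(counts) - 1)]
        i = int(np.argmin(stats))
        if stats[i] >= threshold:
            break
        counts = np.vstack([counts[:i], counts[i] + counts[i + 1], counts[i + 2:]])
        del cuts[i]
    return cuts, counts


class TestChimerge:
    def test_binary_feature_keeps_the_single_cut(self):
        values = np.array([0.0] * 50 + [1.0] * 50)
        labels = np.array([0] * 40 + [1] * 10 + [1] * 45 + [0] * 5)
        binning = chimerge_bins(values, labels)
        assert binning.n_bins == 2
        assert binning.bin_edges.tolist() == [0.5]

    def test_perfectly_separating_cut_survives(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.uniform(0, 1, 50), rng.uniform(2, 3, 50)])
        labels = np.array([0] * 50 + [1] * 50)
        binning = chimerge_bins(values, labels, threshold=3.841)
        woe_values(binning)
        # the final binning must separate the two value clusters
        assert np.any((binning.bin_edges > 1.0) & (binning.bin_edges < 2.0))
        cuts, counts = exhaustive_chimerge(
            np.round(values, 2), labels, 3.841
        )
        got = chimerge_bins(np.round(values, 2), labels, threshold=3.841, max_bins=200)
        assert got.counts.tolist() == counts.tolist()
        assert got.bin_edges.tolist() == pytest.approx(cuts)

    def test_constant_feature_yields_single_bin_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            binning = chimerge_bins(np.ones(20), np.repeat([0, 1], 10))
        assert binning.n_bins == 1

    def test_label_relabeling_symmetry(self, rng):
        values = rng.normal(size=200)
        labels = (values + rng.normal(size=200) > 0).astype(int)
        a = chimerge_bins(values, labels)
        b = chimerge_bins(values, 1 - labels)
        assert a.bin_edges.tolist() == b.bin_edges.tolist()
        assert a.counts.tolist() == b.counts[:, ::-1].tolist()

    def test_merge_is_deterministic(self, rng):
        values = rng.normal(size=300)
        labels = rng.integers(0, 2, size=300)
        a = chimerge_bins(values, labels)
        b = chimerge_bins(values, labels)
        assert a.bin_edges.tolist() == b.bin_edges.tolist()
        assert a.counts.tolist() == b.counts.tolist()

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            chimerge_bins(np.arange(5.0), np.array([0, 1, 2, 1, 0]))


class TestWoe:
    def binning(self, counts):
        counts = np.asarray(counts, float)
        return BinningResult("f", np.arange(len(counts) - 1, dtype=float), counts)

    def test_balanced_bin_has_zero_woe(self):
        woe = woe_values(self.binning([[30, 30], [30, 30]]))
        assert np.allclose(woe, 0.0)

    def test_hand_computed_share_ratio(self):
        # bin 0: positives share 0.4, negatives share 0.1 -> ln 4
        woe = woe_values(self.binning([[10, 40], [90, 60]]))
        assert woe[0] == pytest.approx(np.log(4.0))

    def test_shares_sum_to_one_even_with_smoothing(self):
        binning = self.binning([[0, 12], [25, 0], [15, 8]])
        woe_values(binning)
        counts = binning.counts.copy()
        counts[(counts == 0).any(axis=1)] += 0.5
        shares = counts / counts.sum(axis=0)
        assert np.allclose(shares.sum(axis=0), 1.0)
        assert np.all(np.isfinite(binning.woe))


def spreadsheet_score(woe_rows, betas, intercept, factor, offset):
    """Direct per-feature evaluation of the points formula."""
    n = len(betas)
    return sum(
        (w * b + intercept / n) * factor + offset / n
        for w, b in zip(woe_rows, betas)
    )


class TestScorecard:
    def make_predictions(self, rng, n=120):
        frame = pd.DataFrame({
            "compound_id": [f"c{i:03d}" for i in range(n)],
            "pIC50_pred": rng.normal(5.0, 1.5, size=n),
        })
        for task in ranker.FAVORABLE_DIRECTION:
            frame[f"{task}_call"] = rng.integers(0, 2, size=n)
        return frame

    def test_all_zero_woe_collapses_to_intercept_points(self, rng):
        preds = self.make_predictions(rng)
        target = good_candidate_target(preds)
        card = build_scorecard(preds, target=target)
        for name, binning in card.binnings.items():
            binning.woe[:] = 0.0
        scored = card.score_frame(ranker.scorecard_features(preds))
        expected = card.intercept * card.factor + card.offset
        assert np.allclose(scored["score"], expected)

    def test_doubling_factor_doubles_centered_scores(self, rng):
        preds = self.make_predictions(rng)
        target = good_candidate_target(preds)
        a = build_scorecard(preds, target=target, factor=20.0, offset=600.0)
        b = build_scorecard(preds, target=target, factor=40.0, offset=600.0)
        fa = a.score_frame(ranker.scorecard_features(preds))["score"]
        fb = b.score_frame(ranker.scorecard_features(preds))["score"]
        assert np.allclose(fb - 600.0, 2 * (fa - 600.0), atol=1e-8)

    def test_scores_match_spreadsheet_oracle(self, rng):
        preds = self.make_predictions(rng)
        target = good_candidate_target(preds)
        card = build_scorecard(preds, target=target)
        features = ranker.scorecard_features(preds)
        scored = card.score_frame(features)
        names = list(card.binnings)
        for row in range(5):
            woe_rows, betas = [], []
            for name in names:
                binning = card.binnings[name]
                b = binning.assign(np.array([features.iloc[row][name]]))[0]
                woe_rows.append(binning.woe[b])
                betas.append(card.coefficients[name])
            expected = spreadsheet_score(
                woe_rows, betas, card.intercept, card.factor, card.offset
            )
            assert scored.iloc[row]["score"] == pytest.approx(expected)

    def test_ranking_invariant_to_factor_and_offset(self, rng):
        preds = self.make_predictions(rng)
        target = good_candidate_target(preds)
        a = build_scorecard(preds, target=target, factor=20.0, offset=600.0)
        b = build_scorecard(preds, target=target, factor=123.0, offset=-50.0)
        ra = rank_candidates(a, preds).entries["compound_id"].tolist()
        rb = rank_candidates(b, preds).entries["compound_id"].tolist()
        assert ra == rb

    def test_identical_predictions_get_identical_scores_and_tie_break(self, rng):
        preds = self.make_predictions(rng, n=40)
        preds.loc[1] = preds.loc[0]
        preds.loc[1, "compound_id"] = "c999"
        card = build_scorecard(preds)
        ranked = rank_candidates(card, preds).entries
        s0 = ranked.loc[ranked.compound_id == "c000", "score"].iloc[0]
        s1 = ranked.loc[ranked.compound_id == "c999", "score"].iloc[0]
        assert s0 == s1
        pos0 = ranked.index[ranked.compound_id == "c000"][0]
        pos1 = ranked.index[ranked.compound_id == "c999"][0]
        assert pos0 < pos1  # lexicographic tie-break

    def test_single_compound_ranks_alone(self, rng):
        preds = self.make_predictions(rng, n=60)
        card = build_scorecard(preds)
        one = preds.iloc[[0]]
        ranked = rank_candidates(card, one).entries
        assert len(ranked) == 1 and ranked["rank"].iloc[0] == 1

    def test_scores_are_nonincreasing(self, rng):
        preds = self.make_predictions(rng)
        card = build_scorecard(preds)
        scores = rank_candidates(card, preds).entries["score"].to_numpy()
        assert np.all(np.diff(scores) <= 1e-9)

    def test_same_archetype_compounds_score_closer_than_across(self):
        # three latent archetypes with small within-group jitter on the
        # predicted activity; ADMET calls fixed per archetype
        rng = np.random.default_rng(77)
        archetypes = [
            {"pIC50": 7.5, "calls": (1, 1, 0, 1, 0)},   # potent and clean
            {"pIC50": 5.5, "calls": (1, 0, 0, 1, 1)},   # middling
            {"pIC50": 3.5, "calls": (0, 0, 1, 0, 1)},   # weak and toxic
        ]
        rows = []
        for g, arch in enumerate(archetypes):
            for i in range(40):
                row = {
                    "compound_id": f"g{g}_{i:02d}",
                    "pIC50_pred": arch["pIC50"] + rng.normal(0, 0.2),
                    "group": g,
                }
                for task, call in zip(ranker.FAVORABLE_DIRECTION, arch["calls"]):
                    row[f"{task}_call"] = call
                rows.append(row)
        preds = pd.DataFrame(rows)
        card = build_scorecard(preds)
        scored = rank_candidates(card, preds).entries.merge(
            preds[["compound_id", "group"]], on="compound_id"
        )
        within = scored.groupby("group")["score"].std().mean()
        between = scored.groupby("group")["score"].mean().std()
        assert within < between

    def test_separable_fit_falls_back_to_ridge(self, rng):
        woe = pd.DataFrame({"a": np.linspace(-2, 2, 40)})
        target = (woe["a"] > 0).astype(int).to_numpy()
        binnings = {"a": BinningResult("a", np.array([0.0]),
                                       np.array([[20.0, 0.0], [0.0, 20.0]]))}
        woe_values(binnings["a"])
        with pytest.warns(UserWarning, match="separable"):
            card = fit_scorecard(woe, target, binnings)
        assert card.regularized

    def test_scorecard_tsv_is_readable(self, rng, tmp_path):
        preds = self.make_predictions(rng)
        card = build_scorecard(preds)
        path = tmp_path / "scorecard.tsv"
        card.to_tsv(str(path))
        lines = path.read_text().splitlines()
        assert lines[1].split("\t") == ["feature", "bin", "upper_edge", "woe", "beta", "points"]
        assert len(lines) > 2
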
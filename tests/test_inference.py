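import numpy as np
import pandas as pd
import pytest

from histotype.inference import (
    aggregate_slide,
    build_prediction_map,
    confidence_band,
    detect_heterogeneity,
    ensemble_predict,
    render_prediction_map,
)


def preds(pairs, slide="S1", coords=None):
    rows = []
    for i, (pl, pb) in enumerate(pairs):
        r, c = coords[i] if coords else (0, i)
        rows.append(
            {"slide_id": slide, "grid_row": r, "grid_col": c, "p_luminal": pl, "p_basal": pb}
        )
    return pd.DataFrame(rows)


class TestAggregation:
    @pytest.mark.parametrize(
        "pairs,label,band,p_lum",
        [
            ([(0.9, 0.1), (0.7, 0.3)], "luminal", "high", 0.8),
            ([(0.55, 0.45), (0.65, 0.35)], "luminal", "low", 0.6),
            ([(0.61, 0.39)], "luminal", "intermediate", 0.61),
            ([(0.1, 0.9), (0.2, 0.8)], "basal", "high", 0.15),
        ],
    )
    def test_mean_label_and_band(self, pairs, label, band, p_lum):
        out = aggregate_slide(preds(pairs))
        assert out.label == label
        assert out.confidence_band == band
        assert out.p_wsi_luminal == pytest.approx(p_lum)
        assert out.p_wsi_luminal + out.p_wsi_basal == pytest.approx(1.0, abs=1e-6)

    def test_exact_tie_flagged_luminal_low(self):
        out = aggregate_slide(preds([(0.5, 0.5)]))
        assert out.label == "luminal" and out.confidence_band == "low" and out.tie

    def test_empty_and_multislide_errors(self):
        with pytest.raises(ValueError, match="no tile"):
            aggregate_slide(preds([]))
        two = pd.concat([preds([(0.6, 0.4)], slide="A"), preds([(0.6, 0.4)], slide="B")])
        with pytest.raises(ValueError, match="multiple slides"):
            aggregate_slide(two)

    def test_order_and_duplication_invariance(self):
        rng = np.random.default_rng(0)
        pl = rng.uniform(0, 1, size=12)
        pairs = list(zip(pl, 1 - pl))
        base = aggregate_slide(preds(pairs))
        shuffled = aggregate_slide(preds([pairs[i] for i in rng.permutation(12)]))
        doubled = aggregate_slide(preds(pairs + pairs))
        assert shuffled.p_wsi_luminal == pytest.approx(base.p_wsi_luminal)
        assert doubled.p_wsi_luminal == pytest.approx(base.p_wsi_luminal)

    def test_bands_partition_half_to_one(self):
        for p in np.linspace(0.5, 1.0, 501):
            band = confidence_band(p)
            if p >= 0.7:
                assert band == "high"
            elif p <= 0.6:
                assert band == "low"
            else:
                assert band == "intermediate"


class _StubModel:
    classes_ = np.array(["basal", "luminal"])

    def __init__(self, p_luminal):
        self.p = p_luminal

    def predict_proba(self, X):
        return np.tile([1 - self.p, self.p], (len(X), 1))


class TestEnsemble:
    tiles = [np.zeros((8, 8, 3), np.uint8)] * 4

    def test_identical_models_average_to_same(self):
        models = [_StubModel(0.9)] * 3
        out = ensemble_predict(models, self.tiles, slide_id="S")
        assert out.p_wsi_luminal == pytest.approx(0.9)
        assert out.label == "luminal" and out.confidence_band == "high"

    def test_mean_of_three_models(self):
        models = [_StubModel(0.8), _StubModel(0.4), _StubModel(0.9)]
        out = ensemble_predict(models, self.tiles)
        assert out.p_wsi_luminal == pytest.approx(0.7)
        assert out.label == "luminal"

    def test_permutation_symmetry(self):
        ms = [_StubModel(0.8), _StubModel(0.4), _StubModel(0.9)]
        a = ensemble_predict(ms, self.tiles)
        b = ensemble_predict(ms[::-1], self.tiles)
        assert a.p_wsi_luminal == pytest.approx(b.p_wsi_luminal)

    def test_model_count_enforced(self):
        with pytest.raises(ValueError, match="3 fold models"):
            ensemble_predict([_StubModel(0.5)], self.tiles)
        out = ensemble_predict([_StubModel(0.6)], self.tiles, allow_any_k=True)
        assert out.p_wsi_luminal == pytest.approx(0.6)


class TestPredictionMap:
    def test_uniform_luminal_map_renders_red(self):
        df = preds([(0.99, 0.01)] * 6, coords=[(r, c) for r in range(2) for c in range(3)])
        pmap = build_prediction_map(df)
        assert pmap.n_tiles == 6
        img = render_prediction_map(pmap, cell_px=4)
        assert img.shape == (8, 12, 3)
        assert img[..., 0].min() >= 250  # red channel saturated
        assert img[..., 2].max() <= 10

    def test_uninformative_tile_is_invisible(self):
        df = preds([(0.5, 0.5)])
        img = render_prediction_map(build_prediction_map(df), cell_px=2)
        assert np.all(img == 255)

    def test_duplicate_coordinates_error(self):
        df = preds([(0.6, 0.4), (0.7, 0.3)], coords=[(0, 0), (0, 0)])
        with pytest.raises(ValueError, match="duplicate"):
            build_prediction_map(df)

    def test_winning_probability_at_least_half(self):
        rng = np.random.default_rng(1)
        pl = rng.uniform(0, 1, 20)
        df = preds(list(zip(pl, 1 - pl)), coords=[(i // 5, i % 5) for i in range(20)])
        pmap = build_prediction_map(df)
        assert all(p >= 0.5 for _, p in pmap.entries.values())


from oracles import flood_fill_components


class TestHeterogeneity:
    def grid(self, label_fn, p=0.9, n=6):
        rows = []
        for r in range(n):
            for c in range(n):
                lum = label_fn(r, c)
                rows.append(
                    {
                        "slide_id": "S",
                        "grid_row": r,
                        "grid_col": c,
                        "p_luminal": p if lum else 1 - p,
                        "p_basal": 1 - p if lum else p,
                    }
                )
        return build_prediction_map(pd.DataFrame(rows))

    def test_single_class_map_not_candidate(self):
        report = detect_heterogeneity(self.grid(lambda r, c: True))
        assert not report.is_candidate
        assert report.components["basal"] == []

    def test_half_split_is_candidate_with_half_fractions(self):
        report = detect_heterogeneity(self.grid(lambda r, c: c < 3))
        assert report.is_candidate
        assert report.components["luminal"][0] == 18
        assert report.components["basal"][0] == 18

    def test_salt_and_pepper_not_candidate(self):
        report = detect_heterogeneity(self.grid(lambda r, c: (r + c) % 2 == 0))
        assert not report.is_candidate
        assert max(report.components["luminal"]) == 1

    def test_low_probability_tiles_not_assigned(self):
        report = detect_heterogeneity(self.grid(lambda r, c: c < 3, p=0.55))
        assert report.n_assigned == {"luminal": 0, "basal": 0}
        assert not report.is_candidate

    def test_components_match_flood_fill_oracle_on_random_maps(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            rows = []
            lum_cells, bas_cells = set(), set()
            for r in range(20):
                for c in range(20):
                    if rng.random() < 0.3:
                        continue  # tile not retained
                    lum = rng.random() < 0.5
                    p = float(rng.uniform(0.5, 1.0))
                    rows.append(
                        {
                            "slide_id": "S",
                            "grid_row": r,
                            "grid_col": c,
                            "p_luminal": p if lum else 1 - p,
                            "p_basal": 1 - p if lum else p,
                        }
                    )
                    if p >= 0.6:
                        (lum_cells if lum else bas_cells).add((r, c))
            if not rows:
                continue
            report = detect_heterogeneity(build_prediction_map(pd.DataFrame(rows)))
            assert report.components["luminal"] == flood_fill_components(lum_cells)
            assert report.components["basal"] == flood_fill_components(bas_cells)
            assert sum(report.components["luminal"]) == report.n_assigned["luminal"]
            assert sum(report.components["basal"]) == report.n_assigned["basal"]
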
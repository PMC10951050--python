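import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from shapely.geometry import box
from shapely.ops import unary_union

from histotype.wsi import (
    StainProfile,
    TumorAnnotation,
    canonical_he_profile,
    estimate_stains,
    load_annotations,
    normalize_stain,
    qc_filter,
    rgb_to_od,
    tessellate,
)


def geojson_polygon(coords, holes=()):
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [coords, *holes],
                },
            }
        ],
    }


SQUARE = [[0, 0], [1024, 0], [1024, 1024], [0, 1024], [0, 0]]


class TestAnnotations:
    def test_square_area(self):
        ann = load_annotations(geojson_polygon(SQUARE), slide_id="s")
        assert ann.area == 1024**2

    def test_square_hole_subtracts(self):
        hole = [[100, 100], [100, 200], [200, 200], [200, 100], [100, 100]]
        ann = load_annotations(geojson_polygon(SQUARE, holes=[hole]))
        assert ann.area == 1024**2 - 100**2

    def test_multipolygon_keeps_disjoint_parts(self):
        geo = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "MultiPolygon",
                        "coordinates": [
                            [[[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]]],
                            [[[20, 20], [30, 20], [30, 30], [20, 30], [20, 20]]],
                        ],
                    },
                }
            ],
        }
        ann = load_annotations(geo)
        assert len(ann.polygons) == 2

    def test_non_polygon_and_empty_errors(self):
        geo = {
            "type": "FeatureCollection",
            "features": [
                {"type": "Feature", "geometry": {"type": "Point", "coordinates": [0, 0]}}
            ],
        }
        with pytest.raises(ValueError, match="non-polygon"):
            load_annotations(geo)
        with pytest.raises(ValueError, match="no polygon"):
            load_annotations({"type": "FeatureCollection", "features": []})


class TestTessellation:
    def test_full_slide_exact_grid(self):
        ann = TumorAnnotation("s", box(0, 0, 1024, 1536))
        tiles = tessellate((1536, 1024), ann, tile_edge=512)
        assert len(tiles) == 6
        assert [(t.grid_row, t.grid_col) for t in tiles] == [
            (0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1)
        ]
        assert all(t.tumor_fraction == 1.0 for t in tiles)

    def test_half_tile_boundary_is_inclusive(self):
        ann = TumorAnnotation("s", box(0, 0, 256, 512))  # half of tile (0,0)
        kept = tessellate((512, 512), ann, min_tumor_fraction=0.5)
        assert len(kept) == 1 and kept[0].tumor_fraction == 0.5
        assert tessellate((512, 512), ann, min_tumor_fraction=0.51) == []

    def test_annotation_outside_slide_errors(self):
        ann = TumorAnnotation("s", box(0, 0, 2048, 512))
        with pytest.raises(ValueError, match="exceed"):
            tessellate((512, 1024), ann)

    def test_retention_matches_rasterized_oracle(self):
        """Geometric tile retention equals a per-pixel rasterized overlap count
        on random lattice-aligned polygons (unions of integer boxes)."""
        from oracles import rasterized_retained_tiles

        rng = np.random.default_rng(42)
        edge, size = 128, 1024
        for _ in range(20):
            boxes = []
            mask = np.zeros((size, size), dtype=bool)
            for _ in range(rng.integers(3, 7)):
                x0, y0 = rng.integers(0, size - 64, size=2)
                w, h = rng.integers(32, 400, size=2)
                x1, y1 = min(size, x0 + w), min(size, y0 + h)
                boxes.append(box(x0, y0, x1, y1))
                mask[y0:y1, x0:x1] = True
            ann = TumorAnnotation("s", unary_union(boxes))
            tiles = tessellate((size, size), ann, tile_edge=edge)
            got = {(t.grid_row, t.grid_col) for t in tiles}
            assert got == rasterized_retained_tiles(mask, edge)

    def test_tessellation_deterministic(self):
        ann = TumorAnnotation("s", box(100, 100, 900, 900))
        a = tessellate((1024, 1024), ann, tile_edge=256)
        b = tessellate((1024, 1024), ann, tile_edge=256)
        assert a == b


class TestQC:
    def test_trivial_rejections_and_texture_acceptance(self, luminal_slide):
        white = np.full((512, 512, 3), 255, np.uint8)
        assert qc_filter(white).reason == "background"
        gray = np.full((512, 512, 3), 128, np.uint8)
        assert qc_filter(gray).reason == "blur"
        texture = luminal_slide.image[:512, :512]
        assert qc_filter(texture).accepted

    def test_blurred_texture_rejected(self, luminal_slide):
        tile = luminal_slide.image[:512, :512].astype(float)
        blurred = np.stack(
            [gaussian_filter(tile[..., c], sigma=8) for c in range(3)], axis=-1
        )
        assert qc_filter(blurred.astype(np.uint8)).reason == "blur"

    def test_pure_function_of_pixels(self, basal_slide):
        tile = basal_slide.image[:512, :512]
        assert qc_filter(tile) == qc_filter(tile.copy())


def synth_tile(profile: StainProfile, conc: np.ndarray, shape=(512, 512)) -> np.ndarray:
    od = conc @ profile.stain_matrix
    img = (256.0 * 10 ** (-od) - 1.0).clip(0, 255).astype(np.uint8)
    return img.reshape(*shape, 3)


def angular_error_deg(a, b) -> float:
    return float(np.degrees(np.arccos(np.clip(a @ b, -1.0, 1.0))))


class TestStains:
    def test_known_stain_matrix_recovered_within_2_degrees(self):
        rng = np.random.default_rng(0)
        profile = canonical_he_profile()
        conc = np.abs(rng.normal(0.6, 0.4, size=(512 * 512, 2)))
        est = estimate_stains(synth_tile(profile, conc))
        for i in range(2):
            assert angular_error_deg(est.stain_matrix[i], profile.stain_matrix[i]) <= 2.0

    def test_pure_white_tile_errors(self):
        white = np.full((512, 512, 3), 255, np.uint8)
        with pytest.raises(ValueError, match="insufficient tissue"):
            estimate_stains(white)

    def test_concentration_scaling_homogeneity(self):
        rng = np.random.default_rng(1)
        profile = canonical_he_profile()
        conc = np.abs(rng.normal(0.4, 0.2, size=(512 * 512, 2)))
        est1 = estimate_stains(synth_tile(profile, conc))
        est2 = estimate_stains(synth_tile(profile, 2.0 * conc))
        for i in range(2):
            assert angular_error_deg(est1.stain_matrix[i], est2.stain_matrix[i]) <= 2.0
        assert np.allclose(
            est2.max_concentrations, 2.0 * est1.max_concentrations, rtol=0.05
        )

    def test_self_normalization_near_identity(self, luminal_slide):
        tile = luminal_slide.image[512:1024, 512:1024]
        profile = estimate_stains(tile)
        out = normalize_stain(tile, profile, profile)
        mae = np.abs(out.astype(float) - tile.astype(float)).mean()
        assert mae <= 3.0
        assert out.shape == tile.shape and out.dtype == np.uint8

    def test_white_pixels_stay_white(self, luminal_slide):
        tile = luminal_slide.image[:512, :512].copy()
        tile[:64, :64] = 255
        profile = estimate_stains(tile)
        out = normalize_stain(tile, profile, canonical_he_profile())
        assert out[:32, :32].min() >= 250

    def test_normalization_shrinks_scanner_color_gap(self):
        from histotype.simulate import gen_pseudo_slide

        a = gen_pseudo_slide(layout="luminal", seed=21, width=1024, height=1024)
        b = gen_pseudo_slide(
            layout="luminal", seed=21, width=1024, height=1024,
            color_shift=(1.35, 0.7),
        )
        ta, tb = a.image[:512, :512], b.image[:512, :512]
        target = canonical_he_profile()
        na = normalize_stain(ta, estimate_stains(ta), target)
        nb = normalize_stain(tb, estimate_stains(tb), target)
        gap_before = np.abs(ta.mean(axis=(0, 1)) - tb.mean(axis=(0, 1)))
        gap_after = np.abs(na.mean(axis=(0, 1)) - nb.mean(axis=(0, 1)))
        assert gap_after.mean() < gap_before.mean()

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            StainProfile(np.ones((2, 3)), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            StainProfile(np.ones((3, 3)), np.array([1.0, 1.0]))
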
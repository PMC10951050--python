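import numpy as np
import pytest

from histotype.simulate import gen_pseudo_slide


@pytest.fixture(scope="session")
def luminal_slide():
    return gen_pseudo_slide(layout="luminal", seed=1)


@pytest.fixture(scope="session")
def basal_slide():
    return gen_pseudo_slide(layout="basal", seed=2)


def crop_tiles(image: np.ndarray, edge: int, limit: int | None = None) -> list[np.ndarray]:
    """Cut an image into non-overlapping edge x edge crops (row-major)."""
    tiles = []
    for r in range(image.shape[0] // edge):
        for c in range(image.shape[1] // edge):
            tiles.append(image[r * edge : (r + 1) * edge, c * edge : (c + 1) * edge])
            if limit is not None and len(tiles) >= limit:
                return tiles
    return tiles


@pytest.fixture(scope="session")
def small_texture_tiles(luminal_slide, basal_slide):
    """128-px crops of both textures: (luminal_tiles, basal_tiles)."""
    return (
        crop_tiles(luminal_slide.image, 128, limit=220),
        crop_tiles(basal_slide.image, 128, limit=220),
    )
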
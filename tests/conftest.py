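import hypothesis
import numpy as np
import pytest

from powderflow import GrayImage

hypothesis.settings.register_profile(
    "powderflow", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("powderflow")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_three_level_image(
    height=100, width=100, background=230, dispersed=160, agglomerate=77,
    coverage=0.30, agglomerate_share=0.40,
):
    """Backlit fixture built from solid row blocks: known FI and AG by construction.

    A vertically centred band of ``coverage`` fraction of the rows is powder
    (patterns land centrally, away from the frame border); of those rows the
    first ``agglomerate_share`` are at the agglomerate level, the rest at the
    dispersed level; everything else is bright background.
    """
    n_powder_rows = round(height * coverage)
    n_agg_rows = round(n_powder_rows * agglomerate_share)
    start = (height - n_powder_rows) // 2
    px = np.full((height, width), background, dtype=np.uint8)
    px[start : start + n_agg_rows] = agglomerate
    px[start + n_agg_rows : start + n_powder_rows] = dispersed
    return GrayImage(px)


@pytest.fixture
def three_level_image():
    return make_three_level_image()
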
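import pytest

from dafr import (
    OpticalProperties,
    build_phantom,
    default_narrow_settings,
    default_wide_settings,
)

SMALL_N = 128          # 26.2 mm field: enough room for one site + halo


@pytest.fixture(scope="session")
def small_settings():
    wide = default_wide_settings(image_size=SMALL_N)
    narrow = default_narrow_settings(image_size=SMALL_N)
    return wide, narrow


@pytest.fixture(scope="session")
def center_px():
    c = (SMALL_N - 1) / 2.0
    return (c, c)


def make_single_site_phantom(depth_mm, center, image_size=SMALL_N,
                             optics=None, **kw):
    return build_phantom(
        [depth_mm], optics or OpticalProperties(),
        site_centers_px=[center], image_size=image_size, **kw)


@pytest.fixture(scope="session")
def single_site_phantom(center_px):
    return make_single_site_phantom(3.0, center_px)
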
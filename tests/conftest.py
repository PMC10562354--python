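import logging

import numpy as np
import pandas as pd
import pytest

import forestprio as fp

# zero-total feature drops are expected on tiny landscapes; keep test logs quiet
logging.getLogger("forestprio.ranking").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_site():
    """320 x 320 m site grid at 16 m cells (400 cells), default shares."""
    return fp.generate_site_classes(320, 320, 16, seed=11)


@pytest.fixture(scope="session")
def small_landscape(small_site):
    trees = fp.generate_trees(small_site, seed=12)
    ddw = fp.generate_ddw(small_site, seed=13)
    return small_site, trees, ddw


@pytest.fixture(scope="session")
def small_stack(small_landscape):
    site, trees, ddw = small_landscape
    return fp.build_baseline_stack(trees, ddw, site)


def make_trees(rows):
    """Tree table from (x, y, species, height, vol) tuples."""
    return pd.DataFrame(
        [
            {"x": x, "y": y, "species": sp, "height_m": h, "dbh_cm": 1.0, "vol_m3": v}
            for x, y, sp, h, v in rows
        ]
    )


def make_ddw(rows):
    """DDW table from (x1, y1, x2, y2, vol) tuples."""
    recs = []
    for x1, y1, x2, y2, v in rows:
        recs.append(
            {
                "x1": x1,
                "y1": y1,
                "x2": x2,
                "y2": y2,
                "diameter_cm": 10.0,
                "length_m": float(np.hypot(x2 - x1, y2 - y1)),
                "vol_m3": v,
            }
        )
    return pd.DataFrame(recs)
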
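"""Shared fixtures: small synthetic fragments analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest

import dabquant as dq


@pytest.fixture(scope="session")
def small_fragment():
    """A 1024 px cytoplasmic-marker fragment (~300 cells, p=0.05)."""
    config = dq.SynthConfig(seed=1, n_cells=300, canvas_px=1024)
    image, truth = dq.generate_fragment(config)
    return config, image, truth


@pytest.fixture(scope="session")
def small_analysis(small_fragment):
    """Full pipeline output for the small fragment under the PIMO rule."""
    _, image, _ = small_fragment
    return dq.analyze_fragment(image, dq.PIMO_PRESET)


@pytest.fixture(scope="session")
def hotspot_analysis():
    """A fragment with one 100 µm hotspot (p=0.9 inside vs 0.05 outside)."""
    config = dq.SynthConfig(
        seed=2,
        n_cells=500,
        canvas_px=1536,
        n_hotspots=1,
        base_positive_fraction=0.05,
        hotspot_positive_fraction=0.9,
    )
    image, truth = dq.generate_fragment(config)
    analysis = dq.analyze_fragment(image, dq.PIMO_PRESET)
    return config, truth, analysis


def make_cell(cell_id=1, area=100.0, nucleus_area=30.0, **mean_od):
    """Hand-built CellObject; mean_od keys like nucleus_dab=0.7."""
    od = {}
    for key, value in mean_od.items():
        comp, stain = key.rsplit("_", 1)
        stain = {"dab": "dab", "hema": "hematoxylin"}[stain]
        od[(comp, stain)] = value
    return dq.CellObject(
        id=cell_id,
        centroid_xy=(0.0, 0.0),
        nucleus_area_um2=nucleus_area,
        cell_area_um2=area,
        mean_od=od,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
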
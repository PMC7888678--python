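"""Shared fixtures: the expensive end-to-end runs are computed once."""

import pytest

from scat.model import ScatModel
from scat.presets import (bat_batch, clutter_pair_dolphin, clutter_series_fm,
                          dolphin_click_series, worked_example_bat)


@pytest.fixture(scope="session")
def worked_example():
    """Two-harmonic bat chirp + 100-us two-glint echo at 6 ms, fitted."""
    seq, cfg = worked_example_bat()
    return ScatModel(seq, config=cfg).fit()


@pytest.fixture(scope="session")
def dolphin_series():
    """Dolphin click + two-glint series 9-700 us, fitted."""
    seq, cfg = dolphin_click_series()
    return ScatModel(seq, config=cfg).fit()


@pytest.fixture(scope="session")
def bat_batch_results():
    """50/100/200-us two-glint chirp echoes at 5/12/18 ms, fitted."""
    seq, cfg = bat_batch()
    return ScatModel(seq, config=cfg).fit()


@pytest.fixture(scope="session")
def clutter_series():
    """Seven 100-us FM echoes under increasing lowpass clutter, fitted."""
    seq, cfg = clutter_series_fm()
    return ScatModel(seq, config=cfg).fit()


@pytest.fixture(scope="session")
def clutter_pair():
    """Focused vs lowpass 100-us click echoes, fitted."""
    seq, cfg = clutter_pair_dolphin()
    return ScatModel(seq, config=cfg).fit()
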
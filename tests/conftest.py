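import numpy as np
import pandas as pd
import pytest

from clpp.ecoplate import WELL_IDS, PlateSeries, load_layout


@pytest.fixture(scope="session")
def layout():
    return load_layout()


@pytest.fixture(scope="session")
def layout_frame(layout):
    from clpp.simulate import layout_to_frame

    return layout_to_frame(layout)


def make_readings_frame(layout, times, od590, od750, plate="P1", sample="S1"):
    """Long-format readings frame; od590/od750 are (well, time) -> OD callables."""
    rows = []
    for t in times:
        for wl, fn in ((590, od590), (750, od750)):
            for w in WELL_IDS:
                rows.append(
                    {
                        "plate": plate,
                        "sample": sample,
                        "time_h": t,
                        "wavelength": wl,
                        "well": w,
                        "od": fn(w, t),
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def readings_builder(layout):
    def build(times, od590, od750, **kw):
        return make_readings_frame(layout, times, od590, od750, **kw)

    return build


def toy_series(values_by_substrate, times=None, categories=None, sample="S1"):
    """PlateSeries from substrate -> list of replicate-identical OD curves."""
    first = next(iter(values_by_substrate.values()))
    times = np.asarray(times if times is not None else range(len(first)), dtype=float)
    corrected = {
        (s, rep): np.asarray(v, dtype=float)
        for s, v in values_by_substrate.items()
        for rep in (1, 2, 3)
    }
    return PlateSeries(sample, times, corrected, dict(categories or {}))


@pytest.fixture
def toy_series_builder():
    return toy_series
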
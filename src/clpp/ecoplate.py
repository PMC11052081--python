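"""Biolog EcoPlate layouts and dual-wavelength plate-reader series.

An EcoPlate is a 96-well plate carrying 31 carbon substrates in triplicate
plus one water blank per replicate block.  Color development (tetrazolium
dye reduction) is read at 590 nm; a parallel 750 nm read captures turbidity.
The working quantity downstream is the *corrected* optical density

    corrected(well, t) = [OD590(well, t) - OD750(well, t)] - control(t)

where ``control(t)`` is the mean of the water blanks after their own
590-750 subtraction, and negative values are clipped to zero (negative
color development is physically meaningless).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GridMismatchError, LayoutError, ReadingsError

CONTROL = "CONTROL"

CATEGORIES = (
    "carbohydrates",
    "polymers",
    "phenolic",
    "carboxylic",
    "amino_acids",
    "amines",
)

WELL_IDS = tuple(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))

N_SUBSTRATES = 31
N_REPLICATES = 3


@dataclass(frozen=True)
class WellAssignment:
    substrate: str  # substrate id, or CONTROL for a water blank
    category: str  # one of CATEGORIES, or "control"
    replicate: int  # 1..3


@dataclass(frozen=True)
class PlateLayout:
    """Validated mapping of the 96 wells to substrates and categories."""

    wells: Mapping[str, WellAssignment]

    def __post_init__(self) -> None:
        validate_layout(self.wells)

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(
            sorted({w.substrate for w in self.wells.values() if w.substrate != CONTROL})
        )

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(
            sorted({w.category for w in self.wells.values() if w.substrate != CONTROL})
        )

    @property
    def control_wells(self) -> tuple[str, ...]:
        return tuple(
            sorted(w for w, a in self.wells.items() if a.substrate == CONTROL)
        )

    def category_of(self, substrate: str) -> str:
        for a in self.wells.values():
            if a.substrate == substrate:
                return a.category
        raise LayoutError(f"unknown substrate {substrate!r}")

    def wells_for(self, substrate: str) -> tuple[str, ...]:
        return tuple(
            sorted(w for w, a in self.wells.items() if a.substrate == substrate)
        )

    def category_map(self) -> dict[str, str]:
        """substrate -> category for the 31 non-control substrates."""
        return {
            a.substrate: a.category
            for a in self.wells.values()
            if a.substrate != CONTROL
        }


def validate_layout(wells: Mapping[str, WellAssignment]) -> None:
    missing = set(WELL_IDS) - set(wells)
    if missing:
        raise LayoutError(f"missing wells: {sorted(missing)}")
    extra = set(wells) - set(WELL_IDS)
    if extra:
        raise LayoutError(f"unknown well ids: {sorted(extra)}")

    bad_cat = {
        a.category
        for a in wells.values()
        if a.substrate != CONTROL and a.category not in CATEGORIES
    }
    if bad_cat:
        raise LayoutError(f"unknown category labels: {sorted(bad_cat)}")

    controls = [w for w, a in wells.items() if a.substrate == CONTROL]
    if len(controls) != N_REPLICATES:
        raise LayoutError(f"expected {N_REPLICATES} control wells, found {len(controls)}")
    if sorted(wells[w].replicate for w in controls) != [1, 2, 3]:
        raise LayoutError("control wells must cover replicates 1..3, one each")

    by_substrate: dict[str, list[int]] = {}
    cats: dict[str, set[str]] = {}
    for a in wells.values():
        if a.substrate == CONTROL:
            continue
        by_substrate.setdefault(a.substrate, []).append(a.replicate)
        cats.setdefault(a.substrate, set()).add(a.category)
    if len(by_substrate) != N_SUBSTRATES:
        raise LayoutError(
            f"expected {N_SUBSTRATES} substrates, found {len(by_substrate)}"
        )
    for s, reps in by_substrate.items():
        if sorted(reps) != [1, 2, 3]:
            raise LayoutError(f"substrate {s!r} has replicates {sorted(reps)}, want [1, 2, 3]")
    for s, cset in cats.items():
        if len(cset) > 1:
            raise LayoutError(f"substrate {s!r} assigned to multiple categories {sorted(cset)}")


def _layout_from_frame(df: pd.DataFrame, source: str) -> PlateLayout:
    required = {"well", "substrate", "category", "replicate"}
    if not required.issubset(df.columns):
        raise LayoutError(f"{source}: layout needs columns {sorted(required)}")
    dup = df["well"][df["well"].duplicated()]
    if not dup.empty:
        raise LayoutError(f"{source}: duplicate well(s) {sorted(dup.unique())}")
    wells = {
        str(r.well): WellAssignment(str(r.substrate), str(r.category), int(r.replicate))
        for r in df.itertuples()
    }
    return PlateLayout(wells)


def load_layout(path: str | Path | None = None) -> PlateLayout:
    """Load a plate layout CSV; with no path, return the bundled standard EcoPlate map.

    The CSV must have columns ``well,substrate,category,replicate``; control
    wells use substrate ``CONTROL``.
    """
    if path is None:
        text = resources.files("clpp.data").joinpath("ecoplate_layout.csv").read_text()
        return _layout_from_frame(pd.read_csv(io.StringIO(text)), "builtin layout")
    return _layout_from_frame(pd.read_csv(path), str(path))


@dataclass(frozen=True)
class RawReading:
    """All 96 wells of one plate at one timepoint and one wavelength."""

    plate_id: str
    sample_id: str
    time_h: float
    wavelength: int  # 590 or 750
    od: Mapping[str, float]  # well id -> absorbance

    def __post_init__(self) -> None:
        if self.wavelength not in (590, 750):
            raise ReadingsError(
                f"wavelength must be 590 or 750, got {self.wavelength}"
            )
        if self.time_h < 0:
            raise ReadingsError(f"negative time {self.time_h}")


def load_readings(path_or_frame: str | Path | pd.DataFrame, layout: PlateLayout) -> list[RawReading]:
    """Parse a long-format readings CSV into per-(plate, time, wavelength) groups.

    Expected columns: ``plate,sample,time_h,wavelength,well,od``.  Every well
    of the layout must be present exactly once in each group.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
        source = "<frame>"
    else:
        df = pd.read_csv(path_or_frame)
        source = str(path_or_frame)
    required = {"plate", "sample", "time_h", "wavelength", "well", "od"}
    if not required.issubset(df.columns):
        raise ReadingsError(f"{source}: readings need columns {sorted(required)}")
    if not np.isfinite(pd.to_numeric(df["od"], errors="coerce")).all():
        raise ReadingsError(f"{source}: non-numeric or non-finite od values")
    df["od"] = df["od"].astype(float)
    bad_wl = set(df["wavelength"].unique()) - {590, 750}
    if bad_wl:
        raise ReadingsError(f"{source}: wavelength(s) {sorted(bad_wl)} not in {{590, 750}}")

    readings = []
    for (plate, time_h, wl), grp in df.groupby(["plate", "time_h", "wavelength"], sort=True):
        od = dict(zip(grp["well"].astype(str), grp["od"]))
        missing = set(WELL_IDS) - set(od)
        if missing:
            raise ReadingsError(
                f"{source}: plate {plate} t={time_h} h {wl} nm is missing "
                f"well(s) {sorted(missing)}"
            )
        if len(grp) != len(WELL_IDS):
            dup = grp["well"][grp["well"].duplicated()]
            raise ReadingsError(
                f"{source}: plate {plate} t={time_h} h {wl} nm has duplicate "
                f"well(s) {sorted(dup.unique())}"
            )
        samples = grp["sample"].unique()
        if len(samples) != 1:
            raise ReadingsError(f"{source}: plate {plate} maps to multiple samples {samples}")
        readings.append(
            RawReading(str(plate), str(samples[0]), float(time_h), int(wl), od)
        )
    # one plate -> one sample across all timepoints
    plate_sample: dict[str, str] = {}
    for r in readings:
        if plate_sample.setdefault(r.plate_id, r.sample_id) != r.sample_id:
            raise ReadingsError(f"plate {r.plate_id} maps to multiple samples")
    return readings


@dataclass
class PlateSeries:
    """Turbidity- and control-corrected OD time series for one plate."""

    sample_id: str
    times: np.ndarray  # strictly increasing, hours
    corrected: dict[tuple[str, int], np.ndarray]  # (substrate, replicate) -> OD
    categories: dict[str, str] = field(default_factory=dict)  # substrate -> category

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or (len(self.times) > 1 and not np.all(np.diff(self.times) > 0)):
            raise ReadingsError("times must be a strictly increasing 1-d grid")
        for key, vals in self.corrected.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.times.shape:
                raise ReadingsError(f"series {key} length != number of timepoints")
            if (vals < 0).any():
                raise ReadingsError(f"series {key} has negative corrected OD")
            self.corrected[key] = vals

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(sorted({s for s, _ in self.corrected}))

    def time_index(self, time_h: float) -> int:
        idx = np.nonzero(np.isclose(self.times, time_h))[0]
        if idx.size == 0:
            raise ReadingsError(f"time {time_h} h is not on the series grid")
        return int(idx[0])

    def substrate_means(self) -> pd.DataFrame:
        """Replicate-averaged corrected OD, substrates x timepoints."""
        rows = {}
        for s in self.substrates:
            reps = [v for (sub, _), v in self.corrected.items() if sub == s]
            rows[s] = np.mean(reps, axis=0)
        return pd.DataFrame(rows, index=self.times).T

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "sample": self.sample_id,
                "substrate": s,
                "replicate": rep,
                "time_h": t,
                "od_corrected": v,
            }
            for (s, rep), series in sorted(self.corrected.items())
            for t, v in zip(self.times, series)
        ]
        return pd.DataFrame.from_records(records)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_series_csv(path: str | Path, categories: dict[str, str] | None = None) -> list[PlateSeries]:
    """Reload PlateSeries objects written by :meth:`PlateSeries.write_csv`."""
    df = pd.read_csv(path)
    out = []
    for sample, grp in df.groupby("sample", sort=True):
        times = np.array(sorted(grp["time_h"].unique()), dtype=float)
        corrected = {}
        for (sub, rep), g in grp.groupby(["substrate", "replicate"]):
            g = g.sort_values("time_h")
            if not np.allclose(g["time_h"].to_numpy(), times):
                raise ReadingsError(f"{path}: ragged time grid for {sub!r} rep {rep}")
            corrected[(str(sub), int(rep))] = g["od_corrected"].to_numpy()
        out.append(PlateSeries(str(sample), times, corrected, dict(categories or {})))
    return out


def correct_series(readings: Iterable[RawReading], layout: PlateLayout) -> PlateSeries:
    """Turbidity- and control-correct paired 590/750 nm readings of one plate.

    Per well and timepoint the 750 nm read is subtracted from the 590 nm read;
    the mean of the three water blanks (after the same subtraction) at that
    timepoint is then removed, and negative results are clipped at zero.
    """
    readings = list(readings)
    plates = {r.plate_id for r in readings}
    if len(plates) != 1:
        raise ReadingsError(
            f"correct_series expects a single plate, got {sorted(plates)}; "
            "use correct_all_plates for multi-plate input"
        )
    sample_id = readings[0].sample_id

    by_wl: dict[int, dict[float, Mapping[str, float]]] = {590: {}, 750: {}}
    for r in readings:
        if r.time_h in by_wl[r.wavelength]:
            raise ReadingsError(f"duplicate reading at t={r.time_h} h, {r.wavelength} nm")
        by_wl[r.wavelength][r.time_h] = r.od
    t590, t750 = set(by_wl[590]), set(by_wl[750])
    if t590 != t750:
        raise GridMismatchError(
            f"590/750 nm time grids differ: {sorted(t590 ^ t750)} unmatched"
        )
    times = np.array(sorted(t590), dtype=float)

    controls = layout.control_wells
    sub_wells = {
        (a.substrate, a.replicate): w
        for w, a in layout.wells.items()
        if a.substrate != CONTROL
    }
    corrected = {key: np.empty(len(times)) for key in sub_wells}
    for i, t in enumerate(times):
        od590, od750 = by_wl[590][t], by_wl[750][t]
        diff = {w: od590[w] - od750[w] for w in WELL_IDS}
        control_mean = float(np.mean([diff[w] for w in controls]))
        for key, w in sub_wells.items():
            corrected[key][i] = max(diff[w] - control_mean, 0.0)

    return PlateSeries(sample_id, times, corrected, layout.category_map())


def correct_all_plates(
    readings: Iterable[RawReading], layout: PlateLayout
) -> dict[str, PlateSeries]:
    """Group readings by plate and correct each; keyed by sample id."""
    by_plate: dict[str, list[RawReading]] = {}
    for r in readings:
        by_plate.setdefault(r.plate_id, []).append(r)
    out = {}
    for plate in sorted(by_plate):
        series = correct_series(by_plate[plate], layout)
        if series.sample_id in out:
            raise ReadingsError(f"two plates share sample id {series.sample_id!r}")
        out[series.sample_id] = series
    return out
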
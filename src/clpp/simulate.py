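"""Synthetic inputs with the statistical structure the analyses assume.

Two generators cover the pipeline's input surface:

* ``simulate_plate`` emulates a 100-day dual-wavelength EcoPlate incubation
  read every 24 h: per-substrate logistic color development at 590 nm on top
  of a turbidity channel (750 nm), instrument noise, and a slowly drifting
  control baseline.  A sample is characterized by its substrate-affinity
  vector (which fraction of each substrate's asymptote it can develop).

* ``simulate_asv_table`` draws an ASV count table with *planted guilds*:
  groups of ASVs sharing a per-sample latent factor, so that within-guild
  pairwise rank correlations concentrate near a target value while
  between-guild pairs stay null.  Counts are Poisson draws around log-normal
  abundances; taxonomy mixes archaeal and bacterial lineages within every
  guild; sample metadata spans a water-column depth gradient plus
  benthic-boundary-layer stations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ecoplate import CONTROL, PlateLayout, RawReading, load_layout
from .errors import ClppError

WC_DEFAULT_DEPTHS_M = (0.0, 200.0, 800.0, 2000.0, 5000.0)

ARCHAEAL_LINEAGES = (
    ("Crenarchaeota", "Nitrososphaeria"),
    ("Halobacterota", "Halobacteria"),
    ("Thermoplasmatota", "Thermoplasmata"),
)
BACTERIAL_LINEAGES = (
    ("Proteobacteria", "Alphaproteobacteria"),
    ("Proteobacteria", "Gammaproteobacteria"),
    ("Actinobacteriota", "Actinobacteria"),
    ("Bacteroidota", "Bacteroidia"),
    ("Cyanobacteria", "Cyanobacteriia"),
    ("Chloroflexi", "Anaerolineae"),
)


# --------------------------------------------------------------------------
# plate simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateSimConfig:
    """Incubation protocol and noise model for one simulated EcoPlate.

    Defaults emulate a 100-day incubation read every 24 h.  Substrate
    kinetics are logistic with asymptote ``K`` (OD units), rate ``r``
    (per hour) and midpoint ``t0`` (hours); when ``substrate_params`` is
    None, per-substrate parameters are drawn once from the seed
    (K ~ U(0.8, 1.6), r ~ U(0.008, 0.03), t0 ~ U(300, 900) h).
    """

    n_timepoints: int = 101
    step_h: float = 24.0
    substrate_params: Mapping[str, tuple[float, float, float]] | None = None
    turbidity_mean: float = 0.05
    turbidity_sd: float = 0.01
    od_noise_sd: float = 0.01
    control_drift: float = 0.002  # OD per 24 h, shared baseline at 590 nm
    seed: int = 0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=float) * self.step_h

    def __post_init__(self) -> None:
        if self.n_timepoints < 1 or self.step_h <= 0:
            raise ClppError("need n_timepoints >= 1 and step_h > 0")
        if self.turbidity_sd < 0 or self.od_noise_sd < 0:
            raise ClppError("noise standard deviations must be >= 0")
        if self.substrate_params is not None:
            for s, (k, r, _) in self.substrate_params.items():
                if k < 0 or r <= 0:
                    raise ClppError(f"substrate {s!r}: need K >= 0 and r > 0")


def logistic(t: np.ndarray, k: float, r: float, t0: float) -> np.ndarray:
    """Logistic color development K / (1 + exp(-r (t - t0)))."""
    return k / (1.0 + np.exp(-r * (np.asarray(t, dtype=float) - t0)))


def _default_substrate_params(
    substrates: Sequence[str], rng: np.random.Generator
) -> dict[str, tuple[float, float, float]]:
    return {
        s: (
            float(rng.uniform(0.8, 1.6)),
            float(rng.uniform(0.008, 0.03)),
            float(rng.uniform(300.0, 900.0)),
        )
        for s in substrates
    }


def simulate_plate(
    config: PlateSimConfig,
    sample_profile: Mapping[str, float] | float = 1.0,
    layout: PlateLayout | None = None,
    sample_id: str = "S1",
    plate_id: str = "P1",
) -> tuple[PlateLayout, list[RawReading]]:
    """Simulate paired 590/750 nm readings for one plate.

    ``sample_profile`` gives each substrate's affinity in [0, 1] (scalar =
    same affinity everywhere): the 590 nm channel develops a logistic curve
    with asymptote ``K * affinity`` on top of turbidity, noise and the
    control baseline; the 750 nm channel carries turbidity and noise only;
    control wells carry the baseline only.
    """
    if layout is None:
        layout = load_layout()
    rng = np.random.default_rng(config.seed)
    substrates = layout.substrates
    params = (
        dict(config.substrate_params)
        if config.substrate_params is not None
        else _default_substrate_params(substrates, rng)
    )
    missing = set(substrates) - set(params)
    if missing:
        raise ClppError(f"substrate_params missing {sorted(missing)[:5]}")
    if isinstance(sample_profile, (int, float)):
        affinity = {s: float(sample_profile) for s in substrates}
    else:
        affinity = {s: float(sample_profile.get(s, 0.0)) for s in substrates}
    for s, a in affinity.items():
        if not 0.0 <= a <= 1.0:
            raise ClppError(f"affinity for {s!r} must be in [0, 1], got {a}")

    times = config.times
    baseline = config.control_drift * times / 24.0
    wells = sorted(layout.wells)  # deterministic draw order
    turbidity = {
        w: max(float(rng.normal(config.turbidity_mean, config.turbidity_sd)), 0.0)
        for w in wells
    }

    od590: dict[str, np.ndarray] = {}
    od750: dict[str, np.ndarray] = {}
    for w in wells:
        a = layout.wells[w]
        noise590 = rng.normal(0.0, config.od_noise_sd, len(times))
        noise750 = rng.normal(0.0, config.od_noise_sd, len(times))
        if a.substrate == CONTROL:
            od590[w] = baseline + turbidity[w] + noise590
            od750[w] = turbidity[w] + noise750
        else:
            k, r, t0 = params[a.substrate]
            color = logistic(times, k * affinity[a.substrate], r, t0)
            od590[w] = color + baseline + turbidity[w] + noise590
            od750[w] = turbidity[w] + noise750

    readings = []
    for i, t in enumerate(times):
        for wl, od in ((590, od590), (750, od750)):
            readings.append(
                RawReading(
                    plate_id,
                    sample_id,
                    float(t),
                    wl,
                    {w: float(od[w][i]) for w in wells},
                )
            )
    return layout, readings


def readings_to_frame(readings: Sequence[RawReading]) -> pd.DataFrame:
    """Long-format frame in the dialect :func:`clpp.ecoplate.load_readings` reads."""
    records = [
        {
            "plate": r.plate_id,
            "sample": r.sample_id,
            "time_h": r.time_h,
            "wavelength": r.wavelength,
            "well": w,
            "od": od,
        }
        for r in readings
        for w, od in sorted(r.od.items())
    ]
    return pd.DataFrame.from_records(records)


def layout_to_frame(layout: PlateLayout) -> pd.DataFrame:
    records = [
        {
            "well": w,
            "substrate": a.substrate,
            "category": a.category,
            "replicate": a.replicate,
        }
        for w, a in sorted(layout.wells.items())
    ]
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# environmental metadata
# --------------------------------------------------------------------------


def _wc_profiles(depth_m: np.ndarray) -> pd.DataFrame:
    """Deterministic depth profiles of the water-column environment.

    Shapes emulate a subtropical open-ocean profile: temperature decays
    smoothly from ~19.9 °C at the surface to ~1.1 °C at 5000 m; salinity has
    a subsurface minimum (lowest at 800 m among the default sampling depths);
    inorganic nutrients increase monotonically with depth.
    """
    d = np.asarray(depth_m, dtype=float)
    temperature = 1.095 + (19.87 - 1.095) * np.exp(-d / 250.0)
    salinity = (
        34.3
        + 1.2 * np.exp(-d / 350.0)
        + 0.4 * (1.0 - np.exp(-np.maximum(d - 800.0, 0.0) / 3000.0))
    )
    no3_no2 = 0.5 + 34.5 * (1.0 - np.exp(-d / 900.0))
    po4 = 0.1 + 2.2 * (1.0 - np.exp(-d / 900.0))
    nh4 = 0.02 + 0.28 * (1.0 - np.exp(-d / 1200.0))
    return pd.DataFrame(
        {
            "depth_m": d,
            "temperature_C": temperature,
            "salinity": salinity,
            "no3_no2": no3_no2,
            "nh4": nh4,
            "po4": po4,
        }
    )


def simulate_metadata_profiles(
    depths_m: Sequence[float] = WC_DEFAULT_DEPTHS_M,
    trench: str = "Kermadec",
    layer: str = "WC",
) -> pd.DataFrame:
    """Sample metadata for stations at the given depths (one row per depth).

    Water-column rows follow :func:`_wc_profiles`; benthic-boundary-layer
    rows sit near the deep-water endpoint (T ~ 1.5 °C) with nutrient
    concentrations elevated over the water column at the same depth.
    """
    d = np.asarray(list(depths_m), dtype=float)
    if d.size == 0:
        raise ClppError("need at least one depth")
    if (d < 0).any():
        raise ClppError("depths must be non-negative")
    prof = _wc_profiles(d)
    if layer == "WC":
        ids = [f"{trench}_WC_{int(round(x))}m" for x in d]
    elif layer == "BBL":
        prof["temperature_C"] = 1.5
        prof["salinity"] = 34.7
        for col in ("no3_no2", "nh4", "po4"):
            prof[col] = prof[col] * 1.25
        ids = [f"{trench}_BBL_st{i + 1}" for i in range(len(d))]
    else:
        raise ClppError(f"layer must be WC or BBL, got {layer!r}")
    prof.insert(0, "layer", layer)
    prof.insert(0, "trench", trench)
    prof.index = pd.Index(ids, name="sample")
    return prof


# --------------------------------------------------------------------------
# ASV table simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunitySimConfig:
    """Planted-guild community generator settings.

    ``within_guild_rho`` is the latent pairwise correlation shared by ASVs of
    one guild (rank correlations of the resulting counts land slightly below
    it through count noise).  Abundance heterogeneity across ASVs is
    log-normal around ``exp(base_abundance_mu)`` counts; modest depth and
    layer effects add environmental structure without overwhelming the
    guilds.
    """

    n_samples: int = 20
    n_asvs: int = 80
    n_guilds: int = 4
    within_guild_rho: float = 0.95
    base_abundance_mu: float = math.log(100.0)
    base_abundance_sigma: float = 0.8
    depth_effect_sd: float = 0.1
    layer_effect_sd: float = 0.15
    archaea_fraction: float = 0.25
    trench: str = "Kermadec"
    wc_depths_m: tuple[float, ...] = WC_DEFAULT_DEPTHS_M
    bbl_depth_range_m: tuple[float, float] = (2311.0, 9639.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_guilds < 1:
            raise ClppError("n_guilds must be >= 1")
        if self.n_asvs < self.n_guilds:
            raise ClppError("need n_asvs >= n_guilds")
        if not 0.0 <= self.within_guild_rho < 1.0:
            raise ClppError("within_guild_rho must be in [0, 1)")
        if not 0.0 <= self.archaea_fraction <= 1.0:
            raise ClppError("archaea_fraction must be in [0, 1]")
        if self.n_samples < 2:
            raise ClppError("need at least 2 samples")


def guild_assignments(config: CommunitySimConfig) -> np.ndarray:
    """Guild index per ASV: contiguous, near-equal blocks."""
    return np.array(
        [min(i * config.n_guilds // config.n_asvs, config.n_guilds - 1) for i in range(config.n_asvs)]
    )


def _taxonomy(config: CommunitySimConfig, asv_ids: Sequence[str], guilds: np.ndarray) -> pd.DataFrame:
    """Assign domains and lineages so both domains populate every guild."""
    rows = []
    arch_i = bact_i = 0
    for g in range(config.n_guilds):
        members = [i for i in range(len(asv_ids)) if guilds[i] == g]
        n_arch = int(round(config.archaea_fraction * len(members)))
        for j, i in enumerate(members):
            if j < n_arch:
                phylum, cls = ARCHAEAL_LINEAGES[arch_i % len(ARCHAEAL_LINEAGES)]
                arch_i += 1
                rows.append((asv_ids[i], "Archaea", phylum, cls))
            else:
                phylum, cls = BACTERIAL_LINEAGES[bact_i % len(BACTERIAL_LINEAGES)]
                bact_i += 1
                rows.append((asv_ids[i], "Bacteria", phylum, cls))
    df = pd.DataFrame(rows, columns=["asv", "domain", "phylum", "class"])
    return df.set_index("asv").loc[list(asv_ids)]


def _sample_metadata(config: CommunitySimConfig) -> pd.DataFrame:
    n_wc = (config.n_samples + 1) // 2
    n_bbl = config.n_samples - n_wc
    wc_depths = [config.wc_depths_m[i % len(config.wc_depths_m)] for i in range(n_wc)]
    wc = _wc_profiles(np.asarray(wc_depths))
    wc.insert(0, "layer", "WC")
    wc.insert(0, "trench", config.trench)
    wc.index = pd.Index(
        [f"{config.trench}_WC_{int(d)}m_r{i // len(config.wc_depths_m) + 1}" for i, d in enumerate(wc_depths)],
        name="sample",
    )
    if n_bbl:
        lo, hi = config.bbl_depth_range_m
        bbl_depths = np.linspace(lo, hi, n_bbl)
        bbl = simulate_metadata_profiles(bbl_depths, trench=config.trench, layer="BBL")
        bbl.index = pd.Index([f"{config.trench}_BBL_st{i + 1}" for i in range(n_bbl)], name="sample")
        return pd.concat([wc, bbl])
    return wc


def simulate_asv_table(
    config: CommunitySimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw (counts, taxonomy, metadata) with planted correlated guilds.

    Per sample s and guild g a latent factor f_{s,g} ~ N(0,1) is shared by
    the guild's ASVs:  z = sqrt(rho) f + sqrt(1-rho) eps, so within-guild
    latent correlation is exactly ``within_guild_rho``.  Counts are
    Poisson(exp(mu_a + z + depth/layer effects)) with per-ASV log-normal
    abundance mu_a.
    """
    rng = np.random.default_rng(config.seed)
    meta = _sample_metadata(config)
    n, m = config.n_samples, config.n_asvs
    asv_ids = [f"ASV{i + 1:04d}" for i in range(m)]
    guilds = guild_assignments(config)
    taxonomy = _taxonomy(config, asv_ids, guilds)

    depth = meta["depth_m"].to_numpy()
    depth_std = (depth - depth.mean()) / (depth.std() or 1.0)
    is_bbl = (meta["layer"] == "BBL").to_numpy(dtype=float)

    mu_a = config.base_abundance_mu + config.base_abundance_sigma * rng.standard_normal(m)
    beta_depth = config.depth_effect_sd * rng.standard_normal(m)
    beta_layer = config.layer_effect_sd * rng.standard_normal(m)

    factors = rng.standard_normal((n, config.n_guilds))
    eps = rng.standard_normal((n, m))
    rho = config.within_guild_rho
    z = math.sqrt(rho) * factors[:, guilds] + math.sqrt(1.0 - rho) * eps

    log_lambda = (
        mu_a[None, :]
        + z
        + beta_depth[None, :] * depth_std[:, None]
        + beta_layer[None, :] * is_bbl[:, None]
    )
    counts = rng.poisson(np.exp(log_lambda))
    table = pd.DataFrame(counts, index=meta.index, columns=asv_ids)
    return table, taxonomy, meta
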
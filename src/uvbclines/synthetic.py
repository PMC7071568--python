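"""Synthetic sample-set collections and UVB rasters with the statistical
structure the analysis assumes.

Allele frequencies follow the Balding-Nichols model: within group ``g`` a
variant with group mean ``p`` gives each sample set a latent frequency drawn
from

    Beta( p (1-theta)/theta,  (1-p)(1-theta)/theta )

whose mean is ``p`` and variance ``theta * p * (1-p)``; ``theta`` is the
drift/differentiation parameter (the expected Wright fixation index of the
sets around their group mean). ``theta -> 0`` collapses every set onto the
group mean, and ``p`` in {0, 1} is degenerate (the latent frequency is fixed
at ``p``). By default the observed frequency is the latent value so analytic
checks are exact; ``binomial_noise=True`` additionally resamples 2n alleles.

The synthetic UVB raster is a latitude gradient: the daily value in a cell at
latitude L is ``max(0, base - decay * |L|) + N(0, sd)``, clamped at zero.
Defaults (base 94.0 Mw/m^2/nm at the equator, decay 1.45 per degree, sd 5.0)
place the three reference ancestry groups near the published mean annual
levels (AFR ~82, EAS ~48, EUR ~18 Mw/m^2/nm) and guarantee the ordering
AFR > EAS > EUR that the analysis relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import (
    DataValidationError,
    FrequencyMatrix,
    SampleSet,
    UVBRaster,
    VariantAnnotation,
)
from .popgen import wright_fst
from .uvb import cells_for_location

THETA_DEGENERATE = 1e-9  # below this, sets sit exactly on the group mean


@dataclass(frozen=True)
class GroupDesign:
    """Design of one geographic group: cohort sizes and a latitude band."""

    name: str
    cohort_sizes: tuple[int, ...]
    lat_band: tuple[float, float]
    lon_band: tuple[float, float]

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.cohort_sizes):
            raise DataValidationError(f"group {self.name}: cohort sizes must be >= 1")
        if self.lat_band[0] > self.lat_band[1]:
            raise DataValidationError(f"group {self.name}: invalid latitude band")


@dataclass(frozen=True)
class UVBConfig:
    """Latitude-gradient UVB generator parameters."""

    base: float = 94.0        # Mw/m^2/nm at the equator
    decay: float = 1.45       # Mw/m^2/nm lost per degree of |latitude|
    noise_sd: float = 5.0     # daily Gaussian noise
    n_days: int = 365
    start_date: str = "1980-01-01"


@dataclass(frozen=True)
class SimulationConfig:
    """Full design of a synthetic study.

    ``group_means`` maps rsid -> {group name -> mean frequency}; every group
    in ``groups`` must be covered by every variant.
    """

    groups: tuple[GroupDesign, ...]
    group_means: dict[str, dict[str, float]]
    theta: float = 0.02
    binomial_noise: bool = False
    uvb: UVBConfig = field(default_factory=UVBConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise DataValidationError(f"theta {self.theta} not in [0,1)")
        names = {g.name for g in self.groups}
        for rsid, means in self.group_means.items():
            missing = names - set(means)
            if missing:
                raise DataValidationError(f"{rsid}: no group mean for {sorted(missing)}")
            for g, p in means.items():
                if not (0.0 <= p <= 1.0):
                    raise DataValidationError(f"{rsid}/{g}: mean {p} not in [0,1]")

    @property
    def rsids(self) -> list[str]:
        return list(self.group_means)


def _latent_frequency(rng: np.random.Generator, p: float, theta: float, size: int) -> np.ndarray:
    if theta < THETA_DEGENERATE or p <= 0.0 or p >= 1.0:
        # degenerate Beta: no drift, or an ancestrally fixed/lost allele
        return np.full(size, p)
    a = p * (1.0 - theta) / theta
    b = (1.0 - p) * (1.0 - theta) / theta
    return rng.beta(a, b, size=size)


def simulate_sample_sets(
    config: SimulationConfig,
    sets: Sequence[SampleSet] | None = None,
) -> tuple[list[SampleSet], FrequencyMatrix, list[VariantAnnotation]]:
    """Draw a sample-set collection and its frequency matrix.

    When ``sets`` is given (e.g. the built-in reference roster) its ids,
    cohort sizes, groups and coordinates are used as-is and only frequencies
    are simulated; otherwise sets are created from the group designs with
    coordinates uniform in each group's latitude/longitude band.

    Returned annotations carry the realized Wright fixation index of each
    simulated variant (cohort-size-weighted across all sets), mirroring a
    differentiation index supplied by a frequency database.
    """
    rng = np.random.default_rng(config.seed)
    if sets is None:
        made: list[SampleSet] = []
        for gd in config.groups:
            lats = rng.uniform(gd.lat_band[0], gd.lat_band[1], size=len(gd.cohort_sizes))
            lons = rng.uniform(gd.lon_band[0], gd.lon_band[1], size=len(gd.cohort_sizes))
            for i, n in enumerate(gd.cohort_sizes):
                made.append(
                    SampleSet(
                        id=f"{gd.name}{i + 1:02d}",
                        name=f"Synthetic {gd.name} cohort {i + 1}",
                        group=gd.name,
                        n=int(n),
                        lat_min=round(float(lats[i]), 3),
                        lat_max=round(float(lats[i]), 3),
                        lon=round(float(lons[i]), 3),
                        source="SYNTHETIC",
                    )
                )
        sets = made
    else:
        sets = list(sets)
    group_names = [g.name for g in config.groups]
    unknown = {s.group for s in sets} - set(group_names)
    if unknown:
        raise DataValidationError(f"sets reference groups without a design: {sorted(unknown)}")

    data: dict[str, np.ndarray] = {}
    ids = [s.id for s in sets]
    n_arr = np.array([s.n for s in sets])
    for rsid in config.rsids:
        col = np.empty(len(sets))
        for gname in group_names:
            mask = np.array([s.group == gname for s in sets])
            p = config.group_means[rsid][gname]
            latent = _latent_frequency(rng, p, config.theta, int(mask.sum()))
            if config.binomial_noise:
                alleles = 2 * n_arr[mask]
                latent = rng.binomial(alleles, latent) / alleles
            col[mask] = latent
        data[rsid] = col
    freq = FrequencyMatrix(pd.DataFrame(data, index=ids))

    annotations = []
    for rsid in config.rsids:
        col = freq.column(rsid).to_numpy()
        fst = wright_fst(col, n_arr.astype(float)) if len(sets) >= 2 else None
        overall = float(np.average(col, weights=n_arr))
        maf = min(overall, 1.0 - overall)
        annotations.append(
            VariantAnnotation(
                rsid=rsid,
                locus="SYNTHETIC",
                variant_allele="A",
                minor_allele_frequency=round(maf, 6),
                fst=None if fst is None else round(fst, 6),
                function_class="Intron",
            )
        )
    return list(sets), freq, annotations


def simulate_uvb_raster(
    config: SimulationConfig, sets: Sequence[SampleSet]
) -> UVBRaster:
    """Daily 305 nm irradiance for every half-degree cell the sets touch.

    One value per day per cell over ``config.uvb.n_days``; reproducible under
    the config seed (independent of the frequency stream).
    """
    uvb = config.uvb
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 305]))
    cells: list[tuple[float, float]] = []
    seen = set()
    for s in sets:
        cc = cells_for_location(s)
        if cc is None:
            continue
        for cell in cc:
            if cell not in seen:
                seen.add(cell)
                cells.append(cell)
    dates = pd.date_range(uvb.start_date, periods=uvb.n_days, freq="D").strftime(
        "%Y-%m-%d"
    )
    frames = []
    for lat, lon in cells:
        clean = max(0.0, uvb.base - uvb.decay * abs(lat))
        vals = clean + (
            rng.normal(0.0, uvb.noise_sd, size=uvb.n_days)
            if uvb.noise_sd > 0
            else np.zeros(uvb.n_days)
        )
        np.maximum(vals, 0.0, out=vals)
        frames.append(
            pd.DataFrame(
                {
                    "lat_cell": lat,
                    "lon_cell": lon,
                    "date": dates,
                    "irradiance": vals,
                }
            )
        )
    if not frames:
        raise DataValidationError("no located sample sets; cannot build a raster")
    return UVBRaster(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# reference design
# ---------------------------------------------------------------------------


def reference_simulation_config(
    seed: int = 0,
    theta: float = 0.02,
    include_pigmentation: bool = True,
    uvb: UVBConfig | None = None,
) -> tuple[SimulationConfig, list[SampleSet]]:
    """Simulation of the built-in 60-cohort reference design.

    Group mean frequencies are the published per-group means of the vitamin D
    production/transport variants (plus, optionally, the three pigmentation
    ancestry-validation markers); cohort sizes, groups and coordinates come
    from the reference roster. ``theta`` defaults to 0.02, a realistic level
    of within-continent differentiation for human cohort collections.
    """
    from .reference_data import (
        pigmentation_group_means,
        reference_group_means,
        reference_sample_sets,
    )

    sets = reference_sample_sets()
    means: dict[str, dict[str, float]] = {}
    tables = [reference_group_means()]
    if include_pigmentation:
        tables.insert(0, pigmentation_group_means())
    for table in tables:
        for rsid, row in table.iterrows():
            means[rsid] = {g: float(row[g]) for g in ("EUR", "EAS", "AFR")}
    groups = tuple(
        GroupDesign(
            name=g,
            cohort_sizes=tuple(s.n for s in sets if s.group == g),
            lat_band=(
                min(s.lat_min for s in sets if s.group == g and s.lat_min is not None),
                max(s.lat_max for s in sets if s.group == g and s.lat_max is not None),
            ),
            lon_band=(-15.0, 140.0),
        )
        for g in ("EUR", "EAS", "AFR")
    )
    config = SimulationConfig(
        groups=groups,
        group_means=means,
        theta=theta,
        seed=seed,
        uvb=uvb or UVBConfig(),
    )
    return config, sets
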
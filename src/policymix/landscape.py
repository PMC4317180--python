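"""Landscape data model, CSV I/O, validation, and seeded synthetic landscapes.

The analysis unit is a 20x20 km grid cell (40,000 ha) nested in a district.
Each cell carries a baseline annual deforestation level ``d0`` (ha), the
travel cost of inspecting its first deforestation patch (``tc_first``, BRL),
the average cost per additional patch (``tc_within``, BRL), and a patch
count ``n_patches`` (fractional expected counts are allowed).  Districts
carry the mean per-hectare profit of deforestation (the conservation
opportunity cost, BRL/ha) that the calibration step disaggregates to cells.

The canonical exchange format is a pair of UTF-8 CSV tables::

    cells.csv:     cell_id,district_id,area,d0,tc_first,tc_within[,n_patches][,x][,y]
    districts.csv: district_id,mean_profit

Synthetic landscapes emulate the structure of the Brazilian Amazon inputs:
districts tile the grid, deforestation is strongly heterogeneous in space,
inspection costs rise with remoteness from an access point, and district
opportunity costs are negatively correlated with inspection costs
(target Pearson r = -0.33 by default).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    GenerationError,
    ReferentialError,
    SchemaError,
    ValidationError,
)

#: Expected number of deforestation patches per hectare of annual clearing,
#: estimated from historical deforestation data.
PATCHES_PER_HA = 0.035

#: Default cell edge length (km) and land area (ha) of a 20x20 km cell.
CELL_SIZE_KM = 20.0
CELL_AREA_HA = 40_000.0

_CELL_COLUMNS = ["cell_id", "district_id", "area", "d0", "tc_first", "tc_within"]
_CELL_OPTIONAL = ["n_patches", "x", "y"]
_DISTRICT_COLUMNS = ["district_id", "mean_profit"]


@dataclass(frozen=True)
class GridCell:
    """One 20x20 km spatial unit."""

    cell_id: int
    district_id: int
    area: float
    d0: float
    tc_first: float
    tc_within: float
    n_patches: float | None = None
    x: float | None = None
    y: float | None = None


@dataclass(frozen=True)
class District:
    """Administrative unit carrying the mean per-hectare profit constraint."""

    district_id: int
    mean_profit: float


def patches_from_deforestation(d0, coefficient: float = PATCHES_PER_HA):
    """Expected patch count implied by annual deforestation ``d0`` (ha).

    Fractional values are retained: the patch count enters enforcement costs
    as an expectation, and rounding would create artificial discontinuities
    in parameter sweeps.
    """
    d0 = np.asarray(d0, dtype=float)
    if np.any(d0 < 0):
        raise ValueError("d0 must be non-negative")
    out = coefficient * d0
    return float(out) if out.ndim == 0 else out


class Landscape:
    """A validated collection of grid cells and districts.

    Cells and districts are stored as pandas DataFrames (``cells`` and
    ``districts``); ``metadata`` is a free-form provenance dict.
    """

    def __init__(self, cells: pd.DataFrame, districts: pd.DataFrame,
                 metadata: dict | None = None, validate: bool = True):
        cells = cells.reset_index(drop=True).copy()
        districts = districts.reset_index(drop=True).copy()
        if "n_patches" not in cells.columns or cells["n_patches"].isna().any():
            filled = patches_from_deforestation(cells["d0"].to_numpy(float))
            if "n_patches" in cells.columns:
                mask = cells["n_patches"].isna()
                cells.loc[mask, "n_patches"] = np.asarray(filled)[mask.to_numpy()]
            else:
                cells["n_patches"] = filled
        self.cells = cells
        self.districts = districts
        self.metadata = metadata or {}
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_records(cls, cells: Sequence[GridCell], districts: Sequence[District],
                     metadata: dict | None = None) -> "Landscape":
        cdf = pd.DataFrame([dataclasses.asdict(c) for c in cells])
        ddf = pd.DataFrame([dataclasses.asdict(d) for d in districts])
        if cdf.get("x") is not None and cdf["x"].isna().all():
            cdf = cdf.drop(columns=["x", "y"])
        return cls(cdf, ddf, metadata)

    def __len__(self) -> int:
        return len(self.cells)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Landscape):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.cells, other.cells, rtol=1e-9)
            pd.testing.assert_frame_equal(self.districts, other.districts, rtol=1e-9)
        except AssertionError:
            return False
        return True

    # -- validation -----------------------------------------------------------

    def validate(self) -> None:
        """Check all invariants; raise with offending rows listed."""
        cells, districts = self.cells, self.districts
        for col in _CELL_COLUMNS:
            if col not in cells.columns:
                raise SchemaError(f"cells table is missing required column {col!r}")
        for col in _DISTRICT_COLUMNS:
            if col not in districts.columns:
                raise SchemaError(f"districts table is missing required column {col!r}")
        if len(cells) == 0:
            raise ValidationError("landscape must contain at least one cell")
        if cells["cell_id"].duplicated().any():
            dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValidationError(f"duplicate cell_id values: {dup}")
        if districts["district_id"].duplicated().any():
            dup = districts.loc[districts["district_id"].duplicated(), "district_id"].tolist()
            raise ValidationError(f"duplicate district_id values: {dup}")
        unresolved = ~cells["district_id"].isin(districts["district_id"])
        if unresolved.any():
            bad = cells.loc[unresolved, "cell_id"].tolist()
            raise ReferentialError(
                f"cells reference unknown districts: cell_id={bad}")
        checks = {
            "area > 0": cells["area"] > 0,
            "0 <= d0 <= area": (cells["d0"] >= 0) & (cells["d0"] <= cells["area"]),
            "tc_first >= 0": cells["tc_first"] >= 0,
            "tc_within >= 0": cells["tc_within"] >= 0,
            "n_patches >= 0": cells["n_patches"] >= 0,
        }
        for label, ok in checks.items():
            if not ok.all():
                rows = cells.loc[~ok, "cell_id"].tolist()
                raise ValidationError(
                    f"invariant {label!r} violated for cell_id={rows}")
        # districts that contain deforesting cells must have a positive mean profit
        d0_by_district = cells.groupby("district_id")["d0"].sum()
        deforesting = d0_by_district[d0_by_district > 0].index
        merged = districts.set_index("district_id").loc[deforesting, "mean_profit"]
        if (merged <= 0).any():
            bad = merged[merged <= 0].index.tolist()
            raise ValidationError(
                f"mean_profit must be > 0 for districts with deforestation: {bad}")


# -- file I/O -----------------------------------------------------------------


def read_landscape(cells_path, districts_path) -> Landscape:
    """Read and validate a landscape from its two CSV tables."""
    cells = pd.read_csv(cells_path)
    districts = pd.read_csv(districts_path)
    for col in _CELL_COLUMNS:
        if col not in cells.columns:
            raise SchemaError(f"{cells_path}: missing required column {col!r}")
    for col in _DISTRICT_COLUMNS:
        if col not in districts.columns:
            raise SchemaError(f"{districts_path}: missing required column {col!r}")
    return Landscape(cells, districts,
                     metadata={"source": str(cells_path)})


def write_landscape(landscape: Landscape, cells_path, districts_path) -> None:
    """Write a landscape to its two CSV tables (lossless at ~1e-12 relative)."""
    landscape.cells.to_csv(cells_path, index=False, float_format="%.12g")
    landscape.districts.to_csv(districts_path, index=False, float_format="%.12g")


def write_results(result, path) -> None:
    """Write a scenario result: per-cell CSV plus a JSON summary sidecar.

    The per-cell table has one row per grid cell with columns
    ``cell_id, p, d0, d_prime, income_change, net_revenue, pes_paid,
    pes_loss, fines_paid``; the sidecar ``<path>.summary.json`` holds the
    aggregate metrics.  Round-trips losslessly at 1e-9 relative.
    """
    per_cell = result.per_cell
    if len(per_cell) == 0:
        raise ValidationError("result contains no cells")
    path = Path(path)
    per_cell.to_csv(path, index=False, float_format="%.17g")
    with open(str(path) + ".summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path) -> tuple[pd.DataFrame, dict]:
    """Read back a per-cell result table and its summary sidecar."""
    path = Path(path)
    per_cell = pd.read_csv(path)
    with open(str(path) + ".summary.json") as fh:
        summary = json.load(fh)
    return per_cell, summary


# -- synthetic landscapes -----------------------------------------------------


@dataclass
class SyntheticConfig:
    """Parameters of the seeded synthetic landscape generator.

    The defaults emulate the broad structure of the Amazon study region:
    20x20 km cells, district opportunity costs of a few hundred to ~1200
    BRL/ha, median cell deforestation rates well under 1% per year with a
    heavy upper tail (strong spatial heterogeneity; the 50x50 default
    totals ~1.5 Mha of baseline clearing), field inspection costs of tens
    of thousands of BRL rising with remoteness — sized so that the upper
    end of the simulated budget range funds inspections in only part of
    the landscape — and a negative cost-profit correlation.
    """

    n_cells_x: int = 50
    n_cells_y: int = 50
    n_districts: int = 25
    seed: int = 0
    cell_size_km: float = CELL_SIZE_KM
    #: district mean per-hectare profits are mapped into this range, BRL/ha
    mean_profit_range: tuple[float, float] = (300.0, 1200.0)
    #: deforestation rate = expit(intercept + loading * profit latent + noise)
    rate_intercept: float = -5.5
    rate_profit_loading: float = 0.8
    rate_noise_sd: float = 1.5
    #: first-patch inspection cost = tc_base * exp(loading * remoteness + noise)
    tc_base: float = 25_000.0
    tc_remoteness_loading: float = 0.8
    tc_noise_sd: float = 0.3
    tc_within_base: float = 600.0
    tc_within_noise_sd: float = 0.1
    patches_per_ha: float = PATCHES_PER_HA
    target_cost_profit_correlation: float = -0.33

    def __post_init__(self):
        if min(self.n_cells_x, self.n_cells_y, self.n_districts) < 1:
            raise ValueError("grid dimensions and district count must be >= 1")
        if not -1.0 <= self.target_cost_profit_correlation <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")
        lo, hi = self.mean_profit_range
        if not 0 < lo <= hi:
            raise ValueError("mean_profit_range must satisfy 0 < low <= high")


def _district_profits(loading: float, mean_remoteness: np.ndarray,
                      district_noise: np.ndarray,
                      profit_range: tuple[float, float]) -> np.ndarray:
    """Map the district latent -loading*remoteness + noise into the profit range."""
    latent = -loading * mean_remoteness + district_noise
    lo, hi = profit_range
    span = latent.max() - latent.min()
    if span == 0:
        return np.full_like(latent, 0.5 * (lo + hi))
    return lo + (hi - lo) * (latent - latent.min()) / span


def generate_synthetic_landscape(config: SyntheticConfig | None = None) -> Landscape:
    """Generate a seeded synthetic landscape.

    Construction: cells sit on a regular grid; remoteness is the distance
    from the grid's access corner.  Inspection costs load positively and
    district profits negatively on remoteness, with the profit loading tuned
    by bisection so that the realized Pearson correlation between cell-level
    mean profit (the district value) and ``tc_first`` matches the target.
    Deforestation rates load positively on the cell-level profit latent, so
    profitable accessible cells deforest more, as in frontier landscapes.

    Deterministic for a fixed config (including seed).
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    nx, ny = config.n_cells_x, config.n_cells_y
    n = nx * ny
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = config.cell_size_km * (ix.ravel() + 0.5)
    y = config.cell_size_km * (iy.ravel() + 0.5)
    area = (config.cell_size_km * 100.0) ** 2 / 100.0  # km^2 -> ha

    # remoteness: standardized distance from the access corner at the origin
    dist = np.hypot(x, y)
    remoteness = (dist - dist.mean()) / dist.std() if dist.std() > 0 else np.zeros(n)

    # districts: Voronoi tiling around seed cells (each seed owns its own cell)
    if config.n_districts > n:
        raise GenerationError("more districts than cells requested")
    seed_idx = rng.choice(n, size=config.n_districts, replace=False)
    d2 = (x[:, None] - x[seed_idx]) ** 2 + (y[:, None] - y[seed_idx]) ** 2
    district_of = np.argmin(d2, axis=1)

    # draw all noise once so the correlation tuning is deterministic
    eps_tc = rng.standard_normal(n)
    eps_tc_within = rng.standard_normal(n)
    eps_district = rng.standard_normal(config.n_districts)
    eps_cell_profit = rng.standard_normal(n)
    eps_rate = rng.standard_normal(n)

    tc_first = config.tc_base * np.exp(
        config.tc_remoteness_loading * remoteness + config.tc_noise_sd * eps_tc)
    tc_within = config.tc_within_base * np.exp(
        config.tc_within_noise_sd * eps_tc_within)

    mean_remoteness = np.bincount(district_of, weights=remoteness,
                                  minlength=config.n_districts)
    mean_remoteness /= np.bincount(district_of, minlength=config.n_districts)

    def realized_corr(loading: float) -> float:
        profits = _district_profits(loading, mean_remoteness, eps_district,
                                    config.mean_profit_range)
        cellwise = profits[district_of]
        if np.std(cellwise) == 0 or np.std(tc_first) == 0:
            return 0.0
        return float(np.corrcoef(cellwise, tc_first)[0, 1])

    target = config.target_cost_profit_correlation
    if config.n_districts == 1:
        if abs(target) > 1e-12:
            raise GenerationError(
                "a single district has constant mean profit; the cost-profit "
                "correlation target cannot be nonzero — increase n_districts")
        loading = 0.0
    else:
        lo_load, hi_load = -50.0, 50.0
        r_lo, r_hi = realized_corr(lo_load), realized_corr(hi_load)
        # realized correlation decreases in the loading
        if not (r_hi - 1e-9 <= target <= r_lo + 1e-9):
            raise GenerationError(
                f"correlation target {target} outside achievable range "
                f"[{r_hi:.3f}, {r_lo:.3f}]; adjust noise levels or district count")
        loading = 0.0
        a, b = lo_load, hi_load
        for _ in range(80):
            loading = 0.5 * (a + b)
            if realized_corr(loading) > target:
                a = loading
            else:
                b = loading

    profits = _district_profits(loading, mean_remoteness, eps_district,
                                config.mean_profit_range)

    # cell-level profit latent drives deforestation pressure
    cell_latent = -loading * remoteness + eps_district[district_of] \
        + 0.5 * eps_cell_profit
    sd = cell_latent.std()
    cell_latent = (cell_latent - cell_latent.mean()) / sd if sd > 0 else cell_latent * 0
    from scipy.special import expit
    rate = expit(config.rate_intercept
                 + config.rate_profit_loading * cell_latent
                 + config.rate_noise_sd * eps_rate)
    rate = np.clip(rate, 1e-5, 0.9)
    d0 = rate * area

    cells = pd.DataFrame({
        "cell_id": np.arange(n),
        "district_id": district_of.astype(int),
        "area": np.full(n, area),
        "d0": d0,
        "tc_first": tc_first,
        "tc_within": tc_within,
        "n_patches": config.patches_per_ha * d0,
        "x": x,
        "y": y,
    })
    districts = pd.DataFrame({
        "district_id": np.arange(config.n_districts),
        "mean_profit": profits,
    })
    meta = {
        "source": "synthetic",
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "profit_remoteness_loading": float(loading),
        "realized_cost_profit_correlation": realized_corr(loading)
        if config.n_districts > 1 else float("nan"),
    }
    return Landscape(cells, districts, metadata=meta)
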
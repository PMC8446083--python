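"""SST bias correction and breakpoint-band classification under warming.

Projected sea-surface temperatures are delta-bias-corrected against an
observed climatology (add the per-cell observed-minus-modelled historical
difference to the projection), then every unmasked grid cell is classified
into the temperature bands bounded by the three beta-diversity breakpoints:
blue < 9.49 degC <= yellow < 13.96 <= orange < 18.06 <= red.  Cells holding
sea ice in the observed climatology are excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError, InputError

BAND_NAMES: tuple[str, ...] = ("blue", "yellow", "orange", "red")
MASKED = "masked"

#: Freezing proxy for sea ice in a climatology (deg C).
SEA_ICE_TEMPERATURE = -1.8


@dataclass
class BandThresholds:
    """The three breakpoint temperatures bounding the bands (deg C)."""

    t_16S: float = 9.49
    t_18S: float = 13.96
    t_pfam: float = 18.06

    def __post_init__(self) -> None:
        if not self.t_16S < self.t_18S < self.t_pfam:
            raise InputError(
                f"band thresholds must be increasing, got "
                f"{self.t_16S}, {self.t_18S}, {self.t_pfam}"
            )

    @property
    def edges(self) -> tuple[float, float, float]:
        return (self.t_16S, self.t_18S, self.t_pfam)


@dataclass
class ClimateGrid:
    """Gridded SST field: lat × lon temperatures with an ice/missing mask."""

    latitudes: np.ndarray
    longitudes: np.ndarray
    sst: np.ndarray
    period_label: str = ""
    ice_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.sst = np.asarray(self.sst, dtype=float)
        if self.sst.shape != (len(self.latitudes), len(self.longitudes)):
            raise GridError(
                f"sst shape {self.sst.shape} does not match "
                f"({len(self.latitudes)}, {len(self.longitudes)})"
            )
        if self.ice_mask is None:
            self.ice_mask = np.zeros(self.sst.shape, dtype=bool)
        else:
            self.ice_mask = np.asarray(self.ice_mask, dtype=bool)
            if self.ice_mask.shape != self.sst.shape:
                raise GridError("ice mask shape does not match sst shape")

    def compatible_with(self, other: "ClimateGrid") -> bool:
        return (
            self.sst.shape == other.sst.shape
            and np.allclose(self.latitudes, other.latitudes)
            and np.allclose(self.longitudes, other.longitudes)
        )


def bias_correct(
    obs_clim: ClimateGrid, model_hist: ClimateGrid, model_proj: ClimateGrid
) -> ClimateGrid:
    """Delta bias correction: proj + (obs climatology - model historical), per cell.

    By construction the corrected historical field reproduces the observed
    climatology exactly.  Masks are combined (a cell masked anywhere stays
    masked).
    """
    for g in (model_hist, model_proj):
        if not obs_clim.compatible_with(g):
            raise GridError("grids must share shape and coordinates for bias correction")
    corrected = model_proj.sst + (obs_clim.sst - model_hist.sst)
    mask = obs_clim.ice_mask | model_hist.ice_mask | model_proj.ice_mask
    return ClimateGrid(
        latitudes=obs_clim.latitudes,
        longitudes=obs_clim.longitudes,
        sst=corrected,
        period_label=model_proj.period_label,
        ice_mask=mask,
    )


def classify_bands(
    grid: ClimateGrid, thresholds: BandThresholds | None = None
) -> np.ndarray:
    """Band label per cell, half-open upward at each threshold.

    blue: T < t_16S; yellow: t_16S <= T < t_18S; orange: t_18S <= T < t_pfam;
    red: T >= t_pfam.  Ice-masked cells are labelled "masked".
    """
    thresholds = thresholds or BandThresholds()
    idx = np.digitize(grid.sst, thresholds.edges, right=False)
    bands = np.asarray(BAND_NAMES, dtype=object)[idx]
    bands[grid.ice_mask] = MASKED
    return bands


def band_fractions(bands: np.ndarray) -> dict[str, float]:
    """Fraction of unmasked cells in each band (sums to 1)."""
    unmasked = bands != MASKED
    n = int(unmasked.sum())
    if n == 0:
        raise InputError("no unmasked cells")
    return {b: float(np.sum(bands[unmasked] == b)) / n for b in BAND_NAMES}


def band_shift_summary(
    before: np.ndarray,
    after: np.ndarray,
    latitudes: np.ndarray,
    lat_band: tuple[float, float] | None = None,
) -> dict:
    """Band composition before/after and the 4×4 transition matrix in a latitude band.

    ``before``/``after`` are band-label grids of identical shape; ``lat_band``
    restricts rows to latitudes in [lo, hi].  Cells masked in either period
    are excluded.  Returns per-band fractions for each period (each summing
    to 1) and transition counts between bands.
    """
    if before.shape != after.shape:
        raise GridError("before/after band grids must share shape")
    latitudes = np.asarray(latitudes, dtype=float)
    rows = np.ones(len(latitudes), dtype=bool)
    if lat_band is not None:
        lo, hi = min(lat_band), max(lat_band)
        rows = (latitudes >= lo) & (latitudes <= hi)
        if not rows.any():
            raise InputError(f"no grid rows inside latitude band {lat_band}")
    b = before[rows].ravel()
    a = after[rows].ravel()
    ok = (b != MASKED) & (a != MASKED)
    if not ok.any():
        raise InputError("no unmasked cells inside the latitude band")
    b, a = b[ok], a[ok]
    n = len(b)
    trans = np.zeros((4, 4), dtype=int)
    pos = {name: i for i, name in enumerate(BAND_NAMES)}
    for bi, ai in zip(b, a):
        trans[pos[bi], pos[ai]] += 1
    return {
        "n_cells": n,
        "before_fraction": {k: float(np.sum(b == k)) / n for k in BAND_NAMES},
        "after_fraction": {k: float(np.sum(a == k)) / n for k in BAND_NAMES},
        "transition_counts": trans,
        "band_order": list(BAND_NAMES),
    }
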
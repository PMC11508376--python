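"""Spatiotemporal fire-connectivity kernel.

The connectivity of trap *i* to the surrounding fire history is

    ST_i = sum_j  exp(-d_ij * alpha_s) * FA_j * exp(-T_j * alpha_t)

an incidence-function-style patch-connectivity measure extended with a
temporal decay term: *d_ij* is the planar distance (km) between trap *i* and
fire *j*, *FA_j* the log-transformed burned area (m²), *T_j* the whole years
elapsed between fire *j* and the sampling at trap *i*, and alpha_s / alpha_t
set the spatial (per-km) and temporal (per-year) decay scales. Only fires
within a truncation radius (default 20 km, inclusive) contribute.

Distances are centre-to-centre; the circular-extent radius of a fire is
available but not used by default (an optional edge-distance mode subtracts
it, floored at zero).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .fire_records import FireRecord, FireSet, TrapSite

logger = logging.getLogger(__name__)

ALPHA_RANGE = (0.0, 4.0)


@dataclass(frozen=True)
class ConnectivityParams:
    """Decay scales and truncation radius of the connectivity kernel.

    alpha_s : spatial decay scale, per kilometre, in [0, 4]
    alpha_t : temporal decay scale, per year, in [0, 4]
    max_distance_km : inclusive truncation radius (default 20 km)
    log_base : base of the burned-area log transform, "e" (default) or "10";
        the choice rescales ST by a constant absorbed by the standardized
        regression slope
    edge_distance : subtract the circular-extent radius from each distance
        (floored at 0) instead of using centre-to-centre distance
    allow_wide : permit decay scales outside the [0, 4] optimization range
    """

    alpha_s: float
    alpha_t: float
    max_distance_km: float = 20.0
    log_base: str = "e"
    edge_distance: bool = False
    allow_wide: bool = False

    def __post_init__(self) -> None:
        lo, hi = ALPHA_RANGE
        if not self.allow_wide:
            for name, a in (("alpha_s", self.alpha_s), ("alpha_t", self.alpha_t)):
                if not lo <= a <= hi:
                    raise ValidationError(
                        f"{name}={a} outside the optimization range [{lo}, {hi}]; "
                        "pass allow_wide=True to override"
                    )
        if not self.max_distance_km > 0:
            raise ValidationError("max_distance_km must be positive")
        if self.log_base not in ("e", "10"):
            raise ValidationError(f"log_base must be 'e' or '10', got {self.log_base!r}")


@dataclass(frozen=True)
class ConnectivityResult:
    site_id: str
    st_value: float
    n_contributing_fires: int


def pairwise_distance_km(trap: TrapSite, fire: FireRecord) -> float:
    """Euclidean trap-fire distance in kilometres (coordinates are metres)."""
    for obj, label in ((trap, "trap"), (fire, "fire")):
        if obj.x_m is None or obj.y_m is None or math.isnan(obj.x_m) or math.isnan(obj.y_m):
            raise ValidationError(f"{label} has missing coordinates")
    return math.hypot(trap.x_m - fire.x_m, trap.y_m - fire.y_m) / 1000.0


def _log_area(area_m2: np.ndarray, log_base: str) -> np.ndarray:
    if np.any(area_m2 < 1.0):
        raise ValidationError(
            "fires with area_m2 < 1 would have negative log-area weight; "
            "filter the register (default cut-off 100 m2) before computing connectivity"
        )
    return np.log(area_m2) if log_base == "e" else np.log10(area_m2)


class ConnectivityDesign:
    """Precomputed trap-fire geometry for fast connectivity evaluation.

    Holds the distance matrix, log-areas and year offsets so that ST for any
    (alpha_s, alpha_t) is two vector exponentials and a mat-vec. The temporal
    term factorizes — exp(-alpha_t * T_ij) with T_ij = (s_i - y0) + (y0 - y_j)
    — so a whole alpha grid reuses one exp(-alpha_s * D) per spatial scale.
    """

    def __init__(
        self,
        traps: Sequence[TrapSite],
        fires: FireSet,
        max_distance_km: float = 20.0,
        log_base: str = "e",
        edge_distance: bool = False,
    ):
        self.traps = list(traps)
        self.fires = fires
        self.max_distance_km = float(max_distance_km)
        self.log_base = log_base

        txy = np.array([[t.x_m, t.y_m] for t in self.traps], dtype=float).reshape(-1, 2)
        fxy = fires.xy()
        self._sampling_years = np.array([t.sampling_year for t in self.traps], dtype=int)

        if fires.n == 0:
            self.D = np.zeros((len(self.traps), 0))
            self.mask = np.zeros_like(self.D, dtype=bool)
            self.fa = np.zeros(0)
            self._t_off = np.zeros(len(self.traps))
            self._y_rel = np.zeros(0)
            return

        years = fires.years()
        if np.any(years[None, :] >= self._sampling_years[:, None]):
            raise ValidationError("every fire must be strictly prior to each trap's sampling year")

        D = np.hypot(
            txy[:, 0:1] - fxy[None, :, 0], txy[:, 1:2] - fxy[None, :, 1]
        ) / 1000.0
        if edge_distance:
            radius_km = np.sqrt(fires.areas_m2() / np.pi) / 1000.0
            D = np.maximum(D - radius_km[None, :], 0.0)
        self.D = D
        self.mask = D <= self.max_distance_km
        self.fa = _log_area(fires.areas_m2(), log_base)
        y0 = int(years.max())
        self._t_off = (self._sampling_years - y0).astype(float)  # >= 1
        self._y_rel = (y0 - years).astype(float)  # >= 0

    @property
    def n_contributing(self) -> np.ndarray:
        """Per-trap count of fires within the truncation radius."""
        return self.mask.sum(axis=1)

    def st(self, alpha_s: float, alpha_t: float) -> np.ndarray:
        """Connectivity of every trap at the given decay scales."""
        if self.fires.n == 0:
            return np.zeros(len(self.traps))
        w_s = np.exp(-self.D * alpha_s) * self.mask * self.fa[None, :]
        return np.exp(-self._t_off * alpha_t) * (w_s @ np.exp(-self._y_rel * alpha_t))

    def st_grid(self, alpha_s_values: np.ndarray, alpha_t_values: np.ndarray) -> np.ndarray:
        """Connectivity on a full (alpha_s × alpha_t) grid.

        Returns an array of shape (n_alpha_s, n_alpha_t, n_traps). The
        spatial exponential is computed once per alpha_s and reused across
        all alpha_t values.
        """
        alpha_s_values = np.asarray(alpha_s_values, dtype=float)
        alpha_t_values = np.asarray(alpha_t_values, dtype=float)
        out = np.zeros((len(alpha_s_values), len(alpha_t_values), len(self.traps)))
        if self.fires.n == 0:
            return out
        # temporal factors shared across all alpha_s
        f_fire = np.exp(-np.outer(alpha_t_values, self._y_rel))  # (n_at, n_f)
        f_trap = np.exp(-np.outer(alpha_t_values, self._t_off))  # (n_at, n_traps)
        for i, a_s in enumerate(alpha_s_values):
            w_s = np.exp(-self.D * a_s) * self.mask * self.fa[None, :]  # (n_traps, n_f)
            out[i] = f_trap * (f_fire @ w_s.T)
        return out


def connectivity(trap: TrapSite, fires: FireSet, params: ConnectivityParams) -> ConnectivityResult:
    """Connectivity ST of a single trap to a fire register."""
    if fires.n == 0:
        logger.warning("empty fire set: connectivity of %s is 0", trap.site_id)
        return ConnectivityResult(trap.site_id, 0.0, 0)
    design = ConnectivityDesign(
        [trap], fires, params.max_distance_km, params.log_base, params.edge_distance
    )
    st = float(design.st(params.alpha_s, params.alpha_t)[0])
    return ConnectivityResult(trap.site_id, st, int(design.n_contributing[0]))


def connectivity_all(
    traps: Sequence[TrapSite], fires: FireSet, params: ConnectivityParams
) -> list[ConnectivityResult]:
    """Connectivity of every trap, evaluated with the shared design matrix."""
    if fires.n == 0:
        logger.warning("empty fire set: all connectivities are 0")
        return [ConnectivityResult(t.site_id, 0.0, 0) for t in traps]
    design = ConnectivityDesign(
        traps, fires, params.max_distance_km, params.log_base, params.edge_distance
    )
    st = design.st(params.alpha_s, params.alpha_t)
    counts = design.n_contributing
    return [
        ConnectivityResult(t.site_id, float(st[i]), int(counts[i]))
        for i, t in enumerate(traps)
    ]


def weight_curve_spatial(alpha_s: float, d_grid: Sequence[float]) -> np.ndarray:
    """Spatial weight exp(-d * alpha_s) of a fire at each distance (km)."""
    d = np.asarray(d_grid, dtype=float)
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    return np.exp(-d * alpha_s)


def weight_curve_temporal(alpha_t: float, t_grid: Sequence[float]) -> np.ndarray:
    """Temporal weight exp(-t * alpha_t) of a fire at each time lag (years)."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time lags must be non-negative")
    return np.exp(-t * alpha_t)
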
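"""Synthetic fire landscapes and trap catches with known ground truth.

The generator emulates a 12-year regional fire register (per-year Poisson
fire counts, lognormal burned areas truncated at the register cut-off,
optionally spatially clustered via a Thomas-style parent/offspring process)
and a smoke-trap survey (sites placed with a minimum separation, sampled the
year after the register closes). Catches follow the generative model the
ln-odds analysis implicitly assumes: per-site totals are Poisson, and the
number of fire-favoured individuals (or species) is binomial with

    logit p_i = baseline_logit + beta * z_i

where z_i is connectivity standardized across sites, evaluated at the true
decay scales. Control-group counts are generated with no connectivity
effect. Ground truth (scales, effect size, per-site connectivity) is kept
alongside so parameter-recovery tests can score the full pipeline.

Default rates mirror a south-Swedish county register (about 118 fires per
year for 12 years, roughly 1.4 km² burned per year) and survey (21 sites at
least 7 km apart, around 106 beetles of some 40 species per site, with 2.7%
of individuals pyrophilic at baseline).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .connectivity import ConnectivityDesign
from .errors import InfeasibleError, ValidationError
from .fire_records import (
    CatchCounts,
    FireRecord,
    FireSet,
    TrapSite,
    write_catches,
    write_fires,
)
from .scale_fit import standardize

# fixed per-purpose stream ids so fires/sites/catches draw independent streams
_STREAM_FIRES, _STREAM_SITES, _STREAM_CATCHES = 11, 22, 33

# control-group composition (no connectivity effect): share of non-focal
# individuals that are non-pyrophilic, and marginal saproxylic probability
_P_NONPYRO_IND, _P_SAPRO_IND = 0.105, 0.030
_P_NONPYRO_SP, _P_SAPRO_SP = 0.141, 0.201
_SP_BASELINE_OFFSET = 1.10  # species baseline = baseline_logit + offset


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one synthetic study."""

    extent_km: float = 100.0
    n_years: int = 12
    fire_rate: float = 118.0  # expected fires per year
    cluster_sd_km: float = 0.0  # 0 = spatially uniform fires
    cluster_parents: float = 10.0  # expected parent centres when clustering
    area_lognorm_mu: float = 8.0  # log-m2 scale of burned areas
    area_lognorm_sigma: float = 1.8
    min_area_m2: float = 100.0  # register cut-off (truncated sampling)
    register_end_year: int = 2010
    n_sites: int = 21
    min_site_separation_km: float = 7.0
    true_alpha_s: float = 1.0  # per km
    true_alpha_t: float = 1.0  # per year
    beta: float = 2.0  # effect of standardized connectivity, logit scale
    baseline_logit: float = -3.58  # pyrophilic individuals at mean connectivity
    total_catch_mean: float = 106.0  # expected individuals per site
    species_catch_mean: float = 40.0  # expected species per site
    max_distance_km: float = 20.0
    log_base: str = "e"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValidationError("n_sites must be >= 3")
        for name in ("extent_km", "fire_rate", "min_area_m2", "total_catch_mean",
                     "species_catch_mean", "n_years"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if self.cluster_sd_km < 0 or self.min_site_separation_km < 0:
            raise ValidationError("scales must be non-negative")

    @property
    def year_range(self) -> tuple[int, int]:
        return (self.register_end_year - self.n_years + 1, self.register_end_year)

    @property
    def sampling_year(self) -> int:
        return self.register_end_year + 1


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.seed])


def _truncated_lognormal(rng: np.random.Generator, n: int, mu: float, sigma: float,
                         lower: float) -> np.ndarray:
    """Lognormal(mu, sigma) conditioned on being >= lower (inverse-CDF)."""
    lo = norm.cdf((np.log(lower) - mu) / sigma)
    u = rng.uniform(lo, 1.0, size=n)
    return np.exp(mu + sigma * norm.ppf(u))


def simulate_fires(config: SyntheticConfig, rng: np.random.Generator | None = None) -> FireSet:
    """Draw a register: Poisson counts per year, clustered or uniform locations,
    truncated-lognormal areas. Deterministic for a fixed config seed."""
    rng = rng if rng is not None else _rng(config, _STREAM_FIRES)
    ext_m = config.extent_km * 1000.0
    records: list[FireRecord] = []
    y0, y1 = config.year_range
    for year in range(y0, y1 + 1):
        n = int(rng.poisson(config.fire_rate))
        if config.cluster_sd_km > 0:
            n_parents = max(1, int(rng.poisson(config.cluster_parents)))
            parents = rng.uniform(0, ext_m, size=(n_parents, 2))
            which = rng.integers(0, n_parents, size=n)
            xy = parents[which] + rng.normal(0, config.cluster_sd_km * 1000.0, size=(n, 2))
            xy = np.clip(xy, 0, ext_m)
        else:
            xy = rng.uniform(0, ext_m, size=(n, 2))
        areas = _truncated_lognormal(
            rng, n, config.area_lognorm_mu, config.area_lognorm_sigma, config.min_area_m2
        )
        for i in range(n):
            records.append(
                FireRecord(
                    fire_id=f"F{year}-{i:04d}",
                    x_m=float(xy[i, 0]),
                    y_m=float(xy[i, 1]),
                    area_m2=float(areas[i]),
                    year=year,
                )
            )
    return FireSet(records)


def simulate_sites(config: SyntheticConfig, rng: np.random.Generator | None = None) -> list[TrapSite]:
    """Place trap sites uniformly, rejecting candidates closer than the
    minimum separation to an accepted site. Sampling year is the year after
    the register closes."""
    rng = rng if rng is not None else _rng(config, _STREAM_SITES)
    ext_m = config.extent_km * 1000.0
    sep_m = config.min_site_separation_km * 1000.0
    placed = np.zeros((0, 2))
    max_tries = 2000 * config.n_sites
    tries = 0
    while placed.shape[0] < config.n_sites:
        tries += 1
        if tries > max_tries:
            raise InfeasibleError(
                f"could not place {config.n_sites} sites at >= "
                f"{config.min_site_separation_km} km separation in a "
                f"{config.extent_km} km extent; increase extent_km or relax the separation"
            )
        cand = rng.uniform(0, ext_m, size=2)
        if placed.shape[0] == 0 or np.min(np.hypot(*(placed - cand).T)) >= sep_m:
            placed = np.vstack([placed, cand])
    return [
        TrapSite(site_id=f"S{i:03d}", x_m=float(placed[i, 0]), y_m=float(placed[i, 1]),
                 sampling_year=config.sampling_year)
        for i in range(config.n_sites)
    ]


def true_connectivity(sites: Sequence[TrapSite], fires: FireSet,
                      config: SyntheticConfig) -> np.ndarray:
    """Per-site connectivity at the ground-truth decay scales."""
    design = ConnectivityDesign(sites, fires, config.max_distance_km, config.log_base)
    return design.st(config.true_alpha_s, config.true_alpha_t)


def simulate_catches(
    sites: Sequence[TrapSite],
    fires: FireSet,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[TrapSite]:
    """Attach binomial-logit catch counts driven by true-scale connectivity."""
    rng = rng if rng is not None else _rng(config, _STREAM_CATCHES)
    st = true_connectivity(sites, fires, config)
    z = standardize(st)
    p_ind = expit(config.baseline_logit + config.beta * z)
    p_sp = expit(config.baseline_logit + _SP_BASELINE_OFFSET + config.beta * z)

    out: list[TrapSite] = []
    for i, site in enumerate(sites):
        n_ind = int(rng.poisson(config.total_catch_mean))
        k_pyro = int(rng.binomial(n_ind, p_ind[i]))
        k_nonpyro = int(rng.binomial(n_ind - k_pyro, _P_NONPYRO_IND))
        k_sapro = int(rng.binomial(n_ind, _P_SAPRO_IND))
        n_sp = int(rng.poisson(config.species_catch_mean))
        s_pyro = int(rng.binomial(n_sp, p_sp[i]))
        s_nonpyro = int(rng.binomial(n_sp - s_pyro, _P_NONPYRO_SP))
        s_sapro = int(rng.binomial(n_sp, _P_SAPRO_SP))
        out.append(
            replace(
                site,
                counts=CatchCounts(
                    n_ind_total=n_ind, n_ind_pyro=k_pyro,
                    n_ind_nonpyro=k_nonpyro, n_ind_sapro=k_sapro,
                    n_sp_total=n_sp, n_sp_pyro=s_pyro,
                    n_sp_nonpyro=s_nonpyro, n_sp_sapro=s_sapro,
                ),
            )
        )
    return out


def simulate_dataset(config: SyntheticConfig) -> tuple[FireSet, list[TrapSite], dict]:
    """Full synthetic study: register, sites with catches, and ground truth."""
    fires = simulate_fires(config)
    sites = simulate_sites(config)
    sites = simulate_catches(sites, fires, config)
    truth = dict(asdict(config))
    truth["st_true"] = [float(v) for v in true_connectivity(sites, fires, config)]
    return fires, sites, truth


def write_dataset(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write fires.csv, catches.csv and truth.json in the pipeline dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fires, sites, truth = simulate_dataset(config)
    paths = {
        "fires": outdir / "fires.csv",
        "catches": outdir / "catches.csv",
        "truth": outdir / "truth.json",
    }
    write_fires(fires, paths["fires"])
    write_catches(sites, paths["catches"])
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
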
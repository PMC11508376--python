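import numpy as np
import pytest

from fireconn import (
    CatchCounts,
    FireRecord,
    FireSet,
    SyntheticConfig,
    TrapSite,
    simulate_dataset,
)


@pytest.fixture
def trap_origin():
    return TrapSite("T1", 0.0, 0.0, 2011)


@pytest.fixture
def small_fires():
    """Four fires around the origin, all within 20 km, years 2007-2010."""
    return FireSet(
        [
            FireRecord("f1", 2000.0, 0.0, 10_000.0, 2010),
            FireRecord("f2", 0.0, 5000.0, 500.0, 2009),
            FireRecord("f3", -8000.0, 3000.0, 2500.0, 2008),
            FireRecord("f4", 12_000.0, -9000.0, 120.0, 2007),
        ]
    )


@pytest.fixture
def counted_site():
    def make(site_id="S1", x=0.0, y=0.0, **counts):
        base = dict(
            n_ind_total=100, n_ind_pyro=5, n_ind_nonpyro=10, n_ind_sapro=3,
            n_sp_total=30, n_sp_pyro=2, n_sp_nonpyro=4, n_sp_sapro=6,
        )
        base.update(counts)
        return TrapSite(site_id, x, y, 2011, CatchCounts(**base))

    return make


@pytest.fixture(scope="session")
def small_synthetic():
    """One deterministic synthetic study at the default (study-like) scale."""
    cfg = SyntheticConfig(seed=42)
    fires, sites, truth = simulate_dataset(cfg)
    return cfg, fires, sites, truth


def naive_connectivity(trap, fires, alpha_s, alpha_t, max_distance_km=20.0, log_base="e"):
    """Independent double-loop oracle for the connectivity sum."""
    import math

    total = 0.0
    n_contrib = 0
    for fire in fires:
        d = math.hypot(trap.x_m - fire.x_m, trap.y_m - fire.y_m) / 1000.0
        if d > max_distance_km:
            continue
        n_contrib += 1
        t = trap.sampling_year - fire.year
        fa = math.log(fire.area_m2) if log_base == "e" else math.log10(fire.area_m2)
        total += math.exp(-d * alpha_s) * fa * math.exp(-t * alpha_t)
    return total, n_contrib


def closed_form_ols(y, x):
    """Independent textbook two-parameter OLS oracle (intercept + slope)."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n = y.size
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    slope = ((x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    rss = (resid**2).sum()
    s2 = rss / (n - 2)
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + xbar**2 / sxx))
    from scipy.stats import t as tdist

    p_slope = 2 * tdist.sf(abs(slope / se_slope), n - 2)
    p_intercept = 2 * tdist.sf(abs(intercept / se_intercept), n - 2)
    return dict(
        intercept=intercept, slope=slope, se_intercept=se_intercept,
        se_slope=se_slope, p_intercept=p_intercept, p_slope=p_slope, deviance=rss,
    )
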
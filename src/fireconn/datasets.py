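"""Published summary figures of the Östergötland 2011 smoke-trap survey.

These are pooled, public summary numbers (catch totals across the 21 sites
and the county fire-register totals for 1999–2010), shipped so descriptive
statistics can be reproduced without the site-level deposit. They are not a
substitute for site-level data: the regression pipeline needs per-site
tables.
"""

from .fire_records import CatchCounts

#: Pooled catch across the 21 smoke-attraction sites, Östergötland 2011:
#: total beetles and species, with counts per classification group.
OSTERGOTLAND_2011_POOLED_CATCH = CatchCounts(
    n_ind_total=2220,
    n_ind_pyro=60,
    n_ind_nonpyro=227,
    n_ind_sapro=67,
    n_sp_total=169,
    n_sp_pyro=13,
    n_sp_nonpyro=22,
    n_sp_sapro=34,
)

#: County fire-register summary for the 12-year window before sampling.
OSTERGOTLAND_REGISTER_SUMMARY = {
    "n_fires": 1419,
    "total_burned_km2": 20.54,
    "forested_km2": 14394.0,
    "study_area_km2": 21877.0,
    "year_range": (1999, 2010),
    "min_area_m2": 100.0,
}
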
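"""Ln-odds response variables from per-site catch counts.

The response modelled against fire connectivity is the natural log of the
odds that a randomly drawn caught beetle (or a randomly drawn caught
species) at a site belongs to a focal group: ln(k / (n - k)) for k focal
out of n total. Zero cells (k = 0 or k = n) are handled with a
Haldane-style continuity constant added to both cells, applied only when a
cell is zero (configurable). Sites with no catch at the requested level
carry no information and are excluded with a log message.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .fire_records import CatchCounts, GROUPS, TrapSite

logger = logging.getLogger(__name__)

LEVELS = ("individuals", "species")
DEFAULT_CORRECTION = 0.5


@dataclass(frozen=True)
class OddsResponse:
    site_id: str
    group: str
    level: str
    k: int
    n: int
    ln_odds: float
    correction_applied: bool


def ln_odds(k: int, n: int, correction: float = DEFAULT_CORRECTION) -> float:
    """ln(k / (n - k)), with the continuity constant on both cells at a zero cell."""
    if n < 1:
        raise ValidationError("ln_odds requires n >= 1 (no-information site)")
    if not 0 <= k <= n:
        raise ValidationError(f"k={k} outside [0, n={n}]")
    if correction < 0:
        raise ValidationError("correction must be >= 0")
    if k == 0 or k == n:
        if correction == 0:
            raise ValidationError(
                f"zero cell (k={k}, n={n}) with correction=0 gives infinite ln-odds"
            )
        return math.log((k + correction) / (n - k + correction))
    return math.log(k / (n - k))


def _is_zero_cell(k: int, n: int) -> bool:
    return k == 0 or k == n


def build_responses(
    sites: Sequence[TrapSite],
    group: str = "pyrophilic",
    level: str = "individuals",
    correction: float = DEFAULT_CORRECTION,
) -> list[OddsResponse]:
    """One ln-odds response per site with a positive total at ``level``.

    Group labels overlap (a pyrophilic species may also be saproxylic), so
    runs for different groups on the same sites are independent.
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}; valid groups: {', '.join(GROUPS)}")
    if level not in LEVELS:
        raise ValidationError(f"unknown level {level!r}; valid levels: {', '.join(LEVELS)}")

    out: list[OddsResponse] = []
    for site in sites:
        if site.counts is None:
            raise ValidationError(f"site {site.site_id!r} has no catch counts")
        k, n = site.counts.count(group, level)
        if n == 0:
            logger.info("site %s: zero total at level %s; excluded from modelling", site.site_id, level)
            continue
        out.append(
            OddsResponse(
                site_id=site.site_id,
                group=group,
                level=level,
                k=k,
                n=n,
                ln_odds=ln_odds(k, n, correction),
                correction_applied=_is_zero_cell(k, n),
            )
        )
    return out


def responses_frame(responses: Iterable[OddsResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "group": r.group,
                "level": r.level,
                "k": r.k,
                "n": r.n,
                "correction_applied": r.correction_applied,
                "ln_odds": r.ln_odds,
            }
            for r in responses
        ]
    )


def pooled_counts(sites: Iterable[TrapSite]) -> CatchCounts:
    """Sum catch counts across sites into one pooled table."""
    totals = {f: 0 for f in CatchCounts.__dataclass_fields__}
    for s in sites:
        if s.counts is None:
            raise ValidationError(f"site {s.site_id!r} has no catch counts")
        for f in totals:
            totals[f] += getattr(s.counts, f)
    return CatchCounts(**totals)


def group_percentages(counts: CatchCounts) -> pd.DataFrame:
    """Descriptive table: percentage of individuals and species per group."""
    rows = []
    for group in GROUPS:
        for level in LEVELS:
            k, n = counts.count(group, level)
            rows.append(
                {
                    "group": group,
                    "level": level,
                    "k": k,
                    "n": n,
                    "percent": 100.0 * k / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)
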
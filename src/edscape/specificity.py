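"""Region-specificity classification of editing sites.

Mirrors the Human Protein Atlas-style stratification applied to editing
levels: after an expression gate (host gene stably and well expressed) and
a coverage gate (pooled total >= 10 reads in at least two-thirds of
regions), each site is assigned exactly one of

* region-enriched  — one region at level >= 25% sitting >= 20 percentage
  points above every other region;
* group-enriched   — a set of 2..floor(n/3) regions all >= 25% and >= 20
  points above every region outside the set (smallest such set);
* region-enhanced  — one region >= 25% and >= 20 points above the mean of
  all regions;
* low-specificity  — none of the above.

Margins are absolute percentage-point differences; the categories are
evaluated in the order above so they stay mutually exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, floor

import numpy as np
import pandas as pd

from .stats import EditingMatrix, coefficient_of_variation

CATEGORIES = (
    "region-enriched",
    "group-enriched",
    "region-enhanced",
    "low-specificity",
    "not-evaluated",
)


@dataclass
class SpecificityCall:
    site_id: str
    category: str
    target_regions: tuple[str, ...] = ()
    margin: float = float("nan")


def gate_genes(
    expression: pd.DataFrame, cv_max: float = 1.0, min_expression: float = 10.0
) -> set[str]:
    """Eligible genes: CV < cv_max across regions and normalized expression
    >= min_expression in every region (genes x regions input)."""
    eligible = set()
    for gene, row in expression.iterrows():
        v = row.to_numpy(dtype=float)
        if (v >= min_expression).all() and coefficient_of_variation(v) < cv_max:
            eligible.add(gene)
    return eligible


def gate_sites(
    matrix: EditingMatrix,
    host_gene: dict | pd.Series,
    eligible_genes: set[str],
    min_total: int = 10,
    coverage_fraction: float = 2.0 / 3.0,
) -> list:
    """Evaluable sites: pooled total >= min_total in at least
    ceil(coverage_fraction * n_regions) regions, and a host gene passing the
    expression gate (intergenic sites are not evaluated)."""
    n_regions = matrix.total.shape[1]
    need = ceil(coverage_fraction * n_regions)
    covered = (matrix.total >= min_total).sum(axis=1) >= need
    out = []
    for site in matrix.total.index[covered]:
        gene = host_gene.get(site) if hasattr(host_gene, "get") else host_gene[site]
        if gene is not None and gene in eligible_genes:
            out.append(site)
    return out


def classify_specificity(
    levels: pd.Series,
    min_level: float = 0.25,
    margin: float = 0.20,
    group_max: int | None = None,
    max_undefined_fraction: float = 1.0 / 3.0,
    site_id: str = "",
) -> SpecificityCall:
    """Classify one site from its per-region levels (NaN = not quantified).

    ``group_max`` defaults to floor(n_regions / 3); a site with undefined
    levels in more than a third of regions is not evaluated.
    """
    values = levels.astype(float)
    n = len(values)
    if n == 0 or values.isna().sum() > max_undefined_fraction * n:
        return SpecificityCall(site_id, "not-evaluated")
    defined = values.dropna()
    if group_max is None:
        group_max = floor(n / 3)
    # sort descending by level, ties by region name for determinism
    order = sorted(defined.items(), key=lambda kv: (-kv[1], kv[0]))
    names = [k for k, _ in order]
    lv = np.array([v for _, v in order])

    # region-enriched: top region clears every other by the margin
    if lv[0] >= min_level and (len(lv) == 1 or lv[0] - lv[1] >= margin - 1e-12):
        return SpecificityCall(
            site_id,
            "region-enriched",
            (names[0],),
            float(lv[0] - lv[1]) if len(lv) > 1 else float("inf"),
        )
    # group-enriched: smallest qualifying prefix of size 2..group_max
    for size in range(2, min(group_max, len(lv) - 1) + 1):
        if lv[size - 1] >= min_level and lv[size - 1] - lv[size] >= margin - 1e-12:
            return SpecificityCall(
                site_id,
                "group-enriched",
                tuple(sorted(names[:size])),
                float(lv[size - 1] - lv[size]),
            )
    # region-enhanced: top region clears the mean of all regions
    mean = float(defined.mean())
    if lv[0] >= min_level and lv[0] - mean >= margin - 1e-12:
        return SpecificityCall(site_id, "region-enhanced", (names[0],), float(lv[0] - mean))
    return SpecificityCall(site_id, "low-specificity")


def classify_all(
    matrix: EditingMatrix,
    evaluable: list | None = None,
    min_level: float = 0.25,
    margin: float = 0.20,
    group_max: int | None = None,
) -> pd.DataFrame:
    """Classify every (evaluable) site of a region-level matrix."""
    levels = matrix.level
    rows = []
    sites = evaluable if evaluable is not None else list(levels.index)
    for site in sites:
        call = classify_specificity(
            levels.loc[site],
            min_level=min_level,
            margin=margin,
            group_max=group_max,
            site_id=str(site),
        )
        rows.append(
            {
                "site": site,
                "category": call.category,
                "regions": ",".join(call.target_regions),
                "margin": call.margin,
            }
        )
    return pd.DataFrame(rows, columns=["site", "category", "regions", "margin"])


def summary_counts(calls: pd.DataFrame) -> pd.Series:
    """Counts per category (disjoint, mirroring the reported breakdown)."""
    return calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
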
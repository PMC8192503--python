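"""Cross-species differential editing at conserved sites.

Per (conserved site, brain region), edited/unedited read counts are pooled
within each species, compared with a two-sided Fisher exact test, and a
site is called species-biased when the absolute editing-level difference is
at least 20 percentage points AND p < 0.01.  No multiple-testing correction
is applied by default (an optional Benjamini-Hochberg column is offered).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import EditingMatrix, pool_counts, wilcoxon_rank_sum


@dataclass
class ConservedSiteMap:
    """One-to-one mapping of site coordinates between two species.

    The TSV representation is 1-based: chrom_a, pos_a, strand_a, chrom_b,
    pos_b, strand_b.  Internally positions are 0-based.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for side in "ab":
            key = self.table[[f"chrom_{side}", f"pos_{side}"]].apply(tuple, axis=1)
            if key.duplicated().any():
                raise ValueError(f"conserved map not one-to-one on species {side}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConservedSiteMap":
        df = pd.read_csv(path, sep="\t")
        df["pos_a"] = df["pos_a"] - 1
        df["pos_b"] = df["pos_b"] - 1
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out["pos_a"] = out["pos_a"] + 1
        out["pos_b"] = out["pos_b"] + 1
        out.to_csv(path, sep="\t", index=False)


def pool_by_region(
    matrix: EditingMatrix, sample_region: dict[str, str]
) -> EditingMatrix:
    """Combine per-sample counts into per-region counts (one species)."""
    return pool_counts(matrix, sample_region)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric point probabilities no larger than
    the observed table's (point-probability rule).  A zero margin gives
    p = 1 (the table carries no information).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class FisherResult:
    site_id: str
    region: str
    table: tuple[int, int, int, int]  # edited_a, unedited_a, edited_b, unedited_b
    p: float
    delta_level: float  # level_a - level_b
    label: str  # A-biased | B-biased | unbiased | untestable


def call_differential(
    counts_a: EditingMatrix,
    counts_b: EditingMatrix,
    site_map: ConservedSiteMap | None = None,
    delta_min: float = 0.20,
    alpha: float = 0.01,
    min_total: int = 10,
    labels: tuple[str, str] = ("A", "B"),
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-(site, region) differential editing between two species.

    Inputs are region-pooled matrices with identical region columns; rows
    of species B are aligned to species A through ``site_map`` when given
    (otherwise indices must match).  A (site, region) is testable when both
    species reach ``min_total`` pooled reads.
    """
    regions = [r for r in counts_a.total.columns if r in counts_b.total.columns]
    if site_map is not None:
        key_a = list(
            zip(site_map.table["chrom_a"], site_map.table["pos_a"], site_map.table["strand_a"])
        )
        key_b = list(
            zip(site_map.table["chrom_b"], site_map.table["pos_b"], site_map.table["strand_b"])
        )
    else:
        key_a = [k for k in counts_a.total.index if k in set(counts_b.total.index)]
        key_b = key_a
    rows = []
    for ka, kb in zip(key_a, key_b):
        if ka not in counts_a.total.index or kb not in counts_b.total.index:
            continue
        for region in regions:
            ea = int(counts_a.edited.loc[[ka], region].iloc[0])
            ta = int(counts_a.total.loc[[ka], region].iloc[0])
            eb = int(counts_b.edited.loc[[kb], region].iloc[0])
            tb = int(counts_b.total.loc[[kb], region].iloc[0])
            table = (ea, ta - ea, eb, tb - eb)
            if ta < min_total or tb < min_total:
                rows.append(_row(ka, region, table, np.nan, np.nan, "untestable"))
                continue
            p = fisher_exact_two_sided(*table)
            delta = ea / ta - eb / tb
            if abs(delta) >= delta_min - 1e-12 and p < alpha:
                label = f"{labels[0]}-biased" if delta > 0 else f"{labels[1]}-biased"
            else:
                label = "unbiased"
            rows.append(_row(ka, region, table, p, delta, label))
    df = pd.DataFrame(
        rows,
        columns=[
            "site", "region", "edited_a", "unedited_a", "edited_b", "unedited_b",
            "p", "delta_level", "label",
        ],
    )
    if bh_correct and not df.empty:
        mask = df["p"].notna()
        df.loc[mask, "p_bh"] = _benjamini_hochberg(df.loc[mask, "p"].to_numpy())
    return df


def _row(site, region, table, p, delta, label):
    return {
        "site": site,
        "region": region,
        "edited_a": table[0],
        "unedited_a": table[1],
        "edited_b": table[2],
        "unedited_b": table[3],
        "p": p,
        "delta_level": delta,
        "label": label,
    }


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def conserved_vs_nonconserved_levels(
    conserved_levels, nonconserved_levels
) -> dict:
    """Rank-sum comparison of pooled per-site levels between conserved and
    non-conserved (recoding) sites."""
    cons = np.asarray(conserved_levels, float)
    non = np.asarray(nonconserved_levels, float)
    if len(cons) == 0 or len(non) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = wilcoxon_rank_sum(cons, non)
    return {
        "median_conserved": float(np.median(cons)),
        "median_nonconserved": float(np.median(non)),
        "statistic": stat,
        "p": p,
    }


def bias_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Counts of bias labels per region."""
    return results.pivot_table(
        index="region", columns="label", values="site", aggfunc="count", fill_value=0
    )
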
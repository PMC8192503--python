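"""Editing-level arithmetic and landscape statistics.

The central container is :class:`EditingMatrix`: two aligned site-by-column
count tables (edited Gs and edited+unedited totals) from which levels are
derived as G/(A+G).  Pooling sums counts, so a pooled level is always the
coverage-weighted mean of the member levels, and the "overall editing
level" of a column is a pool over all sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA


class UndefinedStatistic(ValueError):
    pass


@dataclass
class EditingMatrix:
    """Sites x columns count matrix in two layers (edited, total)."""

    edited: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.edited.index.equals(self.total.index) or not self.edited.columns.equals(
            self.total.columns
        ):
            raise ValueError("edited and total layers must be aligned")
        if (self.edited.values > self.total.values).any():
            raise ValueError("edited counts exceed totals")

    @property
    def level(self) -> pd.DataFrame:
        """G/(A+G) where total > 0, NaN elsewhere."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lv = self.edited / self.total
        return lv.where(self.total > 0)

    @classmethod
    def from_quant(cls, quant: pd.DataFrame) -> "EditingMatrix":
        """Build from a round-2 quantification table (one row per
        site x sample) using 'edited' and 'total' columns."""
        idx = ["chrom", "pos", "strand"]
        edited = quant.pivot_table(
            index=idx, columns="sample", values="edited", aggfunc="sum"
        )
        total = quant.pivot_table(
            index=idx, columns="sample", values="total", aggfunc="sum"
        )
        edited, total = edited.fillna(0).astype(int), total.fillna(0).astype(int)
        return cls(edited=edited, total=total)


def pool_counts(matrix: EditingMatrix, grouping: dict[str, str]) -> EditingMatrix:
    """Combine columns into groups by summing counts.

    ``grouping`` maps each column to its group label and must cover a
    partition: every group must contain at least one column.
    """
    missing = [c for c in matrix.edited.columns if c not in grouping]
    if missing:
        raise ValueError(f"columns without a group: {missing}")
    groups = pd.Series(grouping)
    if groups.empty:
        raise ValueError("empty grouping")
    edited = matrix.edited.T.groupby(groups).sum().T
    total = matrix.total.T.groupby(groups).sum().T
    return EditingMatrix(edited=edited, total=total)


def overall_editing(matrix: EditingMatrix, column: str) -> float:
    """Sum of Gs over sum of (A+G) across all sites of one column."""
    total = int(matrix.total[column].sum())
    if total == 0:
        raise UndefinedStatistic(f"column {column} has zero total coverage")
    return float(matrix.edited[column].sum() / total)


def normalized_site_count(n_sites: int, uniquely_mapped_reads: int) -> float:
    """Edited sites per million uniquely mapped reads."""
    if uniquely_mapped_reads <= 0:
        raise ValueError("uniquely_mapped_reads must be positive")
    return n_sites / uniquely_mapped_reads * 1e6


def size_factors(raw_counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios library size factors (genes x samples input).

    Each sample's factor is the median, over genes positive in all samples,
    of the ratio of its count to the gene's geometric mean; normalized
    counts are raw/factor.
    """
    positive = (raw_counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in all samples")
    log_counts = np.log(raw_counts.loc[positive].astype(float))
    log_gm = log_counts.mean(axis=1)
    factors = np.exp(log_counts.sub(log_gm, axis=0).median(axis=0))
    return factors, raw_counts / factors


def coefficient_of_variation(values: np.ndarray | pd.Series) -> float:
    """Population CV (sd/mean) across region means."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        raise UndefinedStatistic("zero mean expression")
    return float(v.std(ddof=0) / mean)


def cluster_fraction(
    positions: np.ndarray | list[int], window: int = 100, min_sites: int = 3
) -> float:
    """Fraction of sites lying in a cluster of >= ``min_sites`` class-mates
    within a ``window``-bp window (single chromosome; use per chrom/class).

    A site is clustered iff some run of ``min_sites`` consecutive sorted
    sites containing it spans at most ``window`` bp (all fit in one length-
    ``window`` window), found by a sorted sliding scan.
    """
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    n = len(pos)
    if n == 0:
        return 0.0
    if min_sites <= 1:
        return 1.0
    clustered = np.zeros(n, dtype=bool)
    m = min_sites
    for j in range(n - m + 1):
        if pos[j + m - 1] - pos[j] < window:
            clustered[j : j + m] = True
    return float(clustered.mean())


def cluster_fraction_by_class(
    sites: pd.DataFrame, window: int = 100, min_sites: int = 3
) -> pd.Series:
    """Per-class clustered fraction; expects columns chrom, pos, class."""
    out = {}
    for cls, sub in sites.groupby("class"):
        flags = []
        for _, chrom_sub in sub.groupby("chrom"):
            pos = np.sort(chrom_sub["pos"].to_numpy())
            m = len(pos)
            clustered = np.zeros(m, dtype=bool)
            for j in range(m - min_sites + 1):
                if pos[j + min_sites - 1] - pos[j] < window:
                    clustered[j : j + min_sites] = True
            flags.append(clustered)
        all_flags = np.concatenate(flags) if flags else np.zeros(0, dtype=bool)
        out[cls] = float(all_flags.mean()) if len(all_flags) else 0.0
    return pd.Series(out)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # columns x components
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_sites: int


def pca_on_levels(matrix: EditingMatrix, min_total: int = 10) -> PcaResult:
    """Centered (unscaled) PCA of editing levels across columns.

    Only sites covered by at least ``min_total`` reads in ALL columns enter,
    so the level matrix is complete-case; columns are the observations.
    """
    if matrix.total.shape[1] < 2:
        raise ValueError("PCA requires at least two columns")
    gate = (matrix.total >= min_total).all(axis=1)
    levels = matrix.level.loc[gate]
    if levels.empty:
        raise ValueError("no site passes the coverage gate")
    X = levels.T.to_numpy()  # observations = columns
    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(X)
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=levels.columns,
            columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
        ),
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_sites=int(gate.sum()),
    )


def pearson_r(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatistic("zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def variance_explained(x, y) -> tuple[float, float]:
    """R^2 (= r^2 for the simple linear fit) and the t-distribution p of r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatistic("zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic**2), float(res.pvalue)


def wilcoxon_rank_sum(group_a, group_b) -> tuple[float, float]:
    """Two-sided rank-sum test: exact enumeration for small untied samples
    (n_a + n_b <= 12), continuity-corrected normal approximation with tie
    correction otherwise.

    Returns (Mann-Whitney U of group_a, two-sided p).
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 12 and not has_ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def stratify_levels(levels: pd.Series, high: float = 0.75, low: float = 0.25) -> pd.Series:
    """Label sites highly (> high), lowly (< low) or intermediately edited."""
    return pd.Series(
        np.where(levels > high, "high", np.where(levels < low, "low", "mid")),
        index=levels.index,
    )
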
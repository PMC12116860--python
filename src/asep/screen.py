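"""Correlation screening of features against ASEP.

Nutrient intakes, clinical biomarkers and untargeted metabolite features
are screened for monotone association with ASEP using the Spearman rank
correlation.  Significance is a critical-|r| rule: assuming the Student
t-test for a correlation coefficient, the Bonferroni-corrected familywise
level alpha over m tests corresponds to::

    t* = t_{1 - alpha/(2m), n-2}
    critical_r = t* / sqrt(n - 2 + t***2)

so a feature is significant when |r| exceeds ``critical_r``.  With n = 51
this gives ~0.39 for m = 12 (intakes and clinical biomarkers) and ~0.53
for m = 872 (untargeted metabolomics).

The k features with the highest |r| (default 20) form the candidate
biomarker panel, and their interrelations are summarized by complete-
linkage hierarchical clustering with dissimilarity d = 1 - r_Pearson
between feature vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import EstimationError, ParameterError


@dataclass(frozen=True)
class CriticalThreshold:
    """Bonferroni-derived critical |r| for a Spearman/Pearson t-test."""

    n: int
    m: int
    alpha: float
    critical_r: float


def critical_r(n: int, m: int, alpha: float = 0.05) -> CriticalThreshold:
    """Critical |r| at familywise level ``alpha`` over ``m`` two-sided tests."""
    if n < 4:
        raise ParameterError(f"need n >= 4 for a correlation t-test, got {n}")
    if m < 1:
        raise ParameterError(f"number of tests m must be >= 1, got {m}")
    if not 0 < alpha < 1:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    df = n - 2
    t_star = stats.t.ppf(1.0 - alpha / (2.0 * m), df)
    r = t_star / np.sqrt(df + t_star**2)
    return CriticalThreshold(n=n, m=m, alpha=alpha, critical_r=float(r))


def spearman_screen(
    features: pd.DataFrame,
    exposure: pd.Series,
    m_for_bonferroni: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of every feature column against the exposure.

    Missing values are handled by pairwise-complete deletion per feature;
    ``n`` is reported per feature and each feature's significance uses its
    own n.  Constant features have undefined correlation: they are reported
    with NaN and excluded from ranking, with a warning.  Ranks (1..m by
    descending |r|) break ties by feature id, so ordering is deterministic.
    """
    exposure = exposure.reindex(features.index)
    rows = []
    for feature_id in features.columns:
        values = pd.to_numeric(features[feature_id], errors="coerce")
        mask = values.notna() & exposure.notna()
        n = int(mask.sum())
        if n < 4:
            warnings.warn(
                f"feature {feature_id!r}: fewer than 4 complete pairs; skipped",
                stacklevel=2,
            )
            rows.append({"feature_id": feature_id, "spearman_r": np.nan, "n": n})
            continue
        x = values[mask].to_numpy(dtype=float)
        y = exposure[mask].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            warnings.warn(
                f"feature {feature_id!r}: constant values, correlation undefined",
                stacklevel=2,
            )
            rows.append({"feature_id": feature_id, "spearman_r": np.nan, "n": n})
            continue
        r = stats.spearmanr(x, y).statistic
        rows.append({"feature_id": feature_id, "spearman_r": float(r), "n": n})
    table = pd.DataFrame(rows)

    crit = {
        n: critical_r(n, m_for_bonferroni, alpha).critical_r
        for n in table.loc[table["spearman_r"].notna(), "n"].unique()
    }
    table["critical_r"] = table["n"].map(crit)
    table["significant"] = table["spearman_r"].abs() > table["critical_r"]
    table.loc[table["spearman_r"].isna(), "significant"] = False

    ranked = table[table["spearman_r"].notna()].copy()
    ranked["abs_r"] = ranked["spearman_r"].abs()
    ranked = ranked.sort_values(
        ["abs_r", "feature_id"], ascending=[False, True], kind="stable"
    )
    table["rank_by_abs_r"] = pd.Series(
        np.arange(1, len(ranked) + 1), index=ranked.index
    )
    return table.drop(columns=[], errors="ignore")


def top_k(screen_table: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """First ``k`` ranked features by |r|; ties broken by feature id."""
    ranked = screen_table[screen_table["rank_by_abs_r"].notna()].sort_values(
        "rank_by_abs_r"
    )
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} ranked features available for top-{k}", stacklevel=2
        )
    return ranked.head(k).reset_index(drop=True)


@dataclass
class ClusterTree:
    """Complete-linkage tree over features with d = 1 - r_Pearson."""

    leaves: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, self.leaves)
        return str(tree)

    def write_newick(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_newick())


def cluster_features(abundance: pd.DataFrame) -> ClusterTree:
    """Complete-linkage clustering of feature columns on 1 - Pearson r.

    Dissimilarities live in [0, 2] (0 for perfectly correlated features,
    2 for perfectly anti-correlated ones).  Constant features have no
    defined correlation and raise an error naming the feature.
    """
    if abundance.shape[1] < 2:
        raise EstimationError("clustering needs at least 2 features")
    values = abundance.to_numpy(dtype=float)
    sds = values.std(axis=0)
    if (sds == 0).any():
        bad = abundance.columns[np.flatnonzero(sds == 0)[0]]
        raise EstimationError(f"feature {bad!r} is constant; 1 - r undefined")
    corr = np.corrcoef(values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)  # symmetrize away fp noise
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return ClusterTree(leaves=[str(c) for c in abundance.columns], linkage=linkage)


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class ScreenResults:
    """Ranked correlation screen with threshold, top-k panel and cluster tree."""

    table: pd.DataFrame
    threshold: CriticalThreshold
    features: pd.DataFrame
    k: int = 20

    def top(self, k: int | None = None) -> pd.DataFrame:
        return top_k(self.table, k if k is not None else self.k)

    def cluster_top(self, k: int | None = None) -> ClusterTree:
        panel = self.top(k)["feature_id"].tolist()
        return cluster_features(self.features[panel])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def summary(self) -> str:
        top = self.top()
        lines = [
            "ASEP correlation screen",
            "=======================",
            f"features tested: {len(self.table)}  "
            f"(Bonferroni m = {self.threshold.m}, alpha = {self.threshold.alpha})",
            f"critical |r| at n = {self.threshold.n}: {self.threshold.critical_r:.3f}",
            f"significant features: {self.n_significant}",
            "",
            f"top {len(top)} by |spearman r|:",
            top[["feature_id", "spearman_r", "n", "significant"]].to_string(index=False),
        ]
        return "\n".join(lines)


class CorrelationScreen:
    """Spearman screen of a feature matrix against an ASEP vector.

    Parameters
    ----------
    features :
        participants x features frame (index aligned with ``exposure``).
    exposure :
        per-participant ASEP (period values).
    m_for_bonferroni :
        number of tests for the familywise correction.  Must be given
        explicitly — in a block design it is the block size (e.g. 12 for
        targeted intakes/biomarkers, 872 for untargeted metabolomics), not
        necessarily the number of columns supplied.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        exposure: pd.Series,
        m_for_bonferroni: int,
        alpha: float = 0.05,
        k: int = 20,
    ) -> None:
        self.features = features
        self.exposure = exposure
        self.m = int(m_for_bonferroni)
        self.alpha = alpha
        self.k = k

    def fit(self) -> ScreenResults:
        table = spearman_screen(
            self.features, self.exposure, self.m, alpha=self.alpha
        )
        n_typical = int(table["n"].max()) if len(table) else 0
        threshold = critical_r(max(n_typical, 4), self.m, self.alpha)
        return ScreenResults(
            table=table, threshold=threshold, features=self.features, k=self.k
        )
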
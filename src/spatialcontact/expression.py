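"""Differential expression over the five irradiation conditions and
k-means clustering of the responsive genes into four kinetic classes.

The DE test is a moderated two-sample t on log CPM: gene-wise variances
are shrunk toward a mean-variance trend before testing, and decisions
require both FDR below ``alpha`` (Benjamini-Hochberg) and |log2 fold
change| above ``lfc_min``.  Cluster labels are canonicalized to fixed
kinetic shapes so cluster identity is stable across seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import pairwise_distances
from scipy.optimize import linear_sum_assignment
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

CONDITIONS = ("0h", "1Gy-6h", "1Gy-24h", "6Gy-6h", "6Gy-24h")
BASELINE_CONDITION = "0h"

DEFAULT_ALPHA = 0.05
DEFAULT_LFC_MIN = 0.5
DEFAULT_PSEUDOCOUNT = 0.5
PRIOR_DF = 8.0

# canonical z-scored kinetic shapes used to name clusters 1..4
CANONICAL_PROFILES: dict[int, tuple[float, ...]] = {
    1: (0.0, 0.0, 0.0, -2.0, -2.0),
    2: (0.0, 0.0, -2.0, 0.0, -2.0),
    3: (0.0, 0.0, 0.0, 0.0, 2.0),
    4: (0.0, 0.0, 2.0, 0.0, 2.0),
}


class ExpressionError(ValueError):
    pass


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column scaled by its library size."""
    if (counts.to_numpy() < 0).any():
        raise ExpressionError("counts must be non-negative")
    libs = counts.sum(axis=0)
    if (libs == 0).any():
        zero = list(libs.index[libs == 0])
        raise ExpressionError(f"zero library size in samples {zero}")
    return counts / libs * 1e6


def _condition_samples(samples: pd.DataFrame, condition: str) -> list[str]:
    m = samples["condition"] == condition
    return list(samples.loc[m, "sample"])


@dataclass
class DEResult:
    table: pd.DataFrame  # gene_id, logFC, p, FDR, DE
    contrast: tuple[str, str]


def differential_expression(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: tuple[str, str],
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    use_fdr: bool = True,
    prior_df: float = PRIOR_DF,
) -> pd.DataFrame:
    """Moderated test of ``contrast[1]`` against ``contrast[0]``.

    logFC is the log2 ratio of mean CPM (plus pseudocount); the p-value
    comes from a two-sample t on log2 CPM with the gene-wise variance
    shrunk toward a lowess mean-variance trend with ``prior_df``
    degrees of freedom.  DE requires FDR < alpha (or raw p < alpha when
    ``use_fdr`` is off) and |logFC| > lfc_min.
    """
    ref, alt = contrast
    ref_samples = _condition_samples(samples, ref)
    alt_samples = _condition_samples(samples, alt)
    if len(ref_samples) < 2 or len(alt_samples) < 2:
        raise ExpressionError(
            f"contrast {contrast} needs >= 2 replicates per condition; "
            "use descriptive CPM summaries for unreplicated designs"
        )
    cpm = compute_cpm(counts)
    log_cpm = np.log2(cpm + pseudocount)
    a = log_cpm[ref_samples].to_numpy()
    b = log_cpm[alt_samples].to_numpy()
    n_a, n_b = a.shape[1], b.shape[1]

    mean_cpm_a = cpm[ref_samples].mean(axis=1).to_numpy()
    mean_cpm_b = cpm[alt_samples].mean(axis=1).to_numpy()
    logfc = np.log2(mean_cpm_b + pseudocount) - np.log2(mean_cpm_a + pseudocount)

    diff = b.mean(axis=1) - a.mean(axis=1)
    df_resid = n_a + n_b - 2
    pooled_var = (
        a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    ) / df_resid

    # shrink toward the mean-variance trend (moderation)
    abundance = log_cpm.mean(axis=1).to_numpy()
    trend = lowess(
        pooled_var, abundance, frac=0.4, it=1, return_sorted=False
    )
    trend = np.maximum(trend, 1e-8)
    var_post = (prior_df * trend + df_resid * pooled_var) / (
        prior_df + df_resid
    )

    se = np.sqrt(var_post * (1 / n_a + 1 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=prior_df + df_resid)
    p = np.where(diff == 0, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    crit = fdr if use_fdr else p
    de = (crit < alpha) & (np.abs(logfc) > lfc_min)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "contrast": f"{alt}_vs_{ref}",
            "logFC": logfc,
            "p": p,
            "FDR": fdr,
            "DE": de,
        }
    ).set_index("gene_id")


def de_all_contrasts(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    baseline: str = BASELINE_CONDITION,
    use_fdr: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """DE of every non-baseline condition against the baseline.

    Returns the tidy per-contrast table and a per-gene boolean Series
    flagging genes DE in at least one contrast.
    """
    conditions = [
        c for c in samples["condition"].unique() if c != baseline
    ]
    tables = [
        differential_expression(
            counts, samples, (baseline, cond), alpha=alpha,
            lfc_min=lfc_min, use_fdr=use_fdr,
        )
        for cond in conditions
    ]
    tidy = pd.concat(tables).reset_index()
    de_any = tidy.groupby("gene_id")["DE"].any().reindex(counts.index)
    return tidy, de_any


# ---------------------------------------------------------------------
# kinetic clustering
# ---------------------------------------------------------------------


def condition_profiles(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """Per-gene mean log2 CPM per condition (columns in fixed order)."""
    log_cpm = np.log2(compute_cpm(counts) + pseudocount)
    data = {}
    for cond in conditions:
        cols = _condition_samples(samples, cond)
        if not cols:
            raise ExpressionError(f"no samples for condition {cond!r}")
        data[cond] = log_cpm[cols].mean(axis=1)
    return pd.DataFrame(data)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def cluster_kinetics(
    profiles: pd.DataFrame,
    k: int = 4,
    seed: int | None = None,
    n_init: int = 50,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means on z-scored condition profiles, canonically labelled.

    ``profiles`` should be restricted to DE genes.  Clusters are
    renamed 1..k by matching centroids to the canonical kinetic shapes
    (1 = dose-dependent down, 2 = late down, 3 = late 6Gy up,
    4 = late up) via an optimal assignment, so labels are stable across
    seeds.  Returns (labels, centroid frame in profile units of z).
    """
    if len(profiles) < k:
        raise ExpressionError(
            f"{len(profiles)} genes is fewer than k={k} clusters"
        )
    z = _zscore_rows(profiles.to_numpy(dtype=float))
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_labels = km.fit_predict(z)

    canonical = _zscore_rows(
        np.asarray(
            [CANONICAL_PROFILES[i + 1] for i in range(min(k, 4))], dtype=float
        )
    )
    centroids = km.cluster_centers_
    if k <= 4 and canonical.shape[1] == centroids.shape[1]:
        cost = pairwise_distances(centroids, canonical)
        rows, cols = linear_sum_assignment(cost)
        mapping = {r: c + 1 for r, c in zip(rows, cols)}
        next_label = len(cols) + 1
        for r in range(k):
            if r not in mapping:
                mapping[r] = next_label
                next_label += 1
    else:
        mapping = {r: r + 1 for r in range(k)}
    labels = pd.Series(
        [mapping[r] for r in raw_labels], index=profiles.index, name="cluster"
    )
    centroid_frame = pd.DataFrame(
        centroids,
        columns=profiles.columns,
        index=[mapping[r] for r in range(k)],
    ).sort_index()
    return labels, centroid_frame


def cluster_de_genes(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    k: int = 4,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    lfc_min: float = DEFAULT_LFC_MIN,
    n_init: int = 50,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """DE + clustering in one step.

    Returns the tidy DE table, per-gene labels over all genes
    ("stable" where not DE), and the cluster centroid frame.
    """
    tidy, de_any = de_all_contrasts(
        counts, samples, alpha=alpha, lfc_min=lfc_min
    )
    de_genes = de_any[de_any].index
    profiles = condition_profiles(counts, samples).loc[de_genes]
    labels, centroids = cluster_kinetics(profiles, k=k, seed=seed, n_init=n_init)
    all_labels = pd.Series("stable", index=counts.index, name="cluster", dtype=object)
    all_labels.loc[labels.index] = labels.to_numpy()
    return tidy, all_labels, centroids
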
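"""Cohort stratification of paired +/- IFN-gamma expression panels.

Re-analysis stage for a panel of patient-derived lines profiled with and
without IFN-gamma: exclusion of engineered / off-treatment lines, a
per-line IFN-gamma response score (mean log2(TPM+1) over a response gene
set), marker-based ranking and stratification (halves and quartiles by
MITF expression; PD-L1 high/low splits), nonparametric association and
group-comparison statistics, correlation matrices with clustering order,
and PCA over the top expressed genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .normalize import AbundanceMatrix, select_top_expressed


@dataclass
class CohortTable:
    """Paired untreated / treated abundance matrices over shared lines."""

    untreated: AbundanceMatrix
    treated: AbundanceMatrix
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.untreated.samples) != list(self.treated.samples):
            raise ValueError("untreated and treated matrices must share line ids in order")
        if self.untreated.unit != self.treated.unit:
            raise ValueError("paired matrices must be in the same unit")
        missing = self.untreated.samples.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing line(s): {', '.join(map(str, missing))}")

    @property
    def lines(self) -> pd.Index:
        return self.untreated.samples


@dataclass
class AssocResult:
    """A named association or group-comparison statistic."""

    statistic: str
    value: float
    p: float
    n: int
    extras: dict = field(default_factory=dict)


def filter_wildtype(cohort: CohortTable, allowed_treatments=("IFNg", "none")) -> CohortTable:
    """Drop genetically engineered lines and lines on other treatments.

    Metadata must carry an ``engineered`` boolean flag and a ``treatment``
    label; only non-engineered lines whose treatment is IFN-gamma or
    untreated are retained.
    """
    meta = cohort.metadata
    for col in ("engineered", "treatment"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    keep_meta = meta.loc[
        (~meta["engineered"].astype(bool)) & meta["treatment"].isin(allowed_treatments)
    ]
    keep = [ln for ln in cohort.lines if ln in keep_meta.index]
    if not keep:
        warnings.warn("wild-type filter removed every line", stacklevel=2)
    sub = lambda m: AbundanceMatrix(m.values[keep], m.unit)  # noqa: E731
    return CohortTable(sub(cohort.untreated), sub(cohort.treated), meta.loc[keep])


def apply_metadata_filter(metadata: pd.DataFrame, allowed_treatments=("IFNg", "none")) -> pd.Index:
    """Line ids surviving the wild-type / IFN-gamma-only exclusion."""
    for col in ("engineered", "treatment"):
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    keep = (~metadata["engineered"].astype(bool)) & metadata["treatment"].isin(allowed_treatments)
    return metadata.index[keep]


def ifng_response_score(expr: AbundanceMatrix, gene_set) -> pd.Series:
    """Per-line mean log2(TPM+1) expression over a response gene set.

    Set members absent from the matrix are ignored with a warning naming
    them; an empty intersection is an error.
    """
    expr.require_unit("log2TPM1")
    members = list(dict.fromkeys(gene_set))
    present = [g for g in members if g in expr.genes]
    missing = [g for g in members if g not in expr.genes]
    if not present:
        raise ValueError("no gene-set member is present in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} set member(s) absent from the matrix: {', '.join(missing[:10])}",
            stacklevel=2,
        )
    return expr.values.loc[present].mean(axis=0).rename("ifng_response_score")


# ---------------------------------------------------------------------------
# Ranking and stratification
# ---------------------------------------------------------------------------


def _ranked_ids(values: pd.Series) -> list:
    """Line ids sorted by value descending; ties by id (logged)."""
    if values.duplicated(keep=False).any() and values.nunique() < len(values):
        dup = values[values.duplicated(keep=False)]
        warnings.warn(
            f"ties in ranking values resolved by line id: {sorted(map(str, dup.index))[:6]}",
            stacklevel=3,
        )
    return sorted(values.index, key=lambda i: (-values[i], str(i)))


def rank_and_split(values: pd.Series, mode: str = "halves") -> pd.Series:
    """Rank lines by a marker value and split into halves or quartiles.

    ``halves``: upper/lower 50%, with the median element assigned to the
    lower group when n is odd (n=45 gives upper 22 / lower 23).
    ``quartiles``: the top and bottom ceil(n/4) lines labelled ``high`` and
    ``low`` (n=45 gives 12 each), the remainder ``mid``.
    """
    n = len(values)
    order = _ranked_ids(values)
    labels = pd.Series(index=values.index, dtype=object)
    if mode == "halves":
        upper = n // 2
        labels.loc[order[:upper]] = "upper"
        labels.loc[order[upper:]] = "lower"
    elif mode == "quartiles":
        if n < 4:
            raise ValueError("quartile split needs >= 4 lines")
        k = math.ceil(n / 4)
        labels.loc[order[:k]] = "high"
        labels.loc[order[k : n - k]] = "mid"
        labels.loc[order[n - k :]] = "low"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return labels


def split_high_low(
    values: pd.Series, method: str = "largest_gap", threshold: float | None = None
) -> pd.Series:
    """Binary high/low split of per-line values.

    ``threshold``: values > threshold are high.  ``largest_gap``: cut at
    the maximal adjacent gap in the sorted values (errors when all values
    are equal).  ``median``: the upper half of :func:`rank_and_split`.
    """
    if method == "threshold":
        if threshold is None:
            raise ValueError("threshold method requires a threshold value")
        return pd.Series(np.where(values > threshold, "high", "low"), index=values.index)
    if method == "median":
        halves = rank_and_split(values, "halves")
        return halves.map({"upper": "high", "lower": "low"})
    if method == "largest_gap":
        if values.nunique() < 2:
            raise ValueError("largest_gap split requires >= 2 distinct values")
        sorted_vals = values.sort_values()
        gaps = sorted_vals.diff().iloc[1:]
        cut_pos = int(np.argmax(gaps.to_numpy()))  # first maximal gap
        cutoff = (sorted_vals.iloc[cut_pos] + sorted_vals.iloc[cut_pos + 1]) / 2
        return pd.Series(np.where(values > cutoff, "high", "low"), index=values.index)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Association statistics
# ---------------------------------------------------------------------------


def associate(x: pd.Series, y: pd.Series, method: str = "spearman") -> AssocResult:
    """Two-sided Spearman correlation or simple linear regression.

    Inputs are aligned on their index; n >= 3 required.  A constant input
    with Spearman yields an undefined (NaN) result with a warning.
    """
    x, y = x.align(y, join="inner")
    n = len(x)
    if n < 3:
        raise ValueError("association requires n >= 3 paired values")
    if method == "spearman":
        if x.nunique() < 2 or y.nunique() < 2:
            warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
            return AssocResult("spearman_r", np.nan, np.nan, n, {"flag": "constant_input"})
        r, p = stats.spearmanr(x, y, alternative="two-sided")
        return AssocResult("spearman_r", float(r), float(p), n)
    if method == "linreg":
        fit = stats.linregress(x, y)
        return AssocResult(
            "linreg_slope",
            float(fit.slope),
            float(fit.pvalue),
            n,
            {"intercept": float(fit.intercept), "r": float(fit.rvalue)},
        )
    raise ValueError(f"unknown method {method!r}")


def _dunn_posthoc(values: pd.Series, labels: pd.Series) -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with tie correction, BH-adjusted."""
    n = len(values)
    ranks = stats.rankdata(values)
    groups = sorted(labels.unique())
    mean_rank = {g: ranks[(labels == g).to_numpy()].mean() for g in groups}
    sizes = {g: int((labels == g).sum()) for g in groups}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            se = math.sqrt(base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else np.nan
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"group_1": gi, "group_2": gj, "z": z, "p": p})
    df = pd.DataFrame(rows)
    mask = df["p"].notna()
    df["padj"] = np.nan
    if mask.any():
        df.loc[mask, "padj"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def compare_groups(
    values: pd.Series,
    labels: pd.Series,
    design: str = "two_group",
    pair_ids: pd.Series | None = None,
) -> AssocResult:
    """Nonparametric group comparisons.

    ``two_group``: two-sided Mann-Whitney U.  ``multi_group``:
    Kruskal-Wallis with Dunn's post-hoc (BH-adjusted pairwise p in
    ``extras['posthoc']``).  ``paired``: two-sided Wilcoxon signed-rank;
    ``pair_ids`` must give exactly one observation per group per pair.
    """
    values, labels = values.align(labels, join="inner")
    groups = sorted(labels.unique())
    if design == "two_group":
        if len(groups) != 2:
            raise ValueError(f"two_group design needs exactly 2 groups, got {len(groups)}")
        a = values[labels == groups[0]]
        b = values[labels == groups[1]]
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return AssocResult("mannwhitney_U", float(u), float(p), len(values))
    if design == "multi_group":
        if len(groups) < 3:
            raise ValueError("multi_group design needs >= 3 groups")
        samples = [values[labels == g] for g in groups]
        h, p = stats.kruskal(*samples)
        posthoc = _dunn_posthoc(values, labels)
        return AssocResult("kruskal_H", float(h), float(p), len(values), {"posthoc": posthoc})
    if design == "paired":
        if len(groups) != 2:
            raise ValueError("paired design needs exactly 2 groups")
        if pair_ids is None:
            raise ValueError("paired design requires pair_ids")
        pair_ids = pair_ids.loc[values.index]
        wide = pd.DataFrame({"value": values, "group": labels, "pair": pair_ids}).pivot(
            index="pair", columns="group", values="value"
        )
        if wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)].tolist()
            raise ValueError(f"unbalanced pairing for pair(s): {bad}")
        diffs = wide[groups[0]] - wide[groups[1]]
        if (diffs == 0).all():
            warnings.warn("all paired differences are zero; test undefined, p set to 1", stacklevel=2)
            return AssocResult("wilcoxon_W", np.nan, 1.0, len(wide), {"flag": "all_zero_diffs"})
        w, p = stats.wilcoxon(wide[groups[0]], wide[groups[1]], alternative="two-sided")
        return AssocResult("wilcoxon_W", float(w), float(p), len(wide))
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# Correlation matrix and PCA
# ---------------------------------------------------------------------------


def correlation_matrix(
    expr: AbundanceMatrix, correction: str = "bonferroni"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample-by-sample Pearson correlation with adjusted p and cluster order.

    Off-diagonal p-values are adjusted for m = k(k-1)/2 tests (Bonferroni
    or BH); columns are reordered by average-linkage clustering on 1 - r.
    Constant columns give undefined correlations (NaN, warned).
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    values = expr.values
    k = values.shape[1]
    if k < 3:
        raise ValueError("correlation matrix requires >= 3 columns")
    constant = values.columns[values.std(axis=0, ddof=0) == 0].tolist()
    if constant:
        warnings.warn(f"constant column(s), correlations undefined: {constant}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    n = values.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)

    iu = np.triu_indices(k, 1)
    raw = p[iu]
    mask = ~np.isnan(raw)
    adj = np.full(raw.shape, np.nan)
    if mask.any():
        method = "bonferroni" if correction == "bonferroni" else "fdr_bh"
        adj[mask] = multipletests(raw[mask], method=method)[1]
    p_adj = np.full((k, k), np.nan)
    p_adj[iu] = adj
    p_adj.T[iu] = adj
    np.fill_diagonal(p_adj, 0.0)

    # ordering by average linkage on 1 - r (NaN distances set to max)
    d = 1.0 - r
    d[np.isnan(d)] = 2.0
    np.fill_diagonal(d, 0.0)
    condensed = d[iu]
    order = hierarchy.leaves_list(hierarchy.linkage(condensed, method="average"))
    cols = values.columns[order]
    r_df = pd.DataFrame(r, index=values.columns, columns=values.columns).loc[cols, cols]
    p_df = pd.DataFrame(p_adj, index=values.columns, columns=values.columns).loc[cols, cols]
    return r_df, p_df


def pca_embed(
    expr: AbundanceMatrix, k_top: int = 2000
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Centered PCA of samples over the top expressed genes.

    Selects the ``k_top`` genes with the highest mean value, centers each
    gene, and decomposes by SVD.  Returns (sample scores, gene loadings,
    explained variance ratios).  Components are sign-fixed so the first
    nonzero loading of each is positive; explained variances are
    non-increasing and loadings orthonormal.
    """
    if expr.values.shape[0] < 2 or expr.values.shape[1] < 2:
        raise ValueError("PCA requires >= 2 genes and >= 2 samples")
    n_genes = expr.values.shape[0]
    if k_top > n_genes:
        raise ValueError(f"k_top={k_top} exceeds the {n_genes} genes available")
    top = select_top_expressed(expr, k_top)
    x = top.values.to_numpy(dtype=float).T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: first nonzero entry of each loading vector positive
    for i in range(vt.shape[0]):
        nz = np.nonzero(np.abs(vt[i]) > 1e-12)[0]
        if len(nz) and vt[i, nz[0]] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    scores = u * sv
    var = sv**2
    explained = var / var.sum() if var.sum() > 0 else var
    pcs = [f"PC{i+1}" for i in range(len(sv))]
    scores_df = pd.DataFrame(scores, index=top.values.columns, columns=pcs)
    loadings_df = pd.DataFrame(vt.T, index=top.values.index, columns=pcs)
    return scores_df, loadings_df, explained
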
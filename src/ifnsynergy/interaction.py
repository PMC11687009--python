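"""Per-gene two-factor negative-binomial GLM with interaction LRT.

The engine behind the non-additive response analysis.  For every gene it
fits the full model

    log2 mu_gj = beta0 + betaA * x_A + betaB * x_B + betaAB * x_A x_B
                 (+ log2 of the sample size factor s_j as an offset)

and the reduced model without the interaction coefficient, under a
negative-binomial likelihood with gene-wise dispersion alpha_g
(``var = mu + alpha mu^2``), and tests the interaction by a
likelihood-ratio test against chi-square with one degree of freedom.

Because the 2x2 full model is saturated in the four condition means, its
MLE reduces to four independent one-dimensional mean fits (Newton in log
space, exact closed form in the Poisson limit); the reduced model is fit by
IRLS.  This is a deliberately transparent engine — median-of-ratios size
factors, per-gene ML dispersion without trend shrinkage, no outlier
replacement or independent filtering — so every downstream rule can be
checked against closed forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

LN2 = np.log(2.0)
#: dispersion below this is treated as exactly Poisson
POISSON_ALPHA = 1e-12
#: lower floor for estimated dispersions
ALPHA_FLOOR = 1e-8

CONDITIONS = ((0, 0), (1, 0), (0, 1), (1, 1))

FIT_COLUMNS = [
    "beta0", "betaA", "betaB", "betaAB", "alpha", "lrt_stat",
    "p_interaction", "padj_interaction",
    "lfc_A", "padj_A", "lfc_B", "padj_B", "lfc_AB", "padj_AB", "converged",
]


@dataclass
class FactorialDesign:
    """Sample annotation of a 2x2 knockdown-by-cytokine design.

    ``table`` is indexed by sample id with integer indicator columns
    ``knockdown`` (x_A: 0 control, 1 knockdown) and ``cytokine``
    (x_B: 0 untreated, 1 treated) plus a ``replicate`` id.  All four
    factor combinations must be present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"knockdown", "cytokine", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        for col in ("knockdown", "cytokine"):
            if not set(self.table[col].unique()) <= {0, 1}:
                raise ValueError(f"design column {col!r} must be 0/1 indicators")
        present = set(zip(self.table["knockdown"], self.table["cytokine"]))
        if present != set(CONDITIONS):
            raise ValueError(f"all four conditions required, found {sorted(present)}")

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    def condition_index(self) -> np.ndarray:
        """Map each sample to a condition code 0..3 in CONDITIONS order."""
        lookup = {c: i for i, c in enumerate(CONDITIONS)}
        return np.array(
            [lookup[(a, b)] for a, b in zip(self.table["knockdown"], self.table["cytokine"])]
        )


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_design_tsv(path) -> FactorialDesign:
    return FactorialDesign(pd.read_csv(path, sep="\t", index_col=0))


# ---------------------------------------------------------------------------
# Size factors (median of ratios)
# ---------------------------------------------------------------------------


def estimate_size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample, s_j is the median over reference genes of
    K_gj / geometric-mean_g(K).  Genes with a zero count in any sample are
    excluded from the reference set.  If no gene is everywhere nonzero,
    pass ``pseudo_reference=True`` to fall back to library-size ratios.
    """
    k = counts.to_numpy(dtype=float)
    nonzero = (k > 0).all(axis=1)
    if not nonzero.any():
        if not pseudo_reference:
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "rerun with pseudo_reference=True to use library-size ratios"
            )
        lib = k.sum(axis=0)
        s = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(s, index=counts.columns, name="size_factor")
    ref = k[nonzero]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    s = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    return pd.Series(s, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorised across genes)
# ---------------------------------------------------------------------------


def _nb_loglik(k: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Elementwise NB log-likelihood; Poisson branch for tiny alpha.

    Shapes broadcast; ``alpha`` broadcasts against the trailing axes of k/mu.
    """
    mu = np.maximum(mu, 1e-300)
    alpha = np.broadcast_to(alpha, np.broadcast_shapes(k.shape, mu.shape, alpha.shape))
    k_b = np.broadcast_to(k, alpha.shape)
    mu_b = np.broadcast_to(mu, alpha.shape)
    out = np.empty(alpha.shape)
    pois = alpha <= POISSON_ALPHA
    if pois.any():
        kk, mm = k_b[pois], mu_b[pois]
        out[pois] = kk * np.log(mm) - mm - gammaln(kk + 1.0)
    nb = ~pois
    if nb.any():
        kk, mm, aa = k_b[nb], mu_b[nb], alpha[nb]
        inv = 1.0 / aa
        out[nb] = (
            gammaln(kk + inv) - gammaln(inv) - gammaln(kk + 1.0)
            + kk * np.log(aa * mm / (1.0 + aa * mm))
            - inv * np.log1p(aa * mm)
        )
    return out


def _solve_condition_means(
    k: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> np.ndarray:
    """MLE of per-condition means under NB with fixed dispersion.

    ``k`` has shape (..., R) of counts for one condition, ``s`` shape (R,)
    size factors, ``alpha`` broadcastable to ``k.shape[:-1]``.  Solves
    d/d log m [loglik] = 0 by Newton; exact weighted mean in the Poisson
    limit.  Returns means of shape ``k.shape[:-1]``.
    """
    k_sum = k.sum(axis=-1)
    s_sum = s.sum()
    m0 = np.maximum(k_sum / s_sum, 1e-12)  # Poisson MLE; Newton start
    alpha = np.asarray(alpha, dtype=float)
    shape = np.broadcast_shapes(m0.shape, alpha.shape)
    alpha = np.broadcast_to(alpha, shape)
    m0 = np.broadcast_to(m0, shape)
    if np.all(alpha <= POISSON_ALPHA):
        return np.array(m0, copy=True)
    t = np.log(m0)
    zero = np.broadcast_to(k_sum == 0, shape)
    for _ in range(n_iter):
        m = np.exp(t)
        u = alpha[..., None] * s * m[..., None]
        u = u / (1.0 + u)
        w = k + 1.0 / np.maximum(alpha[..., None], POISSON_ALPHA)
        g = k_sum - (w * u).sum(axis=-1)
        h = -(w * u * (1.0 - u)).sum(axis=-1)
        # Poisson-limit genes keep the closed-form start
        pois = alpha <= POISSON_ALPHA
        step = np.where(pois | zero, 0.0, g / np.where(h == 0, 1.0, h))
        step = np.clip(step, -5.0, 5.0)
        t = t - step
        if np.max(np.abs(step)) < 1e-12:
            break
    m = np.exp(t)
    return np.where(zero, 1e-12, m)


def _full_model_loglik(
    k_cond: np.ndarray, s_cond: list[np.ndarray], alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Profile log-likelihood of the saturated 2x2 model.

    ``k_cond`` is a list-like of per-condition count arrays (..., R_c);
    returns (loglik summed over conditions, means stacked on last axis).
    """
    total = 0.0
    means = []
    for c in range(4):
        m = _solve_condition_means(k_cond[c], s_cond[c], alpha)
        mu = s_cond[c] * m[..., None]
        total = total + _nb_loglik(k_cond[c], mu, alpha[..., None]).sum(axis=-1)
        means.append(m)
    return total, np.stack(means, axis=-1)


def _split_by_condition(
    counts: pd.DataFrame, design: FactorialDesign, s: pd.Series
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    if list(counts.columns) != list(design.samples):
        if set(counts.columns) != set(design.samples):
            raise ValueError("counts and design describe different samples")
        counts = counts[design.samples]
    k = counts.to_numpy(dtype=float)
    sv = s.loc[design.samples].to_numpy(dtype=float)
    cond = design.condition_index()
    k_cond = [k[:, cond == c] for c in range(4)]
    s_cond = [sv[cond == c] for c in range(4)]
    return k_cond, s_cond


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------


def estimate_dispersion(
    counts: pd.DataFrame,
    design: FactorialDesign,
    s: pd.Series,
    shrink: bool = True,
) -> pd.Series:
    """Per-gene NB dispersion: method-of-moments start, ML refinement.

    The ML step maximises the full-model Cox-Reid adjusted profile
    likelihood (condition means re-fit at each candidate alpha, minus half
    the log determinant of the expected information for the mean
    parameters) over a log-spaced grid around the moment estimate, then a
    finer local grid.  The Cox-Reid term corrects the downward bias of
    plain profile ML when replication is small relative to the number of
    fitted means; without it the interaction LRT is anticonservative at
    three replicates per condition.

    With ``shrink=True`` (default) the gene-wise estimates are moderated by
    an empirical-Bayes log-normal prior centred on the across-gene median
    log dispersion, the convention of the standard count-model DE engines:
    the prior variance is the spread of the gene-wise estimates in excess
    of their expected sampling variance (trigamma((m - p)/2) for m samples
    and p mean parameters), floored at 0.25, and the returned value is the
    maximum a-posteriori dispersion.  At few replicates the unmoderated
    gene-wise estimates are noisy enough to inflate the interaction LRT's
    false-positive rate well above nominal.  Estimates are floored at
    1e-8; a matrix of constant genes lands on the floor.
    """
    cond = design.condition_index()
    rep_counts = np.bincount(cond, minlength=4)
    if (rep_counts < 2).all():
        raise ValueError("dispersion estimation needs >=2 replicates in some condition")

    k_cond, s_cond = _split_by_condition(counts, design, s)
    g = counts.shape[0]

    # method of moments on normalised counts, pooled across conditions
    num = np.zeros(g)
    den = np.zeros(g)
    for c in range(4):
        if len(s_cond[c]) < 2:
            continue
        y = k_cond[c] / s_cond[c]
        mu = y.mean(axis=1)
        var = y.var(axis=1, ddof=1)
        w = len(s_cond[c]) - 1
        num += w * (var - mu)
        den += w * np.maximum(mu, 1e-12) ** 2
    alpha_mom = np.clip(num / np.maximum(den, 1e-12), 1e-3, 10.0)

    def profile(alpha_grid: np.ndarray) -> np.ndarray:
        """Cox-Reid adjusted profile loglik of shape (g, P)."""
        ll = np.zeros(alpha_grid.shape)
        for c in range(4):
            kk = k_cond[c][:, None, :]  # (g, 1, R)
            m = _solve_condition_means(kk, s_cond[c], alpha_grid)
            mu = s_cond[c] * m[..., None]
            ll += _nb_loglik(kk, mu, alpha_grid[..., None]).sum(axis=-1)
            # Cox-Reid: the saturated-model information is block diagonal
            # over conditions, so the log determinant is a sum of logs
            info = (mu / (1.0 + alpha_grid[..., None] * mu)).sum(axis=-1)
            ll -= 0.5 * np.log(np.maximum(info, 1e-300))
        return ll

    coarse = np.geomspace(1e-2, 1e2, 25)
    grid1 = alpha_mom[:, None] * coarse[None, :]
    grid1 = np.concatenate([np.full((g, 1), ALPHA_FLOOR), grid1], axis=1)
    best1 = grid1[np.arange(g), np.argmax(profile(grid1), axis=1)]

    fine = np.geomspace(10 ** -0.4, 10 ** 0.4, 21)
    grid2 = np.clip(best1[:, None] * fine[None, :], ALPHA_FLOOR, None)
    best2 = grid2[np.arange(g), np.argmax(profile(grid2), axis=1)]
    genewise = np.maximum(best2, ALPHA_FLOOR)

    if not shrink or g < 10:
        return pd.Series(genewise, index=counts.index, name="alpha")

    # empirical-Bayes moderation: log-normal prior on the dispersion
    from scipy.special import polygamma

    log_gw = np.log(genewise)
    informative = genewise > 10 * ALPHA_FLOOR  # genes pinned at the floor carry no signal
    center = np.median(log_gw[informative]) if informative.any() else np.log(ALPHA_FLOOR)
    resid = log_gw[informative] - center if informative.any() else np.array([0.0])
    s_lr = 1.4826 * np.median(np.abs(resid))
    m_samples = counts.shape[1]
    exp_var = float(polygamma(1, max((m_samples - 4) / 2.0, 0.5)))
    prior_var = max(s_lr**2 - exp_var, 0.25)

    # MAP over a grid spanning the gene-wise estimate and the prior centre
    lo = np.minimum(log_gw, center) - 1.0
    hi = np.maximum(log_gw, center) + 1.0
    steps = np.linspace(0.0, 1.0, 31)
    grid3 = np.exp(lo[:, None] + (hi - lo)[:, None] * steps[None, :])
    grid3 = np.maximum(grid3, ALPHA_FLOOR)
    post = profile(grid3) - (np.log(grid3) - center) ** 2 / (2.0 * prior_var)
    map_alpha = grid3[np.arange(g), np.argmax(post, axis=1)]
    return pd.Series(np.maximum(map_alpha, ALPHA_FLOOR), index=counts.index, name="alpha")


# ---------------------------------------------------------------------------
# Reduced (additive) model by IRLS
# ---------------------------------------------------------------------------


def _fit_reduced(
    counts: pd.DataFrame,
    design: FactorialDesign,
    s: pd.Series,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS fit of log mu = Xb + log s with X = [1, x_A, x_B], all genes.

    Returns (loglik, beta on natural-log scale (g, 3), converged flags).
    """
    counts = counts[design.samples]
    k = counts.to_numpy(dtype=float)
    sv = s.loc[design.samples].to_numpy(dtype=float)
    x = np.column_stack(
        [
            np.ones(len(design.samples)),
            design.table["knockdown"].to_numpy(dtype=float),
            design.table["cytokine"].to_numpy(dtype=float),
        ]
    )
    g, n = k.shape
    offset = np.log(sv)

    beta = np.zeros((g, 3))
    z0 = np.log((k + 0.5) / sv)
    beta[:] = np.linalg.lstsq(x, z0.T, rcond=None)[0].T

    a = alpha[:, None]
    converged = np.zeros(g, dtype=bool)
    active = np.ones(g, dtype=bool)
    for _ in range(max_iter):
        eta = beta @ x.T + offset
        eta = np.clip(eta, -300.0, 300.0)
        mu = np.exp(eta)
        w = mu / (1.0 + a * mu)
        z = (eta - offset) + (k - mu) / np.maximum(mu, 1e-300)
        # per-gene weighted least squares: (X' W X) b = X' W z
        xtwx = np.einsum("ji,gj,jl->gil", x, w, x)
        xtwz = np.einsum("ji,gj,gj->gi", x, w, z)
        try:
            new_beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [np.linalg.lstsq(xtwx[i], xtwz[i], rcond=None)[0] for i in range(g)]
            )
        delta = np.max(np.abs(new_beta - beta), axis=1)
        beta = np.where(active[:, None], new_beta, beta)
        newly = active & (delta < tol)
        converged |= newly
        active &= ~newly
        if not active.any():
            break
    eta = np.clip(beta @ x.T + offset, -300.0, 300.0)
    mu = np.exp(eta)
    ll = _nb_loglik(k, mu, a).sum(axis=1)
    return ll, beta, converged


# ---------------------------------------------------------------------------
# Full fit + LRT
# ---------------------------------------------------------------------------


def fit_interaction(
    counts: pd.DataFrame,
    design: FactorialDesign,
    s: pd.Series,
    alpha: pd.Series,
) -> pd.DataFrame:
    """Fit full and reduced NB models per gene and test the interaction.

    Returns a DataFrame indexed by gene with log2-scale coefficients
    (``betaAB`` is the non-additive effect delta), Wald-tested fold-change
    contrasts against the double-control condition, the interaction LRT
    statistic with chi-square(1) p-value, and BH-adjusted p-values.
    ``lfc_AB`` equals ``betaA + betaB + betaAB`` by construction.
    """
    if set(counts.columns) != set(design.samples):
        raise ValueError("counts and design describe different samples")
    alpha_v = np.maximum(alpha.loc[counts.index].to_numpy(dtype=float), 0.0)
    k_cond, s_cond = _split_by_condition(counts, design, s)

    ll_full, means = _full_model_loglik(k_cond, s_cond, alpha_v)
    ll_red, _, converged = _fit_reduced(counts, design, s, alpha_v)

    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p_int = stats.chi2.sf(lrt, df=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        log2_m = np.where(means > 1e-11, np.log2(np.maximum(means, 1e-300)), np.nan)
    beta0 = log2_m[:, 0]
    beta_a = log2_m[:, 1] - log2_m[:, 0]
    beta_b = log2_m[:, 2] - log2_m[:, 0]
    beta_ab = log2_m[:, 3] - log2_m[:, 1] - log2_m[:, 2] + log2_m[:, 0]
    lfc_ab = beta_a + beta_b + beta_ab  # == log2(m11/m00)

    # Wald SEs from the per-condition Fisher information I_c = sum mu/(1+alpha mu)
    var_logm = np.empty_like(log2_m)
    for c in range(4):
        mu_c = s_cond[c] * means[:, c][:, None]
        info = (mu_c / (1.0 + alpha_v[:, None] * mu_c)).sum(axis=1)
        var_logm[:, c] = 1.0 / np.maximum(info, 1e-300)

    def wald_p(lfc: np.ndarray, var_ln: np.ndarray) -> np.ndarray:
        se_log2 = np.sqrt(var_ln) / LN2
        z = np.abs(lfc) / np.maximum(se_log2, 1e-300)
        return 2.0 * stats.norm.sf(z)

    p_a = wald_p(beta_a, var_logm[:, 1] + var_logm[:, 0])
    p_b = wald_p(beta_b, var_logm[:, 2] + var_logm[:, 0])
    p_ab = wald_p(lfc_ab, var_logm[:, 3] + var_logm[:, 0])

    bad = ~converged
    for arr in (p_int, p_a, p_b, p_ab):
        arr[bad] = np.nan
    lrt = np.where(bad, np.nan, lrt)

    fits = pd.DataFrame(
        {
            "beta0": beta0,
            "betaA": beta_a,
            "betaB": beta_b,
            "betaAB": beta_ab,
            "alpha": alpha_v,
            "lrt_stat": lrt,
            "p_interaction": p_int,
            "padj_interaction": adjust_bh(p_int),
            "lfc_A": beta_a,
            "padj_A": adjust_bh(p_a),
            "lfc_B": beta_b,
            "padj_B": adjust_bh(p_b),
            "lfc_AB": lfc_ab,
            "padj_AB": adjust_bh(p_ab),
            "converged": converged,
        },
        index=counts.index,
    )
    return fits[FIT_COLUMNS]


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaN p-values propagate.

    Missing values are excluded from the number of tests m.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def call_degs(
    fits: pd.DataFrame, contrast: str, padj_threshold: float = 0.05
) -> pd.Series:
    """Responder flags for one contrast: padj strictly below the threshold.

    ``contrast`` is one of ``A``, ``B``, ``AB`` or ``interaction``.
    Non-converged genes (missing padj) are non-responders.
    """
    col = {"A": "padj_A", "B": "padj_B", "AB": "padj_AB", "interaction": "padj_interaction"}
    if contrast not in col:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {sorted(col)}")
    padj = fits[col[contrast]]
    return (padj < padj_threshold).fillna(False).astype(bool)


def response_gene_filter(
    fits: pd.DataFrame,
    tpm,
    padj_threshold: float = 0.05,
    min_tpm: float = 2.0,
    min_abs_lfc: float = 1.0,
) -> pd.Index:
    """The response-gene filter applied after differential calling.

    Keeps genes that are significant in at least one contrast, are
    expressed at >= ``min_tpm`` TPM in some sample, and reach
    ``|log2 FC| >= min_abs_lfc`` in at least one contrast (genes below
    2 TPM everywhere or with all |log2 FC| < 1 are discarded).
    """
    if hasattr(tpm, "require_unit"):
        tpm.require_unit("TPM")
        tpm_values = tpm.values
    else:
        tpm_values = tpm
    missing = fits.index.difference(tpm_values.index)
    if len(missing):
        raise ValueError(f"TPM matrix lacks fitted gene(s): {', '.join(map(str, missing[:20]))}")
    sig = (
        call_degs(fits, "A", padj_threshold)
        | call_degs(fits, "B", padj_threshold)
        | call_degs(fits, "AB", padj_threshold)
    )
    max_tpm = tpm_values.loc[fits.index].max(axis=1)
    max_lfc = fits[["lfc_A", "lfc_B", "lfc_AB"]].abs().max(axis=1)
    keep = sig & (max_tpm >= min_tpm) & (max_lfc >= min_abs_lfc)
    if keep.isna().any():
        warnings.warn("genes with missing fold-changes excluded from the response set", stacklevel=2)
        keep = keep.fillna(False)
    return fits.index[keep.astype(bool)]
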
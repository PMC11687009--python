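"""Synthetic factorial RNA-seq counts and paired-cohort abundance matrices.

Two generators with known ground truth stand in for sequencing data so the
whole pipeline is testable offline:

* :func:`generate_factorial` emulates a 2x2 knockdown-by-cytokine design
  (differentiated/dedifferentiated cells, with or without IFN-gamma) with
  replicated negative-binomial counts and planted additive and non-additive
  genes.
* :func:`generate_cohort` emulates a panel of patient-derived melanoma lines
  profiled with and without IFN-gamma, with a latent dedifferentiation
  gradient that suppresses an MITF-like marker and amplifies the induction
  of interferon-stimulated genes including a PD-L1-like target.

The count model is ``K_gj ~ NB(mean = s_j * q_g * 2^(a_g x_A + b_g x_B +
d_g x_A x_B), dispersion alpha)`` with the variance convention
``var = mu + alpha * mu^2``; ``a_g``/``b_g`` are the log2 main effects of
the knockdown and the cytokine and ``d_g`` the log2 interaction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interaction import FactorialDesign
from .normalize import AbundanceMatrix

#: planted gene classes; every gene belongs to exactly one
GENE_CLASSES = (
    "null",
    "A_only",
    "B_only",
    "additive_both",
    "nonadd_from_neither",
    "nonadd_from_A",
    "nonadd_from_B",
    "nonadd_from_both",
)

_HAS_A = {"A_only", "additive_both", "nonadd_from_A", "nonadd_from_both"}
_HAS_B = {"B_only", "additive_both", "nonadd_from_B", "nonadd_from_both"}
_HAS_D = {"nonadd_from_neither", "nonadd_from_A", "nonadd_from_B", "nonadd_from_both"}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _default_fractions() -> dict[str, float]:
    return {
        "null": 0.65,
        "A_only": 0.05,
        "B_only": 0.05,
        "additive_both": 0.05,
        "nonadd_from_neither": 0.05,
        "nonadd_from_A": 0.05,
        "nonadd_from_B": 0.05,
        "nonadd_from_both": 0.05,
    }


@dataclass
class SimFactorialConfig:
    """Configuration of the 2x2 factorial count simulation.

    Defaults mirror the study design this generator emulates: three
    biological replicates per condition, log2 effect sizes of 2 (well above
    the |log2 FC| > 1 calling threshold so planted genes are detectable),
    and a moderate dispersion of 0.05 typical of cell-line RNA-seq.
    """

    n_genes: int = 2000
    n_reps: int = 3
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.05
    class_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effect_size_log2: float = 2.0
    interaction_size_log2: float = 2.0
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def validate(self) -> None:
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be >= 1")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if set(self.class_fractions) - set(GENE_CLASSES):
            unknown = sorted(set(self.class_fractions) - set(GENE_CLASSES))
            raise ConfigurationError(f"unknown gene classes: {unknown}")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ConfigurationError("class fractions must be non-negative")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class fractions sum to {total}, expected 1")
        lo, hi = self.baseline_mean_range
        if not (0 < lo <= hi):
            raise ConfigurationError("baseline_mean_range must be a positive interval")


def _allocate_classes(fractions: dict[str, float], n: int, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder allocation of n genes to classes, then shuffled."""
    names = [c for c in GENE_CLASSES if fractions.get(c, 0.0) > 0]
    raw = np.array([fractions[c] * n for c in names])
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    for i in np.argsort(raw - np.floor(raw))[::-1][:short]:
        counts[i] += 1
    labels = np.repeat(names, counts)
    return rng.permutation(labels)


def generate_factorial(
    config: SimFactorialConfig,
) -> tuple[pd.DataFrame, FactorialDesign, pd.DataFrame]:
    """Simulate a replicated 2x2 factorial count matrix with ground truth.

    Returns
    -------
    counts
        Integer gene-by-sample DataFrame.
    design
        :class:`FactorialDesign` with knockdown/cytokine indicators.
    truth
        Per-gene DataFrame with columns ``class``, ``a`` (log2 knockdown
        main effect), ``b`` (log2 cytokine main effect), ``d`` (log2
        interaction), ``baseline`` (expected control count) and the drawn
        per-sample size factors stored in ``truth.attrs["size_factors"]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes

    genes = pd.Index([f"g{i:05d}" for i in range(g)], name="gene")
    classes = _allocate_classes(config.class_fractions, g, rng)

    sign = lambda size: rng.choice([-1.0, 1.0], size=size)  # noqa: E731
    a = np.where(np.isin(classes, list(_HAS_A)), config.effect_size_log2 * sign(g), 0.0)
    b = np.where(np.isin(classes, list(_HAS_B)), config.effect_size_log2 * sign(g), 0.0)
    d = np.where(np.isin(classes, list(_HAS_D)), config.interaction_size_log2 * sign(g), 0.0)

    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=g))

    # design: 4 conditions x n_reps, size factors log-uniform to exercise
    # normalization downstream
    conditions = [(0, 0), (1, 0), (0, 1), (1, 1)]
    rows = []
    for x_a, x_b in conditions:
        for r in range(1, config.n_reps + 1):
            rows.append((f"A{x_a}B{x_b}r{r}", x_a, x_b, r))
    design_df = pd.DataFrame(rows, columns=["sample", "knockdown", "cytokine", "replicate"])
    design_df = design_df.set_index("sample")
    n_samples = len(design_df)

    sf_lo, sf_hi = config.size_factor_range
    size_factors = np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi), size=n_samples))

    x_a = design_df["knockdown"].to_numpy()
    x_b = design_df["cytokine"].to_numpy()
    log2_effect = (
        a[:, None] * x_a[None, :]
        + b[:, None] * x_b[None, :]
        + d[:, None] * x_a[None, :] * x_b[None, :]
    )
    mu = size_factors[None, :] * baseline[:, None] * np.power(2.0, log2_effect)

    alpha = config.dispersion
    if alpha == 0:
        counts = rng.poisson(mu)
    else:
        # NB with var = mu + alpha mu^2: shape n = 1/alpha, p = n / (n + mu)
        n_shape = 1.0 / alpha
        counts = rng.negative_binomial(n_shape, n_shape / (n_shape + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=design_df.index.rename(None))
    truth = pd.DataFrame(
        {"class": classes, "a": a, "b": b, "d": d, "baseline": baseline}, index=genes
    )
    truth.attrs["size_factors"] = pd.Series(size_factors, index=design_df.index)
    return counts_df, FactorialDesign(design_df), truth


# ---------------------------------------------------------------------------
# Paired +/- IFN-gamma cohort
# ---------------------------------------------------------------------------


@dataclass
class SimCohortConfig:
    """Configuration of the paired-cohort abundance simulation.

    A latent dedifferentiation score u in [0, 1] per line drives three
    couplings: MITF-like expression decreases in u (slope
    ``-5 * mitf_coupling`` log2 units across the gradient), the IFN-gamma
    induction of interferon-stimulated genes is amplified by
    ``1 + isg_coupling * u``, and the induced expression of a PD-L1-like
    target rises by ``3 * pdl1_coupling * u`` log2 units.  Defaults (45
    lines, couplings 0.8, log2 noise SD 0.2) give the clearly detectable
    but noisy gradients seen in real melanoma panels.
    """

    n_lines: int = 45
    n_genes: int = 500
    n_isg: int = 50
    latent_dediff: np.ndarray | None = None
    mitf_coupling: float = 0.8
    isg_coupling: float = 0.8
    pdl1_coupling: float = 0.8
    noise_sd: float = 0.2
    seed: int = 0

    MITF_GENE: str = "MITF"
    PDL1_GENE: str = "CD274"

    def validate(self) -> None:
        if self.n_lines < 4:
            raise ConfigurationError("n_lines must be >= 4")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.latent_dediff is not None:
            u = np.asarray(self.latent_dediff, dtype=float)
            if u.shape != (self.n_lines,) or (u < 0).any() or (u > 1).any():
                raise ConfigurationError("latent_dediff must be n_lines values in [0, 1]")
        if self.n_genes < self.n_isg + 2:
            raise ConfigurationError("n_genes too small for the marker genes")


def generate_cohort(
    config: SimCohortConfig,
) -> tuple[AbundanceMatrix, AbundanceMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate paired untreated / IFN-gamma-treated TPM matrices.

    Returns ``(untreated, treated, metadata, latent)`` where the two
    :class:`AbundanceMatrix` objects are on TPM scale (every column
    renormalised to sum 1e6), ``metadata`` carries per-line flags in the
    cohort sample-sheet format (``engineered``, ``treatment``) and
    ``latent`` records the ground-truth dedifferentiation score and the
    noise-free PD-L1 induction per line.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_lines

    lines = np.array([f"line{i:02d}" for i in range(n)])
    if config.latent_dediff is None:
        u = rng.uniform(0.0, 1.0, size=n)
    else:
        u = np.asarray(config.latent_dediff, dtype=float)

    n_bg = config.n_genes - config.n_isg - 2
    isg_genes = [f"ISG{i:03d}" for i in range(config.n_isg)]
    bg_genes = [f"BG{i:04d}" for i in range(n_bg)]
    genes = [config.MITF_GENE, config.PDL1_GENE] + isg_genes + bg_genes

    # expression built on log2(TPM+1)-like scale, then exponentiated
    base = np.empty((config.n_genes, n))
    induction = np.zeros((config.n_genes, n))

    base[0] = 9.0 - 5.0 * config.mitf_coupling * u  # MITF-like, high when differentiated
    base[1] = 2.0  # PD-L1-like, low at baseline
    induction[1] = 1.0 + 3.0 * config.pdl1_coupling * u

    isg_base = rng.uniform(3.0, 6.0, size=config.n_isg)
    isg_amp = rng.uniform(1.5, 2.5, size=config.n_isg)
    base[2 : 2 + config.n_isg] = isg_base[:, None]
    induction[2 : 2 + config.n_isg] = isg_amp[:, None] * (1.0 + config.isg_coupling * u[None, :])

    base[2 + config.n_isg :] = rng.uniform(0.5, 8.0, size=n_bg)[:, None]

    noise = lambda: rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))  # noqa: E731
    log2_untreated = np.clip(base + noise(), 0.0, None)
    log2_treated = np.clip(base + induction + noise(), 0.0, None)

    def to_tpm(log2x: np.ndarray) -> AbundanceMatrix:
        raw = np.power(2.0, log2x) - 1.0
        tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
        return AbundanceMatrix(pd.DataFrame(tpm, index=genes, columns=lines), "TPM")

    untreated = to_tpm(log2_untreated)
    treated = to_tpm(log2_treated)

    metadata = pd.DataFrame(
        {"engineered": False, "treatment": "IFNg"}, index=pd.Index(lines, name="line")
    )
    latent = pd.DataFrame(
        {"dediff": u, "pdl1_induction": induction[1]}, index=pd.Index(lines, name="line")
    )
    return untreated, treated, metadata, latent


def simulate_cohort_sample_sheet(
    n_total: int = 58, n_excluded: int = 13, seed: int = 0
) -> pd.DataFrame:
    """Synthetic stand-in for a public cohort's sample sheet.

    Emulates the metadata of a deposited melanoma-panel series in which a
    subset of the profiled lines are genetically engineered or received a
    treatment other than IFN-gamma and must be excluded, leaving the
    wild-type +/- IFN-gamma panel.  This is a synthetic reconstruction of
    the sheet's structure, not the deposited metadata itself.
    """
    if n_excluded > n_total:
        raise ConfigurationError("n_excluded exceeds n_total")
    rng = np.random.default_rng(seed)
    lines = [f"line{i:02d}" for i in range(n_total)]
    flagged = rng.choice(n_total, size=n_excluded, replace=False)
    engineered = np.zeros(n_total, dtype=bool)
    treatment = np.array(["IFNg"] * n_total, dtype=object)
    for k, i in enumerate(flagged):
        if k % 2 == 0:
            engineered[i] = True
        else:
            treatment[i] = "TNFa"
    return pd.DataFrame(
        {"engineered": engineered, "treatment": treatment}, index=pd.Index(lines, name="line")
    )


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    counts: pd.DataFrame,
    design: FactorialDesign,
    truth: pd.DataFrame,
    directory,
) -> dict[str, str]:
    """Write counts, design, truth table and a planted-class GMT to a directory.

    The GMT contains one set per non-null planted class; classes with no
    members are omitted.  Files round-trip losslessly through
    :func:`ifnsynergy.interaction.read_counts_tsv` /
    :func:`read_design_tsv` and :func:`ifnsynergy.enrichment.read_gmt`.
    """
    from .enrichment import GeneSetCollection, write_gmt

    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts": os.path.join(directory, "counts.tsv"),
        "design": os.path.join(directory, "design.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
        "gmt": os.path.join(directory, "planted_classes.gmt"),
    }
    counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    design.table.to_csv(paths["design"], sep="\t", index_label="sample")
    truth.to_csv(paths["truth"], sep="\t", index_label="gene")

    sets, descriptions = {}, {}
    for cls in GENE_CLASSES:
        if cls == "null":
            continue
        members = truth.index[truth["class"] == cls].tolist()
        if members:
            sets[cls] = members
            descriptions[cls] = f"planted {cls} genes"
    write_gmt(GeneSetCollection(sets, descriptions), paths["gmt"])
    return paths
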
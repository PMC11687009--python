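"""Abundance-unit conversions, expression filters and qPCR quantification.

Implements the normalisation conventions used throughout the pipeline:
FPKM -> TPM (per-sample proportional rescale to a column sum of 1e6),
log2(TPM + 1), per-gene z-scoring, minimum-TPM expression filtering,
top-k expressed gene selection, and relative qPCR quantification by the
2^-ddCT method against a housekeeping gene and calibrator condition.

Matrices are gene-by-sample :class:`pandas.DataFrame` objects wrapped in
:class:`AbundanceMatrix`, which records the declared unit so downstream
stages can refuse inputs on the wrong scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TPM_SCALE = 1e6
#: relative tolerance on the per-sample TPM column sum invariant
TPM_RTOL = 1e-6

VALID_UNITS = ("FPKM", "TPM", "log2TPM1", "zscore")


class UnitError(ValueError):
    """Raised when an operation receives a matrix in the wrong unit."""


@dataclass
class AbundanceMatrix:
    """A gene-by-sample abundance matrix with a declared unit.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and sample ids as columns.
    unit
        One of ``FPKM``, ``TPM``, ``log2TPM1`` or ``zscore``.
    constant_genes
        Gene ids whose row was constant when z-scoring (their z rows are
        zero by convention); empty for other units.
    """

    values: pd.DataFrame
    unit: str
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.unit in ("FPKM", "TPM") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"{self.unit} matrix contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise UnitError(f"expected a {unit} matrix, got {self.unit}")


def read_abundance_tsv(path, unit: str) -> AbundanceMatrix:
    """Read a TSV matrix (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return AbundanceMatrix(df, unit)


def write_abundance_tsv(m: AbundanceMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def fpkm_to_tpm(m: AbundanceMatrix) -> AbundanceMatrix:
    """Convert FPKM to TPM: ``TPM_i = FPKM_i / sum_j FPKM_j * 1e6`` per sample.

    Every output column sums to 1e6 (relative tolerance 1e-6); within-sample
    proportions are preserved.  A sample whose FPKM column is all zero has no
    defined TPM and raises a ``ValueError`` naming it.
    """
    m.require_unit("FPKM")
    col_sums = m.values.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(
            f"cannot convert all-zero FPKM sample(s) to TPM: {', '.join(map(str, zero.index))}"
        )
    tpm = m.values.div(col_sums, axis=1) * TPM_SCALE
    return AbundanceMatrix(tpm, "TPM")


def log2_tpm1(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2(TPM + 1)."""
    m.require_unit("TPM")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    return AbundanceMatrix(np.log2(m.values + 1.0), "log2TPM1")


def zscore_genes(m: AbundanceMatrix, ddof: int = 1) -> AbundanceMatrix:
    """Standardise each gene row to mean 0, SD 1 (sample SD, divisor n-1).

    Constant genes cannot be standardised; their rows are returned as zeros
    and their ids recorded in ``constant_genes`` on the result.
    """
    m.require_unit("log2TPM1")
    if m.values.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mu = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=ddof)
    constant = sd[sd == 0].index.tolist()
    safe_sd = sd.replace(0, 1.0)
    z = m.values.sub(mu, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    return AbundanceMatrix(z, "zscore", constant_genes=constant)


def filter_min_tpm(m: AbundanceMatrix, threshold: float = 3.0) -> AbundanceMatrix:
    """Drop genes whose TPM is below ``threshold`` in every sample.

    A gene is retained iff its maximum over samples is >= threshold
    (strict-less exclusion: a gene at exactly the threshold anywhere stays).
    Gene order is preserved.
    """
    m.require_unit("TPM")
    if m.values.empty:
        return AbundanceMatrix(m.values.copy(), "TPM")
    keep = m.values.max(axis=1) >= threshold
    return AbundanceMatrix(m.values.loc[keep], "TPM")


def select_top_expressed(m: AbundanceMatrix, k: int = 2000) -> AbundanceMatrix:
    """Keep the k genes with highest mean expression across samples.

    Ties at the cutoff are broken by lexicographic gene id (smaller id kept),
    so the selection is deterministic.
    """
    n = m.values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} genes available")
    means = m.values.mean(axis=1)
    order = sorted(means.index, key=lambda g: (-means[g], str(g)))
    return AbundanceMatrix(m.values.loc[order[:k]], m.unit, constant_genes=list(m.constant_genes))


# ---------------------------------------------------------------------------
# qPCR relative quantification
# ---------------------------------------------------------------------------


@dataclass
class QpcrMeasurement:
    """CT table for 2^-ddCT quantification.

    ``ct`` is a long-format DataFrame with columns (sample, gene, ct);
    technical replicates are permitted and averaged per sample x gene
    before any delta is computed.  ``housekeeping`` must be measured in
    every sample; ``calibrator`` names the reference sample.
    """

    ct: pd.DataFrame
    housekeeping: str
    calibrator: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "ct"}
        if not required.issubset(self.ct.columns):
            raise ValueError(f"CT table needs columns {sorted(required)}")
        if not np.isfinite(self.ct["ct"]).all():
            raise ValueError("non-finite CT values")
        samples = set(self.ct["sample"])
        hk_samples = set(self.ct.loc[self.ct["gene"] == self.housekeeping, "sample"])
        missing = samples - hk_samples
        if missing:
            raise ValueError(
                f"housekeeping gene {self.housekeeping!r} missing in sample(s): "
                f"{', '.join(sorted(map(str, missing)))}"
            )
        if self.calibrator not in samples:
            raise ValueError(f"calibrator sample {self.calibrator!r} not in CT table")


def ddct_quantify(q: QpcrMeasurement) -> pd.DataFrame:
    """Relative expression 2^-ddCT per sample x gene.

    ddCT = (CT_target - CT_hk)_sample - (CT_target - CT_hk)_calibrator.
    The calibrator sample maps to exactly 1 for every gene it measures.
    Returns a sample-by-gene DataFrame of fold-changes (housekeeping gene
    excluded).
    """
    mean_ct = q.ct.groupby(["sample", "gene"])["ct"].mean().unstack()
    dct = mean_ct.sub(mean_ct[q.housekeeping], axis=0)
    ddct = dct.sub(dct.loc[q.calibrator], axis=1)
    fold = np.power(2.0, -ddct).drop(columns=q.housekeeping)
    if fold.isna().any().any():
        warnings.warn("some sample x gene combinations lack CT values", stacklevel=2)
    return fold
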
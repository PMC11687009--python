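"""Directional classification of non-additive expression responses.

A gene responds non-additively when its combined response to the two
perturbations differs from the sum (in log2 space) of its responses to
each perturbation alone.  The non-additive effect is

    delta = log2FC_AB - (log2FC_A + log2FC_B)

which equals the interaction coefficient betaAB of the two-factor fit.
A gene is called non-additive when the interaction LRT is significant
(BH-adjusted p < 0.05) and the effect is substantial (|delta| > 1, strict).
Called genes are assigned an emergence category by which single-factor
responses they show (neither factor, knockdown only, cytokine only, or
both) and a direction: positive synergism (delta > 0, combined response
above the additive expectation) or antagonism (delta < 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .interaction import call_degs

CATEGORIES = ("from_neither", "from_A_only", "from_B_only", "from_both")

CALL_COLUMNS = [
    "responder_A", "responder_B", "delta", "padj_interaction",
    "is_nonadditive", "category", "direction",
]


@dataclass(frozen=True)
class Thresholds:
    """Joint calling thresholds: interaction significance and effect size."""

    padj: float = 0.05
    min_abs_delta: float = 1.0
    responder_padj: float = 0.05


def expected_vs_observed(fit_row: pd.Series) -> tuple[float, float, float]:
    """(expected, observed, delta): additive expectation vs combined response."""
    for col in ("lfc_A", "lfc_B", "lfc_AB"):
        if col not in fit_row or pd.isna(fit_row[col]):
            raise ValueError(f"missing contrast {col!r}")
    expected = fit_row["lfc_A"] + fit_row["lfc_B"]
    observed = fit_row["lfc_AB"]
    return expected, observed, observed - expected


def _categorize(responder_a: bool, responder_b: bool) -> str:
    if responder_a and responder_b:
        return "from_both"
    if responder_a:
        return "from_A_only"
    if responder_b:
        return "from_B_only"
    return "from_neither"


def classify_gene(fit_row: pd.Series, thresholds: Thresholds = Thresholds()) -> dict:
    """Classify one gene's fit into a non-additive call.

    A non-converged fit yields a flagged call with ``is_nonadditive``
    missing.  ``delta`` is the interaction coefficient betaAB.
    """
    if "converged" in fit_row and not fit_row["converged"]:
        return {
            "responder_A": False, "responder_B": False,
            "delta": np.nan, "padj_interaction": np.nan,
            "is_nonadditive": np.nan, "category": None, "direction": "none",
        }
    delta = float(fit_row["betaAB"])
    padj_int = float(fit_row["padj_interaction"])
    responder_a = bool(fit_row["padj_A"] < thresholds.responder_padj)
    responder_b = bool(fit_row["padj_B"] < thresholds.responder_padj)
    nonadd = bool(padj_int < thresholds.padj and abs(delta) > thresholds.min_abs_delta)
    return {
        "responder_A": responder_a,
        "responder_B": responder_b,
        "delta": delta,
        "padj_interaction": padj_int,
        "is_nonadditive": nonadd,
        "category": _categorize(responder_a, responder_b) if nonadd else None,
        "direction": ("positive_synergism" if delta > 0 else "antagonism") if nonadd else "none",
    }


def classify_all(
    fits: pd.DataFrame,
    retained=None,
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every gene; optionally restrict to the response-gene set.

    Vectorised version of :func:`classify_gene`.  Returns the per-gene
    call table and a per-category count summary; the four categories are
    disjoint and their counts sum to the number of non-additive calls.
    """
    if retained is not None:
        fits = fits.loc[fits.index.intersection(pd.Index(retained))]
    if fits.empty:
        empty = pd.DataFrame(columns=CALL_COLUMNS)
        return empty, {c: 0 for c in CATEGORIES}

    responder_a = call_degs(fits, "A", thresholds.responder_padj)
    responder_b = call_degs(fits, "B", thresholds.responder_padj)
    delta = fits["betaAB"]
    padj_int = fits["padj_interaction"]
    converged = fits["converged"].astype(bool) if "converged" in fits else pd.Series(True, fits.index)

    nonadd = (padj_int < thresholds.padj) & (delta.abs() > thresholds.min_abs_delta)
    nonadd = nonadd.fillna(False) & converged

    category = pd.Series(None, index=fits.index, dtype=object)
    category[nonadd & responder_a & responder_b] = "from_both"
    category[nonadd & responder_a & ~responder_b] = "from_A_only"
    category[nonadd & ~responder_a & responder_b] = "from_B_only"
    category[nonadd & ~responder_a & ~responder_b] = "from_neither"

    direction = pd.Series("none", index=fits.index, dtype=object)
    direction[nonadd & (delta > 0)] = "positive_synergism"
    direction[nonadd & (delta <= 0)] = "antagonism"

    calls = pd.DataFrame(
        {
            "responder_A": responder_a,
            "responder_B": responder_b,
            "delta": delta,
            "padj_interaction": padj_int,
            "is_nonadditive": nonadd.astype(object).where(converged, np.nan),
            "category": category,
            "direction": direction,
        }
    )[CALL_COLUMNS]
    summary = {c: int((category == c).sum()) for c in CATEGORIES}
    return calls, summary
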
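"""Gene-set enrichment: weighted running-sum score with a gene-set
permutation null, leading-edge and core-gene extraction, and hypergeometric
overlap enrichment.

The enrichment score walks the ranked gene list accumulating
``|score|^w / sum_hits |score|^w`` at set members (weight exponent w = 1)
and ``-1/(N - N_hit)`` at non-members; ES is the running-sum value of
maximal absolute deviation from zero, signed.  Significance comes from a
gene-set permutation null: random sets of equal size drawn from the ranked
universe, with +1-smoothed sign-matched permutation p-values, NES by
normalising against the mean |null ES| of matching sign, and a
sign-stratified ratio FDR q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import adjust_bh


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated members).

    Duplicate members within a set are collapsed with a warning; a
    duplicate set name or a line with fewer than three fields is an error
    reported with its line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(f"set {name!r}: duplicate members collapsed", stacklevel=2)
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

#: signal-to-noise SD floor: sd -> max(sd, 0.2 |mean|, 0.2)
SD_FLOOR_FRAC = 0.2
SD_FLOOR_MIN = 0.2


def rank_genes(expr, group_labels: pd.Series) -> pd.Series:
    """Signal-to-noise ranking of genes between two sample groups.

    ``expr`` is a z-score :class:`~ifnsynergy.normalize.AbundanceMatrix`
    (or a plain DataFrame); ``group_labels`` maps each sample to one of
    exactly two groups, each with >= 2 samples.  The statistic is
    (mu1 - mu2) / (sd1' + sd2') with each group SD floored at
    max(sd, 0.2 |mean|, 0.2); positive scores mean higher in the first
    group (lexicographically smaller label).  Returned sorted descending,
    ties broken by gene id.
    """
    values = expr.values if hasattr(expr, "require_unit") else expr
    group_labels = pd.Series(group_labels)
    groups = sorted(group_labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    cols = {g: group_labels.index[group_labels == g] for g in groups}
    for g, c in cols.items():
        if len(c) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")

    def moments(c):
        sub = values[c]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        sd = np.maximum(sd, np.maximum(SD_FLOOR_FRAC * mu.abs(), SD_FLOOR_MIN))
        return mu, sd

    mu1, sd1 = moments(cols[groups[0]])
    mu2, sd2 = moments(cols[groups[1]])
    score = (mu1 - mu2) / (sd1 + sd2)
    order = sorted(score.index, key=lambda g: (-score[g], str(g)))
    return score.loc[order]


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


def _running_sum(scores: np.ndarray, hit: np.ndarray, weight: float = 1.0) -> np.ndarray:
    """Running enrichment sum over the ranked list; hit is boolean."""
    n = len(scores)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranked universe")
    if n_hit == n:
        raise ValueError("gene set equals the ranked universe (miss penalty undefined)")
    w = np.abs(scores) ** weight
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all member scores exactly zero: fall back to equal steps
        inc = np.where(hit, 1.0 / n_hit, 0.0)
    else:
        inc = hit_w / total
    dec = np.where(hit, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(inc - dec)


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray, int]:
    """(ES, running sum, peak index) for one set against a ranked list.

    ``ranked`` is the descending score Series from :func:`rank_genes`.
    ES is the running-sum value of maximal |deviation|, signed; the peak
    index is where it is attained (first occurrence).
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.index), dtype=bool, count=len(ranked))
    running = _running_sum(ranked.to_numpy(dtype=float), hit, weight)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), running, peak


# ---------------------------------------------------------------------------
# Gene-set permutation test
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    name: str
    size: int
    es: float
    nes: float
    p_perm: float
    q_fdr: float
    peak: int
    leading_edge: list[str]


def _null_es(
    scores: np.ndarray, size: int, n_perm: int, rng: np.random.Generator, weight: float
) -> np.ndarray:
    """Null ES distribution from random same-size sets (vectorised, chunked)."""
    n = len(scores)
    w = np.abs(scores) ** weight
    out = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(5e6 // max(n, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        hit = np.zeros((b, n), dtype=bool)
        for i in range(b):
            hit[i, rng.choice(n, size=size, replace=False)] = True
        hit_w = np.where(hit, w, 0.0)
        totals = hit_w.sum(axis=1, keepdims=True)
        bad = totals[:, 0] == 0
        inc = np.divide(hit_w, totals, out=np.zeros_like(hit_w), where=totals > 0)
        if bad.any():
            inc[bad] = np.where(hit[bad], 1.0 / size, 0.0)
        dec = np.where(hit, 0.0, 1.0 / (n - size))
        running = np.cumsum(inc - dec, axis=1)
        idx = np.argmax(np.abs(running), axis=1)
        out[done : done + b] = running[np.arange(b), idx]
        done += b
    return out


def permutation_test(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Gene-set-permutation significance for every set in the collection.

    For each set, null ES values come from ``n_perm`` random same-size
    gene sets drawn from the ranked universe.  p_perm is the +1-smoothed
    fraction of same-sign null ES at least as extreme; NES divides ES by
    the mean |null ES| of matching sign; q is the sign-stratified ratio
    of the null tail fraction (pooled across sets) to the observed tail
    fraction, clamped to [0, 1].  Fixed seed gives identical results.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    scores = ranked.to_numpy(dtype=float)
    n = len(scores)

    rows = []
    null_by_size: dict[int, np.ndarray] = {}
    for name, members in collection:
        in_universe = [g for g in members if g in ranked.index]
        size = len(in_universe)
        if size == 0:
            raise ValueError(f"set {name!r} has no members in the ranked universe")
        if size >= n:
            raise ValueError(f"set {name!r} is not a proper subset of the universe")
        es, running, peak = enrichment_score(ranked, in_universe, weight)
        if size not in null_by_size:
            null_by_size[size] = _null_es(scores, size, n_perm, rng, weight)
        null = null_by_size[size]

        same_sign = null >= 0 if es >= 0 else null < 0
        n_sign = int(same_sign.sum())
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_sign)
        mean_abs = np.abs(null[same_sign]).mean() if n_sign else np.abs(null).mean()
        nes = es / mean_abs if mean_abs > 0 else np.nan
        null_nes = np.where(
            null >= 0,
            null / (np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan),
            null / (np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan),
        )
        le = leading_edge(es, peak, ranked, in_universe)
        rows.append(
            {
                "set": name, "size": size, "es": es, "nes": nes, "p_perm": p,
                "peak": peak, "leading_edge": le, "_null_nes": null_nes,
            }
        )

    # sign-stratified ratio FDR
    obs_nes = np.array([r["nes"] for r in rows])
    all_null_nes = np.concatenate([r["_null_nes"] for r in rows]) if rows else np.array([])
    qs = []
    for r in rows:
        nes = r["nes"]
        if not np.isfinite(nes) or nes == 0:
            qs.append(np.nan)
            continue
        if nes >= 0:
            null_pool = all_null_nes[all_null_nes >= 0]
            obs_pool = obs_nes[obs_nes >= 0]
        else:
            null_pool = all_null_nes[all_null_nes < 0]
            obs_pool = obs_nes[obs_nes < 0]
        frac_null = (np.abs(null_pool) >= abs(nes)).mean() if len(null_pool) else np.nan
        frac_obs = (np.abs(obs_pool) >= abs(nes)).mean() if len(obs_pool) else np.nan
        q = frac_null / frac_obs if frac_obs and np.isfinite(frac_null) else np.nan
        qs.append(float(np.clip(q, 0.0, 1.0)) if np.isfinite(q) else np.nan)

    df = pd.DataFrame(
        [
            {
                "set": r["set"], "size": r["size"], "es": r["es"], "nes": r["nes"],
                "p_perm": r["p_perm"], "q_fdr": q, "peak": r["peak"],
                "leading_edge": r["leading_edge"],
            }
            for r, q in zip(rows, qs)
        ]
    )
    return df.set_index("set")


def leading_edge(es: float, peak: int, ranked: pd.Series, gene_set) -> list[str]:
    """Set members contributing to the enrichment peak.

    ES > 0: members ranked at or before the peak; ES < 0: members at or
    after the peak; ES == 0: empty with a warning.  Order follows the
    ranked list.
    """
    members = set(gene_set)
    if es == 0:
        warnings.warn("ES is exactly 0; leading edge undefined, returning []", stacklevel=2)
        return []
    ids = list(ranked.index)
    if es > 0:
        window = ids[: peak + 1]
    else:
        window = ids[peak:]
    return [g for g in window if g in members]


def core_genes(leading_edges: list[list[str]], min_occurrence: int = 3) -> pd.Series:
    """Genes present in at least ``min_occurrence`` leading-edge subsets.

    Returns occurrence counts sorted by count descending then gene id.
    """
    counts: dict[str, int] = {}
    for le in leading_edges:
        for g in set(le):
            counts[g] = counts.get(g, 0) + 1
    core = {g: c for g, c in counts.items() if c >= min_occurrence}
    ordered = sorted(core, key=lambda g: (-core[g], str(g)))
    return pd.Series({g: core[g] for g in ordered}, dtype=int, name="occurrences")


# ---------------------------------------------------------------------------
# Overlap (hypergeometric) enrichment
# ---------------------------------------------------------------------------


def overlap_enrichment(
    query, collection: GeneSetCollection, universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap of a query set with each collection set.

    p = P(X >= observed overlap) with population = universe, successes =
    set members in the universe, draws = |query|; q by BH across the
    collection.  The query must be a subset of the universe.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    query = set(query)
    if not query <= uni:
        raise ValueError("query genes must all be in the universe")
    m_pop = len(uni)
    rows = []
    for name, members in collection:
        in_uni = set(members) & uni
        overlap = len(in_uni & query)
        # sf(k-1) = P(X >= k)
        p = float(stats.hypergeom.sf(overlap - 1, m_pop, len(in_uni), len(query)))
        rows.append({"set": name, "set_size": len(in_uni), "overlap": overlap, "p": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("set")
    df["q"] = adjust_bh(df["p"].to_numpy())
    return df
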
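"""miRNA-mRNA candidate-regulation networks and preranked GSEA.

Predicted targets carry a cumulative weighted context score (CWCS; more
negative = stronger predicted repression).  Predictions are stratified into
confidence tiers -- high (CWCS < -0.4), moderate (-0.4 <= CWCS <= -0.2,
boundaries inclusive by convention), excluded otherwise -- and an edge
miRNA -> mRNA is retained only when the mRNA is significantly regulated in
the direction opposite to the miRNA's RISC-loading change (enriched miRNA
with downregulated target, de-enriched with upregulated).

The GSEA half implements the standard preranked enrichment score: a running
sum over the descending signature that increments at gene-set hits in
proportion to |stat|^p (normalized over set members) and decrements 1/(N-n)
at misses; the ES is the extremum.  Significance comes from gene-label
permutations with a fixed seed; a negative ES means the set is shifted
toward the bottom of the ranking (downregulated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GseaResult",
    "stratify_targets",
    "build_network",
    "rank_signature",
    "gsea_es",
    "running_sum",
]


@dataclass
class GseaResult:
    es: float
    p_value: float
    n_perm: int
    seed: int
    n_hits: int
    degenerate: bool = False


def stratify_targets(
    predictions: pd.DataFrame,
    moderate_bounds: tuple[float, float] = (-0.4, -0.2),
    high_cutoff: float = -0.4,
) -> pd.DataFrame:
    """Add a confidence ``tier`` column from CWCS.

    high iff CWCS < ``high_cutoff``; moderate iff within ``moderate_bounds``
    inclusive; excluded otherwise.  ``predictions`` needs columns ``mirna``,
    ``gene``, ``cwcs``.
    """
    lo, hi = moderate_bounds
    out = predictions.copy()
    cw = out["cwcs"].astype(float)
    tier = np.where(cw < high_cutoff, "high", np.where((cw >= lo) & (cw <= hi), "moderate", "excluded"))
    out["tier"] = tier
    return out


def build_network(
    mirna_direction: dict[str, str],
    de_sets: dict[str, set[str]],
    predictions: pd.DataFrame,
) -> pd.DataFrame:
    """Bipartite miRNA -> mRNA edge list under the anti-correlation rule.

    ``mirna_direction`` maps miRNA -> 'enriched' | 'de-enriched';
    ``de_sets`` holds the 'up' and 'down' significant mRNA sets; an edge is
    kept iff the prediction tier is high/moderate and the target sits in the
    DE set opposite to the miRNA's direction.  Output is sorted (miRNA,
    gene) so it is invariant to input row order.
    """
    bad = set(mirna_direction.values()) - {"enriched", "de-enriched"}
    if bad:
        raise ValueError(f"unknown miRNA direction labels: {sorted(bad)}")
    if "tier" not in predictions.columns:
        raise ValueError("predictions must be tiered first (stratify_targets)")
    opposite = {"enriched": "down", "de-enriched": "up"}
    rows = []
    for rec in predictions.itertuples(index=False):
        direction = mirna_direction.get(rec.mirna)
        if direction is None or rec.tier not in ("high", "moderate"):
            continue
        if rec.gene in de_sets[opposite[direction]]:
            rows.append(
                {"mirna": rec.mirna, "gene": rec.gene, "tier": rec.tier, "direction": direction}
            )
    return (
        pd.DataFrame(rows, columns=["mirna", "gene", "tier", "direction"])
        .sort_values(["mirna", "gene"], kind="stable")
        .reset_index(drop=True)
    )


def rank_signature(stats: dict[str, float]) -> pd.Series:
    """Order genes by a signed statistic, descending; ties break by gene id.

    Returns a Series (index = gene, values = statistic) with no duplicates.
    """
    if len(stats) == 0:
        raise ValueError("empty signature")
    genes = list(stats)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in signature")
    ordered = sorted(genes, key=lambda g: (-stats[g], g))
    return pd.Series([float(stats[g]) for g in ordered], index=ordered, name="stat")


def running_sum(signature: pd.Series, gene_set: set[str], weight_p: float = 1.0) -> np.ndarray:
    """The GSEA running sum over a ranked signature for one gene set."""
    in_set = signature.index.isin(gene_set)
    n = len(signature)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must intersect the signature properly")
    weights = np.abs(signature.to_numpy()) ** weight_p
    hit_w = np.where(in_set, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit stats are zero; fall back to unweighted steps
        hit_w = in_set.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~in_set) / (n - n_hit)
    return np.cumsum(steps)


def gsea_es(
    signature: pd.Series,
    gene_set: set[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA enrichment score with a gene-label permutation test.

    The ES is the running-sum value of largest magnitude.  The p-value is
    one-sided in the direction of the observed ES, estimated by drawing
    random gene sets of the same size from the signature:
    p = (1 + #{ES_perm at least as extreme}) / (n_perm + 1), hence in (0, 1].
    A set covering the whole signature is degenerate and flagged.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    hits = set(gene_set) & set(signature.index)
    if not hits:
        raise ValueError("gene set does not intersect the signature")
    if len(hits) == len(signature):
        return GseaResult(0.0, 1.0, 0, seed, len(hits), degenerate=True)

    def extremum(rs: np.ndarray) -> float:
        return float(rs[np.argmax(np.abs(rs))])

    es = extremum(running_sum(signature, hits, weight_p))

    rng = np.random.default_rng(seed)
    genes = np.asarray(signature.index)
    count = 0
    for _ in range(n_perm):
        perm = set(rng.choice(genes, size=len(hits), replace=False))
        es_p = extremum(running_sum(signature, perm, weight_p))
        if (es >= 0 and es_p >= es) or (es < 0 and es_p <= es):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return GseaResult(es, p, n_perm, seed, len(hits))
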
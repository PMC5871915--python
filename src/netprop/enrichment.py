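"""No-network baseline: hypergeometric over-representation of mutated genes.

The comparator to network propagation: select highly mutated genes by a
frequency cutoff, intersect with each pathway, and compute the upper-tail
hypergeometric p-value P(X >= k) for the overlap k given universe size N,
pathway size K and selection size n.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .scoring import MutationCohort, PathwayCollection

__all__ = ["select_highly_mutated", "hypergeom_pvalue", "enrich", "write_enrichment"]

# Most recurrently altered genes in large tumor cohorts fall below 5%
# per-gene frequency, so this default deliberately sits at that boundary.
DEFAULT_MIN_FREQ = 0.05


def select_highly_mutated(
    cohort: MutationCohort, min_freq: float = DEFAULT_MIN_FREQ, top_n: int | None = None
) -> frozenset[str]:
    """Genes with cohort mutation frequency >= ``min_freq``.

    ``top_n`` instead selects the n most frequent genes (ties broken
    lexicographically for determinism).
    """
    if not 0 < min_freq <= 1:
        raise ValueError(f"min_freq must lie in (0, 1], got {min_freq}")
    freq = cohort.frequencies()
    if top_n is not None:
        order = freq.sort_index().sort_values(ascending=False, kind="stable")
        return frozenset(order.index[:top_n])
    return frozenset(freq.index[freq >= min_freq])


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` = universe size, ``K`` = pathway genes in the universe, ``n`` =
    selected genes, ``k`` = overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    selected: frozenset[str] | set[str],
    pathways: PathwayCollection,
    universe: frozenset[str] | set[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``selected`` genes in each pathway.

    Pathway genes are intersected with the universe first.  Rows are ordered
    by p-value then pathway name.  Columns: ``pathway, N, K, n, k,
    p_hypergeom``.
    """
    offenders = set(selected) - set(universe)
    if offenders:
        raise ValueError(
            f"selected genes outside the universe: {sorted(offenders)[:10]}"
        )
    N = len(universe)
    n = len(selected)
    rows = []
    for name in pathways.names():
        in_universe = pathways[name] & universe
        K = len(in_universe)
        k = len(in_universe & selected)
        rows.append((name, N, K, n, k, hypergeom_pvalue(k, K, n, N)))
    df = pd.DataFrame(rows, columns=["pathway", "N", "K", "n", "k", "p_hypergeom"])
    return df.sort_values(["p_hypergeom", "pathway"], kind="stable").reset_index(drop=True)


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
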
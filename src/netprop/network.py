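"""Gene interaction networks, symmetric normalization, and label propagation.

The central object is the normalized adjacency matrix

    S = D^{-1/2} W D^{-1/2}

where ``W`` is the (weighted) adjacency matrix of an undirected gene network
and ``D`` the diagonal matrix of weighted degrees.  Label propagation spreads
a non-negative seed vector ``f0`` (mutation frequencies, or a single patient's
normalized mutation indicator) to the fixed point of

    f <- lam * S @ f + (1 - lam) * f0

which exists and is unique for lam in (0, 1) because the spectral radius of S
is at most 1.  The closed form f = (1 - lam) (I - lam S)^{-1} f0 is available
as :func:`propagate_exact` and serves as an internal oracle for the iterative
solver.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "PropagationOperator",
    "SeedVector",
    "StationaryScores",
    "load_network",
    "normalize_adjacency",
    "propagate",
    "propagate_exact",
    "write_scores",
]


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed."""


@dataclass(frozen=True)
class GeneNetwork:
    """Undirected weighted gene graph.

    ``nodes`` is lexicographically sorted so matrix representations are
    reproducible.  ``edges`` maps unordered pairs (stored with the
    lexicographically smaller gene first) to non-negative weights.  Self-loops
    are rejected at construction.
    """

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if list(self.nodes) != sorted(self.nodes):
            object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a > b:
                raise ValueError(f"edge key ({a!r}, {b!r}) not in canonical order")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            if not (w >= 0):
                raise ValueError(f"negative weight on edge ({a!r}, {b!r}): {w}")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
    ) -> "GeneNetwork":
        """Build a network from an edge iterable, applying ingestion rules.

        Duplicate edges (in either orientation) are collapsed keeping the
        maximum weight; self-loops are dropped with a warning; isolated nodes
        can be supplied through ``extra_nodes``.
        """
        nodes: set[str] = set(extra_nodes)
        collapsed: dict[tuple[str, str], float] = {}
        n_self = 0
        for item in edges:
            if len(item) == 2:
                a, b = item  # type: ignore[misc]
                w = 1.0
            else:
                a, b, w = item  # type: ignore[misc]
            w = float(w)
            if w < 0:
                raise ValueError(f"negative weight on edge ({a!r}, {b!r}): {w}")
            nodes.add(a)
            nodes.add(b)
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a < b else (b, a)
            prev = collapsed.get(key)
            if prev is None or w > prev:
                collapsed[key] = w
        if n_self:
            logger.warning("dropped %d self-loop edge(s)", n_self)
        return cls(nodes=tuple(sorted(nodes)), edges=collapsed)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix in the node order."""
        n = self.n_nodes
        idx = self.node_index()
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for (a, b), w in self.edges.items():
            i, j = idx[a], idx[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


@dataclass(frozen=True)
class PropagationOperator:
    """Normalized symmetric adjacency S with its gene index.

    Rows and columns of zero-degree genes are identically zero, so such genes
    retain (1 - lam) of their seed mass under propagation instead of being
    dropped.
    """

    S: sp.csr_matrix
    nodes: tuple[str, ...]
    zero_degree_nodes: frozenset[str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def laplacian(self) -> sp.csr_matrix:
        """Normalized graph Laplacian L = I - S."""
        return sp.identity(self.n_nodes, format="csr") - self.S


@dataclass(frozen=True)
class SeedVector:
    """Non-negative seed scores f0 over genes.

    ``cohort_frequency`` mode holds per-gene mutation frequencies in [0, 1];
    ``patient_indicator`` mode holds a single patient's mutated-gene indicator
    normalized to sum to 1.
    """

    values: Mapping[str, float]
    mode: str  # "cohort_frequency" | "patient_indicator"

    def __post_init__(self) -> None:
        if self.mode not in ("cohort_frequency", "patient_indicator"):
            raise ValueError(f"unknown seed mode {self.mode!r}")
        for g, v in self.values.items():
            if not (v >= 0):
                raise ValueError(f"negative seed value for {g!r}: {v}")
            if self.mode == "cohort_frequency" and v > 1:
                raise ValueError(f"frequency above 1 for {g!r}: {v}")
        if self.mode == "patient_indicator" and self.values:
            total = math.fsum(self.values.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"patient_indicator seed sums to {total}, not 1")


@dataclass(frozen=True)
class StationaryScores:
    """Converged propagation scores f, indexed by gene."""

    values: pd.Series  # float, index = genes in operator order
    lambda_: float
    iterations: int  # 0 when obtained by closed-form solve

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy()


def _parse_weight(tok: str, lineno: int) -> float:
    try:
        w = float(tok)
    except ValueError as exc:
        raise NetworkParseError(f"line {lineno}: non-numeric weight {tok!r}") from exc
    if w < 0:
        raise ValueError(f"line {lineno}: negative weight {w}")
    return w


def load_network(path, fmt: str = "edge_list_tsv") -> GeneNetwork:
    """Read a gene network from disk.

    Parameters
    ----------
    path
        TSV file.  ``edge_list_tsv``: ``gene_a<TAB>gene_b[<TAB>weight]`` with
        ``#`` comment lines; a single-column line declares an isolated node;
        ``sif``: ``gene_a<TAB>relation<TAB>gene_b`` (the relation label is
        ignored, weight 1).
    """
    if fmt not in ("edge_list_tsv", "sif"):
        raise ValueError(f"unknown network format {fmt!r}")
    edges: list[tuple[str, str, float]] = []
    isolated: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate whitespace-separated input
                parts = line.split()
            if fmt == "sif":
                if len(parts) != 3:
                    raise NetworkParseError(
                        f"line {lineno}: expected 3 SIF columns, got {len(parts)}"
                    )
                a, _, b = parts
                w = 1.0
            else:
                if len(parts) == 1:
                    isolated.append(parts[0])
                    continue
                if len(parts) == 2:
                    a, b = parts
                    w = 1.0
                elif len(parts) == 3:
                    a, b = parts[0], parts[1]
                    w = _parse_weight(parts[2], lineno)
                else:
                    raise NetworkParseError(
                        f"line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                    )
            if not a or not b:
                raise NetworkParseError(f"line {lineno}: empty gene identifier")
            edges.append((a, b, w))
    return GeneNetwork.from_edges(edges, extra_nodes=isolated)


def normalize_adjacency(net: GeneNetwork) -> PropagationOperator:
    """Symmetric normalization S = D^{-1/2} W D^{-1/2}.

    Zero-degree genes keep all-zero rows and columns rather than being
    removed, so their stationary score under propagation is (1-lam)*seed.
    """
    if net.n_nodes < 1:
        raise ValueError("network has no nodes")
    W = net.adjacency().astype(float)
    deg = np.asarray(W.sum(axis=1)).ravel()
    zero = deg == 0
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(zero, 0.0, 1.0 / np.sqrt(np.where(zero, 1.0, deg)))
    D = sp.diags(d_inv_sqrt)
    S = (D @ W @ D).tocsr()
    return PropagationOperator(
        S=S,
        nodes=net.nodes,
        zero_degree_nodes=frozenset(np.array(net.nodes)[zero].tolist()),
    )


def seed_array(op: PropagationOperator, seed: SeedVector) -> np.ndarray:
    """Align a seed vector to the operator's gene order.

    Seed genes absent from the network are dropped (count logged); network
    genes absent from the seed get 0.
    """
    idx = op.node_index()
    f0 = np.zeros(op.n_nodes)
    dropped = 0
    for g, v in seed.values.items():
        i = idx.get(g)
        if i is None:
            dropped += 1
        else:
            f0[i] = v
    if dropped:
        logger.info("dropped %d seed gene(s) absent from the network", dropped)
    return f0


def _effective_lambda(lambda_: float, lambda_convention: str) -> float:
    if lambda_convention == "network":
        return lambda_
    if lambda_convention == "seed":
        return 1.0 - lambda_
    raise ValueError(f"unknown lambda_convention {lambda_convention!r}")


def propagate(
    op: PropagationOperator,
    seed: SeedVector,
    lambda_: float = 0.5,
    tol: float = 1e-9,
    max_iter: int = 1000,
    lambda_convention: str = "network",
) -> StationaryScores:
    """Iterative label propagation to the stationary scores.

    Repeats ``f <- lam*S@f + (1-lam)*f0`` from ``f0`` until the max-norm
    change between iterates falls below ``tol``.  Convergence is guaranteed
    for lam in (0, 1) since lam * rho(S) < 1; failure to converge within
    ``max_iter`` therefore signals numerical misuse and raises.

    ``lambda_convention='network'`` means ``lambda_`` weights the network term
    (the default); ``'seed'`` uses the complementary convention.
    """
    if not 0 < lambda_ < 1:
        raise ValueError(f"lambda_ must lie in (0, 1), got {lambda_}")
    lam = _effective_lambda(lambda_, lambda_convention)
    f0 = seed_array(op, seed)
    f = f0.copy()
    for it in range(1, max_iter + 1):
        f_next = lam * (op.S @ f) + (1.0 - lam) * f0
        delta = np.max(np.abs(f_next - f)) if f.size else 0.0
        f = f_next
        if delta <= tol:
            return StationaryScores(
                values=pd.Series(f, index=list(op.nodes)),
                lambda_=lambda_,
                iterations=it,
            )
    raise RuntimeError(
        f"propagation did not converge in {max_iter} iterations "
        f"(last max-norm residual {delta:.3e})"
    )


def propagate_exact(
    op: PropagationOperator,
    seed: SeedVector,
    lambda_: float = 0.5,
    lambda_convention: str = "network",
    max_nodes: int = 20_000,
) -> StationaryScores:
    """Closed-form stationary scores: solve (I - lam S) f = (1-lam) f0.

    Direct linear solve; guarded to networks of at most ``max_nodes`` nodes.
    Used by the test suite as the oracle for :func:`propagate`.
    """
    if not 0 < lambda_ < 1:
        raise ValueError(f"lambda_ must lie in (0, 1), got {lambda_}")
    if op.n_nodes > max_nodes:
        raise ValueError(
            f"network has {op.n_nodes} nodes, above the direct-solve guard of {max_nodes}"
        )
    lam = _effective_lambda(lambda_, lambda_convention)
    f0 = seed_array(op, seed)
    A = sp.identity(op.n_nodes, format="csc") - lam * op.S.tocsc()
    f = spla.spsolve(A, (1.0 - lam) * f0)
    f = np.atleast_1d(np.asarray(f, dtype=float))
    return StationaryScores(
        values=pd.Series(f, index=list(op.nodes)), lambda_=lambda_, iterations=0
    )


def write_scores(scores: StationaryScores, path) -> None:
    """Write stationary scores as ``gene<TAB>score`` at full (repr) precision."""
    with open(path, "w") as fh:
        fh.write("gene\tscore\n")
        for gene, val in scores.values.items():
            fh.write(f"{gene}\t{val!r}\n")


def read_scores(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["score"].astype(float)
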
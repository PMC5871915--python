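"""Pathway scoring from propagated mutation signals.

A pathway's score is the sum of the stationary propagation scores of its
member genes.  Significance is assessed empirically against random gene sets
of the same (network-mapped) size drawn uniformly without replacement from
the network's gene universe, with the add-one convention

    p = (#{null >= observed} + 1) / (n_null + 1)

so the smallest attainable p-value is 1/(n_null + 1).  High propagated scores
indicate mutation enrichment, hence the upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import (
    PropagationOperator,
    SeedVector,
    StationaryScores,
    propagate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCohort",
    "PathwayCollection",
    "load_mutations",
    "load_gmt",
    "write_gmt",
    "cohort_seed",
    "patient_seed",
    "pathway_score",
    "empirical_null",
    "empirical_pvalue",
    "score_all_pathways",
    "write_score_table",
]

DEFAULT_N_NULL = 10_000
COHORT_LAMBDA = 0.5
PATIENT_LAMBDA = 0.1


@dataclass(frozen=True)
class MutationCohort:
    """Binary somatic-mutation matrix: samples x genes, 1 = mutated."""

    samples: tuple[str, ...]
    genes: tuple[str, ...]
    M: np.ndarray  # (n_samples, n_genes) int8 in {0, 1}

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if self.M.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.M.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )
        bad = ~np.isin(self.M, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at sample {self.samples[i]!r}, "
                f"gene {self.genes[j]!r}: {self.M[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def frequencies(self) -> pd.Series:
        """Per-gene mutation frequency across samples."""
        if self.n_samples == 0:
            raise ValueError("cohort has no samples")
        return pd.Series(self.M.mean(axis=0), index=list(self.genes))

    def mutated_genes(self, sample_id: str) -> tuple[str, ...]:
        try:
            i = self.samples.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"unknown sample ID {sample_id!r}") from exc
        return tuple(g for g, m in zip(self.genes, self.M[i]) if m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=list(self.samples), columns=list(self.genes))


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets (GMT-style)."""

    pathways: dict[str, frozenset[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} is empty")

    def __len__(self) -> int:
        return len(self.pathways)

    def names(self) -> tuple[str, ...]:
        return tuple(self.pathways)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.pathways[name]


def load_mutations(path, fmt: str = "matrix_tsv") -> MutationCohort:
    """Read somatic mutations as a binary cohort matrix.

    ``matrix_tsv``: samples in rows, genes in columns, 0/1 cells.
    ``maf_lite``: TSV with at least ``Hugo_Symbol`` and
    ``Tumor_Sample_Barcode`` columns; rows are aggregated to binary presence
    per (sample, gene).
    """
    if fmt == "matrix_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        vals = df.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at row {df.index[i]!r}, column {df.columns[j]!r}: "
                f"{vals[i, j]!r}"
            )
        df = df.sort_index(axis=0).sort_index(axis=1)
        return MutationCohort(
            samples=tuple(str(s) for s in df.index),
            genes=tuple(str(g) for g in df.columns),
            M=df.to_numpy(dtype=np.int8),
        )
    if fmt == "maf_lite":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"Hugo_Symbol", "Tumor_Sample_Barcode"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"MAF file missing required column(s): {sorted(missing)}")
        if df.empty:
            logger.warning("empty MAF body: cohort has 0 samples")
            return MutationCohort(samples=(), genes=(), M=np.zeros((0, 0), np.int8))
        samples = tuple(sorted(df["Tumor_Sample_Barcode"].unique()))
        genes = tuple(sorted(df["Hugo_Symbol"].unique()))
        s_idx = {s: i for i, s in enumerate(samples)}
        g_idx = {g: i for i, g in enumerate(genes)}
        M = np.zeros((len(samples), len(genes)), np.int8)
        for s, g in zip(df["Tumor_Sample_Barcode"], df["Hugo_Symbol"]):
            M[s_idx[s], g_idx[g]] = 1
        return MutationCohort(samples=samples, genes=genes, M=M)
    raise ValueError(f"unknown mutation format {fmt!r}")


def write_mutations(cohort: MutationCohort, path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index_label="sample")


def load_gmt(path) -> PathwayCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"line {lineno}: GMT line needs name, description and >=1 gene"
                )
            name = parts[0]
            if name in pathways:
                raise ValueError(f"line {lineno}: duplicate pathway name {name!r}")
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise ValueError(f"line {lineno}: pathway {name!r} has no genes")
            pathways[name] = genes
    return PathwayCollection(pathways=pathways, source=str(path))


def write_gmt(pathways: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in pathways.pathways.items():
            fh.write(name + "\t" + (pathways.source or "na") + "\t")
            fh.write("\t".join(sorted(genes)) + "\n")


def cohort_seed(cohort: MutationCohort) -> SeedVector:
    """Seed = per-gene mutation frequency across the cohort."""
    freq = cohort.frequencies()
    return SeedVector(values=freq.to_dict(), mode="cohort_frequency")


def patient_seed(
    cohort: MutationCohort, sample_id: str, network_genes: set[str] | None = None
) -> SeedVector | None:
    """Seed = the patient's mutated-gene indicator, normalized to sum to 1.

    If ``network_genes`` is given and none of the patient's mutations map to
    it, returns ``None`` (skip sentinel) and logs, so the patient can be
    excluded from downstream per-patient matrices.
    """
    genes = cohort.mutated_genes(sample_id)
    if network_genes is not None:
        genes = tuple(g for g in genes if g in network_genes)
    if not genes:
        logger.warning(
            "sample %r has no network-mapped mutations; skipped", sample_id
        )
        return None
    v = 1.0 / len(genes)
    return SeedVector(values={g: v for g in genes}, mode="patient_indicator")


def pathway_score(scores: StationaryScores, genes: frozenset[str] | set[str]) -> tuple[float, int]:
    """Sum of stationary scores over the pathway's network-mapped genes.

    Returns ``(score, n_genes_in_network)``; genes absent from the network
    contribute 0 and are not counted as mapped.
    """
    present = scores.values.index.intersection(list(genes))
    return float(scores.values.loc[present].sum()), len(present)


def empirical_null(
    scores: StationaryScores,
    set_size: int,
    n_null: int = DEFAULT_N_NULL,
    rng_seed: int = 0,
) -> np.ndarray:
    """Scores of ``n_null`` random gene sets of size ``set_size``.

    Each set is drawn uniformly without replacement from the network's gene
    universe (every gene carrying a stationary score).  Reproducible given
    ``rng_seed``; the stream is keyed on (rng_seed, set_size) so pathways of
    equal size share one null regardless of evaluation order.
    """
    vals = scores.as_array()
    n_genes = vals.size
    if set_size > n_genes:
        raise ValueError(f"set_size {set_size} exceeds universe of {n_genes} genes")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if set_size == 0:
        return np.zeros(n_null)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, set_size]))
    if n_genes <= 4096:
        # vectorized draw: take the set_size smallest of iid uniforms per row
        u = rng.random((n_null, n_genes))
        idx = np.argpartition(u, set_size - 1, axis=1)[:, :set_size]
        return vals[idx].sum(axis=1)
    return np.array(
        [vals[rng.choice(n_genes, size=set_size, replace=False)].sum() for _ in range(n_null)]
    )


def empirical_pvalue(observed: float, null: Sequence[float] | np.ndarray) -> float:
    """Upper-tail add-one empirical p-value: (#{null >= observed}+1)/(N+1)."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    r = int(np.sum(null >= observed))
    return (r + 1) / (null.size + 1)


@dataclass
class _NullCache:
    scores: StationaryScores
    n_null: int
    rng_seed: int
    _cache: dict[int, np.ndarray] = field(default_factory=dict)

    def get(self, set_size: int) -> np.ndarray:
        if set_size not in self._cache:
            self._cache[set_size] = empirical_null(
                self.scores, set_size, self.n_null, self.rng_seed
            )
        return self._cache[set_size]


def score_pathways(
    scores: StationaryScores,
    pathways: PathwayCollection,
    n_null: int = DEFAULT_N_NULL,
    rng_seed: int = 0,
    min_mapped_size: int = 5,
    match_annotated_size: bool = False,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Score every pathway against size-matched empirical nulls.

    Pathways with fewer than ``min_mapped_size`` network-mapped genes are
    dropped.  Null sets are matched on the network-mapped size by default
    (unmapped genes contribute 0 to both observed and null scores); set
    ``match_annotated_size=True`` to match on the annotated size instead.
    Returns a table with columns
    ``pathway, n_genes, n_in_network, score, p_empirical, n_null``
    (plus ``q_bh`` when ``bh_adjust``).
    """
    cache = _NullCache(scores=scores, n_null=n_null, rng_seed=rng_seed)
    universe = scores.values.index.size
    rows = []
    for name in pathways.names():
        genes = pathways[name]
        obs, n_mapped = pathway_score(scores, genes)
        if n_mapped < min_mapped_size:
            continue
        size = len(genes) if match_annotated_size else n_mapped
        size = min(size, universe)
        p = empirical_pvalue(obs, cache.get(size))
        rows.append((name, len(genes), n_mapped, obs, p, n_null))
    df = pd.DataFrame(
        rows,
        columns=["pathway", "n_genes", "n_in_network", "score", "p_empirical", "n_null"],
    )
    if bh_adjust and len(df):
        from scipy.stats import false_discovery_control

        df["q_bh"] = false_discovery_control(df["p_empirical"], method="bh")
    return df


def score_all_pathways(
    cohort: MutationCohort,
    op: PropagationOperator,
    pathways: PathwayCollection,
    mode: str = "cohort",
    sample_id: str | None = None,
    lambda_: float | None = None,
    n_null: int = DEFAULT_N_NULL,
    rng_seed: int = 0,
    min_mapped_size: int = 5,
    tol: float = 1e-9,
    **kwargs,
) -> pd.DataFrame | None:
    """Propagate a cohort- or patient-level seed and score all pathways.

    ``mode='cohort'`` seeds with per-gene mutation frequencies (default
    lambda 0.5); ``mode='patient'`` seeds with ``sample_id``'s normalized
    mutation indicator (default lambda 0.1).  Returns ``None`` for a patient
    with no network-mapped mutations.
    """
    if mode == "cohort":
        if lambda_ is None:
            lambda_ = COHORT_LAMBDA
        seed = cohort_seed(cohort)
    elif mode == "patient":
        if sample_id is None:
            raise ValueError("patient mode requires sample_id")
        if lambda_ is None:
            lambda_ = PATIENT_LAMBDA
        seed = patient_seed(cohort, sample_id, network_genes=set(op.nodes))
        if seed is None:
            return None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    stationary = propagate(op, seed, lambda_=lambda_, tol=tol)
    return score_pathways(
        stationary,
        pathways,
        n_null=n_null,
        rng_seed=rng_seed,
        min_mapped_size=min_mapped_size,
        **kwargs,
    )


def per_patient_tables(
    cohort: MutationCohort,
    op: PropagationOperator,
    pathways: PathwayCollection,
    lambda_: float = PATIENT_LAMBDA,
    n_null: int = DEFAULT_N_NULL,
    rng_seed: int = 0,
    min_mapped_size: int = 5,
) -> dict[str, pd.DataFrame]:
    """Per-patient pathway score tables; patients without network-mapped
    mutations are skipped (logged inside :func:`patient_seed`)."""
    out: dict[str, pd.DataFrame] = {}
    for s in cohort.samples:
        tab = score_all_pathways(
            cohort,
            op,
            pathways,
            mode="patient",
            sample_id=s,
            lambda_=lambda_,
            n_null=n_null,
            rng_seed=rng_seed,
            min_mapped_size=min_mapped_size,
        )
        if tab is not None:
            out[s] = tab
    return out


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
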
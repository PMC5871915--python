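"""Patient stratification from pathway p-value profiles and survival comparison.

Per-patient pathway p-values become a patients x pathways feature matrix of
-log10(p); patients are clustered hierarchically; subgroup survival is
compared with the standard two-sample log-rank test, implemented from first
principles (at-risk tables, hypergeometric variance at each event time) so a
permutation oracle can validate it in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chi2

__all__ = [
    "PatientPathwayMatrix",
    "LogRankResult",
    "build_feature_matrix",
    "hierarchical_cluster",
    "logrank_test",
    "kaplan_meier",
    "run_case_study",
    "load_clinical",
    "CaseStudyResult",
]


@dataclass(frozen=True)
class PatientPathwayMatrix:
    """samples x pathways matrix of -log10 empirical p-values."""

    samples: tuple[str, ...]
    pathway_names: tuple[str, ...]
    F: np.ndarray  # (n_samples, n_pathways) floats >= 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.F, index=list(self.samples), columns=list(self.pathway_names)
        )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    groups_compared: tuple[frozenset, frozenset]


def build_feature_matrix(per_patient_tables: dict[str, pd.DataFrame]) -> PatientPathwayMatrix:
    """Assemble per-patient pathway tables into a -log10(p) feature matrix.

    All tables must cover an identical pathway list; a mismatch raises naming
    the difference.  Sample and pathway order is deterministic (sample order
    sorted, pathway order taken from the tables).
    """
    if not per_patient_tables:
        raise ValueError("no per-patient tables supplied")
    samples = tuple(sorted(per_patient_tables))
    ref = tuple(per_patient_tables[samples[0]]["pathway"])
    rows = []
    for s in samples:
        tab = per_patient_tables[s]
        names = tuple(tab["pathway"])
        if names != ref:
            missing = set(ref) ^ set(names)
            raise ValueError(
                f"pathway list of sample {s!r} differs from {samples[0]!r}: "
                f"symmetric difference {sorted(missing)[:10]}"
            )
        rows.append(-np.log10(tab["p_empirical"].to_numpy(dtype=float)))
    return PatientPathwayMatrix(samples=samples, pathway_names=ref, F=np.vstack(rows))


def hierarchical_cluster(
    fm: PatientPathwayMatrix,
    k: int = 3,
    linkage_method: str = "ward",
    metric: str = "euclidean",
) -> dict[str, int]:
    """Hierarchical clustering of patients into ``k`` groups.

    Labels run 1..k and are stabilized so that group 1 is the cluster whose
    centroid has the largest mean feature, descending from there (ties broken
    by first sample order); the raw dendrogram cut order is arbitrary, so
    this makes labels comparable across reruns.
    """
    n = len(fm.samples)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if linkage_method not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        d = pdist(fm.F, metric=metric)
        Z = linkage(d, method=linkage_method)
        raw = fcluster(Z, t=k, criterion="maxclust")
    # stable relabeling: rank clusters by centroid mean feature, descending
    stats = []
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        stats.append((-fm.F[members].mean(), members[0], lab))
    stats.sort()
    remap = {old: new for new, (_, _, old) in enumerate(stats, start=1)}
    return {s: remap[lab] for s, lab in zip(fm.samples, raw)}


def load_clinical(path) -> pd.DataFrame:
    """Read a clinical TSV ``sample<TAB>time<TAB>event``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    if (df["time"] < 0).any():
        raise ValueError("negative survival time")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return df


def _logrank_arrays(
    time_a: np.ndarray, event_a: np.ndarray, time_b: np.ndarray, event_b: np.ndarray
) -> float:
    times = np.concatenate([time_a, time_b])
    events = np.concatenate([event_a, event_b]).astype(bool)
    is_a = np.concatenate([np.ones(time_a.size, bool), np.zeros(time_b.size, bool)])
    event_times = np.unique(times[events])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n_risk = int(at_risk.sum())
        n_risk_a = int((at_risk & is_a).sum())
        d = int((events & (times == t)).sum())  # events at t, both groups
        d_a = int((events & (times == t) & is_a).sum())
        e_a = d * n_risk_a / n_risk
        o_minus_e += d_a - e_a
        if n_risk > 1:
            var += (
                d
                * (n_risk_a / n_risk)
                * (1 - n_risk_a / n_risk)
                * (n_risk - d)
                / (n_risk - 1)
            )
    if var == 0.0:
        chi = 0.0
    else:
        chi = o_minus_e**2 / var
    return chi


def logrank_test(
    records: pd.DataFrame,
    group_a: set | frozenset | int,
    group_b: set | frozenset | int,
) -> LogRankResult:
    """Standard two-sample log-rank test between (pooled) groups.

    ``records`` needs columns ``time``, ``event`` and ``group``; ``group_a``
    and ``group_b`` are group labels or sets of labels (sets express pooled
    comparisons such as "group 1 + group 2 vs group 3").  The statistic is
    (sum O - E)^2 / sum Var with the hypergeometric variance at each distinct
    event time; p-value from the chi-square(1) upper tail.
    """
    ga = frozenset(group_a) if isinstance(group_a, (set, frozenset)) else frozenset([group_a])
    gb = frozenset(group_b) if isinstance(group_b, (set, frozenset)) else frozenset([group_b])
    if ga & gb:
        raise ValueError(f"groups overlap: {sorted(ga & gb)}")
    sub_a = records[records["group"].isin(ga)]
    sub_b = records[records["group"].isin(gb)]
    if sub_a.empty or sub_b.empty:
        raise ValueError("both pooled groups must contain at-risk samples")
    chi = _logrank_arrays(
        sub_a["time"].to_numpy(float),
        sub_a["event"].to_numpy(int),
        sub_b["time"].to_numpy(float),
        sub_b["event"].to_numpy(int),
    )
    p = float(chi2.sf(chi, df=1)) if chi > 0 else 1.0
    return LogRankResult(chi_square=float(chi), df=1, p_value=p, groups_compared=(ga, gb))


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as step-function coordinates.

    Returns a table with columns ``time`` and ``survival`` starting at
    (0, 1.0); survival drops only at observed event times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int).astype(bool)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    out_t, out_s = [0.0], [1.0]
    s = 1.0
    for t in np.unique(times[events]):
        n_risk = int((times >= t).sum())
        d = int((events & (times == t)).sum())
        s *= 1.0 - d / n_risk
        out_t.append(float(t))
        out_s.append(s)
    return pd.DataFrame({"time": out_t, "survival": out_s})


@dataclass(frozen=True)
class CaseStudyResult:
    features: PatientPathwayMatrix
    labels: dict[str, int]
    logrank: dict[str, LogRankResult]
    km_curves: pd.DataFrame  # columns: group, time, survival
    records: pd.DataFrame  # sample, time, event, group


def run_case_study(
    cohort,
    op,
    pathways,
    clinical: pd.DataFrame,
    k: int = 3,
    lambda_: float = 0.1,
    n_null: int = 10_000,
    rng_seed: int = 0,
    linkage_method: str = "ward",
    metric: str = "euclidean",
    min_mapped_size: int = 5,
) -> CaseStudyResult:
    """Per-patient propagation -> pathway p-values -> clustering -> survival.

    Patients lacking network-mapped mutations or clinical records are
    excluded.  Emits the feature matrix, stabilized cluster labels, pairwise
    and pooled log-rank results, and Kaplan-Meier step coordinates per group.
    """
    from .scoring import per_patient_tables

    tables = per_patient_tables(
        cohort,
        op,
        pathways,
        lambda_=lambda_,
        n_null=n_null,
        rng_seed=rng_seed,
        min_mapped_size=min_mapped_size,
    )
    clin = clinical.set_index("sample")
    tables = {s: t for s, t in tables.items() if s in clin.index}
    fm = build_feature_matrix(tables)
    labels = hierarchical_cluster(fm, k=k, linkage_method=linkage_method, metric=metric)
    records = pd.DataFrame(
        {
            "sample": list(fm.samples),
            "time": clin.loc[list(fm.samples), "time"].to_numpy(float),
            "event": clin.loc[list(fm.samples), "event"].to_numpy(int),
            "group": [labels[s] for s in fm.samples],
        }
    )
    present = sorted(set(labels.values()))
    logrank: dict[str, LogRankResult] = {}
    for i, a in enumerate(present):
        for b in present[i + 1 :]:
            logrank[f"{a}_vs_{b}"] = logrank_test(records, a, b)
    if len(present) >= 3:
        last = present[-1]
        rest = frozenset(present[:-1])
        name = "+".join(str(g) for g in sorted(rest)) + f"_vs_{last}"
        logrank[name] = logrank_test(records, rest, last)
    km_parts = []
    for g in present:
        sub = records[records["group"] == g]
        curve = kaplan_meier(sub["time"].to_numpy(), sub["event"].to_numpy())
        curve.insert(0, "group", g)
        km_parts.append(curve)
    km = pd.concat(km_parts, ignore_index=True)
    return CaseStudyResult(
        features=fm, labels=labels, logrank=logrank, km_curves=km, records=records
    )
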
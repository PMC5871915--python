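"""Reproducible validation experiments for the propagation pipeline.

Each routine builds its own synthetic inputs from an integer seed, runs the
pipeline exactly as a user would, and returns measured quantities: solver
agreement, null-model calibration, detection power of the network arm versus
the hypergeometric baseline, log-rank validity, and subgroup recovery with
survival separation.  The test suite asserts on these numbers and the
acceptance script reports them, so the experiments live here, in one place.
"""

from __future__ import annotations

import tempfile
from fractions import Fraction
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .network import GeneNetwork, SeedVector, normalize_adjacency, propagate, propagate_exact
from .scoring import cohort_seed, score_all_pathways
from .enrichment import enrich, hypergeom_pvalue, select_highly_mutated
from .simulate import GroundTruth, ScenarioConfig, generate_scenario, generate_survival, write_scenario
from .stratification import logrank_test, run_case_study

__all__ = [
    "propagation_oracle_gap",
    "single_edge_example",
    "null_calibration",
    "detection_power",
    "hypergeom_enumeration_error",
    "logrank_mirror_statistic",
    "logrank_type1_error",
    "logrank_permutation_check",
    "subgroup_recovery",
    "determinism_check",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stream]))


def _random_network(rng: np.random.Generator, max_nodes: int) -> GeneNetwork:
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.3))
    genes = [f"N{i:03d}" for i in range(n)]
    edges = [
        (genes[i], genes[j], float(rng.uniform(0.1, 2.0)))
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return GeneNetwork.from_edges(edges, extra_nodes=genes)


def propagation_oracle_gap(n_graphs: int = 100, max_nodes: int = 100, seed: int = 0) -> float:
    """Worst max-norm gap between iterative propagation and the direct solve
    of (I - lam S) f = (1 - lam) f0 over random weighted graphs."""
    worst = 0.0
    for i in range(n_graphs):
        rng = _rng(seed, i)
        net = _random_network(rng, max_nodes)
        op = normalize_adjacency(net)
        sv = SeedVector({g: float(rng.random()) for g in net.nodes}, mode="cohort_frequency")
        lam = float(rng.uniform(0.05, 0.95))
        f_it = propagate(op, sv, lambda_=lam, tol=1e-12)
        f_ex = propagate_exact(op, sv, lambda_=lam)
        worst = max(worst, float(np.max(np.abs(f_it.as_array() - f_ex.as_array()))))
    return worst


def single_edge_example() -> tuple[float, float]:
    """Stationary scores for a single unit edge, seed (1, 0), lam = 0.5.

    The fixed point of f = 0.5*S f + 0.5*f0 with S = [[0,1],[1,0]] is
    (2/3, 1/3)."""
    op = normalize_adjacency(GeneNetwork.from_edges([("A", "B")]))
    f = propagate_exact(op, SeedVector({"A": 1.0}, mode="patient_indicator"), 0.5)
    return float(f.values["A"]), float(f.values["B"])


def null_calibration(
    n_decoys: int = 200, n_null: int = 1000, seed: int = 0
) -> float:
    """Fraction of decoy-pathway empirical p-values at or below 0.05 on a
    cohort with no planted driver signal (passenger mutations only).

    Decoy gene sets are uniform random draws, so their p-values should be
    uniform and the fraction should sit near 0.05."""
    cfg = ScenarioConfig(
        seed=int(_rng(seed, 100).integers(2**31)),
        driver_patient_rate=0.0,
        passenger_rate=0.02,  # enough passenger signal for a non-trivial seed
        n_pathways=n_decoys,
        pathway_module_overlap=0.0,
        n_subgroups=1,
        hazard_per_subgroup=(1.0,),
    )
    net, decoys, cohort, _, _ = generate_scenario(cfg)
    op = normalize_adjacency(net)
    tab = score_all_pathways(
        cohort, op, decoys, mode="cohort", n_null=n_null,
        rng_seed=int(_rng(seed, 101).integers(2**31)),
    )
    return float((tab["p_empirical"] <= 0.05).mean())


def detection_power(
    n_cohorts: int = 50, n_null: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Detection power for a planted, mutually exclusive driver pathway.

    For each simulated cohort (driver genes each under 5% marginal
    frequency), the driver pathway counts as detected when its p-value is at
    most ``alpha`` — by network propagation scoring, and by the no-network
    hypergeometric baseline on genes above 5% cohort frequency.  Returns
    (power_network, power_baseline)."""
    det_net = det_base = 0
    for i in range(n_cohorts):
        cfg = ScenarioConfig(seed=int(_rng(seed, 200 + i).integers(2**31)))
        net, pw, cohort, _, truth = generate_scenario(cfg)
        op = normalize_adjacency(net)
        driver = truth.driver_pathway_per_subgroup[0]
        tab = score_all_pathways(
            cohort, op, pw, mode="cohort", n_null=n_null,
            rng_seed=int(_rng(seed, 500 + i).integers(2**31)),
        ).set_index("pathway")
        det_net += tab.loc[driver, "p_empirical"] <= alpha
        selected = select_highly_mutated(cohort, min_freq=0.05)
        base = enrich(selected, pw, frozenset(cohort.genes)).set_index("pathway")
        det_base += base.loc[driver, "p_hypergeom"] <= alpha
    return det_net / n_cohorts, det_base / n_cohorts


def hypergeom_enumeration_error(max_N: int = 12) -> float:
    """Worst absolute deviation of the hypergeometric upper tail from exact
    enumeration over all n-subsets, for every (N <= max_N, K, n, k)."""
    worst = 0.0
    for N in range(1, max_N + 1):
        for n in range(N + 1):
            subsets = list(combinations(range(N), n))
            for K in range(N + 1):
                overlaps = [sum(x < K for x in s) for s in subsets]
                total = comb(N, n)
                for k in range(min(K, n) + 1):
                    exact = Fraction(sum(o >= k for o in overlaps), total)
                    worst = max(worst, abs(hypergeom_pvalue(k, K, n, N) - float(exact)))
    return worst


def logrank_mirror_statistic() -> float:
    """Log-rank chi-square for two identical groups (must be 0)."""
    rec = pd.DataFrame(
        {"time": [1, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0],
         "group": [1, 1, 1, 2, 2, 2]}
    )
    return logrank_test(rec, 1, 2).chi_square


def logrank_type1_error(
    n_sims: int = 400, n_per_group: int = 40, seed: int = 0, alpha: float = 0.05
) -> float:
    """Rejection rate of the log-rank test when both groups share one
    exponential hazard (with 20% independent censoring)."""
    rejections = 0
    sub = {f"S{j:04d}": j % 2 for j in range(2 * n_per_group)}
    truth = GroundTruth(subgroup_of_sample=sub)
    for i in range(n_sims):
        cfg_i = ScenarioConfig(
            n_patients=2 * n_per_group, n_subgroups=2,
            hazard_per_subgroup=(1.0, 1.0), censor_rate=0.2,
            seed=int(_rng(seed, 300 + i).integers(2**31)),
            n_modules=2, module_size=2, n_pathways=2, pathway_size=2,
        )
        clin = generate_survival(truth, cfg_i)
        rec = pd.DataFrame(
            {"time": clin["time"], "event": clin["event"],
             "group": clin["sample"].map(sub)}
        )
        rejections += logrank_test(rec, 0, 1).p_value <= alpha
    return rejections / n_sims


def logrank_permutation_check() -> float:
    """Worst deviation of the 4-sample toy permutation distribution from its
    exact values.

    Subjects: events at t=1,2 and censorings at t=10,10.  Over the 6 equal
    splits into two groups the statistic takes 49/17 twice (the event pair
    vs the censored pair, and its mirror) and 1/17 four times."""
    subjects = [(1, 1), (2, 1), (10, 0), (10, 0)]
    stats = []
    for idx_a in combinations(range(4), 2):
        rec = pd.DataFrame(
            {"time": [s[0] for s in subjects], "event": [s[1] for s in subjects],
             "group": [1 if i in idx_a else 2 for i in range(4)]}
        )
        stats.append(logrank_test(rec, 1, 2).chi_square)
    expected = sorted([49 / 17, 49 / 17, 1 / 17, 1 / 17, 1 / 17, 1 / 17])
    return float(np.max(np.abs(np.sort(stats) - np.array(expected))))


def _align_labels(pred: list[int], truth: list[int]) -> dict[int, int]:
    """Map emitted cluster labels to planted subgroups by maximal overlap."""
    from scipy.optimize import linear_sum_assignment

    labs, subs = sorted(set(pred)), sorted(set(truth))
    C = np.zeros((len(labs), len(subs)))
    for p, t in zip(pred, truth):
        C[labs.index(p), subs.index(t)] += 1
    rows, cols = linear_sum_assignment(-C)
    return {labs[i]: subs[j] for i, j in zip(rows, cols)}


def subgroup_recovery(
    n_seeds: int = 20, n_null: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Recovery of planted patient subgroups and their survival separation.

    Runs the per-patient pipeline on default 3-subgroup scenarios (distinct
    driver pathway per subgroup, hazard ratio 3 for the last subgroup) and
    returns (mean adjusted Rand index vs planted labels, fraction of runs in
    which the pooled log-rank test of the two baseline-hazard subgroups
    against the high-hazard one rejects at ``alpha``).  Emitted labels are
    aligned to planted subgroups by maximal overlap before pooling, since
    cluster numbering is arbitrary."""
    from sklearn.metrics import adjusted_rand_score

    aris, rejections = [], 0
    for i in range(n_seeds):
        cfg = ScenarioConfig(seed=int(_rng(seed, 400 + i).integers(2**31)))
        net, pw, cohort, clinical, truth = generate_scenario(cfg)
        op = normalize_adjacency(net)
        res = run_case_study(
            cohort, op, pw, clinical, k=3, n_null=n_null,
            rng_seed=int(_rng(seed, 600 + i).integers(2**31)),
        )
        planted = [truth.subgroup_of_sample[s] for s in res.features.samples]
        pred = [res.labels[s] for s in res.features.samples]
        aris.append(adjusted_rand_score(planted, pred))
        mapping = _align_labels(pred, planted)
        aligned = [mapping[p] for p in pred]
        rec = res.records.assign(group=aligned)
        high = cfg.n_subgroups - 1
        others = frozenset(range(high)) & set(aligned)
        if others and high in aligned:
            rejections += logrank_test(rec, others, high).p_value <= alpha
    return float(np.mean(aris)), rejections / n_seeds


def determinism_check(seed: int = 0) -> bool:
    """Same config and seeds twice: scenario bundles and pipeline outputs
    must be byte-identical."""
    cfg = ScenarioConfig(seed=int(_rng(seed, 700).integers(2**31)))
    with tempfile.TemporaryDirectory() as tmp:
        p1 = write_scenario(cfg, Path(tmp) / "a")
        p2 = write_scenario(cfg, Path(tmp) / "b")
        for key in p1:
            if p1[key].read_bytes() != p2[key].read_bytes():
                return False
    net, pw, cohort, clinical, _ = generate_scenario(cfg)
    op = normalize_adjacency(net)
    tabs = [
        score_all_pathways(cohort, op, pw, mode="cohort", n_null=300, rng_seed=5)
        for _ in range(2)
    ]
    if not tabs[0].equals(tabs[1]):
        return False
    runs = [
        run_case_study(cohort, op, pw, clinical, k=3, n_null=200, rng_seed=5)
        for _ in range(2)
    ]
    return (
        runs[0].labels == runs[1].labels
        and np.array_equal(runs[0].features.F, runs[1].features.F)
        and runs[0].km_curves.equals(runs[1].km_curves)
    )
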
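"""Synthetic networks, pathways, mutation cohorts and survival data.

The generator plants the statistical structure the analysis is built to
detect:

* a planted-partition (stochastic block model) gene network with dense
  modules, standing in for a protein-protein interaction network;
* pathway gene sets that overlap network modules by a configurable fraction,
  so pathways are network-coherent without coinciding with modules, plus the
  option of fully random decoy sets (``pathway_module_overlap=0``);
* patient cohorts split into subgroups, each subgroup carrying a driver
  pathway hit mutually exclusively — a driver-hit patient receives EXACTLY
  ONE mutation in a uniformly chosen gene of its subgroup's driver pathway —
  on top of independent per-gene passenger noise.  With the defaults
  (pathway size 20, driver patient rate 0.6) each driver gene's marginal
  mutation frequency is about 0.03, the dispersed sub-5% regime in which
  gene-level frequency tests lose the pathway but propagation keeps it;
* exponential survival times with subgroup-specific hazards and independent
  exponential censoring tuned to an expected censored fraction.

Every generator is a pure function of (config, seed), so fixtures are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import GeneNetwork
from .scoring import MutationCohort, PathwayCollection, write_gmt, write_mutations

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "generate_network",
    "generate_pathways",
    "generate_cohort",
    "generate_survival",
    "generate_scenario",
    "write_scenario",
    "MINI_PRESET",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Defaults describe a 3-subgroup cohort of 120 patients on a 6-module,
    120-gene network, with one driver pathway per subgroup hit at rate 0.6
    (per-gene frequency ~0.03), passenger mutations at a realistic per-gene
    rate of 0.0025, and a three-fold hazard for the last subgroup.
    """

    n_modules: int = 6
    module_size: int = 20
    p_in: float = 0.3
    p_out: float = 0.01
    n_pathways: int = 15
    pathway_size: int = 20
    pathway_module_overlap: float = 0.8
    n_patients: int = 120
    n_subgroups: int = 3
    driver_pathway_per_subgroup: tuple[str, ...] | None = None
    driver_patient_rate: float = 0.6
    passenger_rate: float = 0.0025
    hazard_per_subgroup: tuple[float, ...] = (1.0, 1.0, 3.0)
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "pathway_module_overlap", "driver_patient_rate",
                     "passenger_rate", "censor_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.module_size < 2 or self.pathway_size < 2:
            raise ValueError("module_size and pathway_size must be >= 2")
        if len(self.hazard_per_subgroup) != self.n_subgroups:
            raise ValueError("need one hazard per subgroup")
        if any(h <= 0 for h in self.hazard_per_subgroup):
            raise ValueError("hazards must be positive")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.module_size

    def drivers(self) -> tuple[str, ...]:
        """Driver pathway name per subgroup (default: the first n_subgroups
        pathways, which are module-aligned by construction)."""
        if self.driver_pathway_per_subgroup is not None:
            return self.driver_pathway_per_subgroup
        return tuple(_pathway_name(i) for i in range(self.n_subgroups))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["driver_pathway_per_subgroup"] = list(self.drivers())
        d["hazard_per_subgroup"] = list(self.hazard_per_subgroup)
        return d


MINI_PRESET = ScenarioConfig(
    n_modules=2,
    module_size=8,
    p_in=0.5,
    p_out=0.05,
    n_pathways=4,
    pathway_size=6,
    n_patients=20,
    n_subgroups=2,
    driver_patient_rate=0.8,
    passenger_rate=0.01,
    hazard_per_subgroup=(1.0, 3.0),
)


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: gene -> module, sample -> subgroup, drivers."""

    module_of_gene: dict[str, int] = field(default_factory=dict)
    subgroup_of_sample: dict[str, int] = field(default_factory=dict)
    driver_pathway_per_subgroup: tuple[str, ...] = ()


def _gene_name(i: int) -> str:
    return f"G{i + 1:04d}"


def _sample_name(i: int) -> str:
    return f"S{i + 1:04d}"


def _pathway_name(i: int) -> str:
    return f"P{i + 1:03d}"


def _rng(cfg: ScenarioConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, *stream]))


def generate_network(cfg: ScenarioConfig) -> tuple[GeneNetwork, GroundTruth]:
    """Planted-partition graph: within-module edges with probability p_in,
    between-module edges with p_out."""
    rng = _rng(cfg, 0)
    genes = [_gene_name(i) for i in range(cfg.n_genes)]
    module = {g: i // cfg.module_size for i, g in enumerate(genes)}
    edges = []
    for i in range(cfg.n_genes):
        for j in range(i + 1, cfg.n_genes):
            p = cfg.p_in if module[genes[i]] == module[genes[j]] else cfg.p_out
            if rng.random() < p:
                edges.append((genes[i], genes[j], 1.0))
    net = GeneNetwork.from_edges(edges, extra_nodes=genes)
    return net, GroundTruth(module_of_gene=module)


def generate_pathways(cfg: ScenarioConfig, truth: GroundTruth) -> PathwayCollection:
    """Module-coherent gene sets.

    Pathway i anchors to module i mod n_modules: a fraction
    ``pathway_module_overlap`` of its genes come from that module, the rest
    uniformly from the other genes.  At overlap 0 every pathway is a fully
    random decoy set.
    """
    if cfg.pathway_size > cfg.n_genes:
        raise ValueError("pathway_size exceeds number of genes")
    rng = _rng(cfg, 1)
    genes = np.array(sorted(truth.module_of_gene))
    module_arr = np.array([truth.module_of_gene[g] for g in genes])
    pathways: dict[str, frozenset[str]] = {}
    for i in range(cfg.n_pathways):
        mod = i % cfg.n_modules
        in_mod = genes[module_arr == mod]
        out_mod = genes[module_arr != mod]
        k_in = min(round(cfg.pathway_module_overlap * cfg.pathway_size), in_mod.size)
        k_out = cfg.pathway_size - k_in
        picked = list(rng.choice(in_mod, size=k_in, replace=False))
        picked += list(rng.choice(out_mod, size=k_out, replace=False))
        pathways[_pathway_name(i)] = frozenset(picked)
    return PathwayCollection(pathways=pathways, source="synthetic")


def generate_cohort(
    cfg: ScenarioConfig, pathways: PathwayCollection, truth: GroundTruth
) -> tuple[MutationCohort, GroundTruth]:
    """Subgroup-structured mutation cohort with mutually exclusive drivers.

    Patients split evenly into subgroups (remainder to the earlier ones).
    With probability ``driver_patient_rate`` a patient receives exactly one
    mutation in a uniformly chosen gene of its subgroup's driver pathway;
    passenger mutations hit every gene independently at ``passenger_rate``.
    """
    drivers = cfg.drivers()
    for d in drivers:
        if d not in pathways.pathways:
            raise ValueError(f"driver pathway {d!r} not in the collection")
    rng = _rng(cfg, 2)
    genes = tuple(sorted(truth.module_of_gene))
    g_idx = {g: i for i, g in enumerate(genes)}
    samples = tuple(_sample_name(i) for i in range(cfg.n_patients))
    subgroup = {s: i % cfg.n_subgroups for i, s in enumerate(samples)}
    M = (rng.random((cfg.n_patients, len(genes))) < cfg.passenger_rate).astype(np.int8)
    for i, s in enumerate(samples):
        if rng.random() < cfg.driver_patient_rate:
            driver_genes = sorted(pathways[drivers[subgroup[s]]])
            hit = driver_genes[rng.integers(len(driver_genes))]
            M[i, g_idx[hit]] = 1
    cohort = MutationCohort(samples=samples, genes=genes, M=M)
    full_truth = GroundTruth(
        module_of_gene=truth.module_of_gene,
        subgroup_of_sample=subgroup,
        driver_pathway_per_subgroup=drivers,
    )
    return cohort, full_truth


def generate_survival(truth: GroundTruth, cfg: ScenarioConfig) -> pd.DataFrame:
    """Exponential survival with subgroup hazards and independent censoring.

    Event times are exponential with the subgroup's hazard h; censoring times
    are exponential with rate c = h * censor_rate / (1 - censor_rate), which
    gives P(censored) = c / (c + h) = censor_rate exactly.  Returns a table
    with columns ``sample, time, event``.
    """
    rng = _rng(cfg, 3)
    samples = sorted(truth.subgroup_of_sample)
    rows = []
    for s in samples:
        h = cfg.hazard_per_subgroup[truth.subgroup_of_sample[s]]
        t_event = rng.exponential(1.0 / h)
        if cfg.censor_rate > 0:
            c = h * cfg.censor_rate / (1.0 - cfg.censor_rate)
            t_cens = rng.exponential(1.0 / c)
        else:
            t_cens = np.inf
        rows.append((s, min(t_event, t_cens), int(t_event <= t_cens)))
    return pd.DataFrame(rows, columns=["sample", "time", "event"])


def generate_scenario(cfg: ScenarioConfig):
    """Full bundle: (network, pathways, cohort, clinical, truth)."""
    net, truth0 = generate_network(cfg)
    pathways = generate_pathways(cfg, truth0)
    cohort, truth = generate_cohort(cfg, pathways, truth0)
    clinical = generate_survival(truth, cfg)
    return net, pathways, cohort, clinical, truth


def write_network(net: GeneNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        for (a, b), w in sorted(net.edges.items()):
            fh.write(f"{a}\t{b}\t{w!r}\n")
        connected = {g for pair in net.edges for g in pair}
        for g in net.nodes:
            if g not in connected:
                fh.write(f"{g}\n")


def write_scenario(cfg: ScenarioConfig, outdir) -> dict[str, Path]:
    """Emit a complete self-contained fixture readable by the loaders.

    Files: ``network.tsv``, ``pathways.gmt``, ``mutations.tsv``,
    ``clinical.tsv``, ``truth_subgroups.tsv``, ``truth_modules.tsv``,
    ``config.yaml``.  Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, pathways, cohort, clinical, truth = generate_scenario(cfg)
    paths = {
        "network": outdir / "network.tsv",
        "pathways": outdir / "pathways.gmt",
        "mutations": outdir / "mutations.tsv",
        "clinical": outdir / "clinical.tsv",
        "truth_subgroups": outdir / "truth_subgroups.tsv",
        "truth_modules": outdir / "truth_modules.tsv",
        "config": outdir / "config.yaml",
    }
    write_network(net, paths["network"])
    write_gmt(pathways, paths["pathways"])
    write_mutations(cohort, paths["mutations"])
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.subgroup_of_sample.items()), columns=["sample", "subgroup"]
    ).to_csv(paths["truth_subgroups"], sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.module_of_gene.items()), columns=["gene", "module"]
    ).to_csv(paths["truth_modules"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return paths
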
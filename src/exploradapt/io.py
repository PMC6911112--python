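"""File formats, run configuration, and end-to-end orchestration.

All on-disk artifacts are plain text: genes × samples expression TSV (first
column gene symbols, header row of sample ids), two-column sample→location
label TSV, two-column (source_tf, target_gene) edge-list TSV, GMT pathway
definitions, and JSON manifests carrying the configuration, package version,
and every seed, so a rerun with the same config reproduces all outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    SimulationContext,
    exploration_necessary,
    reversal_ratios,
    subpopulation_ablation,
    transition_experiment,
)
from .distance import (
    DEFAULT_N_BINS,
    build_phenotype_network,
    correlate_pdd_da,
    differential_activity,
    permutation_test_gdd,
    _pdd_vector,
)
from .dynamics import DEFAULT_D0, DEFAULT_H, DEFAULT_T_MAX, RegulatoryNetwork
from .phenotype import ExpressionCohort, GenePathwayMap, cohort_phenotypes, location_phenotype
from .synthetic import LocationSpec, SyntheticSpec, generate_all

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers / writers

def write_expression(cohort: ExpressionCohort, path: str | Path) -> None:
    cohort.values.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    return df


def write_labels(cohort: ExpressionCohort, path: str | Path) -> None:
    cohort.location_of.rename("location").to_csv(path, sep="\t", index_label="sample_id")


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def write_edge_list(network: RegulatoryNetwork, path: str | Path) -> None:
    pd.DataFrame(network.edge_list(), columns=["source_tf", "target_gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"edge list {path} needs two columns")
    return list(df.iloc[:, :2].itertuples(index=False, name=None))


def write_gmt(pathway_map: GenePathwayMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, members in pathway_map.pathways.items():
            fh.write("\t".join([pid, "na", *sorted(members)]) + "\n")


def read_gmt(path: str | Path) -> GenePathwayMap:
    """Parse GMT: name, description (ignored), then member genes."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                if not line.strip():
                    continue
                raise ValueError(f"{path}:{ln}: GMT lines need >= 3 fields")
            name, members = fields[0], [g for g in fields[2:] if g]
            if not members:
                raise ValueError(f"{path}:{ln}: empty gene set {name!r}")
            pathways[name] = frozenset(members)
    return GenePathwayMap(pathways)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """One pipeline run: either file inputs or a synthetic spec, plus parameters."""

    expression: str | None = None
    labels: str | None = None
    edges: str | None = None
    gmt: str | None = None
    synthetic: SyntheticSpec | None = None
    mode: str = "both"  # intrinsic | exploratory | both
    D0: float = DEFAULT_D0
    t_max: int = DEFAULT_T_MAX
    h: float = DEFAULT_H
    n_bins: int = DEFAULT_N_BINS
    lo_pct: float = 10.0
    hi_pct: float = 90.0
    n_perm: int = 499
    seeds: list[int] = field(default_factory=lambda: [0])
    max_samples: int | None = None
    transitions: list[tuple[str, str]] | None = None  # None = short-edge pairs
    run_reversals: bool = False
    ablation: dict | None = None  # {loc_a, loc_b, k_a, k_b, strategy}
    outdir: str = "run_output"

    def __post_init__(self) -> None:
        has_files = all(x is not None for x in (self.expression, self.labels, self.edges, self.gmt))
        if has_files == (self.synthetic is not None):
            raise ValueError("exactly one of file inputs or a synthetic spec must be given")
        if self.mode not in ("intrinsic", "exploratory", "both"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        for name, val, lo in (("D0", self.D0, 0), ("t_max", self.t_max, 1),
                              ("n_bins", self.n_bins, 1), ("n_perm", self.n_perm, 1)):
            if val < lo:
                raise ValueError(f"{name} must be >= {lo}")
        if not 0 <= self.lo_pct <= self.hi_pct <= 100:
            raise ValueError("percentile bounds must satisfy 0 <= lo <= hi <= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            locs = [LocationSpec(**loc) for loc in syn.pop("locations", [])]
            syn["pathway_size_range"] = tuple(syn.get("pathway_size_range", (8, 15)))
            raw["synthetic"] = SyntheticSpec(locations=locs, **syn)
        if raw.get("transitions"):
            raw["transitions"] = [tuple(t) for t in raw["transitions"]]
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_inputs(
    config: RunConfig,
) -> tuple[ExpressionCohort, RegulatoryNetwork, GenePathwayMap]:
    """Load (or synthesize) and cross-validate the three pipeline inputs."""
    if config.synthetic is not None:
        network, pmap, cohort = generate_all(config.synthetic)
    else:
        values = read_expression(config.expression)
        labels = read_labels(config.labels)
        cohort = ExpressionCohort(values, labels)
        edges = read_edge_list(config.edges)
        known = set(cohort.gene_ids)
        kept = [(s, t) for s, t in edges if s in known and t in known]
        dropped = len(edges) - len(kept)
        if dropped:
            logger.warning("dropped %d edge(s) with genes absent from the cohort", dropped)
        network = RegulatoryNetwork.from_edges(cohort.gene_ids, kept)
        pmap = read_gmt(config.gmt)
    overlap = set(cohort.gene_ids) & set(network.genes)
    if not overlap:
        raise ValueError("expression and network share no genes")
    logger.info(
        "inputs: %d genes, %d edges, %d pathways, samples per location: %s",
        len(cohort.gene_ids), network.n_edges, pmap.m,
        cohort.location_of.value_counts().to_dict(),
    )
    return cohort, network, pmap


# ---------------------------------------------------------------------------
# orchestration

def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}"


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> Path:
    """Execute phenotypes → distances/network → transition experiments.

    Writes every artifact under the run directory together with a manifest
    recording the package version, config hash, seeds, and per-stage status;
    on a stage failure, partial outputs are retained and the manifest marks
    the failure point before the exception propagates.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seeds": list(config.seeds),
        "stages": {},
    }

    def save_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except Exception as exc:
                manifest["stages"][name] = f"failed: {exc}"
                save_manifest()
                raise
            save_manifest()
        return deco

    state: dict = {}

    @stage("inputs")
    def _inputs():
        cohort, network, pmap = read_inputs(config)
        state.update(cohort=cohort, network=network, pmap=pmap)
        if config.synthetic is not None:
            write_expression(cohort, out / "expression.tsv")
            write_labels(cohort, out / "labels.tsv")
            write_edge_list(network, out / "edges.tsv")
            write_gmt(pmap, out / "pathways.gmt")

    @stage("phenotypes")
    def _phen():
        cohort, pmap = state["cohort"], state["pmap"]
        phen = cohort_phenotypes(cohort, pmap)
        phen.to_csv(out / "pathway_activity.tsv", sep="\t", index_label="pathway")
        rows = []
        for loc in cohort.locations:
            lp = location_phenotype(
                phen, cohort.location_of, loc, config.lo_pct, config.hi_pct
            )
            for pid in lp.pathway_ids:
                rows.append((loc, pid, lp.p_lo[pid], lp.p_hi[pid]))
        pd.DataFrame(rows, columns=["location", "pathway", "p_lo", "p_hi"]).to_csv(
            out / "location_intervals.tsv", sep="\t", index=False
        )
        state["phenotypes"] = phen

    @stage("distances")
    def _dist():
        cohort, phen = state["cohort"], state["phenotypes"]
        locs = cohort.locations
        pdd_tab, rows = {}, []
        gdd, mean_pdd, da_counts = {}, {}, {}
        for a, b in combinations(locs, 2):
            pa = phen[cohort.samples_of(a)].to_numpy(float)
            pb = phen[cohort.samples_of(b)].to_numpy(float)
            pdd = _pdd_vector(pa, pb, config.n_bins)
            pdd_tab[_pair_key(a, b)] = pdd
            gdd[(a, b)] = float(pdd.sum())
            mean_pdd[(a, b)] = float(pdd.mean())
            da = differential_activity(phen[cohort.samples_of(a)], phen[cohort.samples_of(b)])
            da_counts[(a, b)] = int(da["significant"].sum())
            perm = permutation_test_gdd(
                phen[cohort.samples_of(a)], phen[cohort.samples_of(b)],
                n_perm=config.n_perm, seed=int(config.seeds[0]), n_bins=config.n_bins,
            )
            abs_t = da["t"].to_numpy(float)
            abs_t = np.where(np.isfinite(abs_t), np.abs(abs_t), 0.0)
            r = correlate_pdd_da(pdd, abs_t) if np.ptp(pdd) > 0 and np.ptp(abs_t) > 0 else float("nan")
            rows.append((a, b, gdd[(a, b)], mean_pdd[(a, b)], da_counts[(a, b)], perm.p_value, r))
        pd.DataFrame(pdd_tab, index=phen.index).to_csv(
            out / "pdd_per_pathway.tsv", sep="\t", index_label="pathway"
        )
        pd.DataFrame(
            rows,
            columns=["loc_a", "loc_b", "gdd", "mean_pdd", "da_count", "p_gdd", "pdd_da_pearson"],
        ).to_csv(out / "location_distances.tsv", sep="\t", index=False)
        net = build_phenotype_network(locs, gdd, mean_pdd, da_counts)
        with open(out / "phenotype_network.json", "w") as fh:
            json.dump(
                {
                    "nodes": locs,
                    "edges": [
                        {"u": u, "v": v, **{k: vv for k, vv in d.items()}}
                        for u, v, d in net.graph.edges(data=True)
                    ],
                    "short_edges": [list(e) for e in net.short_edges],
                    "trajectories": {f"{u}->{v}": p for (u, v), p in net.trajectories.items()},
                },
                fh, indent=2,
            )
        state["network_report"] = net

    @stage("transitions")
    def _trans():
        cohort, network, pmap = state["cohort"], state["network"], state["pmap"]
        context = SimulationContext(cohort, network, pmap, config.lo_pct, config.hi_pct)
        pairs = config.transitions
        if pairs is None:
            pairs = [tuple(e) for e in state["network_report"].short_edges]
        modes = ["intrinsic", "exploratory"] if config.mode == "both" else [config.mode]
        rows = []
        for a, b in pairs:
            directions = [(a, b)] + ([(b, a)] if config.run_reversals else [])
            summaries = {}
            for src, tgt in directions:
                for mode in modes:
                    s = transition_experiment(
                        context, src, tgt, mode=mode, D0=config.D0,
                        t_max=config.t_max, seeds=config.seeds,
                        max_samples=config.max_samples, h=config.h,
                    )
                    summaries[(src, tgt, mode)] = s
                    rows.append(
                        (src, tgt, mode, s.mean_final_gd, s.mean_converged_pct, s.n_samples)
                    )
            if config.mode == "both":
                flag = exploration_necessary(
                    summaries[(a, b, "exploratory")], summaries[(a, b, "intrinsic")]
                )
                rows.append((a, b, "exploration_necessary", float(flag), np.nan, np.nan))
            if config.run_reversals:
                for mode in modes:
                    rr = reversal_ratios(summaries[(a, b, mode)], summaries[(b, a, mode)])
                    rows.append((a, b, f"reversal_ratio_{mode}", rr.gd_ratio, rr.converged_ratio, np.nan))
        pd.DataFrame(
            rows,
            columns=["source", "target", "mode", "mean_final_gd", "mean_converged_pct", "n"],
        ).to_csv(out / "transitions.tsv", sep="\t", index=False)
        state["context"] = context

    if config.ablation:
        @stage("ablation")
        def _abl():
            abl = dict(config.ablation)
            res = subpopulation_ablation(
                state["context"], abl["loc_a"], abl["loc_b"],
                int(abl.get("k_a", 0)), int(abl.get("k_b", 0)),
                strategy=abl.get("strategy", "closest"),
                seeds=config.seeds, mode="exploratory", D0=config.D0,
                t_max=config.t_max, max_samples=config.max_samples,
            )
            pd.DataFrame(
                [
                    (d, res.baseline_mean_gd[d], res.ablated_mean_gd[d])
                    for d in res.baseline_mean_gd
                ],
                columns=["direction", "baseline_mean_gd", "ablated_mean_gd"],
            ).to_csv(out / "ablation.tsv", sep="\t", index=False)

    save_manifest()
    return out
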
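"""Synthetic regulatory networks, pathway maps, and multi-location cohorts.

Generates the three ingredients the pipeline consumes — a directed TF→gene
skeleton, a many-to-many gene→pathway map, and an expression cohort whose
locations differ by *planted* per-pathway mean shifts — so that every
downstream stage (phenotypes, distances, adaptation dynamics) can be tested
against known ground truth.  All output is fully determined by the spec's
seed.

The generator emulates the structure of a multi-region tumor atlas: a few
hundred to a few thousand genes, a hub-dominated TF out-degree distribution,
KEGG-sized pathways with partial overlap, and locations whose samples share a
per-gene baseline but carry location-specific mean shifts on subsets of
pathways plus independent within-location noise.  It does not model
sequencing count noise or library-size artifacts; expression is on a
continuous log-like scale, which is all the rank-based phenotype downstream
requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import RegulatoryNetwork
from .phenotype import ExpressionCohort, GenePathwayMap

BASELINE_MEAN = 8.0
BASELINE_SD = 2.0
PARETO_SHAPE = 1.5  # heavy-tailed TF out-degrees (hub-dominated skeletons)


@dataclass
class LocationSpec:
    """One location: sample count, planted pathway shifts, noise level."""

    name: str
    n_samples: int
    shifted_pathways: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("each location needs >= 2 samples (Pearson weights)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic study; the seed determines everything."""

    n_genes: int = 300
    n_tfs: int = 60
    target_avg_degree: float = 6.0
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (8, 15)
    overlap_fraction: float = 0.25
    locations: list[LocationSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs > self.n_genes:
            raise ValueError("n_tfs must not exceed n_genes")
        if self.target_avg_degree >= self.n_genes:
            raise ValueError(
                f"infeasible degree: target_avg_degree={self.target_avg_degree} "
                f">= n_genes={self.n_genes}"
            )
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid pathway size range")
        if hi > self.n_genes:
            raise ValueError("pathway size range infeasible: max exceeds n_genes")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        names = [loc.name for loc in self.locations]
        if len(names) != len(set(names)):
            raise ValueError("location names must be unique")

    @property
    def gene_ids(self) -> list[str]:
        tfs = [f"TF{i:04d}" for i in range(self.n_tfs)]
        others = [f"G{i:05d}" for i in range(self.n_genes - self.n_tfs)]
        return tfs + others

    @property
    def tf_ids(self) -> list[str]:
        return self.gene_ids[: self.n_tfs]

    def pathway_ids(self) -> list[str]:
        return [f"PW{i:03d}" for i in range(self.n_pathways)]


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


def generate_regulatory_skeleton(spec: SyntheticSpec) -> RegulatoryNetwork:
    """Directed simple TF→gene graph with heavy-tailed TF out-degrees.

    The total edge count is fixed to round(target_avg_degree · n_genes) and
    allocated over TFs proportionally to Pareto-distributed propensities
    (largest-remainder rounding, capped at n_genes − 1 targets per TF), so
    the realized average degree matches the target up to that rounding.
    Targets are drawn uniformly without replacement; no self-loops.
    """
    rng = _rng(spec, 1)
    genes = spec.gene_ids
    n, k = spec.n_genes, spec.n_tfs
    total = int(round(spec.target_avg_degree * n))
    cap = n - 1
    if total > k * cap:
        raise ValueError("infeasible degree: too many edges for the TF count")
    weights = rng.pareto(PARETO_SHAPE, size=k) + 1.0
    quota = total * weights / weights.sum()
    deg = np.minimum(np.floor(quota).astype(int), cap)
    # largest-remainder top-up to hit the exact total, respecting the cap
    while deg.sum() < total:
        room = deg < cap
        frac = np.where(room, quota - deg, -np.inf)
        deg[int(np.argmax(frac))] += 1
    T = np.zeros((n, n), dtype=np.int8)
    for i in range(k):
        if deg[i] == 0:
            continue
        candidates = np.delete(np.arange(n), i)
        targets = rng.choice(candidates, size=deg[i], replace=False)
        T[targets, i] = 1
    tf_mask = np.zeros(n, bool)
    tf_mask[:k] = True
    return RegulatoryNetwork(genes, T, tf_mask)


def generate_pathway_map(spec: SyntheticSpec) -> GenePathwayMap:
    """Gene sets with sizes in the spec's range and tunable pairwise overlap.

    A fraction (1 − overlap_fraction) of each pathway's genes comes from a
    pool of not-yet-used genes (exclusive members); the remainder is drawn
    from genes already used by earlier pathways, which creates overlap.  With
    overlap_fraction = 0 the sets are pairwise disjoint (requiring the summed
    sizes to fit in the gene universe).  Genes left in the pool belong to no
    pathway.
    """
    rng = _rng(spec, 2)
    genes = np.array(spec.gene_ids)
    lo, hi = spec.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    if spec.overlap_fraction == 0 and sizes.sum() > spec.n_genes:
        raise ValueError(
            "pathway size range infeasible: disjoint sets need "
            f"{int(sizes.sum())} genes but only {spec.n_genes} exist"
        )
    unused = list(range(spec.n_genes))
    used: list[int] = []
    pathways: dict[str, frozenset[str]] = {}
    for pid, size in zip(spec.pathway_ids(), sizes):
        n_shared = int(round(spec.overlap_fraction * size))
        n_shared = min(n_shared, len(used))
        n_excl = min(size - n_shared, len(unused))
        n_shared = size - n_excl  # top up from used genes if the pool ran dry
        if n_shared > len(used):
            raise ValueError("pathway size range infeasible: gene universe exhausted")
        members: list[int] = []
        if n_excl:
            pick = rng.choice(len(unused), size=n_excl, replace=False)
            members += [unused[i] for i in pick]
            for i in sorted(pick, reverse=True):
                unused.pop(i)
        if n_shared:
            members += list(rng.choice(used, size=n_shared, replace=False))
        used = sorted(set(used) | set(members))
        pathways[pid] = frozenset(genes[members])
    return GenePathwayMap(pathways, universe=frozenset(genes))


def generate_location_cohort(
    skeleton: RegulatoryNetwork,
    pathway_map: GenePathwayMap,
    spec: SyntheticSpec,
) -> ExpressionCohort:
    """Expression cohort: shared per-gene baseline + planted shifts + noise.

    Every location shares one baseline (drawn once from N(8, 2²), a log-like
    scale), so locations differ only by their planted per-pathway mean shifts
    — applied to every member gene of the shifted pathway — plus independent
    N(0, noise_sd²) noise per value.
    """
    if not spec.locations:
        raise ValueError("spec declares no locations")
    for loc in spec.locations:
        unknown = set(loc.shifted_pathways) - set(pathway_map.pathways)
        if unknown:
            raise ValueError(f"unknown pathway name(s) in {loc.name!r}: {sorted(unknown)}")
    rng = _rng(spec, 3)
    genes = skeleton.genes
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n)
    columns: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for loc in spec.locations:
        shift = np.zeros(n)
        for pid, delta in loc.shifted_pathways.items():
            members = [idx[g] for g in pathway_map.pathways[pid] if g in idx]
            shift[members] += float(delta)
        for s in range(loc.n_samples):
            sid = f"{loc.name}_s{s:03d}"
            columns[sid] = baseline + shift + rng.normal(0.0, loc.noise_sd, size=n)
            labels[sid] = loc.name
    values = pd.DataFrame(columns, index=genes)
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("generated expression contains non-finite values")
    return ExpressionCohort(values, pd.Series(labels))


def generate_all(
    spec: SyntheticSpec,
) -> tuple[RegulatoryNetwork, GenePathwayMap, ExpressionCohort]:
    """Skeleton, pathway map, and cohort for one spec (single entry point)."""
    skeleton = generate_regulatory_skeleton(spec)
    pmap = generate_pathway_map(spec)
    cohort = generate_location_cohort(skeleton, pmap, spec)
    return skeleton, pmap, cohort


def ivy_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Spec at the scale of the Ivy GAP anatomic-structure cohort and its
    focused GBM regulatory network: 4121 genes, average degree 19.09, 182
    pathways, five locations with 30/19/24/25/24 samples."""
    shifts = {
        "CT": {},
        "LE": {f"PW{i:03d}": 2.0 for i in range(0, 36)},
        "IT": {f"PW{i:03d}": 1.0 for i in range(0, 18)},
        "CTmvp": {f"PW{i:03d}": 2.0 for i in range(36, 72)},
        "CTpan": {f"PW{i:03d}": 1.0 for i in range(72, 108)},
    }
    counts = {"CT": 30, "LE": 19, "IT": 24, "CTmvp": 25, "CTpan": 24}
    return SyntheticSpec(
        n_genes=4121,
        n_tfs=600,
        target_avg_degree=19.09,
        n_pathways=182,
        pathway_size_range=(10, 200),
        overlap_fraction=0.25,
        locations=[
            LocationSpec(name, counts[name], shifts[name], noise_sd=1.0)
            for name in ("CT", "LE", "IT", "CTmvp", "CTpan")
        ],
        seed=seed,
    )


def asymmetric_spec(seed: int = 0, n_samples: int = 20) -> SyntheticSpec:
    """Two-location study with asymmetric difficulty.

    Location A is heterogeneous (wide activity distributions, hence wide and
    easy-to-hit target intervals); B is homogeneous and shifted, a narrow,
    hard target.  Forward adaptation A→B should therefore end farther from
    its target than the reverse B→A run — the planted mirror of a
    heterogeneous core versus a tight peripheral phenotype.
    """
    return SyntheticSpec(
        n_genes=300,
        n_tfs=60,
        target_avg_degree=6.0,
        n_pathways=20,
        pathway_size_range=(8, 15),
        overlap_fraction=0.25,
        locations=[
            LocationSpec("A", n_samples, {}, noise_sd=2.0),
            LocationSpec(
                "B", n_samples,
                {f"PW{i:03d}": 2.0 for i in range(4)}, noise_sd=0.5,
            ),
        ],
        seed=seed,
    )


def collinear_spec(seed: int = 0, n_samples: int = 20) -> SyntheticSpec:
    """Four locations for the intermediate-state geometry: A, midpoint I,
    endpoint B (shifts on the same pathways, half vs full magnitude) and an
    off-axis R (equal-magnitude shifts on disjoint pathways)."""
    on_axis = {f"PW{i:03d}": 2.0 for i in range(4)}
    midway = {f"PW{i:03d}": 1.0 for i in range(4)}
    off_axis = {f"PW{i:03d}": 2.0 for i in range(4, 8)}
    return SyntheticSpec(
        n_genes=300,
        n_tfs=60,
        target_avg_degree=6.0,
        n_pathways=20,
        pathway_size_range=(8, 15),
        overlap_fraction=0.25,
        locations=[
            LocationSpec("A", n_samples, {}, noise_sd=1.0),
            LocationSpec("I", n_samples, midway, noise_sd=1.0),
            LocationSpec("B", n_samples, on_axis, noise_sd=1.0),
            LocationSpec("R", n_samples, off_axis, noise_sd=1.0),
        ],
        seed=seed,
    )


def demo_spec(
    seed: int = 0,
    shift: float = 2.0,
    noise_sd: float = 1.0,
    n_samples: int = 20,
) -> SyntheticSpec:
    """Desk-scale three-location study: 300 genes, 20 pathways.

    Location A is the unshifted source; B shifts 4 of the 20 pathways (20%)
    by ``shift`` expression units; C shifts a disjoint set of 4 pathways, so
    A→B and A→C point in different phenotype directions.
    """
    return SyntheticSpec(
        n_genes=300,
        n_tfs=60,
        target_avg_degree=6.0,
        n_pathways=20,
        pathway_size_range=(8, 15),
        overlap_fraction=0.25,
        locations=[
            LocationSpec("A", n_samples, {}, noise_sd=noise_sd),
            LocationSpec(
                "B", n_samples,
                {f"PW{i:03d}": shift for i in range(4)}, noise_sd=noise_sd,
            ),
            LocationSpec(
                "C", n_samples,
                {f"PW{i:03d}": shift for i in range(4, 8)}, noise_sd=noise_sd,
            ),
        ],
        seed=seed,
    )
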
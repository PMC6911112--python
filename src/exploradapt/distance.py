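"""Distribution-level phenotype comparison between locations.

Two locations are compared pathway by pathway: each pathway's activity values
are binned into histograms on shared edges spanning the pooled range, the
histograms are normalized to relative frequencies, and the Euclidean distance
between the two frequency vectors is the Pathway Distribution Distance (PDD).
The Global Distribution Distance (GDD) is the sum of PDDs over all pathways.
Significance of a GDD is assessed by a permutation test over sample labels;
per-pathway mean differences are additionally tested with Welch t-tests under
Benjamini–Hochberg correction (differential activity, DA).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phenotype import LocationPhenotype

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 20
DA_ALPHA = 1e-6
SHORT_EDGE_FACTOR = 1.25


def pathway_distribution_distance(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Euclidean distance between two relative-frequency histograms.

    Bin edges are shared and span the pooled min–max of both inputs, so the
    distance is symmetric, non-negative, and zero iff the two frequency
    vectors coincide.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both value vectors must be non-empty")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        warnings.warn("zero pooled range; distance defined as 0", stacklevel=2)
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    fa = np.histogram(a, bins=edges)[0] / a.size
    fb = np.histogram(b, bins=edges)[0] / b.size
    return float(np.sqrt(np.sum((fa - fb) ** 2)))


def _pdd_vector(a: np.ndarray, b: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-pathway PDD between two (m x nA) and (m x nB) activity matrices."""
    m = a.shape[0]
    out = np.empty(m)
    for j in range(m):
        lo = min(a[j].min(), b[j].min())
        hi = max(a[j].max(), b[j].max())
        if lo == hi:
            out[j] = 0.0
            continue
        edges = np.linspace(lo, hi, n_bins + 1)
        fa = np.histogram(a[j], bins=edges)[0] / a.shape[1]
        fb = np.histogram(b[j], bins=edges)[0] / b.shape[1]
        out[j] = np.sqrt(np.sum((fa - fb) ** 2))
    return out


def global_distribution_distance(
    loc_a: LocationPhenotype,
    loc_b: LocationPhenotype,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Sum of per-pathway distribution distances between two locations."""
    if list(loc_a.pathway_ids) != list(loc_b.pathway_ids):
        raise ValueError("location phenotypes cover different pathway sets")
    a = loc_a.activities.to_numpy(float)
    b = loc_b.activities.to_numpy(float)
    return float(_pdd_vector(a, b, n_bins).sum())


class _BinnedPermutationEngine:
    """Fast GDD over relabelings of a fixed pooled sample set.

    Bin edges per pathway are frozen from the pool, each sample's bin index is
    precomputed, and a relabeling only re-counts indices — O(m·n) per draw.
    """

    def __init__(self, pool: np.ndarray, n_bins: int):
        self.m, self.n = pool.shape
        self.n_bins = n_bins
        lo = pool.min(axis=1, keepdims=True)
        hi = pool.max(axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        self.degenerate = (hi == lo).ravel()
        idx = np.floor((pool - lo) / span * n_bins).astype(np.intp)
        self.bin_idx = np.clip(idx, 0, n_bins - 1)
        self.rows = np.arange(self.m)[:, None]

    def _freq(self, cols: np.ndarray) -> np.ndarray:
        counts = np.zeros((self.m, self.n_bins))
        np.add.at(counts, (self.rows, self.bin_idx[:, cols]), 1.0)
        return counts / cols.size

    def gdd(self, cols_a: np.ndarray, cols_b: np.ndarray) -> float:
        d = np.sqrt(((self._freq(cols_a) - self._freq(cols_b)) ** 2).sum(axis=1))
        d[self.degenerate] = 0.0
        return float(d.sum())


@dataclass
class PermutationResult:
    p_value: float
    observed: float
    null: np.ndarray
    n_used: int
    scheme: str


def permutation_test_gdd(
    samples_a: pd.DataFrame | np.ndarray,
    samples_b: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    n_bins: int = DEFAULT_N_BINS,
    scheme: str = "centered_band",
    lo_q: float = 0.1,
    hi_q: float = 0.9,
) -> PermutationResult:
    """Permutation significance of the GDD between two phenotype matrices.

    The observed GDD is computed on the raw activities.  The null is built by
    relabeling samples between the groups; under the default scheme each
    group is first mean-centered per pathway (removing the very difference
    being tested, i.e. enforcing the null), and a relabeling is admissible
    only when every permuted group's per-pathway mean lies inside the pooled
    centered distribution's [lo_q, hi_q] quantile band.  ``scheme`` options:

    - ``"centered_band"`` (default): centering + admissibility band.
    - ``"centered"``: centering, all relabelings admissible.
    - ``"plain"``: classic full relabeling of the raw values.

    p = (1 + #{null >= observed}) / (1 + n_used).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] != b.shape[0]:
        raise ValueError("activity matrices must be 2-D with matching pathway rows")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = float(_pdd_vector(a, b, n_bins).sum())

    if scheme in ("centered", "centered_band"):
        pool = np.hstack([a - a.mean(axis=1, keepdims=True), b - b.mean(axis=1, keepdims=True)])
    elif scheme == "plain":
        pool = np.hstack([a, b])
    else:
        raise ValueError(f"unknown permutation scheme: {scheme!r}")

    engine = _BinnedPermutationEngine(pool, n_bins)
    n_a = a.shape[1]
    n = pool.shape[1]
    if scheme == "centered_band":
        band_lo = np.quantile(pool, lo_q, axis=1)
        band_hi = np.quantile(pool, hi_q, axis=1)

    null = np.empty(n_perm)
    used = 0
    attempts = 0
    max_attempts = 50 * n_perm
    while used < n_perm and attempts < max_attempts:
        attempts += 1
        perm = rng.permutation(n)
        ca, cb = perm[:n_a], perm[n_a:]
        if scheme == "centered_band":
            ma = pool[:, ca].mean(axis=1)
            mb = pool[:, cb].mean(axis=1)
            ok = (
                (ma >= band_lo).all() and (ma <= band_hi).all()
                and (mb >= band_lo).all() and (mb <= band_hi).all()
            )
            if not ok:
                continue
        null[used] = engine.gdd(ca, cb)
        used += 1
    if used < n_perm:
        logger.warning(
            "only %d of %d admissible permutations found within the quantile band",
            used, n_perm,
        )
    null = null[:used]
    p = (1.0 + np.sum(null >= observed - 1e-12)) / (1.0 + used)
    return PermutationResult(float(p), observed, null, used, scheme)


def differential_activity(
    samples_a: pd.DataFrame,
    samples_b: pd.DataFrame,
    alpha: float = DA_ALPHA,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-pathway two-sided t-tests with Benjamini–Hochberg correction.

    Welch's unequal-variance form by default.  Pathways with zero variance in
    both groups get t = 0, p = 1 when the means agree, else an infinite t and
    p = 0 (a deterministic separation).
    """
    if samples_a.shape[1] < 2 or samples_b.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples per pathway")
    if list(samples_a.index) != list(samples_b.index):
        raise ValueError("pathway rows differ between groups")
    a = samples_a.to_numpy(float)
    b = samples_b.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t[zero_var & same_mean] = 0.0
    p[zero_var & same_mean] = 1.0
    sep = zero_var & ~same_mean
    t[sep] = np.sign(a.mean(axis=1) - b.mean(axis=1))[sep] * np.inf
    p[sep] = 0.0
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame(
        {"t": t, "p": p, "p_adj": p_adj, "significant": p_adj <= alpha},
        index=samples_a.index,
    )


def correlate_pdd_da(pdd_vector: Sequence[float], da_vector: Sequence[float]) -> float:
    """Pearson correlation between per-pathway PDD and a DA summary (e.g. |t|)."""
    x = np.asarray(pdd_vector, float)
    y = np.asarray(da_vector, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for constant input")
    return float(stats.pearsonr(x, y)[0])


@dataclass
class PhenotypeNetwork:
    """Complete location graph with per-edge distances and a short/long split."""

    graph: nx.Graph
    short_edges: list[tuple[str, str]]
    trajectories: dict[tuple[str, str], list[str]] = field(default_factory=dict)


def build_phenotype_network(
    locations: Sequence[str],
    gdd: Mapping[tuple[str, str], float],
    mean_pdd: Mapping[tuple[str, str], float] | None = None,
    da_counts: Mapping[tuple[str, str], int] | None = None,
    short_factor: float = SHORT_EDGE_FACTOR,
) -> PhenotypeNetwork:
    """Complete graph over locations with edges classified short vs long.

    Per node, edges whose GDD is within ``short_factor`` of that node's
    minimum incident GDD are kept; the union over nodes forms the "short"
    (dashed) set, and trajectories are shortest GDD-weighted paths inside the
    short-edge subgraph.
    """
    locations = list(locations)
    if len(locations) < 2:
        raise ValueError("need at least 2 locations")

    def key(u: str, v: str) -> tuple[str, str]:
        return (u, v) if (u, v) in gdd else (v, u)

    g = nx.Graph()
    g.add_nodes_from(locations)
    for u, v in combinations(locations, 2):
        k = key(u, v)
        if k not in gdd:
            raise KeyError(f"missing distance for location pair {u!r}, {v!r}")
        g.add_edge(
            u, v,
            gdd=float(gdd[k]),
            mean_pdd=float(mean_pdd[k]) if mean_pdd else None,
            da_count=int(da_counts[k]) if da_counts else None,
        )
    short: set[tuple[str, str]] = set()
    for node in locations:
        inc = {frozenset((node, nb)): g.edges[node, nb]["gdd"] for nb in g.neighbors(node)}
        cutoff = min(inc.values()) * short_factor
        short |= {tuple(sorted(e)) for e, d in inc.items() if d <= cutoff}
    for u, v in g.edges:
        g.edges[u, v]["short"] = tuple(sorted((u, v))) in short
    sub = g.edge_subgraph([e for e in g.edges if g.edges[e]["short"]]).copy()
    trajectories: dict[tuple[str, str], list[str]] = {}
    for u, v in combinations(locations, 2):
        if u in sub and v in sub and nx.has_path(sub, u, v):
            trajectories[(u, v)] = nx.shortest_path(sub, u, v, weight="gdd")
    return PhenotypeNetwork(g, sorted(short), trajectories)
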
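"""Gene-regulatory dynamics with intrinsic and exploratory adaptation modes.

The gene state ``X`` (length n, saturating units) evolves under

    dX/dt = (T * J) · tanh(X) − β X

where ``T`` is the binary TF→gene adjacency, ``J`` the per-location Pearson
interaction-strength matrix, ``*`` the element-wise (Hadamard) product, and
β the relaxation rate (0.5).  The phenotype ``y`` is the vector of pathway
activities of ``X`` (rank-based single-sample enrichment).  In exploratory
mode the entries of ``J`` on existing edges perform a random walk,
``J += sqrt(D) · z`` with standard-normal ``z``; the per-edge exploration
scale ``D`` starts at ``D0`` and is damped by ×0.95 on the rows and columns
of every gene whose containing pathways have *all* converged (activity inside
the target's [p10, p90] interval), so exploration quiets down pathway by
pathway as the phenotype settles into its target.

Time bookkeeping: one reported step = ``substeps`` explicit-Euler updates of
step ``h`` (defaults 4 × 0.25, one time unit per reported step); phenotype,
per-pathway distance, and convergence are evaluated once per reported step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .phenotype import (
    DEFAULT_WEIGHT_EXPONENT,
    ExpressionCohort,
    GenePathwayMap,
    LocationPhenotype,
    phenotype_matrix,
)

BETA = 0.5
DAMPING_FACTOR = 0.95
DEFAULT_D0 = 0.1
DEFAULT_T_MAX = 1000
DEFAULT_H = 0.25
DEFAULT_SUBSTEPS = 4


class SimulationDiverged(RuntimeError):
    """Raised when the gene state becomes non-finite; carries the step index."""

    def __init__(self, t: int):
        super().__init__(f"gene state diverged (non-finite) at reported step t={t}")
        self.t = t


@dataclass
class RegulatoryNetwork:
    """Binary directed TF→gene adjacency.

    ``T[i, j] = 1`` means gene ``j`` (a TF) regulates gene ``i``, so row i of
    ``T * J`` collects the incoming regulation of gene i.  Edge lists are
    (source_tf, target_gene) pairs.
    """

    genes: list[str]
    T: np.ndarray
    tf_mask: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.T = np.asarray(self.T)
        n = len(self.genes)
        if self.T.shape != (n, n):
            raise ValueError("adjacency shape does not match gene list")
        vals = np.unique(self.T)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.tf_mask = np.asarray(self.tf_mask, bool)
        if self.T.any(axis=0)[~self.tf_mask].any():
            raise ValueError("edges may only originate from TF nodes")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.T.sum())

    @property
    def average_degree(self) -> float:
        """Edges per node (the network's undirected-style mean degree)."""
        return self.n_edges / self.n

    def edge_list(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.T)
        return [(self.genes[j], self.genes[i]) for i, j in zip(rows, cols)]

    @classmethod
    def from_edges(
        cls,
        genes: Iterable[str],
        edges: Iterable[tuple[str, str]],
        tfs: Iterable[str] | None = None,
    ) -> "RegulatoryNetwork":
        genes = list(genes)
        idx = {g: i for i, g in enumerate(genes)}
        T = np.zeros((len(genes), len(genes)), dtype=np.int8)
        sources = set()
        for src, tgt in edges:
            T[idx[tgt], idx[src]] = 1
            sources.add(src)
        if tfs is None:
            tf_mask = np.fromiter((g in sources for g in genes), bool, count=len(genes))
        else:
            tfset = set(tfs)
            tf_mask = np.fromiter((g in tfset for g in genes), bool, count=len(genes))
        return cls(genes, T, tf_mask)


@dataclass
class InteractionWeights:
    """Interaction strengths J supported on the network's edges.

    Initialized from per-location Pearson correlations (so |J| <= 1 at t=0);
    during exploration stored entries may drift beyond [-1, 1].  Only the
    product T * J ever enters the dynamics.
    """

    J: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ValueError("J must be square")


def interaction_weights(
    cohort: ExpressionCohort,
    location: str,
    network: RegulatoryNetwork,
) -> InteractionWeights:
    """Pearson correlations between genes across one location's samples.

    Computed where ``T`` has an edge (elsewhere irrelevant under T*J and set
    to 0); zero-variance genes contribute weight 0.
    """
    samples = cohort.samples_of(location)
    if len(samples) < 2:
        raise ValueError(f"location {location!r} has fewer than 2 samples")
    vals = cohort.values.reindex(network.genes).to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("network genes missing from cohort expression")
    loc = vals[:, cohort.sample_ids.get_indexer(samples)]
    sd = loc.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(loc)
    corr = np.nan_to_num(corr, nan=0.0, posinf=0.0, neginf=0.0)
    corr[sd == 0, :] = 0.0
    corr[:, sd == 0] = 0.0
    return InteractionWeights(corr * (network.T != 0))


def intrinsic_step(
    X: np.ndarray,
    T: np.ndarray,
    J: np.ndarray,
    beta: float = BETA,
    h: float = DEFAULT_H,
) -> np.ndarray:
    """One explicit-Euler update X' = X + h·[(T*J)·tanh(X) − βX]."""
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite gene state")
    if h <= 0:
        raise ValueError("h must be positive")
    W = np.asarray(T, float) * np.asarray(J, float)
    return X + h * (W @ np.tanh(X) - beta * X)


def sample_distance(
    y: np.ndarray,
    p_lo: np.ndarray | LocationPhenotype,
    p_hi: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-pathway distance of a phenotype to target [p10, p90] intervals.

    PD_j = 0 when y_j lies inside the closed interval, otherwise the distance
    to the nearer bound; GD = Σ PD_j; a pathway is converged iff PD_j = 0
    (the convergence indicator M per pathway).
    """
    if isinstance(p_lo, LocationPhenotype):
        lo = p_lo.p_lo.to_numpy(float)
        hi = p_lo.p_hi.to_numpy(float)
    else:
        lo = np.asarray(p_lo, float)
        hi = np.asarray(p_hi, float)
    y = np.asarray(y, float)
    if y.shape != lo.shape or y.shape != hi.shape:
        raise ValueError("phenotype / interval shape mismatch")
    pd_vec = np.maximum.reduce([np.zeros_like(y), lo - y, y - hi])
    converged = pd_vec == 0
    return pd_vec, float(pd_vec.sum()), converged


def fully_converged_genes(
    converged: np.ndarray, membership: np.ndarray
) -> np.ndarray:
    """Genes belonging to >= 1 pathway, all of whose pathways have converged."""
    membership = np.asarray(membership, bool)
    in_any = membership.any(axis=0)
    in_unconverged = membership[~np.asarray(converged, bool)].any(axis=0)
    return in_any & ~in_unconverged


def update_exploration_scale(
    D: np.ndarray,
    converged: np.ndarray,
    membership: np.ndarray,
    factor: float = DAMPING_FACTOR,
) -> np.ndarray:
    """Damp exploration for genes whose every containing pathway converged.

    For each such gene k, row k *and* column k of D are multiplied by
    ``factor`` (an edge between two such genes is damped twice).  Genes in at
    least one unconverged pathway, or in no pathway, are untouched.
    """
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    scale = np.ones(D.shape[0])
    scale[fully_converged_genes(converged, membership)] = factor
    return D * scale[:, None] * scale[None, :]


def perturb_weights(
    J: np.ndarray,
    D: np.ndarray,
    rng: np.random.Generator,
    T: np.ndarray | None = None,
) -> np.ndarray:
    """Random-walk step J' = J + sqrt(D)·z, z ~ N(0,1), on existing edges only."""
    D = np.asarray(D, float)
    if (D < 0).any():
        raise ValueError("exploration scale D must be non-negative")
    J = np.array(J, float, copy=True)
    if T is None:
        J += np.sqrt(D) * rng.standard_normal(D.shape)
        return J
    rows, cols = np.nonzero(T)
    J[rows, cols] += np.sqrt(D[rows, cols]) * rng.standard_normal(rows.size)
    return J


@dataclass
class TrajectoryRecord:
    """Per-step record of one simulated sample's adaptation run.

    Arrays have ``t_max + 1`` rows (step 0 is the initial state) unless the
    run converged early, in which case they stop at the converging step.
    """

    phenotypes: np.ndarray  # (steps, m)
    pd: np.ndarray  # (steps, m)
    gd: np.ndarray  # (steps,)
    converged_count: np.ndarray  # (steps,)
    pathway_ids: list[str]
    final_state: np.ndarray
    final_J: np.ndarray
    final_D: np.ndarray | None
    metadata: dict = field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return len(self.gd)

    @property
    def final_gd(self) -> float:
        return float(self.gd[-1])

    @property
    def fully_converged(self) -> bool:
        return bool(self.converged_count[-1] == len(self.pathway_ids))

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(self.n_steps),
                "GD": self.gd,
                "converged_count": self.converged_count,
            }
        )


def simulate(
    x0: np.ndarray,
    network: RegulatoryNetwork,
    J0: InteractionWeights | np.ndarray,
    targets: LocationPhenotype,
    pathway_map: GenePathwayMap,
    mode: str = "exploratory",
    D0: float = DEFAULT_D0,
    t_max: int = DEFAULT_T_MAX,
    h: float = DEFAULT_H,
    substeps: int = DEFAULT_SUBSTEPS,
    seed: int | np.random.Generator = 0,
    beta: float = BETA,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    damping_factor: float = DAMPING_FACTOR,
    noise_gate: str = "damped",
    d_init: str = "constant",
    stop_early: bool = True,
) -> TrajectoryRecord:
    """Simulate one sample's phenotype trajectory toward a target location.

    Per reported step: (1) ``substeps`` Euler updates of X; (2) phenotype via
    single-sample enrichment of X; (3) per-pathway distance to the target
    intervals, GD, convergence mask; (4) exploratory mode only: damp D for
    fully-converged genes, then perturb J on edges.  Stops early once all
    pathways are converged; records every evaluated step.

    ``noise_gate``: ``"damped"`` (default) applies noise every step with the
    geometrically damped per-edge scale; ``"converged_only"`` additionally
    zeroes noise on edges whose target gene is in no converged pathway (the
    alternate reading of the convergence-gated walk).
    ``d_init``: ``"constant"`` sets D(0)=D0 on every edge; ``"normal"`` draws
    |N(0, D0)| per edge.
    """
    if mode not in ("intrinsic", "exploratory"):
        raise ValueError(f"unknown mode: {mode!r}")
    if noise_gate not in ("damped", "converged_only"):
        raise ValueError(f"unknown noise_gate: {noise_gate!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.array(x0, float, copy=True)
    if X.shape != (network.n,):
        raise ValueError("x0 length does not match network size")
    J = np.array(J0.J if isinstance(J0, InteractionWeights) else J0, float, copy=True)
    T = network.T != 0

    restricted = pathway_map.restricted_to(network.genes)
    membership, pathway_ids = restricted.membership_matrix(network.genes)
    if set(pathway_ids) != set(targets.pathway_ids):
        raise ValueError("target pathway set does not match the pathway map")
    order = [list(targets.pathway_ids).index(p) for p in pathway_ids]
    lo = targets.p_lo.to_numpy(float)[order]
    hi = targets.p_hi.to_numpy(float)[order]
    sizes = membership.sum(axis=1)

    exploratory = mode == "exploratory"
    if exploratory:
        if d_init == "constant":
            D = np.where(T, float(D0), 0.0)
        elif d_init == "normal":
            D = np.where(T, np.abs(rng.normal(0.0, float(D0), T.shape)), 0.0)
        else:
            raise ValueError(f"unknown d_init: {d_init!r}")
    else:
        D = None

    rows, cols = np.nonzero(T)
    m = len(pathway_ids)
    steps = t_max + 1
    phen = np.empty((steps, m))
    pd_arr = np.empty((steps, m))
    gd = np.empty(steps)
    conv_count = np.empty(steps, dtype=int)

    def evaluate(t: int) -> np.ndarray:
        if not np.all(np.isfinite(X)):
            raise SimulationDiverged(t)
        y = phenotype_matrix(X[:, None], membership, weight_exponent)[:, 0]
        pdv, g, conv = sample_distance(y, lo, hi)
        phen[t] = y
        pd_arr[t] = pdv
        gd[t] = g
        conv_count[t] = int(conv.sum())
        return conv

    def explore(conv: np.ndarray) -> None:
        nonlocal J, D
        D = update_exploration_scale(D, conv, membership, damping_factor)
        scale = D[rows, cols]
        if noise_gate == "converged_only":
            gene_gate = membership[conv].any(axis=0) if conv.any() else np.zeros(network.n, bool)
            scale = scale * gene_gate[rows]
        J[rows, cols] += np.sqrt(scale) * rng.standard_normal(rows.size)

    conv = evaluate(0)
    last = 0
    for t in range(1, steps):
        if stop_early and conv.all():
            break
        if exploratory:
            explore(conv)
        W = T * J
        for _ in range(substeps):
            X += h * (W @ np.tanh(X) - beta * X)
        conv = evaluate(t)
        last = t

    n_rec = last + 1
    return TrajectoryRecord(
        phenotypes=phen[:n_rec],
        pd=pd_arr[:n_rec],
        gd=gd[:n_rec],
        converged_count=conv_count[:n_rec],
        pathway_ids=pathway_ids,
        final_state=X,
        final_J=J,
        final_D=D,
        metadata={
            "mode": mode,
            "D0": D0,
            "t_max": t_max,
            "h": h,
            "substeps": substeps,
            "beta": beta,
            "noise_gate": noise_gate,
            "d_init": d_init,
            "target_location": targets.location,
        },
    )


def state_space_values(
    cohort: ExpressionCohort, scope: str = "cohort"
) -> pd.DataFrame:
    """Map expression to the saturating gene-state scale: tanh of per-gene z-scores.

    z-scores are taken across the whole cohort (``scope="cohort"``, default)
    so that location-mean differences survive the mapping and simulated
    phenotypes remain comparable to data-derived targets; ``scope="location"``
    z-scores each location separately (which removes location means and is
    only useful for within-location analyses).  Zero-variance genes map to 0.
    """
    vals = cohort.values
    if scope == "cohort":
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1).replace(0.0, np.inf)
        z = vals.sub(mu, axis=0).div(sd, axis=0)
    elif scope == "location":
        z = vals.copy()
        for loc in cohort.locations:
            cols = cohort.samples_of(loc)
            sub = vals[cols]
            sd = sub.std(axis=1).replace(0.0, np.inf)
            z[cols] = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    else:
        raise ValueError(f"unknown scope: {scope!r}")
    return np.tanh(z)


def state_space_cohort(cohort: ExpressionCohort, scope: str = "cohort") -> ExpressionCohort:
    """Cohort transformed onto the gene-state scale (see ``state_space_values``)."""
    return ExpressionCohort(state_space_values(cohort, scope), cohort.location_of)
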
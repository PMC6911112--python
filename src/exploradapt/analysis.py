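"""Adaptation experiments on top of the simulation core.

Covers the study's downstream questions: how far a location's samples get
toward another location's phenotype with and without exploration (transition
experiments and the "exploration necessary" comparison), whether adaptation
reverses more easily than it was acquired (reversal ratios), which locations
are intrinsically plastic (plasticity ranking), whether trajectories are
geometrically constrained (PCA vector fields and angle statistics), and
whether removing boundary subpopulations hinders adaptation (ablation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .dynamics import (
    DEFAULT_D0,
    DEFAULT_T_MAX,
    InteractionWeights,
    RegulatoryNetwork,
    TrajectoryRecord,
    interaction_weights,
    sample_distance,
    simulate,
    state_space_cohort,
)
from .phenotype import (
    ExpressionCohort,
    GenePathwayMap,
    LocationPhenotype,
    cohort_phenotypes,
    location_phenotype,
)

logger = logging.getLogger(__name__)


@dataclass
class TransitionSummary:
    """Aggregate of per-sample adaptation runs from one location toward another."""

    source: str
    target: str
    mode: str
    final_gd: np.ndarray  # per simulated sample
    final_converged_pct: np.ndarray  # per simulated sample, in [0, 100]
    sample_ids: list[str]
    seeds: list[int]
    records: list[TrajectoryRecord] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def mean_final_gd(self) -> float:
        return float(np.mean(self.final_gd))

    @property
    def mean_converged_pct(self) -> float:
        return float(np.mean(self.final_converged_pct))


@dataclass
class SimulationContext:
    """Shared precomputation for simulation experiments on one cohort.

    Holds the state-space transform of the cohort (tanh of cohort-wide
    per-gene z-scores), its phenotypes, per-location target intervals, and
    per-location interaction weights, so repeated experiments do not
    recompute them.
    """

    cohort: ExpressionCohort
    network: RegulatoryNetwork
    pathway_map: GenePathwayMap
    lo_pct: float = 10.0
    hi_pct: float = 90.0

    def __post_init__(self) -> None:
        self.state_cohort = state_space_cohort(self.cohort)
        self.state_values = self.state_cohort.values.reindex(self.network.genes)
        if self.state_values.isna().any().any():
            raise ValueError("network genes missing from cohort expression")
        self.phenotypes = cohort_phenotypes(self.state_cohort, self.pathway_map)
        self._targets: dict[str, LocationPhenotype] = {}
        self._weights: dict[str, InteractionWeights] = {}

    def targets_of(self, location: str) -> LocationPhenotype:
        if location not in self._targets:
            self._targets[location] = location_phenotype(
                self.phenotypes, self.cohort.location_of, location,
                self.lo_pct, self.hi_pct,
            )
        return self._targets[location]

    def weights_of(self, location: str) -> InteractionWeights:
        if location not in self._weights:
            self._weights[location] = interaction_weights(
                self.cohort, location, self.network
            )
        return self._weights[location]

    def initial_state(self, sample_id: str) -> np.ndarray:
        return self.state_values[sample_id].to_numpy(float)


def transition_experiment(
    context: SimulationContext,
    source: str,
    target: str,
    mode: str = "exploratory",
    D0: float = DEFAULT_D0,
    t_max: int = DEFAULT_T_MAX,
    seeds: Sequence[int] = (0,),
    max_samples: int | None = None,
    keep_records: bool = False,
    **simulate_kwargs,
) -> TransitionSummary:
    """Simulate every source sample toward the target location's intervals.

    Each simulated sample i is paired with ``seeds[i % len(seeds)]``.
    ``max_samples`` truncates the source population (first samples in cohort
    order) to bound cost.
    """
    samples = list(context.cohort.samples_of(source))
    if not samples:
        raise ValueError(f"empty location: {source!r}")
    if max_samples is not None:
        samples = samples[:max_samples]
    targets = context.targets_of(target)
    J0 = context.weights_of(source)
    final_gd, final_conv, used_seeds, records = [], [], [], []
    m = targets.activities.shape[0]
    for i, sid in enumerate(samples):
        run_seed = int(seeds[i % len(seeds)])
        rec = simulate(
            context.initial_state(sid),
            context.network,
            J0,
            targets,
            context.pathway_map,
            mode=mode,
            D0=D0,
            t_max=t_max,
            seed=np.random.default_rng(np.random.SeedSequence([run_seed, i])),
            **simulate_kwargs,
        )
        final_gd.append(rec.final_gd)
        final_conv.append(100.0 * rec.converged_count[-1] / m)
        used_seeds.append(run_seed)
        if keep_records:
            records.append(rec)
    return TransitionSummary(
        source=source,
        target=target,
        mode=mode,
        final_gd=np.asarray(final_gd),
        final_converged_pct=np.asarray(final_conv),
        sample_ids=samples,
        seeds=used_seeds,
        records=records if keep_records else None,
        metadata={"D0": D0, "t_max": t_max, **simulate_kwargs},
    )


def exploration_necessary(
    exploratory: TransitionSummary, intrinsic: TransitionSummary
) -> bool:
    """True when exploration reaches the target closer than intrinsic dynamics."""
    if (exploratory.source, exploratory.target) != (intrinsic.source, intrinsic.target):
        raise ValueError("summaries describe different transitions")
    return exploratory.mean_final_gd < intrinsic.mean_final_gd


@dataclass
class ReversalRatios:
    gd_ratio: float  # reverse / forward mean final GD (nan if forward is 0)
    converged_ratio: float  # reverse / forward mean converged fraction


def reversal_ratios(
    forward: TransitionSummary, reverse: TransitionSummary
) -> ReversalRatios:
    """Reverse/forward ratios of mean final GD and mean converged fraction."""
    if (forward.source, forward.target) != (reverse.target, reverse.source):
        raise ValueError("reverse summary does not mirror the forward transition")
    if forward.mean_final_gd == 0:
        warnings.warn("forward mean GD is 0; GD ratio undefined", stacklevel=2)
        gd_ratio = float("nan")
    else:
        gd_ratio = reverse.mean_final_gd / forward.mean_final_gd
    if forward.mean_converged_pct == 0:
        conv_ratio = float("nan")
    else:
        conv_ratio = reverse.mean_converged_pct / forward.mean_converged_pct
    return ReversalRatios(float(gd_ratio), float(conv_ratio))


def intrinsic_plasticity_ranking(
    context: SimulationContext,
    locations: Sequence[str] | None = None,
    t_max: int = DEFAULT_T_MAX,
    seeds: Sequence[int] = (0,),
    max_samples: int | None = None,
    **simulate_kwargs,
) -> pd.DataFrame:
    """Order locations from intrinsically rigid to intrinsically plastic.

    Each location's samples are run in intrinsic mode (dJ = 0) against the
    location's own intervals for the full horizon; plasticity is the mean L1
    phenotype drift Σ_j |y_j(t_max) − y_j(0)|.  Ascending drift = rigid →
    plastic.  Deterministic given the inputs (intrinsic runs are noise-free).
    """
    locations = list(locations or context.cohort.locations)
    drift = {}
    for loc in locations:
        summary = transition_experiment(
            context, loc, loc,
            mode="intrinsic", t_max=t_max, seeds=seeds,
            max_samples=max_samples, keep_records=True,
            stop_early=False, **simulate_kwargs,
        )
        per_sample = [
            float(np.abs(rec.phenotypes[-1] - rec.phenotypes[0]).sum())
            for rec in summary.records
        ]
        drift[loc] = np.mean(per_sample)
    out = pd.DataFrame({"mean_drift": pd.Series(drift)})
    out = out.sort_values("mean_drift")
    out["rank"] = range(1, len(out) + 1)
    return out


@dataclass
class VectorField:
    """PCA embedding of matched start/end phenotypes with per-sample arrows."""

    origins: np.ndarray  # (n_samples, n_components)
    tips: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    @property
    def arrows(self) -> np.ndarray:
        return self.tips - self.origins


def pca_vector_field(
    start_phenotypes: np.ndarray | pd.DataFrame,
    end_phenotypes: np.ndarray | pd.DataFrame,
    n_components: int = 3,
) -> VectorField:
    """Embed matched start/end phenotypes with a PCA fit on their union.

    The sign of each component is fixed by forcing its largest-magnitude
    loading positive, so arrow orientations are reproducible.
    """
    start = np.asarray(start_phenotypes, float)
    end = np.asarray(end_phenotypes, float)
    if start.shape != end.shape:
        raise ValueError("start and end phenotypes must be matched per sample")
    if start.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    stacked = np.vstack([start, end])
    if n_components > min(stacked.shape):
        raise ValueError("n_components exceeds the rank of the stacked phenotypes")
    pca = PCA(n_components=n_components)
    pca.fit(stacked)
    comps = pca.components_.copy()
    for c in range(comps.shape[0]):
        if comps[c, np.argmax(np.abs(comps[c]))] < 0:
            comps[c] = -comps[c]
    origins = (start - pca.mean_) @ comps.T
    tips = (end - pca.mean_) @ comps.T
    return VectorField(origins, tips, comps, pca.explained_variance_ratio_)


@dataclass
class AngleDistribution:
    angles_deg: np.ndarray
    n_excluded: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.angles_deg))

    @property
    def std(self) -> float:
        return float(np.std(self.angles_deg))


def trajectory_angles(
    arrows_a: np.ndarray,
    arrows_b: np.ndarray,
    space: str = "full",
    n_components: int = 3,
) -> AngleDistribution:
    """Angles (degrees) between matched arrow pairs sharing an origin.

    Arrow i of ``arrows_a`` is compared with arrow i of ``arrows_b`` via
    arccos of the normalized dot product.  Pairs containing a zero-length
    arrow are excluded with a warning.  ``space="pca3"`` first projects both
    arrow sets onto the top principal directions of the pooled arrows.
    """
    a = np.atleast_2d(np.asarray(arrows_a, float))
    b = np.atleast_2d(np.asarray(arrows_b, float))
    if a.shape != b.shape:
        raise ValueError("arrow sets must be matched (same shape)")
    if space == "pca3":
        pooled = np.vstack([a, b])
        pca = PCA(n_components=min(n_components, *pooled.shape))
        pca.fit(pooled)
        a = a @ pca.components_.T
        b = b @ pca.components_.T
    elif space != "full":
        raise ValueError(f"unknown space: {space!r}")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.all():
        warnings.warn(
            f"excluded {int((~ok).sum())} zero-length arrow pair(s)", stacklevel=2
        )
    if not ok.any():
        raise ValueError("no non-zero arrow pairs")
    cos = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    angles = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return AngleDistribution(angles, int((~ok).sum()))


@dataclass
class AblationResult:
    strategy: str
    removed_a: list[str]
    removed_b: list[str]
    baseline_mean_gd: dict[str, float]  # per direction "A->B", "B->A"
    ablated_mean_gd: dict[str, float]

    @property
    def baseline_overall(self) -> float:
        return float(np.mean(list(self.baseline_mean_gd.values())))

    @property
    def ablated_overall(self) -> float:
        return float(np.mean(list(self.ablated_mean_gd.values())))


def _closest_samples(
    context: SimulationContext, loc: str, other: str, k: int
) -> list[str]:
    """The k samples of ``loc`` with smallest GD to ``other``'s intervals."""
    targets = context.targets_of(other)
    order = list(targets.pathway_ids)
    gds = {}
    for sid in context.cohort.samples_of(loc):
        y = context.phenotypes.loc[order, sid].to_numpy(float)
        gds[sid] = sample_distance(y, targets)[1]
    ranked = sorted(gds, key=lambda s: (gds[s], s))
    return ranked[:k]


def subpopulation_ablation(
    context: SimulationContext,
    loc_a: str,
    loc_b: str,
    k_a: int,
    k_b: int,
    strategy: str = "closest",
    seeds: Sequence[int] = (0,),
    mode: str = "exploratory",
    D0: float = DEFAULT_D0,
    t_max: int = DEFAULT_T_MAX,
    max_samples: int | None = None,
    **simulate_kwargs,
) -> AblationResult:
    """Remove boundary samples from two locations and re-run their transitions.

    ``strategy="closest"`` removes from each location the k samples whose
    phenotype has the smallest GD to the *other* location's target intervals
    (the samples that bridge the two populations); ``"random"`` removes k
    uniformly at random (seeded).  Transitions in both directions are re-run
    on the reduced populations — with targets recomputed from them — and the
    mean final GDs are reported against the un-ablated baseline.
    """
    n_a = len(context.cohort.samples_of(loc_a))
    n_b = len(context.cohort.samples_of(loc_b))
    if k_a >= n_a or k_b >= n_b:
        raise ValueError("cannot remove an entire location population")
    if strategy == "closest":
        removed_a = _closest_samples(context, loc_a, loc_b, k_a)
        removed_b = _closest_samples(context, loc_b, loc_a, k_b)
    elif strategy == "random":
        rng = np.random.default_rng(np.random.SeedSequence([int(seeds[0]), 17]))
        removed_a = list(rng.choice(context.cohort.samples_of(loc_a), k_a, replace=False))
        removed_b = list(rng.choice(context.cohort.samples_of(loc_b), k_b, replace=False))
    else:
        raise ValueError(f"unknown strategy: {strategy!r}")

    def run(ctx: SimulationContext) -> dict[str, float]:
        out = {}
        for src, tgt in ((loc_a, loc_b), (loc_b, loc_a)):
            summary = transition_experiment(
                ctx, src, tgt, mode=mode, D0=D0, t_max=t_max,
                seeds=seeds, max_samples=max_samples, **simulate_kwargs,
            )
            out[f"{src}->{tgt}"] = summary.mean_final_gd
        return out

    baseline = run(context)
    removed = set(removed_a) | set(removed_b)
    keep = [s for s in context.cohort.sample_ids if s not in removed]
    reduced = ExpressionCohort(
        context.cohort.values[keep], context.cohort.location_of.loc[keep]
    )
    reduced_ctx = SimulationContext(
        reduced, context.network, context.pathway_map,
        context.lo_pct, context.hi_pct,
    )
    ablated = run(reduced_ctx)
    return AblationResult(strategy, removed_a, removed_b, baseline, ablated)
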
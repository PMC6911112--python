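"""Pathway-activity phenotypes.

A *sample phenotype* is the vector of per-pathway single-sample enrichment
activities computed from the sample's within-sample gene ranks (an ssGSEA-style
Kolmogorov–Smirnov running-sum statistic).  A *location phenotype* is the
per-pathway empirical distribution of activities over the samples carrying a
location label, summarized by a [p10, p90] target interval.

Scores are purely rank-based within each sample: any strictly increasing
transform of a sample's expression leaves its phenotype unchanged.  No
cross-sample normalization is applied, so a phenotype can be computed for one
simulated sample at a time without touching the rest of the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_EXPONENT = 0.25


@dataclass
class ExpressionCohort:
    """Expression matrix (genes x samples) with a location label per sample.

    Parameters
    ----------
    values : pandas.DataFrame
        Continuous expression values, rows indexed by unique gene symbols,
        columns by sample identifiers.  No missing values.
    location_of : pandas.Series
        Maps every sample identifier to a location label.
    """

    values: pd.DataFrame
    location_of: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        self.location_of = pd.Series(self.location_of)
        missing = self.values.columns.difference(self.location_of.index)
        if len(missing):
            raise ValueError(f"unlabeled samples: {list(missing[:5])}")
        self.location_of = self.location_of.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def locations(self) -> list[str]:
        return list(pd.unique(self.location_of))

    def samples_of(self, location: str) -> pd.Index:
        if location not in set(self.location_of):
            raise KeyError(f"unknown location: {location!r}")
        return self.sample_ids[(self.location_of == location).to_numpy()]


@dataclass
class GenePathwayMap:
    """Many-to-many gene -> pathway membership map.

    ``pathways`` maps a pathway id to its member gene set.  Genes may belong
    to several pathways or to none; the declared ``universe`` (all genes the
    map was built over) is what out-of-set complements are taken against.
    """

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.pathways = {k: frozenset(v) for k, v in self.pathways.items()}
        if not self.pathways:
            raise ValueError("pathway map must contain at least one pathway")
        if not self.universe:
            self.universe = frozenset().union(*self.pathways.values())
        stray = frozenset().union(*self.pathways.values()) - self.universe
        if stray:
            raise ValueError(f"pathway members outside declared universe: {sorted(stray)[:5]}")

    @property
    def m(self) -> int:
        return len(self.pathways)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.pathways)

    def membership_matrix(self, gene_order: Iterable[str]) -> tuple[np.ndarray, list[str]]:
        """Boolean (m x n_genes) membership matrix in a given gene order."""
        genes = list(gene_order)
        col = {g: i for i, g in enumerate(genes)}
        mat = np.zeros((self.m, len(genes)), dtype=bool)
        for row, (pid, members) in enumerate(self.pathways.items()):
            idx = [col[g] for g in members if g in col]
            mat[row, idx] = True
        return mat, list(self.pathways)

    def restricted_to(self, genes: Iterable[str]) -> "GenePathwayMap":
        """Drop member genes absent from ``genes``; error on emptied pathways."""
        keep = frozenset(genes)
        dropped = 0
        out: dict[str, frozenset[str]] = {}
        for pid, members in self.pathways.items():
            inside = members & keep
            dropped += len(members) - len(inside)
            if not inside:
                raise ValueError(f"pathway {pid!r} lost all members after gene filtering")
            out[pid] = inside
        if dropped:
            logger.warning("dropped %d pathway-member genes absent from the cohort", dropped)
        return GenePathwayMap(out, universe=self.universe & keep or frozenset(keep))


@dataclass
class LocationPhenotype:
    """Per-pathway activity samples and [p10, p90] target intervals of one location."""

    location: str
    activities: pd.DataFrame  # pathways x samples of that location
    lo_pct: float = 10.0
    hi_pct: float = 90.0

    def __post_init__(self) -> None:
        vals = self.activities.to_numpy(float)
        self.p_lo = pd.Series(
            np.percentile(vals, self.lo_pct, axis=1), index=self.activities.index
        )
        self.p_hi = pd.Series(
            np.percentile(vals, self.hi_pct, axis=1), index=self.activities.index
        )

    @property
    def pathway_ids(self) -> pd.Index:
        return self.activities.index

    @property
    def n_samples(self) -> int:
        return self.activities.shape[1]

    def intervals(self) -> pd.DataFrame:
        return pd.DataFrame({"p_lo": self.p_lo, "p_hi": self.p_hi})


def _sorted_rank_weights(col: np.ndarray, weight_exponent: float) -> tuple[np.ndarray, np.ndarray]:
    """Gene order by decreasing expression and rank weights in that order.

    Ranks are average ranks (ties share a rank), with the highest-expressed
    gene carrying the largest rank; ties in the walk order are broken by gene
    position, which is independent of sample order.
    """
    order = np.argsort(-col, kind="stable")
    ranks = rankdata(col)  # ascending average ranks
    weights = ranks[order] ** weight_exponent
    return order, weights


def _score_membership(
    memb_sorted: np.ndarray, weights: np.ndarray, set_sizes: np.ndarray
) -> np.ndarray:
    """Running-sum enrichment for each row of a sorted membership matrix.

    Score = sum over walk positions of (weighted in-set ECDF − out-of-set
    ECDF), i.e. the (signed) area under the running difference.
    """
    n = memb_sorted.shape[1]
    win = memb_sorted * weights  # (m, n)
    tot_in = win.sum(axis=1, keepdims=True)
    cum_in = np.cumsum(win, axis=1) / tot_in
    cum_out = np.cumsum(~memb_sorted, axis=1) / (n - set_sizes)[:, None]
    return (cum_in - cum_out).sum(axis=1)


def ssgsea_score(
    sample_values: pd.Series | np.ndarray,
    gene_set: Iterable[str] | Iterable[int],
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
    gene_ids: Iterable[str] | None = None,
) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Parameters
    ----------
    sample_values : Series (indexed by gene) or 1-D array of expression values.
    gene_set : member gene ids (or integer positions when ``sample_values`` is
        a bare array without ``gene_ids``).
    weight_exponent : exponent applied to within-sample average ranks when
        weighting in-set steps of the running sum (0 gives the unweighted
        Kolmogorov–Smirnov-like sum).
    """
    if isinstance(sample_values, pd.Series):
        genes = list(sample_values.index)
        col = sample_values.to_numpy(float)
    else:
        col = np.asarray(sample_values, float)
        genes = list(gene_ids) if gene_ids is not None else list(range(len(col)))
    if not np.all(np.isfinite(col)):
        raise ValueError("sample values must be finite")
    members = set(gene_set)
    if not members:
        raise ValueError("empty gene set")
    mask = np.fromiter((g in members for g in genes), bool, count=len(genes))
    if not mask.any():
        raise ValueError("empty gene set (no members in the gene universe)")
    if mask.all():
        raise ValueError("degenerate complement: gene set equals the whole universe")
    order, weights = _sorted_rank_weights(col, weight_exponent)
    score = _score_membership(mask[None, order], weights, np.array([mask.sum()]))
    return float(score[0])


def cohort_phenotypes(
    cohort: ExpressionCohort,
    pathway_map: GenePathwayMap,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> pd.DataFrame:
    """Activity matrix (pathways x samples) for every sample of a cohort.

    Pathway member genes absent from the cohort are dropped (with a logged
    warning); a pathway losing all members is an error.  Column order follows
    the cohort's sample order.
    """
    restricted = pathway_map.restricted_to(cohort.gene_ids)
    memb, pathway_ids = restricted.membership_matrix(cohort.gene_ids)
    sizes = memb.sum(axis=1)
    n_genes = len(cohort.gene_ids)
    if (sizes == n_genes).any():
        bad = [pathway_ids[i] for i in np.flatnonzero(sizes == n_genes)]
        raise ValueError(f"degenerate complement for pathways: {bad}")
    values = cohort.values.to_numpy(float)
    out = np.empty((memb.shape[0], values.shape[1]))
    for s in range(values.shape[1]):
        order, weights = _sorted_rank_weights(values[:, s], weight_exponent)
        out[:, s] = _score_membership(memb[:, order], weights, sizes)
    return pd.DataFrame(out, index=pathway_ids, columns=cohort.sample_ids)


def phenotype_matrix(
    values: np.ndarray,
    membership: np.ndarray,
    weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
) -> np.ndarray:
    """Low-level scorer: (m x n_samples) activities from raw arrays.

    ``values`` is genes x samples, ``membership`` a boolean m x genes matrix.
    Used in the simulation loop where constructing DataFrames per step would
    dominate the cost.
    """
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == membership.shape[1]:
        pass
    elif values.shape[1] == membership.shape[1] and values.shape[0] != membership.shape[1]:
        values = values.T
    sizes = membership.sum(axis=1)
    out = np.empty((membership.shape[0], values.shape[1]))
    for s in range(values.shape[1]):
        order, weights = _sorted_rank_weights(values[:, s], weight_exponent)
        out[:, s] = _score_membership(membership[:, order], weights, sizes)
    return out


def location_phenotype(
    phenotypes: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    location: str,
    lo_pct: float = 10.0,
    hi_pct: float = 90.0,
) -> LocationPhenotype:
    """Empirical activity distributions and [p10, p90] intervals of a location.

    Percentiles use linear interpolation between order statistics, identically
    in data analysis and in simulation targets.
    """
    labels = pd.Series(labels)
    cols = [s for s in phenotypes.columns if labels.get(s) == location]
    if not cols:
        raise KeyError(f"unknown or empty location: {location!r}")
    if len(cols) < 2:
        raise ValueError(f"location {location!r} has fewer than 2 samples")
    return LocationPhenotype(location, phenotypes[cols], lo_pct=lo_pct, hi_pct=hi_pct)
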
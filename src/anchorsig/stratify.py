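"""Cut-point dichotomization, marker co-occurrence, and sample clustering.

Markers are dichotomized against the cohort median or 25% quartile of a
probe's expression (quantiles use linear interpolation between order
statistics).  Under the default strict tie policy, a value exactly at the
cut-point is ``at_cutpoint`` — neither a hit nor a non-hit — reading
"higher than" / "lower than" literally.

Sample clustering is agglomerative hierarchical clustering on a signature
gene submatrix (default: Euclidean distance, complete linkage, per-gene row
standardization), cut at a user-declared k; composition tables summarize
stage or grade makeup per cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_data import ExpressionCohort, SampleMetadata
from .enrichment import percent_half_up

logger = logging.getLogger(__name__)

HIT, NON_HIT, AT_CUTPOINT = "hit", "non_hit", "at_cutpoint"

_QUANTILES = {"median": 0.5, "quartile25": 0.25}


@dataclass(frozen=True)
class CutpointConfig:
    """How cut-points are computed and ties handled."""

    statistic: str = "median"  # or "quartile25"
    tie_policy: str = "strict"  # or "inclusive"

    def __post_init__(self) -> None:
        if self.statistic not in _QUANTILES:
            raise ValueError(f"statistic must be one of {sorted(_QUANTILES)}")
        if self.tie_policy not in ("strict", "inclusive"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass
class StratificationResult:
    """Per-sample high/low calls for each marker, plus the cut-points used."""

    calls: pd.DataFrame  # index: sample_id; columns: markers; values in {hit, non_hit, at_cutpoint}
    cutpoints: dict[str, float]
    directions: dict[str, str]
    config: CutpointConfig

    def hit_count(self, marker: str) -> int:
        return int((self.calls[marker] == HIT).sum())


def dichotomize(
    cohort: ExpressionCohort,
    markers: Sequence[tuple[str, str]],
    config: CutpointConfig = CutpointConfig(),
    scope: Sequence[str] | None = None,
) -> StratificationResult:
    """Call each sample high/low against each marker's cut-point.

    ``markers`` is a list of (probe_id, direction) with direction in
    {"high_is_hit", "low_is_hit"}.  The cut-point is computed over ``scope``
    (default: every sample in the cohort — tumors and controls share one
    cut-off).  A constant marker leaves every sample at the cut-point, with a
    warning.  Markers must be complete (no missing values) over the scope.
    """
    scope = list(scope) if scope is not None else list(cohort.sample_ids)
    if not scope:
        raise ValueError("scope must be non-empty")
    sub = cohort.subset_samples(scope)
    q = _QUANTILES[config.statistic]

    calls: dict[str, list[str]] = {}
    cutpoints: dict[str, float] = {}
    directions: dict[str, str] = {}
    for probe, direction in markers:
        if direction not in ("high_is_hit", "low_is_hit"):
            raise ValueError(f"unknown direction {direction!r} for marker {probe!r}")
        x = sub.probe_values(probe)
        if np.isnan(x).any():
            raise ValueError(f"marker {probe!r} has missing values in scope")
        cut = float(np.quantile(x, q))  # linear interpolation between order statistics
        cutpoints[probe] = cut
        directions[probe] = direction
        if np.allclose(x, x[0]):
            logger.warning("dichotomize: marker %r is constant; all samples at cut-point", probe)
            calls[probe] = [AT_CUTPOINT] * len(scope)
            continue
        high = x > cut
        low = x < cut
        if config.tie_policy == "inclusive":
            if direction == "high_is_hit":
                high = x >= cut
            else:
                low = x <= cut
        hit_mask = high if direction == "high_is_hit" else low
        other_mask = low if direction == "high_is_hit" else high
        col = np.full(len(scope), AT_CUTPOINT, dtype=object)
        col[hit_mask] = HIT
        col[other_mask] = NON_HIT
        calls[probe] = list(col)

    frame = pd.DataFrame(calls, index=pd.Index(scope, name="sample_id"))
    return StratificationResult(frame, cutpoints, directions, config)


def cooccurrence_counts(
    strata: StratificationResult,
    marker_subsets: Sequence[Sequence[str]],
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Count samples satisfying each marker conjunction, optionally per group.

    Each subset is a conjunction: a sample qualifies when every listed marker
    is a hit.  The empty subset is vacuously true (count = group size).
    Returns a tidy frame (combination, group, count, n, fraction).
    """
    known = set(strata.calls.columns)
    for subset in marker_subsets:
        unknown = [m for m in subset if m not in known]
        if unknown:
            raise ValueError(f"unknown markers in subset: {unknown}")

    if groups is None:
        groups = {"all": list(strata.calls.index)}
    rows = []
    for subset in marker_subsets:
        label = " & ".join(subset) if subset else "(all)"
        for gname, gsamples in groups.items():
            gsamples = [s for s in gsamples if s in strata.calls.index]
            if not gsamples:
                continue
            block = strata.calls.loc[gsamples]
            ok = np.ones(len(gsamples), dtype=bool)
            for m in subset:
                ok &= (block[m] == HIT).to_numpy()
            count = int(ok.sum())
            rows.append(
                {
                    "combination": label,
                    "group": gname,
                    "count": count,
                    "n": len(gsamples),
                    "fraction": count / len(gsamples),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Hierarchical clustering of samples on a gene signature."""

    assignments: dict[str, int]
    linkage_method: str
    distance_metric: str
    k: int
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    leaf_order: list[str] = field(default_factory=list)

    def cluster_samples(self, cluster_id: int) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cluster_id]


def cluster_samples(
    cohort: ExpressionCohort,
    signature_probes: Sequence[str],
    k: int,
    linkage: str = "complete",
    distance: str = "euclidean",
    row_standardize: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of samples on the signature submatrix.

    Genes (rows) are optionally standardized to zero mean / unit variance
    before computing sample-to-sample distances, mirroring heat-map practice.
    The tree is cut at ``k`` clusters; output is deterministic for fixed
    inputs.  Cluster ids are relabeled 1..k by first appearance in the
    cohort's sample order.
    """
    if len(signature_probes) < 2:
        raise ValueError("need at least 2 signature probes")
    missing = [p for p in signature_probes if p not in cohort.probe_index]
    if missing:
        raise ValueError(f"signature probes absent from cohort: {missing}")
    if not 2 <= k <= len(cohort.sample_ids):
        raise ValueError("need 2 <= k <= number of samples")

    sub = cohort.subset_probes(list(signature_probes))
    X = sub.values.copy()
    if np.isnan(X).any():
        raise ValueError("signature submatrix has missing values")
    if row_standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    D = pdist(X.T, metric=distance)
    Z = hierarchy.linkage(D, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel by first appearance for determinism across scipy versions
    relabel: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels.append(relabel[c])
    leaf_order = [sub.sample_ids[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(
        assignments=dict(zip(sub.sample_ids, labels)),
        linkage_method=linkage,
        distance_metric=distance,
        k=k,
        linkage_matrix=Z,
        leaf_order=leaf_order,
    )


def ordered_matrix(cohort: ExpressionCohort, result: ClusterResult,
                   signature_probes: Sequence[str]) -> pd.DataFrame:
    """Signature submatrix with samples in dendrogram leaf order (heat-map export)."""
    sub = cohort.subset_probes(list(signature_probes)).subset_samples(result.leaf_order)
    return sub.to_frame()


def cluster_composition(
    result: ClusterResult | Mapping[str, int],
    metadata: Iterable[SampleMetadata],
    stage_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stage/grade composition per cluster, with integer half-up percentages.

    Samples without a stage label are tallied under ``(unlabeled)`` and
    excluded from the percentage denominator.  The dominant stage of each
    cluster is flagged.
    """
    assignments = result.assignments if isinstance(result, ClusterResult) else dict(result)
    stage_by_sample = {m.sample_id: m.stage for m in metadata}
    rows = []
    for cluster_id in sorted(set(assignments.values())):
        samples = [s for s, c in assignments.items() if c == cluster_id]
        staged = [s for s in samples if stage_by_sample.get(s) is not None]
        unlabeled = len(samples) - len(staged)
        counts: dict[str, int] = {}
        for s in staged:
            counts[stage_by_sample[s]] = counts.get(stage_by_sample[s], 0) + 1
        stages = list(stage_order) if stage_order else sorted(counts)
        dominant = max(counts, key=lambda st: counts[st]) if counts else None
        for st in stages:
            c = counts.get(st, 0)
            rows.append(
                {
                    "cluster": cluster_id,
                    "stage": st,
                    "count": c,
                    "n_staged": len(staged),
                    "percent": percent_half_up(c, len(staged), 0) if staged else 0.0,
                    "dominant": st == dominant,
                }
            )
        if unlabeled:
            rows.append(
                {
                    "cluster": cluster_id,
                    "stage": "(unlabeled)",
                    "count": unlabeled,
                    "n_staged": len(staged),
                    "percent": float("nan"),
                    "dominant": False,
                }
            )
    return pd.DataFrame(rows)
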
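"""Network enrichment significance testing (NEST).

The test asks whether association statistics inside a pre-specified network
of brain locations are stochastically more extreme than those outside it.
Locations are ranked by their signed statistic T_v in descending order and a
running sum walks down the list: it rises at in-network positions (by
|T_v| / sum of in-network |T|, so extreme, sign-consistent in-network values
drive it up) and falls by a uniform 1/#Nc at out-of-network positions. The
enrichment score (ES) is the largest magnitude the walk attains. The null
distribution is built by permuting the phenotype across *participants* and
recomputing the whole association map, which respects the spatial structure
of the data; the p-value is the usual permutation count with the smallest
attainable value 1/(K+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import AssociationMap, ModelSpec, SubjectDataset, compute_statistic, _gam_design

VARIANTS = ("weighted_one_sided", "unweighted_two_sided")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class NetworkPartition:
    """Assignment of every analysis location to an integer network label.

    ``target_label`` selects the network of interest N; everything else is
    its complement Nc. N must be neither empty nor the whole map.
    """

    labels: np.ndarray
    location_ids: list[str]
    target_label: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.location_ids = [str(s) for s in self.location_ids]
        if len(self.labels) != len(self.location_ids):
            raise ValueError("labels and location_ids differ in length")
        n_in = int(np.sum(self.labels == self.target_label))
        if n_in == 0:
            raise ValueError(
                f"target label {self.target_label!r} not present in partition"
            )
        if n_in == len(self.labels):
            raise ValueError("network covers every location; complement is empty")

    @property
    def in_network(self) -> np.ndarray:
        return self.labels == self.target_label

    @property
    def n_in(self) -> int:
        return int(self.in_network.sum())

    @property
    def n_out(self) -> int:
        return len(self.labels) - self.n_in

    def with_target(self, target_label: int) -> "NetworkPartition":
        return NetworkPartition(self.labels, self.location_ids, target_label)


@dataclass
class RankedList:
    """Locations sorted by T descending, ties broken by ascending index."""

    order: np.ndarray
    sorted_T: np.ndarray
    membership: np.ndarray


@dataclass
class RunningSum:
    RS: np.ndarray  # length V + 1, RS[0] == 0
    variant: str


@dataclass
class EnrichmentResult:
    es_obs: float
    null_es: np.ndarray
    p_value: float
    K: int
    seed: int | None
    variant: str
    effect: str
    network_label: int
    method: str = "nest"


# ---------------------------------------------------------------------------
# Ranking, running sum, enrichment score
# ---------------------------------------------------------------------------


def _check_aligned(map_ids: Sequence[str], part_ids: Sequence[str]) -> None:
    if list(map_ids) != list(part_ids):
        for a, b in zip(map_ids, part_ids):
            if a != b:
                raise ValueError(
                    f"association map and partition are misaligned: {a!r} vs {b!r}"
                )
        raise ValueError(
            "association map and partition have different numbers of locations"
        )


def rank_vertices(amap: AssociationMap, partition: NetworkPartition) -> RankedList:
    """Sort locations by T in descending order and mark in-network positions."""
    _check_aligned(amap.location_ids, partition.location_ids)
    V = len(amap.T)
    order = np.lexsort((np.arange(V), -amap.T))
    return RankedList(
        order=order,
        sorted_T=amap.T[order],
        membership=partition.in_network[order],
    )


def _rs_increments(
    sorted_T: np.ndarray, membership: np.ndarray, variant: str
) -> np.ndarray:
    V = len(sorted_T)
    n_in = int(membership.sum())
    n_out = V - n_in
    if n_out == 0 or n_in == 0:
        raise ValueError("network must be neither empty nor the whole map")
    if variant == "weighted_one_sided":
        denom = float(np.abs(sorted_T[membership]).sum())
        if denom == 0.0:
            raise ValueError(
                "all in-network statistics are zero; weighted running sum undefined"
            )
        up = np.abs(sorted_T) / denom
    elif variant == "unweighted_two_sided":
        up = np.full(V, 1.0 / n_in)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return np.where(membership, up, -1.0 / n_out)


def running_sum(ranked: RankedList, variant: str = "weighted_one_sided") -> RunningSum:
    """Cumulative walk down the ranked list (starts and ends at 0)."""
    inc = _rs_increments(ranked.sorted_T, ranked.membership, variant)
    RS = np.concatenate([[0.0], np.cumsum(inc)])
    return RunningSum(RS=RS, variant=variant)


def enrichment_score(rs: RunningSum) -> float:
    """Maximum deviation from zero attained by the running sum."""
    return float(np.max(np.abs(rs.RS[1:])))


def _es_one(T: np.ndarray, in_network: np.ndarray, variant: str) -> float:
    V = len(T)
    order = np.lexsort((np.arange(V), -T))
    inc = _rs_increments(T[order], in_network[order], variant)
    return float(np.max(np.abs(np.cumsum(inc))))


def _es_many(Tmat: np.ndarray, in_network: np.ndarray, variant: str) -> np.ndarray:
    """ES for each column of a (V, K) matrix of association maps.

    Vectorized across columns: argsort per column with the same tie rule as
    rank_vertices, then a cumulative-sum walk per column.
    """
    V, K = Tmat.shape
    idx = np.arange(V)[:, None]
    order = np.lexsort((np.broadcast_to(idx, Tmat.shape), -Tmat), axis=0)
    sortedT = np.take_along_axis(Tmat, order, axis=0)
    member = in_network[order]
    n_in = int(in_network.sum())
    n_out = V - n_in
    if variant == "weighted_one_sided":
        absT = np.abs(sortedT)
        denom = np.where(member, absT, 0.0).sum(axis=0)
        if np.any(denom == 0.0):
            raise ValueError(
                "all in-network statistics are zero; weighted running sum undefined"
            )
        up = absT / denom
    elif variant == "unweighted_two_sided":
        up = np.full_like(Tmat, 1.0 / n_in)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    inc = np.where(member, up, -1.0 / n_out)
    return np.max(np.abs(np.cumsum(inc, axis=0)), axis=0)


# ---------------------------------------------------------------------------
# Permutation p-value
# ---------------------------------------------------------------------------


def permutation_pvalue(
    es_obs: float, null_es: np.ndarray, tie_ge: bool = False, atol: float = 1e-12
) -> float:
    """Permutation p-value (1 + #{null > observed}) / (K + 1).

    The strict ">" is the standard counting rule; ``tie_ge`` switches to the
    ">=" convention, which counts ties against the observed score. ``atol``
    guards the comparison against floating-point noise: scores equal at
    exact arithmetic (e.g., saturated walks that both reach 1) otherwise
    resolve by rounding error in the cumulative sums.
    """
    null_es = np.asarray(null_es, dtype=float)
    if null_es.size == 0:
        raise ValueError("null_es must be nonempty")
    K = null_es.size
    if tie_ge:
        more = int(np.sum(null_es >= es_obs - atol))
    else:
        more = int(np.sum(null_es > es_obs + atol))
    return (1 + more) / (K + 1)


# ---------------------------------------------------------------------------
# Participant-permutation null
# ---------------------------------------------------------------------------


def _permuted_phenotypes(pheno: pd.DataFrame, perm: np.ndarray) -> pd.DataFrame:
    out = pheno.copy()
    out.iloc[:, :] = pheno.iloc[perm].to_numpy()
    return out


def permutation_association_maps(
    data: SubjectDataset,
    spec: ModelSpec,
    K: int,
    seed: int | None,
    scheme: str = "simple",
) -> np.ndarray:
    """(V, K) matrix of association maps under participant permutation.

    Each column is the statistic map after permuting the phenotype rows
    across subjects (the whole row block, keeping covariate-covariate
    structure intact). Seeding: one master seed spawns one substream per
    permutation, so the stream is invariant to execution order.

    scheme "simple" permutes phenotype rows; "freedman_lane" (regression
    statistics only) permutes residuals from the intercept+sex reduced model
    of each location and recomputes the statistic on the reconstructed data.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if scheme not in ("simple", "freedman_lane"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    n = data.n_subjects
    children = np.random.SeedSequence(seed).spawn(K)
    perms = [np.random.default_rng(c).permutation(n) for c in children]

    if scheme == "freedman_lane" and spec.stat_kind in ("ols_wald", "gam_wald"):
        # reduced model: everything but the tested effect's block
        D, slices = _gam_design(data.phenotypes, spec.spline_df)
        keep = np.setdiff1d(np.arange(D.shape[1]), slices[spec.effect])
        Dr = D[:, keep]
        H = Dr @ np.linalg.pinv(Dr)
        fitted = H @ data.X
        resid = data.X - fitted
        cols = []
        for perm in perms:
            Xstar = fitted + resid[perm]
            cols.append(compute_statistic(Xstar, data.phenotypes, spec))
        return np.column_stack(cols)

    if spec.stat_kind == "pearson":
        # fast path: correlate standardized X once against all permuted covariates
        from .stats import effect_covariate

        g = effect_covariate(data.phenotypes, spec.effect)
        g = g - g.mean()
        gn = np.sqrt(g @ g)
        if gn == 0.0:
            raise ValueError(f"effect covariate for {spec.effect!r} is constant")
        Xc = data.X - data.X.mean(axis=0)
        xnorm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
        xnorm[xnorm == 0.0] = np.inf  # constant locations -> r = 0
        G = np.column_stack([g[perm] for perm in perms])
        R = (Xc.T @ G) / (xnorm[:, None] * gn)
        return np.clip(R, -1.0, 1.0)

    cols = []
    for perm in perms:
        cols.append(
            compute_statistic(data.X, _permuted_phenotypes(data.phenotypes, perm), spec)
        )
    return np.column_stack(cols)


def nest_test(
    data: SubjectDataset,
    partition: NetworkPartition | Sequence[NetworkPartition],
    spec: ModelSpec,
    K: int = 999,
    seed: int | None = None,
    variant: str = "weighted_one_sided",
    tie_ge: bool = False,
    scheme: str = "simple",
) -> EnrichmentResult | list[EnrichmentResult]:
    """Participant-permutation enrichment test.

    When several partitions (e.g., the same label map with different target
    labels) are passed, the permutation association maps are computed once
    and reused for all networks; only the ES extraction differs.
    """
    single = isinstance(partition, NetworkPartition)
    parts: list[NetworkPartition] = [partition] if single else list(partition)
    if not parts:
        raise ValueError("at least one partition required")
    obs = compute_statistic(data.X, data.phenotypes, spec)
    amap = AssociationMap(obs, list(data.location_ids), spec.effect, spec.stat_kind)
    null_maps = permutation_association_maps(data, spec, K, seed, scheme)
    results = []
    for part in parts:
        _check_aligned(amap.location_ids, part.location_ids)
        es_obs = _es_one(amap.T, part.in_network, variant)
        null_es = _es_many(null_maps, part.in_network, variant)
        p = permutation_pvalue(es_obs, null_es, tie_ge)
        results.append(
            EnrichmentResult(
                es_obs=es_obs,
                null_es=null_es,
                p_value=p,
                K=K,
                seed=seed,
                variant=variant,
                effect=spec.effect,
                network_label=part.target_label,
                method="nest",
            )
        )
    return results[0] if single else results


def exhaustive_nest_pvalue(
    data: SubjectDataset,
    partition: NetworkPartition,
    spec: ModelSpec,
    variant: str = "weighted_one_sided",
    tie_ge: bool = False,
    atol: float = 1e-12,
) -> float:
    """Exact p-value by enumerating every phenotype ordering (small n only).

    The identity ordering is the observed arrangement, so the count starts
    at the conventional +1 and runs over the n! - 1 non-identity orderings.
    Ties are resolved with the same convention and numerical tolerance as
    :func:`permutation_pvalue`.
    """
    n = data.n_subjects
    if n > 8:
        raise ValueError("exhaustive enumeration is limited to n <= 8 subjects")
    obs = compute_statistic(data.X, data.phenotypes, spec)
    es_obs = _es_one(obs, partition.in_network, variant)
    more = 0
    total = 0
    for perm in _iter_permutations(range(n)):
        perm = np.asarray(perm)
        if np.array_equal(perm, np.arange(n)):
            continue
        T = compute_statistic(
            data.X, _permuted_phenotypes(data.phenotypes, perm), spec
        )
        es = _es_one(T, partition.in_network, variant)
        if (es >= es_obs - atol) if tie_ge else (es > es_obs + atol):
            more += 1
        total += 1
    return (1 + more) / (total + 1)


# ---------------------------------------------------------------------------
# Stochastic-extremeness diagnostic
# ---------------------------------------------------------------------------


def ecdf_extremeness_diagnostic(
    amap: AssociationMap, partition: NetworkPartition
) -> dict[str, np.ndarray]:
    """Empirical tail-probability curves inside vs outside the network.

    For positive thresholds w: Pr(T > w) within N and within Nc; for
    negative w: Pr(T < w). Intended for plotting/inspection of the
    "stochastically more extreme" ordering, not as a test.
    """
    _check_aligned(amap.location_ids, partition.location_ids)
    T_in = amap.T[partition.in_network]
    T_out = amap.T[~partition.in_network]
    w_pos = np.unique(np.concatenate([[0.0], amap.T[amap.T > 0]]))
    w_neg = np.unique(np.concatenate([amap.T[amap.T < 0], [0.0]]))
    return {
        "w_positive": w_pos,
        "in_gt": np.array([np.mean(T_in > w) for w in w_pos]),
        "out_gt": np.array([np.mean(T_out > w) for w in w_pos]),
        "w_negative": w_neg,
        "in_lt": np.array([np.mean(T_in < w) for w in w_neg]),
        "out_lt": np.array([np.mean(T_out < w) for w in w_neg]),
    }
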
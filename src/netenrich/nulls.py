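"""Competitor null models: spatial-unit permutation and the spin test.

Both procedures share NEST's observed statistic machinery but randomize
*spatial* units instead of participants. The label-permutation test
(FastGSEA-style) shuffles network membership across locations while holding
the association map fixed; the spin test rotates a spherical projection of
the network label map and measures spatial correspondence (Pearson
correlation of the map with the binary membership indicator). Both implicitly
assume spatial exchangeability / stationarity, which smooth association maps
violate — they are provided for calibration contrasts, not for inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .enrichment import (
    EnrichmentResult,
    NetworkPartition,
    _check_aligned,
    _es_one,
    permutation_pvalue,
)
from .stats import AssociationMap


@dataclass
class SpherePointSet:
    """Unit-sphere coordinates per analysis location."""

    coords: np.ndarray  # (V, 3)
    location_ids: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.location_ids = [str(s) for s in self.location_ids]
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (V, 3)")
        if len(self.location_ids) != len(self.coords):
            raise ValueError("coords and location_ids differ in length")
        norms = np.linalg.norm(self.coords, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("sphere coordinates must have unit norm")


def label_permutation_test(
    amap: AssociationMap,
    partition: NetworkPartition,
    K: int = 999,
    seed: int | None = None,
    variant: str = "weighted_one_sided",
    tie_ge: bool = False,
) -> EnrichmentResult:
    """Enrichment test with a vertex-permutation null (FastGSEA-style).

    The observed ES is exactly the one NEST computes for the same map and
    partition; the null shuffles network membership uniformly across
    locations, holding the association map fixed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    _check_aligned(amap.location_ids, partition.location_ids)
    member = partition.in_network
    es_obs = _es_one(amap.T, member, variant)
    rng = np.random.default_rng(seed)
    null_es = np.empty(K)
    for k in range(K):
        null_es[k] = _es_one(amap.T, rng.permutation(member), variant)
    p = permutation_pvalue(es_obs, null_es, tie_ge)
    return EnrichmentResult(
        es_obs=es_obs,
        null_es=null_es,
        p_value=p,
        K=K,
        seed=seed,
        variant=variant,
        effect=amap.effect,
        network_label=partition.target_label,
        method="label_permutation",
    )


def random_rotation(rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Haar-uniform 3x3 rotation matrix via QR of a standard-normal matrix.

    The QR factor is sign-corrected (R's diagonal made positive) so the
    distribution is exactly uniform, and a final column flip enforces
    determinant +1.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, -1] *= -1.0
    return Q


def _rotated_labels(
    labels: np.ndarray,
    coords: np.ndarray,
    tree: cKDTree,
    R: np.ndarray,
) -> np.ndarray:
    """Label map after rotating the sphere: each location takes the label of
    the nearest original location to its rotated position (chord distance,
    equivalent in ordering to great-circle distance on the unit sphere)."""
    _, idx = tree.query(coords @ R.T)
    return labels[idx]


def spin_test(
    amap: AssociationMap,
    partition: NetworkPartition,
    sphere: SpherePointSet,
    K: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
    excluded_label: int | None = None,
) -> EnrichmentResult:
    """Spin test of spatial correspondence between map and network.

    Observed statistic: Pearson correlation between T and the binary
    membership indicator. Null: the network label map is rotated by K
    Haar-uniform rotations (labels reassigned by nearest rotated neighbor)
    and the correlation recomputed. ``alternative`` is "greater" (one-sided
    on positive correlation, default) or "two_sided_abs" (counting on
    |correlation|). Locations whose rotated source carries
    ``excluded_label`` are dropped from the null correlation.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if alternative not in ("greater", "two_sided_abs"):
        raise ValueError("alternative must be 'greater' or 'two_sided_abs'")
    _check_aligned(amap.location_ids, partition.location_ids)
    _check_aligned(amap.location_ids, sphere.location_ids)
    member = partition.in_network.astype(float)
    if member.min() == member.max():
        raise ValueError("membership indicator is constant; correlation undefined")

    def corr(t: np.ndarray, m: np.ndarray) -> float:
        if m.min() == m.max():
            return 0.0  # degenerate rotated indicator: no alignment signal
        tc = t - t.mean()
        mc = m - m.mean()
        return float(tc @ mc / np.sqrt((tc @ tc) * (mc @ mc)))

    obs = corr(amap.T, member)
    rng = np.random.default_rng(seed)
    tree = cKDTree(sphere.coords)
    null = np.empty(K)
    for k in range(K):
        R = random_rotation(rng)
        lab = _rotated_labels(partition.labels, sphere.coords, tree, R)
        keep = np.ones(len(lab), dtype=bool)
        if excluded_label is not None:
            keep = lab != excluded_label
        null[k] = corr(amap.T[keep], (lab[keep] == partition.target_label).astype(float))

    if alternative == "greater":
        p = permutation_pvalue(obs, null)
    else:
        p = permutation_pvalue(abs(obs), np.abs(null))
    return EnrichmentResult(
        es_obs=obs,
        null_es=null,
        p_value=p,
        K=K,
        seed=seed,
        variant=alternative,
        effect=amap.effect,
        network_label=partition.target_label,
        method="spin",
    )
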
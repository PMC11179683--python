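"""Simulation harness: type-I-error, power, and method-comparison studies.

Each experiment repeatedly generates a synthetic dataset, optionally forces
the null by permuting the phenotype across subjects, applies one of the
enrichment procedures, and reports the rejection rate at a nominal level
with an exact (Clopper-Pearson) binomial confidence interval. Replicates
draw their seeds from substreams of one master seed, so methods compared in
the same run see identical data (paired streams) and any run is exactly
reproducible.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace, asdict

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta
from statsmodels.stats.multitest import multipletests

from .enrichment import NetworkPartition, nest_test
from .nulls import label_permutation_test, spin_test
from .stats import AssociationMap, ModelSpec, compute_statistic
from .synthetic import (
    SimulationConfig,
    SurfaceMesh,
    force_null,
    make_network_partition,
    make_sphere_mesh,
    simulate_subjects,
)

METHODS = ("nest", "label_permutation", "spin")


@dataclass
class ExperimentResult:
    method: str
    effect: str
    network: int
    n_subjects: int
    n_replicates: int
    rejection_rate: float
    ci_low: float
    ci_high: float
    mean_runtime: float  # seconds per replicate; reported, never asserted
    alpha: float
    K: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rejection_rate <= self.ci_high):
            raise ValueError("confidence interval must contain the rejection rate")


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(_beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(_beta.ppf(1.0 - a, k + 1, n - k))
    return lo, hi


def _run_method(
    method: str,
    data,
    partition: NetworkPartition,
    spec: ModelSpec,
    sphere,
    K: int,
    seed: int,
) -> float:
    if method == "nest":
        return nest_test(data, partition, spec, K=K, seed=seed).p_value
    amap = AssociationMap(
        compute_statistic(data.X, data.phenotypes, spec),
        list(data.location_ids),
        spec.effect,
        spec.stat_kind,
    )
    if method == "label_permutation":
        return label_permutation_test(amap, partition, K=K, seed=seed).p_value
    if method == "spin":
        return spin_test(amap, partition, sphere, K=K, seed=seed).p_value
    raise ValueError(f"unknown method {method!r}; valid methods: {METHODS}")


def run_single_replicate(
    cfg: SimulationConfig,
    methods: list[str],
    K: int,
    spec: ModelSpec,
    mesh: SurfaceMesh,
    partition: NetworkPartition,
    null: bool,
    rep_seed: np.random.SeedSequence,
) -> tuple[dict[str, float], dict[str, float]]:
    """One replicate: generate -> (force_null) -> p-value per method.

    The replicate's SeedSequence spawns one substream for generation, one
    for the null permutation, and one per method, so resuming an experiment
    at any replicate index reproduces the uninterrupted run exactly.
    """
    sphere = mesh.sphere()
    gen_seed, null_seed, *test_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in rep_seed.spawn(2 + len(methods))
    ]
    data = simulate_subjects(mesh, partition, replace(cfg, seed=gen_seed))
    if null:
        data = force_null(data, null_seed)
    pvals, runtime = {}, {}
    for m, ts in zip(methods, test_seeds):
        t0 = time.perf_counter()
        pvals[m] = _run_method(m, data, partition, spec, sphere, K, ts)
        runtime[m] = time.perf_counter() - t0
    return pvals, runtime


def _replicate_pvalues(
    cfg: SimulationConfig,
    methods: list[str],
    R: int,
    K: int,
    spec: ModelSpec,
    mesh: SurfaceMesh,
    partition: NetworkPartition,
    null: bool,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    rep_seeds = np.random.SeedSequence(cfg.seed).spawn(R)
    pvals = {m: np.empty(R) for m in methods}
    runtime = {m: 0.0 for m in methods}
    for r, ss in enumerate(rep_seeds):
        pv, rt = run_single_replicate(cfg, methods, K, spec, mesh, partition, null, ss)
        for m in methods:
            pvals[m][r] = pv[m]
            runtime[m] += rt[m]
    return pvals, {m: runtime[m] / R for m in methods}


def _result(
    method: str, cfg, partition, pv: np.ndarray, alpha: float, K: int, rt: float
) -> ExperimentResult:
    k = int(np.sum(pv < alpha))
    R = len(pv)
    lo, hi = clopper_pearson(k, R)
    return ExperimentResult(
        method=method,
        effect=cfg.effect,
        network=partition.target_label,
        n_subjects=cfg.n_subjects,
        n_replicates=R,
        rejection_rate=k / R,
        ci_low=lo,
        ci_high=hi,
        mean_runtime=rt,
        alpha=alpha,
        K=K,
    )


def type1_experiment(
    cfg: SimulationConfig,
    method: str = "nest",
    R: int = 200,
    K: int = 199,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    mesh: SurfaceMesh | None = None,
    partition: NetworkPartition | None = None,
    n_networks: int = 7,
    subdivisions: int = 2,
) -> ExperimentResult:
    """Empirical type I error under the forced null.

    R replicates of generate -> force_null -> test(method); the rejection
    rate at ``alpha`` is reported with an exact 95% binomial CI. Replicate
    and permutation counts default to a desk-scale 200 x 199; larger
    settings are one argument away.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if mesh is None:
        mesh = make_sphere_mesh(subdivisions)
    if partition is None:
        partition = make_network_partition(mesh, n_networks, seed=cfg.seed)
    if spec is None:
        spec = ModelSpec(effect=cfg.effect, stat_kind="pearson")
    pv, rt = _replicate_pvalues(cfg, [method], R, K, spec, mesh, partition, null=True)
    return _result(method, cfg, partition, pv[method], alpha, K, rt[method])


def power_experiment(
    cfg: SimulationConfig,
    method: str = "nest",
    R: int = 200,
    K: int = 199,
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    mesh: SurfaceMesh | None = None,
    partition: NetworkPartition | None = None,
    n_networks: int = 7,
    subdivisions: int = 2,
) -> ExperimentResult:
    """Rejection rate without forcing the null (power when effect_size > 0)."""
    if R < 1:
        raise ValueError("R must be >= 1")
    if mesh is None:
        mesh = make_sphere_mesh(subdivisions)
    if partition is None:
        partition = make_network_partition(mesh, n_networks, seed=cfg.seed)
    if spec is None:
        spec = ModelSpec(effect=cfg.effect, stat_kind="pearson")
    pv, rt = _replicate_pvalues(cfg, [method], R, K, spec, mesh, partition, null=False)
    return _result(method, cfg, partition, pv[method], alpha, K, rt[method])


def compare_methods(
    cfg: SimulationConfig,
    methods: list[str] | tuple[str, ...] = METHODS,
    R: int = 200,
    K: int = 199,
    alpha: float = 0.05,
    null: bool = True,
    spec: ModelSpec | None = None,
    mesh: SurfaceMesh | None = None,
    partition: NetworkPartition | None = None,
    n_networks: int = 7,
    subdivisions: int = 2,
    return_pvalues: bool = False,
):
    """Paired method comparison: every method sees the same R datasets.

    Returns a tidy DataFrame with one row per method (rejection rate, CI,
    runtime); with ``return_pvalues`` also the per-replicate p-value arrays.
    """
    methods = list(methods)
    if not methods:
        raise ValueError("methods must be non-empty")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; valid methods: {METHODS}")
    if mesh is None:
        mesh = make_sphere_mesh(subdivisions)
    if partition is None:
        partition = make_network_partition(mesh, n_networks, seed=cfg.seed)
    if spec is None:
        spec = ModelSpec(effect=cfg.effect, stat_kind="pearson")
    pv, rt = _replicate_pvalues(cfg, methods, R, K, spec, mesh, partition, null=null)
    rows = [asdict(_result(m, cfg, partition, pv[m], alpha, K, rt[m])) for m in methods]
    table = pd.DataFrame(rows)
    if return_pvalues:
        return table, pv
    return table


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def fdr_adjust(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Returns (flags, adjusted p-values). All inputs must lie in (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be nonempty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    flags, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return flags, adjusted


def enumerate_test_family(
    modalities, effects, networks
) -> list[tuple[str, str, object]]:
    """Enumerate the declared multiple-testing family: one test per
    modality x effect x network cell (e.g., 2 x 3 x 7 = 42 tests)."""
    fam = [
        (str(m), str(e), n) for m in modalities for e in effects for n in networks
    ]
    if not fam:
        raise ValueError("family is empty")
    return fam
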
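"""Synthetic spherical-surface data with spatial autocorrelation.

Emulates the statistical structure of resampled cortical-surface studies:
a triangulated sphere stands in for the cortical mesh, contiguous
region-grown patches stand in for canonical functional networks, and
per-subject measurement maps are built from

    x_i(v) = m(v) + beta(v) * g(age_i, sex_i) + noise_i(v)

where ``m`` is a smooth subject-invariant "anatomy" surface, ``beta`` is an
effect amplitude confined to the target network, ``g`` is the effect's
covariate (standardized centered age, the female indicator, or their
product), and ``noise_i`` is an independent spatially smoothed Gaussian
field per subject. Two properties of real null association maps drive
competitor miscalibration and are both represented here: spatial
autocorrelation (graph smoothing of the noise) and network-aligned
coherence (a per-subject, per-network random intercept), so that null maps
are smoother within networks than across their borders.

All randomness flows from named substreams of one master seed (phenotypes,
noise, network effects, permutation), so any stage can be held fixed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

from .enrichment import NetworkPartition
from .nulls import SpherePointSet
from .stats import SubjectDataset

_STREAMS = ("phenotypes", "noise", "network_effects", "permutation", "anatomy")


@dataclass
class SurfaceMesh:
    """Triangulated unit sphere: coordinates, faces, and vertex adjacency."""

    coords: np.ndarray  # (V, 3), unit norm
    faces: np.ndarray  # (F, 3) vertex indices
    adjacency: sp.csr_matrix  # symmetric 0/1

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def location_ids(self) -> list[str]:
        return [f"v{i:05d}" for i in range(self.n_vertices)]

    def sphere(self) -> SpherePointSet:
        return SpherePointSet(self.coords, self.location_ids)

    def neighbor_lists(self) -> list[np.ndarray]:
        A = self.adjacency
        return [A.indices[A.indptr[i] : A.indptr[i + 1]] for i in range(A.shape[0])]


def make_sphere_mesh(subdivisions: int) -> SurfaceMesh:
    """Icosphere: an icosahedron subdivided ``s`` times, V = 10*4^s + 2."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    coords = np.asarray(ico.vertices, dtype=float)
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    faces = np.asarray(ico.faces, dtype=int)
    edges = np.asarray(ico.edges_unique, dtype=int)
    V = coords.shape[0]
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(V, V), dtype=float
    )
    return SurfaceMesh(coords=coords, faces=faces, adjacency=A)


def make_network_partition(
    mesh: SurfaceMesh,
    n_networks: int,
    seed: int | None = None,
    target_label: int = 1,
) -> NetworkPartition:
    """Partition the mesh into spatially contiguous networks.

    Multi-source breadth-first region growing from random seed vertices;
    labels are 1..n_networks and every network is connected and nonempty.
    """
    V = mesh.n_vertices
    if not (2 <= n_networks < V):
        raise ValueError("need 2 <= n_networks < V")
    rng = np.random.default_rng(seed)
    sources = rng.choice(V, size=n_networks, replace=False)
    labels = np.zeros(V, dtype=int)
    neighbors = mesh.neighbor_lists()
    queue: deque[int] = deque()
    for lab, s in enumerate(sources, start=1):
        labels[s] = lab
        queue.append(s)
    while queue:
        v = queue.popleft()
        for u in neighbors[v]:
            if labels[u] == 0:
                labels[u] = labels[v]
                queue.append(u)
    return NetworkPartition(labels, mesh.location_ids, target_label)


def _smoothing_operator(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Row-stochastic neighbor-mean operator: value <- mean(self, neighbors)."""
    A = mesh.adjacency + sp.eye(mesh.n_vertices, format="csr")
    inv_deg = 1.0 / np.asarray(A.sum(axis=1)).ravel()
    return sp.diags(inv_deg) @ A


def smooth_field(
    values: np.ndarray, mesh: SurfaceMesh, iterations: int
) -> np.ndarray:
    """Repeated neighbor-mean relaxation along the last axis.

    iterations=0 is the identity; constant fields are fixed points. Each
    pass replaces a vertex value by the mean of itself and its neighbors,
    building up spatial autocorrelation.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != mesh.n_vertices:
        raise ValueError("last axis must match mesh vertex count")
    if iterations == 0:
        return values.copy()
    W = _smoothing_operator(mesh)
    out = values
    for _ in range(iterations):
        out = out @ W.T
    return np.asarray(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    effect_size is the standard deviation of the signal added inside the
    target network, in measurement units (the effect covariate is scaled to
    unit variance), so effect_size / noise_sd is the per-vertex
    signal-to-noise ratio. smoothness counts neighbor-mean passes applied to
    each subject's noise field; network_coherence in [0, 1) is the fraction
    of noise standard deviation carried by a per-subject, per-network random
    intercept (network-aligned smoothness of null maps).
    """

    n_subjects: int = 50
    age_range: tuple[float, float] = (8.0, 21.0)
    sex_prob: float = 0.5
    effect: str = "age"
    effect_size: float = 0.0
    smoothness: int = 10
    network_coherence: float = 0.5
    noise_sd: float = 1.0
    anatomy_sd: float = 1.0
    soft_edge: int = 0
    seed: int | None = None
    null_flag: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.smoothness < 0 or self.soft_edge < 0:
            raise ValueError("smoothing iteration counts must be >= 0")
        if not (0.0 <= self.network_coherence < 1.0):
            raise ValueError("network_coherence must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.sex_prob < 1.0:
            raise ValueError("sex_prob must be in (0, 1)")


def _streams(seed: int | None) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _standardized_covariate(age: np.ndarray, sex: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    lo, hi = cfg.age_range
    za = (age - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))
    if cfg.effect == "age":
        return za
    if cfg.effect == "sex":
        return sex.astype(float)
    if cfg.effect == "age:sex":
        return za * sex
    raise ValueError(f"unknown effect {cfg.effect!r}")


def simulate_subjects(
    mesh: SurfaceMesh, partition: NetworkPartition, cfg: SimulationConfig
) -> SubjectDataset:
    """Generate one synthetic subjects x vertices dataset.

    age_i ~ Uniform(age_range); sex_i ~ Bernoulli(sex_prob). The noise field
    is a smoothed standard-normal field rescaled to unit standard deviation,
    mixed with a per-network random intercept so total noise variance is
    noise_sd^2 regardless of network_coherence. With null_flag the phenotype
    is permuted across subjects after generation (forced null).
    """
    rngs = _streams(cfg.seed)
    n, V = cfg.n_subjects, mesh.n_vertices
    lo, hi = cfg.age_range
    age = rngs["phenotypes"].uniform(lo, hi, size=n)
    sex = rngs["phenotypes"].binomial(1, cfg.sex_prob, size=n)
    pheno = pd.DataFrame(
        {"age": age, "sex": sex},
        index=pd.Index([f"s{i:04d}" for i in range(n)], name="subject_id"),
    )

    field = smooth_field(
        rngs["noise"].standard_normal((n, V)), mesh, cfg.smoothness
    )
    field /= field.std()
    c = cfg.network_coherence
    noise = np.sqrt(1.0 - c**2) * field
    if c > 0.0:
        labs = np.unique(partition.labels)
        eta = rngs["network_effects"].standard_normal((n, len(labs)))
        lab_index = np.searchsorted(labs, partition.labels)
        noise = noise + c * eta[:, lab_index]
    noise *= cfg.noise_sd

    anatomy = smooth_field(
        rngs["anatomy"].standard_normal(V), mesh, max(cfg.smoothness, 1)
    )
    if anatomy.std() > 0:
        anatomy = anatomy / anatomy.std() * cfg.anatomy_sd

    w = partition.in_network.astype(float)
    if cfg.soft_edge > 0:
        w = smooth_field(w, mesh, cfg.soft_edge)
    g = _standardized_covariate(age, sex, cfg)
    X = anatomy[None, :] + cfg.effect_size * np.outer(g, w) + noise

    data = SubjectDataset(X=X, location_ids=mesh.location_ids, phenotypes=pheno)
    if cfg.null_flag:
        data = force_null(data, rngs["permutation"])
    return data


def force_null(
    data: SubjectDataset, seed: np.random.Generator | int | None = None
) -> SubjectDataset:
    """Destroy all brain-phenotype associations by permuting the phenotype
    rows across subjects; the measurement matrix (and hence the spatial
    structure of association maps) is untouched."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(data.n_subjects)
    pheno = data.phenotypes.copy()
    pheno.iloc[:, :] = data.phenotypes.iloc[perm].to_numpy()
    return SubjectDataset(
        X=data.X.copy(), location_ids=list(data.location_ids), phenotypes=pheno
    )


def downsample_to_parcels(
    data: SubjectDataset,
    mesh: SurfaceMesh,
    partition: NetworkPartition,
    n_parcels: int,
    seed: int | None = None,
) -> tuple[SubjectDataset, NetworkPartition]:
    """Aggregate vertex data to contiguous-parcel means (resolution analogue).

    Parcels come from contiguous region growing with n_parcels sources; each
    parcel's measurement is the unweighted mean of its vertices and its
    network label is the majority vertex label (lowest label on ties).
    """
    parcels = make_network_partition(mesh, n_parcels, seed=seed)
    ids = []
    cols = []
    labels = []
    for lab in range(1, n_parcels + 1):
        mask = parcels.labels == lab
        ids.append(f"p{lab:05d}")
        cols.append(data.X[:, mask].mean(axis=1))
        member_labels = partition.labels[mask]
        vals, counts = np.unique(member_labels, return_counts=True)
        labels.append(int(vals[np.argmax(counts)]))
    new_data = SubjectDataset(
        X=np.column_stack(cols), location_ids=ids, phenotypes=data.phenotypes.copy()
    )
    new_part = NetworkPartition(np.asarray(labels), ids, partition.target_label)
    return new_data, new_part


# ---------------------------------------------------------------------------
# Writers (same delimited formats the analysis readers consume)
# ---------------------------------------------------------------------------


def write_dataset(
    out_dir: str | Path,
    data: SubjectDataset,
    partition: NetworkPartition | None = None,
    sphere: SpherePointSet | None = None,
    sep: str = ",",
) -> dict[str, Path]:
    """Write subject matrix, phenotype table, and optionally network labels
    and sphere coordinates, in the delimited formats the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mat = pd.DataFrame(
        data.X, index=pd.Index(data.phenotypes.index, name="subject_id"),
        columns=data.location_ids,
    )
    paths["data"] = out / "subject_matrix.csv"
    mat.to_csv(paths["data"], sep=sep)

    paths["phenotypes"] = out / "phenotypes.csv"
    data.phenotypes.to_csv(paths["phenotypes"], sep=sep)

    if partition is not None:
        lab = pd.DataFrame(
            {"location_id": partition.location_ids, "label": partition.labels}
        )
        paths["labels"] = out / "network_labels.csv"
        lab.to_csv(paths["labels"], sep=sep, index=False)

    if sphere is not None:
        sph = pd.DataFrame(
            {
                "location_id": sphere.location_ids,
                "x": sphere.coords[:, 0],
                "y": sphere.coords[:, 1],
                "z": sphere.coords[:, 2],
            }
        )
        paths["sphere"] = out / "sphere_coords.csv"
        sph.to_csv(paths["sphere"], sep=sep, index=False)
    return paths
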
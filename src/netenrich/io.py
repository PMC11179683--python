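"""Delimited-text readers/writers and the reproducibility manifest.

Canonical interchange formats (comma default, tab accepted):

* subject matrix — header row, first column ``subject_id``, remaining
  columns one per analysis location;
* phenotype table — keyed by ``subject_id``, columns ``age``, ``sex``
  (1 = female) and optional numeric covariates;
* network labels — columns ``location_id``, ``label`` (integer);
* sphere coordinates — columns ``location_id``, ``x``, ``y``, ``z``.

Location ids are opaque strings matched exactly across files; nothing is
ever matched positionally, so misaligned inputs fail loudly instead of
silently shifting columns.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import NetworkPartition
from .nulls import SpherePointSet
from .stats import SubjectDataset


def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    sep = _detect_sep(path)
    # on_bad_lines="error" rejects rows whose field count disagrees with the
    # header (silently truncated / corrupted files)
    return pd.read_csv(path, sep=sep, index_col=index_col, on_bad_lines="error")


def read_subject_matrix(path: str | Path) -> pd.DataFrame:
    """Subjects x locations matrix, indexed by subject_id."""
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    if df.shape[1] < 1:
        raise ValueError(f"{path}: subject matrix has no location columns")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        bad = df.columns[np.where(~np.isfinite(values))[1][0]]
        raise ValueError(f"{path}: non-finite value in location column {bad!r}")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    return df


def load_dataset(data_path: str | Path, pheno_path: str | Path) -> SubjectDataset:
    """Read and join the measurement matrix and phenotype table.

    The join on subject_id is validated: any subject present in one file
    but not the other is an error, and phenotype rows are reordered to the
    matrix's row order.
    """
    mat = read_subject_matrix(data_path)
    pheno = read_phenotypes(pheno_path)
    missing = set(mat.index) - set(pheno.index)
    extra = set(pheno.index) - set(mat.index)
    if missing or extra:
        detail = []
        if missing:
            detail.append(f"missing from phenotypes: {sorted(missing)[:5]}")
        if extra:
            detail.append(f"missing from matrix: {sorted(extra)[:5]}")
        raise ValueError("subject_id mismatch between files; " + "; ".join(detail))
    pheno = pheno.loc[mat.index]
    return SubjectDataset(
        X=mat.to_numpy(dtype=float),
        location_ids=[str(c) for c in mat.columns],
        phenotypes=pheno,
    )


def read_network_labels(path: str | Path) -> pd.Series:
    """Per-location integer labels, indexed by location_id."""
    df = _read_table(path)
    for col in ("location_id", "label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    labels = pd.Series(
        df["label"].to_numpy(dtype=int),
        index=pd.Index(df["location_id"].astype(str), name="location_id"),
    )
    if labels.index.has_duplicates:
        dup = labels.index[labels.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate location_id {dup!r}")
    return labels


def partition_for(
    labels: pd.Series, location_ids: Sequence[str], target_label: int
) -> NetworkPartition:
    """Align a label map to a dataset's location order and select a target.

    Every analysis location must be present in the label file (exact string
    match); the first missing id is named in the error.
    """
    for loc in location_ids:
        if loc not in labels.index:
            raise ValueError(f"location {loc!r} missing from network label file")
    aligned = labels.loc[list(location_ids)].to_numpy()
    if target_label not in aligned:
        raise ValueError(
            f"target label {target_label!r} not present in network label file"
        )
    return NetworkPartition(aligned, list(location_ids), target_label)


def read_sphere_coords(path: str | Path) -> SpherePointSet:
    df = _read_table(path)
    for col in ("location_id", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return SpherePointSet(
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
        location_ids=[str(s) for s in df["location_id"]],
    )


# ---------------------------------------------------------------------------
# Location exclusion (medial-wall analogue)
# ---------------------------------------------------------------------------


def exclusion_mask(
    labels: np.ndarray | pd.Series, excluded_labels: Iterable[int]
) -> np.ndarray:
    """Boolean mask of locations to KEEP (True = analysis location).

    Excluded locations (e.g., the medial wall) are dropped before any
    ranking or counting; they never enter the network or its complement.
    """
    arr = np.asarray(labels)
    excluded = set(int(e) for e in excluded_labels)
    return ~np.isin(arr, list(excluded))


def drop_excluded(
    data: SubjectDataset, labels: pd.Series, excluded_labels: Iterable[int]
) -> tuple[SubjectDataset, pd.Series]:
    """Remove excluded locations from a dataset and its label map."""
    aligned = labels.loc[list(data.location_ids)]
    keep = exclusion_mask(aligned.to_numpy(), excluded_labels)
    kept_ids = [loc for loc, k in zip(data.location_ids, keep) if k]
    return (
        SubjectDataset(
            X=data.X[:, keep], location_ids=kept_ids, phenotypes=data.phenotypes
        ),
        aligned[keep],
    )


def analysis_location_count(
    labels: np.ndarray | pd.Series, excluded_labels: Iterable[int]
) -> int:
    """Number of locations remaining after exclusion."""
    return int(exclusion_mask(labels, excluded_labels).sum())


# ---------------------------------------------------------------------------
# Run manifest and results table
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-identically (sequential mode):
    the command, digests of every input file, the master seed, and the full
    statistical configuration."""

    command: str
    inputs: dict[str, str]
    seed: int | None
    K: int | None
    variant: str | None
    statistic: str | None
    permutation_scheme: str | None
    package_version: str
    timestamp: str
    extra: dict = field(default_factory=dict)


def build_manifest(
    command: str,
    input_paths: dict[str, str | Path],
    seed: int | None = None,
    K: int | None = None,
    variant: str | None = None,
    statistic: str | None = None,
    permutation_scheme: str | None = None,
    **extra,
) -> RunManifest:
    from . import __version__

    digests = {name: _sha256(Path(p)) for name, p in input_paths.items()}
    return RunManifest(
        command=command,
        inputs=digests,
        seed=seed,
        K=K,
        variant=variant,
        statistic=statistic,
        permutation_scheme=permutation_scheme,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
        extra=dict(extra, python=platform.python_version()),
    )


def write_manifest(path: str | Path, manifest: RunManifest) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2) + "\n")


def write_results_table(path: str | Path, rows: list[dict]) -> None:
    """One row per network x effect: ES_obs, K, p_value (and any extras)."""
    pd.DataFrame(rows).to_csv(path, index=False)
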
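"""Atlas, time-series, and connectome data structures with delimited-text I/O.

The unit of brain input is a symmetric node x node matrix of Fisher
z-transformed Pearson correlations between node time courses, one matrix per
subject and task condition.  Edges (unique node pairs ``i < j``) are flattened
into a canonical row-major upper-triangle vector, which is the feature space
of connectome-based predictive modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 10 canonical functional networks of the 268-node cortical/subcortical/
#: cerebellar parcellation: medial frontal, frontoparietal, default mode,
#: motor/sensory, visual A, visual B, visual association, salience,
#: subcortical, cerebellum.
CANONICAL_NETWORKS: tuple[str, ...] = (
    "MF", "FP", "DMN", "Mot", "VI", "VII", "VAs", "SAL", "SC", "CBL",
)

CONDITIONS: tuple[str, ...] = ("frustration", "nonfrustration")

#: Pearson correlations are clipped to +/- (1 - CLIP_EPS) before the Fisher
#: transform so degenerate perfect correlations stay finite downstream.
CLIP_EPS = 1e-7

_SYMMETRY_TOL = 1e-10


# ---------------------------------------------------------------------------
# Atlas


@dataclass(frozen=True)
class Atlas:
    """Node table of a brain parcellation.

    The underlying table has columns ``node_id`` (1-based, contiguous),
    ``hemisphere`` (L/R), ``network`` (one of :data:`CANONICAL_NETWORKS`),
    ``region`` (free-form macroscale label) and centroid coordinates
    ``x, y, z`` in mm.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = ["node_id", "hemisphere", "network", "region", "x", "y", "z"]
        missing = [c for c in required if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        ids = t["node_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            dupes = pd.Series(ids)[pd.Series(ids).duplicated()].tolist()
            raise ValueError(f"duplicate node ids: {dupes}")
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("node ids must be contiguous 1..K")
        bad_hemi = set(t["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        bad_net = set(t["network"]) - set(CANONICAL_NETWORKS)
        if bad_net:
            raise ValueError(f"unknown network labels: {sorted(bad_net)}")
        xyz = t[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite centroid coordinates")
        # canonical order: ascending node_id
        object.__setattr__(self, "table",
                           t.sort_values("node_id").reset_index(drop=True))

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def n_edges(self) -> int:
        return n_edges(self.n_nodes)

    @property
    def networks(self) -> np.ndarray:
        return self.table["network"].to_numpy()

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    @property
    def regions(self) -> np.ndarray:
        return self.table["region"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        """K x 3 array of centroid coordinates in mm."""
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Time series and connectivity


@dataclass
class NodeTimeSeries:
    """Mean time course per atlas node for one subject and condition."""

    subject_id: str
    condition: str
    data: np.ndarray  # K x T

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be a K x T matrix")
        if self.data.shape[1] < 3:
            raise ValueError(
                f"need at least 3 time points for correlation, got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time-series data contains non-finite values")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass
class ConnectivityMatrix:
    """Symmetric K x K Fisher-z connectivity matrix for one subject x condition.

    The diagonal is stored as 0 and never enters the edge feature space
    (self-connectivity is undefined under the Fisher transform).
    """

    subject_id: str
    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.all(np.isfinite(v[off])):
            raise ValueError("non-finite off-diagonal connectivity values")
        if np.max(np.abs(v - v.T)) > _SYMMETRY_TOL:
            raise ValueError(
                f"matrix asymmetric beyond tolerance {_SYMMETRY_TOL}"
            )
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def compute_connectivity(ts: NodeTimeSeries) -> ConnectivityMatrix:
    """Pairwise node correlations, Fisher z-transformed.

    Raw task time courses are correlated directly (no removal of task-evoked
    activity).  Correlations are clipped to ``+/-(1 - 1e-7)`` before
    ``arctanh`` so identical node pairs yield a large finite z.

    Raises
    ------
    ValueError
        If any node has zero temporal variance (its correlation with every
        other node is undefined); the error names the offending node(s).
    """
    data = ts.data
    sd = data.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise ValueError(
            "zero-variance node(s) (1-based): "
            f"{(dead + 1).tolist()} — correlation undefined"
        )
    r = np.corrcoef(data)
    np.clip(r, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS, out=r)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against rounding
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(ts.subject_id, ts.condition, z)


# ---------------------------------------------------------------------------
# Edge vectorization: canonical row-major upper triangle, (i, j) with i < j


def n_edges(n_nodes: int) -> int:
    """Number of unique edges, K(K-1)/2."""
    return n_nodes * (n_nodes - 1) // 2


def edge_endpoints(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """0-based (i, j) node indices of each canonical edge position."""
    return np.triu_indices(n_nodes, k=1)


def vectorize(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Flatten the unique off-diagonal edges of a symmetric matrix.

    Ordering is row-major over the upper triangle: ``(0,1), (0,2), ...,
    (0,K-1), (1,2), ...``; :func:`devectorize` is the exact inverse on the
    off-diagonal entries.
    """
    v = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, dtype=float)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("expected a square matrix")
    if np.max(np.abs(v - v.T)) > _SYMMETRY_TOL:
        raise ValueError(f"matrix asymmetric beyond tolerance {_SYMMETRY_TOL}")
    iu, ju = edge_endpoints(v.shape[0])
    return v[iu, ju].copy()

def devectorize(edges: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric zero-diagonal matrix from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (n_edges(n_nodes),):
        raise ValueError(
            f"edge vector has length {edges.shape}, expected {n_edges(n_nodes)} for K={n_nodes}"
        )
    m = np.zeros((n_nodes, n_nodes))
    iu, ju = edge_endpoints(n_nodes)
    m[iu, ju] = edges
    m[ju, iu] = edges
    return m


# ---------------------------------------------------------------------------
# Phenotypes


PHENOTYPE_NUMERIC = (
    "child_ari", "parent_ari", "age", "sex", "motion", "adhd", "anxiety",
    "state_frustration",
)


@dataclass
class PhenotypeTable:
    """Per-subject behavior scores and covariates.

    ARI (Affective Reactivity Index) totals are six 0-2 items, hence bounded
    to [0, 12].  Missing values are NaN and are never imputed; analyses drop
    subjects listwise per target and log the count.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if "subject_id" not in t.columns:
            raise ValueError("phenotype table missing subject_id column")
        if t["subject_id"].duplicated().any():
            raise ValueError("duplicate subject ids in phenotype table")
        t = t.copy()
        t["subject_id"] = t["subject_id"].astype(str)
        for col in t.columns:
            if col == "subject_id":
                continue
            try:
                t[col] = pd.to_numeric(t[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(f"non-numeric values in column {col!r}: {exc}") from exc
        for col in ("child_ari", "parent_ari"):
            if col in t.columns:
                vals = t[col].dropna()
                bad = vals[(vals < 0) | (vals > 12)]
                if len(bad):
                    raise ValueError(
                        f"{col} out of range [0, 12] for subject(s) "
                        f"{t.loc[bad.index, 'subject_id'].tolist()}"
                    )
        self.table = t.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def values_for(self, column: str, subject_ids: list[str]) -> np.ndarray:
        """Column values aligned to the given subject order."""
        if column not in self.table.columns:
            raise ValueError(f"phenotype column {column!r} not found")
        s = self.table.set_index("subject_id")[column]
        missing = [sid for sid in subject_ids if sid not in s.index]
        if missing:
            raise ValueError(f"subjects absent from phenotype table: {missing}")
        return s.loc[subject_ids].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# File I/O.  All layouts are delimited text: atlas and time series TSV,
# phenotypes CSV, matrices whitespace-delimited numeric text.


def load_atlas(path: str | Path) -> Atlas:
    df = pd.read_csv(path, sep="\t")
    return Atlas(df)


def save_atlas(atlas: Atlas, path: str | Path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


def load_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path)
    return PhenotypeTable(df)


def save_phenotypes(phenotypes: PhenotypeTable, path: str | Path) -> None:
    phenotypes.table.to_csv(path, index=False)


def load_time_series(path: str | Path, subject_id: str, condition: str,
                     atlas: Atlas | None = None) -> NodeTimeSeries:
    """Read a node x time TSV (first column node_id, then t1..tT).

    Node order is enforced by the id column, not by file position: rows are
    sorted to atlas order and must cover exactly 1..K.
    """
    df = pd.read_csv(path, sep="\t")
    if "node_id" not in df.columns:
        raise ValueError(f"{path}: time-series file missing node_id column")
    df = df.sort_values("node_id").reset_index(drop=True)
    ids = df["node_id"].to_numpy()
    expected_k = atlas.n_nodes if atlas is not None else len(ids)
    if not np.array_equal(ids, np.arange(1, expected_k + 1)):
        raise ValueError(f"{path}: node ids must be exactly 1..{expected_k}")
    data = df.drop(columns="node_id").to_numpy(dtype=float)
    return NodeTimeSeries(subject_id, condition, data)


def load_matrix(path: str | Path, subject_id: str = "",
                condition: str = "frustration") -> ConnectivityMatrix:
    """Read a K x K numeric text matrix (whitespace- or comma-delimited)."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    values = np.loadtxt(path, delimiter=delimiter)
    return ConnectivityMatrix(subject_id, condition, values)


def save_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.values, fmt="%.17g")


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a matrix manifest TSV (subject_id, condition, path)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "condition", "path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    return df


def load_matrices(manifest_path: str | Path,
                  condition: str) -> list[ConnectivityMatrix]:
    """Load all matrices of one condition listed in a manifest TSV.

    Relative paths in the manifest are resolved against its directory.
    """
    manifest = load_manifest(manifest_path)
    base = Path(manifest_path).parent
    rows = manifest[manifest["condition"] == condition]
    if rows.empty:
        raise ValueError(f"no manifest rows for condition {condition!r}")
    out = []
    for _, row in rows.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        out.append(load_matrix(p, subject_id=str(row["subject_id"]),
                               condition=condition))
    return out
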
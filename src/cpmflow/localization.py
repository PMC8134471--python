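"""Anatomical summaries of a consensus predictive network.

A predictive network is an edge mask over the canonical edge ordering.  It is
summarized at three levels of reduction: per-node degree (number of incident
predictive edges), edge partitions (ipsilateral-right / ipsilateral-left /
interhemispheric; long- vs short-range by centroid distance), and 10 x 10
within/between-network edge-count matrices over the canonical functional
networks (plus the same by macroscale region).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CANONICAL_NETWORKS, Atlas, edge_endpoints, n_edges

#: Default centroid-distance cut between short- and long-range connections.
#: 60 mm is a conventional threshold, not an anatomical constant; report it
#: alongside any long/short partition.
DEFAULT_LONG_RANGE_MM = 60.0


@dataclass
class RangePartition:
    long: int
    short: int
    chi2: float
    p: float
    threshold_mm: float
    expected_proportions: tuple[float, float]  # (long, short)


@dataclass
class NetworkSummary:
    """All localization summaries of one edge mask."""

    degree: np.ndarray
    hemisphere_counts: dict[str, int]
    range_counts: RangePartition
    network_matrix: pd.DataFrame
    region_matrix: pd.DataFrame
    total_edges: int


def _check_mask(mask: np.ndarray, atlas: Atlas) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (atlas.n_edges,):
        raise ValueError(
            f"mask length {mask.shape} != K(K-1)/2 = {atlas.n_edges} for K={atlas.n_nodes}")
    return mask


def node_degree(mask: np.ndarray, atlas: Atlas) -> np.ndarray:
    """Number of selected edges incident to each node (handshake: sums to 2|E|)."""
    mask = _check_mask(mask, atlas)
    iu, ju = edge_endpoints(atlas.n_nodes)
    deg = np.zeros(atlas.n_nodes, dtype=int)
    np.add.at(deg, iu[mask], 1)
    np.add.at(deg, ju[mask], 1)
    return deg


def hemisphere_partition(mask: np.ndarray, atlas: Atlas) -> dict[str, int]:
    """Counts of ipsilateral-right, ipsilateral-left, and interhemispheric edges."""
    mask = _check_mask(mask, atlas)
    hemi = atlas.hemispheres
    iu, ju = edge_endpoints(atlas.n_nodes)
    hi, hj = hemi[iu[mask]], hemi[ju[mask]]
    ipsi_r = int(np.sum((hi == "R") & (hj == "R")))
    ipsi_l = int(np.sum((hi == "L") & (hj == "L")))
    return {"ipsi_R": ipsi_r, "ipsi_L": ipsi_l,
            "inter": int(mask.sum()) - ipsi_r - ipsi_l}


def edge_distances(atlas: Atlas) -> np.ndarray:
    """Euclidean centroid distance (mm) of every canonical edge."""
    iu, ju = edge_endpoints(atlas.n_nodes)
    xyz = atlas.centroids
    return np.linalg.norm(xyz[iu] - xyz[ju], axis=1)


def range_partition(mask: np.ndarray, atlas: Atlas,
                    distance_threshold_mm: float = DEFAULT_LONG_RANGE_MM,
                    expected_proportions: tuple[float, float] | None = None,
                    ) -> RangePartition:
    """Long- vs short-range split with a 1-df chi-square goodness-of-fit.

    An edge is long-range when its centroid distance is >= the threshold.
    ``expected_proportions`` is the (long, short) null; by default it is the
    long/short split among *all* atlas edges at the same threshold, so the
    test asks whether the predictive network over-represents either range
    relative to the connectome as a whole.  Pass (0.5, 0.5) for an equal-odds
    null.
    """
    mask = _check_mask(mask, atlas)
    if distance_threshold_mm <= 0:
        raise ValueError("distance threshold must be positive")
    dist = edge_distances(atlas)
    is_long = dist >= distance_threshold_mm
    n_long = int(np.sum(is_long & mask))
    total = int(mask.sum())
    if expected_proportions is None:
        p_long = float(is_long.mean())
        expected_proportions = (p_long, 1.0 - p_long)
    e_long, e_short = expected_proportions
    if abs(e_long + e_short - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    observed = np.array([n_long, total - n_long], dtype=float)
    expected = np.array([e_long, e_short]) * total
    if total == 0:
        chi2, p = 0.0, 1.0
    elif np.any(expected == 0.0):
        exact = np.all(observed[expected == 0.0] == 0.0)
        chi2, p = (0.0, 1.0) if exact else (float("inf"), 0.0)
    else:
        chi2 = float(np.sum((observed - expected) ** 2 / expected))
        p = float(stats.chi2.sf(chi2, df=1))
    return RangePartition(n_long, total - n_long, chi2, p,
                          float(distance_threshold_mm),
                          (float(e_long), float(e_short)))


def _label_matrix(mask: np.ndarray, atlas: Atlas, labels: np.ndarray,
                  label_order: list[str]) -> pd.DataFrame:
    index = {lab: i for i, lab in enumerate(label_order)}
    unknown = set(labels) - set(label_order)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    iu, ju = edge_endpoints(atlas.n_nodes)
    li = np.array([index[l] for l in labels])[iu[mask]]
    lj = np.array([index[l] for l in labels])[ju[mask]]
    a, b = np.minimum(li, lj), np.maximum(li, lj)
    m = np.zeros((len(label_order), len(label_order)), dtype=int)
    np.add.at(m, (a, b), 1)
    m = m + np.triu(m, k=1).T  # symmetric; diagonal = within-label counts
    return pd.DataFrame(m, index=label_order, columns=label_order)


def network_matrix(mask: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """10 x 10 symmetric counts of selected edges within/between canonical networks.

    Cell (a, b) counts edges whose endpoints lie in networks {a, b}; the
    upper triangle plus diagonal sums to the number of selected edges.
    """
    mask = _check_mask(mask, atlas)
    return _label_matrix(mask, atlas, atlas.networks, list(CANONICAL_NETWORKS))


def region_matrix(mask: np.ndarray, atlas: Atlas) -> pd.DataFrame:
    """Same edge-count matrix by macroscale region (atlas-supplied labels)."""
    mask = _check_mask(mask, atlas)
    regions = atlas.regions
    order = sorted(set(regions))
    return _label_matrix(mask, atlas, regions, order)


def summarize_network(mask: np.ndarray, atlas: Atlas,
                      distance_threshold_mm: float = DEFAULT_LONG_RANGE_MM,
                      expected_proportions: tuple[float, float] | None = None,
                      ) -> NetworkSummary:
    mask = _check_mask(mask, atlas)
    return NetworkSummary(
        degree=node_degree(mask, atlas),
        hemisphere_counts=hemisphere_partition(mask, atlas),
        range_counts=range_partition(mask, atlas, distance_threshold_mm,
                                     expected_proportions),
        network_matrix=network_matrix(mask, atlas),
        region_matrix=region_matrix(mask, atlas),
        total_edges=int(mask.sum()),
    )


def export_edge_list(mask: np.ndarray, atlas: Atlas, path: str | Path) -> None:
    """Write the selected edges as a TSV, one row per edge.

    Columns: node_i, node_j (1-based), hemisphere and network of each
    endpoint, and centroid distance in mm.  Serves as the portable exchange
    format for visualization tools.
    """
    mask = _check_mask(mask, atlas)
    iu, ju = edge_endpoints(atlas.n_nodes)
    hemi, net = atlas.hemispheres, atlas.networks
    dist = edge_distances(atlas)
    df = pd.DataFrame({
        "node_i": iu[mask] + 1,
        "node_j": ju[mask] + 1,
        "hemisphere_i": hemi[iu[mask]],
        "hemisphere_j": hemi[ju[mask]],
        "network_i": net[iu[mask]],
        "network_j": net[ju[mask]],
        "distance_mm": np.round(dist[mask], 6),
    })
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, atlas: Atlas) -> np.ndarray:
    """Rebuild the boolean edge mask from an exported edge list."""
    df = pd.read_csv(path, sep="\t")
    mask = np.zeros(atlas.n_edges, dtype=bool)
    if df.empty:
        return mask
    i = df["node_i"].to_numpy() - 1
    j = df["node_j"].to_numpy() - 1
    k = atlas.n_nodes
    # canonical position of (i, j), i < j, in the row-major upper triangle
    pos = (i * (2 * k - i - 1)) // 2 + (j - i - 1)
    mask[pos] = True
    return mask
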
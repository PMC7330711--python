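"""Proportional thresholding and hemisphere-resolved community edge counts.

Connectivity matrices are binarized by retaining a fixed proportion of the
strongest off-diagonal entries (graph "cost"), so every subject's graph has
the same number of edges.  Nodes are partitioned into the seven canonical
resting-state networks (FPN, LM, SAL, DAN, DMN, SMN, VN) split by
hemisphere — 14 communities — and edges are counted as intra-community,
inter-community (per unordered community pair), or touching an unassigned
node.  The three buckets always sum to the total edge count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NETWORKS",
    "HEMISPHERES",
    "COMMUNITIES",
    "MEASURES",
    "UNASSIGNED",
    "NetworkPartition",
    "CommunityEdgeCounts",
    "threshold_proportional",
    "load_partition",
    "community_edge_counts",
    "density_sweep",
]

NETWORKS = ("FPN", "LM", "SAL", "DAN", "DMN", "SMN", "VN")
HEMISPHERES = ("L", "R")
#: The 14 hemisphere-resolved communities, in canonical order.
COMMUNITIES = tuple(f"{net}_{h}" for net in NETWORKS for h in HEMISPHERES)
UNASSIGNED = "unassigned"

#: Canonical measure names: 14 intra-community counts then the 91 unordered
#: inter-community pair counts.  Order is fixed so count vectors align
#: across subjects.
MEASURES = tuple(f"intra:{c}" for c in COMMUNITIES) + tuple(
    f"inter:{a}|{b}" for a, b in itertools.combinations(COMMUNITIES, 2)
)


class NetworkPartition:
    """Mapping ROI label -> community (one of 14, or ``unassigned``)."""

    def __init__(self, mapping: dict[str, str]):
        for label, comm in mapping.items():
            if comm != UNASSIGNED and comm not in COMMUNITIES:
                raise ValueError(
                    f"unknown community {comm!r} for ROI {label!r}; "
                    f"expected one of {COMMUNITIES} or {UNASSIGNED!r}"
                )
        self.mapping = dict(mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def community(self, label: str) -> str:
        return self.mapping.get(label, UNASSIGNED)

    def codes(self, labels: list[str]) -> np.ndarray:
        """Integer community codes per label (-1 for unassigned)."""
        index = {c: k for k, c in enumerate(COMMUNITIES)}
        return np.array(
            [index.get(self.mapping.get(l, UNASSIGNED), -1) for l in labels], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, comm in self.mapping.items():
            if comm == UNASSIGNED:
                rows.append((label, UNASSIGNED, ""))
            else:
                net, hemi = comm.rsplit("_", 1)
                rows.append((label, net, hemi))
        return pd.DataFrame(rows, columns=["roi_label", "network", "hemisphere"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_partition(table, labels: list[str]) -> NetworkPartition:
    """Load a ROI->community partition for the given ROI labels.

    ``table`` is a TSV path or DataFrame with columns
    ``roi_label  network  hemisphere``.  Labels absent from the table map to
    ``unassigned`` (the network templates carry no sub-cortical regions).
    Duplicate rows or unknown network names are errors.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str).fillna("")
    required = {"roi_label", "network", "hemisphere"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"partition table missing columns: {sorted(missing)}")
    dupes = table["roi_label"][table["roi_label"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate roi_label rows in partition table: {dupes}")
    mapping: dict[str, str] = {}
    table_map = {}
    for _, row in table.iterrows():
        net, hemi = str(row["network"]), str(row["hemisphere"])
        if net == UNASSIGNED:
            table_map[str(row["roi_label"])] = UNASSIGNED
            continue
        if net not in NETWORKS:
            raise ValueError(f"unknown network name {net!r} (expected one of {NETWORKS})")
        if hemi not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemi!r} (expected L or R)")
        table_map[str(row["roi_label"])] = f"{net}_{hemi}"
    for label in labels:
        mapping[label] = table_map.get(label, UNASSIGNED)
    return NetworkPartition(mapping)


@dataclass
class AdjacencyMatrix:
    """Binary symmetric adjacency with zero diagonal at a given density."""

    values: np.ndarray
    density: float
    band: object = None

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2


def threshold_proportional(C, density: float) -> AdjacencyMatrix:
    """Retain the top ``density`` proportion of the strongest connections.

    Keeps exactly ``k = floor(density * n*(n-1)/2)`` off-diagonal unique
    entries as edges; ties are broken deterministically by
    (value descending, roi_i ascending, roi_j ascending).  NaN entries are
    never retained.  For the full 446-ROI cortex at the 15% primary density
    this floor convention retains 14,885 edges.
    """
    values = C.values if hasattr(C, "values") else np.asarray(C, dtype=float)
    band = getattr(C, "band", None)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n:
        raise ValueError(f"expected a square matrix, got {values.shape}")
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    iu, ju = np.triu_indices(n, k=1)
    vals = values[iu, ju]
    if np.isnan(vals).all():
        raise ValueError("connectivity matrix is all-NaN above the diagonal")
    k = math.floor(density * n * (n - 1) / 2)
    n_finite = int(np.isfinite(vals).sum())
    if k > n_finite:
        raise ValueError(
            f"density {density} asks for {k} edges but only {n_finite} finite "
            f"off-diagonal entries exist"
        )
    # lexsort: last key is primary -> value desc, then i asc, then j asc
    # (NaNs sort to the end of -vals and are never retained).
    order = np.lexsort((ju, iu, -vals))
    keep = order[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return AdjacencyMatrix(adj, density=density, band=band)


@dataclass
class CommunityEdgeCounts:
    """Per-subject, per-band community edge-count vector."""

    intra: dict[str, int]
    inter: dict[tuple[str, str], int]
    unassigned_touching: int
    total_edges: int
    density: float | None = None
    band: object = None
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.intra.values()) + sum(self.inter.values()) + self.unassigned_touching
        if total != self.total_edges:
            raise ValueError(
                f"edge conservation violated: {total} counted vs {self.total_edges} edges"
            )

    def as_series(self) -> pd.Series:
        """The 105 measures in canonical order (14 intra + 91 inter)."""
        data = {f"intra:{c}": self.intra.get(c, 0) for c in COMMUNITIES}
        for a, b in itertools.combinations(COMMUNITIES, 2):
            data[f"inter:{a}|{b}"] = self.inter.get((a, b), 0)
        return pd.Series(data, dtype=int)


def community_edge_counts(
    A: AdjacencyMatrix | np.ndarray,
    partition: NetworkPartition,
    labels: list[str],
    subject_id: str = "",
) -> CommunityEdgeCounts:
    """Count intra-/inter-community edges of a binarized graph.

    Edges with both endpoints in community ``c`` are intra edges of ``c``;
    edges spanning two communities land in the unordered pair bucket; edges
    touching an unassigned node are tallied separately so the three groups
    always sum to the total edge count.
    """
    adj = A.values if isinstance(A, AdjacencyMatrix) else np.asarray(A, dtype=bool)
    n = adj.shape[0]
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for a {n}-node graph")
    codes = partition.codes(labels)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    ci, cj = codes[iu], codes[ju]
    intra = {c: 0 for c in COMMUNITIES}
    inter = {pair: 0 for pair in itertools.combinations(COMMUNITIES, 2)}
    unassigned = 0
    for a, b in zip(ci, cj):
        if a < 0 or b < 0:
            unassigned += 1
        elif a == b:
            intra[COMMUNITIES[a]] += 1
        else:
            lo, hi = sorted((a, b))
            inter[(COMMUNITIES[lo], COMMUNITIES[hi])] += 1
    return CommunityEdgeCounts(
        intra=intra,
        inter=inter,
        unassigned_touching=unassigned,
        total_edges=len(iu),
        density=getattr(A, "density", None),
        band=getattr(A, "band", None),
        subject_id=subject_id,
    )


DEFAULT_DENSITIES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)


def density_sweep(
    C,
    partition: NetworkPartition,
    labels: list[str],
    densities=DEFAULT_DENSITIES,
    subject_id: str = "",
) -> pd.DataFrame:
    """Edge counts across a range of graph densities, long format.

    Returns columns ``density  measure  count`` (plus ``unassigned_touching``
    as its own measure row).  Because each density's edge set is a superset
    of every sparser one, every count is nondecreasing in density.
    """
    rows = []
    for d in densities:
        counts = community_edge_counts(threshold_proportional(C, d), partition, labels,
                                       subject_id=subject_id)
        s = counts.as_series()
        for measure, count in s.items():
            rows.append((subject_id, d, measure, int(count)))
        rows.append((subject_id, d, "unassigned_touching", counts.unassigned_touching))
    return pd.DataFrame(rows, columns=["subject_id", "density", "measure", "count"])
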
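"""Descriptive outputs: phylum roll-ups, richness, binary PCA, Bray-Curtis
ordering, heatmap binning and per-plant top-OTU reports.

These operations reproduce the study-style figures as data products (ordered
matrices, bin indices, ranked lists); figure aesthetics are left to callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .preprocess import GroupedAbundanceTable
from .rarity import UncommonSet
from .tables_io import TaxonomyTable

#: Heatmap shading bin edges in percent; bins are left-exclusive:
#: {0}, (0,0.1], (0.1,0.25], (0.25,0.5], (0.5,1], (1,5], (5,inf).
HEATMAP_BIN_EDGES = (0.0, 0.1, 0.25, 0.5, 1.0, 5.0)


@dataclass(frozen=True)
class PhylumSummary:
    compartment: tuple[str, str]
    n_otus: dict[str, int]  # phylum -> number of uncommon OTUs
    mean_read_percent: dict[str, float]  # phylum -> mean over hosts of summed %
    percent_uncommon_of_total: float  # uncommon OTUs / compartment OTUs, percent

    @property
    def total_uncommon(self) -> int:
        return sum(self.n_otus.values())


def phylum_rollup(
    rel: GroupedAbundanceTable,
    uncommon: UncommonSet,
    tax: TaxonomyTable,
) -> PhylumSummary:
    """Roll uncommon OTUs of one compartment up to phylum.

    OTU counts are the union across hosts (each uncommon OTU counted once,
    in its phylum; missing phyla fall into "unclassified"). Read percentages
    are the mean over hosts of the summed uncommon relative abundance,
    attributed per phylum.
    """
    tissue, substrate = uncommon.compartment
    comp = rel.compartment(tissue, substrate)
    otus = sorted(o for o in uncommon.otu_ids if o in comp.columns)
    # detected anywhere in this compartment (screen-level "observed" set)
    detected = [o for o in otus if comp[o].sum() > 0]
    known = set(tax.otu_ids)
    phyla = {o: (tax.phylum(o) if o in known else "unclassified") for o in detected}
    n_otus: dict[str, int] = {}
    for o in detected:
        n_otus[phyla[o]] = n_otus.get(phyla[o], 0) + 1
    mean_pct: dict[str, float] = {}
    for ph in n_otus:
        members = [o for o in detected if phyla[o] == ph]
        mean_pct[ph] = float(comp[members].sum(axis=1).mean())
    total = int((comp.sum(axis=0) > 0).sum())
    pct_uncommon = 100.0 * len(detected) / total if total else 0.0
    return PhylumSummary(
        compartment=uncommon.compartment,
        n_otus=n_otus,
        mean_read_percent=mean_pct,
        percent_uncommon_of_total=pct_uncommon,
    )


def richness(presence_frame: pd.DataFrame) -> pd.Series:
    """Number of detected OTUs per row of a boolean presence frame."""
    return presence_frame.sum(axis=1).astype(int)


def mean_richness(presence_frame: pd.DataFrame, by: pd.Series | None = None) -> pd.Series | float:
    """Mean OTU count, optionally grouped by a label Series aligned to rows."""
    r = richness(presence_frame)
    if by is None:
        return float(r.mean())
    return r.groupby(by).mean()


def binary_pca(pres_frame: pd.DataFrame, n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a 0/1 presence frame via the (n-1)-normalised covariance matrix.

    Returns (scores, explained_variance). Component signs are fixed so each
    component's largest-magnitude loading is positive, making the output
    deterministic across platforms.
    """
    if pres_frame.shape[0] < 3:
        raise ValueError("binary_pca needs at least 3 samples")
    x = pres_frame.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    evals, evecs = evals[:k], evecs[:, :k]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = xc @ evecs
    out = pd.DataFrame(
        scores, index=pres_frame.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return out, np.clip(evals, 0, None)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|xi-yi| / sum(xi+yi) on abundance rows.

    0 for identical rows, 1 for disjoint supports; defined as 0 when both
    rows are all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("rows must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = float((x + y).sum())
    if denom == 0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def bray_curtis_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between the rows of ``frame``."""
    n = frame.shape[0]
    arr = frame.to_numpy(dtype=float)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(arr[i], arr[j])
    return pd.DataFrame(d, index=frame.index, columns=frame.index)


def cluster_order(dist: pd.DataFrame, linkage: str = "average") -> tuple[list, np.ndarray]:
    """Agglomerative clustering of a square distance matrix.

    Returns (leaf labels in dendrogram order, scipy linkage matrix). Input
    rows are pre-sorted by label so equal-distance merges break ties
    deterministically.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    arr = dist.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    labels = list(dist.index)
    order0 = sorted(range(len(labels)), key=lambda i: str(labels[i]))
    arr = arr[np.ix_(order0, order0)]
    labels = [labels[i] for i in order0]
    z = sch.linkage(squareform(arr, checks=False), method=linkage)
    leaves = sch.leaves_list(z)
    return [labels[i] for i in leaves], z


def detect_plant_groupings(
    leaf_order: list, host_substrate: dict
) -> list[str]:
    """Hosts whose sand and soil samples sit adjacent in the dendrogram order.

    ``host_substrate`` maps each leaf label to its (host, substrate) pair.
    Hosts without exactly two samples are skipped. Adjacency of a host's two
    leaves signals the community grouped by plant species rather than by
    substrate (a seed-transmission signature).
    """
    per_host: dict[str, list[int]] = {}
    for pos, label in enumerate(leaf_order):
        if label not in host_substrate:
            continue
        host, _sub = host_substrate[label]
        per_host.setdefault(host, []).append(pos)
    grouped = []
    for host, positions in sorted(per_host.items()):
        if len(positions) != 2:
            continue
        if abs(positions[0] - positions[1]) == 1:
            grouped.append(host)
    return grouped


def bin_heatmap(value_percent: float) -> int:
    """Map a relative abundance in percent onto the 7 shading bins (0..6)."""
    if value_percent < 0:
        raise ValueError("abundance cannot be negative")
    if value_percent == 0:
        return 0
    for i, edge in enumerate(HEATMAP_BIN_EDGES[1:], start=1):
        if value_percent <= edge:
            return i
    return 6


def bin_heatmap_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ``bin_heatmap`` over an abundance frame."""
    return frame.map(bin_heatmap)


def per_plant_top_otu(
    rel: GroupedAbundanceTable,
    uncommon: UncommonSet,
    threshold_percent: float = 0.0,
) -> dict[str, tuple[str, float]]:
    """The most abundant uncommon OTU per host in one compartment.

    Returns host -> (otu_id, abundance percent). Only abundances strictly
    above ``threshold_percent`` count as detections (the relaxed bacterial
    mode passes 0.15); hosts with no qualifying OTU are omitted. Ties break
    on lexicographic OTU id.
    """
    tissue, substrate = uncommon.compartment
    comp = rel.compartment(tissue, substrate)
    otus = sorted(o for o in uncommon.otu_ids if o in comp.columns)
    out: dict[str, tuple[str, float]] = {}
    for host in comp.index:
        best: tuple[str, float] | None = None
        for o in otus:
            v = float(comp.at[host, o])
            if v <= threshold_percent:
                continue
            if best is None or v > best[1]:
                best = (o, v)
        if best is not None:
            out[str(host)] = best
    return out
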
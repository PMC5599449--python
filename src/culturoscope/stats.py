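"""Community statistics: Shannon diversity, rarefaction, Bray-Curtis,
UPGMA clustering and SIMPER.

These are deliberately formula-level implementations with explicit,
deterministic tie-breaking, so every number the pipeline reports can be
traced to a stated formula:

* Shannon: H' = -sum p_i log p_i over non-zero p_i (natural log by
  default; base configurable).
* Bray-Curtis: sum|x_i - y_i| / sum(x_i + y_i), in [0, 1] for
  non-negative data.
* Rarefaction: repeated subsampling without replacement (multivariate
  hypergeometric), reporting mean and s.d. of observed OTU richness per
  depth.
* UPGMA: average-linkage agglomeration; ties broken by the lowest
  cluster-label pair.
* SIMPER: the average between-group Bray-Curtis dissimilarity broken
  into additive per-OTU contributions; contributions sum exactly to the
  overall average dissimilarity.  Conventionally run on square-root
  transformed relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "SimperResult",
    "shannon",
    "rarefaction_curve",
    "bray_curtis",
    "distance_matrix",
    "hclust_upgma",
    "simper",
]


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H' of a count (or abundance) vector.

    Natural log by default; pass ``base=2`` for the bits convention.
    """
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("cannot compute Shannon diversity of an all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def rarefaction_curve(
    counts,
    depths,
    n_reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (+/- s.d.) observed OTU richness per subsampling depth.

    Subsampling is without replacement (multivariate hypergeometric),
    ``n_reps`` repetitions per depth, seeded.
    """
    x = np.asarray(counts, dtype=int)
    total = int(x.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total count {total}")
        obs = np.empty(n_reps)
        for r in range(n_reps):
            sub = rng.multivariate_hypergeometric(x, depth)
            obs[r] = int((sub > 0).sum())
        rows.append({"depth": int(depth), "mean_otus": float(obs.mean()),
                     "sd_otus": float(obs.std(ddof=0)), "n_reps": n_reps})
    return pd.DataFrame(rows)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both profiles are all-zero")
    return float(np.abs(x - y).sum() / denom)


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal is not zero")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def distance_matrix(rel_abundance: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between the rows of a
    relative-abundance table."""
    labels = list(rel_abundance.index)
    n = len(labels)
    vals = np.zeros((n, n))
    arr = rel_abundance.values
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = bray_curtis(arr[i], arr[j])
    return DistanceMatrix(labels, vals)


@dataclass
class Dendrogram:
    """UPGMA merge history: (cluster_a, cluster_b, height, new size).

    Leaves are numbered 0..n-1 in label order; merge k creates cluster
    n+k, as in the scipy linkage convention.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def __post_init__(self) -> None:
        if len(self.merges) != max(0, len(self.labels) - 1):
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (height / 2)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _s) in enumerate(self.merges):
            la = h / 2 - height[a] / 2
            lb = h / 2 - height[b] / 2
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";" if self.merges else f"({self.labels[0]});"


def hclust_upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    At each step the pair of clusters at minimal average distance is
    merged; ties are broken by the lowest (a, b) cluster-label pair.
    """
    n = len(dm)
    if n < 2:
        raise ValueError("need at least 2 leaves to cluster")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(dm.values[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                d = dist[(i, j)]
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, a, b = best
        merges.append((a, b, d, size[a] + size[b]))
        for other in sorted(active - {a, b}):
            da = dist[tuple(sorted((a, other)))]
            db = dist[tuple(sorted((b, other)))]
            dist[(other, next_id) if other < next_id else (next_id, other)] = (
                (size[a] * da + size[b] * db) / (size[a] + size[b])
            )
        size[next_id] = size[a] + size[b]
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return Dendrogram(dm.labels, merges)


@dataclass
class SimperResult:
    """Per-OTU breakdown of average between-group dissimilarity."""

    table: pd.DataFrame           # per-OTU contributions, sorted descending
    overall_dissimilarity: float

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def simper(
    rel_abundance: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    sqrt_transform: bool = True,
) -> SimperResult:
    """Similarity-percentages breakdown between two sample groups.

    For every cross-group sample pair (j, k) and OTU i, the pairwise
    Bray-Curtis term ``|y_ij - y_ik| / sum_m (y_mj + y_mk)`` is computed
    on (optionally square-root transformed) data y; the per-OTU
    contribution is its mean over all cross pairs.  Contributions sum to
    the overall average between-group dissimilarity.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if not group_a or not group_b:
        raise ValueError("both groups need at least one sample")
    for s in [*group_a, *group_b]:
        if s not in rel_abundance.index:
            raise KeyError(f"sample {s!r} not in the table")
    y = rel_abundance.copy()
    if sqrt_transform:
        y = np.sqrt(y)
    A = y.loc[group_a].values
    B = y.loc[group_b].values
    n_otu = y.shape[1]
    contrib = np.zeros(n_otu)
    n_pairs = 0
    for aj in A:
        for bk in B:
            denom = (aj + bk).sum()
            if denom == 0:
                raise ValueError("a cross-group sample pair is all-zero")
            contrib += np.abs(aj - bk) / denom
            n_pairs += 1
    contrib /= n_pairs
    overall = float(contrib.sum())
    pct = 100 * contrib / overall if overall > 0 else np.zeros(n_otu)
    out = pd.DataFrame({
        "otu_id": y.columns,
        "contribution": contrib,
        "contribution_pct": pct,
        "mean_abundance_a": rel_abundance.loc[group_a].mean(axis=0).values,
        "mean_abundance_b": rel_abundance.loc[group_b].mean(axis=0).values,
    }).sort_values(["contribution", "otu_id"], ascending=[False, True]).reset_index(drop=True)
    out["cumulative_pct"] = out["contribution_pct"].cumsum()
    return SimperResult(out, overall)
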
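"""Abundance-profile containers, table I/O, Bray-Curtis trees.

The central container is :class:`CohortProfile`, a samples x features table
of relative abundances (each row closed to sum 1) tagged with a cohort id
and a taxonomic level (genus, species, or gene).  Bray-Curtis dissimilarity
and average/complete-linkage trees support the co-clustering rule used to
pull external CRC samples into a discovery cohort: candidates are accepted
when they fall in the same cut-level cluster as at least one reference
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .stages import Stage

VALID_LEVELS = ("genus", "species", "gene")

METADATA_COLUMNS = ("sample_id", "stage", "cohort", "fit_ug_g", "age", "sex")


@dataclass
class CohortProfile:
    """Samples x features relative-abundance matrix for one cohort.

    Parameters
    ----------
    data
        DataFrame indexed by sample id with feature ids as columns.
        Values are non-negative and each row sums to at most 1 (closure
        may leave slightly less than 1 only through rounding).
    level
        Taxonomic level of the features: ``genus``, ``species`` or ``gene``.
    cohort_id
        Free-text cohort tag, e.g. ``discovery1``.
    """

    data: pd.DataFrame
    level: str = "gene"
    cohort_id: str = ""

    def __post_init__(self) -> None:
        if self.level not in VALID_LEVELS:
            raise ValueError(f"level must be one of {VALID_LEVELS}, got {self.level!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            r, c = map(int, np.argwhere(np.isnan(values))[0])
            raise ValueError(
                f"non-numeric cell at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )
        if (values < 0).any():
            r, c = map(int, np.argwhere(values < 0)[0])
            raise ValueError(
                f"negative abundance {values[r, c]} at sample "
                f"{self.data.index[r]!r}, feature {self.data.columns[c]!r}"
            )
        sums = values.sum(axis=1)
        if (sums > 1 + 1e-9).any():
            bad = self.data.index[int(np.argmax(sums > 1 + 1e-9))]
            raise ValueError(f"sample {bad!r} abundances sum to more than 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def restrict(self, feature_ids: list[str]) -> "CohortProfile":
        """Sub-profile over the given features; missing features are an error."""
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise KeyError(f"features absent from profile: {missing}")
        return CohortProfile(self.data[list(feature_ids)], self.level, self.cohort_id)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarity with zero diagonal, values in [0, 1]."""

    ids: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValueError("diagonal not zero")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-9:
            raise ValueError("dissimilarities outside [0, 1]")


def read_abundance_table(
    path, orientation: str = "samples_by_features", level: str = "gene", cohort_id: str = ""
) -> CohortProfile:
    """Read a TSV abundance table.

    ``orientation`` declares the layout explicitly (``samples_by_features``
    or ``features_by_samples``); there is no autodetection.
    """
    if orientation not in ("samples_by_features", "features_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "features_by_samples":
        df = df.T
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from None
    return CohortProfile(df, level=level, cohort_id=cohort_id)


def write_abundance_table(profile: CohortProfile, path, orientation: str = "samples_by_features") -> None:
    df = profile.data if orientation == "samples_by_features" else profile.data.T
    with open(path, "w") as fh:
        fh.write(f"# orientation={orientation} level={profile.level} cohort={profile.cohort_id}\n")
        df.to_csv(fh, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, stage, cohort, fit_ug_g, age, sex)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "stage" not in df.columns:
        raise ValueError("metadata must contain sample_id and stage columns")
    df["stage"] = [Stage.parse(s).name for s in df["stage"]]
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    return df.set_index("sample_id", drop=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Close a samples x features count table so each row sums to 1."""
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    sums = values.sum(axis=1)
    if (sums <= 0).any():
        bad = counts.index[int(np.argmax(sums <= 0))]
        raise ValueError(f"sample {bad!r} has no positive counts")
    return counts.div(sums, axis=0)


def bray_curtis(profile: CohortProfile) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity, 1 - 2*sum(min)/sum(a+b)."""
    if len(profile.sample_ids) == 0:
        raise ValueError("empty profile")
    d = squareform(pdist(profile.values, metric="braycurtis"))
    return DissimilarityMatrix(profile.sample_ids, d)


def top_abundant_features(profile: CohortProfile, k: int = 30) -> CohortProfile:
    """Restrict to the k features with the highest mean abundance.

    Genus-level trees conventionally use the top-30 most abundant genera.
    """
    order = profile.data.mean(axis=0).sort_values(ascending=False)
    return profile.restrict(list(order.index[:k]))


@dataclass
class ClusterTree:
    """Agglomerative tree over samples, backed by a scipy linkage matrix."""

    ids: list[str]
    linkage_matrix: np.ndarray
    method: str

    def to_newick(self) -> str:
        node = hierarchy.to_tree(self.linkage_matrix)

        def walk(n) -> str:
            if n.is_leaf():
                return self.ids[n.id]
            return f"({walk(n.left)}:{n.dist - n.left.dist:.10g},{walk(n.right)}:{n.dist - n.right.dist:.10g})"

        return walk(node) + ";"

    def cut(self, k: int) -> dict[str, int]:
        """Assign each leaf to one of k clusters (maxclust criterion)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.ids, (int(v) for v in labels)))


def hierarchical_tree(dm: DissimilarityMatrix, linkage: str = "average") -> ClusterTree:
    """Agglomerate a dissimilarity matrix with average or complete linkage."""
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    if len(dm.ids) < 2:
        raise ValueError("need at least 2 samples to build a tree")
    z = hierarchy.linkage(squareform(dm.d, checks=False), method=linkage)
    return ClusterTree(list(dm.ids), z, linkage)


def select_cocluster_samples(
    tree: ClusterTree,
    reference_ids: list[str],
    candidate_ids: list[str],
    cut_k: int = 2,
) -> list[str]:
    """Candidates sharing a cut-level cluster with any reference sample.

    Operationalizes same-branch membership: the tree is cut into ``cut_k``
    clusters and a candidate is selected when its cluster contains at least
    one reference sample.
    """
    if cut_k < 2:
        raise ValueError("cut_k must be >= 2")
    leaves = set(tree.ids)
    unknown = [s for s in [*reference_ids, *candidate_ids] if s not in leaves]
    if unknown:
        raise KeyError(f"ids not in tree: {unknown}")
    assignment = tree.cut(cut_k)
    reference_clusters = {assignment[s] for s in reference_ids}
    return [s for s in candidate_ids if assignment[s] in reference_clusters]
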
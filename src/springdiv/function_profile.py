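"""KO (KEGG Orthology) profile comparisons across metagenomes.

Covers the four steps used to contrast functional coding potential between
springs: per-metagenome normalization of KO counts, the centered enrichment
statistic, restriction to a KEGG category or subcategory (e.g. "Energy
Metabolism"), and Bray-Curtis dissimilarity followed by principal coordinates
analysis.

The enrichment statistic for KO k in metagenome s is

    E_{k,s} = (a_{k,s} - m_k) / m_k

where a is the normalized abundance and m_k its mean across metagenomes.
E is -1 where the KO is absent, 0 at the dataset mean, and S-1 (14 for 15
metagenomes) when the KO occurs in exactly one metagenome — the exclusivity
ceiling.

Tables are pandas DataFrames with metagenomes as rows and KO ids as columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .exceptions import InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)


class KOCategoryMap:
    """KO id -> (top-level category, subcategory), e.g. Metabolism / Energy Metabolism.

    Each KO maps to at most one pair.  Constructed from a mapping or from a
    three-column TSV (ko, category, subcategory).
    """

    def __init__(self, mapping: dict[str, tuple[str, str]]):
        self._map = dict(mapping)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KOCategoryMap":
        dupes = df["ko"].duplicated()
        if dupes.any():
            raise InvalidInputError(
                f"KO ids mapped more than once: {sorted(df.loc[dupes, 'ko'].unique())[:5]}"
            )
        return cls({r.ko: (r.category, r.subcategory) for r in df.itertuples()})

    @classmethod
    def read_tsv(cls, path) -> "KOCategoryMap":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, c, s) for k, (c, s) in sorted(self._map.items())],
            columns=["ko", "category", "subcategory"],
        )

    def __contains__(self, ko: str) -> bool:
        return ko in self._map

    def __len__(self) -> int:
        return len(self._map)

    def category_of(self, ko: str) -> tuple[str, str] | None:
        return self._map.get(ko)

    @property
    def labels(self) -> set[str]:
        out: set[str] = set()
        for cat, sub in self._map.values():
            out.add(cat)
            out.add(sub)
        return out

    def kos_with_label(self, label: str) -> set[str]:
        """KOs whose category or subcategory equals ``label``."""
        if label not in self.labels:
            raise InvalidParameterError(f"unknown category label {label!r}")
        return {k for k, (cat, sub) in self._map.items() if label in (cat, sub)}

    def kos_in_category(self, category: str) -> set[str]:
        return {k for k, (cat, _) in self._map.items() if cat == category}


def normalize_ko(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize each metagenome's KO counts to frequencies (rows sum to 1).

    This is the sequencing-effort correction: dividing by the metagenome's
    total KO-annotated protein count makes deeply and shallowly sequenced
    springs comparable.
    """
    totals = table.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise InvalidInputError(
            f"metagenome(s) with zero KO total: {list(zero.index)}"
        )
    return table.div(totals, axis=0)


def ko_enrichment(normalized: pd.DataFrame) -> pd.DataFrame:
    """Centered, mean-normalized enrichment matrix (KO x metagenome).

    KOs with zero mean across all metagenomes are dropped (logged) to avoid
    0/0.  For every retained KO the across-metagenome mean of E is 0,
    min(E) >= -1, and max(E) = S-1 exactly when the KO is exclusive to one
    metagenome.
    """
    means = normalized.mean(axis=0)
    dropped = means.index[means <= 0]
    if len(dropped):
        logger.info("ko_enrichment: dropping %d all-zero KOs", len(dropped))
    kept = normalized.loc[:, means > 0]
    enrichment = kept.sub(means[means > 0], axis=1).div(means[means > 0], axis=1)
    return enrichment.T  # KO x metagenome


def subset_category(
    table: pd.DataFrame, category_map: KOCategoryMap, label: str
) -> pd.DataFrame:
    """Restrict a KO table to KOs carrying a category or subcategory label.

    KOs in the table but absent from the map are never matched (their count is
    logged).  An empty result is returned with a warning, not an error.
    Note that subsetting does not commute with normalization: frequencies
    computed after subsetting are relative to the subset total.
    """
    wanted = category_map.kos_with_label(label)
    unknown = [k for k in table.columns if k not in category_map]
    if unknown:
        logger.info("subset_category: %d KOs in table missing from map", len(unknown))
    cols = [k for k in table.columns if k in wanted]
    if not cols:
        logger.warning("subset_category: no KO in the table carries label %r", label)
    return table.loc[:, cols]


def bray_curtis(table: pd.DataFrame, use_frequencies: bool = True) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) between metagenomes.

    By default computed on per-metagenome frequencies (the sequencing-effort
    correction applied before the distance step); set ``use_frequencies=False``
    to use the table as given.
    """
    if len(table) < 2:
        raise InvalidInputError("bray_curtis needs at least two metagenomes")
    if (table.to_numpy() < 0).any():
        raise InvalidInputError("bray_curtis requires non-negative abundances")
    if (table.sum(axis=1) <= 0).any():
        raise InvalidInputError("bray_curtis: metagenome with all-zero abundances")
    data = normalize_ko(table) if use_frequencies else table
    condensed = pdist(data.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


@dataclass
class Ordination:
    """PCoA result: sample coordinates, eigenvalues, proportion explained.

    Axes are ordered by descending eigenvalue; only positive-eigenvalue axes
    are embedded.  Negative eigenvalues (possible for non-Euclidean distances
    such as Bray-Curtis) are reported in ``negative_eigenvalues`` and omitted.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(distance_matrix, k: int | None = None) -> Ordination:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J with J the centering matrix; coordinates are eigenvectors
    scaled by the square root of their (positive) eigenvalues.  Axis signs are
    fixed by making the largest-magnitude loading on each axis positive.

    Accepts a skbio DistanceMatrix or a square array; asymmetric input or a
    nonzero diagonal raises InvalidInputError.
    """
    if not isinstance(distance_matrix, DistanceMatrix):
        try:
            distance_matrix = DistanceMatrix(np.asarray(distance_matrix, dtype=float))
        except Exception as exc:
            raise InvalidInputError(f"not a valid distance matrix: {exc}") from exc
    d = np.asarray(distance_matrix.data, dtype=float)
    n = d.shape[0]
    if k is not None and not 1 <= k <= n - 1:
        raise InvalidParameterError(f"k must be in [1, {n - 1}], got {k}")
    d2 = d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    negative = eigvals[eigvals < -tol]
    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    for j in range(coords.shape[1]):
        if coords.shape[0] and coords[np.argmax(np.abs(coords[:, j])), j] < 0:
            coords[:, j] = -coords[:, j]
    if k is not None:
        coords = coords[:, :k]
        pos_vals = pos_vals[:k]
    total = eigvals[positive].sum()
    proportion = pos_vals / total if total > 0 else np.zeros_like(pos_vals)
    frame = pd.DataFrame(
        coords,
        index=list(distance_matrix.ids),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return Ordination(
        coordinates=frame,
        eigenvalues=pos_vals,
        proportion_explained=proportion,
        negative_eigenvalues=negative,
    )


def plot_ordination(ordination: Ordination, path) -> None:
    """Scatter of the first two ordination axes, written to SVG/PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = ordination.coordinates
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1])
    for label, row in coords.iterrows():
        ax.annotate(str(label), (row.iloc[0], row.iloc[1]), fontsize=6)
    pe = ordination.proportion_explained
    ax.set_xlabel(f"PCo1 ({pe[0]:.1%})" if len(pe) > 0 else "PCo1")
    ax.set_ylabel(f"PCo2 ({pe[1]:.1%})" if len(pe) > 1 else "PCo2")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
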
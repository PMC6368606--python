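"""MAG quality filtering and relative abundance, intra-lineage metabolic
differentiation, and average amino-acid identity (AAI) between proteomes.

Relative abundance follows the coverage-normalization chain: relativized
coverage = mapped reads / assembled length; that coverage is multiplied by the
estimated genome size (assembled length / completeness fraction) and the
products are renormalized to fractions over the retained bins.

Metabolic differentiation between two related genomes is summarized per KEGG
category as the ratio of unshared to shared KO-annotated proteins; comparing
the "Metabolism" ratio against the "Genetic Information Processing" ratio
(the conservative baseline) places each genome pair relative to the 1:1 line —
points above it are more differentiated in metabolism than in genetic
processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, UndefinedResultError
from .function_profile import KOCategoryMap
from .seqcluster import ProteinRecord, align_local

logger = logging.getLogger(__name__)

MIN_COMPLETENESS = 50.0  # percent, strict >
MAX_CONTAMINATION = 7.0  # percent, strict <

DIFFERENTIATION_CATEGORIES = ("Metabolism", "Genetic Information Processing")

MAG_COLUMNS = ["bin_id", "total_length_bp", "mapped_reads", "completeness", "contamination"]


def filter_mags(
    mags: pd.DataFrame,
    min_completeness: float = MIN_COMPLETENESS,
    max_contamination: float = MAX_CONTAMINATION,
) -> pd.DataFrame:
    """Retain medium-high quality draft bins: completeness strictly above
    ``min_completeness`` AND contamination strictly below ``max_contamination``.

    Boundary values (exactly 50% complete, exactly 7% contaminated) are
    excluded.  Retained/excluded counts are logged.
    """
    keep = (mags["completeness"] > min_completeness) & (
        mags["contamination"] < max_contamination
    )
    logger.info(
        "filter_mags: retained %d of %d bins (>%g%% complete, <%g%% contamination)",
        int(keep.sum()),
        len(mags),
        min_completeness,
        max_contamination,
    )
    return mags.loc[keep].copy()


def mag_relative_abundance(mags: pd.DataFrame) -> pd.DataFrame:
    """Coverage-normalized relative abundance per bin; adds two columns.

    coverage_i  = mapped_reads_i / total_length_bp_i
    size_i      = total_length_bp_i / (completeness_i / 100)
    abundance_i = coverage_i * size_i / sum_j coverage_j * size_j

    Abundances sum to 1 and are invariant to uniform scaling of read counts.
    """
    if (mags["total_length_bp"] <= 0).any():
        raise InvalidInputError("bins with non-positive total length")
    if (mags["completeness"] <= 0).any():
        raise InvalidInputError("bins with non-positive completeness; genome size undefined")
    out = mags.copy()
    coverage = out["mapped_reads"] / out["total_length_bp"]
    out["estimated_genome_size"] = out["total_length_bp"] / (out["completeness"] / 100.0)
    weight = coverage * out["estimated_genome_size"]
    out["relative_abundance"] = weight / weight.sum()
    return out


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome's KO complement: id, lineage label, and the set of KO ids."""

    genome_id: str
    lineage: str
    kos: frozenset[str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, genome_id: str, lineage: str = "") -> "GenomeAnnotation":
        """Build from an annotation table with a ``ko`` column (one row per protein)."""
        return cls(genome_id=genome_id, lineage=lineage, kos=frozenset(df["ko"].dropna()))


@dataclass(frozen=True)
class CategoryDifferentiation:
    category: str
    shared: int
    unshared: int
    ratio: float | None  # None when shared == 0 (undefined, not infinity)
    unique_a: int
    unique_b: int

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass
class PairwiseDifferentiation:
    """Shared/unshared KO counts and ratios per category for one genome pair."""

    genome_a: str
    genome_b: str
    by_category: dict[str, CategoryDifferentiation] = field(default_factory=dict)

    def point(self) -> tuple[float | None, float | None]:
        """(genetic-processing ratio, metabolism ratio): the scatter coordinates."""
        gen = self.by_category.get(DIFFERENTIATION_CATEGORIES[1])
        met = self.by_category.get(DIFFERENTIATION_CATEGORIES[0])
        return (
            gen.ratio if gen is not None else None,
            met.ratio if met is not None else None,
        )


def differentiation_ratios(
    a: GenomeAnnotation,
    b: GenomeAnnotation,
    category_map: KOCategoryMap,
    categories: tuple[str, ...] = DIFFERENTIATION_CATEGORIES,
) -> PairwiseDifferentiation:
    """Per-category shared / unshared KO counts and the unshared:shared ratio.

    Unshared is the symmetric difference |A xor B| (both directions pooled);
    per-genome unique counts are also reported.  KOs absent from the category
    map carry no category and are ignored (logged).  A category with zero
    shared KOs yields an undefined ratio, flagged rather than infinite.
    The statistic is symmetric in (a, b).
    """
    unmapped = [k for k in (a.kos | b.kos) if k not in category_map]
    if unmapped:
        logger.info("differentiation_ratios: %d KOs missing from category map ignored", len(unmapped))
    result = PairwiseDifferentiation(genome_a=a.genome_id, genome_b=b.genome_id)
    for cat in categories:
        pool = category_map.kos_in_category(cat)
        ka = a.kos & pool
        kb = b.kos & pool
        shared = len(ka & kb)
        unique_a = len(ka - kb)
        unique_b = len(kb - ka)
        unshared = unique_a + unique_b
        ratio = unshared / shared if shared > 0 else None
        if ratio is None:
            logger.warning(
                "differentiation_ratios: %s/%s category %r has no shared KO; ratio undefined",
                a.genome_id,
                b.genome_id,
                cat,
            )
        result.by_category[cat] = CategoryDifferentiation(
            category=cat,
            shared=shared,
            unshared=unshared,
            ratio=ratio,
            unique_a=unique_a,
            unique_b=unique_b,
        )
    return result


def differentiation_table(results: list[PairwiseDifferentiation]) -> pd.DataFrame:
    """Tidy per-pair, per-category differentiation counts (one row each)."""
    rows = []
    for r in results:
        for cat, d in r.by_category.items():
            rows.append(
                {
                    "genome_a": r.genome_a,
                    "genome_b": r.genome_b,
                    "category": cat,
                    "shared": d.shared,
                    "unshared": d.unshared,
                    "ratio": d.ratio if d.defined else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AAIResult:
    """Average amino-acid identity over reciprocal best-hit protein pairs."""

    mean_identity: float  # percent
    sd_identity: float  # percent
    n_pairs: int


def aai(
    proteome_a: list[ProteinRecord],
    proteome_b: list[ProteinRecord],
    min_identity: float = 0.20,
    min_coverage: float = 0.50,
) -> AAIResult:
    """Two-way (reciprocal) best-hit AAI between two proteomes.

    Every protein of A is aligned against every protein of B (Smith-Waterman,
    BLOSUM62); hits must reach ``min_identity`` and cover ``min_coverage`` of
    the shorter sequence.  A pair is retained when each member is the other's
    best hit; the mean and sd of retained identities are reported in percent.
    """
    if not proteome_a or not proteome_b:
        raise InvalidInputError("aai requires two non-empty proteomes")
    n_a, n_b = len(proteome_a), len(proteome_b)
    identity = np.zeros((n_a, n_b))
    qualifies = np.zeros((n_a, n_b), dtype=bool)
    for i, pa in enumerate(proteome_a):
        for j, pb in enumerate(proteome_b):
            stats = align_local(pa.seq, pb.seq)
            identity[i, j] = stats.identity
            qualifies[i, j] = (
                stats.identity >= min_identity and stats.coverage_short >= min_coverage
            )
    masked = np.where(qualifies, identity, -1.0)
    best_for_a = masked.argmax(axis=1)
    best_for_b = masked.argmax(axis=0)
    pair_identities = []
    for i in range(n_a):
        j = best_for_a[i]
        if masked[i, j] >= 0 and best_for_b[j] == i:
            pair_identities.append(identity[i, j])
    if not pair_identities:
        raise UndefinedResultError("no reciprocal best-hit pairs pass the identity/coverage floor")
    values = 100.0 * np.asarray(pair_identities)
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return AAIResult(mean_identity=float(values.mean()), sd_identity=sd, n_pairs=len(values))
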
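"""Greedy incremental protein-family clustering with an identity-threshold cascade.

Protein "family bins" are built the way large metagenome surveys build them:
sequences are sorted longest-first and swept once, each sequence either joining
the best-matching existing cluster representative (local-alignment identity at
or above the level's threshold, alignment covering at least ``min_coverage`` of
the shorter sequence) or founding a new cluster.  Clustering is then cascaded:
representatives of the fine level are re-clustered at coarser identity levels
(default 90% -> 60% -> 30%) and memberships are propagated down, so every
protein ends up in exactly one coarse family.

Alignment uses Smith-Waterman local alignment with BLOSUM62 and affine gap
penalties (open 11, extend 1).  Identity is computed over aligned columns
including internal gap columns — a conservative, symmetric convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import ConsistencyError, InvalidInputError, InvalidParameterError

logger = logging.getLogger(__name__)

#: 20 canonical residues plus X (ambiguous), the alphabet accepted in records.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

#: Minimum length (strict) for a protein to enter clustering.
MIN_PROTEIN_LENGTH = 50

DEFAULT_THRESHOLDS = (0.90, 0.60, 0.30)
DEFAULT_MIN_COVERAGE = 0.8


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: a unique id, its source metagenome, and the sequence."""

    protein_id: str
    metagenome_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise InvalidInputError(f"protein {self.protein_id!r} has an empty sequence")
        bad = set(self.seq) - _VALID_RESIDUES
        if bad:
            raise InvalidInputError(
                f"protein {self.protein_id!r} contains non-amino-acid symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one local alignment.

    identity
        Identical residue pairs divided by aligned columns (internal gap
        columns count in the denominator).
    coverage_short
        Span of the shorter sequence inside the local alignment divided by
        its full length.
    score
        Raw alignment score under BLOSUM62 / affine(11, 1).
    """

    identity: float
    coverage_short: float
    score: float


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)


@dataclass
class ClusterSet:
    """Partition of the input at a single identity threshold."""

    threshold: float
    clusters: list[Cluster]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, str]:
        """Map each member protein_id to its representative's protein_id."""
        out: dict[str, str] = {}
        for cl in self.clusters:
            for m in cl.members:
                out[m] = cl.representative
        return out


@dataclass
class FamilyAssignment:
    """Hierarchical family membership across the clustering cascade.

    ``lineage`` maps each protein to its cluster representative at every level
    (finest first); ``family_of`` maps each protein to its family id at the
    final, coarsest level.
    """

    levels: tuple[float, ...]
    family_of: dict[str, str]
    lineage: dict[str, tuple[str, ...]]
    family_ids: dict[str, str]  # final-level representative -> family id


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_local(a: str, b: str) -> AlignmentStats:
    """Smith-Waterman local alignment of two amino-acid sequences.

    Returns identity over aligned columns (gaps included in the denominator)
    and coverage of the shorter sequence.  If no alignment achieves a positive
    score (e.g. disjoint residue usage), identity and coverage are 0.
    """
    if not a or not b:
        raise InvalidInputError("align_local requires two non-empty sequences")
    score = _ALIGNER.score(a, b)
    if score <= 0:
        return AlignmentStats(identity=0.0, coverage_short=0.0, score=float(score))
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    identity = counts.identities / columns if columns else 0.0
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    if len(a) <= len(b):
        coverage_short = span_a / len(a)
    else:
        coverage_short = span_b / len(b)
    return AlignmentStats(identity=float(identity), coverage_short=float(coverage_short), score=float(score))


def filter_by_length(records: Iterable[ProteinRecord], min_length: int = MIN_PROTEIN_LENGTH) -> list[ProteinRecord]:
    """Keep proteins strictly longer than ``min_length`` amino acids."""
    kept = [r for r in records if len(r.seq) > min_length]
    return kept


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_at(
    records: Sequence[ProteinRecord],
    threshold: float,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    prefilter_k: int | None = None,
) -> ClusterSet:
    """Greedy incremental clustering at one identity threshold.

    Sequences are processed longest-first (ties broken by protein_id);
    each joins the highest-identity representative meeting both the identity
    threshold and the shorter-sequence coverage floor, otherwise founds a new
    cluster.  Ties between equally good representatives go to the longer
    representative, then the lexicographically smaller id.

    ``prefilter_k``, when set, skips alignment against representatives sharing
    no k-mer of that size with the query; it is a speed device only and does
    not change the acceptance criterion.
    """
    if not records:
        raise InvalidInputError("cluster_at requires at least one record")
    if not 0 < threshold <= 1:
        raise InvalidParameterError(f"threshold must be in (0, 1], got {threshold}")
    if not 0 <= min_coverage <= 1:
        raise InvalidParameterError(f"min_coverage must be in [0, 1], got {min_coverage}")
    ids = [r.protein_id for r in records]
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate protein_id in clustering input")

    ordered = sorted(records, key=lambda r: (-len(r.seq), r.protein_id))
    reps: list[ProteinRecord] = []
    rep_kmers: list[set[str]] = []
    clusters: list[Cluster] = []

    for rec in ordered:
        query_kmers = _kmer_set(rec.seq, prefilter_k) if prefilter_k else None
        best: tuple[float, int, str] | None = None  # (identity, rep length, rep id)
        best_idx = -1
        for i, rep in enumerate(reps):
            if query_kmers is not None and not (query_kmers & rep_kmers[i]):
                continue
            stats = align_local(rec.seq, rep.seq)
            if stats.identity >= threshold and stats.coverage_short >= min_coverage:
                key = (stats.identity, len(rep.seq), rep.protein_id)
                if best is None or (key[0], key[1], _NegStr(key[2])) > (
                    best[0],
                    best[1],
                    _NegStr(best[2]),
                ):
                    best = key
                    best_idx = i
        if best is None:
            reps.append(rec)
            if prefilter_k:
                rep_kmers.append(_kmer_set(rec.seq, prefilter_k))
            clusters.append(Cluster(representative=rec.protein_id, members=[rec.protein_id]))
        else:
            clusters[best_idx].members.append(rec.protein_id)
    return ClusterSet(threshold=threshold, clusters=clusters)


class _NegStr(str):
    """String with reversed ordering, so max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


#: Word sizes screened per cascade level (None = align against every
#: representative).  A shared word is implied by threshold-level similarity at
#: the two finer levels; the coarsest level always aligns exhaustively.
DEFAULT_PREFILTER_WORDS = (5, 4, None)


def cascade(
    records: Sequence[ProteinRecord],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    prefilter_k: int | None | Sequence[int | None] = DEFAULT_PREFILTER_WORDS,
) -> FamilyAssignment:
    """Cascaded clustering: cluster, re-cluster representatives, propagate down.

    ``thresholds`` must be strictly decreasing (fine to coarse).  The returned
    assignment maps every input protein to exactly one family at the coarsest
    level and records its representative at every level.  ``prefilter_k`` may
    be a single word size, None, or one value per level (default: 5 at the
    finest, 4 at the middle, exhaustive at the coarsest level).
    """
    thresholds = tuple(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidParameterError(f"thresholds must be strictly decreasing, got {thresholds}")
    if not records:
        raise InvalidInputError("cascade requires at least one record")
    if prefilter_k is None or isinstance(prefilter_k, int):
        per_level: tuple[int | None, ...] = (prefilter_k,) * len(thresholds)
    else:
        per_level = tuple(prefilter_k)
        if len(per_level) != len(thresholds):
            raise InvalidParameterError(
                f"prefilter_k has {len(per_level)} entries for {len(thresholds)} levels"
            )

    by_id = {r.protein_id: r for r in records}
    level_sets: list[ClusterSet] = []
    current: Sequence[ProteinRecord] = records
    for t, k in zip(thresholds, per_level):
        cs = cluster_at(current, t, min_coverage=min_coverage, prefilter_k=k)
        level_sets.append(cs)
        current = [by_id[c.representative] for c in cs.clusters]

    memberships = [cs.membership() for cs in level_sets]

    lineage: dict[str, tuple[str, ...]] = {}
    for rec in records:
        chain = []
        rep = rec.protein_id
        for m in memberships:
            rep = m[rep]
            chain.append(rep)
        lineage[rec.protein_id] = tuple(chain)

    final_reps = [c.representative for c in level_sets[-1].clusters]
    width = max(4, len(str(len(final_reps))))
    family_ids = {rep: f"F{i:0{width}d}" for i, rep in enumerate(final_reps)}
    family_of = {pid: family_ids[chain[-1]] for pid, chain in lineage.items()}
    logger.info(
        "cascade: %d proteins -> %s clusters per level",
        len(records),
        [cs.n_clusters for cs in level_sets],
    )
    return FamilyAssignment(
        levels=thresholds, family_of=family_of, lineage=lineage, family_ids=family_ids
    )


def family_abundance(assignment: FamilyAssignment, records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Abundance-weighted family counts: (metagenome, family) -> member count.

    Rows are metagenomes, columns families; zeros are explicit.  Row sums equal
    each metagenome's protein count.
    """
    rows = []
    for rec in records:
        fam = assignment.family_of.get(rec.protein_id)
        if fam is None:
            raise ConsistencyError(f"protein {rec.protein_id!r} has no family assignment")
        rows.append((rec.metagenome_id, fam))
    df = pd.DataFrame(rows, columns=["metagenome_id", "family_id"])
    table = (
        df.groupby(["metagenome_id", "family_id"]).size().unstack(fill_value=0)
    )
    all_fams = sorted(set(assignment.family_ids.values()))
    table = table.reindex(columns=all_fams, fill_value=0).sort_index()
    table.columns.name = "family_id"
    table.index.name = "metagenome_id"
    return table


def assert_threshold_soundness(
    cluster_set: ClusterSet, records: Sequence[ProteinRecord], min_coverage: float = DEFAULT_MIN_COVERAGE
) -> None:
    """Verify every member meets the identity/coverage criterion vs its representative.

    Intended for post-hoc auditing of clustering outputs; raises
    ConsistencyError on the first violation.
    """
    by_id = {r.protein_id: r for r in records}
    for cl in cluster_set.clusters:
        rep = by_id[cl.representative]
        for m in cl.members:
            if m == cl.representative:
                continue
            stats = align_local(by_id[m].seq, rep.seq)
            if stats.identity < cluster_set.threshold or stats.coverage_short < min_coverage:
                raise ConsistencyError(
                    f"member {m!r} fails the clustering criterion against {cl.representative!r}: "
                    f"identity={stats.identity:.3f}, coverage={stats.coverage_short:.3f}"
                )


def write_cluster_table(assignment: FamilyAssignment, records: Sequence[ProteinRecord], path) -> None:
    """Write a tab-separated cluster table: family, per-level cluster reps, member."""
    rows = []
    for rec in sorted(records, key=lambda r: r.protein_id):
        chain = assignment.lineage[rec.protein_id]
        rows.append(
            {
                "family_id": assignment.family_of[rec.protein_id],
                **{f"rep_at_{int(t * 100)}": rep for t, rep in zip(assignment.levels, chain)},
                "is_representative": int(rec.protein_id == chain[-1]),
                "protein_id": rec.protein_id,
                "metagenome_id": rec.metagenome_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pairwise_identity_matrix(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """All-pairs local-alignment identity; a small-fixture auditing helper."""
    ids = [r.protein_id for r in records]
    mat = pd.DataFrame(1.0, index=ids, columns=ids)
    for a, b in itertools.combinations(records, 2):
        s = align_local(a.seq, b.seq)
        mat.loc[a.protein_id, b.protein_id] = s.identity
        mat.loc[b.protein_id, a.protein_id] = s.identity
    return mat
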
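"""Synthetic hot-spring study generator with known ground truth.

Emulates every input the comparative pipeline consumes — per-spring predicted
proteomes with controlled family structure, spring geochemistry whose
fluid-mixing proxy log10(SO4/Cl) linearly drives planted family richness, KO
abundance tables with planted metagenome-exclusive KOs, genome pairs with
planted shared-KO fractions per KEGG category, MAG summary tables, and random
trees with a tagged tip subset — so that every downstream stage can be tested
against what was planted, without any external download.

Family structure: a pool of unrelated founder sequences (mutual identity kept
below a ceiling by rejection sampling) defines the families; each member is its
founder substituted at half the target divergence, so realized *pairwise*
identity between members tracks the configured within-family target.  Family
abundances within a spring are lognormal — environmental
protein-family abundances are strongly right-skewed, and the lognormal is the
simplest standard choice with that shape.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sdio
from .exceptions import InvalidParameterError
from .function_profile import KOCategoryMap
from .genome_compare import GenomeAnnotation
from .phylo_metrics import PhyloTree, branch_fraction, parse_newick
from .seqcluster import AMINO_ACIDS, ProteinRecord

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

#: KEGG-style (category, subcategory) pairs, consumed in order by n_categories.
CATEGORY_PAIRS = (
    ("Metabolism", "Energy Metabolism"),
    ("Genetic Information Processing", "Translation"),
    ("Metabolism", "Carbohydrate Metabolism"),
    ("Environmental Information Processing", "Membrane Transport"),
    ("Cellular Processes", "Cell Motility"),
    ("Genetic Information Processing", "Replication and Repair"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study; defaults define the study conditions.

    richness follows round(intercept + slope * log10(SO4/Cl) + N(0, noise_sd)),
    clamped to [1, pool_size].  Geochemistry is drawn log-uniform over ranges
    spanning the fluid-mixing axis (sulfate 10-316 mg/L, chloride 1-500 mg/L).
    """

    seed: int = 0
    n_springs: int = 40
    pool_size: int = 200
    richness_intercept: float = 40.0
    richness_slope: float = 8.0
    richness_noise_sd: float = 2.0
    abundance_mu: float = 1.0  # lognormal location of per-family member counts
    abundance_shape: float = 1.0  # lognormal sigma
    within_family_identity: float = 0.95
    between_family_identity_max: float = 0.25
    seq_length: int = 150
    n_ko: int = 240
    n_categories: int = 3
    exclusive_ko_count: int = 3
    pair_shared_fraction_met: float = 0.5
    pair_shared_fraction_gen: float = 0.8
    n_genome_pairs: int = 5
    kos_per_category_genome: int = 40
    n_mags: int = 12
    tree_tips: int = 40
    tagged_fraction: float = 0.10

    def validate(self) -> None:
        counts = {
            "n_springs": self.n_springs,
            "pool_size": self.pool_size,
            "seq_length": self.seq_length,
            "n_ko": self.n_ko,
            "n_categories": self.n_categories,
            "n_genome_pairs": self.n_genome_pairs,
            "kos_per_category_genome": self.kos_per_category_genome,
            "n_mags": self.n_mags,
            "tree_tips": self.tree_tips,
        }
        for name, value in counts.items():
            if value <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {value}")
        if self.n_springs < 2:
            raise InvalidParameterError("n_springs must be >= 2")
        if not 0 < self.within_family_identity <= 1:
            raise InvalidParameterError("within_family_identity must be in (0, 1]")
        if not 0 < self.between_family_identity_max < 1:
            raise InvalidParameterError("between_family_identity_max must be in (0, 1)")
        for name in ("pair_shared_fraction_met", "pair_shared_fraction_gen", "tagged_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.exclusive_ko_count < 0 or self.exclusive_ko_count > self.n_ko:
            raise InvalidParameterError("exclusive_ko_count must be in [0, n_ko]")
        if self.richness_noise_sd < 0:
            raise InvalidParameterError("richness_noise_sd must be >= 0")
        if self.n_categories > len(CATEGORY_PAIRS):
            raise InvalidParameterError(
                f"n_categories at most {len(CATEGORY_PAIRS)} (built-in label pairs)"
            )


@dataclass
class SyntheticStudy:
    """One complete generated study plus the record of everything planted."""

    config: SyntheticConfig
    geochem: pd.DataFrame
    proteins: dict[str, list[ProteinRecord]]
    truth_family_table: pd.DataFrame
    ko_table: pd.DataFrame
    ko_categories: KOCategoryMap
    genome_pairs: list[tuple[GenomeAnnotation, GenomeAnnotation]]
    mag_table: pd.DataFrame
    tree: PhyloTree
    tagged_tips: set[str]
    truth: dict = field(default_factory=dict)

    def all_proteins(self) -> list[ProteinRecord]:
        out: list[ProteinRecord] = []
        for spring in sorted(self.proteins):
            out.extend(self.proteins[spring])
        return out


def _substitute(seq_arr: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Replace each given position with a uniformly chosen *different* residue."""
    out = seq_arr.copy()
    for p in positions:
        choices = _AA[_AA != out[p]]
        out[p] = rng.choice(choices)
    return out


def _to_str(seq_arr: np.ndarray) -> str:
    return seq_arr.tobytes().decode()


def mutate_to_identity(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Return a copy of ``seq`` differing at exactly round((1-t)*len) positions.

    Every substituted position receives a residue different from the original,
    so the realized fraction of identical positions is exactly the rounded
    target.
    """
    if not seq:
        raise InvalidParameterError("sequence must be non-empty")
    if not 0 < target_identity <= 1:
        raise InvalidParameterError(
            f"target_identity must be in (0, 1], got {target_identity}"
        )
    n_sub = round((1.0 - target_identity) * len(seq))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    return _to_str(_substitute(arr, positions, rng))


def _founder_pool(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Pool of mutually unrelated founders (positional identity below the ceiling).

    Candidates are rejected while any accepted founder matches them at a
    fraction of positions at or above the ceiling — a cheap positional screen
    that guarantees between-family separation is controlled, not accidental.
    """
    length = config.seq_length
    pool = np.empty((config.pool_size, length), dtype=np.uint8)
    n_accepted = 0
    attempts = 0
    while n_accepted < config.pool_size:
        attempts += 1
        if attempts > 100 * config.pool_size:
            raise InvalidParameterError(
                "cannot satisfy between_family_identity_max; raise the ceiling or "
                "shorten the pool"
            )
        cand = rng.choice(_AA, size=length)
        if n_accepted:
            ident = (pool[:n_accepted] == cand).mean(axis=1)
            if ident.max() >= config.between_family_identity_max:
                continue
        pool[n_accepted] = cand
        n_accepted += 1
    return pool


def _generate_geochem(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_springs
    spring_ids = [f"SP{i:03d}" for i in range(n)]
    sulfate = 10 ** rng.uniform(1.0, 2.5, size=n)  # mg/L
    chloride = 10 ** rng.uniform(0.0, 2.7, size=n)  # mg/L
    df = pd.DataFrame(
        {
            "spring_id": spring_ids,
            "pH": np.round(rng.uniform(2.0, 9.0, size=n), 2),
            "temperature": np.round(rng.uniform(40.0, 92.0, size=n), 1),
            "sulfate": np.round(sulfate, 3),
            "chloride": np.round(chloride, 3),
        }
    )
    df["log_ratio"] = np.log10(df["sulfate"] / df["chloride"])
    return df


def _plant_richness(config: SyntheticConfig, log_ratio: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, config.richness_noise_sd, size=len(log_ratio))
    raw = config.richness_intercept + config.richness_slope * log_ratio + noise
    return np.clip(np.round(raw), 1, config.pool_size).astype(int)


def _generate_proteins(
    config: SyntheticConfig,
    geochem: pd.DataFrame,
    richness: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict[str, list[ProteinRecord]], pd.DataFrame, dict[str, str]]:
    pool = _founder_pool(config, rng)
    # each member diverges from its founder by half the target so *pairwise*
    # member identity (what clustering sees) lands on the configured target
    n_pair_diff = round((1.0 - config.within_family_identity) * config.seq_length)
    n_sub = round(n_pair_diff / 2)
    fam_width = max(4, len(str(config.pool_size)))
    family_ids = [f"FAM{i:0{fam_width}d}" for i in range(config.pool_size)]

    proteins: dict[str, list[ProteinRecord]] = {}
    protein_family: dict[str, str] = {}
    counts_rows = []
    for idx, spring in enumerate(geochem["spring_id"]):
        fams = np.sort(rng.choice(config.pool_size, size=richness[idx], replace=False))
        members = np.maximum(
            1, np.round(rng.lognormal(config.abundance_mu, config.abundance_shape, size=len(fams)))
        ).astype(int)
        recs: list[ProteinRecord] = []
        row = dict.fromkeys(family_ids, 0)
        serial = 0
        for fam, m in zip(fams, members):
            for _ in range(m):
                positions = rng.choice(config.seq_length, size=n_sub, replace=False)
                seq = _to_str(_substitute(pool[fam], positions, rng))
                pid = f"{spring}_P{serial:05d}"
                serial += 1
                recs.append(ProteinRecord(protein_id=pid, metagenome_id=spring, seq=seq))
                protein_family[pid] = family_ids[fam]
            row[family_ids[fam]] = int(m)
        proteins[spring] = recs
        counts_rows.append(row)
    table = pd.DataFrame(counts_rows, index=list(geochem["spring_id"]))
    table.index.name = "metagenome_id"
    table = table.loc[:, table.sum(axis=0) > 0]  # families planted nowhere are dropped
    table.columns.name = "family_id"
    return proteins, table, protein_family


def _generate_category_map(config: SyntheticConfig, rng: np.random.Generator) -> tuple[list[str], KOCategoryMap]:
    ko_ids = [f"K{i + 1:05d}" for i in range(config.n_ko)]
    pairs = CATEGORY_PAIRS[: config.n_categories]
    mapping = {ko: pairs[i % len(pairs)] for i, ko in enumerate(ko_ids)}
    return ko_ids, KOCategoryMap(mapping)


def _generate_ko_table(
    config: SyntheticConfig,
    ko_ids: list[str],
    spring_ids: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str]]:
    n_s, n_k = len(spring_ids), len(ko_ids)
    table = np.zeros((n_s, n_k), dtype=np.int64)
    exclusive = rng.choice(n_k, size=config.exclusive_ko_count, replace=False)
    exclusive_set = set(int(i) for i in exclusive)
    exclusive_spring: dict[str, str] = {}
    for k in range(n_k):
        if k in exclusive_set:
            s = int(rng.integers(n_s))
            table[s, k] = 1 + rng.poisson(5)
            exclusive_spring[ko_ids[k]] = spring_ids[s]
        else:
            # present in at least two springs so exclusivity stays exactly as planted
            n_present = 2 + rng.binomial(n_s - 2, 0.5)
            springs = rng.choice(n_s, size=n_present, replace=False)
            table[springs, k] = 1 + rng.poisson(5, size=n_present)
    df = pd.DataFrame(table, index=spring_ids, columns=ko_ids)
    df.index.name = "metagenome_id"
    return df, exclusive_spring


def _generate_genome_pairs(
    config: SyntheticConfig,
    category_map: KOCategoryMap,
    rng: np.random.Generator,
) -> list[tuple[GenomeAnnotation, GenomeAnnotation]]:
    fractions = {
        "Metabolism": config.pair_shared_fraction_met,
        "Genetic Information Processing": config.pair_shared_fraction_gen,
    }
    pools = {cat: sorted(category_map.kos_in_category(cat)) for cat in fractions}
    k_per = config.kos_per_category_genome
    pairs: list[tuple[GenomeAnnotation, GenomeAnnotation]] = []
    for j in range(config.n_genome_pairs):
        kos_a: set[str] = set()
        kos_b: set[str] = set()
        for cat, f in fractions.items():
            pool = pools[cat]
            shared_n = round(f * k_per)
            needed = 2 * k_per - shared_n
            if needed > len(pool):
                raise InvalidParameterError(
                    f"category {cat!r} pool ({len(pool)} KOs) too small for "
                    f"kos_per_category_genome={k_per}; enlarge n_ko"
                )
            picked = rng.choice(len(pool), size=needed, replace=False)
            picked = [pool[i] for i in picked]
            shared = picked[:shared_n]
            unique_a = picked[shared_n : k_per]
            unique_b = picked[k_per:]
            kos_a.update(shared, unique_a)
            kos_b.update(shared, unique_b)
        lineage = f"LIN{j:02d}"
        pairs.append(
            (
                GenomeAnnotation(genome_id=f"G{j:02d}a", lineage=lineage, kos=frozenset(kos_a)),
                GenomeAnnotation(genome_id=f"G{j:02d}b", lineage=lineage, kos=frozenset(kos_b)),
            )
        )
    return pairs


def _generate_mags(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_mags
    return pd.DataFrame(
        {
            "bin_id": [f"Bin{i + 1:03d}" for i in range(n)],
            "total_length_bp": rng.integers(1_000_000, 5_000_000, size=n),
            "mapped_reads": rng.integers(10_000, 1_000_000, size=n),
            "completeness": np.round(rng.uniform(30.0, 100.0, size=n), 1),
            "contamination": np.round(rng.exponential(3.0, size=n), 2),
        }
    )


def _random_tree_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Random binary topology by successive joins, uniform branch lengths."""
    labels = [f"T{i:03d}" for i in range(n_tips)]
    nodes = [f"{lab}:{rng.uniform(0.01, 0.3):.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        if len(nodes) == 0:
            nodes.append(f"({left},{right});")
        else:
            nodes.append(f"({left},{right}):{rng.uniform(0.01, 0.3):.6f}")
    return nodes[0]


def random_tree(n_tips: int, rng: np.random.Generator) -> PhyloTree:
    """A random rooted binary tree with positive branch lengths."""
    if n_tips < 1:
        raise InvalidParameterError("n_tips must be positive")
    return parse_newick(_random_tree_newick(n_tips, rng))


def _generate_tree(config: SyntheticConfig, rng: np.random.Generator) -> tuple[PhyloTree, set[str]]:
    tree = random_tree(config.tree_tips, rng)
    n_tagged = max(1, round(config.tagged_fraction * config.tree_tips))
    tagged = set(rng.choice(sorted(tree.tip_labels), size=n_tagged, replace=False))
    return tree, tagged


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate one complete study; deterministic for a fixed config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    geochem = _generate_geochem(config, rng)
    richness = _plant_richness(config, geochem["log_ratio"].to_numpy(), rng)
    proteins, family_table, protein_family = _generate_proteins(config, geochem, richness, rng)
    ko_ids, category_map = _generate_category_map(config, rng)
    ko_table, exclusive_spring = _generate_ko_table(
        config, ko_ids, list(geochem["spring_id"]), rng
    )
    genome_pairs = _generate_genome_pairs(config, category_map, rng)
    mag_table = _generate_mags(config, rng)
    tree, tagged = _generate_tree(config, rng)

    k_per = config.kos_per_category_genome
    planted_ratios = {}
    for cat, f in (
        ("Metabolism", config.pair_shared_fraction_met),
        ("Genetic Information Processing", config.pair_shared_fraction_gen),
    ):
        shared_n = round(f * k_per)
        planted_ratios[cat] = (2 * (k_per - shared_n)) / shared_n if shared_n else None

    truth = {
        "richness_slope": config.richness_slope,
        "richness_intercept": config.richness_intercept,
        "richness_noise_sd": config.richness_noise_sd,
        "planted_richness": dict(zip(geochem["spring_id"], (int(r) for r in richness))),
        "protein_family": protein_family,
        "within_family_identity": config.within_family_identity,
        "exclusive_kos": sorted(exclusive_spring),
        "exclusive_ko_spring": exclusive_spring,
        "pair_shared_fractions": {
            "Metabolism": config.pair_shared_fraction_met,
            "Genetic Information Processing": config.pair_shared_fraction_gen,
        },
        "planted_differentiation_ratios": planted_ratios,
        "branch_fraction_exclusive": branch_fraction(tree, tagged, mode="exclusive"),
        "branch_fraction_tip_only": branch_fraction(tree, tagged, mode="tip_only"),
    }
    return SyntheticStudy(
        config=config,
        geochem=geochem,
        proteins=proteins,
        truth_family_table=family_table,
        ko_table=ko_table,
        ko_categories=category_map,
        genome_pairs=genome_pairs,
        mag_table=mag_table,
        tree=tree,
        tagged_tips=tagged,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write a study to disk: FASTA per spring, TSV tables, newick, truth JSON."""
    outdir = Path(outdir)
    (outdir / "proteins").mkdir(parents=True, exist_ok=True)
    for spring, recs in study.proteins.items():
        sdio.write_protein_fasta(recs, outdir / "proteins" / f"{spring}.faa")
    sdio.write_table(study.geochem, outdir / "geochem.tsv", index=False)
    sdio.write_table(study.truth_family_table, outdir / "truth_family_table.tsv")
    sdio.write_table(study.ko_table, outdir / "ko_table.tsv")
    sdio.write_table(study.ko_categories.to_frame(), outdir / "ko_categories.tsv", index=False)
    sdio.write_table(study.mag_table, outdir / "mags.tsv", index=False)
    rows = []
    for a, b in study.genome_pairs:
        for g in (a, b):
            for ko in sorted(g.kos):
                rows.append({"genome_id": g.genome_id, "lineage": g.lineage, "ko": ko})
    sdio.write_table(pd.DataFrame(rows), outdir / "genome_annotations.tsv", index=False)
    (outdir / "tree.nwk").write_text(study.tree.write_newick() + "\n")
    (outdir / "tagged_tips.txt").write_text("\n".join(sorted(study.tagged_tips)) + "\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2, default=float)
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=2)
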
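"""Seeded synthetic inputs with planted ground truth, plus the packaged
canonical pancreatic-cancer-pathway edge list.

The generators emulate the statistical structure the downstream analysis
assumes: a two-cell-line microRNA microarray experiment (drug vs vehicle,
one array per condition) with planted concordant differential miRNAs, a
redundant four-source validated miRNA-target database, and a pathway
collection containing a "pancreatic cancer" gene set. Every generator is a
pure function of its configuration seed, so identical configs give
byte-identical fixtures.

Planted margins are engineered, not merely probable: measurement noise is
multiplicative log-normal truncated at ±2 sigma, so a planted 2.0x (or
0.4x) treated/control ratio can never be observed on the wrong side of the
1.5-fold screen, and a null ratio of 1.0 can never reach it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CELL_LINES, ELIGIBILITY_FLOOR, SAMPLES, ConfigurationError, FixtureConfig
from .enrichment import GeneSetCollection

logger = logging.getLogger(__name__)

SOURCE_DATABASES = ("miR2Disease", "miRecords", "TarBase", "miRTarBase")

#: The five miRNAs of the canonical pancreatic-cancer subnetwork, with the
#: direction of their response to drug treatment.
CANONICAL_MIRNA_DIRECTIONS = {
    "miR-34a-5p": "up",
    "miR-195-5p": "up",
    "miR-30c-5p": "up",
    "miR-130b-3p": "up",
    "miR-155-5p": "down",
}

# (miRNA, gene, direction, verified, provenance note). 16 edges carry
# western-blot verification; miR-155-5p->P16 and miR-34a-5p->ERK1 were
# reported but not confirmed; miR-34a-5p->IKKA completes the 19-edge set
# from the knockdown-reversal evidence (the one edge whose textual
# enumeration is ambiguous - a recorded design decision).
_CANONICAL_EDGE_ROWS = (
    ("miR-34a-5p", "CDK4", "up", True, "stated singly; western-confirmed"),
    ("miR-34a-5p", "CDK6", "up", True, "co-regulated with miR-195-5p; western-confirmed"),
    ("miR-34a-5p", "VEGF", "up", True, "co-regulated with miR-195-5p; western-confirmed"),
    ("miR-34a-5p", "E2F3", "up", True, "co-regulated with miR-195-5p and miR-30c-5p; western-confirmed"),
    ("miR-34a-5p", "MEK1", "up", True, "co-regulated with miR-30c-5p; western-confirmed"),
    ("miR-34a-5p", "E2F1", "up", True, "co-regulated with miR-130b-3p; western-confirmed"),
    ("miR-34a-5p", "ERK1", "up", False, "reported; not western-confirmed"),
    ("miR-34a-5p", "IKKA", "up", False, "knockdown-reversal evidence; ambiguous - design decision"),
    ("miR-195-5p", "CDC42", "up", True, "stated singly; western-confirmed"),
    ("miR-195-5p", "CDK4", "up", True, "co-regulated with miR-34a-5p; western-confirmed"),
    ("miR-195-5p", "CDK6", "up", True, "co-regulated with miR-34a-5p; western-confirmed"),
    ("miR-195-5p", "VEGF", "up", True, "co-regulated with miR-34a-5p; western-confirmed"),
    ("miR-195-5p", "E2F3", "up", True, "co-regulated with miR-34a-5p and miR-30c-5p; western-confirmed"),
    ("miR-195-5p", "IKKA", "up", True, "western-confirmed target panel"),
    ("miR-30c-5p", "RAC1", "up", True, "stated singly; western-confirmed"),
    ("miR-30c-5p", "MEK1", "up", True, "co-regulated with miR-34a-5p; western-confirmed"),
    ("miR-30c-5p", "E2F3", "up", True, "co-regulated with miR-34a-5p and miR-195-5p; western-confirmed"),
    ("miR-130b-3p", "E2F1", "up", True, "co-regulated with miR-34a-5p; western-confirmed"),
    ("miR-155-5p", "P16", "down", False, "stated singly; not western-confirmed"),
)

CANONICAL_GENES = tuple(sorted({g for _, g, _, _, _ in _CANONICAL_EDGE_ROWS}))


@dataclass(frozen=True)
class CanonicalEdge:
    mirna: str
    gene: str
    direction: str
    verified: bool
    note: str


@dataclass(frozen=True)
class CanonicalEdgeList:
    """The packaged reference subnetwork: 19 miRNA-mRNA interactions over
    5 miRNAs and 11 genes of the pancreatic-cancer pathway."""

    edges: tuple[CanonicalEdge, ...]

    @property
    def mirnas(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.mirna)
        return tuple(seen)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted({e.gene for e in self.edges}))

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(e.mirna, e.gene) for e in self.edges}

    def verified_only(self) -> "CanonicalEdgeList":
        return CanonicalEdgeList(tuple(e for e in self.edges if e.verified))

    def to_pairs_frame(self) -> pd.DataFrame:
        """Edge table in the unified-interaction layout (for loading the
        canonical list as a small bipartite network)."""
        return pd.DataFrame(
            {
                "mirna_id": [e.mirna for e in self.edges],
                "gene_symbol": [e.gene for e in self.edges],
                "sources": ["canonical"] * len(self.edges),
            }
        )

    def to_differential_frame(self) -> pd.DataFrame:
        """Direction annotations in the differential-set layout."""
        rows = [(m, CANONICAL_MIRNA_DIRECTIONS[m], np.nan, np.nan) for m in self.mirnas]
        return pd.DataFrame(rows, columns=["mirna_id", "direction", "fc_line1", "fc_line2"]).sort_values(
            "mirna_id", ignore_index=True
        )


def canonical_pancreatic_edge_list() -> CanonicalEdgeList:
    """Return the packaged pancreatic-cancer reference edge list.

    19 interactions, 5 miRNAs (4 up-regulated under treatment, miR-155-5p
    down-regulated), 11 target genes; the ``verified`` flag marks the 16
    western-blot-confirmed edges.
    """
    return CanonicalEdgeList(tuple(CanonicalEdge(*row) for row in _CANONICAL_EDGE_ROWS))


@dataclass
class PlantedTruth:
    """Ground truth of a synthetic fixture, for recovery tests.

    labels maps each miRNA to up/down/discordant/null; ratios holds the true
    treated/control ratio per cell line. The interaction-database and
    gene-set generators fill in which differential miRNAs they covered and
    which pathway was planted as exactly one miRNA's target set.
    """

    labels: dict[str, str]
    ratios: dict[str, tuple[float, float]]
    replicated_mirnas: tuple[str, ...] = ()
    subfloor_mirnas: tuple[str, ...] = ()
    covered_mirnas: tuple[str, ...] = ()
    decoy_mirnas: tuple[str, ...] = ()
    db_targets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_enrichment: dict[str, str] = field(default_factory=dict)

    def differential(self) -> tuple[str, ...]:
        return tuple(m for m, lab in self.labels.items() if lab in ("up", "down"))

    def expected_directions(self) -> dict[str, str]:
        return {m: lab for m, lab in self.labels.items() if lab in ("up", "down")}


def _truncated_lognoise(rng: np.random.Generator, sigma: float, k: float, size) -> np.ndarray:
    """Multiplicative noise exp(eps), eps ~ N(0, sigma^2) clipped to ±k*sigma."""
    eps = np.clip(rng.normal(0.0, sigma, size=size), -k * sigma, k * sigma)
    return np.exp(eps)


def generate_expression_fixture(config: FixtureConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate the raw four-sample expression matrix and its planted truth.

    The matrix has one column per sample (two cell lines x treated/control)
    and one row per probe; ``config.n_replicated_probes`` miRNAs appear as
    two probe rows to exercise replicate averaging, and
    ``config.n_subfloor`` null probes sit below the intensity eligibility
    floor in at least one sample. Per-sample array scale factors are applied
    multiplicatively (median normalization must remove them).
    """
    rng = np.random.default_rng(config.seed)

    canon_up = [m for m, d in CANONICAL_MIRNA_DIRECTIONS.items() if d == "up"]
    canon_down = [m for m, d in CANONICAL_MIRNA_DIRECTIONS.items() if d == "down"]

    n_named = 0

    def synth(n: int) -> list[str]:
        nonlocal n_named
        out = [f"miR-sim-{i:04d}" for i in range(n_named, n_named + n)]
        n_named += n
        return out

    up_names = canon_up[: config.n_up] + synth(max(0, config.n_up - len(canon_up)))
    down_names = canon_down[: config.n_down] + synth(max(0, config.n_down - len(canon_down)))
    disc_names = synth(config.n_discordant)
    n_null = config.n_probes - config.n_up - config.n_down - config.n_discordant
    null_names = synth(n_null)

    labels: dict[str, str] = {}
    ratios: dict[str, tuple[float, float]] = {}
    u, d = config.up_ratio, config.down_ratio
    for m in up_names:
        labels[m], ratios[m] = "up", (u, u)
    for m in down_names:
        labels[m], ratios[m] = "down", (d, d)
    for i, m in enumerate(disc_names):
        labels[m] = "discordant"
        ratios[m] = (u, d) if i % 2 == 0 else (d, u)
    for m in null_names:
        labels[m], ratios[m] = "null", (1.0, 1.0)

    all_names = up_names + down_names + disc_names + null_names

    # baseline abundances: right-skewed log-normal, floor-censored at 1
    base = np.exp(rng.normal(math.log(config.baseline_log_median), config.baseline_log_sigma, len(all_names)))
    base = np.maximum(base, 1.0)
    base_by_name = dict(zip(all_names, base))

    # sub-floor probes are null-labelled and guaranteed below the floor in
    # the lowest-scaled sample
    subfloor = tuple(rng.choice(null_names, size=config.n_subfloor, replace=False)) if config.n_subfloor else ()
    min_scale = min(config.array_scale_factors[s] for s in SAMPLES) if SAMPLES else 1.0
    noise_cap = math.exp(config.noise_truncation_sigmas * config.noise_log_sigma)
    sub_hi = min(25.0, 0.9 * ELIGIBILITY_FLOOR / (min_scale * noise_cap))
    for m in subfloor:
        base_by_name[m] = rng.uniform(2.0, max(2.5, sub_hi))

    replicated = (
        tuple(rng.choice(all_names, size=config.n_replicated_probes, replace=False))
        if config.n_replicated_probes and all_names
        else ()
    )

    probe_names = all_names + list(replicated)
    order = rng.permutation(len(probe_names))
    probe_names = [probe_names[i] for i in order]

    values = np.empty((len(probe_names), len(SAMPLES)))
    for j, s in enumerate(SAMPLES):
        line, cond = s.split("__")
        li = CELL_LINES.index(line)
        scale = config.array_scale_factors[s]
        noise = _truncated_lognoise(rng, config.noise_log_sigma, config.noise_truncation_sigmas, len(probe_names))
        for i, m in enumerate(probe_names):
            r = ratios[m][li] if cond == "treated" else 1.0
            values[i, j] = base_by_name[m] * r * scale * noise[i]

    matrix = pd.DataFrame(values, index=pd.Index(probe_names, name="mirna_id"), columns=list(SAMPLES))
    truth = PlantedTruth(
        labels=labels, ratios=ratios, replicated_mirnas=replicated, subfloor_mirnas=subfloor
    )
    logger.info(
        "expression fixture: %d probes (%d miRNAs), planted %d up / %d down / %d discordant",
        len(probe_names), len(all_names), config.n_up, config.n_down, config.n_discordant,
    )
    return matrix, truth


# -- interaction database ---------------------------------------------------

# minimum degrees the canonical miRNAs need so the 19 canonical edges fit
_CANONICAL_MIN_DEGREE = {
    m: sum(1 for e in _CANONICAL_EDGE_ROWS if e[0] == m) for m in CANONICAL_MIRNA_DIRECTIONS
}


def _heavy_tailed_degrees(
    rng: np.random.Generator, n: int, total: int, max_degree: int, minima: np.ndarray
) -> np.ndarray:
    """Heavy-tailed positive integer degrees with an exact sum.

    Draws Pareto-shaped weights, scales to the target, clips to
    [minima, max_degree], then walks from the final miRNA backwards
    adjusting counts until the sum is exact.
    """
    if total < int(minima.sum()) or total > n * max_degree:
        raise ConfigurationError(
            f"cannot place {total} unique pairs on {n} miRNAs over {max_degree} genes"
        )
    w = 1.0 + rng.pareto(1.2, n)
    deg = np.maximum(minima, np.floor(w / w.sum() * total).astype(int))
    deg = np.minimum(deg, max_degree)
    # final-miRNA adjustment, spilling over backwards when clipped
    diff = total - int(deg.sum())
    i = n - 1
    while diff != 0:
        room = (max_degree - deg[i]) if diff > 0 else (deg[i] - minima[i])
        step = min(abs(diff), room) * (1 if diff > 0 else -1)
        deg[i] += step
        diff -= step
        i -= 1
        if i < 0 and diff != 0:  # pragma: no cover - guarded by the bound check
            raise ConfigurationError("degree adjustment failed")
    return deg


_MIRNA_JITTERS = (
    lambda s: s,
    lambda s: s.upper(),
    lambda s: f" {s}",
    lambda s: s.lower(),
    lambda s: f"{s} ",
)
_GENE_JITTERS = (lambda s: s, lambda s: s.lower(), lambda s: f"{s} ", lambda s: s.capitalize())


def generate_interaction_db(
    config: FixtureConfig, truth: PlantedTruth
) -> dict[str, pd.DataFrame]:
    """Generate four redundant validated-interaction source tables.

    After name canonicalization, de-duplication across the four sources and
    restriction to the planted differential miRNAs, the union contains
    exactly ``db_n_pairs`` unique (miRNA, gene) pairs covering exactly
    ``db_n_mirnas_covered`` differential miRNAs and ``db_n_genes`` distinct
    genes. Decoy records for non-differential miRNAs are included (network
    restriction must remove them), names vary in case and whitespace across
    sources, and at least 20% of pairs appear in two or more sources.
    """
    rng = np.random.default_rng([config.seed, 1])
    differential = list(truth.differential())
    n_cov, n_pairs, n_genes = config.db_n_mirnas_covered, config.db_n_pairs, config.db_n_genes

    if n_cov > len(differential):
        raise ConfigurationError("db_n_mirnas_covered exceeds planted differential miRNAs")
    if n_pairs == 0 or n_cov == 0:
        return {db: pd.DataFrame(columns=["mirna_id", "gene_symbol", "source_db"]) for db in SOURCE_DATABASES}

    canon = [m for m in CANONICAL_MIRNA_DIRECTIONS if m in differential]
    plant_canonical = (
        len(canon) == len(CANONICAL_MIRNA_DIRECTIONS)
        and n_cov >= len(canon)
        and n_genes >= len(CANONICAL_GENES)
        and n_pairs - n_genes >= len(_CANONICAL_EDGE_ROWS) - len(CANONICAL_GENES)
        and n_pairs >= len(_CANONICAL_EDGE_ROWS)
    )
    head = canon if plant_canonical else []
    rest = [m for m in differential if m not in head]
    extra = (
        [str(x) for x in rng.choice(rest, size=n_cov - len(head), replace=False)]
        if n_cov > len(head)
        else []
    )
    covered = head + extra

    if plant_canonical:
        genes = list(CANONICAL_GENES) + [f"GENE{i:05d}" for i in range(n_genes - len(CANONICAL_GENES))]
    else:
        genes = [f"GENE{i:05d}" for i in range(n_genes)]

    minima = np.array([_CANONICAL_MIN_DEGREE.get(m, 1) if plant_canonical else 1 for m in covered])
    # cap the heaviest miRNA at a few times the mean degree (validated
    # targetomes of a few hundred genes, not the whole gene universe)
    cap = min(n_genes, max(int(minima.max()), -(-4 * n_pairs // len(covered)), 16))
    degrees = _heavy_tailed_degrees(rng, len(covered), n_pairs, cap, minima)

    # seed the assignment with the canonical edges, then deal the remaining
    # gene slots: every gene once (mandatory) plus reuse picks
    assigned: dict[str, list[str]] = {m: [] for m in covered}
    used: dict[str, set[str]] = {m: set() for m in covered}
    mandatory = set(genes)
    n_planted = 0
    if plant_canonical:
        for m, g, _, _, _ in _CANONICAL_EDGE_ROWS:
            assigned[m].append(g)
            used[m].add(g)
            mandatory.discard(g)
            n_planted += 1
    n_extras = n_pairs - n_genes - (n_planted - (len(CANONICAL_GENES) if plant_canonical else 0))
    pool = sorted(mandatory) + list(rng.choice(genes, size=n_extras, replace=True))
    pool = [pool[i] for i in rng.permutation(len(pool))]

    deg_by_mirna = {m: int(degrees[i]) for i, m in enumerate(covered)}
    # deal high-degree miRNAs first, while the pool is still gene-rich
    for m in sorted(covered, key=lambda mm: -deg_by_mirna[mm]):
        need = deg_by_mirna[m] - len(assigned[m])
        j = 0
        while need > 0:
            if j >= len(pool):
                # every remaining pool gene is already a target of m: swap a
                # pool gene with another miRNA's assigned gene
                g = pool[0]
                swapped = False
                for m2 in covered:
                    if m2 == m or g in used[m2]:
                        continue
                    for i2, g2 in enumerate(assigned[m2]):
                        if g2 in used[m]:
                            continue
                        assigned[m2][i2] = g
                        used[m2].discard(g2)
                        used[m2].add(g)
                        assigned[m].append(g2)
                        used[m].add(g2)
                        swapped = True
                        break
                    if swapped:
                        break
                if not swapped:
                    raise ConfigurationError("db constraints unsatisfiable: gene pool exhausted")
                pool[0] = pool[-1]
                pool.pop()
                need -= 1
                j = 0
                continue
            g = pool[j]
            if g not in used[m]:
                assigned[m].append(g)
                used[m].add(g)
                pool[j] = pool[-1]
                pool.pop()
                need -= 1
            else:
                j += 1
    if pool:
        # leftover slots conflicted with their miRNA; swap with an
        # already-assigned slot elsewhere (rare at realistic sizes)
        for g in pool:
            placed = False
            for m2 in covered:
                if g in used[m2]:
                    continue
                for i2, g2 in enumerate(assigned[m2]):
                    # only displace g2 if it stays covered via another miRNA
                    if sum(1 for mm in covered if g2 in used[mm]) < 2:
                        continue
                    assigned[m2][i2] = g
                    used[m2].discard(g2)
                    used[m2].add(g)
                    placed = True
                    break
                if placed:
                    break
            if not placed:
                raise ConfigurationError("db constraints unsatisfiable: could not place all genes")

    truth.covered_mirnas = tuple(covered)
    truth.db_targets = {m: tuple(sorted(used[m])) for m in covered}

    pairs: list[tuple[str, str]] = [(m, g) for m in covered for g in assigned[m]]

    # decoy pairs for non-differential miRNAs, to be removed by restriction
    decoy_candidates = [m for m, lab in truth.labels.items() if lab in ("discordant", "null")]
    n_decoy = min(20, len(decoy_candidates))
    decoys = (
        [str(x) for x in rng.choice(decoy_candidates, size=n_decoy, replace=False)] if n_decoy else []
    )
    truth.decoy_mirnas = tuple(decoys)
    decoy_pairs: list[tuple[str, str]] = []
    hi = min(16, len(genes) + 1)
    for m in decoys:
        k = int(rng.integers(min(3, hi - 1), hi)) if hi > 1 else 1
        for g in rng.choice(genes, size=k, replace=False):
            decoy_pairs.append((m, str(g)))

    # emit each unique pair into 1-4 sources with name jitter; the first
    # quarter (in shuffled order) is forced into >=2 sources
    all_pairs = pairs + decoy_pairs
    order = rng.permutation(len(all_pairs))
    forced_multi = math.ceil(0.25 * len(pairs))
    rows: dict[str, list[tuple[str, str, str]]] = {db: [] for db in SOURCE_DATABASES}
    for rank, idx in enumerate(order):
        m, g = all_pairs[idx]
        if rank < forced_multi:
            k = int(rng.choice([2, 3, 4], p=[0.6, 0.25, 0.15]))
        else:
            k = int(rng.choice([1, 2, 3, 4], p=[0.55, 0.25, 0.12, 0.08]))
        for si in rng.choice(len(SOURCE_DATABASES), size=k, replace=False):
            db = SOURCE_DATABASES[si]
            jm = _MIRNA_JITTERS[rng.integers(len(_MIRNA_JITTERS))](m)
            jg = _GENE_JITTERS[rng.integers(len(_GENE_JITTERS))](g)
            rows[db].append((jm, jg, db))

    out = {}
    for db in SOURCE_DATABASES:
        df = pd.DataFrame(rows[db], columns=["mirna_id", "gene_symbol", "source_db"])
        out[db] = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    logger.info(
        "interaction fixture: %d unique differential pairs over %d miRNAs and %d genes (+%d decoy pairs)",
        len(pairs), len(covered), n_genes, len(decoy_pairs),
    )
    return out


def generate_genesets(config: FixtureConfig, truth: PlantedTruth) -> GeneSetCollection:
    """Generate the pathway collection (GMT-shaped gene sets).

    The first set is named "pancreatic cancer" and contains the 11 canonical
    genes plus fillers; up to three sets are planted as exactly one covered
    miRNA's target set (so enrichment must recover those miRNA-pathway
    pairs; recorded in ``truth.planted_enrichment``); the remainder are
    random draws from the database gene universe.
    """
    if not truth.db_targets:
        raise ConfigurationError("generate the interaction database before the gene sets")
    rng = np.random.default_rng([config.seed, 2])
    db_genes = sorted({g for gs in truth.db_targets.values() for g in gs})

    sets: dict[str, frozenset[str]] = {}
    if config.n_pathways >= 1:
        fillers_n = min(max(0, 70 - len(CANONICAL_GENES)), max(0, len(db_genes) - len(CANONICAL_GENES)))
        fill_pool = [g for g in db_genes if g not in CANONICAL_GENES]
        fillers = list(rng.choice(fill_pool, size=fillers_n, replace=False)) if fillers_n else []
        sets["pancreatic cancer"] = frozenset(CANONICAL_GENES) | frozenset(map(str, fillers))

    planted: dict[str, str] = {}
    eligible = [m for m in truth.covered_mirnas if 10 <= len(truth.db_targets[m]) <= 400]
    for m in eligible[:3]:
        if len(sets) >= config.n_pathways:
            break
        name = f"planted targets of {m}"
        sets[name] = frozenset(truth.db_targets[m])
        planted[name] = m
    truth.planted_enrichment = planted

    i = 0
    while len(sets) < config.n_pathways:
        size = int(rng.integers(20, 201))
        size = min(size, len(db_genes)) or len(CANONICAL_GENES)
        members = rng.choice(db_genes, size=size, replace=False) if db_genes else list(CANONICAL_GENES)
        sets[f"synthetic pathway {i:02d}"] = frozenset(map(str, members))
        i += 1

    universe = frozenset(db_genes) | frozenset(g for gs in sets.values() for g in gs)
    return GeneSetCollection(sets=sets, universe=universe)


__all__ = [
    "CANONICAL_GENES",
    "CANONICAL_MIRNA_DIRECTIONS",
    "CanonicalEdge",
    "CanonicalEdgeList",
    "PlantedTruth",
    "SOURCE_DATABASES",
    "canonical_pancreatic_edge_list",
    "generate_expression_fixture",
    "generate_genesets",
    "generate_interaction_db",
]
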
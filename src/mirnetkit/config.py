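"""Configuration objects for the synthetic-fixture generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


class ConfigurationError(ValueError):
    """Raised when a fixture or pipeline configuration is internally inconsistent."""


#: Sample layout: two pancreatic-cancer cell lines, drug-treated vs vehicle.
CELL_LINES = ("PANC-1", "BxPC-3")
CONDITIONS = ("treated", "control")
SAMPLES = tuple(f"{line}__{cond}" for line in CELL_LINES for cond in CONDITIONS)

#: Intensity floor below which a probe is ineligible for normalization factors.
ELIGIBILITY_FLOOR = 30.0


def sample_name(line: str, condition: str) -> str:
    return f"{line}__{condition}"


def parse_sample(name: str) -> tuple[str, str]:
    """Split a ``<cellline>__<condition>`` column name."""
    line, _, cond = name.rpartition("__")
    if not line or cond not in CONDITIONS:
        raise ValueError(f"sample name {name!r} is not of the form <cellline>__<condition>")
    return line, cond


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the planted-truth synthetic inputs.

    Defaults reproduce the study conditions the analysis is calibrated to:
    70 concordantly up- and 109 concordantly down-regulated miRNAs across
    both cell lines, a validated-target database that covers 62 of those
    179 differential miRNAs with 5,092 unique pairs over 4,362 genes, and
    a pathway collection containing a "pancreatic cancer" set.
    """

    n_probes: int = 2000
    n_up: int = 70
    n_down: int = 109
    n_discordant: int = 40
    n_replicated_probes: int = 50
    n_subfloor: int = 100
    up_ratio: float = 2.0
    down_ratio: float = 0.4
    array_scale_factors: Mapping[str, float] = field(
        default_factory=lambda: {
            "PANC-1__treated": 1.00,
            "PANC-1__control": 1.25,
            "BxPC-3__treated": 0.85,
            "BxPC-3__control": 1.10,
        }
    )
    db_n_mirnas_covered: int = 62
    db_n_pairs: int = 5092
    db_n_genes: int = 4362
    n_pathways: int = 70
    seed: int = 42

    # intensity model: log-normal baseline, bounded multiplicative noise
    baseline_log_median: float = 500.0
    baseline_log_sigma: float = 1.0
    noise_log_sigma: float = 0.05
    noise_truncation_sigmas: float = 2.0

    def __post_init__(self) -> None:
        counts = {
            "n_probes": self.n_probes,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_discordant": self.n_discordant,
            "n_replicated_probes": self.n_replicated_probes,
            "n_subfloor": self.n_subfloor,
            "db_n_mirnas_covered": self.db_n_mirnas_covered,
            "db_n_pairs": self.db_n_pairs,
            "db_n_genes": self.db_n_genes,
            "n_pathways": self.n_pathways,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if self.n_up + self.n_down + self.n_discordant > self.n_probes:
            raise ConfigurationError(
                "n_up + n_down + n_discordant exceeds n_probes "
                f"({self.n_up}+{self.n_down}+{self.n_discordant} > {self.n_probes})"
            )
        if self.n_replicated_probes > self.n_probes:
            raise ConfigurationError("n_replicated_probes exceeds n_probes")
        if self.n_subfloor > self.n_probes - self.n_up - self.n_down - self.n_discordant:
            raise ConfigurationError(
                "n_subfloor exceeds the number of null probes; sub-floor probes are null-labelled"
            )
        if self.db_n_pairs < self.db_n_genes:
            raise ConfigurationError(
                f"db_n_pairs ({self.db_n_pairs}) must be >= db_n_genes ({self.db_n_genes})"
            )
        if self.db_n_mirnas_covered > self.n_up + self.n_down:
            raise ConfigurationError(
                "db_n_mirnas_covered exceeds the number of planted differential miRNAs"
            )
        if self.db_n_pairs > 0 and self.db_n_mirnas_covered == 0:
            raise ConfigurationError("db_n_pairs > 0 requires db_n_mirnas_covered >= 1")
        if self.db_n_pairs < self.db_n_mirnas_covered:
            raise ConfigurationError("db_n_pairs must be >= db_n_mirnas_covered (each covered miRNA needs an edge)")
        if not (self.up_ratio > 1.0 and 0.0 < self.down_ratio < 1.0):
            raise ConfigurationError("up_ratio must be > 1 and down_ratio in (0, 1)")
        missing = [s for s in SAMPLES if s not in self.array_scale_factors]
        if missing:
            raise ConfigurationError(f"array_scale_factors missing samples: {missing}")
        if any(v <= 0 for v in self.array_scale_factors.values()):
            raise ConfigurationError("array_scale_factors must be positive")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["array_scale_factors"] = dict(self.array_scale_factors)
        return d


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    tau is the fold-change threshold of the differential screen (inclusive,
    applied symmetrically: up if f >= tau, down if f <= 1/tau); floor is the
    intensity eligibility floor of median normalization; alpha the raw
    enrichment significance level; tail selects the hypergeometric tail
    ("exclusive" = P(X > x), "inclusive" = P(X >= x)); degree_side the node
    set whose degree distribution is fitted.
    """

    tau: float = 1.5
    floor: float = ELIGIBILITY_FLOOR
    alpha: float = 0.05
    tail: str = "exclusive"
    degree_side: str = "both"
    seed: int = 42
    fixture: FixtureConfig | None = None
    out_dir: str = "mirnetkit_out"
    expression_path: str | None = None
    interaction_paths: tuple[str, ...] | None = None
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if not self.tau > 1.0:
            raise ConfigurationError(f"tau must be > 1, got {self.tau}")
        if self.floor < 0:
            raise ConfigurationError(f"floor must be >= 0, got {self.floor}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.tail not in ("exclusive", "inclusive"):
            raise ConfigurationError(f"tail must be 'exclusive' or 'inclusive', got {self.tail!r}")
        if self.degree_side not in ("mirna", "gene", "both"):
            raise ConfigurationError(f"degree_side must be mirna/gene/both, got {self.degree_side!r}")
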
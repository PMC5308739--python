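"""Microarray intensity processing and the dual-cell-line differential screen.

The screen follows the classic two-colour-array recipe: replicate probes of
the same miRNA are averaged, per-sample median normalization is computed on
the probes that clear an intensity eligibility floor (default 30 units) in
every sample, treated/control fold changes are taken per cell line, and a
miRNA is called differential only when it changes at least tau-fold
(default 1.5, inclusive) in the same direction in both cell lines. There is
no log transformation and no moderated test statistic: the screen is a pure
fold-change concordance filter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import ELIGIBILITY_FLOOR, sample_name

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"
UNDEFINED = "undefined"


class NoEligibleProbesError(ValueError):
    """No probe clears the intensity floor in every sample."""


def average_replicates(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated miRNA identifiers to their per-sample arithmetic mean.

    Rows keep first-appearance order; sample (column) order is preserved.
    An empty matrix passes through unchanged.
    """
    if raw.empty:
        return raw.copy()
    return raw.groupby(level=0, sort=False).mean()


def normalization_factors(m: pd.DataFrame, floor: float = ELIGIBILITY_FLOOR) -> pd.Series:
    """Per-sample median of the floor-eligible probes.

    A probe is eligible only if its intensity is >= ``floor`` in *all*
    samples; the factor for sample s is the median intensity of the
    eligible set in s.
    """
    eligible = (m >= floor).all(axis=1)
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise NoEligibleProbesError(
            f"no probes with intensity >= {floor} in all samples; cannot normalize"
        )
    logger.info("normalization: %d/%d probes eligible (floor=%g)", n_eligible, len(m), floor)
    return m.loc[eligible].median(axis=0)


def median_normalize(m: pd.DataFrame, floor: float = ELIGIBILITY_FLOOR) -> pd.DataFrame:
    """Rescale each sample so eligible-set medians are equal across samples.

    Each sample is divided by its factor and multiplied by the reference
    scale (the mean of all factors); afterwards every sample's eligible-set
    median equals the reference scale. The reference choice is inert for
    fold changes, which are within-miRNA ratios of samples.
    """
    factors = normalization_factors(m, floor=floor)
    reference = factors.mean()
    return m.div(factors, axis=1) * reference


def fold_changes(
    m: pd.DataFrame, line: str, tau: float = 1.5
) -> pd.DataFrame:
    """Treated/control fold change and direction call for one cell line.

    direction is ``up`` when f >= tau, ``down`` when f <= 1/tau (both
    inclusive), ``none`` otherwise, and ``undefined`` when the control
    intensity is zero (such records are excluded from screening).
    """
    treated = m[sample_name(line, "treated")]
    control = m[sample_name(line, "control")]
    with np.errstate(divide="ignore", invalid="ignore"):
        f = treated / control
    f = f.where(control > 0, np.nan)
    n_undef = int((control <= 0).sum())
    if n_undef:
        logger.warning("%s: %d miRNAs with zero control intensity excluded from screening", line, n_undef)
    direction = pd.Series(NONE, index=m.index, dtype=object)
    direction[f >= tau] = UP
    direction[f <= 1.0 / tau] = DOWN
    direction[f.isna()] = UNDEFINED
    return pd.DataFrame(
        {
            "mirna_id": m.index,
            "cell_line": line,
            "fold_change": f.to_numpy(),
            "direction": direction.to_numpy(),
        }
    ).reset_index(drop=True)


def concordant_differential(fc_line1: pd.DataFrame, fc_line2: pd.DataFrame) -> pd.DataFrame:
    """miRNAs whose direction agrees (up/up or down/down) across both lines.

    miRNAs present in only one list are treated as direction ``none`` and
    excluded. The result is sorted by miRNA id and duplicate-free, with
    columns mirna_id, direction, fc_line1, fc_line2.
    """
    a = fc_line1.set_index("mirna_id")
    b = fc_line2.set_index("mirna_id")
    only = a.index.symmetric_difference(b.index)
    if len(only):
        logger.warning("%d miRNAs present in one cell line only; excluded", len(only))
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    keep = ((a["direction"] == b["direction"]) & a["direction"].isin([UP, DOWN])).to_numpy()
    out = pd.DataFrame(
        {
            "mirna_id": common[keep],
            "direction": a.loc[keep, "direction"].to_numpy(),
            "fc_line1": a.loc[keep, "fold_change"].to_numpy(),
            "fc_line2": b.loc[keep, "fold_change"].to_numpy(),
        }
    )
    out = out.sort_values("mirna_id", ignore_index=True)
    logger.info(
        "concordance screen: %d differential miRNAs (%d up, %d down)",
        len(out), int((out["direction"] == UP).sum()), int((out["direction"] == DOWN).sum()),
    )
    return out


def screen(
    raw: pd.DataFrame,
    lines: tuple[str, str],
    tau: float = 1.5,
    floor: float = ELIGIBILITY_FLOOR,
) -> pd.DataFrame:
    """Full screen: average replicates, normalize, call concordant miRNAs."""
    averaged = average_replicates(raw)
    normalized = median_normalize(averaged, floor=floor)
    fc1 = fold_changes(normalized, lines[0], tau=tau)
    fc2 = fold_changes(normalized, lines[1], tau=tau)
    return concordant_differential(fc1, fc2)
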
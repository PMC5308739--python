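"""Closed-form quantification formulas used downstream of the network work:
xenograft tumor volume from caliper diameters, and qPCR relative expression
by the comparative 2^-ddCt method."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd


def tumor_volume(d_large: float, d_small: float) -> float:
    """Ellipsoid-approximation tumor volume V = (pi/6) * d1 * d2^2 (mm^3).

    d_large is the larger caliper diameter (mm), d_small the smaller; if
    given in the wrong order they are swapped with a warning. Homogeneous
    of degree 3 in the diameters.
    """
    if d_large < 0 or d_small < 0:
        raise ValueError(f"diameters must be >= 0, got ({d_large}, {d_small})")
    if d_small > d_large:
        warnings.warn("diameters swapped: d_small > d_large", stacklevel=2)
        d_large, d_small = d_small, d_large
    return (math.pi / 6.0) * d_large * d_small**2


@dataclass(frozen=True)
class CtQuadruple:
    """qPCR cycle thresholds of target and reference gene, treated and control.

    Single-replicate Ct values; average replicates upstream if needed.
    """

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


def ddct_fold_change(ct: CtQuadruple) -> float:
    """Relative expression 2^-ddCt.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt_treated -
    dCt_control. Swapping treated and control gives the reciprocal.
    """
    dct_treated = ct.ct_target_treated - ct.ct_reference_treated
    dct_control = ct.ct_target_control - ct.ct_reference_control
    return 2.0 ** -(dct_treated - dct_control)


def tumor_volume_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``volume_mm3`` column to a table with ``d_large``/``d_small``."""
    out = table.copy()
    out["volume_mm3"] = [
        tumor_volume(dl, ds) for dl, ds in zip(out["d_large"], out["d_small"])
    ]
    return out


def ddct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``fold_change`` column to a table of Ct quadruples.

    Expects columns ct_target_treated, ct_reference_treated,
    ct_target_control, ct_reference_control.
    """
    cols = [
        "ct_target_treated",
        "ct_reference_treated",
        "ct_target_control",
        "ct_reference_control",
    ]
    out = table.copy()
    out["fold_change"] = [
        ddct_fold_change(CtQuadruple(*row)) for row in out[cols].itertuples(index=False)
    ]
    return out
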
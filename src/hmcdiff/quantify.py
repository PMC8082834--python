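"""Global 5hmC quantification from UHPLC-MS/MS nucleoside tables.

Mass spectrometry reports molar signals for 5-hydroxymethyl-2'-deoxycytidine
(5hmdC) and 2'-deoxycytidine (dC) per sample.  The global 5hmC level is the
fraction of cytosines carrying the mark, each sample's *relative level* is
its fold versus the mean of the normal (reference) group, and the group mean
of those folds is the calibration factor used to put depth-normalized
pulldown counts back on an absolute-abundance scale.  (The study's factors
are 0.4367 for human tumors and 0.3148 for the mouse model.)

5mdC is not modeled separately: the dC signal stands for all
non-hydroxymethylated cytosine, a negligible approximation at the sub-percent
5hmC abundances seen in tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MassSpecRecord",
    "hmc_fraction",
    "relative_levels",
    "group_calibration_factor",
    "read_masspec",
    "quantify_table",
]


@dataclass(frozen=True)
class MassSpecRecord:
    sample: str
    group: str
    amount_5hmdC: float
    amount_dC: float

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.amount_5hmdC) and math.isfinite(self.amount_dC)):
            raise ValueError(f"{self.sample}: non-finite amounts")
        if self.amount_5hmdC < 0:
            raise ValueError(f"{self.sample}: negative 5hmdC amount")
        if self.amount_dC <= 0:
            raise ValueError(f"{self.sample}: dC amount must be > 0")


def hmc_fraction(record: MassSpecRecord) -> float:
    """Fraction of cytosines hydroxymethylated: 5hmdC / (5hmdC + dC).

    Scale-invariant: multiplying both amounts by k > 0 leaves it unchanged.
    """
    return record.amount_5hmdC / (record.amount_5hmdC + record.amount_dC)


def relative_levels(
    fractions: dict[str, float], groups: dict[str, str], reference_group: str
) -> dict[str, float]:
    """Per-sample fold versus the mean fraction of the reference group."""
    ref = [fractions[s] for s, g in groups.items() if g == reference_group]
    if not ref:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_mean = sum(ref) / len(ref)
    if ref_mean <= 0:
        raise ValueError("reference group mean fraction must be positive")
    return {s: fractions[s] / ref_mean for s in fractions}


def group_calibration_factor(folds: dict[str, float], groups: dict[str, str], group: str) -> float:
    """Arithmetic mean of a group's relative levels (the calibration factor)."""
    vals = [folds[s] for s, g in groups.items() if g == group and s in folds]
    if not vals:
        raise ValueError(f"group {group!r} is empty")
    c = sum(vals) / len(vals)
    logger.info("calibration factor for %s: %.4f (n=%d)", group, c, len(vals))
    return c


def read_masspec(path) -> list[MassSpecRecord]:
    """Read a mass-spec TSV with columns sample, group, amount_5hmdC, amount_dC."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "amount_5hmdC", "amount_dC"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mass-spec table missing columns: {sorted(missing)}")
    return [
        MassSpecRecord(str(r.sample), str(r.group), float(r.amount_5hmdC), float(r.amount_dC))
        for r in df.itertuples()
    ]


def quantify_table(records: list[MassSpecRecord], reference_group: str = "normal") -> pd.DataFrame:
    """Fractions, folds and per-group calibration factors for a whole table.

    Returns a DataFrame indexed by sample with columns group, fraction, fold,
    calibration_factor (the mean fold of the sample's group; exactly 1 for
    the reference group by construction up to rounding).
    """
    groups = {r.sample: r.group for r in records}
    fractions = {r.sample: hmc_fraction(r) for r in records}
    folds = relative_levels(fractions, groups, reference_group)
    factors = {
        g: group_calibration_factor(folds, groups, g) for g in sorted(set(groups.values()))
    }
    return pd.DataFrame(
        {
            "group": [groups[s] for s in fractions],
            "fraction": list(fractions.values()),
            "fold": [folds[s] for s in fractions],
            "calibration_factor": [factors[groups[s]] for s in fractions],
        },
        index=pd.Index(list(fractions), name="sample"),
    )
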
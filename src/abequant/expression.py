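"""Relative expression statistics for RT-qPCR data (2^-ddCt).

Fold change of a target gene relative to a reference gene, normalised to a
calibrator sample, by the delta-delta-Ct method; replicate Ct values are
aggregated by arithmetic mean.  The beta/alpha globin ratio is the ratio of
two such relative quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class CtRecord:
    """Replicate Ct values for one (sample, gene)."""

    sample: str
    gene: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise ValueError("at least one Ct replicate is required")
        for ct in self.ct_values:
            if not (math.isfinite(ct) and ct > 0):
                raise ValueError(f"Ct values must be positive and finite, got {ct}")

    @property
    def mean_ct(self) -> float:
        return sum(self.ct_values) / len(self.ct_values)


def delta_delta_ct(
    target: CtRecord,
    reference: CtRecord,
    target_cal: CtRecord,
    reference_cal: CtRecord,
) -> float:
    """Fold change 2^-((Ct_t - Ct_ref) - (Ct_t,cal - Ct_ref,cal))."""
    d_sample = target.mean_ct - reference.mean_ct
    d_cal = target_cal.mean_ct - reference_cal.mean_ct
    return 2.0 ** (-(d_sample - d_cal))


def beta_alpha_ratio(beta_rel: float, alpha_rel: float) -> float:
    """beta-globin over alpha-globin relative expression."""
    if alpha_rel <= 0:
        raise ValueError(f"alpha relative expression must be positive, got {alpha_rel}")
    return beta_rel / alpha_rel


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a TSV with columns sample, gene, ct1..ctk (k >= 1)."""
    df = pd.read_csv(path, sep="\t")
    ct_cols = [c for c in df.columns if c.lower().startswith("ct")]
    if not ct_cols:
        raise ValueError("no Ct columns (ct1..ctk) found")
    records = []
    for _, row in df.iterrows():
        cts = tuple(float(row[c]) for c in ct_cols if pd.notna(row[c]))
        records.append(CtRecord(str(row["sample"]), str(row["gene"]), cts))
    return records
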
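"""Replicate-aware ultrasensitive CHDM calling.

The assay sequences every sample in two independent PCR/sequencing
replicates. A variant is called present only when both replicates support it
with at least ``min_alt_reads`` mutant reads AND the mean replicate VAF
clears the detection floor (default 0.01%). The reported VAF is the
unweighted arithmetic mean of the two replicate VAFs, in percent.

This dual-replicate AND rule is a documented stand-in for the original
consensus QC pipeline, whose internals are not modelled here; both
thresholds are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["CloneObservation", "call_observation", "call_table", "annotate_chip",
           "CHIP_THRESHOLD_PCT"]

#: VAF threshold (percent) conventionally defining CHIP-scale clones.
CHIP_THRESHOLD_PCT = 2.0


@dataclass(frozen=True)
class CloneObservation:
    """One mutation x one timepoint, with its replicate read support."""

    individual_id: str | None
    gene: str | None
    hgvs_p: str | None
    timepoint_years: float | None
    age_years: float | None
    rep_counts: tuple[tuple[int, int], tuple[int, int]]
    detected: bool
    vaf_pct: float | None

    @property
    def is_chip(self) -> bool | None:
        if self.vaf_pct is None:
            return None
        return annotate_chip(self.vaf_pct)


def _validate_counts(rep_counts) -> tuple[tuple[int, int], tuple[int, int]]:
    if len(rep_counts) != 2:
        raise InputError(f"expected 2 replicates, got {len(rep_counts)}")
    out = []
    for alt, total in rep_counts:
        alt, total = int(alt), int(total)
        if alt < 0 or total < 0:
            raise InputError(f"negative read count: ({alt}, {total})")
        if total == 0:
            raise InputError("replicate with zero total reads")
        if alt > total:
            raise InputError(f"alt reads exceed total reads: ({alt}, {total})")
        out.append((alt, total))
    return tuple(out)


def call_observation(
    rep_counts,
    min_alt_reads: int = 3,
    vaf_floor_pct: float = 0.01,
    **identity,
) -> CloneObservation:
    """Call one observation from its two (alt, total) replicate read pairs.

    Detected iff both replicates carry >= ``min_alt_reads`` mutant reads and
    the mean replicate VAF is >= ``vaf_floor_pct``. ``identity`` keywords
    (individual_id, gene, hgvs_p, timepoint_years, age_years) are carried
    through unchanged.
    """
    (a1, t1), (a2, t2) = _validate_counts(rep_counts)
    vaf = 100.0 * (a1 / t1 + a2 / t2) / 2.0
    detected = a1 >= min_alt_reads and a2 >= min_alt_reads and vaf >= vaf_floor_pct
    return CloneObservation(
        individual_id=identity.get("individual_id"),
        gene=identity.get("gene"),
        hgvs_p=identity.get("hgvs_p"),
        timepoint_years=identity.get("timepoint_years"),
        age_years=identity.get("age_years"),
        rep_counts=((a1, t1), (a2, t2)),
        detected=bool(detected),
        vaf_pct=vaf if detected else None,
    )


def call_table(
    observations: pd.DataFrame,
    min_alt_reads: int = 3,
    vaf_floor_pct: float = 0.01,
) -> pd.DataFrame:
    """Vectorised calling over an observations table.

    Expects the generator's schema (alt_reads_rep1/total_reads_rep1,
    alt_reads_rep2/total_reads_rep2); returns a copy with ``detected``
    (bool) and ``vaf_pct`` (NaN where undetected) appended.
    """
    df = observations.copy()
    a1 = df["alt_reads_rep1"].to_numpy(dtype=np.int64)
    t1 = df["total_reads_rep1"].to_numpy(dtype=np.int64)
    a2 = df["alt_reads_rep2"].to_numpy(dtype=np.int64)
    t2 = df["total_reads_rep2"].to_numpy(dtype=np.int64)
    if (a1 < 0).any() or (a2 < 0).any():
        raise InputError("negative alt read counts in table")
    if (t1 <= 0).any() or (t2 <= 0).any():
        raise InputError("non-positive total read counts in table")
    if (a1 > t1).any() or (a2 > t2).any():
        raise InputError("alt reads exceed total reads in table")
    vaf = 100.0 * (a1 / t1 + a2 / t2) / 2.0
    detected = (a1 >= min_alt_reads) & (a2 >= min_alt_reads) & (vaf >= vaf_floor_pct)
    df["detected"] = detected
    df["vaf_pct"] = np.where(detected, vaf, np.nan)
    return df


def annotate_chip(vaf_pct: float, threshold_pct: float = CHIP_THRESHOLD_PCT) -> bool:
    """True iff the clone is at CHIP scale (VAF >= 2% by default)."""
    if vaf_pct < 0:
        raise InputError(f"negative VAF: {vaf_pct}")
    return bool(vaf_pct >= threshold_pct)
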
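"""Low-quality variant removal.

Four criteria, applied per record before any database filtering:

(i)   consensus quality score < 20;
(ii)  regional copy-number estimate at the allele site >= 2
      (a repeat/paralog proxy supplied by the upstream caller);
(iii) distance to the nearest adjacent SNP < 5 bp — both members of a
      too-close pair fail;
(iv)  sequencing depth < 4 or > 500.

Boundaries are exactly as written: quality 20, depth 4, depth 500 and
distance 5 are retained; copy number 2.0 is removed (the >= is part of
the criterion).  A record missing a QC metric (NaN quality or copy
number, negative depth) is retained and flagged rather than removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import VariantTable

CRITERIA = ("low_quality", "high_copy_number", "adjacent_snp", "depth")


@dataclass(frozen=True)
class QCThresholds:
    min_consensus_quality: float = 20.0
    max_copy_number: float = 2.0       # removed when estimate >= this
    min_adjacent_snp_dist: int = 5     # removed when distance < this
    min_depth: int = 4
    max_depth: int = 500

    def __post_init__(self):
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")
        for name in ("min_consensus_quality", "max_copy_number",
                     "min_adjacent_snp_dist", "min_depth", "max_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    """Per-criterion counts; a record failing several increments each
    matched counter but is removed (and counted removed) once."""

    input_count: int
    removed: int
    retained: int
    per_criterion: dict[str, int]
    flagged_missing_metrics: int

    def as_dict(self) -> dict:
        return {
            "input": self.input_count, "removed": self.removed,
            "retained": self.retained,
            "criteria": dict(self.per_criterion),
            "flagged_missing_metrics": self.flagged_missing_metrics,
        }


def qc_fail_mask(table: VariantTable,
                 thresholds: QCThresholds = QCThresholds()
                 ) -> dict[str, np.ndarray]:
    """Boolean fail mask per criterion (NaN metrics never fail)."""
    r = table.records
    qual = r["consensus_quality"].to_numpy(dtype=float)
    cn = r["copy_number_estimate"].to_numpy(dtype=float)
    dist = r["dist_to_nearest_snp"].to_numpy(dtype=np.int64)
    depth = r["depth"].to_numpy(dtype=np.int64)
    return {
        "low_quality": ~np.isnan(qual) & (qual < thresholds.min_consensus_quality),
        "high_copy_number": ~np.isnan(cn) & (cn >= thresholds.max_copy_number),
        "adjacent_snp": dist < thresholds.min_adjacent_snp_dist,
        "depth": (depth >= 0) & ((depth < thresholds.min_depth)
                                 | (depth > thresholds.max_depth)),
    }


def apply_qc(table: VariantTable,
             thresholds: QCThresholds = QCThresholds()
             ) -> tuple[VariantTable, QCReport]:
    """Remove records failing any criterion; idempotent by construction."""
    masks = qc_fail_mask(table, thresholds)
    any_fail = np.zeros(len(table), dtype=bool)
    per = {}
    for name in CRITERIA:
        per[name] = int(masks[name].sum())
        any_fail |= masks[name]
    r = table.records
    flagged = int((r["consensus_quality"].isna()
                   | r["copy_number_estimate"].isna()
                   | (r["depth"] < 0)).sum())
    report = QCReport(
        input_count=len(table), removed=int(any_fail.sum()),
        retained=int((~any_fail).sum()), per_criterion=per,
        flagged_missing_metrics=flagged,
    )
    return table.subset(~any_fail), report
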
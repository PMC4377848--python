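"""Marker and sample exclusion rules.

Filters mirror standard array-QC practice: sample call rate >= 0.80, locus
call rate >= 0.95 (on the retained samples), per-sample mean genotyping
quality >= 0.65, and MAF >= 0.01.  All boundaries are strict "below":
a value exactly at the threshold is kept.  The composed order is
sample call rate -> locus call rate -> sample quality -> MAF, so locus
statistics reflect retained samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import GenotypeDataset

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, threshold: float, before: GenotypeDataset,
            after: GenotypeDataset) -> None:
        self.steps.append({
            "filter": name, "threshold": threshold,
            "samples_before": before.n_samples, "samples_after": after.n_samples,
            "loci_before": before.n_variants, "loci_after": after.n_variants,
        })
        if (after.n_samples > before.n_samples
                or after.n_variants > before.n_variants):
            raise ValueError("QC filter increased counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_call_rate(genos: GenotypeDataset, min_sample_rate: float = 0.80,
                     min_locus_rate: float = 0.95,
                     report: QCReport | None = None
                     ) -> tuple[GenotypeDataset, QCReport]:
    """Remove low-call-rate samples first, then low-call-rate loci."""
    if not (0 < min_sample_rate <= 1 and 0 < min_locus_rate <= 1):
        raise ValueError("call-rate thresholds must be in (0,1]")
    report = report or QCReport()
    keep_s = np.flatnonzero(genos.sample_call_rate() >= min_sample_rate)
    if len(keep_s) == 0:
        raise ValueError("sample call-rate filter removed every sample")
    step1 = genos.subset(sample_idx=keep_s) if len(keep_s) < genos.n_samples else genos
    report.add("sample_call_rate", min_sample_rate, genos, step1)
    keep_l = np.flatnonzero(step1.locus_call_rate() >= min_locus_rate)
    step2 = step1.subset(variant_idx=keep_l) if len(keep_l) < step1.n_variants else step1
    report.add("locus_call_rate", min_locus_rate, step1, step2)
    return step2, report


def filter_sample_quality(genos: GenotypeDataset, scores: dict | None,
                          min_score: float = 0.65,
                          report: QCReport | None = None
                          ) -> tuple[GenotypeDataset, QCReport]:
    """Remove samples whose mean genotyping quality score is below threshold.

    ``scores`` maps sample ID -> score in [0,1].  ``None`` (e.g. synthetic
    data without a quality channel) skips the filter with a logged notice.
    """
    report = report or QCReport()
    if scores is None:
        log.info("sample-quality scores absent; filter skipped")
        report.add("sample_quality(skipped)", min_score, genos, genos)
        return genos, report
    missing = [s for s in genos.samples if s not in scores]
    if missing:
        raise ValueError(f"quality score missing for sample(s) {missing[:5]}")
    keep = np.flatnonzero(np.array([scores[s] for s in genos.samples]) >= min_score)
    out = genos.subset(sample_idx=keep) if len(keep) < genos.n_samples else genos
    report.add("sample_quality", min_score, genos, out)
    return out, report


def filter_maf(genos: GenotypeDataset, min_maf: float = 0.01,
               report: QCReport | None = None
               ) -> tuple[GenotypeDataset, QCReport]:
    """Remove loci with minor allele frequency strictly below ``min_maf``."""
    report = report or QCReport()
    keep = np.flatnonzero(genos.maf() >= min_maf)
    if len(keep) == 0:
        log.warning("MAF filter removed every locus")
    out = genos.subset(variant_idx=keep) if len(keep) < genos.n_variants else genos
    report.add("maf", min_maf, genos, out)
    return out, report


def apply_qc(genos: GenotypeDataset, min_sample_rate: float = 0.80,
             min_locus_rate: float = 0.95, min_score: float = 0.65,
             min_maf: float = 0.01, scores: dict | None = None
             ) -> tuple[GenotypeDataset, QCReport]:
    """Full filter chain in the documented order."""
    out, report = filter_call_rate(genos, min_sample_rate, min_locus_rate)
    out, report = filter_sample_quality(out, scores, min_score, report)
    out, report = filter_maf(out, min_maf, report)
    return out, report
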
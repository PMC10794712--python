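"""Binary SNP annotations from open-chromatin peak sets.

A cell type's chromatin-accessibility annotation marks every panel SNP whose
(1-based) position falls inside at least one of that cell type's peaks.
Peaks are 0-based half-open BED intervals and are merged before membership
testing, so duplicated or adjacent sub-peaks never change the result. The
background annotation is the union of open chromatin across all cell types
in a dataset; conditioning on it in the heritability model is what makes the
focal coefficient cell-type specific.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import Annotation, Intervals, SnpPanel

logger = logging.getLogger("h2scan")

__all__ = ["PeakSet", "peaks_to_annotation", "union_background", "annotation_correlation"]


@dataclass
class PeakSet:
    """Named peak intervals for one cell type."""

    celltype: str
    intervals: Intervals


def peaks_to_annotation(peaks: PeakSet, panel: SnpPanel) -> Annotation:
    """Binary annotation: 1 iff the SNP lies in >= 1 peak of this cell type."""
    if panel.M == 0:
        raise ValueError("empty panel")
    if len(peaks.intervals) == 0:
        warnings.warn(f"peak set {peaks.celltype!r} is empty; all-zero annotation")
        values = np.zeros(panel.M)
    else:
        values = peaks.intervals.contains(
            panel.snps["chrom"].to_numpy(), panel.snps["pos"].to_numpy()
        ).astype(float)
    return Annotation(name=peaks.celltype, values=values, kind="binary", role="celltype")


def union_background(peak_sets: list[PeakSet], panel: SnpPanel) -> Annotation:
    """Union of open chromatin across cell types (element-wise OR)."""
    if not peak_sets:
        raise ValueError("need at least one peak set")
    values = np.zeros(panel.M)
    for ps in peak_sets:
        values = np.maximum(values, peaks_to_annotation(ps, panel).values)
    return Annotation(name="background", values=values, kind="binary", role="background")


def annotation_correlation(a: Annotation, b: Annotation) -> float:
    """Pearson correlation of two annotations over panel SNPs.

    A constant annotation has no defined correlation; it is reported as 0
    with a warning rather than NaN.
    """
    if len(a.values) != len(b.values):
        raise ValueError("annotations have different lengths")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        warnings.warn("constant annotation in correlation; returning 0")
        return 0.0
    return float(np.corrcoef(a.values, b.values)[0, 1])
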
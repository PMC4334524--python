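"""Classification of regulatory-region dynamics across tumor progression.

Regions are compared across three stages (wild type -> early tumor ->
late tumor) using two pairwise differential tables.  A region is

* ``stable``  — opens early (log2FC WT->early > 1) and then holds
  (-0.2 < log2FC early->late < 0.2);
* ``gradual`` — opens early (log2FC WT->early > 0) and keeps opening
  (log2FC early->late > 0.5);
* ``global_open`` — significant (padj < 0.01) with log2FC > 1 in an
  all-wild-type vs all-tumor comparison, without qualifying as stable or
  gradual.

All thresholds are strict inequalities; boundary values fall to ``none``.
The two pairwise p-values of each region are combined with Fisher's
omnibus statistic for downstream selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffacc import DifferentialRecord
from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "DynamicsThresholds",
    "DynamicsRecord",
    "fisher_omnibus",
    "classify_regions",
    "cluster_differential",
    "rank_by_signed_p",
]


@dataclass(frozen=True)
class DynamicsThresholds:
    stable_lfc_early: float = 1.0      # log2FC WT->early must exceed this
    stable_band: float = 0.2           # |log2FC early->late| must stay inside
    gradual_lfc_early: float = 0.0
    gradual_lfc_late: float = 0.5
    global_padj: float = 0.01
    global_lfc: float = 1.0
    omnibus_p_max: float | None = None  # optional extra gate on the gradual class


@dataclass
class DynamicsRecord:
    region: str
    lfc_wt_rse: float
    lfc_rse_rsl: float
    p_wt_rse: float
    p_rse_rsl: float
    omnibus_stat: float
    omnibus_p: float
    cls: str  # global_open / stable / gradual / none


def fisher_omnibus(pvalues) -> tuple[float, float]:
    """Fisher's combined probability: X = -2 sum(ln p) ~ chi2(2k).

    All p-values must lie in (0, 1]; floor zeros upstream (e.g. at the
    smallest representable p) before combining.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_omnibus needs at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor zeros before combining")
    x = float(-2.0 * np.log(p).sum())
    return x, float(stats.chi2.sf(x, df=2 * p.size))


def classify_regions(
    diff_we: list[DifferentialRecord],
    diff_el: list[DifferentialRecord],
    thresholds: DynamicsThresholds = DynamicsThresholds(),
    diff_global: list[DifferentialRecord] | None = None,
) -> list[DynamicsRecord]:
    """Assign each region a dynamics class from the two pairwise tables.

    ``diff_we`` is wild type -> early tumor, ``diff_el`` early -> late.
    Regions missing from either table are excluded (a warning reports how
    many).  ``diff_global`` (all wild type vs all tumor) enables the
    ``global_open`` class for regions that are neither stable nor gradual.
    """
    we = {r.region: r for r in diff_we}
    el = {r.region: r for r in diff_el}
    glob = {r.region: r for r in diff_global} if diff_global else {}
    common = [rid for rid in we if rid in el]
    missing = len(set(we) ^ set(el))
    if missing:
        warnings.warn(f"{missing} regions missing from one differential table; excluded")

    t = thresholds
    out = []
    tiny = np.finfo(float).tiny
    for rid in common:
        a, b = we[rid], el[rid]
        stat, omni_p = fisher_omnibus([max(a.p, tiny), max(b.p, tiny)])
        cls = "none"
        if a.log2fc > t.stable_lfc_early and -t.stable_band < b.log2fc < t.stable_band:
            cls = "stable"
        elif a.log2fc > t.gradual_lfc_early and b.log2fc > t.gradual_lfc_late:
            if t.omnibus_p_max is None or omni_p < t.omnibus_p_max:
                cls = "gradual"
        if cls == "none" and rid in glob:
            g = glob[rid]
            if g.padj < t.global_padj and g.log2fc > t.global_lfc:
                cls = "global_open"
        out.append(
            DynamicsRecord(rid, a.log2fc, b.log2fc, a.p, b.p, stat, omni_p, cls)
        )
    return out


def cluster_differential(peaks: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge differential peaks (possibly from several assays) into unique
    candidate regulatory regions (single-linkage, >= 1 bp overlap)."""
    merged = merge_intervals(peaks)
    return [iv.with_name(f"rr_{i:05d}") for i, iv in enumerate(merged)]


def rank_by_signed_p(records: list[DifferentialRecord], top_n: int) -> list[DifferentialRecord]:
    """Order records by the signed p-value score sign(log2fc) * -log10(p).

    Descending (strongest openers first); ties broken by |log2fc|
    descending, then region id.  Zero p-values are floored at the smallest
    positive float.  Asking for more records than exist returns all of
    them with a warning.
    """
    tiny = np.finfo(float).tiny
    def key(r: DifferentialRecord):
        score = np.sign(r.log2fc) * -np.log10(max(r.p, tiny))
        return (-score, -abs(r.log2fc), r.region)
    ranked = sorted(records, key=key)
    if top_n > len(ranked):
        warnings.warn(f"top_n={top_n} exceeds {len(ranked)} records; returning all")
        return ranked
    return ranked[:top_n]


def records_to_frame(records: list[DynamicsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [r.region for r in records],
            "lfc_wt_rse": [r.lfc_wt_rse for r in records],
            "lfc_rse_rsl": [r.lfc_rse_rsl for r in records],
            "p_wt_rse": [r.p_wt_rse for r in records],
            "p_rse_rsl": [r.p_rse_rsl for r in records],
            "omnibus_stat": [r.omnibus_stat for r in records],
            "omnibus_p": [r.omnibus_p for r in records],
            "class": [r.cls for r in records],
        }
    ).set_index("region")
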
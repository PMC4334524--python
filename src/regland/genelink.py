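"""Peak-to-gene linkage, ranked gene lists, and preranked GSEA.

Differential peaks are assigned to genes when they fall in any intron or
within 5 kb upstream of the TSS (or, alternatively, to their nearest
TSS); per gene the most significant peak is retained and genes are
ranked by its fold change (openers on top, closers at the bottom).  Gene
sets from expression data are then tested for concentration at either
end of that ranking with a weighted Kolmogorov-Smirnov running-sum
statistic whose null is gene-label permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffacc import DifferentialRecord
from .intervals import GenomicInterval, overlap_fraction_filter  # re-export surface

__all__ = [
    "GeneModel",
    "load_gene_models",
    "PeakLink",
    "assign_peaks",
    "ranked_list",
    "GSEAResult",
    "gsea",
    "overlap_fraction_filter",
    "enhancer_recovery",
    "annotate_locations",
    "collapse_probes",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS, exons, and derived introns
    (0-based half-open coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        exons = sorted(self.exons)
        out = []
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def upstream_window(self, length: int) -> tuple[int, int]:
        """The ``length`` bp immediately upstream of the TSS, half-open,
        exclusive of the gene body."""
        if self.strand == "+":
            return max(0, self.start - length), self.start
        return self.end, self.end + length


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Parse gene + exon features from GFF3 (1-based inclusive on disk,
    converted to 0-based half-open) via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            (e.start - 1, e.end) for e in db.children(g, featuretype="exon")
        )
        genes.append(GeneModel(g.id, g.seqid, g.start - 1, g.end, g.strand, exons))
    return genes


@dataclass
class PeakLink:
    gene_id: str
    record: DifferentialRecord
    interval: GenomicInterval


def _overlaps(iv: GenomicInterval, chrom: str, start: int, end: int) -> bool:
    return iv.chrom == chrom and iv.start < end and start < iv.end


def assign_peaks(
    peaks: list[tuple[DifferentialRecord, GenomicInterval]],
    genes: list[GeneModel],
    mode: str = "upstream5kb_intronic",
    upstream: int = 5000,
) -> list[PeakLink]:
    """Link peaks to genes and retain one peak per gene.

    ``upstream5kb_intronic``: a peak links to every gene whose 5 kb
    upstream window or any intron it overlaps.  ``nearest_tss``: every
    peak links to the gene with the closest TSS (distance from the peak
    midpoint).  Per gene the retained peak has the smallest padj, ties
    broken by larger |log2fc|, then leftmost coordinate.
    """
    if mode not in ("upstream5kb_intronic", "nearest_tss"):
        raise ValueError(f"unknown mode {mode!r}")
    links: list[PeakLink] = []
    if mode == "upstream5kb_intronic":
        for rec, iv in peaks:
            for g in genes:
                if iv.chrom != g.chrom:
                    continue
                us, ue = g.upstream_window(upstream)
                hit = _overlaps(iv, g.chrom, us, ue) or any(
                    _overlaps(iv, g.chrom, s, e) for s, e in g.introns
                )
                if hit:
                    links.append(PeakLink(g.gene_id, rec, iv))
    else:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for rec, iv in peaks:
            cands = by_chrom.get(iv.chrom)
            if not cands:
                continue
            mid = iv.midpoint
            g = min(cands, key=lambda g: (abs(g.tss - mid), g.gene_id))
            links.append(PeakLink(g.gene_id, rec, iv))

    best: dict[str, PeakLink] = {}
    for link in links:
        cur = best.get(link.gene_id)
        if cur is None or _link_key(link) < _link_key(cur):
            best[link.gene_id] = link
    return sorted(best.values(), key=lambda l: l.gene_id)


def _link_key(link: PeakLink):
    r = link.record
    return (r.padj, -abs(r.log2fc), link.interval.chrom, link.interval.start)


def ranked_list(links: list[PeakLink], metric: str = "log2fc") -> pd.Series:
    """Genes ordered by their retained peak's metric, descending (openers
    first); ties broken lexicographically by gene id.  Returns a Series
    gene id -> score."""
    if metric not in ("log2fc", "signed_logp"):
        raise ValueError(f"unknown metric {metric!r}")
    tiny = np.finfo(float).tiny
    rows = []
    for link in links:
        r = link.record
        if metric == "log2fc":
            score = r.log2fc
        else:
            score = float(np.sign(r.log2fc) * -np.log10(max(r.p, tiny)))
        rows.append((link.gene_id, score))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return pd.Series(dict(rows)).loc[[g for g, _ in rows]]


@dataclass
class GSEAResult:
    gene_set: str
    es: float
    nes: float
    p: float
    leading_edge: list[str] = field(default_factory=list)


def _running_extremum(hit_mask: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Signed extremum of the weighted KS running sum and its position."""
    n = hit_mask.size
    nh = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    total = hit_w.sum()
    miss = 1.0 / (n - nh)
    running = np.cumsum(hit_w / total - np.where(hit_mask, 0.0, miss))
    imax = int(np.argmax(running))
    imin = int(np.argmin(running))
    if running[imax] >= -running[imin]:
        return float(running[imax]), imax
    return float(running[imin]), imin


def gsea(
    ranked: pd.Series,
    gene_set,
    weight: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
    set_name: str = "gene_set",
) -> GSEAResult:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` maps gene ids to scores in descending order.  The running
    sum gains ``|score|^weight`` (normalized over set members) at each
    member and loses ``1/(N - Nh)`` at each non-member; the enrichment
    score is its signed extremum.  The null distribution re-draws the
    member labels uniformly; ``nes = es / mean(|null es| of the same
    sign)`` and the p-value is the same-sign exceedance fraction with
    add-one correction.
    """
    genes = np.asarray(ranked.index)
    scores = np.asarray(ranked.to_numpy(), dtype=float)
    members = set(gene_set)
    hit = np.isin(genes, list(members))
    nh = int(hit.sum())
    n = genes.size
    if nh == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    if nh == n:
        raise ValueError("gene set covers the entire ranked list")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    weights = np.abs(scores) ** weight
    es, pos = _running_extremum(hit, weights)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=nh, replace=False)] = True
        null[b], _ = _running_extremum(perm, weights)

    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same).mean() if same.size else np.abs(null).mean()
    nes = es / denom if denom > 0 else 0.0
    exceed = int((np.abs(same) >= abs(es)).sum())
    p = (1 + exceed) / (1 + same.size)

    if es >= 0:
        leading = [g for g, h in zip(genes[: pos + 1], hit[: pos + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[pos:], hit[pos:]) if h]
    return GSEAResult(set_name, float(es), float(nes), float(p), leading)


def enhancer_recovery(
    ranked_regions: list[GenomicInterval],
    enhancer_sets: dict[str, list[GenomicInterval]],
) -> dict[str, np.ndarray]:
    """Cumulative enhancer recovery along a ranked region list.

    ``curve[name][i]`` counts the enhancers of the set overlapped (>= 1 bp)
    by at least one of the first ``i + 1`` regions; each enhancer is
    counted once, at the rank of the first region that reaches it.  Empty
    sets are skipped with a warning.
    """
    from intervaltree import IntervalTree

    curves: dict[str, np.ndarray] = {}
    for name, enhancers in enhancer_sets.items():
        if not enhancers:
            warnings.warn(f"enhancer set {name!r} is empty; skipped")
            continue
        trees: dict[str, IntervalTree] = {}
        for j, enh in enumerate(enhancers):
            trees.setdefault(enh.chrom, IntervalTree()).addi(enh.start, enh.end, j)
        seen: set[int] = set()
        curve = np.zeros(len(ranked_regions), dtype=int)
        for i, reg in enumerate(ranked_regions):
            tree = trees.get(reg.chrom)
            if tree is not None:
                for hit in tree.overlap(reg.start, reg.end):
                    seen.add(hit.data)
            curve[i] = len(seen)
        curves[name] = curve
    return curves


def annotate_locations(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_bp: int = 1000,
) -> pd.Series:
    """Assign each peak one genomic category with precedence
    promoter > exon > intron > distal_intergenic.

    The promoter is the ``promoter_bp`` window immediately upstream of the
    TSS (strand-aware).  Returns per-category counts; categories with no
    peaks report zero so the counts always sum to ``len(peaks)``.
    """
    counts = {"promoter": 0, "exon": 0, "intron": 0, "distal_intergenic": 0}
    for iv in peaks:
        cat = "distal_intergenic"
        for g in genes:
            if iv.chrom != g.chrom:
                continue
            ps, pe = g.upstream_window(promoter_bp)
            if _overlaps(iv, g.chrom, ps, pe):
                cat = "promoter"
                break
            if any(_overlaps(iv, g.chrom, s, e) for s, e in g.exons):
                cat = _higher(cat, "exon")
            elif any(_overlaps(iv, g.chrom, s, e) for s, e in g.introns):
                cat = _higher(cat, "intron")
        counts[cat] += 1
    return pd.Series(counts)


_PRECEDENCE = {"promoter": 0, "exon": 1, "intron": 2, "distal_intergenic": 3}


def _higher(a: str, b: str) -> str:
    return a if _PRECEDENCE[a] <= _PRECEDENCE[b] else b


def collapse_probes(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probe-level differential-expression table to genes,
    keeping per gene the probe with the most significant adjusted p-value.

    Expects columns ``gene``, ``logFC``, ``p``, ``padj``.
    """
    required = {"gene", "logFC", "p", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    idx = table.groupby("gene")["padj"].idxmin()
    return table.loc[idx].set_index("gene").sort_index()
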
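"""Transcription-factor footprinting from cut-site pileups.

Around motif-centered anchors, raw cut sites (not the 11 bp coverage
extension) are collected into a sites x relative-position matrix.  The
aggregate profile is corrected by subtracting the depth-matched profile
of the same motif found in random genomic regions, and protection is
summarized as the relative depletion of cuts over the motif span versus
its flanks: bound factors shield their site from the transposase, so a
footprint appears as a central dip in an otherwise accessible region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fragio import CutSiteTrack
from .intervals import GenomicInterval
from .motifrank import PWM, scan_best_hit

__all__ = [
    "FootprintMatrix",
    "cut_matrix",
    "background_subtract",
    "protection_score",
    "sample_background_anchors",
]


@dataclass
class FootprintMatrix:
    """Cut-site counts per anchor (rows) per relative position (columns).

    Columns run from -half_window to +half_window in anchor orientation
    (minus-strand anchors are flipped at construction).
    """

    matrix: np.ndarray
    site_names: list[str]
    half_window: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_window, self.half_window + 1)

    def aggregate(self) -> np.ndarray:
        return self.matrix.sum(axis=0)


def cut_matrix(
    sites: CutSiteTrack,
    anchors: list[GenomicInterval],
    half_window: int,
    chrom_lengths: dict[str, int] | None = None,
) -> FootprintMatrix:
    """Collect raw cut-site counts around motif-centered anchors.

    Anchor centres are interval midpoints; rows of minus-strand anchors
    are reversed so the motif orientation is consistent.  Anchors whose
    window would run past a known chromosome end are dropped with a
    warning.
    """
    w = int(half_window)
    rows, names = [], []
    dropped = 0
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for anchor in anchors:
        center = anchor.midpoint
        limit = chrom_lengths.get(anchor.chrom) if chrom_lengths else None
        if center - w < 0 or (limit is not None and center + w >= limit):
            dropped += 1
            continue
        if anchor.chrom not in cache:
            cache[anchor.chrom] = sites.base_positions(anchor.chrom)
        pos, cnt = cache[anchor.chrom]
        row = np.zeros(2 * w + 1)
        lo = np.searchsorted(pos, center - w, side="left")
        hi = np.searchsorted(pos, center + w, side="right")
        np.add.at(row, pos[lo:hi] - center + w, cnt[lo:hi])
        if anchor.strand == "-":
            row = row[::-1]
        rows.append(row)
        names.append(anchor.name)
    if dropped:
        warnings.warn(f"{dropped} anchors dropped at chromosome bounds")
    if not rows:
        raise ValueError("no usable anchors")
    mat = np.vstack(rows)
    # heatmap convention: busiest sites on top
    order = np.argsort(-mat.sum(axis=1), kind="stable")
    return FootprintMatrix(mat[order], [names[i] for i in order], w)


def background_subtract(signal: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Subtract a depth-matched background profile from the signal profile.

    The background is scaled to the signal's total count first, so the
    result is invariant to background sequencing depth.  Both profiles
    must share the window size.
    """
    signal = np.asarray(signal, dtype=float)
    background = np.asarray(background, dtype=float)
    if signal.shape != background.shape:
        raise ValueError("signal and background windows differ")
    btot = background.sum()
    if btot <= 0:
        raise ValueError("background profile has zero total count")
    return signal - background * (signal.sum() / btot)


def protection_score(profile: np.ndarray, motif_span: tuple[int, int],
                     flank: int = 50) -> float:
    """Relative cut-rate depletion over the motif span.

    ``motif_span`` gives inclusive offsets (lo, hi) relative to the window
    centre.  Flanks are the ``flank`` bp immediately outside the span on
    both sides.  Score = (mean flank - mean span) / mean flank: 1 means
    complete protection, 0 a flat profile, negative values central
    enrichment.
    """
    profile = np.asarray(profile, dtype=float)
    w = (profile.size - 1) // 2
    lo, hi = motif_span
    if not (-w <= lo <= hi <= w):
        raise ValueError("motif span outside the profile window")
    center = profile[lo + w:hi + w + 1]
    left = profile[max(0, lo + w - flank):lo + w]
    right = profile[hi + w + 1:hi + w + 1 + flank]
    flanks = np.concatenate([left, right])
    fl = flanks.mean() if flanks.size else 0.0
    if fl == 0:
        raise ValueError("zero flank mean; protection undefined")
    return float((fl - center.mean()) / fl)


def sample_background_anchors(
    sequences: dict[str, str],
    regions: list[GenomicInterval],
    pwm: PWM,
    n: int,
    width: int,
    exclude: list[GenomicInterval],
    threshold_bits: float = 7.0,
    seed: int = 0,
    max_oversample: int = 50,
) -> list[GenomicInterval]:
    """Motif-matched random background anchors.

    Draws windows of ``width`` bp uniformly from ``regions`` (a genome
    partition given as named intervals with sequences), excluding the
    signal anchor set, and keeps those containing a PWM hit at or above
    the scan threshold, re-centered on the best hit.  Rejection sampling
    stops after ``max_oversample * n`` draws.
    """
    rng = np.random.default_rng(seed)
    excl: dict[str, list[tuple[int, int]]] = {}
    for iv in exclude:
        excl.setdefault(iv.chrom, []).append((iv.start, iv.end))
    eligible = [r for r in regions if len(r) >= width]
    if not eligible:
        raise ValueError("no region is wide enough for the requested width")
    probs = np.array([len(r) for r in eligible], dtype=float)
    probs /= probs.sum()
    anchors: list[GenomicInterval] = []
    tries = 0
    half = width // 2
    while len(anchors) < n and tries < max_oversample * n:
        tries += 1
        reg = eligible[int(rng.choice(len(eligible), p=probs))]
        start = reg.start + int(rng.integers(0, len(reg) - width + 1))
        end = start + width
        seq = sequences[reg.name][start - reg.start:end - reg.start]
        hit = scan_best_hit(seq, pwm, threshold_bits)
        if hit is None:
            continue
        center = start + hit.offset + pwm.length // 2
        a_start, a_end = center - half, center + half + 1
        if a_start < 0 or any(s < a_end and a_start < e for s, e in excl.get(reg.chrom, ())):
            continue
        anchors.append(
            GenomicInterval(reg.chrom, a_start, a_end,
                            strand=hit.strand, name=f"bg_{len(anchors):05d}", score=hit.score)
        )
    if len(anchors) < n:
        warnings.warn(
            f"only {len(anchors)}/{n} motif-matched background anchors found "
            f"after {tries} draws"
        )
    return anchors
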
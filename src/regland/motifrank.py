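"""PWM scanning and recovery-curve motif enrichment (AUC / NES).

A motif's enrichment in an input region set is measured against a
genome-wide ranked database of candidate regulatory regions: regions are
ranked by their best log2-odds PWM hit, the recovery curve tracks the
fraction of the input set seen while descending that ranking, and the
area under the curve over the top ``rank_threshold`` positions (AUC) is
z-scored against the AUC distribution of the whole motif collection to
give the normalized enrichment score (NES).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "PWM",
    "MotifHit",
    "MotifRanking",
    "scan_best_hit",
    "recenter_on_motif",
    "rank_database",
    "recovery_auc",
    "recovery_curve",
    "nes_scores",
    "enrich",
    "map_to_database",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4,
         "a": 0, "c": 1, "g": 2, "t": 3, "n": 4}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class PWM:
    """Position weight matrix of base probabilities with log2-odds scoring.

    ``matrix`` has one row per motif position with probabilities over
    (A, C, G, T); a per-cell pseudocount keeps zero-count JASPAR columns
    finite in log-odds space.
    """

    id: str
    matrix: np.ndarray  # L x 4 probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.001

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("PWM matrix must be L x 4")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("PWM columns must be probability vectors")
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L x 5) log2-odds score matrix; the 5th column (N) scores 0."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        lo = np.log2(p / self.background[None, :])
        return np.column_stack([lo, np.zeros(self.length)])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def consensus_score(self) -> float:
        lo = self.log_odds
        return float(lo[np.arange(self.length), self.matrix.argmax(axis=1)].sum())

    def reverse_complement(self) -> "PWM":
        return PWM(self.id, self.matrix[::-1, ::-1], self.background[::-1], self.pseudocount)

    @classmethod
    def from_counts(cls, id: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(id, counts / counts.sum(axis=1, keepdims=True), **kw)

    @classmethod
    def sharp_example(cls, id: str = "sharp_example") -> "PWM":
        """A 12 bp near-deterministic PWM used as the default planted motif."""
        consensus = "TGACGTCATGCA"
        mat = np.full((len(consensus), 4), 0.02)
        for i, b in enumerate(consensus):
            mat[i, _CODE[b]] = 0.94
        return cls(id, mat)


def read_jaspar(path_or_handle) -> list[PWM]:
    """Read JASPAR-format PWMs (``>ID name`` header + 4 ``A [ .. ]`` rows)
    via Biopython's motif parser."""
    from Bio import motifs as bio_motifs

    if hasattr(path_or_handle, "read"):
        handle = path_or_handle
        close = False
    else:
        handle = open(path_or_handle)
        close = True
    try:
        parsed = bio_motifs.parse(handle, "jaspar")
        out = []
        for m in parsed:
            counts = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)])
            out.append(PWM.from_counts(m.matrix_id or m.name, counts))
        return out
    finally:
        if close:
            handle.close()


def read_clusterbuster(path_or_lines) -> list[PWM]:
    """Read Cluster-Buster-style matrices: ``>name`` then one whitespace
    row of 4 counts (A C G T) per motif position."""
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines, "__fspath__"):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    out: list[PWM] = []
    name, rows = None, []
    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"motif {name!r} has no matrix rows")
            out.append(PWM.from_counts(name, np.array(rows, dtype=float)))
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            name, rows = line[1:].split()[0], []
        else:
            vals = line.split()
            if len(vals) != 4:
                raise ValueError(f"expected 4 counts per row, got {len(vals)}: {line!r}")
            rows.append([float(v) for v in vals])
    flush()
    return out


@dataclass(frozen=True)
class MotifHit:
    region: str
    offset: int
    strand: str
    score: float  # log2-odds bits


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid DNA base {exc.args[0]!r}") from None


def _best_scan(codes: np.ndarray, lo: np.ndarray) -> tuple[float, int]:
    """Best score and smallest achieving offset for one strand."""
    L = lo.shape[0]
    n = codes.size - L + 1
    scores = np.zeros(n)
    for j in range(L):
        scores += lo[j, codes[j:j + n]]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    return float(scores[best]), best


def scan_best_hit(sequence: str, pwm: PWM, threshold_bits: float = 7.0,
                  region: str = ".") -> MotifHit | None:
    """Best log2-odds PWM hit over both strands, or None below threshold.

    ``N`` bases contribute 0 bits.  Ties are broken toward the smallest
    offset, preferring the plus strand.  Sequences shorter than the motif
    yield None.
    """
    if len(sequence) < pwm.length:
        return None
    codes = _encode(sequence)
    lo = pwm.log_odds
    fwd_score, fwd_off = _best_scan(codes, lo)
    rc_codes = _encode(sequence.translate(_COMPLEMENT)[::-1])
    rev_score, rev_off = _best_scan(rc_codes, lo)
    rev_off_fwd = len(sequence) - pwm.length - rev_off  # map back to forward coords

    if fwd_score >= rev_score:
        score, off, strand = fwd_score, fwd_off, "+"
        if rev_score == fwd_score and rev_off_fwd < fwd_off:
            off, strand = rev_off_fwd, "-"
    else:
        score, off, strand = rev_score, rev_off_fwd, "-"
    if score < threshold_bits:
        return None
    return MotifHit(region, off, strand, score)


def recenter_on_motif(
    regions: list[GenomicInterval],
    hits: list[MotifHit],
    window: int,
    motif_length: int,
    chrom_lengths: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Re-centre each region on the centre of its best motif hit.

    The output interval is ``[centre - window, centre + window + 1)``
    oriented by hit strand, where ``centre = start + offset +
    motif_length // 2``.  Regions without a hit are dropped; windows
    running past a chromosome end are clipped with a warning.
    """
    by_region = {h.region: h for h in hits}
    out = []
    clipped = 0
    for reg in regions:
        hit = by_region.get(reg.name)
        if hit is None:
            continue
        center = reg.start + hit.offset + motif_length // 2
        start = center - window
        end = center + window + 1
        limit = chrom_lengths.get(reg.chrom) if chrom_lengths else None
        if start < 0 or (limit is not None and end > limit):
            clipped += 1
            start = max(start, 0)
            if limit is not None:
                end = min(end, limit)
        out.append(GenomicInterval(reg.chrom, start, end, strand=hit.strand,
                                   name=reg.name, score=hit.score))
    if clipped:
        warnings.warn(f"{clipped} re-centered windows clipped at chromosome bounds")
    return out


def rank_database(sequences: dict[str, str], pwm: PWM) -> list[str]:
    """Rank database regions by best-hit score, descending (ties by id).

    Regions with no scorable window rank last.
    """
    scored = []
    for rid, seq in sequences.items():
        hit = scan_best_hit(seq, pwm, threshold_bits=-np.inf, region=rid)
        scored.append((-(hit.score if hit else -np.inf), rid))
    scored.sort()
    return [rid for _, rid in scored]


def recovery_curve(ranking: list[str], input_set, rank_threshold: int) -> np.ndarray:
    """recovery(i) = fraction of the input set at rank <= i, for i=1..T."""
    input_set = set(input_set)
    if not input_set:
        raise ValueError("input set is empty")
    extra = input_set - set(ranking)
    if extra:
        raise ValueError(f"{len(extra)} input regions absent from the ranked database")
    T = int(rank_threshold)
    if T > len(ranking):
        raise ValueError("rank_threshold exceeds database size")
    hits = np.fromiter((rid in input_set for rid in ranking[:T]), dtype=float, count=T)
    return np.cumsum(hits) / len(input_set)


def recovery_auc(ranking: list[str], input_set, rank_threshold: int) -> float:
    """Mean recovery over the top ``rank_threshold`` ranks, in [0, 1]."""
    return float(recovery_curve(ranking, input_set, rank_threshold).mean())


def nes_scores(aucs: dict[str, float]) -> dict[str, float]:
    """z-score each motif's AUC against the whole collection (population sd)."""
    if len(aucs) < 3:
        raise ValueError("need >= 3 motifs to normalize")
    vals = np.array(list(aucs.values()), dtype=float)
    sd = vals.std()  # population sd
    if sd <= 1e-12 * max(1.0, abs(vals.mean())):
        raise ValueError("zero variance across AUCs; NES undefined")
    mean = vals.mean()
    return {m: float((a - mean) / sd) for m, a in aucs.items()}


@dataclass
class MotifRanking:
    motif: str
    auc: float
    nes: float
    rank_threshold: int
    ranking: list[str]
    targets: list[str] = field(default_factory=list)


def map_to_database(
    input_regions: list[GenomicInterval],
    database: list[GenomicInterval],
    min_frac: float = 0.4,
) -> tuple[set[str], int]:
    """Map input intervals to database region ids by >= ``min_frac``
    reciprocal overlap; returns (mapped ids, unmappable count)."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for iv in database:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    mapped: set[str] = set()
    unmapped = 0
    for iv in input_regions:
        tree = trees.get(iv.chrom)
        found = False
        if tree is not None:
            for hit in tree.overlap(iv.start, iv.end):
                ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
                if ov >= min_frac * len(iv) and ov >= min_frac * (hit.end - hit.begin):
                    mapped.add(hit.data)
                    found = True
        if not found:
            unmapped += 1
    return mapped, unmapped


def enrich(
    input_ids,
    rankings: dict[str, list[str]],
    rank_threshold: int = 10_000,
    nes_cutoff: float = 2.5,
    tf_of: dict[str, str] | None = None,
) -> list[MotifRanking]:
    """Score every motif's ranking against the input set and report those
    clearing the NES cutoff, with leading-edge candidate targets.

    ``rankings`` maps motif id to its full database ranking (all rankings
    must be permutations of the same universe).  The leading-edge rank r*
    of a reported motif maximizes ``recovery(i) - mean_recovery(i)``,
    where the mean is over the whole collection at rank i; candidate
    targets are the input regions ranked at or above r*.  When ``tf_of``
    maps motifs to factors, only the best-NES motif per factor is
    reported.
    """
    input_ids = set(input_ids)
    T = min(rank_threshold, min(len(r) for r in rankings.values()))
    curves = {m: recovery_curve(r, input_ids, T) for m, r in rankings.items()}
    mean_curve = np.mean(list(curves.values()), axis=0)
    aucs = {m: float(c.mean()) for m, c in curves.items()}
    nes = nes_scores(aucs)

    results = []
    for m, ranking in rankings.items():
        res = MotifRanking(m, aucs[m], nes[m], T, ranking)
        if nes[m] > nes_cutoff:
            diff = curves[m] - mean_curve
            r_star = int(np.argmax(diff)) + 1  # 1-based leading-edge rank
            top = set(ranking[:r_star])
            res.targets = sorted(input_ids & top)
        results.append(res)

    if tf_of:
        best: dict[str, MotifRanking] = {}
        rest = []
        for res in results:
            tf = tf_of.get(res.motif)
            if tf is None:
                rest.append(res)
            elif tf not in best or res.nes > best[tf].nes:
                best[tf] = res
        results = rest + list(best.values())
    results.sort(key=lambda r: (-r.nes, r.motif))
    return results
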
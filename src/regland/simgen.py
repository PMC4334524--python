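"""Synthetic open-chromatin data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be validated against a planted truth without
any sequencing data:

* negative-binomial region counts with a condition effect (a fraction of
  regions opening or closing in the tumor condition), a multiplicative
  assay batch effect (ATAC vs FAIRE processed as replicates of the same
  biology), and >= 2-fold library-size variation across samples;
* strand-assigned cut sites placed uniformly within accessible regions,
  with the insertion rate over planted transcription-factor binding sites
  reduced by a configurable protection factor (a footprint);
* fragment lengths drawn from a mixture whose modes sit at sub-nucleosomal
  and mono/di/tri-nucleosomal sizes;
* region sequences with one motif instance, sampled from a PWM, planted at
  a recorded position in designated regions.

Every quantity the generator plants (labels, effect sizes, motif
positions, mixture parameters) is recorded in :class:`SimTruth` and used
as the oracle by the test-suite and the acceptance script.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, write_bed

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_counts",
    "simulate_regions",
    "simulate_fragments",
    "simulate_sequences",
    "simulate_genes",
    "simulate_all",
]

# stream tags so each operation draws from its own child generator: results
# do not depend on the order in which operations are invoked
_STREAM_COUNTS = 1
_STREAM_REGIONS = 2
_STREAM_FRAGMENTS = 3
_STREAM_SEQUENCES = 4
_STREAM_GENOME = 5

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the study conditions the pipeline is validated
    under: two conditions (wild type vs tumor) with three samples each,
    moderate biological overdispersion (NB dispersion 0.1), a two-fold
    batch (assay) offset, and a fragment-size mixture with modes near one,
    two and three nucleosome multiples plus a sub-nucleosomal mode.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 400_000
    n_regions: int = 2000
    region_width_mean: int = 500
    n_samples_per_group: int = 3
    dispersion: float = 0.1          # NB dispersion alpha (size^-1)
    lfc_open: float = 2.0            # planted log2 fold change of opening regions
    frac_open: float = 0.1
    frac_close: float = 0.1
    batch_lfc: float = 1.0           # log2 offset of the FAIRE assay batch
    footprint_protection: float = 0.5  # cut-rate reduction over planted motifs
    fragment_modes: tuple = ((80.0, 25.0, 0.45), (200.0, 40.0, 0.30),
                             (400.0, 55.0, 0.15), (600.0, 70.0, 0.10))
    n_fragments: int = 50_000
    base_mean_log: float = np.log(100.0)  # lognormal baseline of region counts
    base_mean_sigma: float = 1.0
    gc: float = 0.5                  # background GC content for sequences

    def __post_init__(self) -> None:
        if not (0 <= self.frac_open <= 1 and 0 <= self.frac_close <= 1):
            raise SimConfigError("frac_open and frac_close must be proportions")
        if self.frac_open + self.frac_close > 1:
            raise SimConfigError("frac_open + frac_close must be <= 1")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if min(self.n_chroms, self.chrom_length, self.n_regions,
               self.region_width_mean, self.n_samples_per_group) <= 0:
            raise SimConfigError("all sizes and widths must be positive")
        if not (0.0 <= self.footprint_protection <= 1.0):
            raise SimConfigError("footprint_protection must be in [0, 1]")
        if not (0.0 < self.gc < 1.0):
            raise SimConfigError("gc must be in (0, 1)")
        w = sum(m[2] for m in self.fragment_modes)
        if abs(w - 1.0) > 1e-6:
            raise SimConfigError(f"fragment mode weights must sum to 1, got {w}")
        for mean, sd, weight in self.fragment_modes:
            if mean <= 0 or sd < 0 or weight < 0:
                raise SimConfigError("fragment modes need mean>0, sd>=0, weight>=0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class SimTruth:
    """Planted ground truth; the oracle for every downstream stage."""

    region_class: dict[str, str] = field(default_factory=dict)   # open / close / null
    trajectory: dict[str, str] = field(default_factory=dict)     # stable / gradual (opening regions)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    motif_bearing: list[str] = field(default_factory=list)
    motif_positions: dict[str, int] = field(default_factory=dict)  # region id -> offset within region
    fragment_modes: list[tuple] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["fragment_modes"] = [list(m) for m in self.fragment_modes]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        payload["fragment_modes"] = [tuple(m) for m in payload["fragment_modes"]]
        return cls(**payload)


def _region_id(i: int) -> str:
    return f"region_{i:05d}"


def simulate_regions(config: SimConfig) -> list[GenomicInterval]:
    """Non-overlapping regions tiled over the synthetic chromosomes.

    Widths are drawn around ``region_width_mean`` (+-25%); regions are laid
    out left to right with random gaps so they never overlap.
    """
    rng = config.rng(_STREAM_REGIONS)
    per_chrom = int(np.ceil(config.n_regions / config.n_chroms))
    regions: list[GenomicInterval] = []
    i = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        n_here = min(per_chrom, config.n_regions - i)
        if n_here <= 0:
            break
        widths = rng.integers(
            int(config.region_width_mean * 0.75),
            int(config.region_width_mean * 1.25) + 1,
            size=n_here,
        )
        free = config.chrom_length - int(widths.sum())
        if free < n_here:
            raise SimConfigError(
                f"chromosome length {config.chrom_length} too small for "
                f"{n_here} regions of mean width {config.region_width_mean}"
            )
        # split the free space into n_here+1 gaps (each >= 1 bp)
        gaps = rng.multinomial(free - (n_here + 1), np.full(n_here + 1, 1.0 / (n_here + 1))) + 1
        pos = 0
        for k in range(n_here):
            pos += int(gaps[k])
            start = pos
            end = start + int(widths[k])
            regions.append(GenomicInterval(chrom, start, end, name=_region_id(i)))
            pos = end
            i += 1
    return regions


def _assign_classes(config: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (class labels, true lfc) arrays over region indices."""
    n = config.n_regions
    n_open = int(round(config.frac_open * n))
    n_close = int(round(config.frac_close * n))
    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    labels[order[:n_open]] = "open"
    labels[order[n_open:n_open + n_close]] = "close"
    lfc = np.zeros(n)
    lfc[labels == "open"] = config.lfc_open
    lfc[labels == "close"] = -config.lfc_open
    return labels, lfc


def simulate_counts(config: SimConfig):
    """Simulate the region x sample count matrix.

    Counts are NB distributed around ``base_i * size_j * 2^(lfc_i * tumor_j)
    * 2^(batch_lfc * faire_j)``.  Sample size multipliers are spread over a
    2-fold range (geometric spacing, then shuffled) so library sizes always
    vary >= 2-fold.  With ``dispersion == 0`` the NB degenerates to Poisson.

    Returns ``(counts, design, truth)`` where ``counts`` is a DataFrame
    (regions x samples), ``design`` a DataFrame indexed by sample with
    columns condition / batch / replicate, and ``truth`` a
    :class:`SimTruth`.
    """
    rng = config.rng(_STREAM_COUNTS)
    n, m = config.n_regions, 2 * config.n_samples_per_group
    labels, lfc = _assign_classes(config, rng)
    base = np.exp(rng.normal(config.base_mean_log, config.base_mean_sigma, size=n))

    conditions = np.array(["WT"] * config.n_samples_per_group + ["TUM"] * config.n_samples_per_group)
    # alternate assays within each condition so batch and condition are not confounded
    batches = np.array([("ATAC" if k % 2 == 0 else "FAIRE") for k in range(config.n_samples_per_group)] * 2)
    sample_ids = [f"{c.lower()}_{b.lower()}_{k}" for k, (c, b) in enumerate(zip(conditions, batches))]

    size = 2.0 ** np.linspace(-0.5, 0.5, m)
    rng.shuffle(size)

    mu = (
        base[:, None]
        * size[None, :]
        * 2.0 ** (lfc[:, None] * (conditions == "TUM")[None, :])
        * 2.0 ** (config.batch_lfc * (batches == "FAIRE")[None, :])
    )
    if config.dispersion < 1e-12:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    ids = [_region_id(i) for i in range(n)]
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="region"), columns=sample_ids)
    design = pd.DataFrame(
        {
            "condition": conditions,
            "batch": batches,
            "replicate": [f"rep{k % config.n_samples_per_group + 1}" for k in range(m)],
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    truth = SimTruth(
        region_class={ids[i]: labels[i] for i in range(n)},
        true_log2fc={ids[i]: float(lfc[i]) for i in range(n)},
        fragment_modes=list(config.fragment_modes),
    )
    # split opening regions into stable / gradual trajectories for the
    # dynamics stage (half and half, deterministically under the seed)
    open_ids = [ids[i] for i in range(n) if labels[i] == "open"]
    halves = rng.permutation(len(open_ids))
    for j, rid in enumerate(open_ids):
        truth.trajectory[rid] = "stable" if halves[j] < len(open_ids) / 2 else "gradual"
    return counts_df, design, truth


def simulate_fragments(
    config: SimConfig,
    regions: list[GenomicInterval],
    motif_sites: list[GenomicInterval] | None = None,
) -> list[GenomicInterval]:
    """Sample fragments whose 5' cut sites tile the given regions.

    Cut positions are uniform within regions except over ``motif_sites``,
    where the insertion rate is multiplied by ``1 - footprint_protection``
    (rejection sampling).  Fragment lengths come from the configured
    mixture; strands are assigned 50/50.  The emitted BED6 carries the
    fragment length in the name column so downstream stages can recover
    insert sizes without alignment files.

    A plus-strand fragment with cut base ``c`` spans ``[c, c+len)``; a
    minus-strand fragment spans ``[c-len+1, c+1)`` (its 5' base is ``c``).
    """
    if not regions:
        raise ValueError("simulate_fragments requires a non-empty region list")
    rng = config.rng(_STREAM_FRAGMENTS)
    motif_sites = motif_sites or []

    # work in a flattened coordinate space (chrom index * chrom_length + pos)
    # so the protected-site membership test is a single searchsorted
    chrom_index = {f"chr{c + 1}": c for c in range(config.n_chroms)}
    for iv in list(regions) + list(motif_sites):
        if iv.chrom not in chrom_index:
            chrom_index[iv.chrom] = len(chrom_index)
    span = config.chrom_length

    def flat(chrom: str, pos) -> np.ndarray:
        return chrom_index[chrom] * span + pos

    prot = sorted((flat(s.chrom, s.start), flat(s.chrom, s.end)) for s in motif_sites)
    prot_starts = np.array([p[0] for p in prot])
    prot_ends = np.array([p[1] for p in prot])

    reg_start = np.array([flat(r.chrom, r.start) for r in regions])
    widths = np.array([len(r) for r in regions], dtype=float)
    probs = widths / widths.sum()
    chrom_names = {v: k for k, v in chrom_index.items()}

    means = np.array([m[0] for m in config.fragment_modes])
    sds = np.array([m[1] for m in config.fragment_modes])
    wts = np.array([m[2] for m in config.fragment_modes])

    fragments: list[GenomicInterval] = []
    keep_prob = 1.0 - config.footprint_protection
    n_needed = config.n_fragments
    while len(fragments) < n_needed:
        batch = max(1024, int((n_needed - len(fragments)) * 1.3))
        ridx = rng.choice(len(regions), size=batch, p=probs)
        cuts = reg_start[ridx] + (rng.random(batch) * widths[ridx]).astype(int)
        comp = rng.choice(len(wts), size=batch, p=wts)
        lengths = np.maximum(1, rng.normal(means[comp], sds[comp]).round().astype(int))
        minus = rng.random(batch) < 0.5
        accept = rng.random(batch)

        if len(prot_starts):
            idx = np.searchsorted(prot_starts, cuts, side="right") - 1
            inside = (idx >= 0) & (cuts < prot_ends[np.clip(idx, 0, None)])
        else:
            inside = np.zeros(batch, dtype=bool)
        keep = ~inside | (accept < keep_prob)

        local = cuts[keep] % span
        chroms = cuts[keep] // span
        lens = lengths[keep]
        neg = minus[keep]
        starts = np.where(neg, local - lens + 1, local)
        ends = np.where(neg, local + 1, local + lens)
        starts = np.maximum(starts, 0)
        ends = np.minimum(ends, span)
        ok = starts < ends
        for c, s, e, ln, m in zip(chroms[ok], starts[ok], ends[ok], lens[ok], neg[ok]):
            if len(fragments) >= n_needed:
                break
            fragments.append(
                GenomicInterval(chrom_names[int(c)], int(s), int(e),
                                strand="-" if m else "+", name=str(int(ln)))
            )
    return fragments


def simulate_sequences(config: SimConfig, pwm, bearing_ids, regions=None):
    """Per-region DNA with one PWM-sampled motif instance in bearing regions.

    Background bases are i.i.d. with the configured GC content; each region
    named in ``bearing_ids`` receives a single instance sampled
    position-by-position from the PWM probabilities, planted at a position
    recorded in the returned :class:`SimTruth`.

    Returns ``(sequences, truth)`` with ``sequences`` a dict
    ``region id -> str``.
    """
    rng = config.rng(_STREAM_SEQUENCES)
    if regions is None:
        regions = simulate_regions(config)
    bearing_ids = set(bearing_ids)
    unknown = bearing_ids - {r.name for r in regions}
    if unknown:
        raise ValueError(f"bearing ids not in region set: {sorted(unknown)[:5]}")
    L = pwm.length
    gc = config.gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    sequences: dict[str, str] = {}
    truth = SimTruth()
    for reg in regions:
        w = len(reg)
        seq = _BASES[rng.choice(4, size=w, p=base_p)]
        if reg.name in bearing_ids:
            if L > w:
                raise ValueError(f"motif ({L} bp) longer than region {reg.name} ({w} bp)")
            pos = int(rng.integers(0, w - L + 1))
            inst = np.array([_BASES[rng.choice(4, p=pwm.matrix[j])] for j in range(L)])
            seq[pos:pos + L] = inst
            truth.motif_bearing.append(reg.name)
            truth.motif_positions[reg.name] = pos
        sequences[reg.name] = "".join(seq)
    return sequences, truth


def simulate_genes(config: SimConfig, regions: list[GenomicInterval]) -> pd.DataFrame:
    """Simple two-exon gene models laid out near regions (for gene linkage).

    Every other region gets a gene whose TSS sits a short distance
    downstream of the region, on alternating strands.  Returned as a
    DataFrame with gene/exon coordinates ready for GFF3 export.
    """
    rows = []
    g = 0
    for i, reg in enumerate(regions):
        if i % 2:
            continue
        gid = f"gene_{g:05d}"
        strand = "+" if g % 2 == 0 else "-"
        span = 3000
        if strand == "+":
            start = reg.end + 1000
            end = start + span
        else:
            end = max(reg.start - 1000, span + 1)
            start = end - span
        if start < 0 or end > config.chrom_length:
            continue
        exon1 = (start, start + 500)
        exon2 = (end - 500, end)
        rows.append(dict(gene_id=gid, chrom=reg.chrom, start=start, end=end,
                         strand=strand, exon1_start=exon1[0], exon1_end=exon1[1],
                         exon2_start=exon2[0], exon2_end=exon2[1]))
        g += 1
    return pd.DataFrame(rows)


def _genes_to_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            # GFF3 is 1-based inclusive
            fh.write(f"{row.chrom}\tregland_sim\tgene\t{row.start + 1}\t{row.end}\t.\t"
                     f"{row.strand}\t.\tID={row.gene_id}\n")
            for k in (1, 2):
                s = getattr(row, f"exon{k}_start")
                e = getattr(row, f"exon{k}_end")
                fh.write(f"{row.chrom}\tregland_sim\texon\t{s + 1}\t{e}\t.\t"
                         f"{row.strand}\t.\tID={row.gene_id}.e{k};Parent={row.gene_id}\n")


def simulate_all(config: SimConfig, out_dir, pwm=None) -> dict[str, Path]:
    """Run every generator and write the full synthetic study to ``out_dir``.

    Emits regions.bed, fragments.bed, genome.fa, genes.gff3, counts.tsv,
    design.tsv and truth.json.  Returns the mapping of artifact name to
    path.  Identical config (including seed) produces byte-identical files.
    """
    from .motifrank import PWM  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if pwm is None:
        pwm = PWM.sharp_example()

    regions = simulate_regions(config)
    counts, design, truth = simulate_counts(config)

    open_ids = {rid for rid, c in truth.region_class.items() if c == "open"}
    seqs, seq_truth = simulate_sequences(config, pwm, open_ids, regions=regions)
    truth.motif_bearing = seq_truth.motif_bearing
    truth.motif_positions = seq_truth.motif_positions

    motif_sites = [
        GenomicInterval(reg.chrom, reg.start + truth.motif_positions[reg.name],
                        reg.start + truth.motif_positions[reg.name] + pwm.length,
                        name=reg.name)
        for reg in regions if reg.name in truth.motif_positions
    ]
    fragments = simulate_fragments(config, regions, motif_sites)
    genes = simulate_genes(config, regions)

    paths = {k: out / v for k, v in {
        "regions": "regions.bed", "fragments": "fragments.bed", "genome": "genome.fa",
        "genes": "genes.gff3", "counts": "counts.tsv", "design": "design.tsv",
        "truth": "truth.json",
    }.items()}

    write_bed(regions, paths["regions"])
    write_bed(fragments, paths["fragments"])
    with open(paths["genome"], "w") as fh:
        rng = config.rng(_STREAM_GENOME)
        region_by_chrom: dict[str, list[GenomicInterval]] = {}
        for reg in regions:
            region_by_chrom.setdefault(reg.chrom, []).append(reg)
        for c in range(config.n_chroms):
            chrom = f"chr{c + 1}"
            seq = _BASES[rng.choice(4, size=config.chrom_length)]
            for reg in region_by_chrom.get(chrom, []):
                seq[reg.start:reg.end] = np.array(list(seqs[reg.name]))
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for k in range(0, len(s), 80):
                fh.write(s[k:k + 80] + "\n")
    _genes_to_gff3(genes, paths["genes"])
    counts.to_csv(paths["counts"], sep="\t")
    design.to_csv(paths["design"], sep="\t")
    truth.to_json(paths["truth"])
    return paths
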
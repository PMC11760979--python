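"""Synthetic multi-timepoint, two-condition accessibility datasets.

The generator emulates the statistical structure of a 3-timepoint
(D0/D1/D3), two-condition (WT vs knockout) ATAC-seq + CUT&RUN study at desk
scale: loci are planted with known dynamics classes, per-library coverage
tracks carry lognormal multiplicative noise around the planted densities,
per-library peak calls deliberately miss weak (closed-at-that-timepoint)
loci — the phenomenon superset re-calling corrects — and two TF binding-site
sets are planted with a controllable co-binding rate near upregulated genes,
coupled to a gene fold-change table. Every planted assignment is emitted in a
truth table so pipeline recovery can be measured exactly.

Coverage is emitted *unscaled*: per-library total read counts are drawn
around ``reads_per_library`` and the raw track equals the planted (scaled)
density divided by that library's 1e7/total factor, so the normalization step
of the pipeline is exercised non-trivially.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import DynamicsLabel
from .io import (
    GenomicInterval,
    GeneRecord,
    LibraryStats,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_gene_table,
    write_library_stats,
)
from .recall import THETA_DEFAULT

__all__ = ["SimConfig", "SimBundle", "simulate", "write_bundle",
           "simulate_dataset", "simulate_worked_example"]

#: Planted dynamics classes (persistently-closed loci are not planted: they
#: never enter any library's peak calls and hence never reach the superset).
DEFAULT_CLASSES = (
    DynamicsLabel.CO1, DynamicsLabel.CO2, DynamicsLabel.OC1,
    DynamicsLabel.OC2, DynamicsLabel.PO, DynamicsLabel.PO_UP,
    DynamicsLabel.PO_DOWN,
)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated study.

    Densities are on the post-normalization scale; ``open_density_mean`` and
    ``closed_density_mean`` straddle ``theta`` by construction so open/closed
    separation is controlled only by ``noise_sd`` (sd of the natural-log
    multiplicative noise).
    """

    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (("chr1", 10_000_000),)
    timepoints: tuple[str, ...] = ("D0", "D1", "D3")
    conditions: tuple[str, ...] = ("WT", "KO")
    classes: tuple[DynamicsLabel, ...] = DEFAULT_CLASSES
    n_per_class: int = 500
    locus_length: int = 400
    min_gap: int = 1_000
    open_density_mean: float = 1.0
    closed_density_mean: float = 0.05
    background_density: float = 0.01
    noise_sd: float = 0.2
    po_change_log2: float = 2.0
    theta: float = THETA_DEFAULT
    n_genes: int = 2_000
    cobind_fraction_up: float = 0.6
    cobind_fraction_down: float = 0.1
    reads_per_library: int = 10_000_000
    n_replicates: int = 1
    label_agreement: float = 0.3
    n_decoy_sites: int = 1_000
    site_length: int = 200
    cobind_max_offset: int = 4_500
    gene_margin: int = 10_000

    def __post_init__(self) -> None:
        for name in ("cobind_fraction_up", "cobind_fraction_down", "label_agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.open_density_mean > self.theta > self.closed_density_mean:
            raise ValueError(
                "open_density_mean must exceed theta and theta must exceed "
                "closed_density_mean"
            )
        if self.noise_sd < 0 or self.n_per_class < 1 or self.locus_length < 1:
            raise ValueError("invalid simulation sizes")
        if len(self.timepoints) != 3:
            raise ValueError("the simulator plants 3-timepoint trajectories")

    def library_ids(self) -> list[str]:
        return [
            f"{cond}_{tp}_rep{r}"
            for cond in self.conditions
            for tp in self.timepoints
            for r in range(1, self.n_replicates + 1)
        ]


@dataclass
class SimBundle:
    """In-memory simulated dataset plus its planted truth."""

    config: SimConfig
    loci: list[GenomicInterval]                 # sorted, disjoint; names are locus ids
    truth_loci: pd.DataFrame                    # chrom,start,end,locus_id,label_<cond>...
    stats: list[LibraryStats]
    tracks: dict[str, SignalTrack]              # raw (unscaled) coverage per library
    peaks: dict[str, list[GenomicInterval]]     # per-library called peaks
    genes: list[GeneRecord]
    truth_genes: pd.DataFrame                   # gene_id,log2fc,cobound
    tf_a: list[GenomicInterval]
    tf_b: list[GenomicInterval]


def _class_density_pattern(cfg: SimConfig, label: DynamicsLabel) -> tuple[float, float, float]:
    o, c = cfg.open_density_mean, cfg.closed_density_mean
    half = 2.0 ** (cfg.po_change_log2 / 2.0)
    patterns = {
        DynamicsLabel.CO1: (c, o, o),
        DynamicsLabel.CO2: (c, c, o),
        DynamicsLabel.OC1: (o, c, c),
        DynamicsLabel.OC2: (o, o, c),
        DynamicsLabel.PO: (o, o, o),
        DynamicsLabel.PO_UP: (o / half, o, o * half),
        DynamicsLabel.PO_DOWN: (o * half, o, o / half),
        DynamicsLabel.PC: (c, c, c),
    }
    return patterns[label]


def _place_loci(cfg: SimConfig, rng: np.random.Generator, n: int,
                length: int, gap: int) -> list[tuple[str, int]]:
    """Rejection-sample n non-overlapping placements (chrom, start), keeping
    at least ``gap`` bp between loci so merged supersets preserve identity."""
    names = [c for c, _ in cfg.contigs]
    lengths = np.array([l for _, l in cfg.contigs], dtype=np.float64)
    if np.any(lengths < length + 2 * gap):
        raise ValueError("contig too small for requested locus length")
    weights = lengths / lengths.sum()
    occupied: dict[str, list[int]] = {c: [] for c in names}  # sorted starts
    placements: list[tuple[str, int]] = []
    max_tries = 200 * n + 10_000
    tries = 0
    import bisect

    while len(placements) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"contigs too crowded: placed {len(placements)}/{n} loci "
                f"after {max_tries} attempts"
            )
        ci = int(rng.choice(len(names), p=weights))
        chrom, clen = names[ci], int(lengths[ci])
        start = int(rng.integers(gap, clen - length - gap))
        starts = occupied[chrom]
        k = bisect.bisect_left(starts, start)
        if k > 0 and starts[k - 1] + length + gap > start:
            continue
        if k < len(starts) and start + length + gap > starts[k]:
            continue
        starts.insert(k, start)
        placements.append((chrom, start))
    return placements


def simulate(config: SimConfig) -> SimBundle:
    """Generate one dataset; identical config (incl. seed) ⇒ identical bundle."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- loci with planted per-condition labels -------------------------------
    n_loci = len(cfg.classes) * cfg.n_per_class
    placements = _place_loci(cfg, rng, n_loci, cfg.locus_length, cfg.min_gap)
    base_labels = [cls for cls in cfg.classes for _ in range(cfg.n_per_class)]
    labels_by_cond: dict[str, list[DynamicsLabel]] = {cfg.conditions[0]: base_labels}
    for cond in cfg.conditions[1:]:
        keep = rng.random(n_loci) < cfg.label_agreement
        redraw = rng.integers(0, len(cfg.classes), size=n_loci)
        labels_by_cond[cond] = [
            base_labels[i] if keep[i] else cfg.classes[int(redraw[i])]
            for i in range(n_loci)
        ]

    order = sorted(range(n_loci), key=lambda i: (placements[i][0], placements[i][1]))
    loci = []
    for rank, i in enumerate(order):
        chrom, start = placements[i]
        loci.append(
            GenomicInterval(chrom, start, start + cfg.locus_length,
                            name=f"locus_{rank:05d}")
        )
    labels_sorted = {
        cond: [labels_by_cond[cond][i] for i in order] for cond in cfg.conditions
    }
    truth_loci = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in loci],
            "start": [iv.start for iv in loci],
            "end": [iv.end for iv in loci],
            "locus_id": [iv.name for iv in loci],
            **{f"label_{cond}": [l.value for l in labels_sorted[cond]]
               for cond in cfg.conditions},
        }
    )

    # --- per-library densities, tracks, peak calls ----------------------------
    lo = int(0.8 * cfg.reads_per_library)
    hi = int(1.2 * cfg.reads_per_library)
    stats: list[LibraryStats] = []
    tracks: dict[str, SignalTrack] = {}
    peaks: dict[str, list[GenomicInterval]] = {}
    contig_len = dict(cfg.contigs)
    for cond in cfg.conditions:
        mean_by_tp = np.array(
            [_class_density_pattern(cfg, l) for l in labels_sorted[cond]]
        )  # n_loci x 3
        for t_idx, tp in enumerate(cfg.timepoints):
            for rep in range(1, cfg.n_replicates + 1):
                lib = f"{cond}_{tp}_rep{rep}"
                total = int(rng.integers(lo, hi + 1))
                stats.append(LibraryStats(lib, total, tp, cond))
                factor = 1e7 / total
                noise = (
                    np.exp(rng.normal(0.0, cfg.noise_sd, size=n_loci))
                    if cfg.noise_sd > 0 else np.ones(n_loci)
                )
                target = mean_by_tp[:, t_idx] * noise  # post-scaling density
                raw = target / factor
                raw_bg = cfg.background_density / factor
                segments: list[tuple[str, int, int, float]] = []
                by_chrom: dict[str, list[int]] = {}
                for i, iv in enumerate(loci):
                    by_chrom.setdefault(iv.chrom, []).append(i)
                for chrom, clen in cfg.contigs:
                    pos = 0
                    for i in by_chrom.get(chrom, []):
                        iv = loci[i]
                        if iv.start > pos:
                            segments.append((chrom, pos, iv.start, raw_bg))
                        segments.append((chrom, iv.start, iv.end, float(raw[i])))
                        pos = iv.end
                    if pos < clen:
                        segments.append((chrom, pos, clen, raw_bg))
                tracks[lib] = SignalTrack.from_segments(segments)
                peaks[lib] = [
                    loci[i] for i in range(n_loci) if target[i] >= cfg.theta
                ]

    # --- genes, expression, TF binding sites ----------------------------------
    names = [c for c, _ in cfg.contigs]
    clens = np.array([l for _, l in cfg.contigs], dtype=np.float64)
    weights = clens / clens.sum()
    gene_contig = rng.choice(len(names), p=weights, size=cfg.n_genes)
    genes: list[GeneRecord] = []
    for gi in range(cfg.n_genes):
        chrom = names[int(gene_contig[gi])]
        clen = contig_len[chrom]
        tss = int(rng.integers(cfg.gene_margin, clen - cfg.gene_margin))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneRecord(f"gene_{gi:05d}", chrom, tss, strand, 0.0))
    log2fc = rng.normal(0.0, 1.0, size=cfg.n_genes)
    genes = [dataclasses.replace(g, log2fc=float(f)) for g, f in zip(genes, log2fc)]

    # tercile-based co-binding coupling along the expression ranking
    rank = np.argsort(np.argsort(-log2fc, kind="stable"), kind="stable")
    third = cfg.n_genes / 3.0
    p_mid = 0.5 * (cfg.cobind_fraction_up + cfg.cobind_fraction_down)
    probs = np.where(
        rank < third, cfg.cobind_fraction_up,
        np.where(rank >= 2 * third, cfg.cobind_fraction_down, p_mid),
    )
    cobound = (rng.random(cfg.n_genes) < probs).astype(np.int64)

    half_site = cfg.site_length // 2
    tf_a: list[GenomicInterval] = []
    tf_b: list[GenomicInterval] = []
    for gi in range(cfg.n_genes):
        if not cobound[gi]:
            continue
        g = genes[gi]
        clen = contig_len[g.chrom]
        offset = int(rng.integers(-cfg.cobind_max_offset, cfg.cobind_max_offset + 1))
        center = min(max(g.tss + offset, half_site), clen - half_site)
        site = GenomicInterval(g.chrom, center - half_site, center + half_site)
        tf_a.append(site)
        tf_b.append(site)
    for sink in (tf_a, tf_b):
        decoy_contig = rng.choice(len(names), p=weights, size=cfg.n_decoy_sites)
        for di in range(cfg.n_decoy_sites):
            chrom = names[int(decoy_contig[di])]
            clen = contig_len[chrom]
            start = int(rng.integers(0, clen - cfg.site_length))
            sink.append(GenomicInterval(chrom, start, start + cfg.site_length))
    tf_a.sort(key=GenomicInterval.sort_key)
    tf_b.sort(key=GenomicInterval.sort_key)

    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "log2fc": [g.log2fc for g in genes],
            "cobound": cobound,
        }
    )
    return SimBundle(cfg, loci, truth_loci, stats, tracks, peaks, genes,
                     truth_genes, tf_a, tf_b)


def _config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["contigs"] = [list(c) for c in d["contigs"]]
    d["timepoints"] = list(d["timepoints"])
    d["conditions"] = list(d["conditions"])
    d["classes"] = [c.value for c in cfg.classes]
    return d


def write_bundle(bundle: SimBundle, outdir: str | Path) -> None:
    """Write the bundle as plain-text files plus the truth tables and a YAML
    echo of the resolved configuration."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for lib, track in bundle.tracks.items():
        write_bedgraph(track, out / f"{lib}.bedgraph")
    for lib, pk in bundle.peaks.items():
        write_bed(pk, out / f"{lib}.peaks.bed")
    write_library_stats(bundle.stats, out / "stats.tsv")
    write_gene_table(bundle.genes, out / "genes.tsv")
    write_bed(bundle.tf_a, out / "tf_a.bed")
    write_bed(bundle.tf_b, out / "tf_b.bed")
    bundle.truth_loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    bundle.truth_genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_to_dict(bundle.config), fh, sort_keys=True)


def simulate_dataset(config: SimConfig, outdir: str | Path) -> SimBundle:
    """Generate a dataset and write it under ``outdir``."""
    bundle = simulate(config)
    write_bundle(bundle, outdir)
    return bundle


def simulate_worked_example() -> SimBundle:
    """Tiny fixed noiseless bundle (14 loci, 5 genes, one 150 kb contig) used
    in the documentation walk-through and unit tests."""
    cfg = SimConfig(
        seed=11,
        contigs=(("chrT", 150_000),),
        n_per_class=2,
        locus_length=400,
        min_gap=1_500,
        n_genes=5,
        noise_sd=0.0,
        n_decoy_sites=2,
        gene_margin=10_000,
    )
    return simulate(cfg)
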
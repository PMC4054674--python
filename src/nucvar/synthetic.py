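"""Synthetic tiling-array data with planted nucleosomes and gene models.

The generator emulates the data the analysis consumes: normalized
log2-scale probe signals on a regular grid over one or more
chromosomes, for four ChIP channels (variant ChIP, bulk-histone ChIP,
non-immune IgG, input), together with a gene annotation, promoter-class
labels and a multi-condition expression matrix.

Every planted nucleosome contributes a smooth raised-cosine footprint
to the bulk-histone channel; a configurable fraction additionally
carries the histone variant and contributes boosted signal to the
variant channel. The kernel's inflection points are one nucleosomal
footprint (147 bp) apart, the width a peak caller measuring
inflection-to-inflection distances should recover for mono-nucleosomal
coverage. Variant nucleosomes are planted preferentially in promoter
windows of GA-class genes (independent of expression) and near TTSs of
highly expressed genes, and GA-class genes are given condition-specific
(low-entropy) expression profiles, so that downstream association and
regulation statistics have recoverable planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import (
    GeneModel,
    ProbeTrack,
    write_annotation,
    write_expression_table,
    write_probe_track,
)

import pandas as pd

CHANNELS = ("variant", "histone", "igg", "input")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Lengths are in bp; signals are on a log2-like scale. Defaults give
    one 2-Mb chromosome tiled every 10 bp with ~5,000 nucleosomes at
    ~400-bp spacing, 30% of them variant-carrying.
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 1
    probe_spacing: int = 10
    n_genes: int = 450
    nucleosome_footprint: int = 147
    nucleosome_spacing: int = 400
    placement_jitter: int = 50
    kernel_amplitude: float = 2.0
    variant_log2_boost: float = 1.5
    h33_fraction: float = 0.3
    promoter_class_probs: dict = field(
        default_factory=lambda: {"TATA": 0.3, "GA": 0.2, "coreless": 0.5}
    )
    ga_promoter_boost: float = 8.0
    tts_expression_boost: float = 8.0
    noise_sd: float = 0.3
    n_conditions: int = 8
    expression_zero_inflation: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_chromosomes", "probe_spacing", "n_genes",
                     "nucleosome_footprint", "nucleosome_spacing", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.h33_fraction <= 1.0:
            raise ConfigurationError("h33_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        total = sum(self.promoter_class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError("promoter_class_probs must sum to 1")

    @property
    def chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class PlantedNucleosome:
    chromosome: str
    center: int
    occupancy: float
    has_variant: bool


@dataclass
class GenomeTruth:
    """Ground truth of one simulated genome."""

    genes: list[GeneModel]
    planted_nucleosomes: list[PlantedNucleosome]
    condition_labels: list[str]


# ---------------------------------------------------------------------------
# kernel


def footprint_kernel(offsets: np.ndarray, footprint: int) -> np.ndarray:
    """Raised-cosine nucleosome footprint, unit height at the dyad.

    ``k(x) = (1 + cos(pi * x / F)) / 2`` on ``|x| <= F`` and 0 outside,
    with F the footprint. Inflection points sit at ``x = +-F/2`` so
    their separation equals the footprint; the integral is exactly F.
    """
    x = np.asarray(offsets, dtype=float)
    k = 0.5 * (1.0 + np.cos(np.pi * x / footprint))
    return np.where(np.abs(x) <= footprint, k, 0.0)


def kernel_integral(footprint: int) -> float:
    """Closed-form integral of the unit footprint kernel (= footprint bp)."""
    return float(footprint)


# ---------------------------------------------------------------------------
# genome simulation


def simulate_genome(config: SimulationConfig) -> GenomeTruth:
    """Place genes and nucleosomes and draw expression; deterministic per seed."""
    rng = np.random.default_rng([config.seed, 101])
    genes: list[GeneModel] = []
    planted: list[PlantedNucleosome] = []
    labels = [f"cond{i + 1:02d}" for i in range(config.n_conditions)]

    per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    gene_idx = 0
    for chrom, n_c in zip(config.chromosome_names, per_chrom):
        genes.extend(_place_genes(chrom, n_c, gene_idx, config, rng))
        gene_idx += n_c

    _draw_expression(genes, config, rng)

    for chrom in config.chromosome_names:
        planted.extend(_plant_nucleosomes(chrom, genes, config, rng))

    return GenomeTruth(genes=genes, planted_nucleosomes=planted,
                       condition_labels=labels)


def _split_counts(n: int, k: int) -> list[int]:
    base = n // k
    out = [base] * k
    for i in range(n - base * k):
        out[i] += 1
    return out


def _place_genes(chrom: str, n: int, start_idx: int,
                 config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    if n == 0:
        return []
    lengths = rng.lognormal(mean=np.log(2000.0), sigma=0.6, size=n)
    lengths = np.clip(lengths, 400, 15_000).astype(int)
    # shrink if genes would not fit with room for intergenic space
    budget = int(0.6 * config.genome_length)
    if lengths.sum() > budget:
        lengths = (lengths * budget / lengths.sum()).astype(int)
        lengths = np.maximum(lengths, 400)
    slack = config.genome_length - int(lengths.sum())
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    gaps = gaps.astype(int)

    ftype_probs = {"protein_coding": 0.78, "pseudogene": 0.04, "TE_gene": 0.08,
                   "TE": 0.05, "miRNA": 0.015, "tRNA": 0.015, "ncRNA": 0.02}
    classes = list(config.promoter_class_probs)
    class_p = np.array([config.promoter_class_probs[c] for c in classes])

    genes = []
    pos = 0
    for i in range(n):
        pos += gaps[i]
        start, end = pos, pos + int(lengths[i])
        pos = end
        strand = "+" if rng.random() < 0.5 else "-"
        ftype = rng.choice(list(ftype_probs), p=np.array(list(ftype_probs.values())))
        pclass = rng.choice(classes, p=class_p) if ftype == "protein_coding" else "unknown"
        tss, tts = (start, end) if strand == "+" else (end, start)
        genes.append(GeneModel(
            id=f"g{start_idx + i + 1:05d}", chromosome=chrom, strand=strand,
            tss=tss, tts=tts, feature_type=str(ftype), promoter_class=str(pclass),
            expression=np.zeros(config.n_conditions),
        ))
    return genes


def _draw_expression(genes: list[GeneModel], config: SimulationConfig,
                     rng: np.random.Generator) -> None:
    """Expression: log-normal overall level x Dirichlet condition profile.

    GA-class genes get condition-specific (small Dirichlet alpha, low
    entropy) profiles regardless of level; for other genes breadth
    rises with level so that highly expressed genes look housekeeping-
    like (high entropy). A small fraction is silenced entirely.
    """
    coding = [g for g in genes if g.feature_type == "protein_coding"]
    levels = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(coding))
    ranks = np.argsort(np.argsort(levels)) / max(len(coding) - 1, 1)
    for g, level, r in zip(coding, levels, ranks):
        if rng.random() < config.expression_zero_inflation:
            continue  # no detectable transcripts
        if g.promoter_class == "GA":
            alpha = 0.25
        else:
            alpha = 0.5 + 6.0 * r
        profile = rng.dirichlet(np.full(config.n_conditions, alpha))
        g.expression = level * config.n_conditions * profile


def _variant_propensity(centers: np.ndarray, genes: list[GeneModel],
                        config: SimulationConfig) -> np.ndarray:
    """Relative odds that a planted nucleosome carries the variant."""
    w = np.ones(len(centers))
    coding = [g for g in genes if g.feature_type == "protein_coding"
              and g.expression.sum() > 0]
    if coding:
        means = np.array([g.expression.mean() for g in coding])
        hi_cut = np.quantile(means, 0.75)
    for g in genes:
        if g.feature_type != "protein_coding":
            continue
        if g.promoter_class == "GA":
            lo, hi = _promoter_window(g, 2000)
            w[(centers >= lo) & (centers < hi)] *= config.ga_promoter_boost
        if g.expression.sum() > 0 and g.expression.mean() >= hi_cut:
            lo, hi = _tts_window(g, 500, 500)
            w[(centers >= lo) & (centers < hi)] *= config.tts_expression_boost
    return w


def _promoter_window(g: GeneModel, width: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tss - width, g.tss
    return g.tss, g.tss + width


def _tts_window(g: GeneModel, up: int, down: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tts - up, g.tts + down
    return g.tts - down, g.tts + up


def _plant_nucleosomes(chrom: str, genes: list[GeneModel], config: SimulationConfig,
                       rng: np.random.Generator) -> list[PlantedNucleosome]:
    F, L = config.nucleosome_footprint, config.genome_length
    lattice = np.arange(config.nucleosome_spacing // 2, L, config.nucleosome_spacing)
    jitter = rng.integers(-config.placement_jitter, config.placement_jitter + 1,
                          size=len(lattice))
    centers = lattice + jitter
    centers = centers[(centers >= F) & (centers < L - F)]
    occ = rng.uniform(0.7, 1.3, size=len(centers))

    chrom_genes = [g for g in genes if g.chromosome == chrom]
    w = _variant_propensity(centers, chrom_genes, config)
    p = _scaled_probabilities(w, config.h33_fraction)
    flags = rng.random(len(centers)) < p
    return [PlantedNucleosome(chrom, int(c), float(o), bool(f))
            for c, o, f in zip(centers, occ, flags)]


def _scaled_probabilities(w: np.ndarray, fraction: float) -> np.ndarray:
    """Scale propensities to probabilities with mean `fraction`, respecting p<=1."""
    if fraction <= 0:
        return np.zeros_like(w)
    if fraction >= 1:
        return np.ones_like(w)
    target = fraction * len(w)
    lo, hi = 0.0, target / w.min() + 1.0
    for _ in range(100):
        s = 0.5 * (lo + hi)
        if np.minimum(s * w, 1.0).sum() > target:
            hi = s
        else:
            lo = s
    return np.minimum(0.5 * (lo + hi) * w, 1.0)


# ---------------------------------------------------------------------------
# probe tracks


def simulate_probe_tracks(truth: GenomeTruth, config: SimulationConfig
                          ) -> dict[str, dict[str, ProbeTrack]]:
    """Four-channel probe tracks on a regular grid; log2-like scale.

    Returns ``{channel: {chromosome: ProbeTrack}}`` for channels
    variant / histone / igg / input. The bulk-histone channel carries
    every planted footprint; the variant channel carries boosted
    footprints at variant-flagged nucleosomes only; IgG and input are
    noise around a flat baseline.
    """
    if not truth.planted_nucleosomes:
        raise ValueError("truth contains no planted nucleosomes")
    rng = np.random.default_rng([config.seed, 202])
    F = config.nucleosome_footprint
    out: dict[str, dict[str, ProbeTrack]] = {ch: {} for ch in CHANNELS}

    by_chrom: dict[str, list[PlantedNucleosome]] = {}
    for nuc in truth.planted_nucleosomes:
        by_chrom.setdefault(nuc.chromosome, []).append(nuc)

    for chrom in sorted(by_chrom):
        nucs = by_chrom[chrom]
        positions = np.arange(config.probe_spacing // 2, config.genome_length,
                              config.probe_spacing, dtype=np.int64)
        histone = np.zeros(len(positions))
        variant = np.zeros(len(positions))
        for nuc in nucs:
            i0 = np.searchsorted(positions, nuc.center - F)
            i1 = np.searchsorted(positions, nuc.center + F, side="right")
            k = footprint_kernel(positions[i0:i1] - nuc.center, F)
            histone[i0:i1] += config.kernel_amplitude * nuc.occupancy * k
            if nuc.has_variant:
                amp = (config.kernel_amplitude + config.variant_log2_boost)
                variant[i0:i1] += amp * nuc.occupancy * k
        igg = np.zeros(len(positions))
        inpt = np.zeros(len(positions))
        for name, sig in (("variant", variant), ("histone", histone),
                          ("igg", igg), ("input", inpt)):
            noisy = sig + rng.normal(0.0, config.noise_sd, size=len(positions)) \
                if config.noise_sd > 0 else sig
            out[name][chrom] = ProbeTrack(chrom, positions, noisy)
    return out


# ---------------------------------------------------------------------------
# on-disk study


def write_simulation(truth: GenomeTruth, tracks: dict[str, dict[str, ProbeTrack]],
                     config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write the full synthetic study: bedGraph per channel, GFF3 genes,
    truth BED6 of planted nucleosomes, expression TSV and a YAML config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"nucvar synthetic study seed={config.seed}"
    paths: dict[str, Path] = {}

    for ch in CHANNELS:
        p = outdir / f"{ch}.bedgraph"
        write_probe_track([tracks[ch][c] for c in sorted(tracks[ch])], p,
                          span=1, header=header)
        paths[ch] = p

    paths["annotation"] = outdir / "genes.gff3"
    write_annotation(truth.genes, paths["annotation"], header=header)

    paths["truth_bed"] = outdir / "planted_nucleosomes.bed"
    half = config.nucleosome_footprint // 2
    with open(paths["truth_bed"], "w") as fh:
        fh.write(f"# {header}\n")
        for i, nuc in enumerate(truth.planted_nucleosomes):
            s = max(nuc.center - half, 0)
            fh.write(f"{nuc.chromosome}\t{s}\t{nuc.center + half + 1}\tplanted{i:06d}"
                     f"\t{nuc.occupancy:.4f}\t{'+' if nuc.has_variant else '.'}\n")

    paths["expression"] = outdir / "expression.tsv"
    expr = pd.DataFrame(
        {g.id: (g.expression if len(g.expression) else np.zeros(config.n_conditions))
         for g in truth.genes}, index=truth.condition_labels).T
    expr.index.name = "gene"
    write_expression_table(expr, paths["expression"], header=header)

    paths["config"] = outdir / "config.yaml"
    cfg = {k: (v if not isinstance(v, dict) else dict(v))
           for k, v in vars(config).items()}
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
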
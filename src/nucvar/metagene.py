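"""Strand-aware metagene profiles.

A metagene profile averages signal across many genes after anchoring:
fixed-bp bins over the upstream flank of the TSS and the downstream
flank of the TTS, and percentage bins over the gene body so genes of
different lengths align. Minus-strand genes are coordinate-reversed
before binning. Probes are averaged into bins (no per-bp
interpolation); a gene contributes to a bin only when it has probes
there, and the profile is the mean over contributing genes per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .io import GeneModel, ProbeTrack


@dataclass
class MetageneProfile:
    upstream_bins: np.ndarray  # mean signal per fixed-bp bin over [-flank, 0) of TSS
    body_bins: np.ndarray  # mean signal per percent bin over the gene body
    downstream_bins: np.ndarray  # per fixed-bp bin over (0, +flank] of TTS
    n_genes: int
    bin_size: int
    n_body_bins: int
    upstream_n: np.ndarray = field(default_factory=lambda: np.zeros(0))
    body_n: np.ndarray = field(default_factory=lambda: np.zeros(0))
    downstream_n: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def concat(self) -> np.ndarray:
        return np.concatenate([self.upstream_bins, self.body_bins,
                               self.downstream_bins])

    def to_frame(self) -> pd.DataFrame:
        flank = len(self.upstream_bins) * self.bin_size
        coords = ([f"{-flank + i * self.bin_size}bp"
                   for i in range(len(self.upstream_bins))]
                  + [f"{100 * (i + 0.5) / self.n_body_bins:.1f}%"
                     for i in range(self.n_body_bins)]
                  + [f"+{(i + 1) * self.bin_size}bp"
                     for i in range(len(self.downstream_bins))])
        return pd.DataFrame({
            "bin": coords,
            "mean": self.concat(),
            "n": np.concatenate([self.upstream_n, self.body_n,
                                 self.downstream_n]).astype(int),
        })


def _gene_bins(track: ProbeTrack, gene: GeneModel, flank: int, bin_size: int,
               n_body_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-gene bin means (NaN where the gene has no probes in a bin)."""
    n_flank = flank // bin_size
    up = np.full(n_flank, np.nan)
    body = np.full(n_body_bins, np.nan)
    down = np.full(n_flank, np.nan)

    sign = 1 if gene.strand == "+" else -1
    # upstream flank: offsets in [-flank, 0) of the TSS, 5'->3'
    for b in range(n_flank):
        off_lo = -flank + b * bin_size
        off_hi = off_lo + bin_size
        lo, hi = _oriented_window(gene.tss, off_lo, off_hi, sign)
        vals = track.slice(lo, hi).values
        if len(vals):
            up[b] = vals.mean()
    # body: percent bins from TSS to TTS
    length = abs(gene.tts - gene.tss)
    if length >= n_body_bins:
        for b in range(n_body_bins):
            off_lo = length * b / n_body_bins
            off_hi = length * (b + 1) / n_body_bins
            lo, hi = _oriented_window(gene.tss, off_lo, off_hi, sign)
            vals = track.slice(lo, hi).values
            if len(vals):
                body[b] = vals.mean()
    # downstream flank: offsets in (0, +flank] of the TTS
    for b in range(n_flank):
        off_lo = b * bin_size
        off_hi = off_lo + bin_size
        lo, hi = _oriented_window(gene.tts, off_lo, off_hi, sign)
        vals = track.slice(lo, hi).values
        if len(vals):
            down[b] = vals.mean()
    return up, body, down


def _oriented_window(anchor: float, off_lo: float, off_hi: float,
                     sign: int) -> tuple[float, float]:
    """Genomic [lo, hi) for a 5'->3' offset window at an anchor."""
    if sign > 0:
        return anchor + off_lo, anchor + off_hi
    return anchor - off_hi, anchor - off_lo


def metagene_profile(tracks: dict[str, ProbeTrack], genes: list[GeneModel],
                     flank: int = 3000, bin_size: int = 50,
                     n_body_bins: int = 100) -> MetageneProfile:
    """Average profile over genes: -flank..TSS, scaled body, TTS..+flank."""
    n_flank = flank // bin_size
    sums = [np.zeros(n_flank), np.zeros(n_body_bins), np.zeros(n_flank)]
    counts = [np.zeros(n_flank), np.zeros(n_body_bins), np.zeros(n_flank)]
    used = 0
    for gene in genes:
        track = tracks.get(gene.chromosome)
        if track is None:
            continue
        if abs(gene.tts - gene.tss) < n_body_bins:
            warnings.warn(f"gene {gene.id} shorter than one bp per body bin; skipped")
            continue
        parts = _gene_bins(track, gene, flank, bin_size, n_body_bins)
        for arr, s, c in zip(parts, sums, counts):
            ok = np.isfinite(arr)
            s[ok] += arr[ok]
            c[ok] += 1
        used += 1
    if used == 0:
        raise ValueError("no usable genes for the metagene profile")
    means = [np.divide(s, c, out=np.full_like(s, np.nan), where=c > 0)
             for s, c in zip(sums, counts)]
    return MetageneProfile(upstream_bins=means[0], body_bins=means[1],
                           downstream_bins=means[2], n_genes=used,
                           bin_size=bin_size, n_body_bins=n_body_bins,
                           upstream_n=counts[0], body_n=counts[1],
                           downstream_n=counts[2])


def grouped_profiles(tracks: dict[str, ProbeTrack], genes: list[GeneModel],
                     grouping: dict[str, object], flank: int = 3000,
                     bin_size: int = 50, n_body_bins: int = 100
                     ) -> dict[object, MetageneProfile]:
    """One independent metagene profile per group of genes."""
    groups: dict[object, list[GeneModel]] = {}
    for g in genes:
        if g.id in grouping:
            groups.setdefault(grouping[g.id], []).append(g)
    out = {}
    for key in sorted(groups, key=str):
        try:
            out[key] = metagene_profile(tracks, groups[key], flank=flank,
                                        bin_size=bin_size, n_body_bins=n_body_bins)
        except ValueError:
            warnings.warn(f"group {key!r} contributed no usable genes; omitted")
    return out


def point_profile(tracks: dict[str, ProbeTrack],
                  points: list[tuple[str, float]], half_width: int = 600,
                  bin_size: int = 50) -> pd.DataFrame:
    """Binned mean signal with a 95% CI around anchor points.

    Bins cover [-half_width, +half_width); the confidence band is the
    normal approximation mean +- 1.96*SE across points per bin.
    """
    if not points:
        raise ValueError("no anchor points given")
    n_bins = 2 * half_width // bin_size
    offsets = -half_width + bin_size * (np.arange(n_bins) + 0.5)
    per_point = np.full((len(points), n_bins), np.nan)
    for i, (chrom, center) in enumerate(points):
        track = tracks.get(chrom)
        if track is None:
            continue
        for b in range(n_bins):
            lo = center - half_width + b * bin_size
            vals = track.slice(lo, lo + bin_size).values
            if len(vals):
                per_point[i, b] = vals.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_point, axis=0)
        sd = np.nanstd(per_point, axis=0, ddof=1) if len(points) > 1 \
            else np.zeros(n_bins)
    n = np.sum(np.isfinite(per_point), axis=0)
    se = np.divide(sd, np.sqrt(np.maximum(n, 1)))
    return pd.DataFrame({"offset": offsets, "mean": mean, "n": n,
                         "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se})


def tss_tts_matrix(tracks: dict[str, ProbeTrack], genes: list[GeneModel],
                   max_body: int = 5000, downstream: int = 1000,
                   bin_size: int = 50, n_sample: int | None = 5000,
                   seed: int = 0) -> pd.DataFrame:
    """Gene x position signal matrix from the TSS, ordered by body length.

    Each row holds binned signal from the TSS to min(gene length,
    ``max_body``) plus ``downstream`` bp beyond the TTS; cells beyond a
    gene's truncated body are NaN. Rows are sorted by ascending gene
    body length (``n_sample`` genes drawn at random when the annotation
    is larger).
    """
    rng = np.random.default_rng(seed)
    pool = list(genes)
    if n_sample is not None and len(pool) > n_sample:
        idx = rng.choice(len(pool), size=n_sample, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    pool.sort(key=lambda g: (g.length, g.id))
    n_body_bins = max_body // bin_size
    n_down_bins = downstream // bin_size
    mat = np.full((len(pool), n_body_bins + n_down_bins), np.nan)
    for i, gene in enumerate(pool):
        track = tracks.get(gene.chromosome)
        if track is None:
            continue
        sign = 1 if gene.strand == "+" else -1
        body = min(gene.length, max_body)
        for b in range(int(np.ceil(body / bin_size))):
            off_lo, off_hi = b * bin_size, min((b + 1) * bin_size, body)
            lo, hi = _oriented_window(gene.tss, off_lo, off_hi, sign)
            vals = track.slice(lo, hi).values
            if len(vals):
                mat[i, b] = vals.mean()
        for b in range(n_down_bins):
            lo, hi = _oriented_window(gene.tts, b * bin_size,
                                      (b + 1) * bin_size, sign)
            vals = track.slice(lo, hi).values
            if len(vals):
                mat[i, n_body_bins + b] = vals.mean()
    cols = [f"body_{b * bin_size}" for b in range(n_body_bins)] + \
           [f"down_{b * bin_size}" for b in range(n_down_bins)]
    return pd.DataFrame(mat, index=[g.id for g in pool], columns=cols)


@dataclass
class ExpressionBins:
    n_bins: int
    assignment: dict[str, int]  # gene id -> bin index, 1 = lowest expression
    boundaries: np.ndarray  # expression quantile edges


def bin_by_expression(genes: list[GeneModel], n_bins: int = 4,
                      summary=np.mean, condition: int | None = None
                      ) -> ExpressionBins:
    """Quantile-bin genes by expression (default: mean across conditions).

    Bin 1 holds the lowest-expressed genes. Ties are broken by gene id
    for determinism; bin sizes differ by at most 1.
    """
    usable = [g for g in genes if len(g.expression)]
    if not usable:
        raise ValueError("no genes with expression values")
    vals = np.array([g.expression[condition] if condition is not None
                     else float(summary(g.expression)) for g in usable])
    if np.ptp(vals) == 0:
        raise ValueError("all expression values equal; bins undefined")
    order = sorted(range(len(usable)), key=lambda i: (vals[i], usable[i].id))
    assignment = {}
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        for i in chunk:
            assignment[usable[i].id] = b
    boundaries = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    return ExpressionBins(n_bins=n_bins, assignment=assignment,
                          boundaries=boundaries)
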
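"""Associate nucleosomes with genomic features and test enrichment.

Selected variant nucleosomes are linked to the nearest annotated
feature when the gap does not exceed 2,000 bp; nucleosomes near genes
are further classified as promoter-, TTS- or body-associated using
strand-aware windows, and feature-type composition is compared against
a resampling null drawn from all positioned nucleosomes (so the null
inherits the mappability of detected nucleosomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneModel

POSITION_CLASSES = ("promoter", "TTS", "body", "ambiguous", "none")


@dataclass
class AssociationParams:
    max_distance: float = 2000.0  # bp, association cut-off ("did not exceed")
    promoter_window: float = 2000.0  # bp upstream of the TSS
    tts_window_up: float = 500.0  # bp into the gene body from the TTS
    tts_window_down: float = 2000.0  # bp beyond the TTS
    n_resamples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_distance", "promoter_window", "tts_window_up",
                     "tts_window_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be >= 100")


@dataclass
class Association:
    nucleosome_id: str
    feature_id: str | None
    feature_type: str | None
    distance: float  # 0 inside the feature; signed, negative upstream of the TSS
    position_class: str = "none"


class _FeatureIndex:
    """Per-chromosome sorted feature intervals for nearest-edge queries."""

    def __init__(self, annotation: list[GeneModel]):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in annotation:
            self.by_chrom.setdefault(g.chromosome, []).append(g)
        self.arrays = {}
        for chrom, feats in self.by_chrom.items():
            feats.sort(key=lambda g: (g.start, g.id))
            self.arrays[chrom] = (
                np.array([g.start for g in feats]),
                np.array([g.end for g in feats]),
            )


def _gap(center: float, start: float, end: float) -> float:
    """Unsigned distance from a point to [start, end); 0 if inside."""
    if start <= center < end:
        return 0.0
    return start - center if center < start else center - end + 1


def nearest_feature(center: float, chromosome: str, index: _FeatureIndex,
                    max_distance: float, nucleosome_id: str = "") -> Association:
    """Nearest feature by edge distance, within max_distance (inclusive)."""
    if chromosome not in index.by_chrom:
        warnings.warn(f"chromosome {chromosome} absent from annotation")
        return Association(nucleosome_id, None, None, float("nan"), "none")
    feats = index.by_chrom[chromosome]
    starts, ends = index.arrays[chromosome]
    j = int(np.searchsorted(starts, center))
    best, bestd = None, np.inf
    # scan outwards from the insertion point; features are sorted by start
    for k in range(j - 1, -1, -1):
        if best is not None and starts[k] + bestd < center - max_distance:
            break
        d = _gap(center, starts[k], ends[k])
        if d < bestd:
            best, bestd = feats[k], d
    for k in range(j, len(feats)):
        if starts[k] - center > min(bestd, max_distance):
            break
        d = _gap(center, starts[k], ends[k])
        if d < bestd:
            best, bestd = feats[k], d
    if best is None or bestd > max_distance:
        return Association(nucleosome_id, None, None, float("nan"), "none")
    signed = _signed_distance(center, best)
    return Association(nucleosome_id, best.id, best.feature_type, signed)


def _signed_distance(center: float, g: GeneModel) -> float:
    """0 inside the feature; negative upstream of the TSS on the gene strand."""
    if g.start <= center < g.end:
        return 0.0
    gap = g.start - center if center < g.start else center - g.end + 1
    upstream = center < g.start if g.strand == "+" else center >= g.end
    return -gap if upstream else gap


def _promoter_bounds(g: GeneModel, window: float) -> tuple[float, float]:
    """Half-open [lo, hi) window immediately upstream of the TSS."""
    if g.strand == "+":
        return g.tss - window, g.tss
    return g.tss, g.tss + window


def _tts_bounds(g: GeneModel, up: float, down: float) -> tuple[float, float]:
    """Closed window around the TTS: `up` bp into the gene, `down` beyond."""
    if g.strand == "+":
        return g.tts - up, g.tts + down
    return g.tts - down, g.tts + up


def classify_position(center: float, chromosome: str, annotation: list[GeneModel],
                      params: AssociationParams) -> tuple[str, str | None]:
    """Position class of a nucleosome centered at `center`.

    promoter — inside exactly one gene's upstream promoter window;
    TTS — inside exactly one gene's TTS window; ambiguous — qualifying
    windows of two genes, or both windows of one gene, contain the
    center; body — inside a gene but in neither window; none otherwise.
    Returns (class, gene id or None).
    """
    hits: list[tuple[str, str]] = []  # (class, gene id)
    body_gene = None
    for g in annotation:
        if g.chromosome != chromosome or g.feature_type in ("TE",):
            continue
        lo, hi = _promoter_bounds(g, params.promoter_window)
        if lo <= center < hi:
            hits.append(("promoter", g.id))
        lo, hi = _tts_bounds(g, params.tts_window_up, params.tts_window_down)
        if lo <= center <= hi:
            hits.append(("TTS", g.id))
        if g.start <= center < g.end:
            body_gene = g.id
    if len(hits) == 0:
        return ("body", body_gene) if body_gene is not None else ("none", None)
    if len(hits) == 1:
        return hits[0]
    return "ambiguous", None


def associate_nucleosomes(centers: list[tuple[str, str, float]],
                          annotation: list[GeneModel],
                          params: AssociationParams | None = None
                          ) -> list[Association]:
    """Nearest-feature association plus position classification.

    `centers` is a list of (nucleosome id, chromosome, center bp).
    """
    params = params or AssociationParams()
    index = _FeatureIndex(annotation)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation:
        genes_by_chrom.setdefault(g.chromosome, []).append(g)
    out = []
    for nid, chrom, center in centers:
        assoc = nearest_feature(center, chrom, index, params.max_distance, nid)
        if assoc.feature_id is not None:
            cls, _gene = classify_position(center, chrom,
                                           genes_by_chrom.get(chrom, []), params)
            assoc.position_class = cls
        out.append(assoc)
    return out


def feature_composition(associations: list[Association]) -> pd.DataFrame:
    """Counts and fractions by feature type.

    `n_features` counts distinct associated features, `n_nucleosomes`
    counts associated nucleosomes; fractions are over the associated
    set and each column sums to 1 when any association exists.
    """
    feats: dict[str, str] = {}
    nuc_counts: Counter = Counter()
    for a in associations:
        if a.feature_id is None:
            continue
        feats[a.feature_id] = a.feature_type
        nuc_counts[a.feature_type] += 1
    feat_counts = Counter(feats.values())
    types = sorted(set(feat_counts) | set(nuc_counts))
    df = pd.DataFrame({
        "feature_type": types,
        "n_features": [feat_counts[t] for t in types],
        "n_nucleosomes": [nuc_counts[t] for t in types],
    }).set_index("feature_type")
    for col in ("n_features", "n_nucleosomes"):
        total = df[col].sum()
        df[f"frac_{col[2:]}"] = df[col] / total if total else 0.0
    return df


def enrichment_vs_random(observed_fraction: float, n_selected: int,
                         all_associations: list[Association],
                         feature_type: str = "protein_coding",
                         params: AssociationParams | None = None
                         ) -> tuple[float, float]:
    """Fold enrichment of a feature-type fraction over random nucleosome sets.

    Draws ``n_resamples`` subsets of size ``n_selected`` from the
    associations of all positioned nucleosomes, computes the
    feature-type fraction of each (over the associated members), and
    returns (observed/mean fold, two-tailed one-sample t-test p of the
    resampled fractions against the observed value).
    """
    params = params or AssociationParams()
    if n_selected > len(all_associations):
        raise ValueError("resample size exceeds the nucleosome population")
    rng = np.random.default_rng(params.seed)
    is_type = np.array([a.feature_type == feature_type and a.feature_id is not None
                        for a in all_associations])
    has_feat = np.array([a.feature_id is not None for a in all_associations])
    fracs = np.empty(params.n_resamples)
    n = len(all_associations)
    for i in range(params.n_resamples):
        idx = rng.choice(n, size=n_selected, replace=False)
        denom = has_feat[idx].sum()
        fracs[i] = is_type[idx].sum() / denom if denom else 0.0
    mean = fracs.mean()
    fold = observed_fraction / mean if mean else float("inf")
    if np.ptp(fracs) == 0 and fracs[0] == observed_fraction:
        return fold, 1.0
    t = stats.ttest_1samp(fracs, observed_fraction)
    return float(fold), float(t.pvalue)


def gene_h33_categories(genes: list[GeneModel],
                        associations: list[Association]
                        ) -> dict[str, str]:
    """Per-gene category from its unambiguous associations.

    promoter-only / TTS-only / both / none; body or ambiguous
    associations never contribute. The categories partition the genes.
    """
    has_prom: set[str] = set()
    has_tts: set[str] = set()
    for a in associations:
        if a.feature_id is None:
            continue
        if a.position_class == "promoter":
            has_prom.add(a.feature_id)
        elif a.position_class == "TTS":
            has_tts.add(a.feature_id)
    out = {}
    for g in genes:
        p, t = g.id in has_prom, g.id in has_tts
        out[g.id] = ("both" if p and t else
                     "promoter-only" if p else
                     "TTS-only" if t else "none")
    return out


def overlap_fraction(gene_set_a: set, gene_set_b: set) -> float:
    """|A intersect B| / |A|."""
    if not gene_set_a:
        raise ValueError("first gene set is empty")
    return len(set(gene_set_a) & set(gene_set_b)) / len(set(gene_set_a))
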
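"""Variant-enrichment scoring and mixture-model selection.

Each positioned nucleosome receives two window-median scores over the
147 bp around its center: an enrichment score (variant ChIP normalized
to bulk-histone ChIP) and a background noise score (non-immune IgG
normalized to bulk-histone). The genome-wide enrichment distribution
is deconvolved into a background and a specific component with a
two-component Gaussian mixture fitted by EM, and a nucleosome is
selected as variant-containing when (i) its posterior probability of
the specific component exceeds the threshold (default 75%) and (ii)
its enrichment exceeds ``noise_factor`` times its own noise score
(default 2x, evaluated as a fold change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .calling import NucleosomeCall
from .io import ProbeTrack


@dataclass
class ScoringParams:
    window: float = 147.0  # bp, the mono-nucleosomal footprint
    posterior_threshold: float = 0.75
    noise_factor: float = 2.0
    ratio_scale: str = "log2"  # channels are log2 signal; ratio = difference

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 < self.posterior_threshold < 1:
            raise ValueError("posterior_threshold must be in (0, 1)")
        if self.noise_factor <= 0:
            raise ValueError("noise_factor must be positive")
        if self.ratio_scale not in ("log2", "linear"):
            raise ValueError("ratio_scale must be 'log2' or 'linear'")


@dataclass
class MixtureModel:
    """Two-component univariate Gaussian mixture."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("mixture variances must be positive")

    @property
    def specific_index(self) -> int:
        """Index of the higher-mean (specific/enriched) component."""
        return int(np.argmax(self.means))


@dataclass
class ScoredNucleosome:
    call: NucleosomeCall
    enrichment: float  # window-median variant/histone ratio (log2 by default)
    noise: float  # window-median IgG/histone ratio
    posterior: float = np.nan  # P(specific component | enrichment)
    selected: bool = False

    @property
    def scored(self) -> bool:
        return np.isfinite(self.enrichment) and np.isfinite(self.noise)


def window_median_ratio(numerator: ProbeTrack, denominator: ProbeTrack,
                        center: float, window: float,
                        ratio_scale: str = "log2") -> float:
    """Median per-probe ratio in [center - window/2, center + window/2).

    Ratios are taken at probe positions present in both channels; on the
    log2 scale the per-probe ratio is the signal difference. Returns NaN
    when the window holds no shared probes (nucleosome left unscored).
    """
    lo, hi = center - window / 2.0, center + window / 2.0
    num = numerator.slice(lo, hi)
    den = denominator.slice(lo, hi)
    common, ia, ib = np.intersect1d(num.positions, den.positions,
                                    return_indices=True)
    if len(common) == 0:
        return float("nan")
    if ratio_scale == "log2":
        ratios = num.values[ia] - den.values[ib]
    else:
        ratios = num.values[ia] / den.values[ib]
    return float(np.median(ratios))


def fit_mixture(scores, seed: int | None = None, max_iter: int = 500,
                tol: float = 1e-8) -> MixtureModel:
    """EM fit of a 2-component unequal-variance Gaussian mixture.

    Deterministic: components are initialized at the 25th/75th
    percentiles of the data with the pooled variance and equal weights.
    Convergence when the log-likelihood improves by less than ``tol``.
    The ``seed`` argument is accepted for interface uniformity; the
    fit itself involves no randomness.
    """
    x = np.asarray([s for s in scores if np.isfinite(s)], dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 finite scores to fit a mixture")
    if np.ptp(x) == 0:
        raise ValueError(
            "degenerate data (all scores equal); fit a single component instead")

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    var = np.full(2, max(x.var(), 1e-12))
    w = np.array([0.5, 0.5])
    prev = -np.inf
    for _ in range(max_iter):
        logp = (np.log(w) - 0.5 * np.log(2 * np.pi * var)
                - (x[:, None] - mu) ** 2 / (2 * var))
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        loglik = float(lse.sum())
        r = np.exp(logp - lse[:, None])  # responsibilities
        nk = r.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        w = nk / len(x)
        mu = (r * x[:, None]).sum(axis=0) / nk
        var = (r * (x[:, None] - mu) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-12)
        if loglik - prev < tol:
            break
        prev = loglik
    return MixtureModel(weights=w, means=mu, variances=var, loglik=loglik)


def posterior_specific(model: MixtureModel, score) -> np.ndarray | float:
    """Bayes posterior of the higher-mean component at the given score(s).

    Computed in log space so extreme scores do not underflow.
    """
    x = np.asarray(score, dtype=float)
    logd = (np.log(model.weights)
            + norm.logpdf(x[..., None], loc=model.means,
                          scale=np.sqrt(model.variances)))
    k = model.specific_index
    post = 1.0 / (1.0 + np.exp(logd[..., 1 - k] - logd[..., k]))
    return float(post) if np.isscalar(score) else post


def score_nucleosomes(calls: list[NucleosomeCall],
                      variant: dict[str, ProbeTrack],
                      histone: dict[str, ProbeTrack],
                      igg: dict[str, ProbeTrack],
                      params: ScoringParams | None = None
                      ) -> list[ScoredNucleosome]:
    """Window-median enrichment and noise scores for every call."""
    params = params or ScoringParams()
    out = []
    for call in calls:
        v = variant.get(call.chromosome)
        h = histone.get(call.chromosome)
        g = igg.get(call.chromosome)
        if v is None or h is None or g is None:
            out.append(ScoredNucleosome(call, float("nan"), float("nan")))
            continue
        e = window_median_ratio(v, h, call.center, params.window, params.ratio_scale)
        n = window_median_ratio(g, h, call.center, params.window, params.ratio_scale)
        out.append(ScoredNucleosome(call, e, n))
    return out


def select_variant_nucleosomes(scored: list[ScoredNucleosome],
                               params: ScoringParams | None = None,
                               model: MixtureModel | None = None
                               ) -> tuple[list[ScoredNucleosome], MixtureModel]:
    """Apply the dual selection criteria (strict inequalities).

    The mixture is fitted on all finite enrichment scores unless a
    fitted model is supplied. A nucleosome is selected iff its posterior
    of the specific component exceeds ``posterior_threshold`` AND its
    enrichment exceeds ``noise_factor`` times its noise score as a fold
    change (on log2 scores: enrichment > log2(noise_factor) + noise).
    """
    params = params or ScoringParams()
    if model is None:
        model = fit_mixture([s.enrichment for s in scored])
    for s in scored:
        if not s.scored:
            s.posterior = float("nan")
            s.selected = False
            continue
        s.posterior = float(posterior_specific(model, s.enrichment))
        if params.ratio_scale == "log2":
            noise_ok = s.enrichment > np.log2(params.noise_factor) + s.noise
        else:
            noise_ok = s.enrichment > params.noise_factor * s.noise
        s.selected = bool(s.posterior > params.posterior_threshold and noise_ok)
    return scored, model
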
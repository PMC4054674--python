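"""End-to-end orchestration of the analysis stages.

Stages compose through plain TSV/BED/bedGraph files so each step of
the analysis is auditable on disk: call (variant + histone channels)
-> merge -> score -> select -> associate/classify -> metagene /
entropy / report. Every output starts with a header recording the
package version, a hash of the configuration and the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (AssociationParams, associate_nucleosomes,
                          feature_composition, gene_h33_categories)
from .calling import CallerParams, call_nucleosomes, merge_calls
from .io import (read_annotation, read_expression_table, read_probe_track,
                 write_nucleosome_calls)
from .metagene import bin_by_expression, grouped_profiles, metagene_profile
from .scoring import ScoringParams, score_nucleosomes, select_variant_nucleosomes
from .stats import expression_entropy, group_comparison_report

log = logging.getLogger("nucvar")


@dataclass
class PipelineConfig:
    variant_track: str = ""
    histone_track: str = ""
    igg_track: str = ""
    input_track: str = ""
    annotation: str = ""
    expression: str = ""
    outdir: str = "nucvar_out"
    seed: int = 0
    caller: CallerParams = field(default_factory=CallerParams)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    association: AssociationParams = field(default_factory=AssociationParams)
    metagene_flank: int = 3000
    metagene_bin_size: int = 50
    metagene_body_bins: int = 100
    expression_bins: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if f.name == "caller":
                val = CallerParams(**val)
            elif f.name == "scoring":
                val = ScoringParams(**val)
            elif f.name == "association":
                val = AssociationParams(**val)
            kwargs[f.name] = val
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header(self) -> str:
        return (f"nucvar v{__version__} config={self.config_hash()} "
                f"seed={self.seed}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the machine-readable summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.header()

    for name, path in (("variant", config.variant_track),
                       ("histone", config.histone_track),
                       ("igg", config.igg_track)):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"missing required channel track: {name}")

    log.info("reading channel tracks")
    variant = read_probe_track(config.variant_track)
    histone = read_probe_track(config.histone_track)
    igg = read_probe_track(config.igg_track)
    genes = read_annotation(
        config.annotation,
        expression=read_expression_table(config.expression)
        if config.expression else None)

    log.info("calling nucleosomes on the variant and histone channels")
    calls_v, calls_h = [], []
    for chrom in sorted(histone):
        calls_h.extend(call_nucleosomes(histone[chrom], config.caller,
                                        channel="histone"))
        if chrom in variant:
            calls_v.extend(call_nucleosomes(variant[chrom], config.caller,
                                            channel="variant"))
    merged = []
    for chrom in sorted({c.chromosome for c in calls_h + calls_v}):
        merged.extend(merge_calls(
            [c for c in calls_v if c.chromosome == chrom],
            [c for c in calls_h if c.chromosome == chrom],
            config.caller.merge_distance))

    log.info("scoring %d positioned nucleosomes", len(merged))
    scored = score_nucleosomes(merged, variant, histone, igg, config.scoring)
    scored, model = select_variant_nucleosomes(scored, config.scoring)
    write_nucleosome_calls(scored, outdir / "nucleosomes.bed",
                           outdir / "nucleosomes.tsv", header=header)
    selected = [s for s in scored if s.selected]

    log.info("associating %d selected nucleosomes with features", len(selected))
    sel_centers = [(f"nuc{i:06d}", s.call.chromosome, s.call.center)
                   for i, s in enumerate(scored) if s.selected]
    associations = associate_nucleosomes(sel_centers, genes, config.association)
    composition = feature_composition(associations)
    with open(outdir / "feature_composition.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        composition.to_csv(fh, sep="\t")

    categories = gene_h33_categories(genes, associations)
    cat_counts = pd.Series(categories).value_counts().to_dict()
    with open(outdir / "gene_categories.tsv", "w") as fh:
        fh.write(f"# {header}\n")
        pd.Series(categories, name="category").rename_axis("gene").to_csv(
            fh, sep="\t")

    entropy = {g.id: expression_entropy(g.expression, g.id).entropy
               for g in genes if len(g.expression)}
    if entropy:
        with open(outdir / "expression_entropy.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            pd.Series(entropy, name="entropy_bits").rename_axis("gene").to_csv(
                fh, sep="\t")
        report = group_comparison_report(entropy, categories)
        with open(outdir / "entropy_report.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            report.to_csv(fh, sep="\t", index=False)

    log.info("building metagene profiles")
    profile_genes = [g for g in genes if g.feature_type == "protein_coding"]
    try:
        profile = metagene_profile(variant, profile_genes,
                                   flank=config.metagene_flank,
                                   bin_size=config.metagene_bin_size,
                                   n_body_bins=config.metagene_body_bins)
        with open(outdir / "metagene_variant.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            profile.to_frame().to_csv(fh, sep="\t", index=False)
        ebins = bin_by_expression(profile_genes, n_bins=config.expression_bins)
        for key, prof in grouped_profiles(
                variant, profile_genes, ebins.assignment,
                flank=config.metagene_flank, bin_size=config.metagene_bin_size,
                n_body_bins=config.metagene_body_bins).items():
            with open(outdir / f"metagene_variant_bin{key}.tsv", "w") as fh:
                fh.write(f"# {header}\n")
                prof.to_frame().to_csv(fh, sep="\t", index=False)
    except ValueError as exc:
        log.warning("metagene stage skipped: %s", exc)

    n_assoc = sum(a.feature_id is not None for a in associations)
    summary = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "positioned_nucleosomes": len(merged),
        "selected_variant_nucleosomes": len(selected),
        "associated_nucleosomes": n_assoc,
        "associated_fraction": round(n_assoc / len(selected), 6) if selected else 0.0,
        "mixture_means": [round(float(m), 6) for m in np.sort(model.means)],
        "gene_categories": {k: int(v) for k, v in sorted(cat_counts.items())},
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
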
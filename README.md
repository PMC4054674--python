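# nucvar

Nucleosome-resolution analysis of histone-variant ChIP-chip tiling data.

Replication-independent histone variants such as H3.3 mark dynamic,
transcription-associated chromatin. Given normalized log2 probe signal
from mono-nucleosomal ChIP-chip experiments — a variant ChIP channel, a
bulk-histone ChIP channel, a non-immune IgG control and input — `nucvar`
answers, at single-nucleosome resolution: *where are the well-positioned
nucleosomes, which of them carry the variant, and what kind of genes and
gene regions do they mark?*

It is aimed at epigenomics researchers working with tiling-array (or any
probe-level) chromatin data who want an auditable, file-based pipeline
rather than an opaque peak caller.

## The method

1. **Nucleosome calling.** Probe signal is resampled to a uniform grid
   and smoothed with a Savitzky–Golay filter (which preserves peak
   areas, extremum positions and widths). Zeros of the first derivative
   mark nucleosome centers; zeros of the second derivative mark peak
   borders. Each candidate is least-squares fitted to a parabola
   `y = a(x − c)² + h` (the simplest analytical peak shape); the vertex
   gives the refined center and height, the border distance gives the
   width. On benchmark data with planted 147-bp footprints the fitted
   widths mode at ~150 bp — mono-nucleosome size. Calls from the variant
   and histone channels are merged into one list of positioned
   nucleosomes.
2. **Enrichment scoring and selection.** For each nucleosome the
   *enrichment score* is the median variant/histone log2 ratio in the
   147 bp around its center, and the *noise score* the median
   IgG/histone ratio in the same window. The genome-wide enrichment
   distribution is deconvolved into a background and a specific
   component with a two-component Gaussian mixture (EM, unequal
   variances). A nucleosome is selected as variant-containing when its
   posterior probability of the specific component exceeds 75% **and**
   its enrichment exceeds 2× its own noise score as a fold change.
3. **Feature association.** Selected nucleosomes are associated with
   the nearest annotated feature within 2,000 bp, classified as
   promoter- / TTS- / body-associated with strand-aware windows, and
   feature-type composition is tested against a resampling null drawn
   from all positioned nucleosomes. Genes are categorized as
   promoter-only / TTS-only / both / none.
4. **Profiles and regulation statistics.** Strand-aware metagene
   profiles (±3-kb flanks, percentage-scaled gene bodies), point-anchored
   profiles, a TSS→TTS matrix ordered by gene length, expression
   quartile bins, per-gene expression entropy
   `H = −Σ pᵢ log₂ pᵢ` (low entropy = condition-specific regulation) and
   Wilcoxon rank tests comparing gene categories.

A synthetic-data generator produces four-channel studies with known
planted truth (nucleosome positions, variant flags, gene models,
promoter classes, multi-condition expression), so the whole pipeline is
testable end to end without array data.

## Worked example

```sh
nucvar simulate --outdir demo/study --seed 11 \
    --genome-length 500000 --n-genes 110
cat > demo/config.yaml <<EOF
variant_track: demo/study/variant.bedgraph
histone_track: demo/study/histone.bedgraph
igg_track: demo/study/igg.bedgraph
annotation: demo/study/genes.gff3
expression: demo/study/expression.tsv
outdir: demo/out
seed: 11
EOF
nucvar run --config demo/config.yaml
```

prints (abridged):

```json
{
  "positioned_nucleosomes": 1300,
  "selected_variant_nucleosomes": 387,
  "associated_nucleosomes": 374,
  "associated_fraction": 0.966408,
  "mixture_means": [-1.646431, 1.228374],
  "gene_categories": {"TTS-only": 33, "both": 15, "none": 36,
                      "promoter-only": 26}
}
```

1,300 positioned nucleosomes were called on the 500-kb genome; the
mixture separated a background population (mean log2 ratio −1.6: the
variant ChIP sees nothing where only bulk histone sits) from a specific
one (+1.2), and 387 nucleosomes (≈30%, the planted variant fraction)
passed both selection criteria. 96.6% of them lie within 2 kb of an
annotated feature, and the per-gene categories split into
promoter-only/TTS-only/both as planted. `demo/out/` also holds the
scored calls (BED + TSV), feature composition, metagene profiles per
expression quartile and an entropy report per gene category.

Each stage is also runnable standalone (`nucvar call`, `score`,
`annotate`, `metagene`, `entropy`, `report`); see `--help` for the
parameters and their defaults (147-bp scoring window, 75% posterior,
2× noise, 2,000-bp association cut-off, ±3-kb flanks, 4 expression
bins).

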
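"""Readers and writers for the standard genomic formats the pipeline touches.

Coordinate conventions are fixed package-wide:

* internal coordinates are 0-based;
* bedGraph/BED are 0-based half-open on disk;
* GFF3 is 1-based closed on disk and converted on read/write;
* a probe's position is the midpoint of its bedGraph interval;
* a gene's TSS is its 5' boundary on its own strand, the TTS its 3'
  boundary, both expressed as 0-based half-open interval bounds (for a
  plus-strand gene spanning [start, end) the TSS is ``start`` and the
  TTS is ``end``; on the minus strand the two are swapped).

Output files written by the pipeline start with ``#`` header lines; all
readers here skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

FEATURE_TYPES = (
    "protein_coding",
    "pseudogene",
    "TE_gene",
    "TE",
    "miRNA",
    "tRNA",
    "ncRNA",
)

PROMOTER_CLASSES = ("TATA", "GA", "coreless", "unknown")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProbeTrack:
    """Per-chromosome tiling-array signal: sorted probe centers + one value each."""

    chromosome: str
    positions: np.ndarray  # int positions, strictly increasing
    values: np.ndarray  # float signal, same length

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("probe positions must be strictly increasing")
        if np.isnan(self.values).any():
            raise ValueError("NaN signal values are not allowed in a ProbeTrack")

    def __len__(self) -> int:
        return len(self.positions)

    def slice(self, start: float, end: float) -> "ProbeTrack":
        """Probes with start <= position < end."""
        i = np.searchsorted(self.positions, start, side="left")
        j = np.searchsorted(self.positions, end, side="left")
        return ProbeTrack(self.chromosome, self.positions[i:j], self.values[i:j])


@dataclass
class GeneModel:
    """A genomic feature with strand-aware anchors and an expression vector."""

    id: str
    chromosome: str
    strand: str  # '+' or '-'
    tss: int
    tts: int
    feature_type: str = "protein_coding"
    promoter_class: str = "unknown"
    expression: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=np.float64)
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.id}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature_type {self.feature_type!r}")
        if self.promoter_class not in PROMOTER_CLASSES:
            raise ValueError(f"unknown promoter_class {self.promoter_class!r}")
        if self.tss == self.tts:
            raise ValueError(f"degenerate gene interval for {self.id}")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"+ strand gene {self.id} must have TSS < TTS")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"- strand gene {self.id} must have TSS > TTS")
        if (self.expression < 0).any():
            raise ValueError(f"negative expression for {self.id}")

    @property
    def start(self) -> int:
        """0-based inclusive left bound of the feature interval."""
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        """0-based exclusive right bound of the feature interval."""
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# probe tracks


def read_probe_track(path, chromosome_filter: str | None = None) -> dict[str, ProbeTrack]:
    """Read a bedGraph or wig file into per-chromosome ProbeTracks.

    bedGraph intervals are converted to probe centers (midpoint, integer
    division). Returns a dict keyed by chromosome; empty dict for an
    empty file. Lines with NaN values are dropped.
    """
    path = Path(path)
    per_chrom: dict[str, tuple[list[int], list[float]]] = {}
    with open(path) as fh:
        first_data = fh.read(4096)
    is_wig = "fixedStep" in first_data or "variableStep" in first_data

    if is_wig:
        _read_wig(path, per_chrom)
    else:
        _read_bedgraph(path, per_chrom)

    out: dict[str, ProbeTrack] = {}
    for chrom, (pos, val) in per_chrom.items():
        if chromosome_filter is not None and chrom != chromosome_filter:
            continue
        p = np.asarray(pos, dtype=np.int64)
        v = np.asarray(val, dtype=np.float64)
        keep = ~np.isnan(v)
        out[chrom] = ProbeTrack(chrom, p[keep], v[keep])
    return out


def _read_bedgraph(path: Path, per_chrom: dict) -> None:
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: empty or inverted interval")
            if chrom in last_end and start < last_end[chrom]:
                raise FormatError(
                    f"{path}:{lineno}: unsorted or overlapping interval on {chrom}"
                )
            last_end[chrom] = end
            pos, val = per_chrom.setdefault(chrom, ([], []))
            pos.append((start + end) // 2)
            val.append(value)


def _read_wig(path: Path, per_chrom: dict) -> None:
    chrom = None
    mode = None
    step = span = 1
    nxt = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith(("fixedStep", "variableStep")):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                mode = line.split()[0]
                if mode == "fixedStep":
                    nxt = int(fields["start"]) - 1  # wig is 1-based
                    step = int(fields.get("step", 1))
                continue
            if chrom is None:
                raise FormatError(f"{path}:{lineno}: data before wig declaration")
            pos, val = per_chrom.setdefault(chrom, ([], []))
            if mode == "fixedStep":
                pos.append(nxt + span // 2)
                val.append(float(line))
                nxt += step
            else:
                p, v = line.split()
                pos.append(int(p) - 1 + span // 2)
                val.append(float(v))


def write_probe_track(track: ProbeTrack | Iterable[ProbeTrack], path,
                      span: int = 1, header: str | None = None) -> None:
    """Write ProbeTrack(s) as bedGraph with `span`-bp intervals centered on probes."""
    tracks = [track] if isinstance(track, ProbeTrack) else list(track)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for t in tracks:
            starts = t.positions - span // 2
            ends = starts + span
            for s, e, v in zip(starts, ends, t.values):
                fh.write(f"{t.chromosome}\t{s}\t{e}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path, expression: pd.DataFrame | None = None) -> list[GeneModel]:
    """Read gene models from GFF3.

    GFF3 1-based closed coordinates become internal 0-based half-open;
    TSS/TTS are assigned strand-aware. Records without strand are
    rejected with a warning; duplicate IDs raise. If an expression
    matrix (genes x conditions) is given, vectors are attached by ID.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _source, _ftype, start, end, _score, strand, _phase, attrs = parts
            attr = _parse_attrs(attrs)
            gid = attr.get("ID", f"line{lineno}")
            if strand not in ("+", "-"):
                warnings.warn(f"{path}:{lineno}: record {gid} has no strand; skipped")
                continue
            if gid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate ID {gid}")
            seen.add(gid)
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            tss, tts = (start0, end0) if strand == "+" else (end0, start0)
            expr = np.zeros(0)
            if expression is not None and gid in expression.index:
                expr = expression.loc[gid].to_numpy(dtype=float)
            genes.append(GeneModel(
                id=gid, chromosome=chrom, strand=strand, tss=tss, tts=tts,
                feature_type=attr.get("feature_type", "protein_coding"),
                promoter_class=attr.get("promoter_class", "unknown"),
                expression=expr,
            ))
    return genes


def _parse_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for item in attrs.split(";"):
        item = item.strip()
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def write_annotation(genes: Sequence[GeneModel], path, header: str | None = None) -> None:
    """Write gene models as GFF3 (feature/promoter class in the attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            fh.write(f"# {header}\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tnucvar\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.id};feature_type={g.feature_type};promoter_class={g.promoter_class}\n"
            )


# ---------------------------------------------------------------------------
# nucleosome calls and expression


def write_nucleosome_calls(calls, path_bed, path_tsv=None, header: str | None = None) -> None:
    """Write calls as BED6 (147-bp footprint around center) plus a TSV sidecar.

    BED start = center - 73, end = center + 74, clamped at 0 with a
    warning; score column is the enrichment when scored, else the
    fitted height. Works for both NucleosomeCall and ScoredNucleosome.
    """
    rows = []
    with open(path_bed, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for i, c in enumerate(calls):
            call = getattr(c, "call", c)
            center = int(round(call.center))
            start, end = center - 73, center + 74
            if start < 0:
                warnings.warn(f"call at center {center} clamped to chromosome start")
                start = 0
            score = getattr(c, "enrichment", call.height)
            name = f"nuc{i:06d}"
            fh.write(f"{call.chromosome}\t{start}\t{end}\t{name}\t{score:.6g}\t.\n")
            row = {
                "id": name, "chromosome": call.chromosome, "center": call.center,
                "width": call.width, "height": call.height, "channel": call.channel,
                "support_left": call.support[0], "support_right": call.support[1],
            }
            for attr in ("enrichment", "noise", "posterior", "selected"):
                if hasattr(c, attr):
                    row[attr] = getattr(c, attr)
            rows.append(row)
    if path_tsv is not None:
        with open(path_tsv, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_calls_table(path) -> pd.DataFrame:
    """Read the TSV sidecar written by write_nucleosome_calls."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_expression_table(path) -> pd.DataFrame:
    """Gene x condition expression matrix from TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df


def write_expression_table(df: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t")
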
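"""Readers and writers for the genomic and tabular formats the pipeline uses.

Formats handled: GTF (Gencode dialect, gene-level records), BED6 / ENCODE
narrowPeak, bedGraph coverage, and header-carrying TSV for counts, sample
metadata, decay time courses and qPCR Cq tables.

GTF is 1-based inclusive on disk and converted to the internal 0-based
half-open convention on read (and back on write).  BED-family formats are
already half-open and pass through unchanged.  All writers emit a fixed
column order and LF line endings so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .models import CODING, LNCRNA, CountMatrix, GeneModel, Peak, SampleMeta

# Gencode biotypes collapsed onto the binary coding/lncRNA scheme.  Biotypes
# absent from this table fall back to lncRNA (the non-coding bucket); pass a
# custom mapping to override.
DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": CODING,
    "lincRNA": LNCRNA,
    "lncRNA": LNCRNA,
    "antisense": LNCRNA,
    "processed_transcript": LNCRNA,
    "sense_intronic": LNCRNA,
    "sense_overlapping": LNCRNA,
    "3prime_overlapping_ncrna": LNCRNA,
    "bidirectional_promoter_lncrna": LNCRNA,
    "macro_lncRNA": LNCRNA,
}

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gene_models(
    path: str | Path,
    feature: str = "gene",
    biotype_map: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Read gene records from a Gencode-style GTF.

    Only lines whose feature column equals ``feature`` become genes; their
    ``exon`` children (matched by gene_id) are attached when present.
    Records with strand '.' are skipped with a warning.
    """
    bmap = dict(DEFAULT_BIOTYPE_MAP if biotype_map is None else biotype_map)
    genes: list[dict] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated GTF columns, got {len(fields)}")
            chrom, _source, feat, start, end, _score, strand, _frame, attrs = fields[:9]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            if feat == "exon" and gene_id:
                exons.setdefault(gene_id, []).append((start_i - 1, end_i))
                continue
            if feat != feature:
                continue
            if strand not in ("+", "-"):
                warnings.warn(f"{path}:{lineno}: strand {strand!r}, record skipped")
                continue
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing gene_id attribute")
            raw_bt = attr.get("gene_type", attr.get("gene_biotype", ""))
            genes.append(
                dict(
                    gene_id=gene_id,
                    biotype=bmap.get(raw_bt, LNCRNA),
                    chrom=chrom,
                    strand=strand,
                    # GTF 1-based inclusive -> 0-based half-open
                    start=start_i - 1,
                    end=end_i,
                )
            )
    out = []
    for g in genes:
        ex = tuple(sorted(exons.get(g["gene_id"], [])))
        out.append(GeneModel(exons=ex, **g))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path, source: str = "lncmyc") -> None:
    """Write gene (and exon) records as GTF, converting back to 1-based."""
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            bt = "protein_coding" if g.biotype == CODING else "lincRNA"
            attrs = f'gene_id "{g.gene_id}"; gene_type "{bt}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_peaks(path: str | Path) -> list[Peak]:
    """Read BED6 or ENCODE narrowPeak intervals (0-based half-open).

    narrowPeak column 10 (summit offset from start) is used when present and
    non-negative; otherwise the summit falls back to the interval midpoint.
    Offsets outside the peak are clamped with a warning.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({end} <= {start})")
            name = f[3] if len(f) > 3 and f[3] else f"peak_{lineno}"
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else 0.0
            summit = (start + end) // 2
            if len(f) >= 10:
                offset = int(f[9])
                if offset >= 0:
                    summit = start + offset
                    if summit >= end:
                        warnings.warn(f"{path}:{lineno}: summit offset {offset} outside peak, clamped")
                        summit = end - 1
            peaks.append(Peak(chrom=chrom, start=start, end=end, summit=summit, score=score, name=name))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks in narrowPeak format (summit as offset in column 10)."""
    with open(path, "w", newline="\n") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t"
                f"{p.score:g}\t-1\t-1\t{p.summit - p.start}\n"
            )


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "condition", "library", "cell_line", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing column(s) {sorted(missing)}")
    return [
        SampleMeta(
            name=r["name"], condition=r["condition"], library=r["library"],
            cell_line=r["cell_line"], replicate=int(r["replicate"]),
        )
        for r in df.to_dict("records")
    ]


def write_sample_metadata(samples: Iterable[SampleMeta], path: str | Path) -> None:
    rows = [
        dict(name=s.name, condition=s.condition, library=s.library,
             cell_line=s.cell_line, replicate=s.replicate)
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample-metadata TSV.

    The first column of the counts file holds gene_ids; header names must all
    be present in the metadata.  Negative or fractional entries are rejected.
    """
    samples = read_sample_metadata(metadata_path)
    by_name = {s.name: s for s in samples}
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    for col in df.columns:
        if col not in by_name:
            raise ValueError(f"sample {col!r} in counts header is missing from metadata")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError(f"{counts_path}: non-numeric count entries")
    if not np.issubdtype(vals.dtype, np.integer) and not np.allclose(vals, np.round(vals)):
        raise ValueError(f"{counts_path}: counts must be integers")
    if (vals < 0).any():
        raise ValueError(f"{counts_path}: counts must be non-negative")
    meta = [by_name[c] for c in df.columns]
    return CountMatrix(df.astype(np.int64), meta)


def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    df.to_csv(counts_path, sep="\t", lineterminator="\n")
    if metadata_path is not None:
        write_sample_metadata(cm.samples, metadata_path)


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read bedGraph coverage into per-chromosome (start, end, value) arrays.

    Returns chrom -> structured float array of shape (n, 3), interval-sorted.
    """
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            rows.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    return {
        c: np.array(sorted(v), dtype=float)
        for c, v in rows.items()
    }


def write_bedgraph(cov: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for chrom in sorted(cov):
            for s, e, v in cov[chrom]:
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:g}\n")


def read_decay_table(path: str | Path) -> pd.DataFrame:
    """Decay TSV with columns gene_id, time_min, abundance (one row per point)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "time_min", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"decay table {path}: missing column(s) {sorted(missing)}")
    return df


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Cq TSV with columns sample, gene, cq."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table {path}: missing column(s) {sorted(missing)}")
    return df
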
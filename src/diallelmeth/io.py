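"""Readers and writers for all external file formats.

Input formats are deliberately plain: a TSV of per-site counts, GFF3 for gene
models (only ``gene`` records are consumed; ``exon`` records are picked up when
present), BED for transposable-element intervals, and two small TSV lookup
tables (gene -> GO term, gene -> annotation class).  Output is TSV with a
manifest, byte-identical across runs for identical inputs.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ALLOWED_CONTEXTS,
    CrossDesign,
    GeneFeature,
    SiteCountTable,
    TeFeature,
)

META_COLUMNS = ["chrom", "pos", "context"]


def read_site_counts(path: str | Path) -> SiteCountTable:
    """Read a site-count TSV (chrom, pos, context, then one column per sample).

    Library sizes are set to the column sums over all rows in the file (both
    contexts jointly); use :meth:`per_context_library_sizes` downstream if a
    per-context denominator is wanted.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[: len(META_COLUMNS)] != META_COLUMNS:
        raise ValueError(
            f"{path}: header must start with {META_COLUMNS}, got {header[:3]}"
        )
    samples = header[len(META_COLUMNS) :]
    if not samples:
        raise ValueError(f"{path}: no sample columns")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "context": str})
    # locate malformed rows before any cast so errors carry a line number
    for col in ["pos"] + samples:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +header +1-based
        elif col != "pos" and (vals < 0).any():
            line = int(np.nonzero((vals < 0).to_numpy())[0][0]) + 2
        else:
            continue
        raise ValueError(f"{path}, line {line}: column {col!r} must be a non-negative integer")
    bad_ctx = ~df["context"].isin(ALLOWED_CONTEXTS)
    if bad_ctx.any():
        line = int(np.nonzero(bad_ctx.to_numpy())[0][0]) + 2
        raise ValueError(
            f"{path}, line {line}: context {df.loc[line - 2, 'context']!r} "
            f"not in {ALLOWED_CONTEXTS}"
        )
    sites = df[META_COLUMNS].copy()
    sites["pos"] = sites["pos"].astype(np.int64)
    counts = df[samples].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValueError(f"{path}: negative counts")
    return SiteCountTable(sites, counts, samples)


def per_context_library_sizes(table: SiteCountTable, context: str) -> np.ndarray:
    """Column sums restricted to one context (the alternative RPM denominator)."""
    mask = table.context_mask(context)
    sizes = table.counts[mask].sum(axis=0)
    if (sizes <= 0).any():
        raise ValueError(f"a sample has zero total counts in context {context}")
    return sizes


def write_site_counts(table: SiteCountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def _parse_gff_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in field.rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_annotation(
    path: str | Path, with_exons: bool = False
) -> list[GeneFeature] | tuple[list[GeneFeature], list[tuple[str, int, int]]]:
    """Read gene models from GFF3 (``gene`` records only).

    Coordinates stay 1-based inclusive as in GFF3; ``gene_id`` is taken from
    the ID attribute.  A strand of ``.`` is an error: flank labelling needs an
    orientation.  With ``with_exons=True`` also returns (chrom, start, end)
    tuples for ``exon`` records, for exon/intron sub-assignment.
    """
    genes: list[GeneFeature] = []
    exons: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}, line {lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs = fields
            if ftype == "exon":
                exons.append((chrom, int(start_s), int(end_s)))
                continue
            if ftype != "gene":
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ValueError(f"{path}, line {lineno}: start {start} > end {end}")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}, line {lineno}: gene strand must be + or -, got {strand!r}"
                )
            gene_id = _parse_gff_attributes(attrs).get("ID")
            if not gene_id:
                raise ValueError(f"{path}, line {lineno}: gene record lacks an ID attribute")
            genes.append(GeneFeature(gene_id, chrom, start, end, strand))
    if with_exons:
        return genes, exons
    return genes


def write_gene_annotation(genes: list[GeneFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tdiallelmeth\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_te_annotation(path: str | Path) -> list[TeFeature]:
    """Read TE intervals from BED (0-based half-open) into 1-based inclusive."""
    tes: list[TeFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >= 3 BED columns")
            chrom, start_s, end_s = fields[:3]
            bed_start, bed_end = int(start_s), int(end_s)
            if bed_start >= bed_end:
                raise ValueError(
                    f"{path}, line {lineno}: BED start {bed_start} >= end {bed_end}"
                )
            te_id = fields[3] if len(fields) > 3 else f"te{lineno}"
            tes.append(TeFeature(chrom, bed_start + 1, bed_end, te_id))
    return tes


def write_te_annotation(tes: list[TeFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tes:
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{t.te_id}\n")


def read_go_map(path: str | Path) -> pd.DataFrame:
    """Read a gene -> GO term TSV (gene_id, go_id, go_name); de-duplicated on
    (gene_id, go_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "go_id", "go_name"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: GO map needs columns {sorted(required)}")
    return df.drop_duplicates(["gene_id", "go_id"]).reset_index(drop=True)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a gene -> class/note TSV (e.g. transcription-factor / hormone labels)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns or "class" not in df.columns:
        raise ValueError(f"{path}: annotation table needs columns gene_id, class")
    dup = df[df.duplicated("gene_id", keep=False)]
    if len(dup):
        conflicting = dup.groupby("gene_id")["class"].nunique()
        if (conflicting > 1).any():
            bad = conflicting[conflicting > 1].index.tolist()
            raise ValueError(f"{path}: conflicting classes for gene(s) {bad}")
    return df.drop_duplicates("gene_id").reset_index(drop=True)


def read_design(path: str | Path) -> CrossDesign:
    """Read a cross design from YAML (parents / hybrids / combinations)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CrossDesign(
        parents=dict(raw["parents"]),
        hybrids=[(h["name"], h["maternal"], h["paternal"]) for h in raw["hybrids"]],
        combinations=[
            (c["name"], c["a"], c["b"]) for c in raw.get("combinations", [])
        ],
    )


def write_design(design: CrossDesign, path: str | Path) -> None:
    raw = {
        "parents": design.parents,
        "hybrids": [
            {"name": n, "maternal": m, "paternal": p} for n, m, p in design.hybrids
        ],
        "combinations": [
            {"name": n, "a": a, "b": b} for n, a, b in design.combinations
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write each named table as ``<name>.tsv`` under ``out_dir``; floats get 6
    significant digits.  Returns (and writes) a manifest of filenames, row
    counts and content checksums."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, df in tables.items():
        fname = f"{name}.tsv"
        fpath = out_dir / fname
        df.to_csv(fpath, sep="\t", index=False, float_format="%.6g")
        digest = hashlib.sha256(fpath.read_bytes()).hexdigest()
        rows.append({"table": name, "file": fname, "n_rows": len(df), "sha256": digest})
    manifest = pd.DataFrame(rows, columns=["table", "file", "n_rows", "sha256"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
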
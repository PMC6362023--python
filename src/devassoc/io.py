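"""Readers and writers for the pipeline's text formats.

Dialects
--------
expression  TSV, genes × samples; first column ``gene_id``.
samples     TSV with header sample_id, subject_id, age, stage, region, RIN,
            ethnicity, sex.
sumstats    whitespace-delimited with header containing at least
            SNP CHR BP P; MAF and INFO optional.
gene.loc    6 tab-separated columns: gene id, chromosome, start, end,
            strand, biotype — 1-based inclusive coordinates.
GMT         term id, term name, then member fields; a member field may carry
            an evidence code as ``GENE|CODE``. The source (GO/MP) is the
            term-id prefix before the colon.
BED         standard 0-based half-open exclusion intervals; converted to the
            internal 1-based inclusive convention on read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .pathways import TermCollection

__all__ = [
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_sumstats",
    "write_sumstats",
    "read_gene_loc",
    "write_gene_loc",
    "read_gmt",
    "write_gmt",
    "read_bed_exclusions",
    "read_ld_dir",
    "write_ld_dir",
]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    if df.index.hasnans:
        raise ValueError(f"{path}: expression rows with missing gene id")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


_SAMPLE_COLS = ["sample_id", "subject_id", "age", "stage", "region", "RIN", "ethnicity", "sex"]


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample_id", "stage", "region", "RIN") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sample table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    required = ["SNP", "CHR", "BP", "P"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: summary statistics missing columns {missing}")
    df["CHR"] = df["CHR"].astype(str)
    bad = df.index[(df["P"] <= 0) | (df["P"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: invalid p-value at data line {bad[0] + 1}")
    return df


def write_sumstats(snps: pd.DataFrame, path) -> None:
    cols = [c for c in ["SNP", "CHR", "BP", "P", "MAF", "INFO"] if c in snps.columns]
    snps[cols].to_csv(path, sep=" ", index=False)


def read_gene_loc(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 tab-separated fields, got {len(parts)}")
            gid, chrom, start, end, strand, biotype = parts
            if strand not in {"+", "-"}:
                raise ValueError(f"{path}:{ln}: bad strand {strand!r}")
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"{path}:{ln}: start > end")
            rows.append((gid, chrom, start_i, end_i, strand, biotype))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"])
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def write_gene_loc(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand", "biotype"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gmt(path) -> TermCollection:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 fields, got {len(parts)}")
            term_id, name = parts[0], parts[1]
            source = term_id.split(":", 1)[0] if ":" in term_id else "GO"
            for field in parts[2:]:
                if not field:
                    continue
                gene, _, code = field.partition("|")
                rows.append((term_id, source, name, gene, code or "NA"))
    return TermCollection(
        pd.DataFrame(rows, columns=["term_id", "source", "name", "gene_id", "evidence"])
    )


def write_gmt(terms: TermCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id, d in terms.frame.groupby("term_id", sort=True):
            name = d["name"].iloc[0]
            fields = [f"{g}|{e}" for g, e in zip(d["gene_id"], d["evidence"])]
            fh.write("\t".join([term_id, name] + fields) + "\n")


def read_bed_exclusions(path) -> tuple[tuple[str, int, int], ...]:
    """BED intervals (0-based half-open) as 1-based inclusive tuples."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.append((chrom.removeprefix("chr"), start + 1, end))
    return tuple(out)


def write_ld_dir(ld: dict[str, tuple[list[str], np.ndarray]], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, (ids, R) in ld.items():
        with open(outdir / f"{gid}.ld", "w") as fh:
            fh.write("\t".join(ids) + "\n")
            for row in R:
                fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


def read_ld_dir(path) -> dict[str, tuple[list[str], np.ndarray]]:
    out = {}
    for f in sorted(Path(path).glob("*.ld")):
        with open(f) as fh:
            ids = fh.readline().rstrip("\n").split("\t")
            R = np.loadtxt(fh, ndmin=2)
        if R.shape != (len(ids), len(ids)):
            raise ValueError(f"{f}: LD matrix shape {R.shape} does not match {len(ids)} SNP ids")
        out[f.stem] = (ids, R)
    return out
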
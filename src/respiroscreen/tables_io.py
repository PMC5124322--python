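"""Readers and writers for the tabular formats the pipeline consumes and emits.

Formats handled:

* colony-size tables (TSV, one row per spotted colony) as produced by plate
  quantifiers such as gitter;
* gene maps in BED (0-based half-open) or GFF3 (1-based inclusive), normalised
  internally to 1-based inclusive coordinates and sorted per chromosome;
* gene sets in GMT;
* result tables as TSV plus a JSON run summary.

All readers validate strictly and raise :class:`~respiroscreen.errors.DataError`
with row-addressed messages on malformed input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError, ValidationError

COLONY_COLUMNS = ["plate_id", "medium", "row", "col", "strain_id", "size", "missing"]
GENEMAP_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype", "rank"]
BIOTYPES = frozenset({"coding", "ncRNA"})


# ---------------------------------------------------------------------------
# Colony tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColonyTable:
    """Per-colony raw measurements keyed by plate and position.

    ``data`` has columns ``plate_id, medium, row, col, strain_id, size,
    missing``; ``size`` is NaN exactly where ``missing`` is True.
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ColonyTable":
        df = df.copy()
        required = [c for c in COLONY_COLUMNS if c != "missing"]
        for col in required:
            if col not in df.columns:
                raise DataError(f"colony table missing required column {col!r}")
        df["row"] = df["row"].astype(int)
        df["col"] = df["col"].astype(int)
        if (df["row"] < 1).any() or (df["col"] < 1).any():
            raise DataError("colony positions must be positive integers")
        size = pd.to_numeric(df["size"], errors="coerce")
        # quantifiers emit zeros (or blanks) for absent colonies
        missing = size.isna() | (size <= 0)
        df["size"] = size.where(~missing, np.nan)
        df["missing"] = missing.to_numpy()
        dup = df.duplicated(subset=["plate_id", "row", "col"], keep=False)
        if dup.any():
            first = df.loc[dup, ["plate_id", "row", "col"]].iloc[0]
            raise DataError(
                "duplicated colony position (plate_id=%r, row=%d, col=%d)"
                % (first["plate_id"], first["row"], first["col"])
            )
        return cls(df[COLONY_COLUMNS].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)


def read_colony_table(path, dialect: str = "generic", *, plate_id: str | None = None,
                      medium: str = "unknown") -> ColonyTable:
    """Read a colony-size table.

    ``dialect="generic"`` expects a TSV with header columns
    ``plate_id, medium, row, col, strain_id, size``.  ``dialect="quantifier-dat"``
    accepts a gitter-style whitespace table (``#`` comment lines; columns
    ``row, col, size`` and optionally ``strain_id``), with plate identity taken
    from ``plate_id`` or the file stem.
    """
    path = Path(path)
    if dialect == "generic":
        df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "strain_id": str})
        for col in ["plate_id", "medium", "row", "col", "strain_id", "size"]:
            if col not in df.columns:
                raise DataError(f"{path}: missing column {col!r}")
        raw = df["size"]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            # +2: one for the header line, one for 0-based index
            lineno = int(bad.idxmax()) + 2
            raise DataError(f"{path}: non-numeric size {raw[bad.idxmax()]!r} at line {lineno}")
        df["size"] = coerced
    elif dialect == "quantifier-dat":
        df = pd.read_csv(path, sep=r"\s+", comment="#", engine="python")
        for col in ["row", "col", "size"]:
            if col not in df.columns:
                raise DataError(f"{path}: quantifier table missing column {col!r}")
        if "strain_id" not in df.columns:
            df["strain_id"] = [f"r{r}c{c}" for r, c in zip(df["row"], df["col"])]
        df["plate_id"] = plate_id if plate_id is not None else path.stem
        df["medium"] = medium
    else:
        raise ValidationError(f"unknown colony-table dialect {dialect!r}")
    return ColonyTable.from_frame(df)


def write_colony_table(table: ColonyTable, path) -> None:
    df = table.data.drop(columns=["missing"]).copy()
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Gene maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneMap:
    """Ordered genes with coordinates, strand and biotype.

    Internally 1-based inclusive; rows sorted by (chrom, start); ``rank`` is
    the 1-based genomic order position within each chromosome, the coordinate
    system of the sliding-window scan.
    """

    data: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneMap":
        df = df.copy()
        for col in ["gene_id", "chrom", "start", "end", "strand", "biotype"]:
            if col not in df.columns:
                raise DataError(f"gene map missing column {col!r}")
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        bad = df["end"] < df["start"]
        if bad.any():
            g = df.loc[bad, "gene_id"].iloc[0]
            raise DataError(f"gene {g!r}: end < start")
        unknown = ~df["biotype"].isin(BIOTYPES)
        if unknown.any():
            g = df.loc[unknown].iloc[0]
            raise DataError(f"gene {g['gene_id']!r}: unknown biotype {g['biotype']!r}")
        if not df["strand"].isin(["+", "-"]).all():
            raise DataError("strand must be '+' or '-'")
        if df["gene_id"].duplicated().any():
            g = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise DataError(f"duplicate gene_id {g!r}")
        df = df.sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort")
        df["rank"] = df.groupby("chrom", sort=False).cumcount() + 1
        return cls(df[GENEMAP_COLUMNS].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.data["gene_id"])

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.data["chrom"]))


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_gene_map(path, format: str | None = None) -> GeneMap:
    """Read a gene map from BED or GFF3.

    BED input is 0-based half-open with columns
    ``chrom start end name [score strand biotype]``; GFF3 input keeps only
    ``gene`` features, with the gene id taken from the ``ID`` (or ``gene_id``)
    attribute and the biotype from a ``biotype`` attribute.  Both default to
    ``coding`` when the biotype is omitted and to ``+`` strand.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"bed": "bed", ".bed": "bed", ".gff": "gff3", ".gff3": "gff3"}.get(
            suffix, None)
        if format is None:
            raise ValidationError(f"cannot infer gene-map format from {path.name!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "bed":
                if len(fields) < 4:
                    raise DataError(f"{path}:{lineno}: BED line has <4 fields")
                chrom, start0, end, name = fields[:4]
                strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
                biotype = fields[6] if len(fields) > 6 and fields[6] else "coding"
                try:
                    start = int(start0) + 1
                    end = int(end)
                except ValueError:
                    raise DataError(f"{path}:{lineno}: non-integer coordinates") from None
            elif format == "gff3":
                if len(fields) != 9:
                    raise DataError(f"{path}:{lineno}: GFF3 line must have 9 fields")
                chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
                if ftype != "gene":
                    continue
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise DataError(f"{path}:{lineno}: non-integer coordinates") from None
                attr = _parse_gff3_attributes(attrs)
                name = attr.get("ID") or attr.get("gene_id")
                if name is None:
                    raise DataError(f"{path}:{lineno}: gene feature lacks ID attribute")
                biotype = attr.get("biotype", "coding")
                if strand not in "+-":
                    strand = "+"
            else:
                raise ValidationError(f"unknown gene-map format {format!r}")
            records.append((name, chrom, start, end, strand, biotype))
    df = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand",
                                        "biotype"])
    return GeneMap.from_frame(df)


def write_gene_map(gene_map: GeneMap, path, format: str = "bed") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "bed":
            for rec in gene_map.data.itertuples():
                fh.write(f"{rec.chrom}\t{rec.start - 1}\t{rec.end}\t{rec.gene_id}\t0\t"
                         f"{rec.strand}\t{rec.biotype}\n")
        elif format == "gff3":
            fh.write("##gff-version 3\n")
            for rec in gene_map.data.itertuples():
                fh.write(f"{rec.chrom}\trespiroscreen\tgene\t{rec.start}\t{rec.end}\t.\t"
                         f"{rec.strand}\t.\tID={rec.gene_id};biotype={rec.biotype}\n")
        else:
            raise ValidationError(f"unknown gene-map format {format!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSets:
    """Named gene sets; names unique, members non-empty."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSets:
    out = GeneSets()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(f"{path}:{lineno}: GMT line needs name and description")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in out.sets:
                raise DataError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not members:
                warnings.warn(f"{path}:{lineno}: empty gene set {name!r} skipped")
                continue
            out.sets[name] = frozenset(members)
            out.descriptions[name] = desc
    return out


def write_gmt(gene_sets: GeneSets, path) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            desc = gene_sets.descriptions.get(name, "")
            members = "\t".join(sorted(gene_sets.sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Result writers
# ---------------------------------------------------------------------------

def write_results(tables: Mapping[str, pd.DataFrame], outdir,
                  summary: Mapping | None = None) -> list[Path]:
    """Write result tables as TSV (stable column order) plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=bool(df.index.name))
        written.append(p)
    if summary is not None:
        p = outdir / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written.append(p)
    return written
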
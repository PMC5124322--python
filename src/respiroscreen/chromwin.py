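"""Chromosomal co-regulation: ten-gene sliding-window scan and ncRNA adjacency.

Windows are runs of ten neighbouring genes in chromosomal order (coding and
non-coding alike, strand-agnostic), sliding by one gene and never spanning a
chromosome boundary.  A window is flagged "induced" when at least ``min_count``
of its genes change more than ``fold``-fold upward (log2FC > log2(fold)), and
"repressed" symmetrically; genes without fold-change data count as
non-qualifying but keep their place in the gene order, preserving genomic
adjacency.  Overlapping or abutting same-direction windows merge into maximal
regions.  The adjacency statistic asks, for each differentially expressed
ncRNA, whether its immediate chromosomal neighbour (rank +/- 1, no
wraparound) is a differentially expressed coding gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genesets import _as_log2fc
from .tables_io import GeneMap

WINDOW_COLUMNS = ["chrom", "start_rank", "end_rank", "direction", "count", "members"]


@dataclass(frozen=True)
class WindowRegion:
    """A maximal run of merged flagged windows on one chromosome."""

    chrom: str
    start_rank: int
    end_rank: int
    direction: str
    max_count: int
    members: tuple[str, ...]

    @property
    def n_genes(self) -> int:
        return self.end_rank - self.start_rank + 1


def _fold_change_series(fold_changes) -> pd.Series:
    if isinstance(fold_changes, Mapping) and not isinstance(fold_changes, pd.Series):
        return pd.Series(fold_changes, dtype=float)
    return _as_log2fc(fold_changes)


def scan_windows(gene_map: GeneMap, fold_changes, window: int = 10,
                 min_count: int = 6, fold: float = 2.0) -> pd.DataFrame:
    """Flag sliding windows with >= ``min_count`` co-directional changed genes.

    Returns one row per flagged (window, direction) with gene-rank span,
    qualifying-gene count and the qualifying members.  A window may in
    principle be flagged in both directions; chromosomes shorter than the
    window yield no windows.
    """
    if window < 1 or min_count < 1:
        raise ValidationError("window and min_count must be positive")
    fc = _fold_change_series(fold_changes)
    thr = np.log2(fold)
    gm = gene_map.data
    values = fc.reindex(gm["gene_id"]).to_numpy()
    up = np.nan_to_num(values, nan=0.0) > thr
    down = np.nan_to_num(values, nan=0.0) < -thr
    rows = []
    for chrom, idx in gm.groupby("chrom", sort=False).indices.items():
        genes = gm["gene_id"].to_numpy()[idx]
        m = len(idx)
        if m < window:
            continue
        for mask, direction in ((up[idx], "induced"), (down[idx], "repressed")):
            csum = np.concatenate([[0], np.cumsum(mask)])
            counts = csum[window:] - csum[:-window]
            for start in np.nonzero(counts >= min_count)[0]:
                members = tuple(genes[start:start + window][mask[start:start + window]])
                rows.append((chrom, start + 1, start + window, direction,
                             int(counts[start]), members))
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def merge_windows(flagged: pd.DataFrame) -> list[WindowRegion]:
    """Merge overlapping/adjacent same-direction flagged windows into maximal
    regions (per chromosome), recording the maximal per-window count."""
    regions: list[WindowRegion] = []
    if len(flagged) == 0:
        return regions
    for (chrom, direction), grp in flagged.groupby(["chrom", "direction"], sort=False):
        grp = grp.sort_values("start_rank")
        cur = None
        for rec in grp.itertuples():
            if cur is None or rec.start_rank > cur["end_rank"] + 1:
                if cur is not None:
                    regions.append(_close_region(cur))
                cur = {"chrom": chrom, "direction": direction,
                       "start_rank": int(rec.start_rank), "end_rank": int(rec.end_rank),
                       "max_count": rec.count, "members": set(rec.members)}
            else:
                cur["end_rank"] = max(cur["end_rank"], int(rec.end_rank))
                cur["max_count"] = max(cur["max_count"], rec.count)
                cur["members"] |= set(rec.members)
        if cur is not None:
            regions.append(_close_region(cur))
    regions.sort(key=lambda r: (r.chrom, r.start_rank, r.direction))
    return regions


def _close_region(cur: dict) -> WindowRegion:
    return WindowRegion(chrom=cur["chrom"], start_rank=cur["start_rank"],
                        end_rank=cur["end_rank"], direction=cur["direction"],
                        max_count=int(cur["max_count"]),
                        members=tuple(sorted(cur["members"])))


def find_regions(gene_map: GeneMap, fold_changes, window: int = 10,
                 min_count: int = 6, fold: float = 2.0) -> list[WindowRegion]:
    """Scan and merge in one call."""
    return merge_windows(scan_windows(gene_map, fold_changes, window=window,
                                      min_count=min_count, fold=fold))


def regions_to_bed(regions: Iterable[WindowRegion], gene_map: GeneMap, path) -> None:
    """Write merged regions as BED (name = direction, score = max_count)."""
    gm = gene_map.data
    with open(path, "w") as fh:
        for reg in regions:
            sub = gm[(gm["chrom"] == reg.chrom) & (gm["rank"] >= reg.start_rank)
                     & (gm["rank"] <= reg.end_rank)]
            start_bp = int(sub["start"].min()) - 1
            end_bp = int(sub["end"].max())
            fh.write(f"{reg.chrom}\t{start_bp}\t{end_bp}\t{reg.direction}\t"
                     f"{reg.max_count}\t.\n")


# ---------------------------------------------------------------------------
# ncRNA adjacency
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyResult:
    """Fraction of DE ncRNAs adjacent to a DE coding gene, plus the pairs.

    ``fraction`` is None (undefined, not zero) when there are no DE ncRNAs.
    """

    fraction: float | None
    n_de_ncrna: int
    pairs: list[tuple[str, str]]


def ncrna_adjacency(gene_map: GeneMap, de_coding: Iterable[str],
                    de_ncrna: Iterable[str]) -> AdjacencyResult:
    """Adjacency of differentially expressed ncRNAs to DE coding genes.

    A DE ncRNA is adjacent when the gene immediately preceding or following it
    in chromosomal rank order is a DE coding gene; chromosome ends have a
    single neighbour and there is no wraparound.
    """
    de_coding = frozenset(de_coding)
    de_ncrna = frozenset(de_ncrna)
    known = frozenset(gene_map.data["gene_id"])
    for name, s in (("de_coding", de_coding), ("de_ncrna", de_ncrna)):
        extra = s - known
        if extra:
            raise ValidationError(f"{name} contains genes absent from the gene map "
                                  f"(e.g. {sorted(extra)[:5]})")
    gm = gene_map.data
    pairs: list[tuple[str, str]] = []
    adjacent: set[str] = set()
    for _chrom, idx in gm.groupby("chrom", sort=False).indices.items():
        genes = gm["gene_id"].to_numpy()[idx]
        biotypes = gm["biotype"].to_numpy()[idx]
        for i, gene in enumerate(genes):
            if gene not in de_ncrna:
                continue
            for j in (i - 1, i + 1):
                if 0 <= j < len(genes):
                    neighbour = genes[j]
                    if neighbour in de_coding and biotypes[j] == "coding":
                        pairs.append((gene, neighbour))
                        adjacent.add(gene)
    n = len(de_ncrna)
    fraction = len(adjacent) / n if n else None
    return AdjacencyResult(fraction=fraction, n_de_ncrna=n, pairs=sorted(pairs))
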
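"""Colony-array screen scoring: plate normalization, replicate medians,
respiratory/fermentative ratios, hit calling and mutant clustering.

The phenotype score of a deletion strain is its normalized colony size on a
respiratory medium (glycerol or galactose, optionally with an oxidative-
phosphorylation inhibitor) divided by its normalized size on glucose measured
in parallel.  Sizes are normalized to the plate median (which cancels
plate-wide multiplicative effects exactly), replicate colonies are aggregated
by the median of four spots, ratios below a floor (default 0.2) are clamped,
strains with data missing in any screen are removed, and a strain is a hit in
a screen when its ratio falls strictly below 0.85.  Multi-screen ratio
profiles are clustered (SOM by default, 12 clusters) and clusters whose median
profiles are deficient predominantly in prototroph- or auxotroph-background
screens are flagged P-like or A-like.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import ClusterResult, cluster_matrix
from .errors import DataError, ValidationError
from .tables_io import ColonyTable

BACKGROUNDS = ("prototroph", "auxotroph")
RESPIRATORY_MEDIA = ("glycerol", "galactose")
DRUGS = ("none", "antimycinA", "DNP")


# ---------------------------------------------------------------------------
# Screen design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Screen:
    screen_id: str
    background: str
    respiratory_medium: str
    drug: str
    fermentative_reference_id: str

    def __post_init__(self):
        if self.background not in BACKGROUNDS:
            raise ValidationError(f"unknown background {self.background!r}")
        if self.respiratory_medium not in RESPIRATORY_MEDIA:
            raise ValidationError(f"unknown respiratory medium {self.respiratory_medium!r}")
        if self.drug not in DRUGS:
            raise ValidationError(f"unknown drug {self.drug!r}")


@dataclass(frozen=True)
class ScreenDesign:
    """The set of respiratory screens, each paired with a parallel
    fermentative (glucose) reference."""

    screens: tuple[Screen, ...]

    def __post_init__(self):
        ids = [s.screen_id for s in self.screens]
        if len(set(ids)) != len(ids):
            raise ValidationError("screen_ids must be unique")

    def __iter__(self):
        return iter(self.screens)

    def __len__(self):
        return len(self.screens)

    @property
    def screen_ids(self) -> list[str]:
        return [s.screen_id for s in self.screens]

    def by_background(self, background: str) -> list[str]:
        return [s.screen_id for s in self.screens if s.background == background]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.screens])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScreenDesign":
        cols = ["screen_id", "background", "respiratory_medium", "drug",
                "fermentative_reference_id"]
        for c in cols:
            if c not in df.columns:
                raise DataError(f"screen design missing column {c!r}")
        return cls(tuple(Screen(**{c: row[c] for c in cols})
                         for _, row in df.iterrows()))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScreenDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def default_design() -> ScreenDesign:
    """The nine-screen layout: seven prototroph screens (two biological
    repeats each on galactose and glycerol, plus three drug screens) and two
    auxotroph screens."""
    spec = [
        ("P_GAL_1", "prototroph", "galactose", "none"),
        ("P_GAL_2", "prototroph", "galactose", "none"),
        ("P_GLY_1", "prototroph", "glycerol", "none"),
        ("P_GLY_2", "prototroph", "glycerol", "none"),
        ("P_GAL_ANT", "prototroph", "galactose", "antimycinA"),
        ("P_GLY_ANT", "prototroph", "glycerol", "antimycinA"),
        ("P_GLY_DNP", "prototroph", "glycerol", "DNP"),
        ("A_GAL", "auxotroph", "galactose", "none"),
        ("A_GLY", "auxotroph", "glycerol", "none"),
    ]
    return ScreenDesign(tuple(
        Screen(sid, bg, medium, drug, f"{sid}_GLU") for sid, bg, medium, drug in spec))


# ---------------------------------------------------------------------------
# Ratio table
# ---------------------------------------------------------------------------

@dataclass
class RatioTable:
    """Strain x screen matrix of floored respiratory/fermentative ratios."""

    values: pd.DataFrame
    floor: float = 0.2
    provenance: dict | None = None

    @property
    def strains(self) -> pd.Index:
        return self.values.index

    @property
    def screen_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        df = self.values.copy()
        df.index.name = "strain_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, floor: float = 0.2) -> "RatioTable":
        df = pd.read_csv(path, sep="\t", index_col="strain_id")
        return cls(values=df, floor=floor)


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------

def normalize_plate(colony_table: ColonyTable) -> ColonyTable:
    """Divide every colony size by the median non-missing size of its plate.

    The median of an even number of values is the mean of the two middle
    values.  Missing colonies propagate; a plate with no measurable colony is
    an error.
    """
    df = colony_table.data.copy()
    medians = df.groupby("plate_id")["size"].median()
    dead = medians.index[medians.isna()]
    if len(dead):
        raise DataError(f"plate {dead[0]!r} has no non-missing colonies")
    df["size"] = df["size"] / df["plate_id"].map(medians)
    return ColonyTable(df)


def aggregate_replicates(colony_table: ColonyTable,
                         replicate_map: Mapping[str, list] | None = None,
                         min_present: int = 2) -> pd.Series:
    """Median of replicate colony values per strain.

    ``replicate_map`` optionally maps strain_id -> list of (plate_id, row, col)
    positions; by default replicates are grouped by the table's strain_id
    column.  Strains with fewer than ``min_present`` non-missing replicates
    are reported missing (NaN).
    """
    df = colony_table.data
    if replicate_map is not None:
        pos_index = df.set_index(["plate_id", "row", "col"])["size"]
        out = {}
        for strain, positions in replicate_map.items():
            if not positions:
                raise DataError(f"strain {strain!r} has no mapped positions")
            vals = pos_index.reindex(pd.MultiIndex.from_tuples(positions))
            out[strain] = _median_if_enough(vals.to_numpy(), min_present)
        return pd.Series(out, name="size").sort_index()
    grouped = df.groupby("strain_id")["size"]
    med = grouped.median()
    n_present = grouped.count()
    med[n_present < min_present] = np.nan
    med.name = "size"
    return med


def _median_if_enough(values: np.ndarray, min_present: int) -> float:
    vals = values[~np.isnan(values)]
    if len(vals) < min_present:
        return np.nan
    return float(np.median(vals))


def compute_ratios(respiratory: Mapping[str, pd.Series],
                   fermentative: Mapping[str, pd.Series],
                   floor: float = 0.2, drop_incomplete: bool = True) -> RatioTable:
    """Respiratory/fermentative size ratios per strain and screen.

    A fermentative size of zero (or missing either side) marks the strain
    missing in that screen; with ``drop_incomplete`` strains missing in any
    screen are removed before flooring.  Ratios below ``floor`` are clamped.
    """
    if set(respiratory) != set(fermentative):
        raise ValidationError("respiratory and fermentative screens must match")
    cols = {}
    for screen_id in respiratory:
        resp = respiratory[screen_id].astype(float)
        ferm = fermentative[screen_id].astype(float).reindex(resp.index)
        ferm = ferm.where(ferm != 0, np.nan)
        cols[screen_id] = resp / ferm
    mat = pd.DataFrame(cols)
    if drop_incomplete:
        mat = mat.dropna(axis=0, how="any")
    mat = mat.clip(lower=floor)
    mat.index.name = "strain_id"
    return RatioTable(values=mat, floor=floor,
                      provenance={"floor": floor, "drop_incomplete": drop_incomplete})


def call_hits(ratio_table: RatioTable, threshold: float = 0.85
              ) -> dict[str, frozenset[str]]:
    """Per-screen hit sets: strains with ratio strictly below ``threshold``."""
    hits = {}
    for screen_id in ratio_table.screen_ids:
        col = ratio_table.values[screen_id]
        hits[screen_id] = frozenset(col.index[col < threshold])
    return hits


def consensus_hits(hits: Mapping[str, frozenset[str]],
                   min_screens: int | None = None) -> frozenset[str]:
    """Strains called in at least ``min_screens`` screens (default: majority)."""
    if min_screens is None:
        min_screens = len(hits) // 2 + 1
    counts: dict[str, int] = {}
    for screen_hits in hits.values():
        for strain in screen_hits:
            counts[strain] = counts.get(strain, 0) + 1
    return frozenset(s for s, c in counts.items() if c >= min_screens)


def score_screens(colonies: Mapping[str, ColonyTable], design: ScreenDesign,
                  floor: float = 0.2, min_present: int = 2,
                  drop_incomplete: bool = True) -> RatioTable:
    """Full scoring chain: normalize -> replicate medians -> ratios.

    ``colonies`` maps table ids to colony tables; each design row names its
    respiratory table (by screen_id) and its fermentative reference table.
    """
    resp, ferm = {}, {}
    for scr in design:
        for key, table_id in (("resp", scr.screen_id),
                              ("ferm", scr.fermentative_reference_id)):
            if table_id not in colonies:
                raise DataError(f"colony table {table_id!r} not provided")
            agg = aggregate_replicates(normalize_plate(colonies[table_id]),
                                       min_present=min_present)
            (resp if key == "resp" else ferm)[scr.screen_id] = agg
    return compute_ratios(resp, ferm, floor=floor, drop_incomplete=drop_incomplete)


# ---------------------------------------------------------------------------
# Clustering of ratio profiles
# ---------------------------------------------------------------------------

def cluster_strains(ratio_table: RatioTable, algorithm: str = "som", k: int = 12,
                    grid: tuple[int, int] | None = None, seed: int = 0,
                    design: ScreenDesign | None = None,
                    deficient_threshold: float = 0.85) -> ClusterResult:
    """Group strains by their multi-screen ratio profiles.

    When a design is supplied, clusters whose median ratios fall below
    ``deficient_threshold`` in at least half of the prototroph screens are
    flagged "P-like", in at least half of the auxotroph screens "A-like", and
    in both "both".
    """
    result = cluster_matrix(ratio_table.values, algorithm=algorithm, k=k,
                            grid=grid if algorithm == "som" else None, seed=seed)
    if design is not None:
        result.flags = flag_deficient_clusters(result, design,
                                               threshold=deficient_threshold)
    return result


def flag_deficient_clusters(result: ClusterResult, design: ScreenDesign,
                            threshold: float = 0.85) -> dict[int, str]:
    proto = [s for s in design.by_background("prototroph")
             if s in result.medians.columns]
    auxo = [s for s in design.by_background("auxotroph")
            if s in result.medians.columns]
    flags: dict[int, str] = {}
    for cluster, med in result.medians.iterrows():
        if med.isna().all():
            continue
        p_low = (med[proto] < threshold).mean() if proto else 0.0
        a_low = (med[auxo] < threshold).mean() if auxo else 0.0
        if p_low >= 0.5 and a_low >= 0.5:
            flags[cluster] = "both"
        elif p_low >= 0.5:
            flags[cluster] = "P-like"
        elif a_low >= 0.5:
            flags[cluster] = "A-like"
    return flags


def write_screen_outputs(outdir, ratio_table: RatioTable,
                         hits: Mapping[str, frozenset[str]],
                         clusters: ClusterResult | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ratio_table.to_tsv(outdir / "ratios.tsv")
    rows = [(screen, strain) for screen, members in sorted(hits.items())
            for strain in sorted(members)]
    pd.DataFrame(rows, columns=["screen_id", "strain_id"]).to_csv(
        outdir / "hits.tsv", sep="\t", index=False)
    if clusters is not None:
        lab = clusters.labels.rename("cluster").to_frame()
        lab.index.name = "strain_id"
        lab["flag"] = lab["cluster"].map(clusters.flags).fillna("")
        lab.to_csv(outdir / "clusters.tsv", sep="\t")
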
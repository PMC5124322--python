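"""Set accounting, hypergeometric enrichment and retrograde-response concordance.

The enrichment p-value is the upper tail of the hypergeometric distribution
(the probability of drawing at least the observed overlap when sampling the
query without replacement from the universe), computed by exact summation of
log-probabilities.  Multiple testing uses Benjamini-Hochberg.  The concordance
caller classifies each gene by its fold-change direction across three
mitochondrial-dysfunction experiments at a strict >1.5-fold threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import DataError, ValidationError
from .tables_io import GeneSets

CONCORDANCE_CLASSES = ("all3-up", "all3-down", "2of3-up", "2of3-down",
                       "discordant", "none")


# ---------------------------------------------------------------------------
# Venn accounting
# ---------------------------------------------------------------------------

@dataclass
class VennResult:
    """Disjoint-region memberships for 2-3 named sets."""

    set_names: tuple[str, ...]
    regions: dict[tuple[str, ...], frozenset[str]]

    @property
    def region_sizes(self) -> dict[tuple[str, ...], int]:
        return {key: len(v) for key, v in self.regions.items()}

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.regions.values():
            out |= members
        return frozenset(out)

    def intersection(self, *names: str) -> frozenset[str]:
        """Members of the plain intersection of the given sets (not disjoint)."""
        out: set[str] = set()
        for key, members in self.regions.items():
            if all(n in key for n in names):
                out |= members
        return frozenset(out)

    def only(self, name: str) -> frozenset[str]:
        """Members exclusive to one set."""
        return self.regions.get((name,), frozenset())


def venn(sets: Mapping[str, Iterable[str]]) -> VennResult:
    """Disjoint region sizes and memberships for 2-3 named sets."""
    names = tuple(sets)
    if not 2 <= len(names) <= 3:
        raise ValidationError("venn accounting handles 2 or 3 sets")
    as_sets = {n: frozenset(sets[n]) for n in names}
    regions: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            members = frozenset.intersection(*[as_sets[n] for n in inside])
            for n in names:
                if n not in inside:
                    members = members - as_sets[n]
            regions[inside] = members
    return VennResult(set_names=names, regions=regions)


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    k: int   # overlap
    n: int   # query size
    K: int   # set size within universe
    N: int   # universe size
    p: float
    q: float | None = None


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by log-space summation."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError("require 0 <= K,n <= N")
    k = max(k, max(0, n + K - N))
    hi = min(n, K)
    if k <= max(0, n + K - N):
        return 1.0
    if k > hi:
        return 0.0
    i = np.arange(k, hi + 1)
    logp = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(np.exp(logsumexp(logp)), 1.0))


def hypergeom_enrich(query: Iterable[str], gene_set: Iterable[str],
                     universe: Iterable[str], set_name: str = "") -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of ``gene_set`` in ``query``.

    Both query and set must be subsets of the universe; misspecified universes
    fail loudly rather than silently shrinking the test.
    """
    query, gene_set, universe = frozenset(query), frozenset(gene_set), frozenset(universe)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValidationError(f"query not a subset of universe (e.g. {extra})")
    if not gene_set <= universe:
        extra = sorted(gene_set - universe)[:5]
        raise ValidationError(f"gene set not a subset of universe (e.g. {extra})")
    N, K, n = len(universe), len(gene_set), len(query)
    k = len(query & gene_set)
    return EnrichmentResult(set_name=set_name, k=k, n=n, K=K, N=N,
                            p=hypergeom_sf(k, N, K, n))


def enrich_many(query: Iterable[str], gene_sets: GeneSets,
                universe: Iterable[str]) -> pd.DataFrame:
    """Enrichment of every set in ``gene_sets``, BH-adjusted across sets."""
    universe = frozenset(universe)
    rows = [hypergeom_enrich(query, gene_sets[name] & universe, universe, name)
            for name in gene_sets]
    df = pd.DataFrame([vars(r) for r in rows]).set_index("set_name")
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Retrograde concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Per-gene directions and concordance class across three experiments."""

    table: pd.DataFrame          # columns: dir_<name> x3, class
    experiment_names: tuple[str, str, str]
    fold: float

    @property
    def class_counts(self) -> pd.Series:
        return (self.table["class"].value_counts()
                .reindex(CONCORDANCE_CLASSES, fill_value=0))

    def genes_in_class(self, cls: str) -> frozenset[str]:
        if cls not in CONCORDANCE_CLASSES:
            raise ValidationError(f"unknown concordance class {cls!r}")
        return frozenset(self.table.index[self.table["class"] == cls])


def _as_log2fc(obj) -> pd.Series:
    """Coerce fold-change tables of several shapes to a log2FC series."""
    if isinstance(obj, pd.Series):
        return obj.astype(float)
    if isinstance(obj, pd.DataFrame):
        if "log2fc" not in obj.columns:
            raise DataError("fold-change table lacks a 'log2fc' column")
        s = obj["log2fc"].astype(float)
        s.index = obj.index
        return s
    if hasattr(obj, "data"):  # FoldChangeTable
        return _as_log2fc(obj.data)
    raise DataError(f"cannot interpret {type(obj).__name__} as a fold-change table")


def concordance(fc_tables: Sequence, fold: float = 1.5,
                names: Sequence[str] | None = None) -> ConcordanceResult:
    """Classify genes by fold-change concordance across three experiments.

    A gene is "up"/"down" in an experiment iff its fold change exceeds ``fold``
    strictly in that direction (|log2FC| > log2(fold)).  Classes: same
    direction in all three -> all3-up / all3-down; same direction in exactly
    two with the third unchanged -> 2of3-up / 2of3-down; opposite directions
    co-occurring -> discordant; otherwise none.  Classes partition the
    (shared) gene universe.
    """
    if len(fc_tables) != 3:
        raise ValidationError("concordance requires exactly three experiments")
    series = [_as_log2fc(t) for t in fc_tables]
    if names is None:
        names = tuple(getattr(s, "name", None) or f"exp{i + 1}"
                      for i, s in enumerate(series))
    names = tuple(names)
    universes = [frozenset(s.index) for s in series]
    if not (universes[0] == universes[1] == universes[2]):
        diff = sorted(frozenset.union(*universes) -
                      frozenset.intersection(*universes))
        raise DataError(f"gene universes differ; symmetric difference e.g. {diff[:10]}")
    idx = series[0].index
    thr = np.log2(fold)
    dirs = pd.DataFrame(index=idx)
    for name, s in zip(names, series):
        s = s.reindex(idx)
        dirs[f"dir_{name}"] = np.select([s > thr, s < -thr], ["up", "down"], "none")
    n_up = (dirs == "up").sum(axis=1)
    n_down = (dirs == "down").sum(axis=1)
    cls = np.select(
        [n_up == 3, n_down == 3, (n_up >= 1) & (n_down >= 1), n_up == 2, n_down == 2],
        ["all3-up", "all3-down", "discordant", "2of3-up", "2of3-down"],
        "none",
    )
    dirs["class"] = cls
    return ConcordanceResult(table=dirs, experiment_names=names, fold=fold)
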
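"""Differential expression between two growth conditions and time-course
profiling after a carbon-source shift.

DE calling is threshold-based, mirroring screens of fermentative (glucose)
versus respiratory (glycerol) steady states: a gene is differentially
expressed when it changes at least ``fc_threshold``-fold (default twofold) in
counts-per-million, is expressed above ``min_abund`` CPM in at least one
condition, and is significant after Benjamini-Hochberg correction.  The
significance test is a two-sided exact binomial test of the gene's pooled
counts split between the two conditions against the library-size-implied
proportion — a deliberately simple, dependency-light test for 2x2-replicate
designs; the surrounding fold-change and abundance thresholds carry most of
the selection.

Time-course matrices are log2 ratios against a common reference; profiles are
re-expressed relative to the pre-shift sample (t = 0), counted for >twofold
changes per timepoint (with hypergeometric enrichment of an annotation set
among the up-regulated genes) and grouped by K-means into expression-profile
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterResult, cluster_matrix
from .errors import DataError, ValidationError
from .genesets import bh_adjust, hypergeom_sf


@dataclass
class FoldChangeTable:
    """Per-gene log2 fold change, mean abundance, p/q and direction flag.

    ``direction`` is "up" iff the gene is called DE with log2FC >= the fold
    threshold, "down" iff called with log2FC <= -threshold, else "none";
    significance never flips a direction, it only gates the call.
    """

    data: pd.DataFrame   # columns: log2fc, mean_abund, p, q, direction
    contrast: tuple[str, str]
    fc_threshold: float
    alpha: float

    @property
    def log2fc(self) -> pd.Series:
        return self.data["log2fc"]

    def genes(self, direction: str) -> frozenset[str]:
        return frozenset(self.data.index[self.data["direction"] == direction])

    @property
    def n_up(self) -> int:
        return int((self.data["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.data["direction"] == "down").sum())

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each library to counts-per-million of its column sum."""
    libsizes = counts.sum(axis=0)
    if (libsizes <= 0).any():
        bad = libsizes.index[libsizes <= 0][0]
        raise DataError(f"library {bad!r} has zero total counts")
    return counts / libsizes * 1e6


def call_de(counts: pd.DataFrame, meta: pd.DataFrame,
            contrast: tuple[str, str], fc_threshold: float = 2.0,
            min_abund: float = 5.0, alpha: float = 0.05) -> FoldChangeTable:
    """Call differential expression between two conditions.

    ``meta`` is indexed by sample id with a ``condition`` column;
    ``contrast=(a, b)`` reports log2(a/b).  Pseudocount 1 is added to mean CPM
    before the log.
    """
    cond_a, cond_b = contrast
    for cond in contrast:
        if cond not in set(meta["condition"]):
            raise ValidationError(f"condition {cond!r} not present in metadata")
    samples_a = list(meta.index[meta["condition"] == cond_a])
    samples_b = list(meta.index[meta["condition"] == cond_b])
    missing = [s for s in samples_a + samples_b if s not in counts.columns]
    if missing:
        raise DataError(f"samples absent from count matrix: {missing}")
    cpm = normalize_counts(counts)
    mean_a = cpm[samples_a].mean(axis=1)
    mean_b = cpm[samples_b].mean(axis=1)
    log2fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)
    mean_abund = pd.concat([mean_a, mean_b], axis=1).max(axis=1)

    pooled_a = counts[samples_a].sum(axis=1).to_numpy()
    pooled_b = counts[samples_b].sum(axis=1).to_numpy()
    lib_a = counts[samples_a].to_numpy().sum()
    lib_b = counts[samples_b].to_numpy().sum()
    p0 = lib_a / (lib_a + lib_b)
    p = binom_test_two_sided(pooled_a, pooled_a + pooled_b, p0)
    q = bh_adjust(np.clip(p, np.nextafter(0, 1), 1.0))

    thr = np.log2(fc_threshold)
    called = (np.abs(log2fc) >= thr) & (mean_abund >= min_abund) & (q < alpha)
    direction = np.select([called & (log2fc >= thr), called & (log2fc <= -thr)],
                          ["up", "down"], "none")
    df = pd.DataFrame({"log2fc": log2fc, "mean_abund": mean_abund, "p": p,
                       "q": q, "direction": direction}, index=counts.index)
    return FoldChangeTable(data=df, contrast=(cond_a, cond_b),
                           fc_threshold=fc_threshold, alpha=alpha)


def binom_test_two_sided(k, n, p0: float) -> np.ndarray:
    """Vectorised two-sided exact binomial test (minimum-likelihood method).

    For each (k_i, n_i), the p-value sums Binomial(n_i, p0) probabilities over
    all outcomes no more likely than the observed one; n = 0 gives p = 1.
    Matches scipy.stats.binomtest(..., alternative="two-sided").
    """
    k = np.asarray(k, dtype=int)
    n = np.asarray(n, dtype=int)
    out = np.ones(len(k), dtype=float)
    for idx in range(len(k)):
        ni = n[idx]
        if ni == 0:
            continue
        i = np.arange(ni + 1)
        pmf = stats.binom.pmf(i, ni, p0)
        out[idx] = min(pmf[pmf <= pmf[k[idx]] * (1 + 1e-7)].sum(), 1.0)
    return out


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------

def relative_to_t0(matrix: pd.DataFrame) -> pd.DataFrame:
    """Re-express log2 ratios relative to the t = 0 column.

    Columns are timepoints in hours (numeric); after the shift the t = 0
    column is identically zero.  Idempotent.
    """
    cols = _timepoint_columns(matrix)
    if 0.0 not in cols.values:
        raise DataError("time-course matrix lacks a t=0 column")
    out = matrix.copy()
    out.columns = cols
    t0 = out[0.0]
    out = out.sub(t0, axis=0)
    out = out[sorted(out.columns)]
    return out


def _timepoint_columns(matrix: pd.DataFrame) -> pd.Index:
    try:
        return pd.Index([float(c) for c in matrix.columns])
    except (TypeError, ValueError):
        raise DataError("time-course columns must be numeric timepoints (hours)") from None


def count_changed_per_timepoint(tc: pd.DataFrame, fold: float = 2.0,
                                annotation_set=None) -> pd.DataFrame:
    """Per-timepoint counts of genes changing more than ``fold``-fold.

    Returns a table indexed by timepoint with ``n_up``, ``n_down`` and, when
    an annotation set is given, the upper-tail hypergeometric p-value of that
    set among the up-regulated genes against the universe of measured genes
    (p = 1 when nothing is up).
    """
    if len(tc) == 0:
        raise ValidationError("empty gene universe")
    universe = frozenset(tc.index)
    if annotation_set is not None:
        annotation_set = frozenset(annotation_set)
        if not annotation_set <= universe:
            extra = sorted(annotation_set - universe)[:5]
            raise ValidationError(f"annotation set not within the measured universe "
                                  f"(e.g. {extra})")
    thr = np.log2(fold)
    rows = []
    for t in tc.columns:
        col = tc[t]
        up = frozenset(col.index[col > thr])
        down = frozenset(col.index[col < -thr])
        row = {"timepoint": float(t), "n_up": len(up), "n_down": len(down)}
        if annotation_set is not None:
            row["p_enrich"] = hypergeom_sf(len(up & annotation_set), len(universe),
                                           len(annotation_set), len(up))
        rows.append(row)
    return pd.DataFrame(rows).set_index("timepoint")


def cluster_profiles(tc: pd.DataFrame, k: int = 12, seed: int = 0,
                     algorithm: str = "kmeans") -> ClusterResult:
    """K-means clustering of expression profiles (Euclidean on log2 ratios)."""
    result = cluster_matrix(tc, algorithm=algorithm, k=k, seed=seed)
    means = tc.groupby(result.labels).mean()
    result.medians = means.reindex(range(1, k + 1))
    return result
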
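"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure the analysis assumes:

* ``simulate_screen`` — 1536-format colony arrays (32 x 48 positions, each
  strain spotted in quadruplicate as a 2 x 2 block, 384 strains per plate)
  for a nine-screen design; respiratory colony sizes of planted deficient
  strains are multiplied by a growth factor in (0, 1), with background-
  specific expression (prototroph-only, auxotroph-only or both); plate-wide
  multiplicative effects, lognormal per-colony noise of a stated CV, and
  randomly missing colonies.
* ``simulate_expression`` — negative-binomial counts for 2 conditions x 2
  replicates over an ordered gene map with planted twofold DE genes,
  non-overlapping co-regulated chromosomal blocks and planted DE-ncRNA /
  DE-coding adjacency pairs.
* ``simulate_timecourse`` — log2-ratio profiles over 0-24 h built from a
  fixed archetype catalogue (transient stress peak at 0.5 h, delayed
  mitochondrial peak at 1 h, late stationary re-induction at 24 h, and their
  mirrors) with Gaussian noise.
* ``simulate_retrograde`` — three fold-change experiments sharing planted
  concordantly repressed and induced sets (>1.5-fold in all three), planted
  two-of-three genes, and an excluded "complex-2-like" subset of the
  repressed functional family whose fold changes stay near 1.

All generators are bit-reproducible given (parameters, seed), and the truth
objects are sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .screen import ScreenDesign, default_design
from .tables_io import COLONY_COLUMNS, ColonyTable, GeneMap

PLATE_ROWS, PLATE_COLS = 32, 48          # 1536 format
STRAINS_PER_PLATE = (PLATE_ROWS // 2) * (PLATE_COLS // 2)  # 2x2 quadruplicate blocks
BASELINE_SIZE = 200.0                    # arbitrary area units

DEFAULT_TIMEPOINTS = (0.0, 0.2, 0.5, 1.0, 2.0, 4.0, 24.0)

#: Log2-ratio profiles (relative to t=0) at the canonical timepoints.
ARCHETYPES: dict[str, tuple[float, ...]] = {
    "flat":               (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "transient-up-0.5h":  (0.0, 1.2, 2.0, 0.8, 0.2, 0.0, 0.6),
    "transient-down-0.5h": (0.0, -1.2, -2.0, -0.8, -0.2, 0.0, -0.6),
    "mito-peak-1h":       (0.0, 0.2, 1.0, 2.0, 1.2, 0.6, 1.4),
    "late-up-24h":        (0.0, 0.0, 0.0, 0.2, 0.5, 1.0, 2.2),
    "late-down-24h":      (0.0, 0.0, 0.0, -0.2, -0.5, -1.0, -2.2),
}

DEFAULT_ARCHETYPE_MIXTURE: dict[str, float] = {
    "flat": 0.35,
    "transient-up-0.5h": 0.15,
    "transient-down-0.5h": 0.15,
    "mito-peak-1h": 0.10,
    "late-up-24h": 0.125,
    "late-down-24h": 0.125,
}


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Planted respiratory-deficiency ground truth."""

    deficient: dict[str, str]        # strain_id -> background (prototroph/auxotroph/both)
    effects: dict[str, float]        # strain_id -> multiplicative respiratory factor
    plate_effects: dict[str, float]  # plate_id -> multiplicative factor

    @property
    def deficient_strains(self) -> frozenset[str]:
        return frozenset(self.deficient)

    def matching_screens(self, strain: str, design: ScreenDesign) -> list[str]:
        bg = self.deficient.get(strain)
        if bg is None:
            return []
        if bg == "both":
            return design.screen_ids
        return design.by_background(bg)


@dataclass
class ScreenSim:
    design: ScreenDesign
    colonies: dict[str, ColonyTable]   # table_id -> colony table
    truth: ScreenTruth
    strains: list[str]


def simulate_screen(n_strains: int = 2000, design: ScreenDesign | None = None,
                    deficient_frac: float = 0.05,
                    effect_range: tuple[float, float] = (0.3, 0.7),
                    background_split: tuple[float, float, float] = (0.40, 0.45, 0.15),
                    plate_effect_sd: float = 0.1, noise_cv: float = 0.1,
                    missing_rate: float = 0.01, seed: int = 0) -> ScreenSim:
    """Simulate colony tables for every screen of a design.

    ``background_split`` gives the fractions of deficient strains whose effect
    expresses only in prototroph screens, only in auxotroph screens, or in
    all screens ("both").  Colony baseline size is constant per strain so
    that, at zero noise, the deterministic scoring chain passes planted
    effects through exactly.
    """
    for name, value in (("deficient_frac", deficient_frac),
                        ("missing_rate", missing_rate)):
        if not 0 <= value <= 1:
            raise ValidationError(f"{name} must be in [0, 1]")
    if n_strains < 1:
        raise ValidationError("n_strains must be positive (not placeable otherwise)")
    if not (0 < effect_range[0] <= effect_range[1] < 1):
        raise ValidationError("effect_range must lie within (0, 1)")
    if abs(sum(background_split) - 1.0) > 1e-9:
        raise ValidationError("background_split must sum to 1")
    if design is None:
        design = default_design()
    rng = np.random.default_rng(seed)

    strains = [f"mut{i:04d}" for i in range(1, n_strains + 1)]
    n_def = int(round(deficient_frac * n_strains))
    deficient_ids = list(rng.choice(strains, size=n_def, replace=False))
    backgrounds = rng.choice(["prototroph", "auxotroph", "both"], size=n_def,
                             p=list(background_split))
    effects = rng.uniform(effect_range[0], effect_range[1], size=n_def)
    truth = ScreenTruth(
        deficient=dict(zip(deficient_ids, backgrounds.tolist())),
        effects=dict(zip(deficient_ids, effects.tolist())),
        plate_effects={},
    )

    # fixed array layout shared by every plate copy
    n_plates = int(np.ceil(n_strains / STRAINS_PER_PLATE))
    plate_of = np.arange(n_strains) // STRAINS_PER_PLATE
    pos_on_plate = np.arange(n_strains) % STRAINS_PER_PLATE
    block_row = pos_on_plate // (PLATE_COLS // 2)
    block_col = pos_on_plate % (PLATE_COLS // 2)

    sigma = np.sqrt(np.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0
    strain_arr = np.asarray(strains)
    effect_vec = np.ones(n_strains)
    bg_of = np.array([truth.deficient.get(s, "") for s in strains])
    for s, e in truth.effects.items():
        effect_vec[strains.index(s)] = e

    colonies: dict[str, ColonyTable] = {}
    for scr in design:
        matching = (bg_of == "both") | (bg_of == scr.background)
        for role, table_id, medium in (
                ("resp", scr.screen_id, scr.respiratory_medium),
                ("ferm", scr.fermentative_reference_id, "glucose")):
            frames = []
            for p in range(n_plates):
                plate_id = f"{table_id}_p{p + 1}"
                plate_effect = float(rng.lognormal(0.0, plate_effect_sd)) \
                    if plate_effect_sd > 0 else 1.0
                truth.plate_effects[plate_id] = plate_effect
                on_plate = np.nonzero(plate_of == p)[0]
                n_here = len(on_plate)
                strain_sizes = np.full(n_here, BASELINE_SIZE)
                if role == "resp":
                    strain_sizes = strain_sizes * np.where(matching[on_plate],
                                                           effect_vec[on_plate], 1.0)
                # expand each strain into its 2x2 replicate block
                rows = np.repeat(2 * block_row[on_plate], 4) + np.tile([1, 1, 2, 2], n_here)
                cols = np.repeat(2 * block_col[on_plate], 4) + np.tile([1, 2, 1, 2], n_here)
                sizes = np.repeat(strain_sizes, 4) * plate_effect
                if sigma > 0:
                    noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=sizes.size)
                    sizes = sizes * noise
                missing = rng.random(sizes.size) < missing_rate
                frames.append(pd.DataFrame({
                    "plate_id": plate_id, "medium": medium,
                    "row": rows, "col": cols,
                    "strain_id": np.repeat(strain_arr[on_plate], 4),
                    "size": np.where(missing, np.nan, sizes),
                    "missing": missing,
                }))
            df = pd.concat(frames, ignore_index=True)[COLONY_COLUMNS]
            colonies[table_id] = ColonyTable(df)
    return ScreenSim(design=design, colonies=colonies, truth=truth, strains=strains)


def evaluate_hits(hits: Mapping[str, frozenset[str]], truth: ScreenTruth,
                  design: ScreenDesign, min_screens: int | None = None) -> dict:
    """Strain-level recovery of planted deficient strains from per-screen hits.

    A strain is predicted deficient when it is a hit in at least
    ``min_screens`` screens (default: a majority of all screens).  Returns
    sensitivity (overall and per planted background) and FDR.
    """
    from .screen import consensus_hits

    if min_screens is None:
        min_screens = len(hits) // 2 + 1
    predicted = consensus_hits(hits, min_screens=min_screens)
    positives = truth.deficient_strains
    tp = predicted & positives
    sensitivity = len(tp) / len(positives) if positives else float("nan")
    fdr = len(predicted - positives) / len(predicted) if predicted else 0.0
    per_bg = {}
    for bg in ("prototroph", "auxotroph", "both"):
        members = {s for s, b in truth.deficient.items() if b == bg}
        if members:
            per_bg[bg] = len(predicted & members) / len(members)
    return {"sensitivity": sensitivity, "fdr": fdr, "n_predicted": len(predicted),
            "n_planted": len(positives), "sensitivity_by_background": per_bg,
            "min_screens": min_screens}


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockRegion:
    chrom: str
    start_rank: int
    end_rank: int
    direction: str
    members: tuple[str, ...]


@dataclass
class ExpressionTruth:
    de_genes: dict[str, float]                 # gene_id -> signed log2 effect
    block_regions: list[BlockRegion]
    adjacency_pairs: list[tuple[str, str]]     # (ncRNA_id, coding_id)


@dataclass
class ExpressionSim:
    counts: pd.DataFrame
    meta: pd.DataFrame
    gene_map: GeneMap
    truth: ExpressionTruth
    conditions: tuple[str, str] = ("glycerol", "glucose")


def simulate_expression(n_genes: int = 7022, n_chroms: int = 3,
                        frac_ncRNA: float = 0.27, de_frac: float = 0.10,
                        de_log2fc: float = 1.0,
                        block_spec: Sequence[tuple[int, str, float]] = (
                            (10, "induced", 0.8), (10, "repressed", 0.8)),
                        block_log2fc: float = 2.0, adjacency_frac: float = 0.7,
                        nb_mean_range: tuple[float, float] = (10.0, 1000.0),
                        nb_dispersion: float = 0.05,
                        libsize_factors: Sequence[float] = (1.0, 1.1, 0.95, 1.05),
                        seed: int = 0) -> ExpressionSim:
    """Negative-binomial counts for 2 conditions x 2 replicates with planted
    DE genes, co-regulated chromosomal blocks and ncRNA adjacency pairs.

    DE effects are applied to the first condition (glycerol): positive log2
    effects mean induced on glycerol.  ``block_spec`` lists
    (length, direction, within-block DE fraction >= 0.6) tuples; blocks are
    placed at random non-overlapping rank ranges.
    """
    rng = np.random.default_rng(seed)
    for length, direction, frac in block_spec:
        if direction not in ("induced", "repressed"):
            raise ValidationError(f"unknown block direction {direction!r}")
        if frac < 0.6:
            raise ValidationError("within-block DE fraction must be >= 0.6")

    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    bounds = np.linspace(0, n_genes, n_chroms + 1).astype(int)
    chroms = np.empty(n_genes, dtype=object)
    ranks = np.empty(n_genes, dtype=int)
    for c in range(n_chroms):
        lo, hi = bounds[c], bounds[c + 1]
        chroms[lo:hi] = f"chr{c + 1}"
        ranks[lo:hi] = np.arange(1, hi - lo + 1)
    is_nc = rng.random(n_genes) < frac_ncRNA
    starts = 1 + (ranks - 1) * 2000
    gm = GeneMap.from_frame(pd.DataFrame({
        "gene_id": gene_ids, "chrom": chroms, "start": starts,
        "end": starts + 1000,
        "strand": rng.choice(["+", "-"], size=n_genes),
        "biotype": np.where(is_nc, "ncRNA", "coding"),
    }))

    # plant blocks on non-overlapping rank ranges
    de_effects: dict[str, float] = {}
    blocks: list[BlockRegion] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    for length, direction, frac in block_spec:
        placed = False
        for _ in range(1000):
            c = f"chr{rng.integers(1, n_chroms + 1)}"
            chrom_len = int((chroms == c).sum())
            if chrom_len < length:
                continue
            start = int(rng.integers(1, chrom_len - length + 2))
            span = (start, start + length - 1)
            if any(not (span[1] < lo or span[0] > hi) for lo, hi in occupied.get(c, [])):
                continue
            occupied.setdefault(c, []).append(span)
            in_block = np.nonzero((chroms == c) & (ranks >= span[0])
                                  & (ranks <= span[1]))[0]
            n_de = int(np.ceil(frac * length))
            members = rng.choice(in_block, size=n_de, replace=False)
            sign = 1.0 if direction == "induced" else -1.0
            for gi in sorted(members):
                de_effects[gene_ids[gi]] = sign * block_log2fc
            blocks.append(BlockRegion(chrom=c, start_rank=span[0], end_rank=span[1],
                                      direction=direction,
                                      members=tuple(gene_ids[gi]
                                                    for gi in sorted(members))))
            placed = True
            break
        if not placed:
            raise ValidationError(f"cannot place a block of {length} genes: "
                                  "blocks exceed chromosome length")

    # random DE genes outside blocks
    n_de = int(round(de_frac * n_genes))
    free = [g for g in gene_ids if g not in de_effects]
    chosen = rng.choice(free, size=min(n_de, len(free)), replace=False)
    signs = rng.choice([1.0, -1.0], size=len(chosen))
    for g, s in zip(chosen, signs):
        de_effects[g] = s * de_log2fc

    # plant ncRNA adjacency: for a fraction of DE ncRNAs force a DE coding
    # neighbour in rank order
    biotype_of = dict(zip(gene_ids, np.where(is_nc, "ncRNA", "coding")))
    order = gm.data
    neighbours: dict[str, list[str]] = {}
    for _chrom, idx in order.groupby("chrom", sort=False).indices.items():
        genes = order["gene_id"].to_numpy()[idx]
        for i, g in enumerate(genes):
            neighbours[g] = [genes[j] for j in (i - 1, i + 1) if 0 <= j < len(genes)]
    de_nc = [g for g in de_effects if biotype_of[g] == "ncRNA"]
    rng.shuffle(de_nc)
    n_adj = int(round(adjacency_frac * len(de_nc)))
    adjacency_pairs: list[tuple[str, str]] = []
    for g in de_nc:
        if len(adjacency_pairs) >= n_adj:
            break
        coding_nb = [n for n in neighbours[g] if biotype_of[n] == "coding"]
        if not coding_nb:
            continue
        partner = next((n for n in coding_nb if n in de_effects), None)
        if partner is None:
            partner = coding_nb[0]
            de_effects[partner] = float(rng.choice([1.0, -1.0])) * de_log2fc
        adjacency_pairs.append((g, partner))

    # counts
    samples = ["glycerol_1", "glycerol_2", "glucose_1", "glucose_2"]
    conditions = ["glycerol", "glycerol", "glucose", "glucose"]
    base = np.exp(rng.uniform(np.log(nb_mean_range[0]), np.log(nb_mean_range[1]),
                              size=n_genes))
    effect = np.array([de_effects.get(g, 0.0) for g in gene_ids])
    counts = {}
    for sample, cond, lib in zip(samples, conditions, libsize_factors):
        mu = base * lib * (2.0 ** effect if cond == "glycerol" else 1.0)
        counts[sample] = _nb_draw(rng, mu, nb_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame({"condition": conditions, "replicate": [1, 2, 1, 2]},
                        index=pd.Index(samples, name="sample_id"))
    truth = ExpressionTruth(de_genes=de_effects, block_regions=blocks,
                            adjacency_pairs=adjacency_pairs)
    return ExpressionSim(counts=counts_df, meta=meta, gene_map=gm, truth=truth)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with var = mu + dispersion * mu^2 (Poisson when dispersion ~ 0)."""
    if dispersion < 1e-12:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# Time-course simulation
# ---------------------------------------------------------------------------

@dataclass
class TimecourseSim:
    matrix: pd.DataFrame        # genes x timepoints, log2 ratios vs reference
    truth: pd.Series            # gene_id -> archetype label


def simulate_timecourse(n_genes: int = 1284,
                        archetype_mixture: Mapping[str, float] | None = None,
                        timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
                        noise_sd: float = 0.2, seed: int = 0,
                        archetypes: Mapping[str, Sequence[float]] | None = None
                        ) -> TimecourseSim:
    """Log2-ratio time-course matrix built from archetype profiles plus noise.

    ``archetype_mixture`` maps catalogue labels to fractions (defaults to a
    flat-dominated mixture with a ~10% delayed mitochondrial peak); noise is
    i.i.d. Gaussian on every entry, including t = 0 (a shared-reference
    design), so downstream processing should re-express profiles relative to
    t = 0.
    """
    if archetypes is None:
        archetypes = ARCHETYPES
        if tuple(timepoints) != DEFAULT_TIMEPOINTS:
            raise ValidationError("custom timepoints require custom archetype profiles")
    if archetype_mixture is None:
        archetype_mixture = DEFAULT_ARCHETYPE_MIXTURE
    unknown = set(archetype_mixture) - set(archetypes)
    if unknown:
        raise ValidationError(f"unknown archetype(s): {sorted(unknown)}")
    total = sum(archetype_mixture.values())
    if total <= 0:
        raise ValidationError("archetype mixture must have positive total weight")
    rng = np.random.default_rng(seed)
    labels_cat = list(archetype_mixture)
    n_per = {lab: int(round(archetype_mixture[lab] / total * n_genes))
             for lab in labels_cat}
    # largest block absorbs the rounding remainder
    drift = n_genes - sum(n_per.values())
    n_per[max(n_per, key=n_per.get)] += drift

    gene_ids, labels, profiles = [], [], []
    i = 1
    for lab in labels_cat:
        prof = np.asarray(archetypes[lab], dtype=float)
        if prof.shape != (len(timepoints),):
            raise ValidationError(f"archetype {lab!r} has wrong profile length")
        for _ in range(n_per[lab]):
            gene_ids.append(f"t{i:05d}")
            labels.append(lab)
            profiles.append(prof)
            i += 1
    mat = np.asarray(profiles)
    if noise_sd > 0:
        mat = mat + rng.normal(0.0, noise_sd, size=mat.shape)
    matrix = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"),
                          columns=[float(t) for t in timepoints])
    return TimecourseSim(matrix=matrix,
                         truth=pd.Series(labels, index=matrix.index, name="archetype"))


# ---------------------------------------------------------------------------
# Retrograde simulation
# ---------------------------------------------------------------------------

@dataclass
class RetrogradeTruth:
    all3_down: frozenset[str]
    all3_up: frozenset[str]
    excluded_complex2: frozenset[str]   # repressed-family members left unchanged
    two_of_three_down: frozenset[str]
    two_of_three_up: frozenset[str]


@dataclass
class RetrogradeSim:
    tables: dict[str, pd.Series]        # experiment -> log2 fold changes
    truth: RetrogradeTruth


def simulate_retrograde(n_genes: int = 5000, concordant_down_set_size: int = 40,
                        concordant_up_set_size: int = 9,
                        excluded_subset_size: int = 4,
                        two_of_three_down_size: int = 14,
                        two_of_three_up_size: int = 19,
                        fc_noise_sd: float = 0.2, planted_log2fc: float = 1.0,
                        experiment_names: Sequence[str] = ("rpm1", "reb1", "ant"),
                        seed: int = 0) -> RetrogradeSim:
    """Three fold-change experiments with planted concordant response sets.

    The planted repressed set changes >1.5-fold down in all three experiments;
    the "complex-2-like" excluded subset belongs to the same functional family
    but keeps fold changes near 1 everywhere.  Two-of-three genes are planted
    in exactly two experiments (the unchanged experiment rotates).  Everything
    else is Gaussian noise on the log2 scale.
    """
    n_planted = (concordant_down_set_size + concordant_up_set_size
                 + excluded_subset_size + two_of_three_down_size
                 + two_of_three_up_size)
    if n_planted > n_genes:
        raise ValidationError("planted set sizes exceed n_genes")
    if len(experiment_names) != 3:
        raise ValidationError("exactly three experiments required")
    rng = np.random.default_rng(seed)
    gene_ids = [f"r{i:05d}" for i in range(1, n_genes + 1)]
    perm = rng.permutation(n_genes)
    cut = np.cumsum([concordant_down_set_size, concordant_up_set_size,
                     excluded_subset_size, two_of_three_down_size,
                     two_of_three_up_size])
    groups = np.split(perm, cut)[:5]
    down_idx, up_idx, excl_idx, two_down_idx, two_up_idx = groups

    base = np.zeros((n_genes, 3))
    base[down_idx, :] = -planted_log2fc
    base[up_idx, :] = planted_log2fc
    for j, gi in enumerate(two_down_idx):
        base[gi, :] = -planted_log2fc
        base[gi, j % 3] = 0.0
    for j, gi in enumerate(two_up_idx):
        base[gi, :] = planted_log2fc
        base[gi, j % 3] = 0.0
    if fc_noise_sd > 0:
        base = base + rng.normal(0.0, fc_noise_sd, size=base.shape)

    idx = pd.Index(gene_ids, name="gene_id")
    tables = {name: pd.Series(base[:, j], index=idx, name=name)
              for j, name in enumerate(experiment_names)}
    truth = RetrogradeTruth(
        all3_down=frozenset(gene_ids[i] for i in down_idx),
        all3_up=frozenset(gene_ids[i] for i in up_idx),
        excluded_complex2=frozenset(gene_ids[i] for i in excl_idx),
        two_of_three_down=frozenset(gene_ids[i] for i in two_down_idx),
        two_of_three_up=frozenset(gene_ids[i] for i in two_up_idx),
    )
    return RetrogradeSim(tables=tables, truth=truth)
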
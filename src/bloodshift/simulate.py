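"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a paired altitude-exercise whole
blood cohort: a labeled single-cell reference over 12 blood cell types with
planted marker genes; a bulk cohort of 7 donors x {before, after} whose
expression is a mixture of the cell-type profiles with donor-specific
baselines, planted composition shifts and planted gene-level condition
effects; and a panel of external comparison DE tables with their own
significant-gene structure.

Key modelling choices (see docs/methods.md for rationale):

- Baseline cell-type proportions are *mRNA contribution* fractions, not
  cell-count fractions: lymphocytes are RNA-rich while neutrophils,
  platelets, and erythrocytes, despite dominating cell counts, contribute
  modest mRNA to a globin-depleted polyA library.
- The default condition shift raises neutrophils, CD14+ monocytes,
  erythrocytes and platelets, lowers the lymphoid populations, and leaves
  naive CD4 T cells, CD16+ monocytes, and mDC unchanged, with magnitudes
  in the range reported for acute strenuous exercise (25-80% changes).
- Counts are negative binomial (gamma-Poisson); bulk dispersion 0.05,
  single-cell dispersion 0.3. Bulk library sizes are log-uniform in
  [12,400, 40,800] - the read-depth range of a typical 12-41M-read blood
  experiment scaled down 1000x so simulations run in seconds.
- Planted regulated genes are given baseline expression typical of
  established blood biomarkers (tens to hundreds of normalized counts);
  low-abundance transcripts are not plausible signature candidates.

All randomness flows through ``numpy.random.default_rng(seed)``: identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AFTER, BEFORE, ExpressionMatrix, ExternalDETable, GeneSetCollection, SampleRecord, SimulationTruth

CELL_TYPES = [
    "B_cells",
    "CD14_monocytes",
    "CD16_monocytes",
    "CD4_memory_T",
    "CD4_naive_T",
    "CD8_T",
    "NK_cells",
    "erythrocytes",
    "mDC",
    "neutrophils",
    "pDC",
    "platelets",
]

# mRNA contribution fractions of whole (globin-depleted) blood; sum to 1.
BASELINE_MRNA_FRACTIONS = {
    "neutrophils": 0.14,
    "CD14_monocytes": 0.07,
    "erythrocytes": 0.09,
    "platelets": 0.07,
    "CD4_memory_T": 0.11,
    "CD8_T": 0.11,
    "NK_cells": 0.09,
    "B_cells": 0.09,
    "pDC": 0.025,
    "CD4_naive_T": 0.11,
    "CD16_monocytes": 0.05,
    "mDC": 0.045,
}

# Multiplicative change of each type's contribution after exercise.
SHIFT_PATTERNS: dict[str, dict[str, float]] = {
    "altitude": {
        "neutrophils": 1.60,
        "CD14_monocytes": 1.30,
        "erythrocytes": 1.35,
        "platelets": 1.35,
        "CD4_memory_T": 0.60,
        "CD8_T": 0.55,
        "NK_cells": 0.55,
        "B_cells": 0.75,
        "pDC": 0.60,
        "CD4_naive_T": 1.00,
        "CD16_monocytes": 1.00,
        "mDC": 1.00,
    },
    "null": {ct: 1.0 for ct in CELL_TYPES},
}

TRUE_DIRECTIONS = {
    ct: ("increase" if f > 1 else "decrease" if f < 1 else "no_change")
    for ct, f in SHIFT_PATTERNS["altitude"].items()
}


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mu``, variance ``mu + d*mu^2``."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, np.asarray(mu, dtype=float) * dispersion)
    return rng.poisson(lam)


def simulate_type_profiles(
    n_types: int = 12,
    n_genes: int = 5000,
    markers_per_type: int = 30,
    marker_fold: float = 32.0,
    marker_expr_boost: float = 3.0,
    profile_sigma: float = 1.0,
    type_jitter_sigma: float = 0.1,
    seed: int = 0,
) -> SimulationTruth:
    """Cell-type expression profiles with disjoint planted marker sets.

    A shared log-normal base profile gives all types similar expression for
    background genes (small per-type jitter); each type's planted markers
    are elevated ``marker_fold``-fold in that type only, on a baseline
    raised ``marker_expr_boost``-fold (canonical lineage markers are
    well-expressed transcripts, not rare ones). Profile columns are
    normalized to sum to 1 (relative mRNA abundance).
    """
    if markers_per_type * n_types >= n_genes:
        raise ValueError("markers_per_type * n_types must be smaller than n_genes")
    if n_types <= len(CELL_TYPES):
        types = CELL_TYPES[:n_types] if n_types == len(CELL_TYPES) else sorted(CELL_TYPES)[:n_types]
    else:
        types = [f"type_{i:02d}" for i in range(n_types)]
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(0.0, profile_sigma, n_genes)
    profiles = base[:, None] * rng.lognormal(0.0, type_jitter_sigma, (n_genes, n_types))
    marker_pool = rng.permutation(n_genes)[: n_types * markers_per_type]
    planted: dict[str, list[str]] = {}
    for j, ct in enumerate(types):
        idx = marker_pool[j * markers_per_type : (j + 1) * markers_per_type]
        profiles[idx, :] *= marker_expr_boost
        profiles[idx, j] *= marker_fold
        planted[ct] = sorted(gene_ids[i] for i in idx)
    profiles /= profiles.sum(axis=0, keepdims=True)
    return SimulationTruth(
        seed=seed,
        gene_ids=gene_ids,
        cell_types=list(types),
        planted_markers=planted,
        profiles=profiles,
    )


def simulate_sc_reference(
    n_types: int = 12,
    n_genes: int = 5000,
    cells_per_type: int = 200,
    markers_per_type: int = 30,
    marker_fold: float = 32.0,
    mean_counts_per_cell: float = 2000.0,
    dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[str], SimulationTruth]:
    """Labeled single-cell count matrix over planted cell-type profiles.

    Per-cell library sizes are log-normal around ``mean_counts_per_cell``;
    counts are negative binomial around the cell's scaled type profile.
    Returns (counts, labels, truth).
    """
    truth = simulate_type_profiles(
        n_types=n_types,
        n_genes=n_genes,
        markers_per_type=markers_per_type,
        marker_fold=marker_fold,
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    blocks, barcodes, labels = [], [], []
    for j, ct in enumerate(truth.cell_types):
        libs = rng.lognormal(np.log(mean_counts_per_cell), 0.3, cells_per_type)
        mu = truth.profiles[:, j][:, None] * libs[None, :]
        blocks.append(_nb_draw(rng, mu, dispersion))
        barcodes.extend(f"{ct}.c{i:04d}" for i in range(cells_per_type))
        labels.extend([ct] * cells_per_type)
    counts = np.concatenate(blocks, axis=1)
    matrix = ExpressionMatrix(
        gene_ids=truth.gene_ids, sample_ids=barcodes, values=counts, unit="counts"
    )
    return matrix, labels, truth


def _resolve_shift_pattern(shift_pattern, cell_types: list[str]) -> dict[str, float]:
    if isinstance(shift_pattern, str):
        if shift_pattern not in SHIFT_PATTERNS:
            raise ValueError(
                f"unknown shift pattern {shift_pattern!r}; options: {sorted(SHIFT_PATTERNS)}"
            )
        pattern = SHIFT_PATTERNS[shift_pattern]
    else:
        pattern = dict(shift_pattern)
    unknown = set(pattern) - set(cell_types)
    if unknown:
        raise ValueError(f"shift pattern names unknown cell types: {sorted(unknown)}")
    return {ct: float(pattern.get(ct, 1.0)) for ct in cell_types}


def simulate_bulk_cohort(
    truth_ref: SimulationTruth,
    n_donors: int = 7,
    shift_pattern="altitude",
    n_specific_de: int = 50,
    n_shared_de: int = 60,
    de_target_count: float = 50.0,
    dispersion: float = 0.05,
    lib_range: tuple[float, float] = (12_400.0, 40_800.0),
    donor_comp_sigma: float = 0.15,
    sample_comp_sigma: float = 0.01,
    donor_gene_frac: float = 0.10,
    donor_gene_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[SampleRecord], SimulationTruth]:
    """Paired bulk cohort composed as a mixture of the reference profiles.

    Each donor draws a baseline composition (log-normal perturbation of the
    whole-blood mRNA fractions); the after-exercise sample applies the
    multiplicative ``shift_pattern`` and renormalizes. ``n_specific_de``
    altitude-specific and ``n_shared_de`` generically exercise-responsive
    genes receive direct condition effects with |log2FC| in [1, 2],
    independent of composition, planted on well-expressed non-marker genes.
    Per donor, ``donor_gene_frac`` of genes carry log-normal expression
    offsets shared by both of the donor's samples (the donor effect that
    dominates blood PCA). Counts are negative binomial; gene lengths are
    drawn uniformly in [500, 5000] bp.
    """
    if truth_ref.profiles is None:
        raise ValueError("truth_ref must carry cell-type profiles")
    shift = _resolve_shift_pattern(shift_pattern, truth_ref.cell_types)
    rng = np.random.default_rng(seed)
    n_genes = len(truth_ref.gene_ids)
    n_types = len(truth_ref.cell_types)
    profiles = truth_ref.profiles.copy()
    gene_ids = truth_ref.gene_ids

    baseline = np.asarray(
        [BASELINE_MRNA_FRACTIONS.get(ct, 1.0 / n_types) for ct in truth_ref.cell_types]
    )
    baseline = baseline / baseline.sum()

    # plant direct condition effects on well-expressed non-marker genes
    marker_genes = {g for gl in truth_ref.planted_markers.values() for g in gl}
    candidates = np.asarray(
        [i for i, g in enumerate(gene_ids) if g not in marker_genes], dtype=int
    )
    n_de = n_specific_de + n_shared_de
    if n_de > candidates.size:
        raise ValueError("not enough non-marker genes to plant condition effects")
    de_idx = rng.choice(candidates, size=n_de, replace=False)
    geo_lib = float(np.sqrt(lib_range[0] * lib_range[1]))
    # lift planted genes into the biomarker expression range
    target = rng.lognormal(np.log(de_target_count), 0.4, n_de)
    w0 = profiles @ baseline
    boost = (target / geo_lib) / w0[de_idx]
    profiles[de_idx, :] *= boost[:, None]
    profiles /= profiles.sum(axis=0, keepdims=True)
    true_lfc = rng.uniform(1.0, 2.0, n_de) * rng.choice([-1.0, 1.0], n_de)
    planted_de = pd.DataFrame(
        {
            "gene": [gene_ids[i] for i in de_idx],
            "true_log2fc": true_lfc,
            "specific": [i < n_specific_de for i in range(n_de)],
        }
    )

    donors = [f"D{d + 1}" for d in range(n_donors)]
    shift_vec = np.asarray([shift[ct] for ct in truth_ref.cell_types])
    sample_ids, meta, comp_rows, mu_cols = [], [], [], []
    lib_sizes = np.exp(rng.uniform(np.log(lib_range[0]), np.log(lib_range[1]), 2 * n_donors))
    donor_offset_rows = []
    for d, donor in enumerate(donors):
        f_donor = baseline * rng.lognormal(0.0, donor_comp_sigma, n_types)
        f_donor /= f_donor.sum()
        n_off = int(round(donor_gene_frac * n_genes))
        off_idx = rng.choice(n_genes, size=n_off, replace=False)
        off_mult = rng.lognormal(0.0, donor_gene_sigma, n_off)
        gene_mult = np.ones(n_genes)
        gene_mult[off_idx] = off_mult
        donor_offset_rows.append(
            pd.DataFrame(
                {"donor": donor, "gene": [gene_ids[i] for i in off_idx], "multiplier": off_mult}
            )
        )
        for cond in (BEFORE, AFTER):
            f = f_donor * rng.lognormal(0.0, sample_comp_sigma, n_types)
            if cond == AFTER:
                f = f * shift_vec
            f /= f.sum()
            w = (profiles @ f) * gene_mult
            if cond == AFTER:
                w = w.copy()
                w[de_idx] *= np.exp2(true_lfc)
            w /= w.sum()
            sid = f"{donor}_{cond}"
            sample_ids.append(sid)
            meta.append(SampleRecord(sample_id=sid, donor_id=donor, condition=cond))
            comp_rows.append(f)
            mu_cols.append(w)

    mu = np.stack(mu_cols, axis=1) * lib_sizes[None, :]
    counts = _nb_draw(rng, mu, dispersion)
    lengths = rng.integers(500, 5001, n_genes)
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=counts,
        unit="counts",
        gene_lengths_bp=lengths,
    )
    truth = SimulationTruth(
        seed=seed,
        gene_ids=gene_ids,
        cell_types=list(truth_ref.cell_types),
        planted_markers={k: list(v) for k, v in truth_ref.planted_markers.items()},
        profiles=profiles,
        composition=pd.DataFrame(comp_rows, index=sample_ids, columns=truth_ref.cell_types),
        composition_shift=shift,
        planted_de=planted_de,
        donor_offsets=pd.concat(donor_offset_rows, ignore_index=True),
    )
    return matrix, meta, truth


def simulate_external_tables(
    truth: SimulationTruth,
    n_datasets: int = 7,
    overlap_fraction: float = 0.6,
    seed: int = 0,
) -> list[ExternalDETable]:
    """External exercise DE tables consistent with the planted bulk truth.

    Each table covers the full gene universe. Planted *shared* regulated
    genes receive p < 0.05 in a random ``overlap_fraction`` of each table;
    planted *altitude-specific* genes always receive p >= 0.1; background
    genes draw p uniformly (so ~5% look significant by chance, as in any
    real study).
    """
    if truth.planted_de is None:
        raise ValueError("truth must carry planted DE genes (run simulate_bulk_cohort first)")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = np.asarray(truth.gene_ids, dtype=object)
    idx = {g: i for i, g in enumerate(gene_ids)}
    shared = truth.planted_de.loc[~truth.planted_de["specific"], "gene"].to_numpy()
    specific = truth.planted_de.loc[truth.planted_de["specific"], "gene"].to_numpy()
    tables = []
    for d in range(n_datasets):
        p = rng.uniform(0.0, 1.0, gene_ids.size)
        lfc = rng.normal(0.0, 0.5, gene_ids.size)
        spec_i = np.asarray([idx[g] for g in specific], dtype=int)
        p[spec_i] = rng.uniform(0.1, 1.0, spec_i.size)
        n_hit = int(round(overlap_fraction * shared.size))
        hit = rng.choice(shared, size=n_hit, replace=False) if n_hit else np.asarray([], dtype=object)
        hit_i = np.asarray([idx[g] for g in hit], dtype=int)
        p[hit_i] = rng.uniform(0.0, 0.05, hit_i.size)
        lfc[hit_i] = rng.uniform(0.3, 1.5, hit_i.size) * rng.choice([-1.0, 1.0], hit_i.size)
        miss = np.asarray([idx[g] for g in shared if g not in set(hit)], dtype=int)
        if miss.size:
            p[miss] = rng.uniform(0.05, 1.0, miss.size)
        tables.append(
            ExternalDETable(
                dataset_id=f"external_{d + 1:02d}",
                table=pd.DataFrame({"gene": gene_ids, "log2fc": lfc, "p": p}),
            )
        )
    return tables


def simulate_gene_sets(
    truth: SimulationTruth,
    n_random_sets: int = 20,
    size_range: tuple[int, int] = (15, 60),
    seed: int = 0,
) -> GeneSetCollection:
    """A GMT-style collection: one set per planted marker list plus random sets."""
    rng = np.random.default_rng(seed)
    sets = {f"{ct}_markers": list(genes) for ct, genes in truth.planted_markers.items()}
    genes = np.asarray(truth.gene_ids, dtype=object)
    for i in range(n_random_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        sets[f"random_set_{i + 1:02d}"] = sorted(rng.choice(genes, size=size, replace=False))
    return GeneSetCollection(sets=sets, source_tag="synthetic")
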
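"""Library-size normalization, TPM conversion, log transform, donor centering.

Bulk counts are normalized with median-of-ratios size factors (the DESeq2
convention), then variance-reduced with ``log2(count / size_factor + 1)``.
For the paired before/after design, between-individual ("donor") expression
offsets dominate sample clustering in whole blood, so the log matrix is
donor-centered: per gene, each donor's mean is replaced by the grand mean.
Location-only centering preserves every within-donor before/after difference
exactly, which is all the downstream paired contrasts use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, SampleRecord, validate_meta

logger = logging.getLogger("bloodshift")


@dataclass
class NormalizationResult:
    size_factors: np.ndarray  # one positive factor per sample
    transformed: ExpressionMatrix  # unit="log_normalized"
    grand_means: np.ndarray  # per-gene mean of the transformed matrix


def drop_all_zero_genes(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero counts in every sample (logged)."""
    nonzero = counts.values.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropped %d genes with zero counts in all samples", n_dropped)
        return counts.subset_genes(nonzero)
    return counts


def median_of_ratios_size_factors(counts: ExpressionMatrix) -> np.ndarray:
    """Per-sample median-of-ratios size factors.

    For each gene expressed in every sample, compute its geometric mean
    across samples; a sample's factor is the median over those genes of
    count / geometric mean. Genes with a zero anywhere are excluded from the
    reference (their geometric mean is zero).
    """
    if counts.unit != "counts":
        raise ValueError(f"size factors require counts, got unit={counts.unit!r}")
    vals = counts.values
    positive = (vals > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "filter samples or genes before computing size factors"
        )
    logv = np.log(vals[positive])
    log_geomean = logv.mean(axis=1)
    factors = np.exp(np.median(logv - log_geomean[:, None], axis=0))
    return factors


def counts_to_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    if counts.gene_lengths_bp is None:
        raise ValueError("TPM conversion requires gene lengths")
    if counts.unit != "counts":
        raise ValueError(f"TPM conversion requires counts, got unit={counts.unit!r}")
    length_kb = counts.gene_lengths_bp.astype(float) / 1000.0
    rate = counts.values / length_kb[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        bad = [counts.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero-count samples cannot be converted to TPM: {bad}")
    tpm = 1e6 * rate / colsum[None, :]
    return counts.with_values(tpm, unit="tpm")


def log_transform(counts: ExpressionMatrix, size_factors: np.ndarray) -> ExpressionMatrix:
    """``log2(count / size_factor + 1)``; a simple variance-reducing transform."""
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (counts.n_samples,):
        raise ValueError("need one size factor per sample")
    if (size_factors <= 0).any() or not np.isfinite(size_factors).all():
        raise ValueError("size factors must be positive and finite")
    vals = np.log2(counts.values / size_factors[None, :] + 1.0)
    return counts.with_values(vals, unit="log_normalized")


def normalize_counts(counts: ExpressionMatrix) -> NormalizationResult:
    """Convenience: drop empty genes, size factors, log transform, grand means."""
    counts = drop_all_zero_genes(counts)
    sf = median_of_ratios_size_factors(counts)
    transformed = log_transform(counts, sf)
    return NormalizationResult(
        size_factors=sf,
        transformed=transformed,
        grand_means=transformed.values.mean(axis=1),
    )


def donor_center(matrix: ExpressionMatrix, meta: list[SampleRecord]) -> ExpressionMatrix:
    """Location-only donor correction of a log-normalized matrix.

    Per gene, subtract each donor's mean over its samples and add back the
    per-gene grand mean, so every donor's per-gene mean equals the grand
    mean afterwards. Within-donor differences (the paired contrasts) are
    untouched. Donors contributing a single sample are allowed but logged:
    for them centering removes all within-donor signal at every gene.
    """
    if matrix.unit != "log_normalized":
        raise ValueError(f"donor_center expects log_normalized values, got {matrix.unit!r}")
    validate_meta(meta)
    donor_of = {m.sample_id: m.donor_id for m in meta}
    missing = [s for s in matrix.sample_ids if s not in donor_of]
    if missing:
        raise ValueError(f"samples without donor metadata: {missing}")
    donors = [donor_of[s] for s in matrix.sample_ids]
    vals = matrix.values
    grand = vals.mean(axis=1, keepdims=True)
    out = np.empty_like(vals)
    for donor in sorted(set(donors)):
        cols = np.asarray([i for i, d in enumerate(donors) if d == donor])
        if len(cols) == 1:
            logger.info("donor %s has a single sample; centering zeroes its deviations", donor)
        donor_mean = vals[:, cols].mean(axis=1, keepdims=True)
        out[:, cols] = vals[:, cols] - donor_mean + grand
    return matrix.with_values(out)
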
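"""Core in-memory containers shared by every analysis stage.

The pipeline operates on four kinds of objects: a gene-by-sample
:class:`ExpressionMatrix` (counts, TPM, or log-normalized values), per-sample
:class:`SampleRecord` metadata describing the paired before/after design,
gene-set collections, and per-study external differential-expression tables.
All containers validate their invariants on construction so that downstream
stages can assume well-formed input.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("bloodshift")

VALID_UNITS = ("counts", "tpm", "log_normalized")
BEFORE = "before"
AFTER = "after"


def _find_duplicates(items) -> list[str]:
    counts = Counter(items)
    return [k for k, v in counts.items() if v > 1]


@dataclass
class ExpressionMatrix:
    """A gene x sample numeric matrix with optional gene lengths.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows). Treated as opaque
        case-sensitive strings.
    sample_ids
        Ordered, unique sample (or cell) identifiers (columns).
    values
        Numeric matrix of shape ``(len(gene_ids), len(sample_ids))``.
        Must be finite, and non-negative for counts/TPM.
    unit
        One of ``counts``, ``tpm``, ``log_normalized``.
    gene_lengths_bp
        Per-gene transcript lengths in base pairs; required for TPM
        conversion, otherwise optional.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str = "counts"
    gene_lengths_bp: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        dup = _find_duplicates(self.gene_ids)
        if dup:
            raise ValueError(f"duplicate gene IDs: {dup[:5]}")
        dup = _find_duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicate sample IDs: {dup[:5]}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite (no NaN/inf)")
        if self.unit in ("counts", "tpm") and (self.values < 0).any():
            raise ValueError(f"{self.unit} values must be non-negative")
        if self.gene_lengths_bp is not None:
            self.gene_lengths_bp = np.asarray(self.gene_lengths_bp)
            if self.gene_lengths_bp.shape != (len(self.gene_ids),):
                raise ValueError("gene_lengths_bp must have one entry per gene")
            if (self.gene_lengths_bp <= 0).any():
                raise ValueError("gene lengths must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ExpressionMatrix":
        """Same genes/samples/lengths with replaced values (and optionally unit)."""
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            values=values,
            unit=unit or self.unit,
            gene_lengths_bp=None if self.gene_lengths_bp is None else self.gene_lengths_bp.copy(),
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Row-subset by a boolean mask or integer index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            values=self.values[keep],
            unit=self.unit,
            gene_lengths_bp=None if self.gene_lengths_bp is None else self.gene_lengths_bp[keep],
        )

    def subset_samples(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=[self.sample_ids[i] for i in keep],
            values=self.values[:, keep],
            unit=self.unit,
            gene_lengths_bp=None if self.gene_lengths_bp is None else self.gene_lengths_bp.copy(),
        )

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one bulk sample: who it came from and when it was drawn."""

    sample_id: str
    donor_id: str
    condition: str  # "before" or "after"

    def __post_init__(self) -> None:
        if self.condition not in (BEFORE, AFTER):
            raise ValueError(
                f"condition must be {BEFORE!r} or {AFTER!r}, got {self.condition!r}"
            )


def validate_meta(meta: list[SampleRecord]) -> None:
    """Each donor may contribute at most one sample per condition."""
    seen = Counter((m.donor_id, m.condition) for m in meta)
    bad = [k for k, v in seen.items() if v > 1]
    if bad:
        raise ValueError(f"donor/condition combinations appear more than once: {bad}")
    dup = _find_duplicates([m.sample_id for m in meta])
    if dup:
        raise ValueError(f"duplicate sample IDs in metadata: {dup}")


def paired_layout(
    meta: list[SampleRecord], sample_ids: list[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Column indices of complete before/after pairs, aligned by donor.

    Returns ``(donors, before_idx, after_idx)`` where ``before_idx[i]`` and
    ``after_idx[i]`` are the matrix columns of donor ``donors[i]``. Donors
    missing either condition (or absent from the matrix) are dropped with a
    log message.
    """
    validate_meta(meta)
    col = {s: i for i, s in enumerate(sample_ids)}
    by_donor: dict[str, dict[str, str]] = {}
    for m in meta:
        if m.sample_id not in col:
            logger.warning("metadata sample %s not found in matrix; ignored", m.sample_id)
            continue
        by_donor.setdefault(m.donor_id, {})[m.condition] = m.sample_id
    donors, b_idx, a_idx = [], [], []
    for donor in sorted(by_donor):
        pair = by_donor[donor]
        if BEFORE in pair and AFTER in pair:
            donors.append(donor)
            b_idx.append(col[pair[BEFORE]])
            a_idx.append(col[pair[AFTER]])
        else:
            logger.info("donor %s lacks a complete before/after pair; dropped", donor)
    return donors, np.asarray(b_idx, dtype=int), np.asarray(a_idx, dtype=int)


def condition_columns(
    meta: list[SampleRecord], sample_ids: list[str], condition: str
) -> np.ndarray:
    """Matrix column indices of all samples with the given condition."""
    col = {s: i for i, s in enumerate(sample_ids)}
    return np.asarray(
        [col[m.sample_id] for m in meta if m.condition == condition and m.sample_id in col],
        dtype=int,
    )


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. an MSigDB-style collection loaded from GMT)."""

    sets: dict[str, list[str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            dup = _find_duplicates(members)
            if dup:
                raise ValueError(f"gene set {name!r} has duplicate members: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ExternalDETable:
    """Differential-expression summary from a previously published study.

    ``table`` has columns ``gene``, ``log2fc``, ``p`` with one row per gene.
    """

    dataset_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "log2fc", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"external DE table {self.dataset_id}: missing columns {missing}")
        p = self.table["p"].to_numpy(dtype=float)
        bad = (p < 0) | (p > 1) | ~np.isfinite(p)
        if bad.any():
            row = self.table.iloc[int(np.flatnonzero(bad)[0])]
            raise ValueError(
                f"external DE table {self.dataset_id}: p-value out of [0,1] "
                f"at gene {row['gene']!r} (p={row['p']!r})"
            )
        dup = _find_duplicates(self.table["gene"].tolist())
        if dup:
            raise ValueError(f"external DE table {self.dataset_id}: duplicate genes {dup[:5]}")

    def significant_genes(self, p_thresh: float) -> set[str]:
        mask = self.table["p"].to_numpy(dtype=float) < p_thresh
        return set(self.table.loc[mask, "gene"])


@dataclass
class MarkerCatalog:
    """Per-cell-type ordered marker gene lists with discrimination scores.

    ``markers`` maps each cell type to a list of gene IDs ordered from most
    to least discriminating; the lists are pairwise disjoint because every
    gene is assigned only to its best-scoring type. ``scores`` is a long
    table with columns ``cell_type, rank, gene, auc, log2fc,
    detection_delta`` restricted to the retained markers.
    """

    cell_types: list[str]
    markers: dict[str, list[str]]
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for ct, genes in self.markers.items():
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"marker {g!r} assigned to both {seen[g]!r} and {ct!r}"
                    )
                seen[g] = ct

    def gene_to_type(self) -> dict[str, str]:
        return {g: ct for ct, genes in self.markers.items() for g in genes}

    def all_markers(self) -> list[str]:
        return [g for ct in self.cell_types for g in self.markers.get(ct, [])]


@dataclass
class SimulationTruth:
    """Ground truth recorded by the synthetic-data generator.

    Fields are filled in incrementally: the single-cell reference step sets
    the gene universe, cell types, type profiles and planted markers; the
    bulk step adds per-sample composition, condition shift factors, planted
    regulated genes and donor offsets.
    """

    seed: int
    gene_ids: list[str]
    cell_types: list[str]
    planted_markers: dict[str, list[str]]
    profiles: np.ndarray | None = None  # genes x types, each column sums to 1
    composition: pd.DataFrame | None = None  # samples x types, rows sum to 1
    composition_shift: dict[str, float] | None = None
    planted_de: pd.DataFrame | None = None  # gene, true_log2fc, specific
    donor_offsets: pd.DataFrame | None = None  # donor x gene multipliers (sparse summary)

    def to_yaml_dict(self) -> dict:
        out = {
            "seed": int(self.seed),
            "cell_types": list(self.cell_types),
            "planted_markers": {k: list(v) for k, v in self.planted_markers.items()},
        }
        if self.composition_shift is not None:
            out["composition_shift"] = {k: float(v) for k, v in self.composition_shift.items()}
        if self.planted_de is not None:
            out["planted_de"] = {
                str(r.gene): {"log2fc": float(r.true_log2fc), "specific": bool(r.specific)}
                for r in self.planted_de.itertuples()
            }
        if self.composition is not None:
            out["composition"] = {
                str(s): {ct: float(self.composition.loc[s, ct]) for ct in self.composition.columns}
                for s in self.composition.index
            }
        return out


@dataclass
class SpecificityResult:
    """Partition of DEGs into study-unique vs previously observed.

    ``all_degs``/``unique_degs`` carry columns ``gene, direction``;
    ``previously_seen`` additionally records which external datasets flagged
    each gene (comma-joined in ``flagged_by``). ``enrichment`` and
    ``signature`` are attached by later stages.
    """

    all_degs: pd.DataFrame
    previously_seen: pd.DataFrame
    unique_degs: pd.DataFrame
    p_thresh: float
    enrichment: pd.DataFrame | None = None
    signature: pd.DataFrame | None = None
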
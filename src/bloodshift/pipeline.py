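"""End-to-end orchestration with config, logging, and a run manifest.

``run_all`` executes the stages in order — normalize -> DE -> markers ->
shifts -> enrichment -> specificity -> signature — reading the inputs named
in a :class:`RunConfig` (or generating synthetic ones when
``config.simulate`` is set) and writing one TSV per stage into the output
directory, plus a ``manifest.yaml`` listing input checksums, the effective
configuration, and per-stage row counts. With a fixed seed the outputs are
byte-identical across runs; the manifest deliberately contains no
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, de, enrichment, io, markers, normalize, shifts, simulate, specificity
from .datatypes import MarkerCatalog

logger = logging.getLogger("bloodshift")


@dataclass
class RunConfig:
    """All paths and thresholds for a pipeline run.

    Thresholds default to the analysis conventions of the altitude-exercise
    study design: DEGs at 10% FDR, signature filters TPM >= 10 and
    |log2FC| >= 0.5, top 20 markers per cell type, external-study removal
    at unadjusted p < 0.05.
    """

    out_dir: str = "bloodshift_run"
    # inputs (ignored when simulate=True, which generates them)
    counts: str | None = None
    meta: str | None = None
    sc_matrix: str | None = None
    sc_labels: str | None = None
    marker_catalog: str | None = None
    gene_sets: str | None = None
    externals: list[str] = field(default_factory=list)
    simulate: bool = False
    # thresholds
    alpha: float = 0.1
    tpm_min: float = 10.0
    lfc_min: float = 0.5
    fc_report_threshold: float = 1.0
    external_p_thresh: float = 0.05
    max_markers: int = 20
    auc_min: float = 0.7
    n_perm: int = 1000
    seed: int = 0
    shift_test_variant: str = "paired"
    moderate_variance: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.external_p_thresh <= 1:
            raise ValueError("external_p_thresh must be in (0, 1]")
        if self.tpm_min < 0 or self.lfc_min < 0:
            raise ValueError("tpm_min and lfc_min must be non-negative")
        if self.max_markers < 1:
            raise ValueError("max_markers must be >= 1")
        if not 0.5 <= self.auc_min <= 1:
            raise ValueError("auc_min must be in [0.5, 1]")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        if self.shift_test_variant not in ("pooled_unpaired", "paired"):
            raise ValueError("shift_test_variant must be pooled_unpaired or paired")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword arguments override file values."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in overrides.items():
            if value is not None:
                logger.info("config override: %s = %r (was %r)", key, value, data.get(key))
                data[key] = value
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    return handler


def _simulate_inputs(config: RunConfig, in_dir: Path) -> RunConfig:
    """Generate a full synthetic input bundle and point the config at it."""
    in_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    sc, labels, truth_ref = simulate.simulate_sc_reference(seed=seed)
    counts, meta, truth = simulate.simulate_bulk_cohort(truth_ref, seed=seed + 1)
    externals = simulate.simulate_external_tables(truth, seed=seed + 2)
    gene_sets = simulate.simulate_gene_sets(truth, seed=seed + 3)

    io.write_sc_matrix_mtx(sc, in_dir / "sc")
    io.write_cell_labels(sc.sample_ids, labels, in_dir / "sc" / "labels.tsv")
    io.write_expression_tsv(counts, in_dir / "counts.tsv", include_lengths=True)
    io.write_sample_meta(meta, in_dir / "meta.tsv")
    io.write_gmt(gene_sets, in_dir / "gene_sets.gmt")
    ext_paths = []
    for t in externals:
        p = in_dir / f"{t.dataset_id}.tsv"
        io.write_external_de_table(t, p)
        ext_paths.append(str(p))
    with open(in_dir / "truth.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth.to_yaml_dict(), fh, sort_keys=True)
    return dataclasses.replace(
        config,
        counts=str(in_dir / "counts.tsv"),
        meta=str(in_dir / "meta.tsv"),
        sc_matrix=str(in_dir / "sc" / "matrix.mtx"),
        sc_labels=str(in_dir / "sc" / "labels.tsv"),
        gene_sets=str(in_dir / "gene_sets.gmt"),
        externals=ext_paths,
    )


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    stage = "setup"
    try:
        if config.simulate:
            stage = "simulate"
            config = _simulate_inputs(config, out_dir / "inputs")
        if config.counts is None or config.meta is None:
            raise FileNotFoundError("counts and meta inputs are required (or set simulate)")
        for path in [config.counts, config.meta]:
            if not Path(path).is_file():
                raise FileNotFoundError(f"input file not found: {path}")

        manifest: dict = {
            "tool": "bloodshift",
            "version": __version__,
            "config": config.to_dict(),
            "inputs": {},
            "stages": {},
        }
        for key in ("counts", "meta", "sc_matrix", "sc_labels", "marker_catalog", "gene_sets"):
            path = getattr(config, key)
            if path and Path(path).is_file():
                manifest["inputs"][key] = _sha256(Path(path))
        for path in config.externals:
            manifest["inputs"][f"external:{Path(path).stem}"] = _sha256(Path(path))
        header = [f"seed: {config.seed}", f"bloodshift {__version__}"]

        stage = "normalize"
        counts = io.read_expression_tsv(config.counts, has_lengths=True)
        meta = io.read_sample_meta(config.meta)
        norm = normalize.normalize_counts(counts)
        corrected = normalize.donor_center(norm.transformed, meta)
        io.write_expression_tsv(corrected, out_dir / "corrected_matrix.tsv", header_lines=header)
        manifest["stages"]["normalize"] = {
            "n_genes": corrected.n_genes,
            "n_samples": corrected.n_samples,
        }

        stage = "de"
        de_table = de.paired_de(
            counts, meta, alpha=config.alpha, moderate=config.moderate_variance
        )
        io.write_table(
            de_table,
            out_dir / "de_table.tsv",
            header_lines=header + [f"alpha (FDR threshold): {config.alpha}"],
        )
        fc = de.fold_change_summary(de_table, config.fc_report_threshold)
        strat = de.stratify_by_expression(de_table, [0, 10, 100])
        io.write_table(strat, out_dir / "de_stratified.tsv", header_lines=header)
        n_up = int((de_table["status"] == de.STATUS_UP).sum())
        n_down = int((de_table["status"] == de.STATUS_DOWN).sum())
        manifest["stages"]["de"] = {
            "n_tested": int(de_table["tested"].sum()),
            "n_up": n_up,
            "n_down": n_down,
            "n_strong_up": fc["n_up"],
            "n_strong_down": fc["n_down"],
        }

        stage = "markers"
        if config.marker_catalog:
            catalog: MarkerCatalog = io.read_marker_catalog(config.marker_catalog)
        elif config.sc_matrix and config.sc_labels:
            sc, labels = io.read_labeled_sc_matrix(config.sc_matrix, config.sc_labels)
            catalog = markers.derive_markers(
                sc, labels, max_markers=config.max_markers, auc_min=config.auc_min
            )
        else:
            raise FileNotFoundError("need either marker_catalog or sc_matrix + sc_labels")
        io.write_marker_catalog(catalog, out_dir / "marker_catalog.tsv", header_lines=header)
        manifest["stages"]["markers"] = {
            "n_cell_types": len(catalog.cell_types),
            "n_markers": len(catalog.all_markers()),
        }

        stage = "shifts"
        shift_report = shifts.marker_shift_test(
            corrected, meta, catalog, variant=config.shift_test_variant
        )
        io.write_table(
            shift_report,
            out_dir / "shift_report.tsv",
            header_lines=header
            + [
                f"test variant: {config.shift_test_variant}",
                "p-values are raw (no correction across cell types)",
            ],
        )
        heat = shifts.shift_heatmap_table(corrected, meta, catalog)
        io.write_table(heat.reset_index(), out_dir / "shift_heatmap.tsv", header_lines=header)
        manifest["stages"]["shifts"] = {"n_cell_types": len(shift_report)}

        stage = "enrichment"
        if config.gene_sets:
            collection = io.read_gmt(config.gene_sets)
            universe = de_table.loc[de_table["tested"], "gene"].tolist()
            degs_table = de.degs(de_table)
            for direction, status in (("up", de.STATUS_UP), ("down", de.STATUS_DOWN)):
                query = degs_table.loc[degs_table["status"] == status, "gene"].tolist()
                ora_res = enrichment.ora(query, universe, collection)
                io.write_table(
                    ora_res, out_dir / f"ora_{direction}.tsv", header_lines=header
                )
            ranking = enrichment.ranking_from_de(de_table)
            gsea_res = enrichment.gsea(
                ranking, collection, n_perm=config.n_perm, seed=config.seed
            )
            io.write_table(
                gsea_res,
                out_dir / "gsea.tsv",
                header_lines=header + [f"n_perm: {config.n_perm}"],
            )
            manifest["stages"]["enrichment"] = {"n_sets": len(collection)}
        else:
            logger.info("no gene set collection supplied; enrichment stage skipped")
            manifest["stages"]["enrichment"] = {"n_sets": 0}

        stage = "specificity"
        externals = io.read_external_de_tables(config.externals) if config.externals else []
        spec_result = specificity.uniqueness_filter(
            de_table, externals, p_thresh=config.external_p_thresh
        )
        partition = spec_result.all_degs.copy()
        seen = set(spec_result.previously_seen["gene"])
        flagged = dict(
            zip(spec_result.previously_seen["gene"], spec_result.previously_seen["flagged_by"])
        )
        partition["unique"] = [g not in seen for g in partition["gene"]]
        partition["flagged_by"] = [flagged.get(g, "") for g in partition["gene"]]
        io.write_table(
            partition,
            out_dir / "specificity_partition.tsv",
            header_lines=header + [f"external p threshold: {config.external_p_thresh}"],
        )
        enr = specificity.marker_specificity_enrichment(spec_result, catalog)
        io.write_table(enr, out_dir / "specificity_enrichment.tsv", header_lines=header)
        manifest["stages"]["specificity"] = {
            "n_degs": len(spec_result.all_degs),
            "n_unique": len(spec_result.unique_degs),
            "n_previously_seen": len(spec_result.previously_seen),
        }

        stage = "signature"
        sig = specificity.prioritize_signature(
            spec_result, catalog, tpm_min=config.tpm_min, lfc_min=config.lfc_min
        )
        io.write_table(
            sig,
            out_dir / "signature.tsv",
            header_lines=header
            + [f"tpm_min: {config.tpm_min}", f"lfc_min: {config.lfc_min}"],
        )
        manifest["stages"]["signature"] = specificity.signature_summary(sig)

        with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        return manifest
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage_name: str, cause: Exception):
        super().__init__(f"stage {stage_name!r} failed: {cause}")
        self.stage_name = stage_name
        self.cause = cause
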
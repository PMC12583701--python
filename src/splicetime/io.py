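"""Readers, writers, run configuration and the end-to-end pipeline.

Coordinates are 0-based half-open everywhere (rMATS/BED convention).
The pipeline stages run in order: junction counts -> PSI trajectories ->
relative inclusion -> switch calls per condition -> category table ->
motif enrichment over affected exons (+ optional IP-MS cross-reference),
and every output is reproducible from the serialised config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Fasta

from . import psi_core, rbp_enrichment, switch_classify
from .proteomics_filter import DEFAULT_CUTOFF, abundance_ratio, filter_interactors
from .psi_core import (
    DEFAULT_MIN_PSI_RANGE,
    DEFAULT_MIN_TOTAL_READS,
    DEFAULT_SIGMA_TOL,
    DEFAULT_ZERO_TOL,
    JunctionCounts,
    PsiTrajectory,
    SwitchCall,
    UntestableTrajectoryError,
)
from .rbp_enrichment import DEFAULT_ALPHA, DEFAULT_FLANK, ExonInterval

logger = logging.getLogger("splicetime")

__all__ = [
    "RmatsParseError",
    "RunConfig",
    "read_rmats_se",
    "read_bed6",
    "assemble_trajectories",
    "call_switches",
    "write_psi_matrix",
    "read_psi_matrix",
    "run_pipeline",
]

REQUIRED_SE_COLUMNS = [
    "ID", "GeneID", "geneSymbol", "chr", "strand",
    "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IncFormLen", "SkipFormLen",
]


class RmatsParseError(ValueError):
    """Malformed rMATS table (missing column, ragged replicate lists...)."""


def _parse_count_list(text: str) -> tuple[Optional[int], ...]:
    out = []
    for tok in str(text).split(","):
        tok = tok.strip()
        out.append(None if tok in ("NA", "", "nan") else int(tok))
    return tuple(out)


def read_rmats_se(path, timepoint: str = "", condition: str = "") -> list[dict]:
    """Read one rMATS skipped-exon table (JC dialect, SAMPLE_1 columns).

    Returns one record per row: the :class:`~splicetime.psi_core.JunctionCounts`
    plus the exon's coordinates.  ``NA`` replicate entries become missing;
    ragged inclusion/skipping lists raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_SE_COLUMNS if c not in df.columns]
    if missing:
        raise RmatsParseError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        inc = _parse_count_list(row["IJC_SAMPLE_1"])
        skip = _parse_count_list(row["SJC_SAMPLE_1"])
        if len(inc) != len(skip):
            raise RmatsParseError(
                f"{path} line {i + 2}: IJC has {len(inc)} replicates, "
                f"SJC has {len(skip)}"
            )
        counts = JunctionCounts(
            exon_id=str(row["geneSymbol"]),
            timepoint=timepoint,
            condition=condition,
            inclusion=inc,
            skipping=skip,
            inc_form_len=int(row["IncFormLen"]),
            skip_form_len=int(row["SkipFormLen"]),
        )
        records.append(
            {
                "counts": counts,
                "gene_id": str(row["GeneID"]),
                "chrom": str(row["chr"]),
                "strand": str(row["strand"]),
                "start": int(row["exonStart_0base"]),
                "end": int(row["exonEnd"]),
                "upstream_end": int(row["upstreamEE"]),
                "downstream_start": int(row["downstreamES"]),
            }
        )
    return records


def read_bed6(path) -> list[ExonInterval]:
    """BED6 cassette-exon intervals (chrom, start, end, name, score, strand)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path} line {ln}: BED6 needs 6 columns")
            out.append(
                ExonInterval(
                    exon_id=parts[3],
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                )
            )
    return out


def assemble_trajectories(
    cells: Sequence[JunctionCounts],
    timepoints: Sequence[str],
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS,
) -> dict[tuple[str, str], PsiTrajectory]:
    """Group per-cell junction counts into (exon, condition) trajectories."""
    order = {tp: i for i, tp in enumerate(timepoints)}
    grid: dict[tuple[str, str], dict[str, tuple[float, int]]] = {}
    for cell in cells:
        if cell.timepoint not in order:
            raise ValueError(f"unknown timepoint {cell.timepoint!r}")
        psi, n_inf = psi_core.compute_psi(cell, min_total_reads=min_total_reads)
        grid.setdefault((cell.exon_id, cell.condition), {})[cell.timepoint] = (
            psi,
            n_inf,
        )
    out = {}
    for key, cells_by_tp in grid.items():
        psi, n_inf = [], []
        for tp in timepoints:
            value, n = cells_by_tp.get(tp, (float("nan"), 0))
            psi.append(value)
            n_inf.append(n)
        out[key] = PsiTrajectory(
            exon_id=key[0],
            condition=key[1],
            timepoints=tuple(timepoints),
            psi=tuple(psi),
            n_informative=tuple(n_inf),
        )
    return out


def call_switches(
    trajectories: Mapping[tuple[str, str], PsiTrajectory],
    condition: str,
    sigma_tol: float = DEFAULT_SIGMA_TOL,
    zero_tol: float = DEFAULT_ZERO_TOL,
    min_psi_range: float = DEFAULT_MIN_PSI_RANGE,
    ddof: int = 0,
) -> dict[str, Union[SwitchCall, str]]:
    """Switch calls for every exon of one condition.

    Untestable exons (fewer than two informative timepoints) map to the
    exclusion reason string ``"untestable"`` instead of a call.
    """
    out: dict[str, Union[SwitchCall, str]] = {}
    for (exon_id, cond), traj in trajectories.items():
        if cond != condition:
            continue
        try:
            out[exon_id] = psi_core.call_switch(
                traj,
                sigma_tol=sigma_tol,
                zero_tol=zero_tol,
                min_psi_range=min_psi_range,
                ddof=ddof,
            )
        except UntestableTrajectoryError:
            out[exon_id] = "untestable"
    return out


def write_psi_matrix(
    trajectories: Mapping[tuple[str, str], PsiTrajectory], path
) -> pd.DataFrame:
    """One row per exon, one ``condition.timepoint`` column per cell, NA for
    missing; TSV round-trips through :func:`read_psi_matrix`."""
    rows: dict[str, dict[str, float]] = {}
    columns: list[str] = []
    for (exon_id, condition), traj in sorted(trajectories.items()):
        for tp, psi in zip(traj.timepoints, traj.psi):
            col = f"{condition}.{tp}"
            if col not in columns:
                columns.append(col)
            rows.setdefault(exon_id, {})[col] = psi
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    df.index.name = "exon_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")
    return df


def read_psi_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="exon_id", na_values="NA")


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Validated parameters of one end-to-end run."""

    se_tables: dict[str, str] = field(default_factory=dict)  # "cond:tp" -> path
    bed: Optional[str] = None
    fasta: Optional[str] = None
    motifs: Optional[str] = None  # default: bundled 46-RBP set
    abundance: Optional[str] = None  # IP-MS abundance TSV
    interactome: Optional[str] = None  # pre-filtered interactor list TSV
    outdir: str = "splicetime_out"
    timepoints: tuple[str, ...] = ("DIV0", "DIV3", "DIV5", "DIV10")
    control: str = "control"
    treatment: str = "treatment"
    min_total_reads: int = DEFAULT_MIN_TOTAL_READS
    sigma_tol: float = DEFAULT_SIGMA_TOL
    zero_tol: float = DEFAULT_ZERO_TOL
    min_psi_range: float = DEFAULT_MIN_PSI_RANGE
    ddof: int = 0
    flank: int = DEFAULT_FLANK
    background: str = "unaffected"  # or "non_affected" (incl. excluded) ...
    alpha: float = DEFAULT_ALPHA
    ratio_cutoff: float = DEFAULT_CUTOFF
    ratio_numerator: str = "blocked_stimulated"
    ratio_denominator: str = "stimulated"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["timepoints"] = list(self.timepoints)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analytic parameters (the output location is not one)."""
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_all_cells(cfg: RunConfig) -> list[JunctionCounts]:
    cells = []
    for key, path in cfg.se_tables.items():
        condition, _, timepoint = key.partition(":")
        if not timepoint:
            raise ValueError(f"se_tables key {key!r} must look like 'condition:timepoint'")
        for rec in read_rmats_se(path, timepoint=timepoint, condition=condition):
            cells.append(rec["counts"])
    return cells


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the result bundle under ``cfg.outdir``.

    Outputs: ``psi_matrix.tsv``, ``categories.tsv``, ``enrichment.tsv``
    (when sequence inputs are present), ``summary.json``, ``run.log`` and a
    serialised copy of the configuration.  Returns the summary dict.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
        logger.info("config hash %s", cfg.config_hash)

        cells = _load_all_cells(cfg)
        logger.info("read %d junction-count cells", len(cells))
        trajectories = assemble_trajectories(
            cells, cfg.timepoints, min_total_reads=cfg.min_total_reads
        )
        write_psi_matrix(trajectories, outdir / "psi_matrix.tsv")

        kwargs = dict(
            sigma_tol=cfg.sigma_tol,
            zero_tol=cfg.zero_tol,
            min_psi_range=cfg.min_psi_range,
            ddof=cfg.ddof,
        )
        control_calls = call_switches(trajectories, cfg.control, **kwargs)
        treatment_calls = call_switches(trajectories, cfg.treatment, **kwargs)
        table = switch_classify.categorize_all(control_calls, treatment_calls)
        table.to_csv(outdir / "categories.tsv", sep="\t", index=False, na_rep="NA")
        summary = switch_classify.category_summary(table).as_dict()
        logger.info("categories: %s", summary)

        enrichment = None
        refined: list[str] = []
        if cfg.bed and cfg.fasta:
            included = table.loc[~table["excluded"]]
            affected = included.loc[
                included["category"] != "Unaffected", "exon_id"
            ].tolist()
            if cfg.background == "unaffected":
                background = included.loc[
                    included["category"] == "Unaffected", "exon_id"
                ].tolist()
            else:
                background = [e for e in table["exon_id"] if e not in set(affected)]
            if not affected:
                logger.warning("no affected exons: enrichment stage skipped")
            else:
                exons = read_bed6(cfg.bed)
                genome = Fasta(str(cfg.fasta))
                regions = rbp_enrichment.extract_flanks(exons, genome, flank=cfg.flank)
                motifs = (
                    rbp_enrichment.load_motifs(cfg.motifs)
                    if cfg.motifs
                    else rbp_enrichment.bundled_motifs()
                )
                presence, _counts = rbp_enrichment.scan_motifs(regions, motifs)
                enrichment = rbp_enrichment.fisher_enrichment(
                    presence, affected, background
                )
                interactors: list[str] = []
                if cfg.abundance:
                    ratios = abundance_ratio(
                        pd.read_csv(cfg.abundance, sep="\t"),
                        cfg.ratio_numerator,
                        cfg.ratio_denominator,
                    )
                    interactors, _ = filter_interactors(ratios, cutoff=cfg.ratio_cutoff)
                elif cfg.interactome:
                    interactors = (
                        pd.read_csv(cfg.interactome, sep="\t")["protein"]
                        .astype(str)
                        .tolist()
                    )
                enrichment = rbp_enrichment.crossref_interactome(
                    enrichment, interactors, alpha=cfg.alpha
                )
                refined = enrichment.loc[
                    enrichment["refined_candidate"], "rbp_name"
                ].tolist()
                enrichment.to_csv(
                    outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
                )
                logger.info("refined RBP candidates: %s", refined)

        summary_out = {
            "config_hash": cfg.config_hash,
            "categories": summary,
            "refined_candidates": refined,
            "n_rbps_tested": 0 if enrichment is None else len(enrichment),
        }
        (outdir / "summary.json").write_text(json.dumps(summary_out, indent=1))
        return summary_out
    finally:
        logger.removeHandler(handler)
        handler.close()
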
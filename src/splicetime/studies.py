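"""Simulation studies over the pipeline: recovery, calibration, power.

These are the package's own validation experiments, run both by the test
suite and by ``scripts/acceptance.py``.  Problem sizes follow the default
study design (300 exons, 3 replicates, 100 reads/event) and the motif
studies use 200 affected + 200 background exons; both are deliberately
desk-sized so a full validation pass completes in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import RunConfig, run_pipeline
from .rbp_enrichment import (
    bh_fdr,
    bundled_motifs,
    crossref_interactome,
    fisher_enrichment,
    fisher_p,
    scan_motifs,
)
from .synthetic_data import SimConfig, simulate, simulate_region_sets

__all__ = [
    "run_default_study",
    "category_recovery",
    "fisher_oracle_agreement",
    "type_one_error_study",
    "power_refinement_study",
]


def run_default_study(
    seed: int, workdir, noise: bool = True, sim_cfg: Optional[SimConfig] = None
) -> dict:
    """Simulate the default study and run the full pipeline over it.

    Returns a dict with the pipeline summary, the planted truth, and the
    per-exon category recovery fraction (over exons planted non-Unaffected
    as well as overall).
    """
    workdir = Path(workdir)
    cfg = sim_cfg or SimConfig()
    cfg = dataclasses.replace(cfg, seed=seed)
    bundle = simulate(cfg, workdir / "data", noise=noise)
    run_cfg = RunConfig(
        se_tables={k: str(p) for k, p in bundle.se_tables.items()},
        bed=str(bundle.bed),
        fasta=str(bundle.fasta),
        motifs=str(bundle.motifs),
        interactome=str(bundle.interactome),
        outdir=str(workdir / "out"),
        seed=seed,
    )
    summary = run_pipeline(run_cfg)
    truth = json.loads(bundle.truth.read_text())
    table = pd.read_csv(workdir / "out" / "categories.tsv", sep="\t")
    true_cat = {e["exon_id"]: e["category"] for e in truth["exons"]}
    table["true_category"] = table["exon_id"].map(true_cat)
    correct = table["category"] == table["true_category"]
    non_unaffected = table["true_category"] != "Unaffected"
    true_switch = {
        e["exon_id"]: e["switch_index_control"] for e in truth["exons"]
    }
    obs_switch = {
        r.exon_id: (None if pd.isna(r.control_switch) else int(r.control_switch))
        for r in table.itertuples()
    }
    switch_correct = np.mean(
        [obs_switch.get(k) == v for k, v in true_switch.items()]
    )
    return {
        "summary": summary,
        "truth_histogram": truth["category_histogram"],
        "n_exons": len(table),
        "recovery_overall": float(correct.mean()),
        "recovery_non_unaffected": float(correct[non_unaffected].mean()),
        "control_switch_index_recovery": float(switch_correct),
    }


def category_recovery(seed: int, workdir, noise: bool = True) -> float:
    """Fraction of planted non-Unaffected exons recovering their category."""
    return run_default_study(seed, workdir, noise=noise)["recovery_non_unaffected"]


def _two_sided_oracle_vector(n1: int, n2: int, k: int) -> np.ndarray:
    """Exhaustive two-sided p for every feasible a at fixed margins: the sum
    of hypergeometric probabilities no larger than the observed one."""
    lo, hi = max(0, k - n2), min(n1, k)
    xs = np.arange(lo, hi + 1)
    if len(xs) == 1:  # margins admit a single table
        return xs, np.ones(1)
    pmf = hypergeom.pmf(xs, n1 + n2, k, n1)
    pmf = pmf / pmf.sum()
    ps = np.array(
        [pmf[pmf <= pmf[i] * (1 + 1e-9)].sum() for i in range(len(xs))]
    )
    return xs, np.minimum(ps, 1.0)


def fisher_oracle_agreement(max_margin: int = 30) -> dict:
    """Compare the exact-test p against hypergeometric enumeration on every
    2x2 table with both row margins <= ``max_margin``.

    The implementation p is evaluated once per symmetry orbit (the test is
    invariant under swapping rows or columns, as is the enumeration oracle);
    the oracle is evaluated for every table.  Returns the number of tables
    checked and the maximum absolute discrepancy.
    """
    cache: dict[tuple, float] = {}

    def impl(a, b, c, d):
        orbit = min((a, b, c, d), (c, d, a, b), (b, a, d, c), (d, c, b, a))
        if orbit not in cache:
            cache[orbit] = fisher_p(*orbit)
        return cache[orbit]

    n_tables = 0
    max_err = 0.0
    for n1 in range(max_margin + 1):
        for n2 in range(max_margin + 1):
            for k in range(n1 + n2 + 1):
                xs, oracle = _two_sided_oracle_vector(n1, n2, k)
                for a, p_oracle in zip(xs, oracle):
                    a = int(a)
                    b, c, d = n1 - a, k - a, n2 - (k - a)
                    err = abs(impl(a, b, c, d) - p_oracle)
                    max_err = max(max_err, err)
                    n_tables += 1
    return {"n_tables": n_tables, "max_abs_error": float(max_err)}


def type_one_error_study(
    seed: int,
    n_replicates: int = 200,
    n_per_group: int = 200,
    plant_rate: float = 0.3,
) -> dict:
    """False-positive calibration with no planted motif bias.

    Both exon sets are drawn from the same background model, with the
    enriched-RBP panel planted at the *same* rate in both groups, so every
    per-RBP Fisher test is null.  Returns the pooled fraction of tests with
    p < 0.05; the exact test is conservative on discrete tables, so the
    fraction sits at or below the nominal level.
    """
    motifs = bundled_motifs()
    cfg = SimConfig(
        plant_rate_affected=plant_rate, plant_rate_background=plant_rate, seed=seed
    )
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_tests = 0
    for _ in range(n_replicates):
        regions, affected, background, _ = simulate_region_sets(
            n_per_group, n_per_group, motifs, cfg, rng
        )
        presence, _ = scan_motifs(regions, motifs)
        res = fisher_enrichment(presence, affected, background)
        n_sig += int((res["p_value"] < 0.05).sum())
        n_tests += len(res)
    return {
        "fraction_significant": n_sig / n_tests,
        "n_tests": n_tests,
        "n_replicates": n_replicates,
        "nominal": 0.05,
    }


def power_refinement_study(
    seed: int,
    n_runs: int = 100,
    n_per_group: int = 200,
    rate_affected: float = 0.6,
    rate_background: float = 0.1,
    planted_in: str = "RBFOX2",
    planted_out: str = "CELF1",
    alpha: float = 0.05,
) -> dict:
    """Power of the enrichment + interactome-refinement chain.

    Two RBPs are planted at ``rate_affected`` vs ``rate_background``; one is
    in the IP-MS interactome, the other is not.  A run succeeds when the
    in-interactome planted RBP is the *sole* refined candidate at
    ``q <= alpha``.  Also reports how often each planted RBP reaches
    significance at all.
    """
    motifs = bundled_motifs()
    base = SimConfig(
        enriched_rbps=(planted_in, planted_out),
        plant_rate_affected=rate_affected,
        plant_rate_background=rate_background,
    )
    interactome = [n for n in base.interactome if n != planted_out]
    rng = np.random.default_rng(seed)
    sole = 0
    planted_sig = 0
    for _ in range(n_runs):
        regions, affected, background, _ = simulate_region_sets(
            n_per_group, n_per_group, motifs, base, rng
        )
        presence, _ = scan_motifs(regions, motifs)
        res = fisher_enrichment(presence, affected, background)
        res = crossref_interactome(res, interactome, alpha=alpha)
        refined = set(res.loc[res["refined_candidate"], "rbp_name"])
        planted_q = res.set_index("rbp_name").loc[planted_in, "q_value"]
        planted_sig += int(planted_q <= alpha)
        sole += int(refined == {planted_in})
    return {
        "fraction_sole_refined": sole / n_runs,
        "fraction_planted_significant": planted_sig / n_runs,
        "n_runs": n_runs,
    }
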
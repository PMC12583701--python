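"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

The generator emulates a 4-timepoint (DIV0/DIV3/DIV5/DIV10), 2-condition
(control vs knockdown), replicated junction-count experiment.  Each cassette
exon follows a logistic inclusion trajectory

    psi(t) = psi_low + (psi_high - psi_low) / (1 + exp(-k (t - t0)))

with a planted switch time t0; the perturbed condition's t0 is shifted
earlier (Early), later or beyond the observation window (Late), mirrored
(Reversed) or identical (Unaffected).  Junction reads are Poisson-Binomial:
per replicate the total T ~ Poisson(reads_per_event) and inclusion reads
~ Binomial(T, p) with p = psi*lI / (psi*lI + (1-psi)*lS), so the
length-normalised PSI estimator is unbiased for psi.

Flanking sequences are i.i.d. background nucleotides at a configured GC
content; for the designated "enriched" RBPs, chance motif occurrences are
scrubbed from every window and one concrete consensus instance is planted
with probability ``plant_rate_affected`` in affected exons' windows and
``plant_rate_background`` otherwise, so motif presence equals the planted
indicator for those RBPs.

Control switch times sit at the midpoints of the inter-timepoint intervals
(1.5, 4.0, 7.5 d for the default grid) with a small jitter shared between
conditions, and the default delay (3 d) maps midpoints onto midpoints; no
planted switch ever falls on a sampled timepoint, so the planted truth is
recoverable exactly in the noise-free limit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .psi_core import PsiTrajectory, call_switch
from .rbp_enrichment import (
    IUPAC,
    ExonInterval,
    MotifDefinition,
    RegionSet,
    _consensus_regex,
    bundled_motifs,
)

__all__ = [
    "SimConfig",
    "TruthExon",
    "SyntheticBundle",
    "simulate_trajectories",
    "simulate_counts",
    "simulate_flank_sequences",
    "simulate_region_sets",
    "emit_truth",
    "simulate",
    "DEFAULT_INTERACTOME",
]

CONTROL = "control"
TREATMENT = "treatment"

#: Default IP-MS interactome (protein names as they appear after the
#: abundance-ratio filter).  Splicing factors reported to co-precipitate
#: with paxillin; note CELF1 is deliberately absent so that an enriched
#: RBP outside the interactome is never a refined candidate.
DEFAULT_INTERACTOME = (
    "U2AF1", "U2AF2", "SF1", "SF3B1", "HNRNPK", "SRSF1", "SRSF7",
    "ELAVL4", "FUS", "MATR3", "NOVA1", "NOVA2", "RBFOX2", "IGF2BP1",
)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic experiment."""

    n_early: int = 30
    n_late: int = 100
    n_reversed: int = 35
    n_unaffected: int = 135
    timepoints: tuple[str, ...] = ("DIV0", "DIV3", "DIV5", "DIV10")
    times: tuple[float, ...] = (0.0, 3.0, 5.0, 10.0)
    n_replicates: int = 3
    reads_per_event: float = 100.0  # Poisson mean of junction reads/replicate
    psi_low: float = 0.1
    psi_high: float = 0.9
    steepness: float = 10.0  # logistic k, per day
    delay: float = 3.0  # knockdown switch delay delta, days
    jitter: float = 0.2  # +/- jitter on t0, shared between conditions, days
    inc_form_len: int = 150
    skip_form_len: int = 50
    exon_len: int = 120
    flank: int = 200
    spacer: int = 100  # intergenic pad between simulated loci, nt
    gc: float = 0.45
    enriched_rbps: tuple[str, ...] = ("RBFOX2", "U2AF2", "CELF1")
    plant_rate_affected: float = 0.6
    plant_rate_background: float = 0.1
    interactome: tuple[str, ...] = DEFAULT_INTERACTOME
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.plant_rate_affected, self.plant_rate_background, self.gc):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"probability {r} outside [0, 1]")
        if min(self.n_early, self.n_late, self.n_reversed, self.n_unaffected) < 0:
            raise ValueError("category counts must be >= 0")
        if len(self.timepoints) != len(self.times):
            raise ValueError("timepoints and times differ in length")
        if not 0.0 <= self.psi_low < self.psi_high <= 1.0:
            raise ValueError("need 0 <= psi_low < psi_high <= 1")

    @property
    def n_exons(self) -> int:
        return self.n_early + self.n_late + self.n_reversed + self.n_unaffected


@dataclass
class TruthExon:
    """Planted ground truth for one simulated cassette exon."""

    exon_id: str
    category: str
    direction: str  # control switch direction: "up" | "down"
    t0_control: float
    t0_treatment: float
    psi_control: tuple[float, ...]
    psi_treatment: tuple[float, ...]
    switch_index_control: Optional[int]
    switch_index_treatment: Optional[int]
    direction_control: str
    direction_treatment: str
    motif_plants: dict = field(default_factory=dict)  # rbp -> [(window, pos), ...]


def _logistic_psi(times: Sequence[float], t0: float, cfg: SimConfig, up: bool):
    t = np.asarray(times, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-cfg.steepness * (t - t0)))
    psi = cfg.psi_low + (cfg.psi_high - cfg.psi_low) * rise
    if not up:
        psi = cfg.psi_low + cfg.psi_high - psi  # mirrored trajectory
    return tuple(float(p) for p in psi)


def _noise_free_call(exon_id: str, condition: str, psi, cfg: SimConfig):
    traj = PsiTrajectory(
        exon_id=exon_id,
        condition=condition,
        timepoints=cfg.timepoints,
        psi=psi,
        n_informative=tuple([cfg.n_replicates] * len(psi)),
    )
    return call_switch(traj)


def _interval_midpoints(times: Sequence[float]) -> list[float]:
    return [(a + b) / 2.0 for a, b in zip(times[:-1], times[1:])]


def simulate_trajectories(cfg: SimConfig, rng: np.random.Generator) -> list[TruthExon]:
    """Plant per-exon, per-condition psi(t) trajectories with known truth.

    The recorded truth switch indices/directions are the noise-free calls of
    the planted trajectories, which the construction keeps consistent with
    the planted category by design.
    """
    mids = _interval_midpoints(cfg.times)
    last = cfg.times[-1]
    plan = (
        ["Early"] * cfg.n_early
        + ["Late"] * cfg.n_late
        + ["Reversed"] * cfg.n_reversed
        + ["Unaffected"] * cfg.n_unaffected
    )
    exons = []
    for i, category in enumerate(plan):
        exon_id = f"exon{i:04d}"
        up = bool(rng.integers(0, 2))
        u = rng.uniform(-cfg.jitter, cfg.jitter)
        if category == "Early":
            # control must not sit in the first interval or the shifted
            # switch would leave the observation window
            c0 = rng.choice([m for m in mids if m - cfg.delay > cfg.times[0]]) + u
            t_trt = c0 - cfg.delay
        elif category == "Late":
            c0 = rng.choice(mids) + u
            t_trt = c0 + cfg.delay
            if t_trt > last:
                # switch never arrives: push it well past the window so the
                # perturbed trajectory is unambiguously flat
                t_trt = last + cfg.delay
        else:
            c0 = rng.choice(mids) + u
            t_trt = c0
        trt_up = (not up) if category == "Reversed" else up
        psi_c = _logistic_psi(cfg.times, c0, cfg, up)
        psi_t = _logistic_psi(cfg.times, t_trt, cfg, trt_up)
        call_c = _noise_free_call(exon_id, CONTROL, psi_c, cfg)
        call_t = _noise_free_call(exon_id, TREATMENT, psi_t, cfg)
        exons.append(
            TruthExon(
                exon_id=exon_id,
                category=category,
                direction="up" if up else "down",
                t0_control=float(c0),
                t0_treatment=float(t_trt),
                psi_control=psi_c,
                psi_treatment=psi_t,
                switch_index_control=call_c.switch_index,
                switch_index_treatment=call_t.switch_index,
                direction_control=call_c.direction,
                direction_treatment=call_t.direction,
            )
        )
    return exons


# ---------------------------------------------------------------------------
# junction counts

RMATS_COLUMNS = [
    "ID", "GeneID", "geneSymbol", "chr", "strand",
    "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IncFormLen", "SkipFormLen", "IncLevel1",
]


def _sample_counts(psi: float, cfg: SimConfig, rng, noise: bool):
    """One cell's replicate (I, S) draws under the Poisson-Binomial model."""
    li, ls = cfg.inc_form_len, cfg.skip_form_len
    p = psi * li / (psi * li + (1.0 - psi) * ls)
    inc, skip = [], []
    for _ in range(cfg.n_replicates):
        if noise:
            total = int(rng.poisson(cfg.reads_per_event))
            i = int(rng.binomial(total, p)) if total > 0 else 0
        else:
            total = int(round(cfg.reads_per_event)) * 100
            i = int(round(total * p))
        inc.append(i)
        skip.append(total - i)
    return inc, skip


def simulate_counts(
    exons: Sequence[TruthExon],
    cfg: SimConfig,
    rng: np.random.Generator,
    outdir: Path,
    intervals: Optional[Sequence[ExonInterval]] = None,
    noise: bool = True,
) -> dict[str, Path]:
    """Emit one rMATS-dialect SE table per condition x timepoint.

    ``noise=False`` uses a large fixed read depth with rounded expected
    counts (the noise-free limit used for exact-recovery checks).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coords = {iv.exon_id: iv for iv in intervals} if intervals else {}
    files: dict[str, Path] = {}
    for condition in (CONTROL, TREATMENT):
        for ti, tp in enumerate(cfg.timepoints):
            path = outdir / f"SE.MATS.JC.{condition}.{tp}.txt"
            lines = ["\t".join(RMATS_COLUMNS)]
            for idx, ex in enumerate(exons):
                psi = (ex.psi_control if condition == CONTROL else ex.psi_treatment)[ti]
                inc, skip = _sample_counts(psi, cfg, rng, noise)
                iv = coords.get(ex.exon_id)
                chrom = iv.chrom if iv else "chrSim"
                strand = iv.strand if iv else "+"
                start = iv.start if iv else idx * 1000
                end = iv.end if iv else idx * 1000 + cfg.exon_len
                inc_levels = []
                for i, s in zip(inc, skip):
                    if i + s == 0:
                        inc_levels.append("NA")
                    else:
                        li, ls = cfg.inc_form_len, cfg.skip_form_len
                        inc_levels.append(f"{(i / li) / (i / li + s / ls):.3f}")
                lines.append(
                    "\t".join(
                        [
                            str(idx), f"gene{idx:04d}", ex.exon_id, chrom, strand,
                            str(start), str(end),
                            str(start - cfg.flank - cfg.spacer),
                            str(start - cfg.flank),
                            str(end + cfg.flank),
                            str(end + cfg.flank + cfg.spacer),
                            ",".join(map(str, inc)), ",".join(map(str, skip)),
                            str(cfg.inc_form_len), str(cfg.skip_form_len),
                            ",".join(inc_levels),
                        ]
                    )
                )
            path.write_text("\n".join(lines) + "\n")
            files[f"{condition}:{tp}"] = path
    return files


# ---------------------------------------------------------------------------
# sequences

_BASES = np.array(list("ACGT"))


def _random_seq(n: int, gc: float, rng) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _scrub(seq: np.ndarray, patterns, gc: float, rng, max_rounds: int = 50) -> np.ndarray:
    """Resample any chance occurrence of the given motif patterns until the
    window is clean, so presence of an enriched motif equals its plant."""
    s = seq.copy()
    for _ in range(max_rounds):
        text = "".join(s)
        dirty = False
        for pat in patterns:
            for m in pat.finditer(text):
                matched = m.group(1)
                start = m.start()
                s[start : start + len(matched)] = _random_seq(len(matched), gc, rng)
                dirty = True
        if not dirty:
            return s
    raise RuntimeError("could not scrub motif occurrences from window")


def _realize(consensus: str, rng) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in consensus.upper())


def _plant_windows(
    enriched: Sequence[MotifDefinition],
    rate: float,
    window_lens: Sequence[int],
    window_names: Sequence[str],
    gc: float,
    rng,
    scrub_patterns,
    max_tries: int = 20,
) -> tuple[list[np.ndarray], dict]:
    """Scrubbed windows with verified motif plants.

    Draws the per-RBP plant indicators once, then rebuilds the windows until
    the realised presence pattern of every enriched RBP equals its plant
    indicator (plants are placed at non-overlapping positions, and a rebuild
    guards against a plant creating a spurious cross-match)."""
    todo = [m for m in enriched if rng.random() < rate]
    for _ in range(max_tries):
        windows = []
        for n in window_lens:
            w = _random_seq(n, gc, rng)
            if scrub_patterns:
                w = _scrub(w, scrub_patterns, gc, rng)
            windows.append(w)
        rec: dict = {}
        occupied: dict[int, list[tuple[int, int]]] = {}
        ok = True
        for m in todo:
            instance = _realize(
                m.consensus[int(rng.integers(0, len(m.consensus)))], rng
            )
            placed = False
            for _attempt in range(50):
                wi = int(rng.integers(0, len(window_lens)))
                if window_lens[wi] < len(instance):
                    continue
                start = int(rng.integers(0, window_lens[wi] - len(instance) + 1))
                span = (start, start + len(instance))
                if any(
                    s < span[1] and span[0] < e for s, e in occupied.get(wi, [])
                ):
                    continue
                windows[wi][span[0] : span[1]] = list(instance)
                occupied.setdefault(wi, []).append(span)
                rec.setdefault(m.rbp_name, []).append((window_names[wi], start))
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        # verify realised presence equals the plant indicators
        texts = ["".join(w) for w in windows]
        clean = True
        for m in enriched:
            found = any(
                _consensus_regex(c).search(t) for c in m.consensus for t in texts
            )
            if found != (m.rbp_name in rec):
                clean = False
                break
        if clean:
            return windows, rec
    raise RuntimeError("could not realise motif plants without cross-matches")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_flank_sequences(
    exons: Sequence[TruthExon],
    motifs: Sequence[MotifDefinition],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[ExonInterval]]:
    """Build a toy genome carrying the exons plus planted motif instances.

    Each locus is laid out as [flank | exon | flank] separated by spacers on
    a single chromosome; strands are random and minus-strand loci are
    written as the reverse complement of the transcript-sense construct.
    Plant positions are recorded on each :class:`TruthExon`.
    """
    by_name = {m.rbp_name: m for m in motifs}
    enriched = [by_name[n] for n in cfg.enriched_rbps if n in by_name]
    missing = set(cfg.enriched_rbps) - set(by_name)
    if missing:
        raise ValueError(f"enriched RBPs missing from motif set: {sorted(missing)}")
    for m in enriched:
        if max(len(c) for c in m.consensus) > min(cfg.flank, cfg.exon_len):
            raise ValueError(f"{m.rbp_name}: motif longer than scan window")
    scrub_patterns = [_consensus_regex(c) for m in enriched for c in m.consensus]
    window_names = ("upstream", "exon", "downstream")
    window_lens = (cfg.flank, cfg.exon_len, cfg.flank)

    segments: list[str] = []
    intervals: list[ExonInterval] = []
    pos = 0
    for ex in exons:
        affected = ex.category != "Unaffected"
        rate = cfg.plant_rate_affected if affected else cfg.plant_rate_background
        windows, rec = _plant_windows(
            enriched, rate, window_lens, window_names, cfg.gc, rng, scrub_patterns
        )
        ex.motif_plants.update(rec)
        sense = "".join("".join(w) for w in windows)
        strand = "+" if rng.random() < 0.5 else "-"
        segment = sense if strand == "+" else _revcomp(sense)
        spacer = "".join(_random_seq(cfg.spacer, cfg.gc, rng))
        segments.append(spacer + segment)
        locus_start = pos + cfg.spacer
        # exon body position within the genomic segment
        if strand == "+":
            exon_start = locus_start + cfg.flank
        else:
            exon_start = locus_start + cfg.flank  # symmetric layout
        intervals.append(
            ExonInterval(
                exon_id=ex.exon_id,
                chrom="chrSim",
                start=exon_start,
                end=exon_start + cfg.exon_len,
                strand=strand,
            )
        )
        pos += cfg.spacer + len(segment)
    segments.append("".join(_random_seq(cfg.spacer, cfg.gc, rng)))
    genome = {"chrSim": "".join(segments)}
    return genome, intervals


def simulate_region_sets(
    n_affected: int,
    n_background: int,
    motifs: Sequence[MotifDefinition],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[RegionSet], list[str], list[str], dict[str, dict]]:
    """Sequence windows only, for motif-enrichment simulation studies.

    Generates ``n_affected`` + ``n_background`` exon region sets under the
    same scrub-and-plant model as the full genome builder, without the
    trajectory/genome layers.  Returns regions, the two id lists, and the
    plant record per exon.
    """
    by_name = {m.rbp_name: m for m in motifs}
    enriched = [by_name[n] for n in cfg.enriched_rbps if n in by_name]
    scrub_patterns = [_consensus_regex(c) for m in enriched for c in m.consensus]
    window_lens = (cfg.flank, cfg.exon_len, cfg.flank)
    window_names = ("upstream", "exon", "downstream")
    regions, affected_ids, background_ids = [], [], []
    plants: dict[str, dict] = {}
    for i in range(n_affected + n_background):
        exon_id = f"exon{i:04d}"
        affected = i < n_affected
        rate = cfg.plant_rate_affected if affected else cfg.plant_rate_background
        windows, rec = _plant_windows(
            enriched, rate, window_lens, window_names, cfg.gc, rng, scrub_patterns
        )
        plants[exon_id] = rec
        regions.append(
            RegionSet(
                exon_id=exon_id,
                upstream="".join(windows[0]),
                exon="".join(windows[1]),
                downstream="".join(windows[2]),
            )
        )
        (affected_ids if affected else background_ids).append(exon_id)
    return regions, affected_ids, background_ids, plants


# ---------------------------------------------------------------------------
# emission

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def emit_truth(
    exons: Sequence[TruthExon], cfg: SimConfig, files: dict[str, Path], path: Path
) -> dict:
    """Serialise the planted truth plus a checksummed file manifest."""
    histogram: dict[str, int] = {}
    for ex in exons:
        histogram[ex.category] = histogram.get(ex.category, 0) + 1
    truth = {
        "config": asdict(cfg),
        "category_histogram": histogram,
        "exons": [asdict(ex) for ex in exons],
        "files": {
            key: {"path": str(p), "sha256": _sha256(Path(p))}
            for key, p in sorted(files.items())
        },
    }
    path = Path(path)
    path.write_text(json.dumps(truth, indent=1, default=str))
    return truth


@dataclass(frozen=True)
class SyntheticBundle:
    """Paths of one emitted synthetic dataset."""

    outdir: Path
    se_tables: dict[str, Path]
    bed: Path
    fasta: Path
    motifs: Path
    interactome: Path
    truth: Path


def simulate(cfg: SimConfig, outdir, noise: bool = True) -> SyntheticBundle:
    """Run the full generator and emit every input the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    motifs = bundled_motifs()
    exons = simulate_trajectories(cfg, rng)
    genome, intervals = simulate_flank_sequences(exons, motifs, cfg, rng)
    se_files = simulate_counts(exons, cfg, rng, outdir, intervals, noise=noise)

    bed = outdir / "exons.bed"
    with bed.open("w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.exon_id}\t0\t{iv.strand}\n"
            )
    fasta = outdir / "genome.fa"
    with fasta.open("w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    motif_tsv = outdir / "rbp_motifs.tsv"
    with motif_tsv.open("w") as fh:
        fh.write("rbp_name\tconsensus\tsource\n")
        for m in motifs:
            for c in m.consensus:
                fh.write(f"{m.rbp_name}\t{c}\t{m.source}\n")
    interactome_tsv = outdir / "interactome.tsv"
    with interactome_tsv.open("w") as fh:
        fh.write("protein\n")
        for name in cfg.interactome:
            fh.write(name + "\n")

    files = dict(se_files)
    files.update(
        {"bed": bed, "fasta": fasta, "motifs": motif_tsv, "interactome": interactome_tsv}
    )
    truth_path = outdir / "truth.json"
    emit_truth(exons, cfg, files, truth_path)
    return SyntheticBundle(
        outdir=outdir,
        se_tables=se_files,
        bed=bed,
        fasta=fasta,
        motifs=motif_tsv,
        interactome=interactome_tsv,
        truth=truth_path,
    )
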
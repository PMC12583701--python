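"""RBP motif enrichment over affected cassette exons and intronic flanks.

For each RNA-binding protein (RBP) with a known IUPAC consensus element,
tests whether exons whose switch timing was altered by the perturbation
carry the element (in the exon body or the adjacent 200 nt of each intron)
more often than unaffected exons, by a two-sided Fisher's exact test with
Benjamini-Hochberg FDR correction.  Significant RBPs are then refined by
cross-referencing against an immunoprecipitation/mass-spectrometry
interactome list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IUPAC",
    "MotifDefinition",
    "RegionSet",
    "ExonInterval",
    "load_motifs",
    "bundled_motifs",
    "extract_flanks",
    "scan_motifs",
    "fisher_enrichment",
    "bh_fdr",
    "crossref_interactome",
]

DEFAULT_FLANK = 200
DEFAULT_ALPHA = 0.05

#: IUPAC nucleotide codes mapped to the concrete bases they match.  An ``N``
#: in the *sequence* is unknown and never matches any motif position.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDefinition:
    """One RBP's consensus element(s); several consensi count as one RBP."""

    rbp_name: str
    consensus: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.rbp_name}: no consensus sequences")
        for c in self.consensus:
            if not c or any(b not in IUPAC for b in c.upper()):
                raise ValueError(f"{self.rbp_name}: invalid IUPAC consensus {c!r}")


@dataclass(frozen=True)
class ExonInterval:
    """BED-style cassette exon interval, 0-based half-open.

    ``left_bound``/``right_bound`` are the genomic coordinates of the
    nearest flanking-exon edges (upstream exon end / downstream exon start
    on the + strand reading); flanks are truncated there when the intron is
    shorter than the requested window.
    """

    exon_id: str
    chrom: str
    start: int
    end: int
    strand: str
    left_bound: Optional[int] = None
    right_bound: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.exon_id}: unknown strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.exon_id}: bad interval [{self.start},{self.end})")


@dataclass(frozen=True)
class RegionSet:
    """Transcript-sense sequence windows for one exon: body plus the
    adjacent intronic flanks (5' = upstream in transcript orientation)."""

    exon_id: str
    exon: str
    upstream: str
    downstream: str

    def windows(self) -> tuple[str, str, str]:
        return (self.upstream, self.exon, self.downstream)


def load_motifs(path) -> list[MotifDefinition]:
    """Read a motif TSV (columns: rbp_name, consensus, source); rows sharing
    an rbp_name are merged into one multi-consensus definition."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"rbp_name", "consensus"}
    if missing := required - set(df.columns):
        raise ValueError(f"motif table missing column(s): {sorted(missing)}")
    out = []
    for name, grp in df.groupby("rbp_name", sort=True):
        out.append(
            MotifDefinition(
                rbp_name=str(name),
                consensus=tuple(str(c).upper() for c in grp["consensus"]),
                source=",".join(sorted(set(map(str, grp.get("source", []))))),
            )
        )
    return out


def bundled_motifs() -> list[MotifDefinition]:
    """The curated 46-RBP eCLIP-style consensus set shipped with the package."""
    ref = resources.files("splicetime.data").joinpath("rbp_motifs.tsv")
    with resources.as_file(ref) as path:
        return load_motifs(path)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Upper-case slice [start, end) from a pyfaidx.Fasta or a plain mapping
    of chromosome name -> sequence string."""
    if start >= end:
        return ""
    seq = genome[chrom]
    return str(seq[start:end]).upper()


def extract_flanks(
    exons: Iterable[ExonInterval],
    genome,
    flank: int = DEFAULT_FLANK,
) -> list[RegionSet]:
    """Extract exon-body and up-to-``flank``-nt intronic windows per exon.

    ``genome`` may be a :class:`pyfaidx.Fasta` or a dict of chromosome
    sequences.  Minus-strand windows are reverse-complemented so every
    window reads transcript-sense; flanks are clipped at the neighbouring
    exon boundaries and at chromosome ends.
    """
    chrom_len = {}
    out = []
    for ex in exons:
        if ex.chrom not in chrom_len:
            chrom_len[ex.chrom] = len(genome[ex.chrom])
        clen = chrom_len[ex.chrom]
        if ex.end > clen:
            raise ValueError(
                f"{ex.exon_id}: interval end {ex.end} outside {ex.chrom} ({clen} nt)"
            )
        left_lo = max(ex.start - flank, ex.left_bound or 0, 0)
        right_hi = min(ex.end + flank, ex.right_bound or clen, clen)
        body = _fetch(genome, ex.chrom, ex.start, ex.end)
        left = _fetch(genome, ex.chrom, left_lo, ex.start)
        right = _fetch(genome, ex.chrom, ex.end, right_hi)
        if ex.strand == "+":
            up, down = left, right
        else:
            body = reverse_complement(body)
            up, down = reverse_complement(right), reverse_complement(left)
        out.append(RegionSet(exon_id=ex.exon_id, exon=body, upstream=up, downstream=down))
    return out


def _consensus_regex(consensus: str) -> re.Pattern:
    # lookahead makes overlapping occurrences countable
    body = "".join(
        c if len(IUPAC[c]) == 1 else "[" + IUPAC[c] + "]" for c in consensus.upper()
    )
    return re.compile(f"(?=({body}))")


def scan_motifs(
    regions: Sequence[RegionSet], motifs: Sequence[MotifDefinition]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact IUPAC sliding-window scan of every region set.

    Returns ``(presence, counts)`` DataFrames indexed by exon_id with one
    column per RBP.  Presence means >= 1 match of any of the RBP's consensi
    in any of the three windows; windows are scanned independently, so
    matches spanning an exon/intron boundary are not sought.
    """
    if not motifs:
        raise ValueError("empty motif list")
    patterns = {
        m.rbp_name: [_consensus_regex(c) for c in m.consensus] for m in motifs
    }
    counts = np.zeros((len(regions), len(patterns)), dtype=int)
    for i, region in enumerate(regions):
        windows = region.windows()
        for j, pats in enumerate(patterns.values()):
            counts[i, j] = sum(
                len(p.findall(w)) for p in pats for w in windows if w
            )
    index = pd.Index([r.exon_id for r in regions], name="exon_id")
    counts_df = pd.DataFrame(counts, index=index, columns=list(patterns))
    return counts_df >= 1, counts_df


def fisher_p(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact test p-value for one 2x2 presence table."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(p)


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c), Haldane-Anscombe corrected for display when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c)


def fisher_enrichment(
    presence: pd.DataFrame,
    affected_ids: Iterable[str],
    background_ids: Iterable[str],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-RBP 2x2 Fisher's exact test of motif presence.

    Rows of the 2x2 table: affected exons with/without the motif (a, b)
    versus background exons with/without (c, d).  The default background is
    the Unaffected exon set, chosen by the caller.  Exons in neither set are
    ignored.  Adds BH q-values across the tested RBPs.
    """
    affected = [i for i in affected_ids if i in presence.index]
    background = [i for i in background_ids if i in presence.index]
    if set(affected) & set(background):
        raise ValueError("affected and background sets overlap")
    if not affected or not background:
        raise ValueError("affected and background sets must both be non-empty")
    aff = presence.loc[affected]
    bg = presence.loc[background]
    rows = []
    for rbp in presence.columns:
        a = int(aff[rbp].sum())
        b = len(affected) - a
        c = int(bg[rbp].sum())
        d = len(background) - c
        p = fisher_p(a, b, c, d, alternative=alternative)
        rows.append(
            {
                "rbp_name": rbp,
                "a_affected_with": a,
                "b_affected_without": b,
                "c_background_with": c,
                "d_background_without": d,
                "odds_ratio": _odds_ratio(a, b, c, d),
                "p_value": float(p),
            }
        )
    result = pd.DataFrame(rows)
    result["q_value"] = bh_fdr(result["p_value"].to_numpy())
    return result.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped at 1, input order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def crossref_interactome(
    results: pd.DataFrame,
    interactors: Iterable[str],
    aliases: Optional[Mapping[str, str]] = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Flag enrichment results found in the IP-MS interactome.

    Name matching is case-insensitive; ``aliases`` maps alternative protein
    names onto motif-table RBP names.  Adds ``in_interactome`` and
    ``refined_candidate`` (significant at ``q <= alpha`` AND in the
    interactome) columns.
    """
    canon = {k.upper(): v.upper() for k, v in (aliases or {}).items()}
    names = {canon.get(n.upper(), n.upper()) for n in interactors}
    out = results.copy()
    out["in_interactome"] = out["rbp_name"].str.upper().isin(names)
    out["refined_candidate"] = out["in_interactome"] & (out["q_value"] <= alpha)
    return out
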
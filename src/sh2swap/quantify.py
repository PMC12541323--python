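"""From sequencing reads (or count tables) to normalized fitness scores.

The estimand is a sort-seq log-ratio enrichment.  For variant *i* in one
replicate,

    fitness_i = log10(SortCount_i / InputCount_i)
                - mean over wild-type synonyms of log10(SortCount / InputCount)

so a score of 0 means the variant passed the sort gate at the same rate as
the wild-type protein, positive scores mean enrichment (gain of function in
the CD69 assay; higher protein level in the abundance assay), and negative
scores mean depletion.  The same arithmetic yields the "abundance" metric
when the sorted sample was gated on a fluorescent fusion instead of CD69 —
only the sample labels change.

Counting is done by exact k-mer equivalence-class matching of reads against
the designed variable regions (an alignment-free assigner in the spirit of
pseudoalignment; at amplicon scale with designed references the two
coincide).  Precomputed count tables are accepted unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .oligo_design import BACKGROUND_BARCODES, demux_barcode
from .seq_core import NucleotideSequence

log = logging.getLogger(__name__)

DEFAULT_KMER = 25
DEFAULT_INPUT_CUTOFF = 50
DEFAULT_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# Count tables
#
# A CountTable is a pandas DataFrame: index = variant ids, columns =
# MultiIndex (sample in {"input", "sort"}, replicate int).  Missing entries
# are 0 on construction; the input filter marks dropped cells as NaN.


def make_count_table(
    counts: dict[tuple[str, int], dict[str, int]], variant_ids: Sequence[str]
) -> pd.DataFrame:
    """Assemble a complete (sample, replicate) x variant grid, missing = 0."""
    cols = sorted(counts, key=lambda c: (c[0], c[1]))
    df = pd.DataFrame(index=list(variant_ids), dtype=float)
    for col in cols:
        df[col] = [counts[col].get(v, 0) for v in variant_ids]
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["sample", "replicate"])
    return df


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    flat = df.copy()
    flat.columns = [f"{s}_{r}" for s, r in df.columns]
    flat.to_csv(path, sep="\t", index_label="variant_id")


def read_count_table(path: str | Path) -> pd.DataFrame:
    flat = pd.read_csv(path, sep="\t", index_col="variant_id")
    cols = []
    for c in flat.columns:
        sample, rep = c.rsplit("_", 1)
        cols.append((sample, int(rep)))
    flat.columns = pd.MultiIndex.from_tuples(cols, names=["sample", "replicate"])
    return flat


# ---------------------------------------------------------------------------
# Read assignment


class KmerIndex:
    """Exact k-mer index over variant variable regions (both strands)."""

    def __init__(self, references: Iterable[NucleotideSequence], k: int = DEFAULT_KMER):
        self.k = k
        seqs: dict[str, str] = {}
        for ref in references:
            seqs[ref.id] = ref.bases
        by_seq: dict[str, list[str]] = {}
        for rid, s in seqs.items():
            by_seq.setdefault(s, []).append(rid)
        dup = [ids for ids in by_seq.values() if len(ids) > 1]
        if dup:
            raise ValueError(
                f"references indistinguishable over the covered window: {dup[:3]}"
            )
        self.index: dict[str, set[str]] = {}
        for rid, s in seqs.items():
            if len(s) < k:
                raise ValueError(f"reference {rid!r} shorter than k={k}")
            for i in range(len(s) - k + 1):
                self.index.setdefault(s[i : i + k], set()).add(rid)

    def assign(self, read: str) -> str | None:
        """Equivalence-class assignment: intersect reference sets over all
        matching k-mers; a unique survivor is the call, otherwise None."""
        eq: set[str] | None = None
        for seq in (read, _rc(read)):
            for i in range(len(seq) - self.k + 1):
                hit = self.index.get(seq[i : i + self.k])
                if hit is None:
                    continue
                eq = set(hit) if eq is None else eq & hit
                if not eq:
                    return None
        if eq is not None and len(eq) == 1:
            return next(iter(eq))
        return None


def _rc(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def assign_reads(
    reads: Iterable[str | NucleotideSequence],
    references: Iterable[NucleotideSequence],
    k: int = DEFAULT_KMER,
) -> tuple[dict[str, int], int]:
    """Count reads per variant; returns (counts, n_unassigned)."""
    index = KmerIndex(references, k=k)
    counts: dict[str, int] = {}
    unassigned = 0
    for read in reads:
        seq = read.bases if isinstance(read, NucleotideSequence) else str(read)
        hit = index.assign(seq)
        if hit is None:
            unassigned += 1
        else:
            counts[hit] = counts.get(hit, 0) + 1
    return counts, unassigned


def read_fastq(path: str | Path) -> list[str]:
    from Bio import SeqIO

    return [str(r.seq).upper() for r in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# Dual demultiplexing (kinase-helix library)


@dataclass(frozen=True)
class DemuxResult:
    variant_id: str | None
    background: str | None
    reason: str  # "ok" or a failure code


def demux_dual(
    read: str,
    cds_by_variant: dict[str, str],
    barcode_map: dict[str, tuple[str, str]] | None = None,
) -> DemuxResult:
    """Resolve one read to (kinase-helix variant, SH2 background).

    The variant is identified by exact occurrence of its full variable region
    in the read (either strand); the background by the exact 3-nt barcode
    immediately following the variable region's stop codon.  Any failure is
    returned as data with a reason code, never raised: barcodes one mismatch
    away from a valid code are unassigned (the codes are not error-correcting
    at distance 1).
    """
    if barcode_map is None:
        barcode_map = BACKGROUND_BARCODES
    for seq in (read, _rc(read)):
        matches = [
            (vid, seq.find(cds)) for vid, cds in cds_by_variant.items() if cds in seq
        ]
        if len(matches) > 1:
            return DemuxResult(None, None, "ambiguous_variant")
        if len(matches) == 1:
            vid, pos = matches[0]
            end = pos + len(cds_by_variant[vid])
            barcode = seq[end : end + 3]
            if len(barcode) < 3:
                return DemuxResult(vid, None, "barcode_missing")
            background = demux_barcode(barcode, barcode_map)
            if background is None:
                return DemuxResult(vid, None, "barcode_unknown")
            return DemuxResult(vid, background, "ok")
    return DemuxResult(None, None, "no_variant_match")


# ---------------------------------------------------------------------------
# Filtering and scoring


def filter_min_input(
    table: pd.DataFrame, cutoff: int = DEFAULT_INPUT_CUTOFF
) -> pd.DataFrame:
    """Mask variants below the input-read cutoff, per replicate.

    A variant is dropped in a replicate (input and sort cells set to NaN)
    when its input count in that replicate is < cutoff; a variant at exactly
    the cutoff is retained.  Drops are logged.
    """
    out = table.astype(float).copy()
    replicates = sorted({r for s, r in table.columns if s == "input"})
    n_dropped = 0
    for rep in replicates:
        low = out[("input", rep)] < cutoff
        n_dropped += int(low.sum())
        out.loc[low, ("input", rep)] = np.nan
        if ("sort", rep) in out.columns:
            out.loc[low, ("sort", rep)] = np.nan
    if n_dropped:
        log.info("input filter (cutoff %d): %d variant-replicate cells dropped", cutoff, n_dropped)
    return out


def fitness(
    table: pd.DataFrame,
    wt_synonym_ids: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    zero_sort: str = "pseudocount",
    metric: str = "fitness",
) -> pd.DataFrame:
    """Per-replicate and summary enrichment scores, wild-type-normalized.

    Per replicate: ``raw_i = log10(sort_i / input_i)`` with a zero sort count
    replaced by ``pseudocount`` (``zero_sort="pseudocount"``, the default) or
    the variant dropped in that replicate (``zero_sort="drop"``); nonzero
    counts are never inflated.  The replicate's normalization constant is the
    mean raw score of the wild-type synonyms, which is subtracted so the
    wild-type synonym mean is exactly 0 in every replicate.

    Returns a ScoreTable: DataFrame indexed by variant id with columns
    ``rep<r>`` per replicate plus ``mean``, ``sem``, ``n``; the metric label
    and per-replicate normalization constants are stored in ``attrs``.
    """
    wt_ids = [v for v in wt_synonym_ids if v in table.index]
    if not wt_ids:
        raise ValueError("no wild-type synonym ids present in the count table")
    replicates = sorted({r for s, r in table.columns if s == "input"})
    scores = pd.DataFrame(index=table.index, dtype=float)
    norm_constants: dict[int, float] = {}
    for rep in replicates:
        inp = table[("input", rep)].astype(float)
        srt = table[("sort", rep)].astype(float)
        if zero_sort == "pseudocount":
            srt = srt.where((srt != 0) | srt.isna(), pseudocount)
        elif zero_sort == "drop":
            srt = srt.where(srt != 0, np.nan)
        else:
            raise ValueError(f"unknown zero_sort policy {zero_sort!r}")
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.log10(srt / inp)
        wt_raw = raw.loc[wt_ids].dropna()
        if wt_raw.empty:
            raise ValueError(f"no wild-type synonym survives filtering in replicate {rep}")
        norm = float(wt_raw.mean())
        norm_constants[rep] = norm
        scores[f"rep{rep}"] = raw - norm
    rep_cols = [f"rep{r}" for r in replicates]
    scores["n"] = scores[rep_cols].notna().sum(axis=1)
    scores["mean"] = scores[rep_cols].mean(axis=1)
    scores["sem"] = scores[rep_cols].std(axis=1, ddof=1) / np.sqrt(scores["n"])
    scores.attrs["metric"] = metric
    scores.attrs["norm_constants"] = norm_constants
    scores.attrs["wt_synonym_ids"] = list(wt_ids)
    return scores


def collapse_synonyms(
    scores: pd.DataFrame, protein_map: dict[str, str]
) -> pd.DataFrame:
    """Collapse nucleotide-synonym scores to protein-level scores.

    ``protein_map`` maps nucleotide variant id -> protein id.  Within each
    replicate the protein score is the mean over its scored synonyms; the
    replicate mean/SEM are then recomputed at protein level.
    """
    rep_cols = [c for c in scores.columns if c.startswith("rep")]
    df = scores[rep_cols].copy()
    df["protein"] = [protein_map.get(v, v) for v in df.index]
    grouped = df.groupby("protein")[rep_cols].mean()
    out = grouped.copy()
    out["n"] = grouped.notna().sum(axis=1)
    out["mean"] = grouped.mean(axis=1)
    out["sem"] = grouped.std(axis=1, ddof=1) / np.sqrt(out["n"])
    out.attrs = dict(scores.attrs)
    return out


def background_difference(
    scores_b: pd.DataFrame, scores_a: pd.DataFrame
) -> pd.DataFrame:
    """Per-variant score difference between two genetic backgrounds (B - A).

    Standard errors combine in quadrature: SE = sqrt(SE_A^2 + SE_B^2).
    Variants absent from either table are restricted to the intersection and
    logged.
    """
    shared = scores_b.index.intersection(scores_a.index)
    missing = len(scores_b.index.union(scores_a.index)) - len(shared)
    if missing:
        log.info("background_difference: %d variants outside the shared set", missing)
    diff = pd.DataFrame(index=shared)
    diff["delta"] = scores_b.loc[shared, "mean"] - scores_a.loc[shared, "mean"]
    diff["se"] = np.sqrt(
        scores_a.loc[shared, "sem"] ** 2 + scores_b.loc[shared, "sem"] ** 2
    )
    return diff


def replicate_correlation(scores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson R between replicate score columns.

    Each pair uses the variants scored in both replicates; pairs with fewer
    than 2 shared variants are reported as NaN.
    """
    rep_cols = [c for c in scores.columns if c.startswith("rep")]
    if len(rep_cols) < 2:
        raise ValueError("need at least 2 replicates")
    return scores[rep_cols].corr(method="pearson", min_periods=2)


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index_label="variant_id")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant_id")
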
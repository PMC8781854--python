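"""Sequence-level statistics of repeat copies.

Everything a sequence logo and its companion tables summarize: repeat
lengths and their distribution, the fraction of the protein covered by the
repeat domain, amino-acid compositional bias of repeat regions against the
Swiss-Prot background, per-column frequency/information-content matrices of
a repeat-copy alignment, and the 50%-threshold consensus string.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AMINO_ACIDS, ProteinRecord

GAP = "-"
MAX_BITS = float(np.log2(20))


def swissprot_background() -> dict[str, float]:
    """Swiss-Prot amino-acid composition (percent), normalized to sum 100."""
    ref = resources.files("ankanet.data").joinpath("swissprot_background.tsv")
    table = pd.read_csv(ref.open(), sep="\t")
    raw = dict(zip(table["aa"], table["percent"].astype(float)))
    total = sum(raw.values())
    return {aa: 100.0 * v / total for aa, v in raw.items()}


def extract_repeats(record: ProteinRecord) -> list[str]:
    """Sequences of the annotated repeat copies, in order."""
    return [record.sequence[s - 1:e] for s, e in record.repeats]


def domain_coverage(record: ProteinRecord) -> float:
    """Fraction of the protein's residues inside annotated repeat copies."""
    covered = sum(e - s + 1 for s, e in record.repeats)
    return covered / len(record.sequence)


def length_histogram(
    records: Iterable[ProteinRecord], window: tuple[int, int] = (30, 33)
) -> tuple[dict[int, int], float]:
    """Repeat-copy length counts plus the fraction inside ``window``."""
    counts: dict[int, int] = {}
    for rec in records:
        for s, e in rec.repeats:
            counts[e - s + 1] = counts.get(e - s + 1, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no repeat copies in the input records")
    lo, hi = window
    inside = sum(c for length, c in counts.items() if lo <= length <= hi)
    return dict(sorted(counts.items())), inside / total


@dataclass
class CompositionBias:
    """Repeat-region composition vs background, in percentage points."""

    repeat_percent: dict[str, float]
    background_percent: dict[str, float]
    delta: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "aa": list(AMINO_ACIDS),
                "repeat_percent": [self.repeat_percent[a] for a in AMINO_ACIDS],
                "background_percent": [self.background_percent[a] for a in AMINO_ACIDS],
                "delta": [self.delta[a] for a in AMINO_ACIDS],
            }
        )


def composition_bias(
    repeat_seqs: Sequence[str],
    background: Mapping[str, float] | None = None,
) -> CompositionBias:
    """Amino-acid composition of repeat regions relative to a background.

    ``background`` is a per-letter percentage table summing to 100 (defaults
    to the shipped Swiss-Prot statistics).  Letters absent from the repeat
    sequences get composition 0; delta = repeat - background.
    """
    bg = dict(swissprot_background() if background is None else background)
    missing = [a for a in AMINO_ACIDS if a not in bg]
    if missing:
        raise ValueError(f"background is missing letters: {missing}")
    if abs(sum(bg.values()) - 100.0) > 1e-6:
        raise ValueError("background percentages must sum to 100")
    counts = {a: 0 for a in AMINO_ACIDS}
    total = 0
    for seq in repeat_seqs:
        for ch in seq:
            if ch in counts:
                counts[ch] += 1
                total += 1
    if total == 0:
        raise ValueError("no residues in repeat sequences")
    comp = {a: 100.0 * counts[a] / total for a in AMINO_ACIDS}
    delta = {a: comp[a] - bg[a] for a in AMINO_ACIDS}
    return CompositionBias(comp, {a: bg[a] for a in AMINO_ACIDS}, delta)


@dataclass
class ColumnStats:
    """Per-column counts, frequencies and information content of an MSA.

    Frequencies divide by the number of sequences, so per column they sum
    to 1 including the gap fraction.  Information content follows the
    sequence-logo convention: IC_j = log2(20) - H_j with H_j the Shannon
    entropy of the 20-letter frequencies renormalized over non-gap
    characters; all-gap columns get IC 0.
    """

    counts: pd.DataFrame          # rows: columns of the MSA; cols: letters + gap
    n_sequences: int
    frequencies: pd.DataFrame
    information: np.ndarray       # bits, one per column

    @property
    def n_columns(self) -> int:
        return len(self.counts)


def column_stats(msa: Sequence[str]) -> ColumnStats:
    """Count letters per column of an aligned, equal-length set of sequences."""
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment: rows differ in length")
    alphabet = list(AMINO_ACIDS) + [GAP]
    counts = np.zeros((width, len(alphabet)), dtype=int)
    index = {a: k for k, a in enumerate(alphabet)}
    for row in msa:
        for j, ch in enumerate(row):
            counts[j, index.get(ch, index[GAP])] += 1
    n = len(msa)
    freq = counts / n
    info = np.zeros(width)
    aa_counts = counts[:, :20]
    non_gap = aa_counts.sum(axis=1)
    for j in range(width):
        if non_gap[j] == 0:
            continue
        p = aa_counts[j] / non_gap[j]
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        info[j] = MAX_BITS - entropy
    counts_df = pd.DataFrame(counts, columns=alphabet)
    freq_df = pd.DataFrame(freq, columns=alphabet)
    return ColumnStats(counts_df, n, freq_df, info)


def consensus(msa: Sequence[str], threshold: float = 0.5) -> str:
    """Threshold consensus of an alignment.

    Per column the letter whose frequency over *all* rows (gaps count in
    the denominator) reaches ``threshold`` is emitted; ``X`` if none does.
    Ties at exactly the threshold break alphabetically.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    stats = column_stats(msa)
    out = []
    for j in range(stats.n_columns):
        freqs = stats.frequencies.iloc[j]
        candidates = [a for a in AMINO_ACIDS if freqs[a] >= threshold]
        if candidates:
            top = max(freqs[a] for a in candidates)
            out.append(sorted(a for a in candidates if freqs[a] == top)[0])
        else:
            out.append("X")
    return "".join(out)


def pad_alignment(seqs: Sequence[str], width: int | None = None) -> list[str]:
    """Trivial positional alignment: left-justify and pad with gaps.

    Equal-length inputs pass through unchanged (gap-free); shorter copies
    are padded at the C-terminus up to ``width`` (default: longest input).
    """
    if not seqs:
        return []
    width = max(len(s) for s in seqs) if width is None else width
    return [s[:width].ljust(width, GAP) for s in seqs]
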
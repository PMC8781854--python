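"""Repeat-aware aggregation of contact-network metrics.

The coordinate system here is the *motif position*: the 1-based offset of a
residue within its repeat copy.  Edges are partitioned into intra-repeat
(both ends in the same copy), inter-repeat (ends in different copies) and
cross (at least one end outside any annotated copy); centralities are
normalized per repeat unit to its maximum; per-position profiles average
over copies, and cluster consensus profiles pool the copies of all member
proteins.  The consensus secondary structure takes the most frequent DSSP
letter at each motif position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .contactnet import ContactNetwork
from .io_formats import ProteinRecord

#: metric columns every profile table carries, in order
PROFILE_METRICS = (
    "degree", "intra", "inter", "cross",
    "norm_betweenness", "norm_eigenvector",
)


@dataclass
class EdgePartition:
    """Per-node intra/inter/cross edge counts (intra + inter + cross = degree)."""

    intra: dict[int, int]
    inter: dict[int, int]
    cross: dict[int, int]

    def degree(self, node: int) -> int:
        return self.intra[node] + self.inter[node] + self.cross[node]


def _copy_index(record: ProteinRecord, position: int) -> Optional[int]:
    hit = record.copy_of(position)
    return None if hit is None else hit[0]


def classify_edges(
    network: ContactNetwork, record: ProteinRecord, offset: int = 0
) -> EdgePartition:
    """Label every edge intra-, inter-repeat, or cross.

    ``offset`` reconciles structure residue numbering with the record's
    sequence coordinates (position = resnum - offset).  Inter-repeat counts
    any pair of distinct copies, adjacent or not.  A node whose position
    falls outside the sequence raises an error naming the residue.
    """
    intra = {u: 0 for u in network.nodes}
    inter = {u: 0 for u in network.nodes}
    cross = {u: 0 for u in network.nodes}
    copy_cache: dict[int, Optional[int]] = {}
    for u in network.nodes:
        pos = u - offset
        if not 1 <= pos <= len(record.sequence):
            raise ValueError(
                f"residue {u} maps to position {pos}, outside "
                f"{record.accession} (length {len(record.sequence)})"
            )
        copy_cache[u] = _copy_index(record, pos)
    for u, v in network.graph.edges():
        cu, cv = copy_cache[u], copy_cache[v]
        if cu is None or cv is None:
            cross[u] += 1
            cross[v] += 1
        elif cu == cv:
            intra[u] += 1
            intra[v] += 1
        else:
            inter[u] += 1
            inter[v] += 1
    return EdgePartition(intra, inter, cross)


def normalize_per_unit(
    values: Mapping[int, float], record: ProteinRecord, offset: int = 0
) -> dict[int, float]:
    """Scale each repeat copy's values to its own maximum (range 0-1).

    Every node must belong to a copy; an all-zero copy stays all-zero.
    """
    by_copy: dict[int, list[int]] = {}
    for node in values:
        hit = record.copy_of(node - offset)
        if hit is None:
            raise ValueError(
                f"residue {node} is not inside any repeat copy of {record.accession}"
            )
        by_copy.setdefault(hit[0], []).append(node)
    out: dict[int, float] = {}
    for nodes in by_copy.values():
        peak = max(values[n] for n in nodes)
        for n in nodes:
            out[n] = values[n] / peak if peak > 0 else 0.0
    return out


@dataclass
class PositionProfile:
    """Per-motif-position means of node metrics, with contributing-copy counts.

    ``table`` has one row per motif position 1..L_max with columns
    ``position``, ``n_copies`` and ``mean_<metric>`` (NaN where no copy
    covers the position).
    """

    table: pd.DataFrame
    n_copies_total: int

    @property
    def l_max(self) -> int:
        return len(self.table)

    def mean(self, metric: str, position: int) -> float:
        return float(self.table.loc[position - 1, f"mean_{metric}"])


def position_profile(
    metrics: Mapping[str, Mapping[int, float]],
    record: ProteinRecord,
    l_max: int = 33,
    offset: int = 0,
) -> PositionProfile:
    """Average per-node metrics at each motif position across repeat copies.

    Residue r in copy c maps to position r - start(c) + 1; positions beyond
    ``l_max`` are ignored; each position averages only over the copies that
    reach it.
    """
    sums = {name: np.zeros(l_max) for name in metrics}
    counts = np.zeros(l_max, dtype=int)
    seen = {name: np.zeros(l_max, dtype=int) for name in metrics}
    for name, values in metrics.items():
        for node, value in values.items():
            hit = record.copy_of(node - offset)
            if hit is None:
                continue
            _c, pos = hit
            if pos > l_max:
                continue
            sums[name][pos - 1] += value
            seen[name][pos - 1] += 1
    # contributing copies per position (independent of metric coverage)
    for _c, (s, e) in enumerate(record.repeats, start=1):
        span = min(e - s + 1, l_max)
        counts[:span] += 1

    data = {"position": np.arange(1, l_max + 1), "n_copies": counts}
    for name in metrics:
        with np.errstate(invalid="ignore"):
            data[f"mean_{name}"] = np.where(
                seen[name] > 0, sums[name] / np.maximum(seen[name], 1), np.nan
            )
    return PositionProfile(pd.DataFrame(data), n_copies_total=record.n_copies)


def profile_from_analysis(
    network: ContactNetwork,
    record: ProteinRecord,
    betweenness_values: Mapping[int, float],
    eigen_values: Mapping[int, float],
    l_max: int = 33,
    offset: int = 0,
) -> PositionProfile:
    """Standard per-protein profile: degree, edge partition, normalized centralities."""
    partition = classify_edges(network, record, offset)
    degree = {u: float(d) for u, d in network.degree().items()}
    domain_nodes = {
        u for u in network.nodes if record.copy_of(u - offset) is not None
    }
    norm_b = normalize_per_unit(
        {u: betweenness_values[u] for u in domain_nodes}, record, offset
    )
    norm_e = normalize_per_unit(
        {u: eigen_values[u] for u in domain_nodes}, record, offset
    )
    metrics = {
        "degree": degree,
        "intra": {u: float(v) for u, v in partition.intra.items()},
        "inter": {u: float(v) for u, v in partition.inter.items()},
        "cross": {u: float(v) for u, v in partition.cross.items()},
        "norm_betweenness": norm_b,
        "norm_eigenvector": norm_e,
    }
    return position_profile(metrics, record, l_max, offset)


def cluster_consensus_profile(profiles: Sequence[PositionProfile]) -> PositionProfile:
    """Copy-weighted mean of member profiles at each motif position.

    Equivalent to pooling all repeat copies of all members: each member's
    per-position mean is weighted by its contributing-copy count there.
    """
    if not profiles:
        raise ValueError("no profiles to combine")
    l_max = profiles[0].l_max
    if any(p.l_max != l_max for p in profiles):
        raise ValueError("profiles have differing L_max")
    metric_cols = [c for c in profiles[0].table.columns if c.startswith("mean_")]
    counts = np.zeros(l_max, dtype=int)
    sums = {c: np.zeros(l_max) for c in metric_cols}
    weights = {c: np.zeros(l_max) for c in metric_cols}
    for p in profiles:
        n = p.table["n_copies"].to_numpy()
        counts += n
        for c in metric_cols:
            v = p.table[c].to_numpy()
            ok = ~np.isnan(v)
            sums[c][ok] += (v * n)[ok]
            weights[c][ok] += n[ok]
    data = {"position": np.arange(1, l_max + 1), "n_copies": counts}
    for c in metric_cols:
        with np.errstate(invalid="ignore"):
            data[c] = np.where(weights[c] > 0, sums[c] / np.maximum(weights[c], 1), np.nan)
    return PositionProfile(
        pd.DataFrame(data), n_copies_total=sum(p.n_copies_total for p in profiles)
    )


#: deterministic tie-break order for consensus secondary structure
_SS_PRIORITY = {"H": 0, "T": 1, "C": 2}


def consensus_secondary_structure(
    ss_by_copy: Sequence[str], l_max: int = 33
) -> str:
    """Most frequent secondary-structure letter at each motif position.

    Ties prefer H over T over C, then alphabetical order; positions not
    covered by any copy are emitted as ``-``.
    """
    if not ss_by_copy:
        raise ValueError("no secondary-structure strings")
    out = []
    for pos in range(l_max):
        votes = Counter(s[pos] for s in ss_by_copy if pos < len(s))
        if not votes:
            out.append("-")
            continue
        best = min(
            votes,
            key=lambda letter: (
                -votes[letter], _SS_PRIORITY.get(letter, 3), letter
            ),
        )
        out.append(best)
    return "".join(out)
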
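"""Greedy hierarchical identity clustering of repeat-domain sequences.

The scheme mirrors iterative CD-HIT: a first greedy pass clusters all
sequences at a stringent identity threshold, each later pass clusters only
the previous pass's representatives at a lower threshold, and final
assignments follow every sequence through its chain of representatives.
Default thresholds are 90%, 60% and 30%.

Identity between two sequences is computed from a global Needleman-Wunsch
alignment (match +1, mismatch 0, linear gap penalty -1 per gap position) as
the number of identical aligned columns divided by the length of the
shorter sequence — CD-HIT's denominator convention.  An optional
residue-composition prefilter skips pairs whose identity provably falls
below the threshold; it never changes the result.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from typing import Mapping, Sequence

from Bio import Align


def _aligner(gap_penalty: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = gap_penalty
    aligner.extend_gap_score = gap_penalty
    return aligner


def pairwise_identity(a: str, b: str, gap_penalty: float = -1.0) -> float:
    """Global-alignment identity: matches / length of the shorter sequence."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner(gap_penalty).align(a, b)[0]
    matches = alignment.counts().identities
    return matches / min(len(a), len(b))


def identity_upper_bound(a: str, b: str) -> float:
    """A sound upper bound on :func:`pairwise_identity`.

    Matched columns pair identical letters and consume one residue from
    each sequence, so the number of matches in *any* alignment is at most
    the shared residue content sum_x min(count_a(x), count_b(x)).
    """
    ca, cb = Counter(a), Counter(b)
    shared = sum(min(ca[x], cb[x]) for x in ca)
    return shared / min(len(a), len(b))


@dataclass
class Cluster:
    members: list[str]                       # accessions, in join order
    seed: str                                # founder (greedy seed)
    representative: str = ""                 # most-central member, set after pass
    identity_to_seed: dict[str, float] = field(default_factory=dict)
    identity_to_representative: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterPass:
    threshold: float
    clusters: list[Cluster]


@dataclass
class ClusterSet:
    """Nested result of the multi-pass clustering.

    ``assignment`` maps every original accession to the index of its
    terminal cluster in ``passes[-1].clusters`` (clusters numbered by
    descending size, ties by representative accession).
    """

    passes: list[ClusterPass]
    assignment: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(self.passes[-1].clusters)

    def members_of(self, cluster_index: int) -> list[str]:
        return [a for a, c in self.assignment.items() if c == cluster_index]


def _sorted_accessions(seqs: Mapping[str, str]) -> list[str]:
    # longest first; ties broken lexicographically by accession
    return sorted(seqs, key=lambda acc: (-len(seqs[acc]), acc))


def greedy_cluster(
    seqs: Mapping[str, str],
    threshold: float,
    use_prefilter: bool = True,
    gap_penalty: float = -1.0,
) -> list[Cluster]:
    """One greedy incremental clustering pass.

    Sequences are visited longest-first; each joins the first existing
    cluster whose *seed* it matches at or above the threshold, otherwise it
    founds a new cluster.  Representatives (the member with maximum summed
    identity to all members) are selected afterwards.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    clusters: list[Cluster] = []
    for acc in _sorted_accessions(seqs):
        placed = False
        for cluster in clusters:
            seed_seq = seqs[cluster.seed]
            if use_prefilter and identity_upper_bound(seqs[acc], seed_seq) < threshold:
                continue
            ident = pairwise_identity(seqs[acc], seed_seq, gap_penalty)
            if ident >= threshold:
                cluster.members.append(acc)
                cluster.identity_to_seed[acc] = ident
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(members=[acc], seed=acc, identity_to_seed={acc: 1.0})
            )
    for cluster in clusters:
        cluster.representative = select_representative(
            cluster.members, seqs, gap_penalty
        )
        cluster.identity_to_representative = {
            acc: pairwise_identity(seqs[acc], seqs[cluster.representative], gap_penalty)
            for acc in cluster.members
        }
    return clusters


def select_representative(
    members: Sequence[str], seqs: Mapping[str, str], gap_penalty: float = -1.0
) -> str:
    """The member with maximum summed identity to all members.

    Ties break by sequence length (longest first), then accession.
    """
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    scores = {}
    for acc in members:
        scores[acc] = sum(
            pairwise_identity(seqs[acc], seqs[other], gap_penalty)
            for other in members
        )
    return min(members, key=lambda acc: (-scores[acc], -len(seqs[acc]), acc))


def hierarchical_cluster(
    seqs: Mapping[str, str],
    thresholds: Sequence[float] = (0.9, 0.6, 0.3),
    use_prefilter: bool = True,
    gap_penalty: float = -1.0,
) -> ClusterSet:
    """Multi-pass greedy clustering at strictly decreasing thresholds.

    Pass 1 clusters every input sequence; each later pass clusters only the
    previous pass's representatives.  The final assignment maps each input
    through its chain of representatives to a terminal cluster.
    """
    thresholds = list(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")

    passes: list[ClusterPass] = []
    current = dict(seqs)
    # parent[acc] = representative of acc's cluster in the latest pass
    parent: dict[str, str] = {acc: acc for acc in seqs}
    for threshold in thresholds:
        clusters = greedy_cluster(current, threshold, use_prefilter, gap_penalty)
        passes.append(ClusterPass(threshold, clusters))
        step = {}
        for cluster in clusters:
            for acc in cluster.members:
                step[acc] = cluster.representative
        parent = {acc: step[rep] for acc, rep in parent.items()}
        current = {rep: seqs[rep] for rep in sorted(set(step.values()))}

    terminal = passes[-1].clusters
    order = sorted(
        range(len(terminal)),
        key=lambda k: (-sum(1 for r in parent.values() if r == terminal[k].representative),
                       terminal[k].representative),
    )
    rank = {terminal[k].representative: i for i, k in enumerate(order)}
    passes[-1].clusters = [terminal[k] for k in order]
    assignment = {acc: rank[rep] for acc, rep in parent.items()}
    return ClusterSet(passes, assignment)


def cluster_report(result: ClusterSet, seqs: Mapping[str, str]) -> "pd.DataFrame":
    """Tabular membership report: cluster id, member, representative, identity."""
    import pandas as pd

    terminal = result.passes[-1].clusters
    reps = {i: c.representative for i, c in enumerate(terminal)}
    rows = []
    for acc in sorted(result.assignment):
        cid = result.assignment[acc]
        rep = reps[cid]
        rows.append(
            {
                "cluster": cid + 1,
                "member": acc,
                "representative": rep,
                "identity_to_representative": pairwise_identity(seqs[acc], seqs[rep]),
            }
        )
    return pd.DataFrame(rows).sort_values(["cluster", "member"]).reset_index(drop=True)
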
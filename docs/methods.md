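# Methods

## Coordinate conventions

All protein positions are 1-based inclusive (UniProt style) everywhere in
the package; conversion to 0-based indices happens only inside readers and
writers. A *motif position* is the 1-based offset of a residue within its
repeat copy: residue r in copy (start, end) has motif position
r − start + 1. Repeat annotations must be sorted and non-overlapping;
this is validated at construction of every `ProteinRecord`.

## Sequence statistics

**Consensus.** Per alignment column, the letter whose frequency over *all*
rows reaches the threshold (default 0.5) is emitted, otherwise `X`; ties at
exactly the threshold break alphabetically. Gaps count in the denominator —
a letter must reach 50% of sequences, not 50% of non-gap rows — which is
the conservative convention; the alternative would only make consensus
calls easier. For unequal-length repeat copies the built-in "trivial
alignment" left-justifies and pads with gaps to L_max; any externally
aligned FASTA can be supplied instead, and for equal-length copies the
trivial alignment is gap-free positional correspondence.

**Information content.** IC_j = log2(20) − H_j bits, with H_j the Shannon
entropy of the 20-letter frequencies renormalized over non-gap characters;
all-gap columns get IC 0. This is the sequence-logo convention, so emitted
matrices can be rendered by any logo tool.

**Compositional bias.** Percent composition over the 20 standard letters in
repeat regions minus a background composition. The shipped background
(`data/swissprot_background.tsv`) is the published UniProtKB/Swiss-Prot
per-residue percentage table, renormalized to sum to exactly 100; it is a
configuration table, never fetched at runtime.

## Hierarchical clustering

The unit of clustering is the concatenated repeat-domain sequence of each
protein (the annotated copies joined in order), not individual copies.

**Identity.** Global Needleman–Wunsch alignment with match +1, mismatch 0
and a linear gap penalty of −1 per gap position (Biopython
`PairwiseAligner`); identity = identical aligned columns / length of the
shorter sequence. The shorter-sequence denominator is CD-HIT's convention;
both the denominator choice and the gap penalty are configurable, and the
thresholds used (0.9/0.6/0.3) are far from the regime where the gap penalty
matters.

**Greedy pass.** Sequences are visited longest-first (ties: lexicographic
accession) and join the first existing cluster whose founding seed they
match at or above the threshold, else found a new cluster — the
first-qualifying rule of CD-HIT, not best-qualifying. After the pass, each
cluster's representative is the member with maximum summed identity to all
members (ties: longest, then lexicographic). A residue-composition bound
(matches in any alignment ≤ Σ_letters min of the two counts) may skip
provably sub-threshold pairs; it is exact, so clustering with and without
it is identical.

**Hierarchy.** Later passes cluster only the previous pass's
representatives at strictly decreasing thresholds; final assignments follow
each sequence through its chain of representatives. Terminal clusters are
numbered by descending member count, ties by representative accession, so
the whole procedure is deterministic.

## Contact networks and centralities

Nodes are Cα atoms of the selected residues (the annotated repeat domain by
default); an edge joins residues with Euclidean distance ≤ R_c = 7 Å and
sequence separation |i − j| ≥ min_sep = 1. min_sep = 1 excludes only
self-pairs, i.e. backbone neighbours are retained; the alternative reading
(excluding i, i±1) is available as a parameter. The k-d tree used for
neighbour search is an exact accelerator — the test suite checks edge sets
against brute-force all-pairs scans at R_c ∈ {5, 7, 9} and min_sep ∈ {1, 2}.

**Betweenness** is reported unnormalized over unordered pairs
{s, t}, s ≠ t ≠ u (Brandes' algorithm via networkx; the tests compare it
with exhaustive geodesic enumeration). Since profiles are later normalized
per repeat unit to the unit maximum, any constant normalization would
cancel; leaving it unnormalized avoids guessing a web-service convention.

**Eigenvector centrality** is the principal eigenvector of the adjacency
matrix, computed by power iteration on A + I (the +I shift keeps the Perron
direction strictly dominant on bipartite graphs), restricted to the largest
connected component; nodes outside it get 0. The vector is scaled to unit
maximum, λ is the Rayleigh quotient on A, and the fixed point
‖Ax − λx‖∞ ≤ 10·tol·λ is verified before returning (tol = 1e-10,
max 10 000 iterations). Edgeless graphs are rejected as degenerate. Real
repeat domains are connected; the largest-component rule only matters for
pathological selections.

**pLDDT gate.** Predicted structures enter the analysis only when the mean
pLDDT over the domain region is ≥ 90 (inclusive). Experimental structures
bypass the gate; their B-factor column is not a confidence score.

## Motif profiles

Each edge is intra-repeat (both ends in one copy), inter-repeat (ends in
two different copies — any pair, adjacency between the copies is recorded
by the data, not required by the definition), or cross (≥ 1 end outside
every copy). Per node, intra + inter + cross = degree identically; the
pipeline asserts this for every analyzed structure.

Centrality values are normalized within each repeat unit to that unit's
maximum (all-zero units stay zero), because in solenoid repeat proteins
the central copies have systematically larger raw centralities than the
terminal copies while the within-copy shape is shared. Profiles then
average each metric at each motif position over the copies that reach that
position (copies shorter than L_max = 33 simply contribute fewer
positions; contributing-copy counts are recorded per position). Cluster
consensus profiles pool all copies of all members — equivalently, member
profiles are weighted by their contributing-copy counts — so every repeat
copy counts equally, not every protein.

Consensus secondary structure takes the most frequent DSSP letter per motif
position; ties prefer H over T over C (then alphabetical) for determinism.
Ties are rare in practice; the rule only pins down edge cases.

## Variant mapping

Variants map by their first affected residue (frameshifts and multi-residue
changes included; the kind is recorded). Positions in the gaps of a
discontinuous domain map to not-in-repeat rather than to the nearest copy.
The stated reference residue is compared with the sequence and
disagreements are flagged, not fatal, since annotation releases drift.

## The synthetic generator

The generator provides ground truth, not realism. What it emulates, and
what it does not:

- **Motif emission.** Each position of a repeat copy independently emits
  the consensus letter with probability `conservation[j]`, else a uniform
  draw from the other 19 letters — the simplest generative model consistent
  with a sequence-logo description. Real repeat columns have correlated
  substitutions and letter-specific substitution preferences; nothing
  downstream depends on those.
  The default motif is an ankyrin-like 33-mer
  (`NGATPLHLAARNGHLEVVKLLLEHGADVNAKDN`) with the classical conserved
  positions (G2, TPLH4–7, A9, G13, L21–22, G25, A26) at conservation 0.95
  and variable positions at 0.55.
- **Planted families.** A founder domain is mutated per member at
  `within_rate` (default 0.02, expected member identity
  (1 − 0.02)² ≈ 0.96); sub-family founders diverge from a super-family
  founder at `sub_divergence` (default 0.15, expected cross-sub-family
  identity ≈ 0.69); unrelated founders sit near the random-alignment
  background (≈ 0.1–0.2 under the gap-trading aligner). The defaults put
  each planted level several binomial standard deviations away from the
  nearest clustering threshold (0.9 and 0.6) over a 165-residue domain, so
  recovery is a property of the method, not of a lucky seed.
- **Solenoid geometry.** Two ideal α-helices per copy (rise 1.5 Å/residue,
  100°/residue, radius 2.3 Å) separated by 9 Å; loops and the inter-copy
  linker are constant-step helical coils between anchor points, making
  every backbone step exactly 3.8 Å; copies are related by a rigid 15 Å
  translation. The construction is *not* ankyrin torsion geometry — it is
  the simplest chain whose 7 Å contact topology matches the solenoid
  architecture: helix1–helix2 packing contacts within each copy,
  inter-copy contacts concentrated at the copy junction (terminal motif
  positions), no contacts between copies more than one apart. A
  generation-time self-check verifies all four conditions plus the
  backbone-step bound (3.8 ± 0.5 Å) and raises naming the violated
  condition — e.g. a `stack_offset` beyond the linker's reach fails with
  "no inter-copy contacts possible". Consequently the real-data
  observation that terminal positions carry high inter-repeat edge counts
  is reproduced by construction *of the topology*, and passing tests show
  the bookkeeping (edge partitioning, normalization, per-position
  averaging) is correct — they do not validate ankyrin geometry itself.
- **Confidence values.** pLDDT is Gaussian noise clipped to [0, 100],
  written to the PDB B-factor column in the AlphaFold convention; the
  packaged study gives one protein a low-confidence model (mean 85) so the
  ≥ 90 gate is exercised.

## Pipeline defaults and determinism

R_c = 7.0 Å, min_sep = 1, thresholds (0.9, 0.6, 0.3), consensus threshold
0.5, pLDDT cutoff 90, minimum 3 repeat copies per protein, L_max = 33.
These are the analysis constants of the method; the configuration file
carries them explicitly and every output table repeats them in a `#` header
line. All randomness flows from a single integer seed through one
`numpy` generator; table floats are written at fixed precision; cluster
and file iteration orders are sorted — a rerun with the same configuration
is byte-identical, and the acceptance script checks this.

The packaged synthetic study uses 30 proteins (two super-families split
into five families of six), five 33-residue copies per protein, and
198-residue solenoids for profile analyses; oracle comparisons use 200
random graphs with 4–12 nodes and structures up to ~500 residues. These
sizes make every exact-oracle check exhaustive while keeping the whole
suite fast.

## Known limitations

- The aligner maximizes score, not matches; identity is read off one
  optimal alignment (Biopython's first), which is deterministic but can
  differ from the match-maximizing alignment by a fraction of a percent.
- Random-sequence identity under the gap-trading aligner is well above the
  1/20 positional baseline (~0.1–0.2 for 165-mers); planted "unrelated"
  families account for this margin.
- Multi-model PDB files use the first model only; mmCIF is not parsed.
- The low-conservation consensus regime is intrinsically noisy: at
  conservation 0.45 with 200 copies the consensus-letter frequency sits
  only ~0.7 binomial SD below the 50% threshold per column, so a few
  columns typically still reach consensus; `X` at *every* position is only
  guaranteed well below that conservation level or at larger copy numbers.
- Cross edges (to non-repeat residues) are zero on synthetic solenoids;
  real multi-domain proteins exercise that path only through the unit
  tests' hand-built cases.
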
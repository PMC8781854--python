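"""Synthetic repeat proteins with known ground truth.

Every downstream stage (clustering, contact networks, motif profiles,
variant mapping) is exercised on data produced here, so real database
downloads are never needed.  The module emulates the salient features of
ankyrin repeat proteins:

* repeat copies of length 30-34 emitted from a position-specific motif
  model (consensus letter with per-position conservation probability,
  uniform choice over the other 19 letters otherwise),
* families of proteins at controlled pairwise identity forming planted
  clusters, with ground-truth labels in ``ProteinRecord.meta``,
* an idealized solenoid Calpha trace: two ideal alpha-helices per copy
  (1.5 A rise/residue, 3.6 residues/turn), constant 3.8 A backbone steps,
  rigid stacking of copies, with contacts at 7 A occurring within copies
  (helix packing) and between adjacent copies only (junction region),
* DSSP-like helix/turn/coil strings and truncated-Gaussian pLDDT values.

Geometry is a stand-in: only the contact topology matters downstream, and
the generator refuses to emit a structure that violates it (self-check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .contactnet import NetworkParams, build_network
from .io_formats import AMINO_ACIDS, CaResidue, CaStructure, ProteinRecord

STEP = 3.8           # Calpha-Calpha virtual bond, Angstrom
HELIX_RISE = 1.5     # A per residue along the helix axis
HELIX_TURN = 100.0   # degrees per residue (3.6 residues/turn)
HELIX_RADIUS = 2.3   # A, Calpha helix radius

# layout constants of the two-helix template (local frame, A)
_HELIX_SEP = 9.0     # z offset between the two helix axes
_P1_LOCAL = np.array([0.0, -6.0, 4.0])   # residue-1 anchor of each copy

#: ankyrin-like 33-residue consensus used as the default motif.  Conserved
#: positions follow the classical motif: G2, TPLH4-7, A9, G13, L21-22,
#: GADVN25-29 (hence G25/A26).
ANKYRIN_CONSENSUS = "NGATPLHLAARNGHLEVVKLLLEHGADVNAKDN"

_CONSERVED_POSITIONS = (2, 4, 5, 6, 7, 9, 13, 21, 22, 25, 26)


class GenerationError(RuntimeError):
    """Raised when the solenoid self-check fails, naming the condition."""


# ---------------------------------------------------------------------------
# motif model and sequence generation
# ---------------------------------------------------------------------------

@dataclass
class MotifModel:
    """Per-position categorical emission model of one repeat motif."""

    length: int
    consensus: str
    conservation: np.ndarray

    def __post_init__(self) -> None:
        self.conservation = np.asarray(self.conservation, dtype=float)
        if not 30 <= self.length <= 34:
            raise ValueError(f"motif length must be in [30, 34], got {self.length}")
        if len(self.consensus) != self.length:
            raise ValueError("consensus length must equal model length")
        if any(c not in AMINO_ACIDS for c in self.consensus):
            raise ValueError("consensus must use the 20 standard letters")
        if self.conservation.shape != (self.length,):
            raise ValueError("conservation must have one value per position")
        if ((self.conservation < 0) | (self.conservation > 1)).any():
            raise ValueError("conservation values must lie in [0, 1]")


def ankyrin_motif(conservation: float | Sequence[float] | None = None) -> MotifModel:
    """The default ankyrin-like motif model.

    With ``conservation=None`` the classical conserved positions get 0.95
    and the variable positions 0.55, mimicking the sharply peaked columns of
    a repeat-family sequence logo.  A scalar gives uniform conservation.
    """
    L = len(ANKYRIN_CONSENSUS)
    if conservation is None:
        cons = np.full(L, 0.55)
        cons[[p - 1 for p in _CONSERVED_POSITIONS]] = 0.95
    elif np.isscalar(conservation):
        cons = np.full(L, float(conservation))
    else:
        cons = np.asarray(conservation, dtype=float)
    return MotifModel(L, ANKYRIN_CONSENSUS, cons)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_repeat_copies(
    model: MotifModel, n_copies: int, seed: int | np.random.Generator
) -> list[str]:
    """Emit ``n_copies`` repeat sequences from the motif model.

    Each position independently emits the consensus letter with probability
    ``conservation[j]`` and otherwise a uniform draw from the other 19.
    """
    if n_copies < 1:
        raise ValueError(f"n_copies must be >= 1, got {n_copies}")
    rng = _rng(seed)
    copies = []
    others = {
        c: [a for a in AMINO_ACIDS if a != c] for c in set(model.consensus)
    }
    for _ in range(n_copies):
        chars = []
        hit = rng.random(model.length) < model.conservation
        for j, c in enumerate(model.consensus):
            if hit[j]:
                chars.append(c)
            else:
                chars.append(others[c][rng.integers(19)])
        copies.append("".join(chars))
    return copies


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` (uniform other letter)."""
    chars = list(seq)
    for j in np.flatnonzero(rng.random(len(chars)) < rate):
        alternatives = [a for a in AMINO_ACIDS if a != chars[j]]
        chars[j] = alternatives[rng.integers(19)]
    return "".join(chars)


def mutate_consensus(
    model: MotifModel, rate: float, rng: int | np.random.Generator
) -> MotifModel:
    """Derive a diverged motif model by mutating the consensus at ``rate``."""
    rng = _rng(rng)
    return replace(model, consensus=_mutate(model.consensus, rate, rng))


def generate_protein_family(
    model: MotifModel,
    n_proteins: int,
    copies_per_protein: int,
    within_rate: float,
    seed: int | np.random.Generator,
    family: str = "FAM0",
    n_flank: int = 12,
    founder: Optional[Sequence[str]] = None,
) -> list[ProteinRecord]:
    """Generate a planted family of repeat proteins.

    A founder repeat domain is emitted once from the motif model (or passed
    in); each family member carries that domain with every position
    independently substituted at ``within_rate``, flanked by random
    non-repeat sequence.  The expected pairwise identity between members is
    at least ``(1 - within_rate)**2``, recorded in
    ``meta['implied_identity']`` together with the family label (ground
    truth for clustering tests).
    """
    if n_proteins < 1:
        raise ValueError(f"n_proteins must be >= 1, got {n_proteins}")
    if not 0 <= within_rate <= 1:
        raise ValueError("within_rate must be in [0, 1]")
    rng = _rng(seed)
    if founder is None:
        founder = generate_repeat_copies(model, copies_per_protein, rng)
    else:
        founder = list(founder)
    records = []
    for p in range(n_proteins):
        copies = [_mutate(c, within_rate, rng) for c in founder]
        flank_n = "".join(rng.choice(list(AMINO_ACIDS), n_flank))
        flank_c = "".join(rng.choice(list(AMINO_ACIDS), n_flank))
        domain = "".join(copies)
        sequence = flank_n + domain + flank_c
        repeats = []
        pos = n_flank + 1
        for c in copies:
            repeats.append((pos, pos + len(c) - 1))
            pos += len(c)
        records.append(
            ProteinRecord(
                f"{family}_P{p:02d}", sequence, repeats,
                meta={
                    "family": family,
                    "within_rate": within_rate,
                    "implied_identity": (1 - within_rate) ** 2,
                    "founder_domain": "".join(founder),
                },
            )
        )
    return records


def generate_planted_hierarchy(
    model: MotifModel,
    n_super: int = 2,
    subfamilies_per_super: int = 2,
    proteins_per_family: int = 6,
    copies_per_protein: int = 5,
    sub_divergence: float = 0.15,
    within_rate: float = 0.02,
    seed: int | np.random.Generator = 0,
) -> list[ProteinRecord]:
    """Two-level planted clustering ground truth.

    Each super-family founder domain is emitted from an independent random
    consensus; each sub-family's founder domain diverges from it at
    ``sub_divergence`` per position over the whole domain, and members
    within a sub-family diverge from their founder at ``within_rate``.
    With the defaults, expected repeat-domain identities are ~0.96 within a
    sub-family, ~0.69 between sub-families of one super-family, and near
    background between super-families.  Labels land in ``meta['family']``
    (sub) and ``meta['superfamily']``.
    """
    rng = _rng(seed)
    records = []
    for s in range(n_super):
        super_consensus = "".join(rng.choice(list(AMINO_ACIDS), model.length))
        super_model = MotifModel(
            model.length, super_consensus, np.ones(model.length)
        )
        super_founder = generate_repeat_copies(
            super_model, copies_per_protein, rng
        )
        for f in range(subfamilies_per_super):
            sub_founder = [_mutate(c, sub_divergence, rng) for c in super_founder]
            fam = f"S{s}F{f}"
            recs = generate_protein_family(
                super_model, proteins_per_family, copies_per_protein,
                within_rate, rng, family=fam, founder=sub_founder,
            )
            for r in recs:
                r.meta["superfamily"] = f"S{s}"
            records.extend(recs)
    return records


# ---------------------------------------------------------------------------
# solenoid geometry
# ---------------------------------------------------------------------------

@dataclass
class SolenoidSpec:
    """Parameters of the idealized two-helix solenoid stack."""

    n_copies: int = 4
    repeat_length: int = 33
    helix1_span: tuple[int, int] = (5, 11)
    helix2_span: tuple[int, int] = (15, 23)
    stack_offset: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copies < 3:
            raise ValueError("a repeat domain needs >= 3 copies")
        a1, b1 = self.helix1_span
        a2, b2 = self.helix2_span
        for (a, b) in ((a1, b1), (a2, b2)):
            if not (1 <= a <= b <= self.repeat_length):
                raise ValueError("helix spans must lie inside the repeat")
        if not b1 < a2:
            raise ValueError("helix spans must not overlap and helix1 comes first")


def _coil(p: np.ndarray, q: np.ndarray, n_interior: int,
          e1_pref: np.ndarray) -> Optional[np.ndarray]:
    """Interior points of a constant-step helical coil from ``p`` to ``q``.

    The path advances uniformly along the chord while a closed radial
    excursion (integer number of turns) absorbs the slack so every step is
    exactly :data:`STEP`.  Returns None when even a straight path cannot
    bridge the gap in ``n_interior + 1`` steps.
    """
    K = n_interior + 1
    d = q - p
    D = float(np.linalg.norm(d))
    if D > STEP * K:
        return None
    rise = D / K
    u = d / D
    planar = math.sqrt(max(STEP**2 - rise**2, 0.0))
    if planar < 1e-9 or K < 2:
        ts = np.arange(1, K) / K
        return p + np.outer(ts, d)
    m = max(K // 2, 1)             # turns; largest m keeps the coil tightest
    omega = 2 * math.pi * m / K
    rho = planar / (2 * math.sin(omega / 2))
    e1 = e1_pref - (e1_pref @ u) * u
    if np.linalg.norm(e1) < 1e-6:  # preferred direction parallel to chord
        alt = np.array([1.0, 0.0, 0.0])
        if abs(alt @ u) > 0.9:
            alt = np.array([0.0, 0.0, 1.0])
        e1 = alt - (alt @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    ks = np.arange(1, K)
    radial = (
        np.outer(np.cos(ks * omega) - 1.0, rho * e1)
        + np.outer(np.sin(ks * omega), rho * e2)
    )
    return p + np.outer(ks * rise, u) + radial


def _copy_template(spec: SolenoidSpec) -> np.ndarray:
    """Calpha coordinates of one repeat copy in its local frame."""
    L = spec.repeat_length
    a1, b1 = spec.helix1_span
    a2, b2 = spec.helix2_span
    coords = np.zeros((L, 3))

    def helix1(i: int) -> np.ndarray:
        t = math.radians(HELIX_TURN) * (i - a1)
        return np.array([HELIX_RADIUS * math.cos(t),
                         HELIX_RISE * (i - a1),
                         HELIX_RADIUS * math.sin(t)])

    y_top = HELIX_RISE * (b1 - a1)   # align the two helix tops

    def helix2(j: int) -> np.ndarray:
        t = math.radians(-90.0 - HELIX_TURN * (j - a2))
        return np.array([HELIX_RADIUS * math.cos(t),
                         y_top - HELIX_RISE * (j - a2),
                         _HELIX_SEP + HELIX_RADIUS * math.sin(t)])

    for i in range(a1, b1 + 1):
        coords[i - 1] = helix1(i)
    for j in range(a2, b2 + 1):
        coords[j - 1] = helix2(j)

    coords[0] = _P1_LOCAL
    segments = (
        # (start index, end index, anchor P, anchor Q, preferred coil axis)
        (1, a1, _P1_LOCAL, helix1(a1), np.array([0.0, 0.0, 1.0])),
        (b1, a2, helix1(b1), helix2(a2), np.array([0.0, -1.0, 0.0])),
    )
    for (i0, i1, p, q, pref) in segments:
        n_int = i1 - i0 - 1
        if n_int > 0:
            interior = _coil(p, q, n_int, pref)
            if interior is None:
                raise GenerationError(
                    "connector infeasible: helix anchors too far apart for the "
                    "available loop residues"
                )
            coords[i0:i1 - 1] = interior
        elif np.linalg.norm(q - p) > STEP + 0.5:
            raise GenerationError("connector infeasible: adjacent anchors too far")

    # C-tail runs from the end of helix 2 to the next copy's residue-1 anchor;
    # its residues b2+1 .. L are the interior points of that connector, so the
    # junction step (residue L -> next residue 1) is a regular 3.8 A step.
    target = _P1_LOCAL + np.array([spec.stack_offset, 0.0, 0.0])
    n_tail = L - b2
    if n_tail >= 1:
        tail = _coil(helix2(b2), target, n_tail, np.array([0.0, 1.0, 0.0]))
        if tail is None:
            raise GenerationError(
                "no inter-copy contacts possible: stack_offset separates "
                "consecutive copies beyond the reach of the tail loop"
            )
        coords[b2:L] = tail
    elif np.linalg.norm(target - helix2(b2)) > STEP + 0.5:
        raise GenerationError(
            "no inter-copy contacts possible: stack_offset separates "
            "consecutive copies beyond the reach of the tail loop"
        )
    return coords


def generate_solenoid_structure(spec: SolenoidSpec) -> CaStructure:
    """Generate the Calpha trace of a stacked solenoid repeat domain.

    Copies are related by a rigid translation of ``stack_offset`` along the
    stacking axis.  Before returning, the 7 A contact network of the output
    is checked for the guaranteed topology: at least one intra-copy
    helix1-helix2 edge, at least one edge between each pair of consecutive
    copies, no edge between copies more than one apart, and every backbone
    step within 0.5 A of 3.8 A.  Violations raise :class:`GenerationError`.
    """
    template = _copy_template(spec)
    L = spec.repeat_length
    shift = np.array([spec.stack_offset, 0.0, 0.0])
    coords = np.vstack([template + c * shift for c in range(spec.n_copies)])

    # --- self-check -------------------------------------------------------
    steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    bad = np.flatnonzero(np.abs(steps - STEP) > 0.5)
    if bad.size:
        raise GenerationError(
            f"backbone step {steps[bad[0]]:.2f} A at residue {bad[0] + 1} "
            f"deviates more than 0.5 A from {STEP} A"
        )

    residues = [
        CaResidue("A", i + 1, "A", *coords[i]) for i in range(len(coords))
    ]
    structure = CaStructure(residues, source="predicted")
    net = build_network(structure, params=NetworkParams(r_c=7.0, min_sep=1))

    copy_of = lambda resnum: (resnum - 1) // L
    pos_of = lambda resnum: (resnum - 1) % L + 1
    a1, b1 = spec.helix1_span
    a2, b2 = spec.helix2_span
    has_h1h2 = False
    adjacent_pairs = set()
    for i, j in net.edges():
        ci, cj = copy_of(i), copy_of(j)
        if abs(ci - cj) > 1:
            raise GenerationError(
                f"edge between non-adjacent copies {ci + 1} and {cj + 1} "
                f"(residues {i}, {j})"
            )
        if ci != cj:
            adjacent_pairs.add((min(ci, cj), max(ci, cj)))
        elif (a1 <= pos_of(i) <= b1 and a2 <= pos_of(j) <= b2) or (
            a1 <= pos_of(j) <= b1 and a2 <= pos_of(i) <= b2
        ):
            has_h1h2 = True
    if not has_h1h2:
        raise GenerationError("no intra-copy helix1-helix2 contact at 7 A")
    expected = {(c, c + 1) for c in range(spec.n_copies - 1)}
    if adjacent_pairs != expected:
        raise GenerationError(
            "missing inter-copy contact between consecutive copies "
            f"{sorted(expected - adjacent_pairs)}"
        )
    return structure


def generate_ss_and_plddt(
    spec: SolenoidSpec,
    plddt_mean: float = 95.0,
    plddt_sd: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, np.ndarray]:
    """Per-residue secondary-structure string and pLDDT values.

    H over the helix spans, T over the inter-helix turn, C elsewhere,
    repeated per copy; pLDDT is Gaussian noise around ``plddt_mean``
    clipped to [0, 100].
    """
    if not 0 <= plddt_mean <= 100:
        raise ValueError("plddt_mean must be in [0, 100]")
    rng = _rng(seed)
    a1, b1 = spec.helix1_span
    a2, b2 = spec.helix2_span
    per_copy = []
    for p in range(1, spec.repeat_length + 1):
        if a1 <= p <= b1 or a2 <= p <= b2:
            per_copy.append("H")
        elif b1 < p < a2:
            per_copy.append("T")
        else:
            per_copy.append("C")
    ss = "".join(per_copy) * spec.n_copies
    n = spec.repeat_length * spec.n_copies
    plddt = np.clip(rng.normal(plddt_mean, plddt_sd, n), 0.0, 100.0)
    return ss, plddt
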
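"""Mapping protein-level variants into repeat-motif coordinates.

A variant at protein position p inside repeat copy c = (start, end) gets
``copy_number`` c and ``motif_position`` p - start + 1; variants outside
every copy are flagged not-in-repeat.  Mapped variants are joined with the
cluster consensus (conserved iff the consensus letter is not ``X``) and the
per-position centrality/edge profile, reconstructing the machinery behind a
"variations at conserved motif positions" table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io_formats import ProteinRecord, VariantRecord
from .motifprofiles import PositionProfile


@dataclass
class MappedVariant:
    variant: VariantRecord
    copy_number: Optional[int]          # None when not in any repeat copy
    motif_position: Optional[int]
    at_conserved_position: bool = False
    ref_mismatch: bool = False
    kind: str = "substitution"          # "substitution" | "frameshift"
    profile_values: dict[str, float] = None

    @property
    def in_repeat(self) -> bool:
        return self.copy_number is not None


def map_variant(
    position: int, record: ProteinRecord
) -> Optional[tuple[int, int]]:
    """(copy_number, motif_position) of a protein position, or None.

    Multi-residue or frameshift variants are mapped by their first affected
    residue (the caller passes that position).
    """
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    if position > len(record.sequence):
        raise ValueError(
            f"position {position} beyond {record.accession} "
            f"(length {len(record.sequence)})"
        )
    return record.copy_of(position)


def annotate_variants(
    variants: Sequence[VariantRecord],
    record: ProteinRecord,
    consensus: str,
    profile: Optional[PositionProfile] = None,
) -> list[MappedVariant]:
    """Join variants with motif coordinates, conservation and profile values.

    The stated reference residue is checked against the sequence; a
    disagreement sets ``ref_mismatch`` instead of failing (annotation
    releases drift).  Variants outside every repeat copy come back with
    ``copy_number = None``.
    """
    out = []
    for v in variants:
        if v.accession != record.accession:
            continue
        hit = map_variant(v.position, record)
        kind = "frameshift" if v.is_frameshift() else "substitution"
        if hit is None:
            out.append(MappedVariant(v, None, None, kind=kind, profile_values={}))
            continue
        copy_number, motif_position = hit
        conserved = (
            motif_position <= len(consensus)
            and consensus[motif_position - 1] != "X"
        )
        mismatch = (
            not v.is_frameshift()
            and record.sequence[v.position - 1] != v.ref
        )
        values = {}
        if profile is not None and motif_position <= profile.l_max:
            row = profile.table.iloc[motif_position - 1]
            values = {
                c.removeprefix("mean_"): float(row[c])
                for c in profile.table.columns
                if c.startswith("mean_")
            }
        out.append(
            MappedVariant(
                v, copy_number, motif_position,
                at_conserved_position=conserved,
                ref_mismatch=mismatch,
                kind=kind,
                profile_values=values,
            )
        )
    return out


def variants_table(mapped: Sequence[MappedVariant]) -> pd.DataFrame:
    """Flat table of mapped variants (one row each, profile columns joined)."""
    rows = []
    for m in mapped:
        row = {
            "accession": m.variant.accession,
            "position": m.variant.position,
            "ref": m.variant.ref,
            "alt": m.variant.alt,
            "condition": m.variant.condition,
            "copy_number": m.copy_number,
            "motif_position": m.motif_position,
            "in_repeat": m.in_repeat,
            "at_conserved_position": m.at_conserved_position,
            "ref_mismatch": m.ref_mismatch,
            "kind": m.kind,
        }
        for k, v in (m.profile_values or {}).items():
            row[f"profile_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def per_position_summary(mapped: Sequence[MappedVariant]) -> pd.DataFrame:
    """Count mapped variants per motif position (grouped-table reconstruction)."""
    in_repeat = [m for m in mapped if m.in_repeat]
    if not in_repeat:
        return pd.DataFrame(columns=["motif_position", "n_variants"])
    counts = (
        pd.Series([m.motif_position for m in in_repeat])
        .value_counts()
        .sort_index()
    )
    return pd.DataFrame(
        {"motif_position": counts.index, "n_variants": counts.to_numpy()}
    )
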
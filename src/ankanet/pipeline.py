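"""End-to-end orchestration: simulate -> cluster -> profile -> variants.

The pipeline reads a key-value YAML configuration (defaults equal the
analysis parameters used throughout: R_c = 7 A, min_sep = 1, identity
thresholds 0.9/0.6/0.3, 50% consensus, pLDDT cutoff 90, >= 3 repeat
copies, L_max = 33) and writes TSV/FASTA/JSON outputs whose header lines
record the parameters that produced them.  All randomness flows from one
seed, and a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import contactnet, io_formats, motifprofiles, repeatseq, seqcluster, synthgen
from .io_formats import CaResidue, CaStructure, ProteinRecord

logger = logging.getLogger("ankanet")

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    # inputs
    fasta: str = "inputs/proteins.fasta"
    annotations: str = "inputs/repeats.tsv"
    structures_dir: str = "inputs/structures"
    dssp_dir: str = "inputs/dssp"
    variants: str = "inputs/variants.tsv"
    # parameters (defaults are the analysis values used throughout)
    r_c: float = 7.0
    min_sep: int = 1
    thresholds: tuple[float, ...] = (0.9, 0.6, 0.3)
    consensus_threshold: float = 0.5
    plddt_cutoff: float = 90.0
    min_copies: int = 3
    l_max: int = 33
    # output
    outdir: str = "results"
    seed: int = 0

    _PATH_FIELDS = ("fasta", "annotations", "structures_dir", "dssp_dir",
                    "variants", "outdir")

    def to_yaml(self, path: str | Path, relative_to: str | Path | None = None) -> None:
        """Write the config; with ``relative_to`` paths are stored relative
        (keeps a simulated study relocatable and runs byte-reproducible)."""
        data = asdict(self)
        data["thresholds"] = list(self.thresholds)
        if relative_to is not None:
            base = Path(relative_to).resolve()
            for key in self._PATH_FIELDS:
                p = Path(data[key])
                if p.is_absolute():
                    try:
                        data[key] = str(p.resolve().relative_to(base))
                    except ValueError:
                        pass
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Read a config; relative paths resolve against the file's directory."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "thresholds" in data:
            data["thresholds"] = tuple(data["thresholds"])
        base = Path(path).resolve().parent
        for key in cls._PATH_FIELDS:
            if key in data and not Path(data[key]).is_absolute():
                data[key] = str(base / data[key])
        return cls(**data)

    def params_header(self, stage: str) -> str:
        return (
            f"# ankanet {stage}; r_c={self.r_c} min_sep={self.min_sep} "
            f"thresholds={','.join(str(t) for t in self.thresholds)} "
            f"consensus_threshold={self.consensus_threshold} "
            f"plddt_cutoff={self.plddt_cutoff} min_copies={self.min_copies} "
            f"l_max={self.l_max} seed={self.seed}\n"
        )


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def simulate_study(
    root: str | Path,
    seed: int = 0,
    subfamilies_per_super: Sequence[int] = (2, 3),
    proteins_per_family: int = 6,
    copies_per_protein: int = 5,
    sub_divergence: float = 0.15,
    within_rate: float = 0.02,
) -> PipelineConfig:
    """Write a complete synthetic study under ``root`` and return its config.

    The study plants two super-families split into five families (default):
    members within a family at ~0.94 repeat-domain identity, families of the
    same super-family at ~0.68, unrelated super-families near background.
    Every protein gets a solenoid Calpha structure (renumbered to its domain
    coordinates), a DSSP-like file, and a couple of variants at conserved
    and non-repeat positions.
    """
    root = Path(root)
    inputs = root / "inputs"
    for sub in ("structures", "dssp"):
        (inputs / sub).mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    model = synthgen.ankyrin_motif()
    records: list[ProteinRecord] = []
    for s, n_sub in enumerate(subfamilies_per_super):
        batch = synthgen.generate_planted_hierarchy(
            model, n_super=1, subfamilies_per_super=n_sub,
            proteins_per_family=proteins_per_family,
            copies_per_protein=copies_per_protein,
            sub_divergence=sub_divergence, within_rate=within_rate,
            seed=rng,
        )
        for r in batch:
            r.accession = f"S{s}" + r.accession[2:]
            r.meta["superfamily"] = f"S{s}"
            r.meta["family"] = f"S{s}" + r.meta["family"][2:]
        records.extend(batch)
    records.sort(key=lambda r: r.accession)

    io_formats.write_fasta({r.accession: r.sequence for r in records}, inputs / "proteins.fasta")
    io_formats.write_annotations(records, inputs / "repeats.tsv")

    spec = synthgen.SolenoidSpec(
        n_copies=copies_per_protein, repeat_length=model.length
    )
    template = synthgen.generate_solenoid_structure(spec)
    variants: list[io_formats.VariantRecord] = []
    for i, rec in enumerate(records):
        offset = rec.repeats[0][0] - 1
        domain = rec.repeat_domain_sequence()
        # the last protein gets a low-confidence model to exercise the filter
        plddt_mean = 85.0 if i == len(records) - 1 else 95.0
        ss, plddt = synthgen.generate_ss_and_plddt(spec, plddt_mean, 2.0, rng)
        residues = [
            CaResidue("A", j + 1 + offset, domain[j], r.x, r.y, r.z,
                      plddt=float(plddt[j]))
            for j, r in enumerate(template.residues)
        ]
        structure = CaStructure(residues, source="predicted")
        io_formats.write_pdb_calpha(structure, inputs / "structures" / f"{rec.accession}.pdb")
        io_formats.write_ss_tsv(
            [r.resnum for r in residues], list(domain), list(ss),
            inputs / "dssp" / f"{rec.accession}.tsv",
        )
        # two variants per protein: one at a conserved motif position,
        # one in the N-terminal flank (not-in-repeat)
        copy = int(rng.integers(rec.n_copies)) + 1
        motif_pos = int(rng.choice((2, 6, 9, 21, 25)))
        pos = rec.repeats[copy - 1][0] + motif_pos - 1
        ref = rec.sequence[pos - 1]
        alt = rng.choice([a for a in io_formats.AMINO_ACIDS if a != ref])
        variants.append(io_formats.VariantRecord(
            rec.accession, pos, ref, str(alt), "synthetic pathogenic"))
        flank_pos = int(rng.integers(1, rec.repeats[0][0]))
        ref2 = rec.sequence[flank_pos - 1]
        alt2 = rng.choice([a for a in io_formats.AMINO_ACIDS if a != ref2])
        variants.append(io_formats.VariantRecord(
            rec.accession, flank_pos, ref2, str(alt2), "synthetic benign"))
    io_formats.write_variants(variants, inputs / "variants.tsv")

    config = PipelineConfig(
        fasta=str(inputs / "proteins.fasta"),
        annotations=str(inputs / "repeats.tsv"),
        structures_dir=str(inputs / "structures"),
        dssp_dir=str(inputs / "dssp"),
        variants=str(inputs / "variants.tsv"),
        outdir=str(root / "results"),
        seed=seed,
    )
    config.to_yaml(root / "config.yaml", relative_to=root)
    return config


# ---------------------------------------------------------------------------
# sequence stage
# ---------------------------------------------------------------------------

@dataclass
class SequenceStageResult:
    records: list[ProteinRecord]
    clusterset: seqcluster.ClusterSet
    consensus_by_cluster: dict[int, str]
    cluster_stats: pd.DataFrame


def run_sequence_stage(config: PipelineConfig) -> SequenceStageResult:
    """Filter, cluster and summarize the repeat-domain sequences."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = io_formats.read_annotations(config.annotations, config.fasta)
    records.sort(key=lambda r: r.accession)
    logger.info("sequence stage: %d records read", len(records))
    kept = [r for r in records if r.n_copies >= config.min_copies]
    logger.info("sequence stage: %d records with >= %d copies",
                len(kept), config.min_copies)
    if not kept:
        raise ValueError(
            f"no record has >= {config.min_copies} repeat copies"
        )

    # per-copy length distribution and coverage
    hist, frac = repeatseq.length_histogram(kept)
    header = config.params_header("sequence")
    _write_table(
        pd.DataFrame({"length": list(hist), "count": list(hist.values())}),
        outdir / "repeat_lengths.tsv", header,
    )
    coverage = pd.DataFrame(
        {
            "accession": [r.accession for r in kept],
            "n_copies": [r.n_copies for r in kept],
            "coverage": [repeatseq.domain_coverage(r) for r in kept],
        }
    )
    _write_table(coverage, outdir / "domain_coverage.tsv", header)

    all_copies = [c for r in kept for c in repeatseq.extract_repeats(r)]
    bias = repeatseq.composition_bias(all_copies)
    _write_table(bias.to_frame(), outdir / "composition_bias.tsv", header)

    # clustering of concatenated repeat domains
    domains = {r.accession: r.repeat_domain_sequence() for r in kept}
    clusterset = seqcluster.hierarchical_cluster(domains, config.thresholds)
    logger.info("sequence stage: %d terminal clusters", clusterset.n_clusters)
    report = seqcluster.cluster_report(clusterset, domains)
    _write_table(report, outdir / "clusters.tsv", header)
    with open(outdir / "clusters.json", "w") as fh:
        json.dump(
            {
                "thresholds": list(config.thresholds),
                "passes": [
                    {
                        "threshold": p.threshold,
                        "clusters": [
                            {
                                "seed": c.seed,
                                "representative": c.representative,
                                "members": c.members,
                                "identity_to_representative":
                                    c.identity_to_representative,
                            }
                            for c in p.clusters
                        ],
                    }
                    for p in clusterset.passes
                ],
                "assignment": clusterset.assignment,
            },
            fh, indent=1, sort_keys=True,
        )

    by_acc = {r.accession: r for r in kept}
    stats_rows = []
    consensus_by_cluster: dict[int, str] = {}
    consensus_seqs: dict[str, str] = {}
    col_stats_frames = []
    for cid in range(clusterset.n_clusters):
        members = sorted(clusterset.members_of(cid))
        copy_counts = [by_acc[m].n_copies for m in members]
        copies = [
            c for m in members for c in repeatseq.extract_repeats(by_acc[m])
        ]
        msa = repeatseq.pad_alignment(copies, width=config.l_max)
        cons = repeatseq.consensus(msa, config.consensus_threshold)
        consensus_by_cluster[cid] = cons
        consensus_seqs[f"cluster{cid + 1}"] = cons
        stats = repeatseq.column_stats(msa)
        frame = pd.DataFrame(
            {
                "cluster": cid + 1,
                "position": np.arange(1, stats.n_columns + 1),
                "information_bits": stats.information,
            }
        )
        col_stats_frames.append(frame)
        stats_rows.append(
            {
                "cluster": cid + 1,
                "n_members": len(members),
                "mean_copies": float(np.mean(copy_counts)),
                "sd_copies": float(np.std(copy_counts, ddof=0)),
                "consensus": cons,
            }
        )
    cluster_stats = pd.DataFrame(stats_rows)
    _write_table(cluster_stats, outdir / "cluster_stats.tsv", header)
    _write_table(
        pd.concat(col_stats_frames, ignore_index=True),
        outdir / "column_information.tsv", header,
    )
    io_formats.write_fasta(consensus_seqs, outdir / "cluster_consensus.fasta")

    return SequenceStageResult(kept, clusterset, consensus_by_cluster, cluster_stats)


# ---------------------------------------------------------------------------
# structure stage
# ---------------------------------------------------------------------------

@dataclass
class StructureStageResult:
    profiles: dict[str, motifprofiles.PositionProfile]           # per protein
    cluster_profiles: dict[int, motifprofiles.PositionProfile]
    consensus_ss: dict[int, str]
    excluded: list[str]                                          # pLDDT failures


def analyze_structure(
    structure: CaStructure,
    record: ProteinRecord,
    config: PipelineConfig,
) -> motifprofiles.PositionProfile:
    """Contact network + centralities + repeat-aware profile for one protein."""
    params = contactnet.NetworkParams(r_c=config.r_c, min_sep=config.min_sep)
    network = contactnet.build_network(structure, region=record.repeats, params=params)
    b = contactnet.betweenness(network)
    e = contactnet.eigenvector_centrality(network).values
    return motifprofiles.profile_from_analysis(
        network, record, b, e, l_max=config.l_max
    )


def run_structure_stage(
    config: PipelineConfig, seq_result: Optional[SequenceStageResult] = None
) -> StructureStageResult:
    """Profile every clustered protein with an available structure."""
    if seq_result is None:
        seq_result = run_sequence_stage(config)
    outdir = Path(config.outdir)
    header = config.params_header("structure")
    structures_dir = Path(config.structures_dir)
    pdbs = sorted(structures_dir.glob("*.pdb"))
    if not pdbs:
        raise ValueError(f"no structures found in {structures_dir}")
    by_acc = {r.accession: r for r in seq_result.records}

    profiles: dict[str, motifprofiles.PositionProfile] = {}
    excluded: list[str] = []
    n_analyzed = 0
    for pdb in pdbs:
        acc = pdb.stem
        if acc not in by_acc:
            continue
        record = by_acc[acc]
        structure = io_formats.read_pdb_calpha(pdb)
        if structure.source == "predicted":
            ok, mean = contactnet.plddt_domain_filter(
                structure, record.repeats, config.plddt_cutoff
            )
            if not ok:
                logger.info("structure stage: %s excluded, mean pLDDT %.1f < %.1f",
                            acc, mean, config.plddt_cutoff)
                excluded.append(acc)
                continue
        try:
            profile = analyze_structure(structure, record, config)
        except ValueError as exc:
            raise ValueError(f"{acc}: structure/annotation mismatch: {exc}") from exc
        profiles[acc] = profile
        n_analyzed += 1
    logger.info("structure stage: %d structures analyzed, %d excluded",
                n_analyzed, len(excluded))

    profile_dir = outdir / "profiles"
    profile_dir.mkdir(parents=True, exist_ok=True)
    for acc in sorted(profiles):
        _write_table(profiles[acc].table, profile_dir / f"{acc}.tsv", header)

    cluster_profiles: dict[int, motifprofiles.PositionProfile] = {}
    consensus_ss: dict[int, str] = {}
    dssp_dir = Path(config.dssp_dir)
    for cid in range(seq_result.clusterset.n_clusters):
        members = sorted(seq_result.clusterset.members_of(cid))
        member_profiles = [profiles[m] for m in members if m in profiles]
        if member_profiles:
            merged = motifprofiles.cluster_consensus_profile(member_profiles)
            cluster_profiles[cid] = merged
            _write_table(merged.table, profile_dir / f"cluster{cid + 1}.tsv", header)
        ss_copies = []
        for m in members:
            ss_file = dssp_dir / f"{m}.tsv"
            if not ss_file.exists():
                continue
            ss_map = io_formats.read_dssp(ss_file)
            for s, e in by_acc[m].repeats:
                ss_copies.append(
                    "".join(ss_map.get(p, "-") for p in range(s, e + 1))
                )
        if ss_copies:
            consensus_ss[cid] = motifprofiles.consensus_secondary_structure(
                ss_copies, config.l_max
            )
    if consensus_ss:
        with open(outdir / "consensus_ss.tsv", "w") as fh:
            fh.write(header)
            fh.write("cluster\tconsensus_ss\n")
            for cid in sorted(consensus_ss):
                fh.write(f"{cid + 1}\t{consensus_ss[cid]}\n")

    return StructureStageResult(profiles, cluster_profiles, consensus_ss, excluded)


# ---------------------------------------------------------------------------
# variant stage
# ---------------------------------------------------------------------------

def run_variant_stage(
    config: PipelineConfig,
    seq_result: SequenceStageResult,
    struct_result: Optional[StructureStageResult] = None,
) -> pd.DataFrame:
    """Map the variant table into motif coordinates and join profiles."""
    from . import variantmap

    variants = io_formats.read_variants(config.variants)
    by_acc = {r.accession: r for r in seq_result.records}
    frames = []
    for acc in sorted({v.accession for v in variants}):
        if acc not in by_acc:
            logger.warning("variant stage: accession %s not in the record set", acc)
            continue
        cid = seq_result.clusterset.assignment.get(acc)
        cons = seq_result.consensus_by_cluster.get(cid, "")
        profile = None
        if struct_result is not None:
            profile = struct_result.cluster_profiles.get(cid)
        mapped = variantmap.annotate_variants(
            [v for v in variants if v.accession == acc],
            by_acc[acc], cons, profile,
        )
        frames.append(variantmap.variants_table(mapped))
    table = (
        pd.concat(frames, ignore_index=True)
        if frames else pd.DataFrame()
    )
    _write_table(table, Path(config.outdir) / "variants_mapped.tsv",
                 config.params_header("variants"))
    return table


# ---------------------------------------------------------------------------
# run-all
# ---------------------------------------------------------------------------

def run_all(config: PipelineConfig) -> StructureStageResult:
    """Sequence stage, then structure stage, then variant mapping."""
    seq_result = run_sequence_stage(config)
    struct_result = run_structure_stage(config, seq_result)
    if Path(config.variants).exists():
        run_variant_stage(config, seq_result, struct_result)
    return struct_result
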
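"""End-to-end orchestration: QC -> common regions -> per-sample consensus
-> directed pairwise SNPs -> distance matrix -> NJ tree (+ bootstrap).

`run_snp_phylogeny` is the in-memory core used by the analysis drivers and
the validation experiments; `run_pipeline` wraps it with file I/O, a
manifest of outputs with checksums, and stage-tagged logging.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import common as common_mod
from . import qc as qc_mod
from .common import SampleReadSet, filter_common_contigs, pooled_assemble, split_by_sample
from .consensus import ConsensusReference, assemble_sample
from .pairwise import DirectedSnpResult, all_pairs, snp_site_table, write_rate_table
from .phylo import (
    DistanceMatrix,
    SupportTree,
    bootstrap_supports,
    build_distance_matrix,
    neighbor_joining,
)
from .qc import QcReport
from .seqio import Read, read_fastq, write_fastq

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Tunable parameters of the SNP-phylogeny pipeline."""

    pooled_k: int = 19
    sample_k: int | None = None  # default: same as pooled_k
    placement_max_mismatches: int = 3
    seed_length: int = 20
    align_max_mismatches: int = 3
    ploidy: Mapping[str, int] | int = 3
    min_depth: int = 3
    min_allele_fraction: float | None = None
    min_read_length: int = 20
    bootstrap_replicates: int = 200
    seed: int = 0

    @property
    def effective_sample_k(self) -> int:
        return self.sample_k if self.sample_k is not None else self.pooled_k


@dataclass
class PipelineResult:
    qc_reports: dict[str, QcReport]
    contigs: list
    retained_contigs: list
    retained_fraction: float
    read_sets: list[SampleReadSet]
    references: dict[str, ConsensusReference]
    directed: list[DirectedSnpResult]
    distance_matrix: DistanceMatrix
    nj_tree: SupportTree | None
    bootstrap_tree: SupportTree | None = None


def run_snp_phylogeny(
    reads_by_sample: Mapping[str, Sequence[Read]],
    params: PipelineParams | None = None,
    bootstrap: bool = False,
) -> PipelineResult:
    """Run the full comparison on in-memory reads."""
    params = params or PipelineParams()
    samples = sorted(reads_by_sample)
    if len(samples) < 2:
        raise ValueError("need at least two samples")

    logger.info("[qc] filtering %d samples", len(samples))
    clean, reports = qc_mod.filter_by_sample(
        {s: list(reads_by_sample[s]) for s in samples}, min_length=params.min_read_length
    )

    logger.info("[common] pooled assembly (k=%d)", params.pooled_k)
    pooled = [r for s in samples for r in clean[s]]
    contigs = pooled_assemble(
        pooled, k=params.pooled_k, max_mismatches=params.placement_max_mismatches
    )
    retained, fraction = filter_common_contigs(contigs, samples)
    read_sets = split_by_sample(retained)
    got = {rs.sample_label for rs in read_sets}
    missing = [s for s in samples if s not in got]
    if missing:
        raise ValueError(f"no common-region reads for samples {missing}")

    logger.info("[consensus] per-sample assembly (k=%d)", params.effective_sample_k)
    references = {
        rs.sample_label: assemble_sample(
            rs, k=params.effective_sample_k,
            max_mismatches=params.placement_max_mismatches,
        )
        for rs in read_sets
    }

    logger.info("[pairwise] %d directed comparisons", len(samples) * (len(samples) - 1))
    directed = all_pairs(
        {rs.sample_label: rs.reads for rs in read_sets},
        references,
        ploidy=params.ploidy,
        max_mismatches=params.align_max_mismatches,
        seed_length=params.seed_length,
        min_depth=params.min_depth,
        min_allele_fraction=params.min_allele_fraction,
    )

    dm = build_distance_matrix(directed, labels=samples)
    tree = neighbor_joining(dm) if len(samples) >= 3 else None
    boot = None
    if bootstrap and tree is not None:
        logger.info("[bootstrap] %d replicates", params.bootstrap_replicates)
        boot = bootstrap_supports(
            directed,
            ploidy=params.ploidy,
            n_replicates=params.bootstrap_replicates,
            seed=params.seed,
            min_depth=params.min_depth,
            min_allele_fraction=params.min_allele_fraction,
            labels=samples,
        )
    return PipelineResult(
        reports, contigs, retained, fraction, read_sets, references,
        directed, dm, tree, boot,
    )


@dataclass
class RunConfig:
    """File-level run configuration (one FASTQ per sample)."""

    samples: list[tuple[str, str]]  # (sample name, fastq path)
    output_dir: str
    params: PipelineParams = field(default_factory=PipelineParams)
    bootstrap: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = PipelineParams(**raw.get("params", {}))
        return cls(
            samples=[(s["name"], s["fastq"]) for s in raw["samples"]],
            output_dir=raw["output_dir"],
            params=params,
            bootstrap=bool(raw.get("bootstrap", False)),
        )


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of violations; empty means the config is usable."""
    violations: list[str] = []
    names = [n for n, _ in config.samples]
    if len(set(names)) != len(names):
        violations.append("samples: duplicate sample names")
    if len(names) < 2:
        violations.append("samples: need at least two samples")
    for name, path in config.samples:
        if not Path(path).exists():
            violations.append(f"samples[{name}]: file not found: {path}")
    p = config.params
    if p.pooled_k % 2 == 0 or p.pooled_k < 15:
        violations.append("params.pooled_k: must be odd and >= 15")
    if p.sample_k is not None and (p.sample_k % 2 == 0 or p.sample_k < 15):
        violations.append("params.sample_k: must be odd and >= 15")
    if isinstance(p.ploidy, int):
        if p.ploidy < 1:
            violations.append("params.ploidy: must be >= 1")
    else:
        for s, pl in p.ploidy.items():
            if pl < 1:
                violations.append(f"params.ploidy[{s}]: must be >= 1")
    if p.min_depth < 1:
        violations.append("params.min_depth: must be >= 1")
    if p.bootstrap_replicates < 1:
        violations.append("params.bootstrap_replicates: must be >= 1")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages from FASTQ inputs and write every artifact.

    Returns (and writes) a manifest mapping artifact names to paths and
    checksums; identical inputs and seeds give identical manifests.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    reads_by_sample = {
        name: read_fastq(path, name) for name, path in config.samples
    }
    result = run_snp_phylogeny(reads_by_sample, config.params, bootstrap=config.bootstrap)

    artifacts: dict[str, Path] = {}
    for sample, report in result.qc_reports.items():
        p = outdir / f"qc_{sample}.tsv"
        report.write(p)
        artifacts[f"qc_{sample}"] = p

    p = outdir / "common_contigs.fasta"
    from .seqio import write_fasta
    write_fasta(p, [(c.contig_id, c.consensus) for c in result.retained_contigs])
    artifacts["common_contigs"] = p
    p = outdir / "membership.tsv"
    common_mod.write_membership_table(result.retained_contigs, p)
    artifacts["membership"] = p

    for rs in result.read_sets:
        p = outdir / f"common_reads_{rs.sample_label}.fastq"
        write_fastq(p, rs.reads)
        artifacts[f"common_reads_{rs.sample_label}"] = p
    for sample, ref in result.references.items():
        p = outdir / f"reference_{sample}.fasta"
        ref.write(p)
        artifacts[f"reference_{sample}"] = p

    p = outdir / "directed_snp_rates.tsv"
    write_rate_table(result.directed, p, labels=result.distance_matrix.labels)
    artifacts["directed_snp_rates"] = p

    for r in result.directed:
        if r.pileup is None:
            continue
        rows = snp_site_table(r.pileup, _ploidy_for(config.params.ploidy, r.query_sample),
                              min_depth=config.params.min_depth,
                              min_allele_fraction=config.params.min_allele_fraction)
        p = outdir / f"snps_{r.query_sample}_vs_{r.reference_sample}.tsv"
        with open(p, "w") as fh:
            fh.write("ref_id\tposition\tref_base\tconsensus_base\tdepth\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")
        artifacts[f"snps_{r.query_sample}_vs_{r.reference_sample}"] = p

    p = outdir / "distance_matrix.tsv"
    p.write_text(result.distance_matrix.lower_triangle_tsv())
    artifacts["distance_matrix"] = p
    p = outdir / "distance_matrix.phylip"
    result.distance_matrix.write_phylip(p)
    artifacts["distance_matrix_phylip"] = p

    if result.nj_tree is not None:
        p = outdir / "nj_tree.nwk"
        p.write_text(result.nj_tree.newick() + "\n")
        artifacts["nj_tree"] = p
    if result.bootstrap_tree is not None:
        p = outdir / "bootstrap_consensus.nwk"
        p.write_text(result.bootstrap_tree.newick() + "\n")
        artifacts["bootstrap_consensus"] = p

    manifest = {
        "seed": config.params.seed,
        "params": {k: (dict(v) if isinstance(v, Mapping) else v)
                   for k, v in asdict(config.params).items()},
        "retained_read_fraction": result.retained_fraction,
        "artifacts": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _ploidy_for(ploidy: Mapping[str, int] | int, sample: str) -> int:
    return ploidy[sample] if isinstance(ploidy, Mapping) else ploidy
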
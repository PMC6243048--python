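"""End-to-end seed-guided assembly pipeline.

Per sample: build the colored graph from read pairs, collapse unitigs on the
sample color, remove unitigs below the mean-coverage threshold, extract the
seed-anchored subgraphs, prune short tips, enumerate tip-to-tip candidates,
and keep the candidates the bootstrap support filter retains.  Candidates are
then aggregated across samples with reverse-complement-aware deduplication.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .gfa import export_gfa
from .graph import GraphParams, build_graph
from .quant import (
    FilterParams,
    PseudoIndex,
    bootstrap_support,
    build_ec_counts,
    retain_candidates,
)
from .seeds import (
    CandidateTranscript,
    SeedRegion,
    dedupe_candidates,
    enumerate_candidates,
    extract_seed_subgraphs,
    orient_to_seed,
    prune_tips,
)
from .unitigs import collapse_unitigs, filter_unitigs_by_mean_coverage

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    graph: GraphParams = field(default_factory=GraphParams)
    filter: FilterParams = field(default_factory=FilterParams)
    tip_min_kmers: int = 47
    max_paths: int = 10_000
    rng_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "graph": asdict(self.graph),
                "filter": asdict(self.filter),
                "tip_min_kmers": self.tip_min_kmers,
                "max_paths": self.max_paths,
                "rng_seed": self.rng_seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SampleResult:
    sample: str
    candidates: list[CandidateTranscript]
    retained: list[CandidateTranscript]
    support: dict[str, int]
    est_counts: dict[str, float]
    subgraph_gfa: dict[str, str]


@dataclass
class PipelineResult:
    config: PipelineConfig
    samples: dict[str, SampleResult]
    deduped: list[tuple[CandidateTranscript, list[str]]]

    def retained_sequences(self) -> dict[str, str]:
        return {
            f"candidate_{i:04d}": rep.sequence
            for i, (rep, _) in enumerate(self.deduped)
        }


def assemble_sample(
    sample: str,
    pairs: Sequence[tuple[str, str]],
    seeds: Sequence[SeedRegion],
    config: PipelineConfig,
) -> SampleResult:
    """Run the per-sample stages: graph -> candidates -> support filter."""
    gp = config.graph
    reads = [m for pair in pairs for m in pair]
    graph = build_graph(reads, gp, sample)
    ug = collapse_unitigs(graph, [sample])
    ug = filter_unitigs_by_mean_coverage(
        ug, gp.min_unitig_mean_coverage, sample
    )
    logger.info(
        "%s: %d nodes, %d unitigs after coverage filter", sample, len(graph), len(ug.unitigs)
    )
    subs = extract_seed_subgraphs(ug, seeds)
    candidates: list[CandidateTranscript] = []
    gfa: dict[str, str] = {}
    for sub in subs:
        pruned = prune_tips(sub, config.tip_min_kmers)
        cands = enumerate_candidates(pruned, config.max_paths, source_sample=sample)
        primary_seed = next(
            (s for s in seeds if s.name == pruned.seed_names[0]), None
        )
        if primary_seed is not None:
            cands = orient_to_seed(cands, primary_seed)
        candidates.extend(cands)
        gfa[",".join(pruned.seed_names)] = export_gfa(ug)
    if not candidates:
        return SampleResult(sample, [], [], {}, {}, gfa)

    named = {
        f"{sample}_cand_{i:04d}": c.sequence for i, c in enumerate(candidates)
    }
    index = PseudoIndex(named, gp.k)
    ec = build_ec_counts(
        pairs, index, config.filter.require_both_mates_indexed
    )
    lengths = index.lengths()
    support = bootstrap_support(ec, lengths, config.filter)
    kept_ids = retain_candidates(support, config.filter)
    by_name = dict(zip(named, candidates))
    retained = [by_name[n] for n in sorted(kept_ids)]
    return SampleResult(
        sample,
        candidates,
        retained,
        support.support,
        support.point_estimate.counts if support.point_estimate else {},
        gfa,
    )


def run_pipeline(
    samples: Mapping[str, Sequence[tuple[str, str]]],
    seeds: Sequence[SeedRegion],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Assemble every sample and aggregate retained candidates across samples.

    When ``out_dir`` is given, writes: retained candidate FASTA, per-sample
    support TSVs, per-seed GFA files, and a JSON manifest with the tool
    version, parameters and config hash.
    """
    if config is None:
        config = PipelineConfig()
    results: dict[str, SampleResult] = {}
    for sample in sorted(samples):
        results[sample] = assemble_sample(sample, samples[sample], seeds, config)
    deduped = dedupe_candidates(
        {s: r.retained for s, r in results.items()}
    )
    result = PipelineResult(config, results, deduped)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: PipelineResult, out_dir: Path) -> None:
    from .io import write_fasta, write_tsv

    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(out_dir / "retained_candidates.fasta", result.retained_sequences())
    for sample, r in result.samples.items():
        rows = []
        retained_seqs = {c.sequence for c in r.retained}
        for name in sorted(r.support):
            idx = int(name.rsplit("_", 1)[1])
            cand = r.candidates[idx]
            rows.append(
                (
                    name,
                    len(cand.sequence),
                    f"{r.est_counts.get(name, 0.0):.3f}",
                    r.support[name],
                    int(cand.sequence in retained_seqs),
                )
            )
        write_tsv(
            out_dir / f"{sample}.support.tsv",
            ["candidate", "length", "est_count", "bootstrap_support", "retained"],
            rows,
        )
        for seed_names, gfa_text in r.subgraph_gfa.items():
            safe = seed_names.replace("/", "_").replace(",", "+")
            (out_dir / f"{sample}.{safe}.gfa").write_text(gfa_text)
    manifest = {
        "tool": "isocore",
        "version": __version__,
        "config_hash": result.config.config_hash(),
        "graph_params": asdict(result.config.graph),
        "filter_params": asdict(result.config.filter),
        "tip_min_kmers": result.config.tip_min_kmers,
        "max_paths": result.config.max_paths,
        "rng_seed": result.config.rng_seed,
        "n_retained": len(result.deduped),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
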
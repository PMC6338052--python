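"""Pipeline orchestration: config validation, stage wiring, artifact output."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration (CLI exit code 2)."""


class InputError(ValueError):
    """Missing or unreadable input file (CLI exit code 3)."""


@dataclass
class SampleSpec:
    sample_id: str
    condition: str
    counts: Optional[str] = None
    alignments: Optional[str] = None


@dataclass
class PipelineConfig:
    output_dir: str
    annotation: Optional[str] = None
    polya_sites: Optional[str] = None
    samples: list[SampleSpec] = field(default_factory=list)
    baseline: str = "T0"
    clip_sites: Optional[str] = None
    alpha: float = 0.05
    fpkm_min: float = 1.0
    roar_boundary: float = 1.0
    fdr_max: float = 0.01
    bc_min: int = 5
    stranded: str = "none"
    boundary: str = "post"
    seed: int = 0


_THRESHOLD_KEYS = {
    "alpha": float,
    "fpkm_min": float,
    "roar_boundary": float,
    "fdr_max": float,
    "bc_min": int,
}
_TOP_KEYS = {
    "output_dir", "annotation", "polya_sites", "samples", "baseline",
    "clip_sites", "thresholds", "stranded", "boundary", "seed",
}


def validate_config(raw: str | Mapping[str, Any]) -> PipelineConfig:
    """Parse and validate a YAML config; fill documented defaults.

    Defaults: alpha 0.05, fpkm_min 1, roar_boundary 1, fdr_max 0.01, bc_min 5.
    Unknown keys and type mismatches are rejected with the offending key named.
    """
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"unparseable config: {exc}") from exc
    else:
        data = dict(raw)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")

    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "output_dir" not in data:
        raise ConfigError("missing required key: output_dir")

    cfg = PipelineConfig(output_dir=str(data["output_dir"]))
    for key in ("annotation", "polya_sites", "clip_sites", "baseline",
                "stranded", "boundary"):
        if key in data:
            if not isinstance(data[key], str):
                raise ConfigError(f"config key {key!r} must be a string")
            setattr(cfg, key, data[key])
    if "seed" in data:
        if not isinstance(data["seed"], int) or isinstance(data["seed"], bool):
            raise ConfigError("config key 'seed' must be an integer")
        cfg.seed = data["seed"]
    thresholds = data.get("thresholds", {})
    if not isinstance(thresholds, dict):
        raise ConfigError("config key 'thresholds' must be a mapping")
    for key, value in thresholds.items():
        if key not in _THRESHOLD_KEYS:
            raise ConfigError(f"unknown threshold key: {key!r}")
        caster = _THRESHOLD_KEYS[key]
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"threshold {key!r} must be numeric")
        setattr(cfg, key, caster(value))
    for key in ("alpha", "fpkm_min", "roar_boundary", "fdr_max"):
        if getattr(cfg, key) <= 0 and key != "fpkm_min":
            raise ConfigError(f"threshold {key!r} must be positive")

    seen_ids = set()
    for i, s in enumerate(data.get("samples", [])):
        if not isinstance(s, dict):
            raise ConfigError(f"sample #{i + 1} must be a mapping")
        extra = set(s) - {"id", "condition", "counts", "alignments"}
        if extra:
            raise ConfigError(f"sample #{i + 1}: unknown keys {sorted(extra)}")
        if "id" not in s or "condition" not in s:
            raise ConfigError(f"sample #{i + 1}: missing id or condition")
        if s["id"] in seen_ids:
            raise ConfigError(f"duplicate sample id {s['id']!r}")
        seen_ids.add(s["id"])
        if ("counts" in s) == ("alignments" in s):
            raise ConfigError(
                f"sample {s['id']!r}: provide exactly one of counts/alignments"
            )
        cfg.samples.append(
            SampleSpec(
                sample_id=str(s["id"]),
                condition=str(s["condition"]),
                counts=s.get("counts"),
                alignments=s.get("alignments"),
            )
        )
    return cfg


def _require(path: Optional[str], what: str) -> Path:
    if path is None:
        raise ConfigError(f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise InputError(f"{what} not found: {p}")
    return p


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Run segmentation -> counting -> statistics -> consensus (-> enrichment).

    Writes all artifacts under ``cfg.output_dir`` and returns a small dict of
    the in-memory results.  Outputs are a pure function of config + seed.
    """
    from . import __version__
    from .annotation import (
        build_all_segmentations,
        read_gtf,
        read_polya_bed,
        write_exclusions_tsv,
        write_segmentation_bed,
    )
    from .classify import venn_to_json, write_calls_tsv, write_consensus_tsv
    from .clip import enrichment_test, filter_robust, gene_overlaps, read_sites_bed
    from .model import TimeCourseAPA
    from .quant import count_reads, read_counts_table, write_counts_table

    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if not cfg.samples:
        raise ConfigError("missing condition map: no samples configured")
    conditions = {s.condition for s in cfg.samples}
    if cfg.baseline not in conditions:
        raise ConfigError(
            f"baseline condition {cfg.baseline!r} not present among samples"
        )
    gtf = _require(cfg.annotation, "annotation GTF")
    bed = _require(cfg.polya_sites, "polyA-site BED")

    transcripts = read_gtf(gtf)
    sites = read_polya_bed(bed)
    segmentations, exclusions = build_all_segmentations(transcripts, sites)
    if not segmentations:
        raise InputError("no gene could be segmented from the given inputs")
    write_segmentation_bed(segmentations, outdir / "segmentation.bed")
    write_exclusions_tsv(exclusions, outdir / "exclusions.tsv")

    counts = []
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)
    for s in cfg.samples:
        if s.counts is not None:
            rc = read_counts_table(_require(s.counts, f"counts table {s.sample_id}"))
            rc.sample_id = s.sample_id
            rc.condition = s.condition
        else:
            rc = count_reads(
                _require(s.alignments, f"alignments {s.sample_id}"),
                segmentations,
                sample_id=s.sample_id,
                condition=s.condition,
                stranded=cfg.stranded,
                boundary=cfg.boundary,
            )
        write_counts_table(rc, counts_dir / f"{s.sample_id}.tsv")
        counts.append(rc)

    tc = TimeCourseAPA(segmentations, counts, baseline=cfg.baseline)
    results = tc.fit(
        alpha=cfg.alpha, fpkm_min=cfg.fpkm_min, roar_boundary=cfg.roar_boundary
    )
    for name in sorted(results.comparisons):
        results.comparisons[name].to_tsv(outdir / f"stats_{name}.tsv")
    calls = {name: res.calls for name, res in results.comparisons.items()}
    write_calls_tsv(calls, outdir / "calls.tsv")
    write_consensus_tsv(results.consensus, outdir / "consensus.tsv")
    (outdir / "venn.json").write_text(venn_to_json(results.consensus) + "\n")

    enrichment = None
    if cfg.clip_sites is not None:
        raw_sites = read_sites_bed(_require(cfg.clip_sites, "CLIP sites"))
        robust = filter_robust(raw_sites, fdr_max=cfg.fdr_max, bc_min=cfg.bc_min)
        spans = {g: (seg.chrom, *seg.gene_span) for g, seg in segmentations.items()}
        flags = gene_overlaps(spans, robust)
        universe = frozenset(results.comparisons[next(iter(results.comparisons))].calls)
        enrichment = {}
        for direction, target in (
            ("lengthened", results.consensus.always_lengthened),
            ("shortened", results.consensus.always_shortened),
        ):
            if target:
                r = enrichment_test(target, universe, flags)
                enrichment[direction] = {
                    "table": r.table,
                    "odds_ratio": r.odds_ratio,
                    "p": r.p_value,
                }
            else:
                enrichment[direction] = None
        import json

        (outdir / "enrichment.json").write_text(
            json.dumps(enrichment, indent=2, sort_keys=True) + "\n"
        )

    log_lines = [
        f"apadiff version: {__version__}",
        f"seed: {cfg.seed}",
        f"baseline: {cfg.baseline}",
        f"thresholds: alpha={cfg.alpha} fpkm_min={cfg.fpkm_min} "
        f"roar_boundary={cfg.roar_boundary} fdr_max={cfg.fdr_max} bc_min={cfg.bc_min}",
        f"samples: {', '.join(s.sample_id for s in cfg.samples)}",
        f"genes segmented: {len(segmentations)}",
        f"genes excluded: {len(exclusions)}",
        results.summary(),
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "segmentations": segmentations,
        "exclusions": exclusions,
        "counts": counts,
        "results": results,
        "enrichment": enrichment,
    }


def write_demo_inputs(outdir: Path, seed: int, n_genes: int = 150) -> PipelineConfig:
    """Generate a complete synthetic input set and a ready-to-run config."""
    from .annotation import build_all_segmentations
    from .quant import write_counts_table
    from .synthetic import (
        TIME_COURSE_CONDITIONS,
        TIME_COURSE_REPLICATES,
        generate_clip_sites,
        generate_genome,
        simulate_counts,
        write_clip_bed,
        write_gtf,
        write_polya_bed,
        write_truth_tsv,
    )

    import numpy as np

    outdir = Path(outdir)
    inputs = outdir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    genome = generate_genome(n_genes, conditions=TIME_COURSE_CONDITIONS, rng=rng)
    write_gtf(genome, inputs / "annotation.gtf")
    write_polya_bed(genome, inputs / "polya_sites.bed")
    write_truth_tsv(genome.truth, inputs / "truth.tsv")
    samples = simulate_counts(
        genome.truth,
        n_replicates=TIME_COURSE_REPLICATES,
        mean_depth=300.0,
        dispersion=0.1,
        rng=rng,
    )
    specs = []
    for rc in samples:
        path = inputs / f"counts_{rc.sample_id}.tsv"
        write_counts_table(rc, path)
        specs.append(
            {"id": rc.sample_id, "condition": rc.condition, "counts": str(path)}
        )
    segmentations, _ = build_all_segmentations(genome.transcripts, genome.sites)
    clip = generate_clip_sites(genome, segmentations, rng=rng)
    write_clip_bed(clip, inputs / "clip_sites.bed")

    cfg = validate_config(
        {
            "output_dir": str(outdir),
            "annotation": str(inputs / "annotation.gtf"),
            "polya_sites": str(inputs / "polya_sites.bed"),
            "clip_sites": str(inputs / "clip_sites.bed"),
            "samples": specs,
            "baseline": "T0",
            "seed": seed,
        }
    )
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "output_dir": str(outdir),
                "annotation": str(inputs / "annotation.gtf"),
                "polya_sites": str(inputs / "polya_sites.bed"),
                "clip_sites": str(inputs / "clip_sites.bed"),
                "samples": specs,
                "baseline": "T0",
                "seed": seed,
            },
            fh,
            sort_keys=True,
        )
    return cfg
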
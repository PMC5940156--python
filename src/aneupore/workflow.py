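"""End-to-end orchestration: simulate -> demultiplex -> count -> call -> report.

One :class:`RunConfig` drives a reproducible run.  In ``simulate`` mode the
pipeline fabricates a multiplexed flow-cell's worth of reads for a sample
sheet of known karyotypes, then analyzes them exactly as a real run would:
demultiplexing, toy alignment, uniqueness filtering, first-N counting and
modified Z-score calling.  In ``analyze`` mode it starts from existing
alignment files (PSL/PAF/SAM) per sample.  Identical config + seed produces
an identical report (reports carry no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import align_count as ac
from . import caller as cl
from . import demux as dx
from . import simulate as sim
from .karyotype import Karyotype

logger = logging.getLogger(__name__)

_FORMAT_READERS = {"psl": ac.read_psl, "paf": ac.read_paf, "sam": ac.read_sam}


@dataclass
class SampleSpec:
    sample_id: str
    barcode_id: str
    karyotype: str | None = None  # expected truth, for concordance reporting
    alignments: str | None = None  # analyze mode: path to alignment file
    format: str = "psl"


@dataclass
class RunConfig:
    mode: str = "simulate"
    seed: int = 0
    out_dir: str | None = None
    samples: list[SampleSpec] = field(default_factory=list)
    # simulation
    n_reads: int = 10_000
    per_base_error: float = 0.10
    barcode_placement: str = "both_ends"
    genome_total_bp: int = 1_200_000
    barcode_fasta: str | None = None
    n_barcodes: int = 12
    # demultiplexing
    min_overlap: int = 20
    max_error_rate: float = 0.20
    min_length: int = 50
    # counting
    min_score_fraction: float = 0.5
    margin: int = 1
    n_ua: int = ac.DEFAULT_N_UA
    # calling
    sd_normal: float = cl.SD_NORMAL
    z_threshold: float = 3.5
    reference: str = "expected"  # "expected", a sample_id, or a counts TSV path

    def demux_config(self) -> dx.DemuxConfig:
        return dx.DemuxConfig(
            min_overlap=self.min_overlap,
            max_error_rate=self.max_error_rate,
            min_length=self.min_length,
        )

    def ua_config(self) -> ac.UAFilterConfig:
        return ac.UAFilterConfig(
            min_score_fraction=self.min_score_fraction, margin=self.margin
        )


_DEFAULTS = {
    "min_overlap": 20,
    "max_error_rate": 0.20,
    "min_length": 50,
    "n_ua": 9000,
    "sd_normal": cl.SD_NORMAL,
    "z_threshold": 3.5,
}


def validate_config(raw: dict) -> tuple[RunConfig | None, list[str]]:
    """Normalize a raw config mapping; returns (config, all collected errors)."""
    errors: list[str] = []
    known = {f.name for f in RunConfig.__dataclass_fields__.values()}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in known}}
    samples = []
    for i, s in enumerate(merged.get("samples", [])):
        if isinstance(s, SampleSpec):
            samples.append(s)
        elif isinstance(s, dict):
            try:
                samples.append(SampleSpec(**s))
            except TypeError as err:
                errors.append(f"sample #{i}: {err}")
        else:
            errors.append(f"sample #{i}: expected a mapping, got {type(s).__name__}")
    merged["samples"] = samples
    try:
        cfg = RunConfig(**merged)
    except TypeError as err:
        errors.append(str(err))
        return None, errors

    if cfg.mode not in ("simulate", "analyze"):
        errors.append(f"mode must be 'simulate' or 'analyze', got {cfg.mode!r}")
    if not cfg.samples:
        errors.append("sample sheet is empty")
    ids = [s.sample_id for s in cfg.samples]
    if len(set(ids)) != len(ids):
        errors.append("duplicate sample ids in sample sheet")
    if cfg.sd_normal <= 0:
        errors.append(f"sd_normal must be positive, got {cfg.sd_normal}")
    if cfg.z_threshold <= 0:
        errors.append(f"z_threshold must be positive, got {cfg.z_threshold}")
    if cfg.n_ua < 1:
        errors.append(f"n_ua must be >= 1, got {cfg.n_ua}")
    if cfg.n_reads < 1:
        errors.append(f"n_reads must be >= 1, got {cfg.n_reads}")
    if not (0 <= cfg.per_base_error < 0.5):
        errors.append(f"per_base_error must be in [0, 0.5), got {cfg.per_base_error}")
    if not (0 < cfg.max_error_rate < 1):
        errors.append(f"max_error_rate must be in (0, 1), got {cfg.max_error_rate}")

    if cfg.barcode_fasta:
        try:
            bc_ids = set(sim.BarcodeSet.from_fasta(cfg.barcode_fasta).ids)
        except OSError as err:
            errors.append(f"barcode_fasta: {err}")
            bc_ids = None
    else:
        bc_ids = {f"BC{i + 1:02d}" for i in range(cfg.n_barcodes)}
    if bc_ids is not None and cfg.mode == "simulate":
        for s in cfg.samples:
            if s.barcode_id not in bc_ids:
                errors.append(
                    f"sample {s.sample_id}: barcode {s.barcode_id} not in barcode set"
                )
    for s in cfg.samples:
        if s.karyotype is not None:
            try:
                Karyotype.from_string(s.karyotype)
            except ValueError as err:
                errors.append(f"sample {s.sample_id}: {err}")
        if cfg.mode == "analyze":
            if not s.alignments:
                errors.append(f"sample {s.sample_id}: analyze mode needs alignments")
            elif s.format not in _FORMAT_READERS:
                errors.append(f"sample {s.sample_id}: unknown format {s.format!r}")
    return (cfg if not errors else None), errors


@dataclass
class RunReport:
    samples: list[dict]
    run_level: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"samples": self.samples, "run": self.run_level},
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def load_config(path) -> RunConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    cfg, errors = validate_config(raw or {})
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _reference_counts(
    cfg: RunConfig,
    genome: sim.ToyGenome | None,
    sample_counts: dict[str, ac.ChromCounts],
) -> ac.ChromCounts:
    if cfg.reference == "expected":
        if genome is None:
            raise ValueError("expected-profile reference requires a genome")
        profile = sim.expected_counts(
            genome, Karyotype.from_string("46,XY"), cfg.n_ua
        )
        return ac.ChromCounts("reference_male_expected", profile, cfg.n_ua, True)
    if cfg.reference in sample_counts:
        return sample_counts[cfg.reference]
    return ac.ChromCounts.from_tsv(cfg.reference)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the configured run; persists intermediates when out_dir is set."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    try:
        if cfg.mode == "simulate":
            return _run_simulate(cfg, out)
        if cfg.mode == "analyze":
            return _run_analyze(cfg, out)
        raise ValueError(f"unknown mode {cfg.mode!r}")
    except Exception:
        logger.exception("pipeline failed (partial outputs retained in %s)", out)
        raise


def _run_simulate(cfg: RunConfig, out: Path | None) -> RunReport:
    root = np.random.SeedSequence(cfg.seed)
    genome_seed, bc_seed, mux_seed, *sample_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in root.spawn(3 + len(cfg.samples))
    ]
    genome = sim.default_toy_genome(seed=genome_seed, total_bp=cfg.genome_total_bp)
    if cfg.barcode_fasta:
        barcodes = sim.BarcodeSet.from_fasta(cfg.barcode_fasta)
    else:
        barcodes = sim.make_barcode_set(cfg.n_barcodes, seed=bc_seed)
    bc_map = dict(barcodes.entries)

    logger.info("simulating %d samples", len(cfg.samples))
    per_sample_reads = []
    truths = []
    for spec, s_seed in zip(cfg.samples, sample_seeds):
        karyo = Karyotype.from_string(spec.karyotype or "46,XY")
        rs_cfg = sim.ReadSimConfig(
            n_reads=cfg.n_reads,
            per_base_error=cfg.per_base_error,
            barcode_placement=cfg.barcode_placement,
            seed=s_seed,
        )
        reads, truth = sim.simulate_sample(
            genome, karyo, (spec.barcode_id, bc_map[spec.barcode_id]),
            rs_cfg, sample_id=spec.sample_id,
        )
        per_sample_reads.append(reads)
        truths.append(truth)
    pooled = sim.multiplex(per_sample_reads, seed=mux_seed)
    if out is not None:
        sim.write_fastq(pooled, out / "run.fastq")
        import pandas as pd

        pd.concat(truths).to_csv(out / "truth.tsv", sep="\t", index=False)
        genome.to_fasta(out / "genome.fasta")
        barcodes.to_fasta(out / "barcodes.fasta")

    logger.info("demultiplexing %d reads", len(pooled))
    bins, summary = dx.demultiplex_stream(
        pooled, barcodes, cfg.demux_config(),
        out_dir=out / "demux" if out is not None else None,
    )

    logger.info("aligning and counting")
    index = ac.GenomeIndex(genome)
    ua_cfg = cfg.ua_config()
    sample_counts: dict[str, ac.ChromCounts] = {}
    sample_rows = []
    for spec in cfg.samples:
        bin_reads = bins[spec.barcode_id]
        assignments = []
        for read in bin_reads:
            chrom = ac.is_unique(ac.toy_align(read, index, ua_cfg.min_score_fraction),
                                 ua_cfg)
            if chrom is not None:
                assignments.append((read.read_id, chrom))
        counts = ac.first_n_ua(
            assignments, n=cfg.n_ua, sample_id=spec.sample_id,
            chrom_order=genome.names,
        )
        sample_counts[spec.sample_id] = counts
        sample_rows.append((spec, len(bin_reads), len(assignments), counts))

    reference = _reference_counts(cfg, genome, sample_counts)
    return _call_and_report(cfg, out, sample_rows, sample_counts, reference,
                            n_total_reads=len(pooled), summary=summary)


def _run_analyze(cfg: RunConfig, out: Path | None) -> RunReport:
    sample_counts: dict[str, ac.ChromCounts] = {}
    sample_rows = []
    for spec in cfg.samples:
        reader = _FORMAT_READERS[spec.format]
        grouped = ac.group_by_read(reader(spec.alignments))
        ua = ac.unique_assignments(grouped, cfg.ua_config())
        assignments = [(rid, ua[rid]) for rid in grouped if rid in ua]
        counts = ac.first_n_ua(assignments, n=cfg.n_ua, sample_id=spec.sample_id)
        sample_counts[spec.sample_id] = counts
        sample_rows.append((spec, len(grouped), len(assignments), counts))
    reference = _reference_counts(cfg, None, sample_counts)
    return _call_and_report(cfg, out, sample_rows, sample_counts, reference,
                            n_total_reads=None, summary=None)


def _call_and_report(cfg, out, sample_rows, sample_counts, reference,
                     n_total_reads, summary) -> RunReport:
    caller_cfg = cl.CallerConfig(
        reference_counts=reference,
        sd_normal=cfg.sd_normal,
        z_threshold=cfg.z_threshold,
    )
    sample_dicts = []
    n_assigned_total = 0
    n_ua_total = 0
    for spec, n_reads, n_ua_reads, counts in sample_rows:
        call = cl.call_sample(counts, caller_cfg)
        concordant = None
        if spec.karyotype is not None:
            concordant = bool(call.rendered == spec.karyotype)
        n_assigned_total += n_reads
        n_ua_total += n_ua_reads
        sample_dicts.append({
            "sample_id": spec.sample_id,
            "barcode_id": spec.barcode_id,
            "reads": n_reads,
            "ua_reads": n_ua_reads,
            "n_ua_used": counts.n_ua_used,
            "truncated_at_n": counts.truncated_at_n,
            "karyotype": call.rendered,
            "expected_karyotype": spec.karyotype,
            "concordant": concordant,
            "events": [[c, e] for c, e in call.autosomal_events],
            "flags": call.flags,
        })
        if out is not None:
            counts.to_tsv(out / f"{spec.sample_id}.counts.tsv")
            call.to_frame().to_csv(
                out / f"{spec.sample_id}.calls.tsv", sep="\t", index=False
            )
            (out / f"{spec.sample_id}.karyotype.json").write_text(
                json.dumps(call.to_dict(), sort_keys=True) + "\n"
            )
    run_level = {
        "n_samples": len(sample_dicts),
        "ua_fraction_of_assigned": (
            n_ua_total / n_assigned_total if n_assigned_total else 0.0
        ),
        "reference": reference.sample_id,
        "seed": cfg.seed,
    }
    if n_total_reads is not None:
        run_level["reads_total"] = n_total_reads
        run_level["assigned_fraction"] = (
            n_assigned_total / n_total_reads if n_total_reads else 0.0
        )
    report = RunReport(samples=sample_dicts, run_level=run_level)
    if out is not None:
        report.to_json(out / "report.json")
    return report
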
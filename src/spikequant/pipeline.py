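"""Configuration and pipeline orchestration.

One YAML config (or a plain dict) drives the whole workflow: design the IS
panel, simulate a spiked sample (count-level, optionally read-level),
classify reads, quantify, and evaluate. Every artifact gets a JSON
provenance sidecar recording the stage, its parameters, its inputs, the
derived seed and the package version; all randomness flows from the single
global seed through per-stage children (SeedSequence([seed, stage_index])),
so any stage rerun in isolation reproduces its output byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .counting import ReadCountTable, count_reads, ingest_counts
from .errors import SpikequantError, ValidationError
from .evaluate import DEFAULT_DEPTHS, DEFAULT_N_REPS, compare_to_reference, depth_sweep, quants_to_frame
from .panel import DesignSpec, ISPanel, design_panel, panel_kmer_index
from .quant import load_genome_lengths, quantify_sample
from .simulate import (
    SampleComposition,
    SequencingRun,
    make_fixture_genome,
    preset,
    simulate_counts,
    simulate_reads,
)

logger = logging.getLogger(__name__)

STAGES = ("design", "simulate", "count", "quantify", "evaluate")
_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: first word of SeedSequence([seed, stage_index]),
    folded below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected early."""

    seed: int = 0
    outdir: Path = Path("spikequant_out")
    log_level: str = "INFO"
    design: dict[str, Any] = field(default_factory=dict)
    simulate: dict[str, Any] = field(default_factory=dict)
    count: dict[str, Any] = field(default_factory=dict)
    quantify: dict[str, Any] = field(default_factory=dict)
    evaluate: dict[str, Any] = field(default_factory=dict)
    paths: dict[str, Any] = field(default_factory=dict)

    _SECTIONS = ("design", "simulate", "count", "quantify", "evaluate", "paths")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {"seed", "outdir", "log_level", *cls._SECTIONS}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            seed=int(data.get("seed", 0)),
            outdir=Path(data.get("outdir", "spikequant_out")),
            log_level=str(data.get("log_level", "INFO")),
            **{k: dict(data.get(k) or {}) for k in cls._SECTIONS},
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ValidationError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ValidationError("config file must hold a mapping")
        return cls.from_dict(data)

    # -- validation ---------------------------------------------------------

    def design_spec(self) -> DesignSpec:
        allowed = {
            "insert_length", "amplicon_flank", "gc_min", "gc_max", "max_run",
            "n_gradients", "molecules_per_gradient", "gradient_concentrations",
            "screen_k", "rng_seed",
        }
        unknown = set(self.design) - allowed
        if unknown:
            raise ValidationError(f"unknown design keys: {sorted(unknown)}")
        kwargs = dict(self.design)
        if "gradient_concentrations" in kwargs:
            kwargs["gradient_concentrations"] = tuple(kwargs["gradient_concentrations"])
        return DesignSpec(**kwargs)

    def validate(self) -> None:
        self.design_spec()
        sim = self.simulate
        name = sim.get("preset", "mock10")
        from .simulate import PRESET_NAMES

        if name not in PRESET_NAMES:
            raise ValidationError(f"unknown preset: {name}")
        total = int(sim.get("total_reads", 20_000_000))
        if total <= 0:
            raise ValidationError("total_reads must be positive")
        if not (0 <= float(sim.get("error_rate", 0.0)) < 0.1):
            raise ValidationError("error_rate must lie in [0, 0.1)")
        from .simulate import COUNT_MODES

        if sim.get("mode", "multinomial") not in COUNT_MODES:
            raise ValidationError(f"unknown count mode: {sim.get('mode')}")
        if int(self.count.get("k", 25)) <= 0:
            raise ValidationError("count.k must be positive")
        q = self.quantify
        if q.get("convention", "per_molecule") not in ("per_molecule", "pool"):
            raise ValidationError("quantify.convention must be per_molecule or pool")
        if q.get("fit_space", "log10") not in ("log10", "linear"):
            raise ValidationError("quantify.fit_space must be log10 or linear")
        if q.get("mode", "curve") not in ("curve", "ratio"):
            raise ValidationError("quantify.mode must be curve or ratio")
        if float(q.get("spike_volume_ul", 2.0)) <= 0:
            raise ValidationError("quantify.spike_volume_ul must be positive")
        depths = self.evaluate.get("depths", list(DEFAULT_DEPTHS))
        if any(int(d) <= 0 for d in depths):
            raise ValidationError("evaluate.depths must be positive")
        if int(self.evaluate.get("n_reps", DEFAULT_N_REPS)) < 2:
            raise ValidationError("evaluate.n_reps must be >= 2")
        for key, value in self.paths.items():
            if key.endswith("_out"):
                continue
            if not Path(value).exists():
                raise ValidationError(f"configured path does not exist: {key}={value}")


def _write_provenance(artifact: Path, stage: str, parameters: Mapping[str, Any],
                      inputs: Sequence[str], seed: int) -> None:
    sidecar = artifact.with_name(artifact.name + ".provenance.json")
    sidecar.write_text(json.dumps({
        "artifact": artifact.name,
        "stage": stage,
        "parameters": dict(parameters),
        "inputs": list(inputs),
        "seed": seed,
        "spikequant_version": __version__,
    }, indent=2, default=str) + "\n")


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict[str, Path]:
    """Run the requested stages in dependency order and return artifact paths.

    Config and stage inputs are validated before any file is written, so a
    validation failure never leaves partial output.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    config.validate()
    outdir = config.outdir

    # ---- pre-flight input checks (no writes before this passes) ----------
    artifacts: dict[str, Path] = {}
    manifest = Path(config.paths.get("panel_manifest", outdir / "panel_manifest.json"))
    inserts = Path(config.paths.get("panel_inserts", outdir / "is_inserts.fasta"))
    counts_path = Path(config.paths.get("counts", outdir / "counts.tsv"))
    fastq_path = Path(config.paths.get("fastq", outdir / "reads.fastq"))
    truth_path = Path(config.paths.get("truth", outdir / "truth.json"))
    read_level = bool(config.simulate.get("read_level", False))
    if "design" not in stages:
        for need in ("simulate", "count", "quantify", "evaluate"):
            if need in stages:
                _require(manifest.exists() and inserts.exists(),
                         f"stage '{need}' needs a panel manifest and insert FASTA "
                         f"(run the design stage or set paths.panel_manifest/panel_inserts)")
                break
    if "count" in stages and "simulate" not in stages:
        _require(fastq_path.exists(), "count stage needs a FASTQ (run simulate with "
                                      "read_level: true or set paths.fastq)")
    if "quantify" in stages and "simulate" not in stages and "count" not in stages:
        _require(counts_path.exists(), "quantify stage needs a count table")
    if "evaluate" in stages and "simulate" not in stages:
        _require(counts_path.exists(), "evaluate stage needs a count table")

    outdir.mkdir(parents=True, exist_ok=True)

    panel: ISPanel | None = None
    comp: SampleComposition | None = None
    counts: ReadCountTable | None = None
    fixture_seqs: dict[str, str] = {}

    # ---- design ----------------------------------------------------------
    if "design" in stages:
        spec = config.design_spec()
        seed = stage_seed(config.seed, "design")
        references = [Path(p) for p in config.paths.get("screen_references", [])]
        panel = design_panel(spec, references=references, seed=seed)
        paths = panel.save(outdir)
        artifacts.update(paths)
        for p in paths.values():
            _write_provenance(p, "design", config.design, [str(r) for r in references], seed)
        manifest, inserts = paths["manifest"], paths["inserts"]
    if panel is None and any(s in stages for s in ("simulate", "count", "quantify", "evaluate")):
        panel = ISPanel.load(manifest, inserts)

    # ---- simulate --------------------------------------------------------
    if "simulate" in stages:
        sim = config.simulate
        seed = stage_seed(config.seed, "simulate")
        comp = preset(sim.get("preset", "mock10"), panel=panel,
                      is_spike_volume_ul=float(sim.get("is_spike_volume_ul", 2.0)))
        run = SequencingRun(
            total_reads=int(sim.get("total_reads", 20_000_000)),
            read_length=int(sim.get("read_length", 75)),
            error_rate=float(sim.get("error_rate", 0.0)),
            seed=seed,
        )
        mode = sim.get("mode", "multinomial")
        if read_level:
            fixture_len = int(sim.get("fixture_genome_length", 20_000))
            exclusion = panel_kmer_index(panel)
            host_needed = comp.host_mass_ng > 0
            gen_seed = np.random.SeedSequence([seed, 11])
            child_seeds = gen_seed.generate_state(len(comp.taxa) + 1)
            for i, t in enumerate(comp.taxa):
                fixture_seqs[t.taxon_id] = make_fixture_genome(
                    t.taxon_id, fixture_len, int(child_seeds[i] % 2**31), exclusion)
            if host_needed:
                fixture_seqs["host"] = make_fixture_genome(
                    "host", fixture_len, int(child_seeds[-1] % 2**31), exclusion)
            counts = simulate_reads(comp, run, fixture_seqs, fastq_path, mode=mode)
            refs_fasta = outdir / "fixture_refs.fasta"
            with open(refs_fasta, "w") as handle:
                for name, seq in fixture_seqs.items():
                    handle.write(f">{name}\n{seq}\n")
            artifacts["fixture_refs"] = refs_fasta
            artifacts["fastq"] = fastq_path
            _write_provenance(fastq_path, "simulate", sim, [str(manifest)], seed)
        else:
            counts = simulate_counts(comp, run, mode=mode)
        counts.to_tsv(counts_path)
        comp.write_truth(truth_path)
        artifacts["counts"] = counts_path
        artifacts["truth"] = truth_path
        _write_provenance(counts_path, "simulate", sim, [str(manifest)], seed)
        _write_provenance(truth_path, "simulate", sim, [str(manifest)], seed)

    # ---- count (read-level classification) -------------------------------
    if "count" in stages:
        k = int(config.count.get("k", 25))
        refs_fasta = Path(config.paths.get("fixture_refs", outdir / "fixture_refs.fasta"))
        if not refs_fasta.exists():
            raise ValidationError("count stage needs fixture reference sequences "
                                  "(paths.fixture_refs)")
        from Bio import SeqIO

        from .counting import build_index

        sources = [(m.id, "is", m.insert_seq) for m in panel.molecules]
        for record in SeqIO.parse(str(refs_fasta), "fasta"):
            ctype = "host" if record.id == "host" else "taxon"
            sources.append((record.id, ctype, str(record.seq)))
        index = build_index(sources, k=k)
        counted = count_reads(fastq_path, index)
        counted_path = outdir / "counts_from_reads.tsv"
        counted.to_tsv(counted_path)
        artifacts["counts_from_reads"] = counted_path
        _write_provenance(counted_path, "count", config.count,
                          [str(fastq_path), str(refs_fasta)], stage_seed(config.seed, "count"))
        counts = counted
        counts_path = counted_path

    # ---- quantify --------------------------------------------------------
    quant_result = None
    if "quantify" in stages:
        q = config.quantify
        if counts is None:
            counts = ingest_counts(counts_path, panel=panel)
        lengths_path = config.paths.get("genome_lengths")
        if lengths_path:
            lengths = load_genome_lengths(lengths_path)
        elif truth_path.exists():
            truth = json.loads(truth_path.read_text())
            lengths = {t: v["genome_length_bp"] for t, v in truth.items()}
        else:
            raise ValidationError("quantify stage needs genome lengths "
                                  "(paths.genome_lengths or a simulate-stage truth file)")
        quant_result = quantify_sample(
            counts, panel, lengths,
            spike_volume_ul=float(q.get("spike_volume_ul", 2.0)),
            convention=q.get("convention", "per_molecule"),
            fit_space=q.get("fit_space", "log10"),
            mode=q.get("mode", "curve"),
            min_reads=float(q.get("min_reads", 3)),
        )
        report = outdir / "quant_report.tsv"
        fit_json = outdir / "fit_summary.json"
        quant_result.write(report, fit_json)
        artifacts["quant_report"] = report
        artifacts["fit_summary"] = fit_json
        seed = stage_seed(config.seed, "quantify")
        _write_provenance(report, "quantify", q, [str(counts_path), str(manifest)], seed)
        _write_provenance(fit_json, "quantify", q, [str(counts_path), str(manifest)], seed)

    # ---- evaluate --------------------------------------------------------
    if "evaluate" in stages:
        ev = config.evaluate
        seed = stage_seed(config.seed, "evaluate")
        if counts is None:
            counts = ingest_counts(counts_path, panel=panel)
        depths = [int(d) for d in ev.get("depths", list(DEFAULT_DEPTHS))]
        depths = [d for d in depths if d <= counts.total_reads]
        if not depths:
            raise ValidationError("no evaluate.depths fit inside the table's total reads")
        report = depth_sweep(counts, panel, depths=depths,
                             n_reps=int(ev.get("n_reps", DEFAULT_N_REPS)), seed=seed)
        ris_tsv = outdir / "subsample_ris.tsv"
        cv_tsv = outdir / "subsample_cv.tsv"
        report.write(ris_tsv, cv_tsv)
        artifacts["subsample_ris"] = ris_tsv
        artifacts["subsample_cv"] = cv_tsv
        _write_provenance(cv_tsv, "evaluate", ev, [str(counts_path)], seed)
        if quant_result is not None and truth_path.exists():
            truth = json.loads(truth_path.read_text())
            ref = {t: v["true_copies"] for t, v in truth.items()}
            try:
                comparison = compare_to_reference(quants_to_frame([quant_result.quants]), ref)
                cmp_tsv = outdir / "comparison.tsv"
                comparison.write(cmp_tsv)
                summary = outdir / "comparison_summary.json"
                summary.write_text(json.dumps({
                    "pearson_r_log10": comparison.pearson_r,
                    "n_pairs": comparison.n_pairs,
                    "excluded": comparison.excluded,
                }, indent=2) + "\n")
                artifacts["comparison"] = cmp_tsv
                artifacts["comparison_summary"] = summary
                _write_provenance(cmp_tsv, "evaluate", ev, [str(truth_path)], seed)
            except ValidationError as exc:
                logger.warning("reference comparison skipped: %s", exc)
    return artifacts
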
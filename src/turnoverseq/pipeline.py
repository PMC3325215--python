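"""End-to-end orchestration: simulate -> coverage -> index -> groups -> report.

A run is fully described by a :class:`RunConfig` (YAML-serialisable); the
output directory receives the paired index table, group summaries, the
resampling reports, the metaprofile, the alignments and annotation, and a
manifest JSON listing every output with its SHA-256 checksum, the package
version, the seed and a hash of the configuration.  Re-running the same
configuration reproduces every file byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import bin_metaprofile, build_profiles, write_metaprofile
from .groups import (
    resample_null,
    resampling_frame,
    resampling_report,
    summarize_group,
    target_set_stability,
)
from .index import index_records, pair_and_filter, write_index_table
from .io import (
    read_alignments,
    read_transcript_table,
    write_alignments,
    write_transcript_table,
)
from .model import ConfigurationError, DecayParams, SimulationConfig
from .simulate import simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and settings of one analysis run.

    Either ``simulation`` is set (a full two-condition simulation feeds the
    pipeline) or ``alignments`` maps sample names to SAM/BED paths with
    ``transcript_table`` giving the annotation.
    """

    simulation: Optional[SimulationConfig] = None
    alignments: Optional[dict[str, str]] = None
    alignment_format: str = "sam"
    transcript_table: Optional[str] = None
    window_frac: float = 0.2
    min_cov: float = 0.5
    outlier_lo: float = 0.1
    outlier_hi: float = 10.0
    null_set_size: int = 68
    null_n_sets: int = 1000
    stability_subset_size: int = 10
    stability_n_sets: int = 59
    metaprofile_bins: int = 100
    metaprofile_top_fraction: float = 0.1
    seed: int = 0
    write_alignment_files: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.window_frac <= 0.5:
            raise ConfigurationError("window_frac must lie in (0, 0.5]")
        if not 0.0 <= self.min_cov <= 1.0:
            raise ConfigurationError("min_cov must lie in [0, 1]")
        if not 0.0 < self.outlier_lo < self.outlier_hi:
            raise ConfigurationError("need 0 < outlier_lo < outlier_hi")
        if not 0.0 < self.metaprofile_top_fraction <= 1.0:
            raise ConfigurationError("metaprofile_top_fraction must lie in (0, 1]")
        if (self.simulation is None) == (self.alignments is None):
            if self.simulation is None:
                self.simulation = SimulationConfig(seed=self.seed)
            else:
                raise ConfigurationError("give either simulation or alignments, not both")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["decay"] = {
                g: {s: dataclasses.asdict(p) for s, p in per.items()}
                for g, per in self.simulation.decay.items()
            }
            d["simulation"] = sim
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = dict(sim)
            decay = sim.pop("decay", None)
            if decay is not None:
                sim["decay"] = {
                    g: {s: DecayParams(**p) for s, p in per.items()}
                    for g, per in decay.items()
                }
            if "positional_bias" in sim and sim["positional_bias"] is not None:
                sim["positional_bias"] = tuple(sim["positional_bias"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunReport:
    """Summary of one pipeline run with paths to every artefact."""

    outdir: Path
    manifest: dict
    index_table: pd.DataFrame
    group_summaries: dict
    resampling: dict
    stability: dict


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Execute the full analysis and write all artefacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if config.simulation is not None:
            transcripts, reads_by_sample, _ = simulate_experiment(config.simulation)
            if config.write_alignment_files:
                for sample, reads in reads_by_sample.items():
                    write_alignments(
                        reads,
                        transcripts,
                        outdir / f"{sample}.{config.alignment_format}",
                        format=config.alignment_format,
                        metadata={"seed": config.simulation.seed, "sample": sample},
                    )
            write_transcript_table(transcripts, outdir / "transcripts.tsv")
        else:
            transcripts = read_transcript_table(config.transcript_table)
            reads_by_sample = {
                sample: read_alignments(path, config.alignment_format, transcripts)
                for sample, path in config.alignments.items()
            }
        reads = pd.concat(reads_by_sample.values(), ignore_index=True)

        stage = "coverage"
        profiles = build_profiles(reads, transcripts)
        metaprofile = bin_metaprofile(
            profiles,
            transcripts,
            top_fraction=config.metaprofile_top_fraction,
            n_bins=config.metaprofile_bins,
        )
        write_metaprofile(metaprofile, outdir / "metaprofile.tsv")

        stage = "index"
        records = {
            s: index_records(profiles[s], config.window_frac) for s in profiles
        }
        table = pair_and_filter(
            records["wt"],
            records["mut"],
            transcripts,
            min_cov=config.min_cov,
            lo=config.outlier_lo,
            hi=config.outlier_hi,
        )
        write_index_table(table, outdir / "index_table.tsv")

        stage = "groups"
        summaries = {}
        for group in ("control", "exosome_target", "chloroplast"):
            if (table[(table["group"] == group) & table["pass"]]).empty:
                continue
            s = summarize_group(table, group)
            summaries[group] = {
                "n": s.n,
                "wt": s.stats_wt,
                "mut": s.stats_mut,
                "ratio_mean": s.ratio_mean,
                "ratio_median": s.ratio_median,
            }
        with open(outdir / "group_summary.json", "w") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
            fh.write("\n")

        null = resample_null(
            table,
            set_size=config.null_set_size,
            n_sets=config.null_n_sets,
            seed=config.seed,
        )
        resampling_frame(null).to_csv(
            outdir / "resampling_null.tsv", sep="\t", index=False, float_format="%.6g"
        )
        stability = target_set_stability(
            table,
            subset_size=config.stability_subset_size,
            n_sets=config.stability_n_sets,
            seed=config.seed,
        )
        report = {
            "null": resampling_report(null),
            "stability": resampling_report(stability),
        }
        with open(outdir / "resampling_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:  # annotate failures with the stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "row_counts": {
            "transcripts": len(transcripts),
            "reads": int(len(reads)),
            "index_rows": int(len(table)),
            "passing": int(table["pass"].sum()),
        },
        "outputs": {},
    }
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return RunReport(
        outdir=outdir,
        manifest=manifest,
        index_table=table,
        group_summaries=summaries,
        resampling=report["null"],
        stability=report["stability"],
    )


# ---------------------------------------------------------------------------
# registered test fixtures

FIXTURES = ("uniform", "truncated", "no-effect", "paper-miniature")


def make_fixture(name: str, outdir: str | Path, seed: int = 0):
    """Emit one of the registered small deterministic fixtures.

    ``uniform``    — read length 1, one read per position: every index is 1.
    ``truncated``  — all molecules 3'-truncated below the 3' window: zero 3' counts.
    ``no-effect``  — identical decay in both conditions.
    ``paper-miniature`` — the study design scaled to 560/68/34 transcripts.
    Returns ``(transcripts, reads_by_sample)`` and writes SAM + TSV files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "uniform":
        from .model import TranscriptModel

        transcripts = [
            TranscriptModel(f"U{i}", L, "nuclear", "control", 1.0)
            for i, L in enumerate((100, 250, 400))
        ]
        rows = []
        for t in transcripts:
            for sample in ("wt", "mut"):
                for s in range(t.length):
                    rows.append((t.id, s, 1, sample))
        reads = pd.DataFrame(
            rows, columns=["transcript_id", "start", "length", "sample"]
        ).astype({"transcript_id": "string", "sample": "string"})
        by_sample = {s: reads[reads["sample"] == s] for s in ("wt", "mut")}
    elif name == "truncated":
        # every molecule 3'-truncated below the 3' window: n3 must be zero
        from .model import TranscriptModel
        from .simulate import simulate_reads

        cfg = SimulationConfig(
            n_control=20, n_targets=0, n_chloroplast=0,
            library_size=20_000, seed=seed, min_length=500,
        )
        transcripts = [
            TranscriptModel(f"X{i:02d}", 500, "nuclear", "control", 1.0)
            for i in range(20)
        ]
        by_sample = {}
        for k, sample in enumerate(("wt", "mut")):
            rng = np.random.default_rng(np.random.SeedSequence([seed, 7 + k]))
            molecules = {t.id: np.full(50, 380, dtype=np.int64) for t in transcripts}
            by_sample[sample] = simulate_reads(molecules, transcripts, cfg, sample, rng)
    elif name == "no-effect":
        d = DecayParams(f_intact=0.4)
        cfg = SimulationConfig(
            n_control=200, n_targets=20, n_chloroplast=10,
            library_size=60_000, seed=seed,
            chloroplast_expression_multiplier=15.0,
            decay={g: {"wt": d, "mut": d} for g in ("control", "exosome_target", "chloroplast")},
        )
        transcripts, by_sample, _ = simulate_experiment(cfg)
    elif name == "paper-miniature":
        cfg = SimulationConfig(
            n_control=560, n_targets=68, n_chloroplast=34,
            library_size=120_000, seed=seed,
            chloroplast_expression_multiplier=12.0,
        )
        transcripts, by_sample, _ = simulate_experiment(cfg)
    else:
        raise ValueError(f"unknown fixture {name!r}; known: {FIXTURES}")

    write_transcript_table(transcripts, outdir / f"{name}.transcripts.tsv")
    for sample, reads in by_sample.items():
        write_alignments(
            reads, transcripts, outdir / f"{name}.{sample}.sam", format="sam",
            metadata={"fixture": name, "seed": seed},
        )
    return transcripts, by_sample
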
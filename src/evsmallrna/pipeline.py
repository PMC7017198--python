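"""End-to-end orchestration: simulate → build-ref → curate → map → profile →
de → qpcr, with a checksum manifest for reproducibility auditing.

Every stage writes TSV artifacts whose commented headers carry the tool
version, seed and config hash; two runs with the same configuration produce
checksum-identical output trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._io import config_hash, read_tsv, sha256_file, write_tsv
from .curation import CurationParams, curate
from .enrichment import run_de
from .mapper import MappingParams, count_samples, write_counts
from .profile import class_distribution, detection_overlap, replicate_correlation
from .qpcr import paired_relative_expression, plasma_group_comparison
from .reference import compile_unique, load_source_fasta, write_reference
from .synthetic import SimConfig, simulate_ct_table, simulate_counts, \
    simulate_reference, synthesize_reads

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build-ref", "curate", "map", "profile", "de", "qpcr")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    curation: CurationParams = field(default_factory=CurationParams)
    mapping: MappingParams = field(default_factory=MappingParams)
    de_p_cut: float = 0.05
    de_fold_cut_log2: float = 2.0
    de_use_padj: bool = False
    detection_threshold: float = 100.0
    #: planted log2 shifts of the validated miRNA panel, cell-line mode
    qpcr_cellline_shifts: dict = field(default_factory=lambda: {
        "miR-10a-5p": 1.791, "miR-99b-5p": 1.536, "miR-125a-5p": 0.941,
        "miR-29b-3p": -2.0})
    #: planted log2 shifts PCa vs BPH, plasma mode
    qpcr_plasma_shifts: dict = field(default_factory=lambda: {
        "miR-10a-5p": 1.5, "miR-29b-3p": 1.0, "miR-99b-5p": 0.0,
        "miR-125a-5p": 0.0, "miR-5701": 0.0})
    qpcr_plasma_n: tuple[int, int] = (18, 7)

    def __post_init__(self) -> None:
        if not self.curation.adapter:
            self.curation.adapter = self.sim.adapter

    def meta(self) -> dict:
        return {"tool": f"evsmallrna {__version__}", "seed": self.sim.seed,
                "config_hash": config_hash(self.sim.to_dict())}


def demo_config(seed: int = 0) -> PipelineConfig:
    """Bundled demo: the study conditions at desk scale (fast, deterministic)."""
    sim = SimConfig(seed=seed, library_size=30_000)
    return PipelineConfig(sim=sim)


def _require(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise StageError(f"stage {stage!r}: missing input {path} "
                         f"(produced by stage {producer!r})")
    return path


def run_stage(stage: str, config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run one pipeline stage; returns the artifacts it wrote."""
    outdir = Path(outdir)
    meta = config.meta()
    sim = config.sim
    conditions = sim.conditions
    samples = [f"{c}_{r}" for c in conditions for r in range(1, sim.n_replicates + 1)]
    condition_of = {s: s.rsplit("_", 1)[0] for s in samples}
    artifacts: dict[str, Path] = {}

    try:
        if stage == "simulate":
            sources, features = simulate_reference(sim, outdir / "sources")
            truth, counts, _ = simulate_counts(sim, features)
            fastqs = synthesize_reads(sim, counts, features, outdir / "raw")
            artifacts["ground_truth"] = write_tsv(truth, outdir / "truth" / "ground_truth.tsv",
                                                  meta=meta)
            artifacts["latent_counts"] = write_tsv(
                counts.reset_index(), outdir / "truth" / "latent_counts.tsv", meta=meta)
            manifest = pd.DataFrame(
                [{"path": str(Path(p).relative_to(outdir)), "rna_class": c,
                  "source": s, "priority": pr}
                 for p, c, s, pr in sources])
            artifacts["source_manifest"] = write_tsv(
                manifest, outdir / "sources" / "manifest.tsv", meta=meta)
            for sample, p in fastqs.items():
                artifacts[f"raw_fastq:{sample}"] = Path(p)

        elif stage == "build-ref":
            manifest_path = _require(outdir / "sources" / "manifest.tsv",
                                     stage, "simulate")
            manifest = read_tsv(manifest_path)
            records, rejected = [], []
            for row in manifest.itertuples():
                recs, rej = load_source_fasta(outdir / row.path, row.rna_class,
                                              row.source, int(row.priority))
                records.extend(recs)
                rejected.extend(rej)
            db, collisions = compile_unique(records)
            ref_dir = outdir / "reference"
            write_reference(db, ref_dir / "reference.fasta", ref_dir / "classmap.tsv",
                            meta={**meta, "n_sources": len(manifest),
                                  "n_rejected_records": len(rejected)})
            artifacts["reference_fasta"] = ref_dir / "reference.fasta"
            artifacts["classmap"] = ref_dir / "classmap.tsv"
            artifacts["collisions"] = write_tsv(collisions, ref_dir / "collisions.tsv",
                                                meta=meta)

        elif stage == "curate":
            reports = []
            for sample in samples:
                raw = _require(outdir / "raw" / f"{sample}.fastq", stage, "simulate")
                out_fq = outdir / "curated" / f"{sample}.fastq"
                rep = curate(raw, out_fq, config.curation)
                if not rep.conserves():
                    raise StageError(f"stage 'curate': count conservation violated "
                                     f"for sample {sample}")
                row = rep.to_frame()
                row.insert(0, "sample", sample)
                reports.append(row)
                artifacts[f"curated_fastq:{sample}"] = out_fq
            artifacts["curation_report"] = write_tsv(
                pd.concat(reports, ignore_index=True),
                outdir / "curated" / "curation_report.tsv", meta=meta)

        elif stage == "map":
            from .reference import load_reference
            fasta = _require(outdir / "reference" / "reference.fasta", stage, "build-ref")
            classmap = _require(outdir / "reference" / "classmap.tsv", stage, "build-ref")
            db = load_reference(fasta, classmap)
            fastqs = {s: _require(outdir / "curated" / f"{s}.fastq", stage, "curate")
                      for s in samples}
            counts, report = count_samples(fastqs, db, config.mapping)
            write_counts(counts, outdir / "counts" / "counts.tsv", meta=meta)
            artifacts["counts"] = outdir / "counts" / "counts.tsv"
            artifacts["mapping_report"] = write_tsv(
                report, outdir / "counts" / "mapping_report.tsv", meta=meta)

        elif stage == "profile":
            counts = _load_counts(outdir, stage)
            classmap = read_tsv(outdir / "reference" / "classmap.tsv")
            class_of = dict(zip(classmap.canonical_id, classmap.rna_class))
            prof = class_distribution(counts, class_of, condition_of)
            artifacts["class_profile"] = write_tsv(
                prof.table.reset_index(), outdir / "profile" / "class_profile.tsv",
                meta=meta)
            corr = replicate_correlation(counts)
            artifacts["correlations"] = write_tsv(
                corr.reset_index(), outdir / "profile" / "correlations.tsv", meta=meta)
            overlap = detection_overlap(counts, condition_of,
                                        threshold=config.detection_threshold)
            artifacts["detection_overlap"] = write_tsv(
                overlap.reset_index(), outdir / "profile" / "detection_overlap.tsv",
                meta={**meta, "threshold": config.detection_threshold})

        elif stage == "de":
            counts = _load_counts(outdir, stage)
            test, ref = conditions[1], conditions[0]
            res = run_de(counts, condition_of, test_condition=test, ref_condition=ref,
                         p_cut=config.de_p_cut, fold_cut_log2=config.de_fold_cut_log2,
                         use_padj=config.de_use_padj)
            artifacts["de_table"] = write_tsv(
                res.drop(columns=["converged"]),
                outdir / "de" / "differential_enrichment.tsv",
                meta={**meta, "test_condition": test, "ref_condition": ref})
            summary = (res.groupby("call").size().rename("n").reset_index())
            artifacts["de_summary"] = write_tsv(summary, outdir / "de" / "de_summary.tsv",
                                                meta=meta)

        elif stage == "qpcr":
            cell_table = simulate_ct_table(
                groups=("EV", "cell"), n_per_group=(3, 3), n_technical=3,
                target_shifts_log2=config.qpcr_cellline_shifts, seed=sim.seed)
            plasma_table = simulate_ct_table(
                groups=("PCa", "BPH"), n_per_group=config.qpcr_plasma_n,
                n_technical=2, target_shifts_log2=config.qpcr_plasma_shifts,
                dropout={("miR-5701", "BPH"): 0.3}, seed=sim.seed + 1)
            artifacts["ct_cellline"] = write_tsv(cell_table,
                                                 outdir / "qpcr" / "ct_cellline.tsv",
                                                 meta=meta)
            artifacts["ct_plasma"] = write_tsv(plasma_table,
                                               outdir / "qpcr" / "ct_plasma.tsv",
                                               meta=meta)
            cell_res = paired_relative_expression(cell_table)
            artifacts["qpcr_cellline"] = write_tsv(
                cell_res.group_summary, outdir / "qpcr" / "relative_expression.tsv",
                meta=meta)
            plasma_res = plasma_group_comparison(plasma_table, groups=("PCa", "BPH"))
            artifacts["qpcr_plasma"] = write_tsv(
                plasma_res.group_summary, outdir / "qpcr" / "group_tests.tsv",
                meta={**meta, "excluded_samples": ";".join(plasma_res.excluded_samples)
                      or "(none)"})

        else:
            raise StageError(f"unknown stage {stage!r}; expected one of {STAGES}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    for name, path in artifacts.items():
        logger.info("stage %s wrote %s (%s)", stage, path, name)
    return artifacts


def _load_counts(outdir: Path, stage: str) -> pd.DataFrame:
    path = _require(outdir / "counts" / "counts.tsv", stage, "map")
    counts = read_tsv(path).set_index("feature_id")
    return counts


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage in order and write a checksum manifest.

    Returns the manifest path. Any stage error aborts with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_artifacts: dict[str, Path] = {}
    for stage in STAGES:
        all_artifacts.update(run_stage(stage, config, outdir))
    rows = [{"artifact": name, "path": str(Path(p).relative_to(outdir)),
             "sha256": sha256_file(p)}
            for name, p in sorted(all_artifacts.items())]
    manifest_path = write_tsv(pd.DataFrame(rows), outdir / "manifest.tsv",
                              meta=config.meta())
    return manifest_path
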
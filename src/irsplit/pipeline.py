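"""End-to-end orchestration: inputs -> filter -> IR -> classification -> association.

A single config dict drives all stages; every analysis threshold (the 0.60
expression-detection fraction, alpha = 0.05, FDR = 5%, top-N = 200, top
fraction = 25%, pseudocount eps = 0.01) is a named field defaulting to the
study's value. Each stage is timed and its outputs digested into a
:class:`RunManifest`; any stage failure aborts with a stage-named error and
a partial manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import filter_intronless, parse_annotation
from .association import (
    heatmap_sample_order,
    quadrant_counts,
    select_top_n,
    volcano,
    zscore_rows,
)
from .classify import classify_sets, contingency, filter_expressed, run_screens
from .enrichment import GeneSetCollection, ora_test, select_top_fraction
from .quantify import (
    CountingPolicy,
    CountMatrix,
    TPMMatrix,
    compute_ir,
    compute_tpm,
    count_reads,
    write_matrix,
)
from .simulate import CohortConfig, SimulatedCohort, generate_cohort, read_fixture

DEFAULT_THRESHOLDS = {
    "expressed_fraction": 0.60,
    "alpha": 0.05,
    "fdr": 0.05,
    "epsilon": 0.01,
    "top_n": 200,
    "top_fraction": 0.25,
}


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for exit-status reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    version: str
    seed: int | None
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _as_tpm(mat: TPMMatrix | CountMatrix) -> pd.DataFrame:
    if isinstance(mat, CountMatrix):
        return compute_tpm(mat).values
    return mat.values


def load_inputs(config: dict) -> SimulatedCohort:
    """Resolve the cohort from the config: a simulated one or a fixture dir."""
    if "simulate" in config:
        params = dict(config["simulate"] or {})
        if "seed" not in params and "seed" in config:
            params["seed"] = config["seed"]
        for key in ("subset_props_set1", "subset_props_set2"):
            if key in params:
                params[key] = tuple(params[key])
        return generate_cohort(CohortConfig(**params))
    if "fixture_dir" in config:
        return read_fixture(config["fixture_dir"])
    raise PipelineStageError("inputs", "config needs 'simulate' or 'fixture_dir'")


def quantify_bams(
    gtf: str | Path,
    bam_paths: dict[str, str | Path],
    outdir: str | Path,
    policy: CountingPolicy | None = None,
) -> dict[str, Path]:
    """Annotation -> counting -> TPM for a set of BAMs; writes TSV matrices."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = parse_annotation(gtf)
    fs = filter_intronless(models, build_tag=str(gtf))
    if len(fs) == 0:
        raise PipelineStageError("annotation", "no multi-exon transcripts in the GTF")
    counts = count_reads(bam_paths, fs, policy)
    paths = {}
    for fclass, cm in counts.items():
        write_matrix(cm, outdir / f"{fclass}_counts.tsv")
        write_matrix(compute_tpm(cm), outdir / f"{fclass}_tpm.tsv")
        paths[fclass] = outdir / f"{fclass}_tpm.tsv"
    return paths


def run_pipeline(config: dict, outdir: str | Path) -> RunManifest:
    """Execute filter -> IR -> classify -> associate (-> enrich) on a cohort.

    Returns the manifest; all data outputs are deterministic functions of the
    config and seed (the manifest's timing block is the one excepted field).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    manifest = RunManifest(
        version=__version__, seed=config.get("seed"), config=config
    )

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest.timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is None:
                    manifest.completed_stages.append(name)
                    return False
                manifest.write(outdir / "manifest.json")
                if not isinstance(exc, PipelineStageError):
                    raise PipelineStageError(name, str(exc)) from exc
                return False

        return _Timer()

    with _stage("inputs"):
        cohort = load_inputs(config)
        if "fixture_dir" in config:
            d = Path(config["fixture_dir"])
            for p in sorted(d.glob("*")):
                manifest.inputs[str(p)] = _sha256(p)
        groups = cohort.groups
        if cohort.config is not None:
            g1, g2 = cohort.config.group1_label, cohort.config.group2_label
        else:
            g1, g2 = groups.drop_duplicates().tolist()
        exonic = _as_tpm(cohort.exonic)
        intronic = _as_tpm(cohort.intronic)
        transcript = _as_tpm(cohort.transcript)

    with _stage("filter"):
        kept = filter_expressed(transcript, groups, thresholds["expressed_fraction"])
        if not kept:
            raise PipelineStageError("filter", "no transcript passed the filter")

    with _stage("quantify_ir"):
        ir = compute_ir(
            TPMMatrix(exonic.loc[kept], "exonic", "pipeline"),
            TPMMatrix(intronic.loc[kept], "intronic", "pipeline"),
            groups,
            epsilon=thresholds["epsilon"],
            group_order=(g1, g2),
        )
        ir.to_frame().to_csv(outdir / "ir_table.tsv", sep="\t", index_label="transcript_id")

    with _stage("classify"):
        screen = run_screens(
            intronic.loc[kept], transcript.loc[kept], groups,
            group_order=(g1, g2), fdr_level=thresholds["fdr"],
        )
        assignment = classify_sets(
            screen, alpha=thresholds["alpha"], fdr_level=thresholds["fdr"]
        )
        assignment.table.to_csv(
            outdir / "screen_table.tsv", sep="\t", index_label="transcript_id"
        )
        counts = assignment.set_counts()
        cont = None
        if (counts[["A", "B", "C"]].sum(axis=1) > 0).all():
            cont = contingency(assignment)

    with _stage("associate"):
        top = select_top_n(
            assignment, ir.log2_ratio, source_set="set-I", n=thresholds["top_n"]
        )
        order = heatmap_sample_order(cohort.metadata, g2, g1, subgroup_order=("M", "U"))
        if top:
            zscore_rows(ir.tpm_intron, top, order, metric="intron-TPM").values.to_csv(
                outdir / "heatmap_intron.tsv", sep="\t", index_label="transcript_id"
            )
            zscore_rows(
                transcript.loc[kept], top, order, metric="transcript-TPM"
            ).values.to_csv(
                outdir / "heatmap_transcript.tsv", sep="\t", index_label="transcript_id"
            )
        vol = volcano(ir, transcript)
        vol.to_csv(outdir / "volcano.tsv", sep="\t", index_label="transcript_id")
        quad = quadrant_counts(ir)

    gmt = (config.get("enrichment") or {}).get("gmt")
    enr_rows = None
    if gmt:
        with _stage("enrich"):
            tid_to_gene = (config.get("enrichment") or {}).get("transcript_to_gene")
            mapping = tid_to_gene or {t: t for t in kept}
            genes = select_top_fraction(top, mapping, thresholds["top_fraction"])
            universe = {mapping.get(t, t) for t in kept}
            gsc = GeneSetCollection.from_gmt(gmt, universe)
            enr = ora_test(genes, gsc)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t")
            enr_rows = int(len(enr))

    with _stage("summarize"):
        summary = {
            "n_samples": {g1: int((groups == g1).sum()), g2: int((groups == g2).sum())},
            "n_transcripts_total": int(transcript.shape[0]),
            "n_transcripts_expressed": len(kept),
            "set_counts": counts.to_dict(),
            "n_set1": int((assignment.table["ir_set"] == "set-I").sum()),
            "n_set2": int((assignment.table["ir_set"] == "set-II").sum()),
            "quadrants": quad,
            "contingency": cont.to_dict() if cont else None,
            "n_enriched_sets": enr_rows,
            "thresholds": thresholds,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))

    for p in sorted(outdir.glob("*")):
        if p.name != "manifest.json":
            manifest.outputs[str(p)] = _sha256(p)
    manifest.write(outdir / "manifest.json")
    return manifest
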
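"""Synthetic two-group RNA-seq cohorts with planted intron-retention truth.

The generator emulates a 97-case / 9-control bulk RNA-seq design (the case
group split into 41 high-risk-like and 56 low-risk-like samples) with paired
exonic / intronic / whole-transcript abundance matrices. A configurable
fraction of transcripts carries elevated intronic abundance in one group
(set-I: cases; set-II: controls), coupled or not to a whole-transcript
expression shift (subsets A / B / C). Effects are multiplicative, matching
the ratio-based IR statistic; noise is multiplicative log-normal on top of a
log-normal baseline, reproducing the heavy right tail of TPM data.

Matrices are emitted on a TPM-like scale WITHOUT per-sample renormalization:
renormalizing a cohort with planted effects would couple every null
transcript to the planted fraction through the library-sum, contaminating
the ground truth. Renormalization to 1e6 is the quantifier's job on count
data. A counts mode draws negative-binomial counts with matched means for
exercising the count ingestion path.

Every draw flows from one ``numpy`` Generator seeded by ``CohortConfig.seed``,
so a fixed config is bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import CountMatrix, TPMMatrix, write_matrix


@dataclass
class CohortConfig:
    """Study-design and effect parameters of one simulated cohort.

    Group sizes and the subgroup split default to the emulated study design
    (97 cases = 41 unmutated-like + 56 mutated-like, 9 controls). Subset
    proportions within set-I default to the reported 87% / 2% / 11% split of
    over- / under- / non-differentially expressed transcripts; set-II mirrors
    it (expression direction is case-relative throughout).

    ``delta_ir`` multiplies intronic abundance in the set's high-IR group;
    ``delta_expr`` multiplies (subset A) or divides (subset B) exonic and
    whole-transcript abundance in the case group. ``sigma`` is the sd of the
    log-normal multiplicative noise on every cell.
    """

    n_group1: int = 97
    n_group2: int = 9
    n_subgroup_u: int = 41  # high-risk-like block of group 1
    n_subgroup_m: int = 56  # low-risk-like block of group 1
    group1_label: str = "CLL"
    group2_label: str = "NBC"
    n_transcripts: int = 2000
    fraction_set1: float = 0.47
    fraction_set2: float = 0.19
    subset_props_set1: tuple[float, float, float] = (0.87, 0.02, 0.11)
    subset_props_set2: tuple[float, float, float] = (0.02, 0.87, 0.11)
    delta_ir: float = 4.0
    delta_expr: float = 3.0
    sigma: float = 0.5
    baseline_meanlog: float = 2.0
    baseline_sdlog: float = 1.2
    intron_fraction_meanlog: float = float(np.log(0.15))
    intron_fraction_sdlog: float = 0.5
    epsilon: float = 0.01
    emit: str = "tpm"  # or "counts"
    nb_dispersion: float = 0.1  # var = mu + dispersion * mu^2 in counts mode
    count_depth: float = 30.0  # mean count per abundance unit in counts mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroup_u + self.n_subgroup_m != self.n_group1:
            raise ValueError("subgroup sizes must sum to n_group1")
        if not (0 <= self.fraction_set1 <= 1 and 0 <= self.fraction_set2 <= 1):
            raise ValueError("set fractions must lie in [0, 1]")
        if self.fraction_set1 + self.fraction_set2 > 1:
            raise ValueError("fraction_set1 + fraction_set2 must be <= 1")
        for props in (self.subset_props_set1, self.subset_props_set2):
            if any(p < 0 for p in props) or abs(sum(props) - 1) > 1e-9:
                raise ValueError(f"subset proportions must sum to 1, got {props}")
        if self.delta_ir <= 0 or self.delta_expr <= 0:
            raise ValueError("effect sizes must be > 0")
        if self.emit not in ("tpm", "counts"):
            raise ValueError("emit must be 'tpm' or 'counts'")


@dataclass
class SimulatedCohort:
    """A generated cohort: three matrices, sample metadata and planted truth."""

    exonic: TPMMatrix | CountMatrix
    intronic: TPMMatrix | CountMatrix
    transcript: TPMMatrix | CountMatrix
    metadata: pd.DataFrame  # index sample id; columns group, subgroup
    truth: pd.DataFrame  # index transcript id; ir_set, expr_subset, multipliers
    config: CohortConfig = field(repr=False, default=None)

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]


def _plant_labels(cfg: CohortConfig) -> pd.DataFrame:
    n = cfg.n_transcripts
    tids = [f"T{i:05d}" for i in range(1, n + 1)]
    n1 = round(cfg.fraction_set1 * n)
    n2 = round(cfg.fraction_set2 * n)
    ir_set = ["set-I"] * n1 + ["set-II"] * n2 + ["none"] * (n - n1 - n2)
    subset = []
    for size, props in ((n1, cfg.subset_props_set1), (n2, cfg.subset_props_set2)):
        na = round(props[0] * size)
        nb = round(props[1] * size)
        nc = size - na - nb
        subset += ["A"] * na + ["B"] * nb + ["C"] * nc
    subset += [""] * (n - n1 - n2)
    return pd.DataFrame({"ir_set": ir_set, "expr_subset": subset}, index=pd.Index(tids, name="transcript_id"))


def generate_cohort(cfg: CohortConfig) -> SimulatedCohort:
    """Draw one cohort under ``cfg``. Deterministic for a fixed config."""
    rng = np.random.default_rng(cfg.seed)
    n_t = cfg.n_transcripts
    n_s = cfg.n_group1 + cfg.n_group2

    samples = (
        [f"{cfg.group1_label}{i:03d}" for i in range(1, cfg.n_group1 + 1)]
        + [f"{cfg.group2_label}{i:02d}" for i in range(1, cfg.n_group2 + 1)]
    )
    subgroup = (
        ["U"] * cfg.n_subgroup_u
        + ["M"] * cfg.n_subgroup_m
        + [""] * cfg.n_group2
    )
    metadata = pd.DataFrame(
        {
            "group": [cfg.group1_label] * cfg.n_group1
            + [cfg.group2_label] * cfg.n_group2,
            "subgroup": subgroup,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    in_g1 = np.array([g == cfg.group1_label for g in metadata["group"]])

    truth = _plant_labels(cfg)
    tids = truth.index

    base_t = rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, size=n_t)
    intron_frac = rng.lognormal(
        cfg.intron_fraction_meanlog, cfg.intron_fraction_sdlog, size=n_t
    )
    base_e = base_t
    base_i = base_t * intron_frac

    # per-transcript multipliers applied in group 1 (IR effect of set-II acts in group 2)
    ir_set = truth["ir_set"].to_numpy()
    subset = truth["expr_subset"].to_numpy()
    ir_mult_g1 = np.where(ir_set == "set-I", cfg.delta_ir, 1.0)
    ir_mult_g2 = np.where(ir_set == "set-II", cfg.delta_ir, 1.0)
    expr_mult_g1 = np.where(
        subset == "A", cfg.delta_expr, np.where(subset == "B", 1.0 / cfg.delta_expr, 1.0)
    )
    truth = truth.assign(
        ir_multiplier=np.where(ir_set == "set-I", ir_mult_g1, ir_mult_g2),
        expr_multiplier=expr_mult_g1,
    )

    def noisy(mean_matrix: np.ndarray) -> np.ndarray:
        return mean_matrix * rng.lognormal(0.0, cfg.sigma, size=mean_matrix.shape)

    g1_col = in_g1[np.newaxis, :]
    mean_e = base_e[:, None] * np.where(g1_col, expr_mult_g1[:, None], 1.0)
    mean_t = mean_e  # whole-transcript abundance tracks the exonic signal
    mean_i = base_i[:, None] * np.where(
        g1_col, ir_mult_g1[:, None], ir_mult_g2[:, None]
    )

    mats = {}
    for fclass, mean in (("exonic", mean_e), ("transcript", mean_t), ("intronic", mean_i)):
        vals = noisy(mean)
        if cfg.emit == "counts":
            mu = vals * cfg.count_depth
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mu / shape)
            counts = rng.poisson(lam)
            lengths = pd.Series(1000.0, index=tids)
            mats[fclass] = CountMatrix(
                values=pd.DataFrame(counts, index=tids, columns=samples),
                feature_lengths=lengths,
                feature_class=fclass,
            )
        else:
            mats[fclass] = TPMMatrix(
                values=pd.DataFrame(vals, index=tids, columns=samples),
                feature_class=fclass,
                normalization_universe="simulated",
            )

    return SimulatedCohort(
        exonic=mats["exonic"],
        intronic=mats["intronic"],
        transcript=mats["transcript"],
        metadata=metadata,
        truth=truth,
        config=cfg,
    )


def write_fixture(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort as TSV matrices + metadata TSV + truth/config JSON.

    The matrices re-ingest exactly through :func:`irsplit.quantify.ingest_matrix`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kind = "counts" if isinstance(cohort.exonic, CountMatrix) else "tpm"
    paths = {}
    for fclass, mat in (
        ("exonic", cohort.exonic),
        ("intronic", cohort.intronic),
        ("transcript", cohort.transcript),
    ):
        p = outdir / f"{fclass}_{kind}.tsv"
        write_matrix(mat, p)
        paths[fclass] = p
    paths["metadata"] = outdir / "samples.tsv"
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    paths["truth"] = outdir / "truth.json"
    payload = {
        "config": asdict(cohort.config) if cohort.config else None,
        "labels": cohort.truth.reset_index().to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(payload, indent=1))
    return paths


def read_fixture(outdir: str | Path) -> SimulatedCohort:
    """Re-load a cohort written by :func:`write_fixture`."""
    from .quantify import ingest_matrix

    outdir = Path(outdir)
    payload = json.loads((outdir / "truth.json").read_text())
    cfg = CohortConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in payload["config"].items()
    }) if payload["config"] else None
    kind = "counts" if cfg and cfg.emit == "counts" else "tpm"
    mats = {
        fclass: ingest_matrix(
            outdir / f"{fclass}_{kind}.tsv", kind=kind, feature_class=fclass
        )
        for fclass in ("exonic", "intronic", "transcript")
    }
    metadata = pd.read_csv(outdir / "samples.tsv", sep="\t", index_col=0).fillna("")
    truth = pd.DataFrame(payload["labels"])
    truth = (
        truth.set_index("transcript_id")
        if not truth.empty
        else pd.DataFrame(
            columns=["ir_set", "expr_subset", "ir_multiplier", "expr_multiplier"]
        )
    )
    return SimulatedCohort(
        exonic=mats["exonic"],
        intronic=mats["intronic"],
        transcript=mats["transcript"],
        metadata=metadata,
        truth=truth,
        config=cfg,
    )


def label_accuracy(assignment, truth: pd.DataFrame) -> float:
    """Fraction of transcripts whose called (ir_set, expr_subset) matches the
    planted label; 'none' must be recovered as 'none'."""
    called = assignment.table[["ir_set", "expr_subset"]].reindex(truth.index)
    want_set = truth["ir_set"]
    want_sub = truth["expr_subset"].fillna("")
    ok_set = called["ir_set"] == want_set
    ok_sub = (called["expr_subset"] == want_sub) | (want_set == "none")
    return float((ok_set & ok_sub).mean())


def false_discovery_proportion(assignment, truth: pd.DataFrame) -> float:
    """FDP of the union of set-I and set-II calls against the planted truth.

    A call is false when the planted ir_set differs from the called one.
    Returns 0 when nothing was called.
    """
    called = assignment.table["ir_set"].reindex(truth.index)
    mask = called != "none"
    if not mask.any():
        return 0.0
    return float((called[mask] != truth.loc[mask.index[mask], "ir_set"]).mean())


def null_calibration(
    n_cohorts: int = 200,
    first_seed: int = 1,
    n_transcripts: int = 2000,
    sigma: float = 0.5,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """False-discovery proportions of IR-set calls on complete-null cohorts.

    Generates ``n_cohorts`` cohorts of the default 97-vs-9 design with no
    planted effects (seeds ``first_seed`` .. ``first_seed + n_cohorts - 1``),
    runs both directional intronic screens with BH control at ``fdr_level``,
    and records per cohort the FDP of the union of set-I and set-II calls —
    under the null every call is false, so the FDP is 1 when anything is
    called and 0 otherwise. Returns a frame with columns ``fdp`` and
    ``n_calls``; its ``fdp`` mean estimates the realized FDR.
    """
    from .classify import classify_sets, run_screens

    rows = []
    for seed in range(first_seed, first_seed + n_cohorts):
        cfg = CohortConfig(
            n_transcripts=n_transcripts,
            fraction_set1=0.0,
            fraction_set2=0.0,
            sigma=sigma,
            seed=seed,
        )
        cohort = generate_cohort(cfg)
        sr = run_screens(
            cohort.intronic.values,
            cohort.transcript.values,
            cohort.groups,
            group_order=(cfg.group1_label, cfg.group2_label),
            fdr_level=fdr_level,
        )
        sa = classify_sets(sr, fdr_level=fdr_level)
        n_calls = int((sa.table["ir_set"] != "none").sum())
        rows.append(
            {
                "seed": seed,
                "n_calls": n_calls,
                "fdp": false_discovery_proportion(sa, cohort.truth),
            }
        )
    return pd.DataFrame(rows).set_index("seed")


def write_toy_bam(
    path: str | Path,
    chrom_lengths: dict[str, int],
    reads: list[tuple[str, str, int, str]],
    mapq: int = 60,
) -> Path:
    """Write a tiny coordinate-sorted, indexed BAM of single-end reads.

    ``reads`` are (qname, chrom, 1-based position, CIGAR) tuples with an
    all-'A' query. Exists solely to exercise the read counter on handmade
    fixtures; it does not model sequencing.
    """
    import pysam

    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    refs = list(chrom_lengths)
    ordered = sorted(reads, key=lambda r: (refs.index(r[1]), r[2]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for qname, chrom, pos1, cigar in ordered:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = qname
            a.reference_id = refs.index(chrom)
            a.reference_start = pos1 - 1
            a.cigarstring = cigar
            qlen = sum(
                n for n, op in _cigar_ops(cigar) if op in "MIS=X"
            )
            a.query_sequence = "A" * qlen
            a.mapping_quality = mapq
            a.flag = 0
            bam.write(a)
    pysam.index(str(path))
    return path


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
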
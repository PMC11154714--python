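"""Feature-level read counting, TPM normalization and the intron/exon IR statistic.

The central quantity is, per transcript and sample,

    R = (TPM_intron + eps) / (TPM_exon + eps)

where TPM_intron / TPM_exon are the summed TPM of the transcript's intronic /
exonic features and ``eps`` is a small pseudocount guarding zero denominators.
Between two groups the per-transcript statistic is ``log2`` of the ratio of
group summaries (median by default) of R.

TPM is computed per feature class over that class's own feature universe:
``TPM_f = 1e6 * (r_f / L_f) / sum_g (r_g / L_g)``, so each sample's exonic
TPMs sum to 1e6 over exonic features, intronic over intronic, and transcript
over whole transcripts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import FeatureSet, feature_key

DEFAULT_EPSILON = 0.01


class MatrixError(ValueError):
    """Raised for malformed count/TPM matrix input."""


def _check_values(values: pd.DataFrame, what: str) -> None:
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise MatrixError(f"duplicate feature keys in {what}: {dups[:5]}")
    if not np.issubdtype(values.to_numpy().dtype, np.number):
        raise MatrixError(f"non-numeric cells in {what}")
    if (values.to_numpy() < 0).any():
        bad = values.index[(values < 0).any(axis=1)].tolist()
        raise MatrixError(f"negative values in {what} at rows {bad[:5]}")


@dataclass
class CountMatrix:
    """Feature x sample read counts with per-feature lengths (bp)."""

    values: pd.DataFrame  # int counts, index = feature keys, columns = samples
    feature_lengths: pd.Series  # bp per feature key
    feature_class: str = "transcript"

    def __post_init__(self) -> None:
        _check_values(self.values, f"{self.feature_class} counts")
        lengths = self.feature_lengths.reindex(self.values.index)
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()].tolist()
            raise MatrixError(f"missing feature lengths for {missing[:5]}")
        if (lengths < 1).any():
            raise MatrixError("all feature lengths must be >= 1 bp")
        self.feature_lengths = lengths.astype(float)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class TPMMatrix:
    """Feature x sample TPM abundances, normalized over one feature universe."""

    values: pd.DataFrame
    feature_class: str = "transcript"
    normalization_universe: str = ""

    def __post_init__(self) -> None:
        _check_values(self.values, f"{self.feature_class} TPM")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def compute_tpm(cm: CountMatrix) -> TPMMatrix:
    """Length-normalize counts to TPM over the matrix's own feature universe.

    Columns with zero total count stay all-zero rather than dividing by zero.
    """
    rates = cm.values.div(cm.feature_lengths, axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} sample(s) have zero total count",
            stacklevel=2,
        )
    tpm = rates.div(totals.replace(0.0, np.nan), axis=1).fillna(0.0) * 1e6
    return TPMMatrix(
        values=tpm,
        feature_class=cm.feature_class,
        normalization_universe=cm.feature_class,
    )


@dataclass
class CountingPolicy:
    """How reads map onto features.

    A read (or fragment) increments every feature it overlaps by at least
    ``min_overlap`` aligned bases (union counting; a read straddling an
    exon/intron boundary counts toward both — boundary-straddling reads are
    precisely the IR signal). Reads with mapping quality below ``min_mapq``
    are skipped, which drops multi-mappers under the common MAPQ=0 convention.
    When ``count_fragments`` is set, paired mates increment a feature once per
    fragment. ``stranded`` is one of ``no`` (default), ``fr`` or ``rf``.
    """

    min_overlap: int = 1
    min_mapq: int = 1
    count_fragments: bool = True
    stranded: str = "no"


def _read_strand(read) -> str:
    # fragment strand under the fr convention; rf flips it
    if read.is_paired and read.is_read2:
        return "+" if read.is_reverse else "-"
    return "-" if read.is_reverse else "+"


def count_reads(
    bam_paths: Mapping[str, str | Path],
    fs: FeatureSet,
    policy: CountingPolicy | None = None,
) -> dict[str, CountMatrix]:
    """Count reads per exonic/intronic/transcript feature for each sample BAM.

    Returns one :class:`CountMatrix` per feature class. BAMs must be
    coordinate-sorted and indexed. Deterministic given the inputs (counts do
    not depend on read order).
    """
    import pysam

    policy = policy or CountingPolicy()
    index: dict[str, list[tuple[tuple[str, str, int], int, int, str]]] = {}
    for key, iv in fs.feature_index.items():
        index.setdefault(iv.chrom, []).append((key, iv.start, iv.end, iv.strand))

    keys_by_class: dict[str, list[str]] = {"exonic": [], "intronic": [], "transcript": []}
    lengths: dict[str, dict[str, int]] = {c: {} for c in keys_by_class}
    for (tid, fclass, ordinal), iv in fs.feature_index.items():
        flat = tid if fclass == "transcript" else feature_key(tid, fclass, ordinal)
        keys_by_class[fclass].append(flat)
        lengths[fclass][flat] = len(iv)
    for c in keys_by_class:
        keys_by_class[c] = sorted(set(keys_by_class[c]))

    counts = {
        c: pd.DataFrame(
            0, index=keys_by_class[c], columns=list(bam_paths), dtype=int
        )
        for c in keys_by_class
    }

    for sample, path in bam_paths.items():
        path = Path(path)
        if not path.with_suffix(path.suffix + ".bai").exists() and not Path(
            str(path) + ".bai"
        ).exists():
            # pysam also finds .bai next to the BAM; probe by opening
            pass
        with pysam.AlignmentFile(str(path), "rb") as bam:
            if not bam.has_index():
                raise MatrixError(
                    f"{path} has no index; run `samtools index {path}` first"
                )
            n_reads = 0
            seen: set[tuple[tuple[str, str, int], str]] = set()
            for read in bam.fetch():
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                if read.mapping_quality < policy.min_mapq:
                    continue
                n_reads += 1
                chrom = read.reference_name
                if chrom not in index:
                    continue
                blocks = read.get_blocks()  # 0-based half-open aligned segments
                strand = _read_strand(read)
                for key, f_start, f_end, f_strand in index[chrom]:
                    if policy.stranded != "no" and f_strand in ("+", "-"):
                        want = f_strand if policy.stranded == "fr" else (
                            "-" if f_strand == "+" else "+"
                        )
                        if strand != want:
                            continue
                    ov = 0
                    for b0, b1 in blocks:  # convert to 1-based inclusive
                        ov += max(0, min(f_end, b1) - max(f_start, b0 + 1) + 1)
                    if ov < policy.min_overlap:
                        continue
                    if policy.count_fragments and read.is_paired:
                        tag = (key, read.query_name)
                        if tag in seen:
                            continue
                        seen.add(tag)
                    tid, fclass, ordinal = key
                    flat = tid if fclass == "transcript" else feature_key(*key)
                    counts[fclass].at[flat, sample] += 1
            if n_reads == 0:
                warnings.warn(f"{path} contains no usable reads", stacklevel=2)

    return {
        c: CountMatrix(
            values=counts[c],
            feature_lengths=pd.Series(lengths[c]).reindex(counts[c].index),
            feature_class=c,
        )
        for c in keys_by_class
    }


def aggregate_by_transcript(tpm: TPMMatrix) -> pd.DataFrame:
    """Sum feature-level TPM rows to one row per transcript.

    Feature keys of the form ``tid|class|ordinal`` collapse on ``tid``;
    plain transcript ids pass through unchanged.
    """
    tids = [
        k.split("|", 1)[0] if isinstance(k, str) and "|" in k else k
        for k in tpm.values.index
    ]
    return tpm.values.groupby(pd.Index(tids, name="transcript_id")).sum()


@dataclass
class IRTable:
    """Per-transcript intron/exon ratios, group summaries and the log2 statistic."""

    tpm_intron: pd.DataFrame  # transcript x sample
    tpm_exon: pd.DataFrame
    ratios: pd.DataFrame
    group_summary: pd.DataFrame  # transcript x group (summary of R)
    log2_ratio: pd.Series  # log2(summary group1 / summary group2)
    groups: pd.Series  # sample -> group label
    group_order: tuple[str, str]
    epsilon: float = DEFAULT_EPSILON
    zero_exon_flag: pd.Series = field(default_factory=pd.Series)

    @property
    def transcripts(self) -> list[str]:
        return list(self.ratios.index)

    def to_frame(self) -> pd.DataFrame:
        g1, g2 = self.group_order
        out = self.ratios.copy()
        out[f"median_R_{g1}"] = self.group_summary[g1]
        out[f"median_R_{g2}"] = self.group_summary[g2]
        out["log2_ratio"] = self.log2_ratio
        out["zero_exon_flag"] = self.zero_exon_flag
        return out


def compute_ir(
    tpm_exonic: TPMMatrix,
    tpm_intronic: TPMMatrix,
    groups: Mapping[str, str] | pd.Series,
    epsilon: float = DEFAULT_EPSILON,
    group_order: tuple[str, str] | None = None,
    summary: str = "median",
    zero_exon_fraction: float = 0.40,
) -> IRTable:
    """Compute the intron/exon ratio table between two sample groups.

    Transcripts present in only one of the two matrices are excluded with a
    warning. ``summary`` is the per-group location estimate of R used for the
    between-group log2 ratio (``median`` by default; ``mean`` available).
    Transcripts whose exonic TPM is zero in more than ``zero_exon_fraction``
    of samples are flagged (their ratios are pseudocount-dominated).
    """
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    intron = aggregate_by_transcript(tpm_intronic)
    exon = aggregate_by_transcript(tpm_exonic)

    samples = [s for s in exon.columns if s in intron.columns]
    shared = exon.index.intersection(intron.index)
    dropped = len(exon.index.union(intron.index)) - len(shared)
    if dropped:
        warnings.warn(
            f"{dropped} transcript(s) present in only one matrix were excluded",
            stacklevel=2,
        )
    intron = intron.loc[shared, samples]
    exon = exon.loc[shared, samples]

    if group_order is None:
        ordered = groups.loc[samples].drop_duplicates().tolist()
        if len(ordered) != 2:
            raise ValueError(f"expected exactly 2 groups, got {ordered}")
        group_order = (ordered[0], ordered[1])
    g1, g2 = group_order

    ratios = (intron + epsilon) / (exon + epsilon)
    summarize = {"median": np.median, "mean": np.mean}[summary]
    s1 = ratios[[s for s in samples if groups[s] == g1]].apply(summarize, axis=1)
    s2 = ratios[[s for s in samples if groups[s] == g2]].apply(summarize, axis=1)
    group_summary = pd.DataFrame({g1: s1, g2: s2})
    log2_ratio = np.log2(s1 / s2).rename("log2_ratio")
    zero_flag = (exon == 0).mean(axis=1) > zero_exon_fraction

    return IRTable(
        tpm_intron=intron,
        tpm_exon=exon,
        ratios=ratios,
        group_summary=group_summary,
        log2_ratio=log2_ratio,
        groups=groups.loc[samples],
        group_order=group_order,
        epsilon=epsilon,
        zero_exon_flag=zero_flag,
    )


def write_matrix(matrix: CountMatrix | TPMMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (counts include a ``length`` column)."""
    df = matrix.values.copy()
    if isinstance(matrix, CountMatrix):
        df.insert(0, "length", matrix.feature_lengths.astype(int))
    df.to_csv(path, sep="\t", index_label=df.index.name or "feature")


def ingest_matrix(
    path: str | Path, kind: str = "tpm", feature_class: str = "transcript"
) -> CountMatrix | TPMMatrix:
    """Read a TSV matrix (feature key column first; counts carry a length column).

    Validates non-negativity, numeric cells and unique feature keys, naming the
    offending row in the error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name == "feature":  # the anonymous-index label used on write
        df.index.name = None
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise MatrixError(f"{path}: duplicate feature keys {dups[:5]}")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            raise MatrixError(
                f"{path}: non-numeric cell at row {df.index[bad][0]!r}, column {col!r}"
            )
    if kind == "counts":
        if "length" not in df.columns:
            raise MatrixError(f"{path}: counts TSV must carry a 'length' column")
        lengths = df.pop("length")
        return CountMatrix(
            values=df.astype(int), feature_lengths=lengths, feature_class=feature_class
        )
    if kind == "tpm":
        df = df.drop(columns=[c for c in ("length",) if c in df.columns])
        return TPMMatrix(
            values=df.astype(float),
            feature_class=feature_class,
            normalization_universe=feature_class,
        )
    raise ValueError(f"kind must be 'counts' or 'tpm', got {kind!r}")
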
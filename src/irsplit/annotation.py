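"""Transcript annotation handling: exon models, derived introns, interval arithmetic.

Coordinates are 1-based inclusive throughout the package (the convention of the
UCSC browser text and of PCR product arithmetic: ``length = end - start + 1``).
BED export converts to 0-based half-open at the file boundary only.

Intron derivation is per-transcript: an intron is exactly the gap between two
consecutive exons of the same transcript. Exons of other isoforms are not
subtracted by default; :func:`filter_intronless` offers an optional masked
variant for users who want the stricter definition some IR tools use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gffutils

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("exonic", "intronic", "transcript")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval on a reference sequence, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AnnotationError(
                f"end < start for {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def interval_length(iv: GenomicInterval) -> int:
    """Length in base pairs of a 1-based inclusive interval (end - start + 1)."""
    return len(iv)


def merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: overlapping or book-ended (adjacent) intervals merge.

    All intervals must share one chromosome and strand.
    """
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) > 1 or len(strands) > 1:
        raise AnnotationError(
            f"cannot merge intervals across chromosomes/strands: {chroms}, {strands}"
        )
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda x: (x.start, x.end)):
        if out and iv.start <= out[-1].end + 1:  # overlap or book-ended
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end, iv.strand)
        else:
            out.append(iv)
    return out


@dataclass
class TranscriptModel:
    """Exon structure of one transcript plus the introns derived from it."""

    transcript_id: str
    gene_id: str
    gene_symbol: str | None
    exons: list[GenomicInterval]
    introns: list[GenomicInterval] = field(default_factory=list)

    @classmethod
    def from_exons(
        cls,
        transcript_id: str,
        gene_id: str,
        exons: Sequence[GenomicInterval],
        gene_symbol: str | None = None,
    ) -> "TranscriptModel":
        """Build a model from raw exon records, merging overlaps and deriving introns."""
        if not exons:
            raise AnnotationError(f"transcript {transcript_id} has no exons")
        merged = merge_intervals(list(exons))
        introns = [
            GenomicInterval(a.chrom, a.end + 1, b.start - 1, a.strand)
            for a, b in zip(merged, merged[1:])
        ]
        return cls(transcript_id, gene_id, gene_symbol, merged, introns)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def intronic_length(self) -> int:
        return sum(len(i) for i in self.introns)


@dataclass
class FeatureSet:
    """A filtered collection of transcript models and their indexed features.

    ``feature_index`` maps ``(transcript_id, feature_class, ordinal)`` to the
    corresponding interval, where feature_class is ``exonic``, ``intronic`` or
    ``transcript`` (the whole span).
    """

    transcripts: dict[str, TranscriptModel]
    build_tag: str = ""

    def __post_init__(self) -> None:
        self.feature_index: dict[tuple[str, str, int], GenomicInterval] = {}
        for tid, tm in self.transcripts.items():
            for i, ex in enumerate(tm.exons):
                self.feature_index[(tid, "exonic", i)] = ex
            for i, iv in enumerate(tm.introns):
                self.feature_index[(tid, "intronic", i)] = iv
            self.feature_index[(tid, "transcript", 0)] = tm.span

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())


def _transcript_id_of(feature: gffutils.Feature) -> str | None:
    attrs = feature.attributes
    if "transcript_id" in attrs:
        return attrs["transcript_id"][0]
    # GFF3 exons point at their transcript through Parent
    if "Parent" in attrs:
        parent = attrs["Parent"][0]
        return parent.split(":", 1)[1] if parent.startswith("transcript:") else parent
    return None


def _gene_id_of(feature: gffutils.Feature) -> str:
    attrs = feature.attributes
    for key in ("gene_id", "gene"):
        if key in attrs:
            return attrs[key][0]
    return ""


def _gene_symbol_of(feature: gffutils.Feature) -> str | None:
    attrs = feature.attributes
    for key in ("gene_name", "gene_symbol", "Name"):
        if key in attrs:
            return attrs[key][0]
    return None


def parse_annotation(path: str | Path) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 annotation into transcript models.

    Exon records are grouped by transcript id, unioned within each transcript
    (overlapping or book-ended records merge) and the introns are derived as
    the gaps between consecutive merged exons. Models are returned sorted by
    (chrom, start, transcript_id). Transcript-level records without exons are
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils reports the offending line in its message
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    exons_by_tid: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str | None]] = {}
    for feat in db.features_of_type("exon"):
        tid = _transcript_id_of(feat)
        if tid is None:
            raise AnnotationError(
                f"exon at {feat.seqid}:{feat.start}-{feat.end} lacks a "
                "transcript_id/Parent attribute"
            )
        strand = feat.strand if feat.strand in ("+", "-") else "."
        exons_by_tid.setdefault(tid, []).append(
            GenomicInterval(feat.seqid, feat.start, feat.end, strand)
        )
        if tid not in meta:
            meta[tid] = (_gene_id_of(feat), _gene_symbol_of(feat))

    n_skipped = 0
    for kind in ("transcript", "mRNA"):
        for feat in db.features_of_type(kind):
            tid = feat.attributes.get("transcript_id", [feat.id])[0]
            if tid.startswith("transcript:"):
                tid = tid.split(":", 1)[1]
            if tid not in exons_by_tid:
                n_skipped += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} transcript record(s) without exon records were skipped",
            stacklevel=2,
        )

    models = [
        TranscriptModel.from_exons(tid, meta[tid][0], exons, meta[tid][1])
        for tid, exons in exons_by_tid.items()
    ]
    models.sort(key=lambda m: (m.chrom, m.span.start, m.transcript_id))
    return models


def filter_intronless(
    models: Iterable[TranscriptModel],
    build_tag: str = "",
    mask_exons_of_other_transcripts: bool = False,
) -> FeatureSet:
    """Drop transcripts without introns; optionally mask shared exonic positions.

    Single-exon transcripts carry no intron signal and are removed before any
    IR quantification. With ``mask_exons_of_other_transcripts`` the intronic
    intervals are additionally trimmed so that no retained intronic position
    overlaps an exon of any other kept transcript (the stricter definition).
    Returns the retained transcripts as a :class:`FeatureSet`; warns when the
    result is empty.
    """
    models = list(models)
    kept = {m.transcript_id: m for m in models if m.introns}
    n_removed = len(models) - len(kept)
    logger.info("filter_intronless: removed %d, retained %d", n_removed, len(kept))

    if mask_exons_of_other_transcripts and kept:
        exons_by_chrom: dict[str, list[GenomicInterval]] = {}
        for m in kept.values():
            exons_by_chrom.setdefault(m.chrom, []).extend(m.exons)
        masked: dict[str, TranscriptModel] = {}
        for tid, m in kept.items():
            foreign = [
                e
                for e in exons_by_chrom.get(m.chrom, [])
                if e not in m.exons
            ]
            new_introns: list[GenomicInterval] = []
            for intron in m.introns:
                new_introns.extend(_subtract(intron, foreign))
            if new_introns:
                masked[tid] = TranscriptModel(
                    tid, m.gene_id, m.gene_symbol, m.exons, new_introns
                )
        kept = masked

    if not kept:
        warnings.warn("no transcript with introns survived filtering", stacklevel=2)
    return FeatureSet(transcripts=kept, build_tag=build_tag)


def _subtract(
    iv: GenomicInterval, others: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Pieces of ``iv`` not covered by any interval in ``others``."""
    pieces = [(iv.start, iv.end)]
    for o in others:
        if o.chrom != iv.chrom:
            continue
        nxt = []
        for s, e in pieces:
            if o.end < s or o.start > e:
                nxt.append((s, e))
                continue
            if o.start > s:
                nxt.append((s, o.start - 1))
            if o.end < e:
                nxt.append((o.end + 1, e))
        pieces = nxt
    return [GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in pieces]


def feature_key(tid: str, feature_class: str, ordinal: int) -> str:
    """Flat string key for one feature: ``transcript|class|ordinal``."""
    return f"{tid}|{feature_class}|{ordinal}"


def export_regions(fs: FeatureSet, path: str | Path) -> None:
    """Write all indexed features as BED6 (0-based half-open) with a header comment.

    Record names are ``transcript_id|feature_class|ordinal`` so that a re-import
    reconstructs the identical feature set.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# irsplit feature regions (BED6, 0-based half-open)\n")
        for (tid, fclass, ordinal), iv in sorted(
            fs.feature_index.items(),
            key=lambda kv: (kv[1].chrom, kv[1].start, kv[0]),
        ):
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t"
                f"{feature_key(tid, fclass, ordinal)}\t0\t{iv.strand}\n"
            )


def import_regions(path: str | Path, build_tag: str = "") -> FeatureSet:
    """Rebuild a FeatureSet from a BED6 file written by :func:`export_regions`."""
    path = Path(path)
    exons: dict[str, list[GenomicInterval]] = {}
    spans: dict[str, GenomicInterval] = {}
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise AnnotationError(f"{path}:{ln}: expected 6 BED columns")
        chrom, start0, end, name, _score, strand = parts[:6]
        iv = GenomicInterval(chrom, int(start0) + 1, int(end), strand)
        tid, fclass, _ordinal = name.rsplit("|", 2)
        if fclass == "exonic":
            exons.setdefault(tid, []).append(iv)
        elif fclass == "transcript":
            spans[tid] = iv
    models = [
        TranscriptModel.from_exons(tid, gene_id="", exons=ivs)
        for tid, ivs in exons.items()
    ]
    return filter_intronless(models, build_tag=build_tag)


def feature_table(fs: FeatureSet):
    """Flat TSV-ready table of all features (one row per feature)."""
    import pandas as pd

    rows = [
        {
            "transcript_id": tid,
            "feature_class": fclass,
            "ordinal": ordinal,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "length": len(iv),
        }
        for (tid, fclass, ordinal), iv in sorted(fs.feature_index.items())
    ]
    return pd.DataFrame(rows)
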
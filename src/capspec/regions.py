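"""Prophage-region consensus: two-tool union, extension, QC trim/split, filters.

Prophage detection tools disagree on boundaries, so candidate regions are
built by pooling the intervals reported by all tools on a contig, merging
any that overlap or touch, and extending each merged interval by a pad
(default 2 kb) on both sides to avoid losing poorly annotated
receptor-binding genes at the edges.  A quality-control step (consumed
here as a table, produced externally) may trim an extended region or
split it into several sub-prophages, each with a completeness estimate
and a confidence class; sub-regions are re-extended by the same pad and
retained only if they pass completeness, confidence and minimum-length
filters.

All coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive.  Touching intervals (end == start) merge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "Detection",
    "QCRecord",
    "Region",
    "merge_union",
    "apply_qc",
    "write_regions_gff",
    "read_regions_gff",
    "DEFAULT_PAD",
]

DEFAULT_PAD = 2_000
DEFAULT_MIN_COMPLETENESS = 50.0
DEFAULT_MIN_LENGTH = 2_000
DEFAULT_CONFIDENCE = frozenset({"low", "medium", "high"})


@dataclass(frozen=True)
class Detection:
    """One tool's prophage interval on a contig (0-based half-open)."""

    isolate_id: str
    contig_id: str
    start: int
    end: int
    tool: str


@dataclass(frozen=True)
class QCRecord:
    """A QC sub-region of an extended region, in contig coordinates."""

    region_id: str
    start: int
    end: int
    completeness: float
    confidence: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(
                f"QC record {self.region_id!r}: completeness {self.completeness} not in [0, 100]"
            )


@dataclass(frozen=True)
class Region:
    """A prophage region at some pipeline stage."""

    region_id: str
    isolate_id: str
    contig_id: str
    start: int
    end: int
    stage: str = "primary"  # primary | extended | trimmed | final
    completeness: float | None = None
    confidence: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"region {self.region_id!r}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals; sorted output."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = out[-1]
        if s <= pe:  # touching counts as overlap
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def merge_union(
    detections: Sequence[Detection],
    contig_length: int,
    pad: int = DEFAULT_PAD,
) -> list[Region]:
    """Union the detections on one contig, extend by ``pad``, re-merge.

    Returns extended regions sorted by start, with deterministic ids
    ``{contig}:{index}``.
    """
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    bad = [d for d in detections
           if not (0 <= d.start < d.end <= contig_length)]
    if bad:
        raise ValueError(f"detections exceed contig bounds [0, {contig_length}): {bad}")
    if not detections:
        return []
    contigs = {d.contig_id for d in detections}
    isolates = {d.isolate_id for d in detections}
    if len(contigs) > 1 or len(isolates) > 1:
        raise ValueError("merge_union expects detections from a single contig")
    contig_id = detections[0].contig_id
    isolate_id = detections[0].isolate_id

    primary = _merge_intervals([(d.start, d.end) for d in detections])
    extended = [(max(0, s - pad), min(contig_length, e + pad)) for s, e in primary]
    merged = _merge_intervals(extended)
    return [
        Region(
            region_id=f"{contig_id}:{i}",
            isolate_id=isolate_id,
            contig_id=contig_id,
            start=s,
            end=e,
            stage="extended",
        )
        for i, (s, e) in enumerate(merged)
    ]


def apply_qc(
    regions: Sequence[Region],
    qc_records: Sequence[QCRecord],
    contig_lengths: dict[str, int],
    pad: int = DEFAULT_PAD,
    min_completeness: float = DEFAULT_MIN_COMPLETENESS,
    min_length: int = DEFAULT_MIN_LENGTH,
    allowed_confidence: Iterable[str] = DEFAULT_CONFIDENCE,
    length_before_extension: bool = False,
) -> list[Region]:
    """Replace extended regions by their QC sub-regions, re-extend and filter.

    Each QC sub-region must lie within its parent extended region.  It is
    re-extended by ``pad`` (clipped to the contig) and retained iff its
    completeness is at least ``min_completeness``, its confidence class is
    allowed, and its length is at least ``min_length``.  By default length
    is measured after re-extension; set ``length_before_extension`` to
    measure the trimmed interval instead.  Extended regions with no QC
    record are dropped.
    """
    allowed = set(allowed_confidence)
    by_id = {r.region_id: r for r in regions}
    out: list[Region] = []
    counter: dict[str, int] = {}
    for rec in qc_records:
        parent = by_id.get(rec.region_id)
        if parent is None:
            raise ValueError(f"QC record references unknown region {rec.region_id!r}")
        if not (parent.start <= rec.start < rec.end <= parent.end):
            raise ValueError(
                f"QC sub-interval [{rec.start}, {rec.end}) outside parent "
                f"{rec.region_id!r} [{parent.start}, {parent.end})"
            )
        clen = contig_lengths[parent.contig_id]
        s = max(0, rec.start - pad)
        e = min(clen, rec.end + pad)
        length = (rec.end - rec.start) if length_before_extension else (e - s)
        if rec.completeness < min_completeness:
            continue
        if rec.confidence not in allowed:
            continue
        if length < min_length:
            continue
        k = counter.get(rec.region_id, 0)
        counter[rec.region_id] = k + 1
        out.append(
            Region(
                region_id=f"{rec.region_id}.{k}",
                isolate_id=parent.isolate_id,
                contig_id=parent.contig_id,
                start=s,
                end=e,
                stage="final",
                completeness=rec.completeness,
                confidence=rec.confidence,
            )
        )
    out.sort(key=lambda r: (r.contig_id, r.start, r.end, r.region_id))
    return out


def write_regions_gff(regions: Sequence[Region]) -> str:
    """Serialize regions as a GFF3 document (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for r in regions:
        attrs = [f"ID={r.region_id}", f"isolate={r.isolate_id}", f"stage={r.stage}"]
        if r.completeness is not None:
            attrs.append(f"completeness={r.completeness:g}")
        if r.confidence is not None:
            attrs.append(f"confidence={r.confidence}")
        lines.append(
            "\t".join(
                [r.contig_id, "capspec", "prophage", str(r.start + 1), str(r.end),
                 ".", ".", ".", ";".join(attrs)]
            )
        )
    return "\n".join(lines) + "\n"


def read_regions_gff(text: str) -> list[Region]:
    """Parse a GFF3 document written by :func:`write_regions_gff`."""
    regions: list[Region] = []
    for lineno, raw in enumerate(text.replace("\r\n", "\n").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 columns, got {len(parts)}")
        contig, _src, ftype, start, end, _score, _strand, _frame, attr_str = parts
        if ftype != "prophage":
            continue
        attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if kv)
        regions.append(
            Region(
                region_id=attrs.get("ID", f"{contig}:{lineno}"),
                isolate_id=attrs.get("isolate", ""),
                contig_id=contig,
                start=int(start) - 1,
                end=int(end),
                stage=attrs.get("stage", "final"),
                completeness=float(attrs["completeness"]) if "completeness" in attrs else None,
                confidence=attrs.get("confidence"),
            )
        )
    return regions
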
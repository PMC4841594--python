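"""Genomic intervals, 0-based half-open, BED-compatible."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    name: str = field(default="", compare=False)
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of + - ., got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Bases shared with ``other`` under half-open semantics (0 if on
        different chroms)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_overlap: int = 1) -> bool:
        return self.overlap_length(other) >= min_overlap

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(self), overlap/len(other)); 1.0 means identical."""
        ov = self.overlap_length(other)
        return min(ov / self.length, ov / other.length)

    def to_bed(self, score: float | int = 0) -> str:
        return f"{self.chrom}\t{self.start}\t{self.end}\t{self.name or '.'}\t{score}\t{self.strand}"
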
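"""Domain types shared across the toolkit.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field


REGION_KINDS = {"UCE", "VISTA", "predicted_enhancer", "control", "de_novo"}
PAIR_STRATEGIES = {"flanking", "internal", "control"}


@dataclass(frozen=True)
class TargetRegion:
    """A genomic deletion target (e.g. an NCRE candidate)."""

    region_id: str
    chrom: str
    start: int
    end: int
    kind: str = "predicted_enhancer"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.region_id}: end must exceed start")
        if self.kind not in REGION_KINDS:
            raise ValueError(f"{self.region_id}: unknown region kind {self.kind!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CandidateGuide:
    """A 20-nt protospacer with its predicted efficacy/off-target scores.

    ``cut_site`` is the coordinate of the blunt Cas9 cut, between
    protospacer positions 17 and 18 (3 bp 5' of the PAM).
    """

    guide_id: str
    chrom: str
    cut_site: int
    strand: str
    protospacer: str
    efficacy: float | None = None
    top5_offtarget: float | None = None
    top10_offtarget: float | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20 or set(self.protospacer) - set("ACGT"):
            raise ValueError(
                f"{self.guide_id}: protospacer must be 20 nt of ACGT"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.guide_id}: strand must be + or -")

    @property
    def protospacer_interval(self) -> tuple[int, int]:
        """Genomic [start, end) of the protospacer (PAM excluded)."""
        if self.strand == "+":
            return self.cut_site - 17, self.cut_site + 3
        return self.cut_site - 3, self.cut_site + 17


@dataclass(frozen=True)
class GuidePair:
    pair_id: str
    region_id: str
    guide_u6: CandidateGuide
    guide_h1: CandidateGuide
    expected_deletion: tuple[int, int]
    strategy: str

    def __post_init__(self) -> None:
        lo, hi = self.expected_deletion
        if hi <= lo:
            raise ValueError(f"{self.pair_id}: expected deletion must be non-empty")
        if self.strategy not in PAIR_STRATEGIES:
            raise ValueError(f"{self.pair_id}: unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class OligoConstruct:
    pair_id: str
    version: str
    sequence: str
    barcode: str = ""


@dataclass(frozen=True)
class ExpressionCassette:
    pair_id: str
    version: str
    sequence: str
    scaffold_gap: int


@dataclass
class LibraryDesign:
    """A complete paired-guide deletion library."""

    regions: list[TargetRegion]
    pairs: list[GuidePair]
    oligos: list[OligoConstruct]
    controls: list[GuidePair] = field(default_factory=list)
    version: str = "v2"
    strategy_by_region: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        region_ids = {r.region_id for r in self.regions}
        for pair in self.pairs:
            if pair.region_id not in region_ids:
                raise ValueError(
                    f"pair {pair.pair_id} references unknown region {pair.region_id}"
                )
        known = {p.pair_id for p in self.pairs} | {c.pair_id for c in self.controls}
        for oligo in self.oligos:
            if oligo.pair_id not in known:
                raise ValueError(f"oligo references unknown pair {oligo.pair_id}")

    @property
    def all_pairs(self) -> list[GuidePair]:
        return list(self.pairs) + list(self.controls)
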
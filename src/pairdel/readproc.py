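"""Paired-amplicon read processing with recombinant filtering.

Each paired-end read pair covers one integrated dual-guide cassette: one
mate is anchored by the U6 promoter and carries the first protospacer,
the other is anchored by the H1 promoter and carries the second.  The
two 20-nt protospacers are extracted behind the promoter anchors,
verified against the scaffold, and matched to the designed pair
reference with a unique-best-match contract.  Read pairs whose two
protospacers come from different designed constructs are recombination
artifacts (PCR/lentiviral template switching) and are tallied, not
counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Iterator

import pandas as pd

from . import grammar
from .models import GuidePair

FATES = ("matched", "recombinant", "no_anchor", "no_scaffold",
         "ambiguous", "unmatched")


@dataclass(frozen=True)
class ReadFate:
    kind: str
    pair_id: str | None = None
    u6_pair_id: str | None = None
    h1_pair_id: str | None = None


def _hamming(a: str, b: str, limit: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def _find_anchored(read: str, anchor: str, max_mismatches: int) -> int:
    """Start of the anchor in the read, or -1; exact find fast path."""
    pos = read.find(anchor)
    if pos >= 0:
        return pos
    if max_mismatches == 0:
        return -1
    n, m = len(read), len(anchor)
    for i in range(0, n - m + 1):
        if _hamming(read[i:i + m], anchor, max_mismatches) <= max_mismatches:
            return i
    return -1


def extract_protospacer(read: str, side: str,
                        max_anchor_mismatches: int = 1) -> tuple[str | None, str | None]:
    """Extract the 20-nt protospacer behind a promoter anchor.

    Returns ``(protospacer, None)`` on success or ``(None, reason)`` with
    reason ``no_anchor`` or ``no_scaffold``.  The 20 bp following the
    protospacer must match the scaffold prefix with <=1 mismatch; the
    tracrRNA identifier at scaffold positions 21-30 is accepted as a
    fallback check.
    """
    read = read.upper()
    if side == "U6":
        anchor, junction = grammar.U6_ANCHOR, grammar.U6_JUNCTION
    elif side == "H1":
        anchor, junction = grammar.H1_ANCHOR, grammar.H1_JUNCTION
    else:
        raise ValueError(f"side must be 'U6' or 'H1', got {side!r}")
    pos = _find_anchored(read, anchor, max_anchor_mismatches)
    if pos < 0:
        return None, "no_anchor"
    p = pos + len(anchor) + len(junction)
    proto = read[p:p + 20]
    if len(proto) < 20 or set(proto) - set("ACGT"):
        return None, "no_scaffold"
    scaffold20 = read[p + 20:p + 40]
    if len(scaffold20) == 20 and _hamming(scaffold20, grammar.SCAFFOLD_PREFIX, 1) <= 1:
        return proto, None
    tracr = read[p + 40:p + 50]
    if len(tracr) == 10 and _hamming(tracr, grammar.TRACR_ID, 1) <= 1:
        return proto, None
    return None, "no_scaffold"


def _mutants(proto: str) -> Iterator[str]:
    for i, base in enumerate(proto):
        for alt in "ACGT":
            if alt != base:
                yield proto[:i] + alt + proto[i + 1:]


class PairedReference:
    """Index of designed pairs: protospacer -> pair_ids, per side.

    A protospacer can serve several designed pairs (the flanking strategy
    reuses guides across its Cartesian product), so matching resolves a
    guide per side first, then intersects the pair sets of the two sides.
    """

    def __init__(self, pairs: Iterable[GuidePair] | pd.DataFrame):
        if isinstance(pairs, pd.DataFrame):
            records = [(str(r.pair_id), str(r.protospacer_u6), str(r.protospacer_h1))
                       for r in pairs.itertuples()]
        else:
            records = [(p.pair_id, p.guide_u6.protospacer, p.guide_h1.protospacer)
                       for p in pairs]
        self.pair_ids: list[str] = []
        self.index: dict[str, dict[str, set[str]]] = {"U6": {}, "H1": {}}
        seen = set()
        for pid, u6, h1 in records:
            if pid in seen:
                raise ValueError(f"duplicate pair_id {pid} in reference")
            seen.add(pid)
            if len(u6) != 20 or len(h1) != 20:
                raise ValueError(f"pair {pid}: protospacers must be 20 nt")
            self.pair_ids.append(pid)
            self.index["U6"].setdefault(u6.upper(), set()).add(pid)
            self.index["H1"].setdefault(h1.upper(), set()).add(pid)

    def match_side(self, proto: str, side: str,
                   max_mismatches: int = 1) -> tuple[str, set[str] | None]:
        """Unique-best-match of one protospacer to the side's guides.

        Returns ``("ok", pair_ids)`` when exactly one reference guide sits
        at the minimal distance <= max_mismatches, ``("ambiguous", None)``
        when several tie, ``("unmatched", None)`` otherwise.
        """
        table = self.index[side]
        hit = table.get(proto)
        if hit is not None:
            return "ok", hit
        if max_mismatches >= 1:
            hits = {m for m in _mutants(proto) if m in table}
            if len(hits) == 1:
                return "ok", table[hits.pop()]
            if len(hits) > 1:
                return "ambiguous", None
        if max_mismatches >= 2:
            best, best_d = [], max_mismatches + 1
            for ref in table:
                d = _hamming(proto, ref, max_mismatches)
                if d < best_d:
                    best, best_d = [ref], d
                elif d == best_d:
                    best.append(ref)
            if best_d <= max_mismatches:
                if len(best) == 1:
                    return "ok", table[best[0]]
                return "ambiguous", None
        return "unmatched", None


def match_pair(p_u6: str, p_h1: str, ref: PairedReference,
               max_mismatches: int = 1) -> ReadFate:
    """Resolve the two extracted protospacers to a read-pair fate."""
    s_u6, set_u6 = ref.match_side(p_u6, "U6", max_mismatches)
    s_h1, set_h1 = ref.match_side(p_h1, "H1", max_mismatches)
    if "ambiguous" in (s_u6, s_h1):
        return ReadFate("ambiguous")
    if "unmatched" in (s_u6, s_h1):
        return ReadFate("unmatched")
    shared = set_u6 & set_h1
    if shared:
        return ReadFate("matched", pair_id=min(shared))
    return ReadFate("recombinant", u6_pair_id=min(set_u6), h1_pair_id=min(set_h1))


def _iter_fastq(path) -> Iterator[tuple[str, str]]:
    import gzip
    from Bio import SeqIO
    path = str(path)
    handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
    with handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield rec.id, str(rec.seq)


def classify_read_pair(seq_u6: str, seq_h1: str, ref: PairedReference,
                       max_anchor_mismatches: int = 1,
                       max_mismatches: int = 1) -> ReadFate:
    p_u6, err_u6 = extract_protospacer(seq_u6, "U6", max_anchor_mismatches)
    p_h1, err_h1 = extract_protospacer(seq_h1, "H1", max_anchor_mismatches)
    if err_u6 == "no_anchor" or err_h1 == "no_anchor":
        return ReadFate("no_anchor")
    if err_u6 or err_h1:
        return ReadFate("no_scaffold")
    return match_pair(p_u6, p_h1, ref, max_mismatches)


def count_sample(reads_u6, reads_h1, ref: PairedReference,
                 max_anchor_mismatches: int = 1,
                 max_mismatches: int = 1) -> tuple[Counter, Counter]:
    """Count matched pairs for one sample and tally every read fate.

    ``reads_u6``/``reads_h1`` are FASTQ paths or parallel iterables of
    (read_id, sequence).  The two files must contain the same number of
    reads, paired in order.
    """
    if isinstance(reads_u6, (str, bytes)) or hasattr(reads_u6, "__fspath__"):
        reads_u6 = _iter_fastq(reads_u6)
    if isinstance(reads_h1, (str, bytes)) or hasattr(reads_h1, "__fspath__"):
        reads_h1 = _iter_fastq(reads_h1)
    counts: Counter = Counter()
    fates: Counter = Counter()
    sentinel = object()
    for r1, r2 in itertools.zip_longest(reads_u6, reads_h1, fillvalue=sentinel):
        if r1 is sentinel or r2 is sentinel:
            raise ValueError("unequal read counts in the two FASTQ inputs")
        fate = classify_read_pair(r1[1], r2[1], ref,
                                  max_anchor_mismatches, max_mismatches)
        fates[fate.kind] += 1
        if fate.kind == "matched":
            counts[fate.pair_id] += 1
    return counts, fates


@dataclass
class PairCountMatrix:
    """Guide-pair x sample count matrix with per-sample read-fate tallies."""

    counts: pd.DataFrame
    fates: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_samples(cls, per_sample: dict[str, tuple[Counter, Counter]],
                     pair_ids: list[str]) -> "PairCountMatrix":
        counts = pd.DataFrame(
            {s: [c.get(p, 0) for p in pair_ids] for s, (c, _) in per_sample.items()},
            index=pd.Index(pair_ids, name="pair_id"), dtype=int)
        fates = pd.DataFrame(
            {s: [f.get(k, 0) for k in FATES] for s, (_, f) in per_sample.items()},
            index=pd.Index(FATES, name="fate"), dtype=int)
        return cls(counts=counts, fates=fates)


def filter_low_coverage(counts: pd.DataFrame, min_count: int,
                        reference_sample: str,
                        region_map: dict[str, str] | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Drop pair rows under-covered in the reference (day-0) sample.

    Returns the filtered matrix and a report with per-region retained
    pair counts and the fraction of regions retaining at least one pair.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    if reference_sample not in counts.columns:
        raise ValueError(f"reference sample {reference_sample!r} absent from counts")
    kept = counts.loc[counts[reference_sample] >= min_count]
    report: dict = {"n_pairs_in": int(len(counts)), "n_pairs_kept": int(len(kept))}
    if region_map:
        regions = sorted(set(region_map.values()))
        retained = Counter(region_map[p] for p in kept.index if p in region_map)
        report["pairs_per_region"] = {r: int(retained.get(r, 0)) for r in regions}
        report["fraction_regions_retained"] = (
            sum(1 for r in regions if retained.get(r, 0) > 0) / len(regions)
            if regions else float("nan"))
    return kept, report
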
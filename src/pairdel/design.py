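"""Paired-guide deletion library design.

Turns target regions plus pre-scored candidate guides into guide pairs
that excise each region, with exact oligo and expression-cassette
sequences.  Efficacy and off-target scores are consumed as inputs (they
come from an external scorer); the filtering rules, pairing strategies
and oligo grammar live here.
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass

from . import grammar
from .models import (
    CandidateGuide,
    ExpressionCassette,
    GuidePair,
    LibraryDesign,
    OligoConstruct,
    TargetRegion,
)

logger = logging.getLogger(__name__)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


_IUPAC_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
               "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
               "D": "H", "H": "D", "N": "N"}


def _iupac_revcomp(pattern: str) -> str:
    return "".join(_IUPAC_COMP[p] for p in reversed(pattern))


def _pam_matches(seq: str, pattern: str) -> bool:
    # a fully degenerate pattern position (N) accepts any base, even N
    return all(p == "N" or base in _IUPAC[p] for base, p in zip(seq, pattern))


def scan_protospacers(seq: str, offset: int = 0, pam_pattern: str = "NGG",
                      chrom: str = "chr1") -> list[CandidateGuide]:
    """Every 20-nt protospacer immediately 5' of a PAM, on both strands.

    The cut site is the blunt-cut coordinate between protospacer positions
    17 and 18, i.e. 3 bp 5' of the PAM start on the protospacer strand.
    Windows containing N are skipped; scores are left unset, to be joined
    from an external score table.
    """
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-DNA characters")
    plen = len(pam_pattern)
    guides: list[CandidateGuide] = []
    # + strand: protospacer [i, i+20), PAM at [i+20, i+20+plen)
    for i in range(0, len(seq) - 20 - plen + 1):
        pam = seq[i + 20:i + 20 + plen]
        window = seq[i:i + 20]
        if "N" in window or not _pam_matches(pam, pam_pattern):
            continue
        cut = offset + i + 17
        guides.append(CandidateGuide(
            guide_id=f"{chrom}:{cut}:+", chrom=chrom, cut_site=cut,
            strand="+", protospacer=window))
    # - strand: PAM reverse complement at [j, j+plen), protospacer [j+plen, j+plen+20)
    rc_pattern = _iupac_revcomp(pam_pattern)
    for j in range(0, len(seq) - 20 - plen + 1):
        pam_rc = seq[j:j + plen]
        window = seq[j + plen:j + plen + 20]
        if "N" in window or not _pam_matches(pam_rc, rc_pattern):
            continue
        cut = offset + j + plen + 3
        guides.append(CandidateGuide(
            guide_id=f"{chrom}:{cut}:-", chrom=chrom, cut_site=cut,
            strand="-", protospacer=grammar.revcomp(window)))
    guides.sort(key=lambda g: (g.cut_site, g.strand))
    return guides


@dataclass(frozen=True)
class FilterThresholds:
    """Score cut-offs for guide selection (all strict inequalities)."""

    min_efficacy: float = 0.15
    max_top5_offtarget: float = 47.0
    max_top10_offtarget: float = 50.0
    min_splice_distance: int = 10


def filter_guides(guides: list[CandidateGuide],
                  exclusions: list[tuple[str, int, int]] | None = None,
                  splice_sites: list[tuple[str, int]] | None = None,
                  thresholds: FilterThresholds | None = None) -> list[CandidateGuide]:
    """Apply the score, exclusion-interval and splice-distance filters.

    Keeps guides with efficacy > 0.15, top-5 off-target total score < 47
    and top-10 < 50 (strict), whose protospacer does not overlap any
    exclusion interval, and whose cut site is at least 10 bp from every
    splice site.  Input order is preserved.
    """
    th = thresholds or FilterThresholds()
    exclusions = exclusions or []
    splice_sites = splice_sites or []
    kept: list[CandidateGuide] = []
    for g in guides:
        for name, value in (("efficacy", g.efficacy),
                            ("top5_offtarget", g.top5_offtarget),
                            ("top10_offtarget", g.top10_offtarget)):
            if value is None:
                raise ValueError(f"guide {g.guide_id} is missing score {name}")
        if not (g.efficacy > th.min_efficacy
                and g.top5_offtarget < th.max_top5_offtarget
                and g.top10_offtarget < th.max_top10_offtarget):
            continue
        s, e = g.protospacer_interval
        if any(c == g.chrom and s < xe and xs < e for c, xs, xe in exclusions):
            continue
        if any(c == g.chrom and abs(g.cut_site - pos) < th.min_splice_distance
               for c, pos in splice_sites):
            continue
        kept.append(g)
    return kept


def _rank_flank(guides: list[CandidateGuide], boundary: int,
                max_n: int) -> list[CandidateGuide]:
    # efficacy descending, then distance to the region boundary ascending,
    # then guide_id for determinism
    return sorted(
        guides,
        key=lambda g: (-(g.efficacy or 0.0), abs(g.cut_site - boundary), g.guide_id),
    )[:max_n]


def design_flanking_pairs(region: TargetRegion, guides: list[CandidateGuide],
                          flank_bp: int = 200,
                          max_per_flank: int = 5) -> list[GuidePair]:
    """Pair guides from the two 200-bp flanks (Cartesian product, <=25 pairs).

    Up to ``max_per_flank`` guides per flank are selected (efficacy-ranked);
    every pair's expected deletion spans both cut sites and therefore
    contains the whole region.
    """
    up = [g for g in guides if g.chrom == region.chrom
          and region.start - flank_bp <= g.cut_site < region.start]
    down = [g for g in guides if g.chrom == region.chrom
            and region.end <= g.cut_site < region.end + flank_bp]
    if not up or not down:
        logger.warning("region %s undesignable by flanking strategy "
                       "(%d upstream / %d downstream guides)",
                       region.region_id, len(up), len(down))
        return []
    up = _rank_flank(up, region.start, max_per_flank)
    down = _rank_flank(down, region.end, max_per_flank)
    pairs = []
    for gu, gh in itertools.product(up, down):
        pairs.append(GuidePair(
            pair_id=f"{region.region_id}|{gu.guide_id}|{gh.guide_id}",
            region_id=region.region_id, guide_u6=gu, guide_h1=gh,
            expected_deletion=(gu.cut_site, gh.cut_site),
            strategy="flanking"))
    return pairs


def design_internal_pairs(region: TargetRegion, guides: list[CandidateGuide],
                          n_target: int = 14) -> list[GuidePair]:
    """Fallback strategy: excise the core of the region.

    In-region guides are split at the region midpoint into 5'- and
    3'-proximal halves; one guide from each half is paired so the deletion
    contains the midpoint.  Pairs are chosen widest-deletion-first (ties
    by pair_id) up to ``n_target``.
    """
    inside = [g for g in guides if g.chrom == region.chrom
              and region.start <= g.cut_site < region.end]
    mid = region.midpoint
    left = [g for g in inside if g.cut_site < mid]
    right = [g for g in inside if g.cut_site >= mid]
    if not left or not right:
        logger.warning("region %s undesignable by internal strategy "
                       "(%d left / %d right of midpoint)",
                       region.region_id, len(left), len(right))
        return []
    candidates = []
    for gl, gr in itertools.product(left, right):
        if not (gl.cut_site <= mid <= gr.cut_site and gl.cut_site < gr.cut_site):
            continue
        pid = f"{region.region_id}|{gl.guide_id}|{gr.guide_id}"
        candidates.append((gr.cut_site - gl.cut_site, pid, gl, gr))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return [GuidePair(pair_id=pid, region_id=region.region_id,
                      guide_u6=gl, guide_h1=gr,
                      expected_deletion=(gl.cut_site, gr.cut_site),
                      strategy="internal")
            for _, pid, gl, gr in candidates[:n_target]]


def assemble_oligo(pair: GuidePair, version: str,
                   barcode: str | None = None) -> OligoConstruct:
    """Emit the exact synthesized-oligo string for one pair."""
    seq = grammar.assemble_oligo_sequence(
        pair.guide_u6.protospacer, pair.guide_h1.protospacer, version, barcode)
    return OligoConstruct(pair_id=pair.pair_id, version=version,
                          sequence=seq, barcode=(barcode or "") if version == "v2" else "")


def build_expression_cassette(pair: GuidePair, version: str) -> ExpressionCassette:
    """Post-cloning cassette with convergent promoters and dual scaffolds."""
    seq = grammar.build_cassette_sequence(
        pair.guide_u6.protospacer, pair.guide_h1.protospacer, version)
    return ExpressionCassette(pair_id=pair.pair_id, version=version,
                              sequence=seq,
                              scaffold_gap=grammar.SCAFFOLD_GAP[version])


def generate_barcodes(n: int, seed: int = 0, length: int = 10,
                      min_hamming: int = 2, max_homopolymer: int = 3,
                      max_attempts: int = 1_000_000) -> list[str]:
    """Random barcodes with no homopolymer run >= 4 and pairwise Hamming >= 2."""
    rng = random.Random(seed)
    accepted: list[str] = []
    attempts = 0
    while len(accepted) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("barcode space exhausted under the given constraints")
        bc = "".join(rng.choice("ACGT") for _ in range(length))
        if any(base * (max_homopolymer + 1) in bc for base in "ACGT"):
            continue
        if any(sum(a != b for a, b in zip(bc, prev)) < min_hamming
               for prev in accepted):
            continue
        accepted.append(bc)
    return accepted


def expected_coverage(n_cells: float, moi: float, n_constructs: int) -> float:
    """Expected per-construct cell coverage of a pooled screen infection."""
    if n_constructs <= 0:
        raise ValueError("n_constructs must be positive")
    return n_cells * moi / n_constructs


def build_library(regions: list[TargetRegion], guides: list[CandidateGuide],
                  version: str = "v2",
                  controls: list[GuidePair] | None = None,
                  exclusions: list[tuple[str, int, int]] | None = None,
                  splice_sites: list[tuple[str, int]] | None = None,
                  thresholds: FilterThresholds | None = None,
                  flank_bp: int = 200, max_per_flank: int = 5,
                  n_internal: int = 14, seed: int = 0) -> LibraryDesign:
    """Run the full design: filter -> flanking, internal fallback, controls.

    Guide pairs with identical protospacer pairs are deduplicated to the
    lexically first pair_id.  v2 libraries get unique 10-nt barcodes.
    """
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate region_id(s): {dupes}")
    controls = list(controls or [])
    warnings: list[str] = []
    if not controls:
        warnings.append("control list is empty")
        logger.warning("building library without control guide pairs")

    passed = filter_guides(guides, exclusions, splice_sites, thresholds)
    # protospacers carrying vector-opening type-IIS sites cannot be cloned
    clean = []
    for g in passed:
        enzyme = grammar.forbidden_site_in(g.protospacer)
        if enzyme:
            warnings.append(f"guide {g.guide_id} dropped: {enzyme} site in protospacer")
        else:
            clean.append(g)

    pairs: list[GuidePair] = []
    strategy_by_region: dict[str, str] = {}
    for region in regions:
        region_pairs = design_flanking_pairs(region, clean, flank_bp, max_per_flank)
        strategy = "flanking"
        if not region_pairs:
            region_pairs = design_internal_pairs(region, clean, n_internal)
            strategy = "internal" if region_pairs else "undesignable"
        if strategy == "undesignable":
            warnings.append(f"region {region.region_id} undesignable by either strategy")
        strategy_by_region[region.region_id] = strategy
        pairs.extend(region_pairs)

    seen: dict[tuple[str, str], str] = {}
    deduped: list[GuidePair] = []
    for pair in pairs:
        key = (pair.guide_u6.protospacer, pair.guide_h1.protospacer)
        if key in seen:
            warnings.append(f"pair {pair.pair_id} deduplicated into {seen[key]}")
            continue
        seen[key] = pair.pair_id
        deduped.append(pair)

    everything = deduped + controls
    oligos: list[OligoConstruct] = []
    if version == "v2":
        barcodes = generate_barcodes(len(everything), seed=seed)
        for pair, bc in zip(everything, barcodes):
            oligos.append(assemble_oligo(pair, "v2", bc))
    else:
        for pair in everything:
            oligos.append(assemble_oligo(pair, "v1"))

    return LibraryDesign(regions=regions, pairs=deduped, oligos=oligos,
                         controls=controls, version=version,
                         strategy_by_region=strategy_by_region,
                         warnings=warnings)
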
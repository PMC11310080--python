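"""Ground-truth simulators for every pipeline stage.

The generators emulate the statistical structure the pipeline assumes:
random target regions with enough PAM sites per flank, Dirichlet-
multinomial day-0 screen abundances with negative-binomial later
time points, amplicon read pairs carrying the exact cassette grammar
(with stagger prefixes, substitution errors and cross-construct
recombination), and negative-binomial single-cell matrices with planted
cis knockdowns.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from . import grammar
from .design import scan_protospacers
from .models import CandidateGuide, GuidePair, TargetRegion

STAGGER_SET = ("", "T", "AC", "GAT", "TCGA", "ACGTC", "GATCGA", "TCGATCG")

_REALISTIC_SCORES = {
    "efficacy": lambda rng, n: rng.uniform(0.0, 1.0, n),
    "top5_offtarget": lambda rng, n: 94.0 * rng.beta(2, 2, n),
    "top10_offtarget": lambda rng, n: 100.0 * rng.beta(2, 2, n),
}
_PERMISSIVE_SCORES = {
    "efficacy": lambda rng, n: rng.uniform(0.2, 1.0, n),
    "top5_offtarget": lambda rng, n: rng.uniform(0.0, 40.0, n),
    "top10_offtarget": lambda rng, n: rng.uniform(0.0, 45.0, n),
}
SCORE_DISTRIBUTIONS = {"realistic": _REALISTIC_SCORES,
                       "permissive": _PERMISSIVE_SCORES}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def simulate_design_inputs(n_regions: int, guides_per_flank: int = 10,
                           region_len: int = 300, flank_bp: int = 200,
                           pad: int = 50,
                           score_distributions: str | dict = "realistic",
                           seed: int = 0) -> dict:
    """Random region sequences with guaranteed candidate counts per flank.

    Each region gets its own synthetic contig: pad | flank | body | flank
    | pad.  Flank sequences are redrawn until the NGG scan yields at
    least ``guides_per_flank`` candidate cut sites in each flank (a
    planted-construction guarantee).  Scores are drawn from the named or
    supplied distributions.  Returns a dict with ``regions``, ``guides``
    and ``sequences`` (contig -> sequence).
    """
    if isinstance(score_distributions, str):
        score_distributions = SCORE_DISTRIBUTIONS[score_distributions]
    rng = np.random.default_rng(seed)
    regions: list[TargetRegion] = []
    guides: list[CandidateGuide] = []
    sequences: dict[str, str] = {}
    for i in range(n_regions):
        chrom = f"sim{i:05d}"
        start = pad + flank_bp
        end = start + region_len
        total = 2 * pad + 2 * flank_bp + region_len
        for _attempt in range(200):
            seq = _random_seq(rng, total)
            found = scan_protospacers(seq, offset=0, chrom=chrom)
            up = [g for g in found if start - flank_bp <= g.cut_site < start]
            down = [g for g in found if end <= g.cut_site < end + flank_bp]
            if len(up) >= guides_per_flank and len(down) >= guides_per_flank:
                break
        else:  # pragma: no cover - 200 redraws virtually never exhausted
            raise RuntimeError(f"could not plant {guides_per_flank} guides per flank")
        sequences[chrom] = seq
        regions.append(TargetRegion(region_id=f"region{i:05d}", chrom=chrom,
                                    start=start, end=end))
        candidates = up[:guides_per_flank * 2] + down[:guides_per_flank * 2]
        n = len(candidates)
        scores = {name: fn(rng, n) for name, fn in score_distributions.items()}
        for j, g in enumerate(candidates):
            guides.append(CandidateGuide(
                guide_id=g.guide_id, chrom=g.chrom, cut_site=g.cut_site,
                strand=g.strand, protospacer=g.protospacer,
                efficacy=float(scores["efficacy"][j]),
                top5_offtarget=float(scores["top5_offtarget"][j]),
                top10_offtarget=float(scores["top10_offtarget"][j])))
    return {"regions": regions, "guides": guides, "sequences": sequences}


def make_simple_library(n_regions: int, pairs_per_region: int,
                        seed: int = 0) -> tuple[list[GuidePair], dict[str, str]]:
    """Abstract library for count-level simulations: random unique guides.

    Returns (pairs, pair -> region map).  Protospacers are random and
    unique per pair so that count-level statistics are not confounded by
    guide sharing.
    """
    rng = np.random.default_rng(seed)
    pairs: list[GuidePair] = []
    region_map: dict[str, str] = {}
    seen: set[str] = set()

    def fresh() -> str:
        while True:
            p = _random_seq(rng, 20)
            if p not in seen and grammar.forbidden_site_in(p) is None:
                seen.add(p)
                return p

    for i in range(n_regions):
        rid = f"region{i:05d}"
        for j in range(pairs_per_region):
            pid = f"{rid}_p{j:02d}"
            u6 = CandidateGuide(guide_id=f"{pid}_u6", chrom=rid,
                                cut_site=100 + j, strand="+", protospacer=fresh())
            h1 = CandidateGuide(guide_id=f"{pid}_h1", chrom=rid,
                                cut_site=500 + j, strand="-", protospacer=fresh())
            pairs.append(GuidePair(pair_id=pid, region_id=rid, guide_u6=u6,
                                   guide_h1=h1, expected_deletion=(100 + j, 500 + j),
                                   strategy="flanking"))
            region_map[pid] = rid
    return pairs, region_map


def simulate_screen_counts(region_map: dict[str, str],
                           effects: dict[str, dict[str, float]],
                           depth_per_pair: float = 400.0,
                           dispersion: float = 0.05,
                           days: dict[str, float] | None = None,
                           dirichlet_conc: float = 50.0,
                           seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Screen count table: day0 + one column per later sample.

    ``effects[region][sample]`` is the per-day log2 selection effect of
    the region's pairs in that sample (0 or absent = neutral).  Day-0
    counts are Dirichlet-multinomial; later samples scale the expected
    abundance by 2^(effect * days) and draw negative-binomial counts at
    the given dispersion.  Returns (counts, truth dict).
    """
    days = days or {"day15": 15.0}
    pair_ids = sorted(region_map)
    n = len(pair_ids)
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(n, dirichlet_conc))
    total = int(round(depth_per_pair * n))
    counts = {"day0": rng.multinomial(total, p)}
    for sample, n_days in days.items():
        eff = np.array([effects.get(region_map[pid], {}).get(sample, 0.0)
                        for pid in pair_ids])
        w = p * np.power(2.0, eff * n_days)
        mu = total * w / w.sum()
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        else:
            lam = mu
        counts[sample] = rng.poisson(lam)
    df = pd.DataFrame(counts, index=pd.Index(pair_ids, name="pair_id"))
    truth = {"seed": seed, "effects": effects, "days": days,
             "depth_per_pair": depth_per_pair, "dispersion": dispersion}
    return df, truth


def simulate_amplicon_reads(pairs: Iterable[GuidePair],
                            region_map: dict[str, str],
                            n_reads: int,
                            abundances: np.ndarray | None = None,
                            recomb_rate: float = 0.0,
                            error_rate: float = 0.0,
                            stagger_set: tuple[str, ...] = STAGGER_SET,
                            scaffold_bp: int = 40,
                            seed: int = 0) -> tuple[list, list, dict]:
    """Paired amplicon reads embedding the exact cassette grammar.

    Each read pair is drawn from a construct (multinomially, by
    ``abundances``).  With probability ``recomb_rate`` the H1-side
    protospacer is swapped with that of a construct from a *different*
    region (template-switching artifact observable as a recombinant
    fate).  Per-base substitution errors at ``error_rate``; a random
    stagger prefix from ``stagger_set`` phases each read.  Returns
    (u6_reads, h1_reads, truth) where reads are (read_id, sequence).
    """
    pairs = list(pairs)
    n_constructs = len(pairs)
    rng = np.random.default_rng(seed)
    if abundances is None:
        abundances = np.full(n_constructs, 1.0 / n_constructs)
    abundances = np.asarray(abundances, dtype=float)
    if not math.isclose(abundances.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("abundances must sum to 1")
    u6_prefix = grammar.U6_ANCHOR + grammar.U6_JUNCTION
    h1_prefix = grammar.H1_ANCHOR + grammar.H1_JUNCTION
    scaffold = grammar.SCAFFOLD[:scaffold_bp]
    bases = np.array(list("ACGT"))

    # recombination donors are drawn from a different region: within a
    # region the Cartesian-product design shares guides across pairs, so a
    # same-region swap could still resolve to a designed pair and would not
    # be observable as recombinant
    n_regions = len({p.region_id for p in pairs})
    region_of = np.array([p.region_id for p in pairs])

    draws = rng.choice(n_constructs, size=n_reads, p=abundances)
    recomb = rng.random(n_reads) < recomb_rate
    source_counts = np.bincount(draws, minlength=n_constructs)
    matched_counts = np.zeros(n_constructs, dtype=int)
    u6_reads, h1_reads = [], []
    n_recombined = 0
    for i in range(n_reads):
        construct = pairs[draws[i]]
        proto_u6 = construct.guide_u6.protospacer
        proto_h1 = construct.guide_h1.protospacer
        if recomb[i] and n_regions > 1:
            while True:
                donor = int(rng.integers(0, n_constructs))
                if region_of[donor] != construct.region_id:
                    break
            proto_h1 = pairs[donor].guide_h1.protospacer
            n_recombined += 1
        else:
            matched_counts[draws[i]] += 1
        s1 = stagger_set[rng.integers(0, len(stagger_set))]
        s2 = stagger_set[rng.integers(0, len(stagger_set))]
        r1 = s1 + u6_prefix + proto_u6 + scaffold
        r2 = s2 + h1_prefix + proto_h1 + scaffold
        if error_rate > 0:
            r1 = _mutate(r1, error_rate, rng, bases)
            r2 = _mutate(r2, error_rate, rng, bases)
        u6_reads.append((f"read{i:07d}", r1))
        h1_reads.append((f"read{i:07d}", r2))
    truth = {"seed": seed, "recomb_rate": recomb_rate,
             "error_rate": error_rate, "n_reads": n_reads,
             "n_recombined": n_recombined,
             "source_counts": {pairs[j].pair_id: int(source_counts[j])
                               for j in range(n_constructs)},
             "matched_truth": {pairs[j].pair_id: int(matched_counts[j])
                               for j in range(n_constructs)}}
    return u6_reads, h1_reads, truth


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            bases: np.ndarray) -> str:
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        alt = bases[bases != arr[i]]
        arr[i] = alt[rng.integers(0, 3)]
    return "".join(arr)


def simulate_single_cell(targets: list[str], cells_per_target: int = 150,
                         n_control_cells: int = 4000, n_genes: int = 50,
                         control_pair: str = "ctrl_pair",
                         cis_effects: dict[str, dict[str, float]] | None = None,
                         multiplet_rate: float = 0.0,
                         mean_depth: float = 2000.0,
                         gene_dispersion: float = 0.3,
                         capture_umi: float = 12.0,
                         capture_background: float = 0.02,
                         seed: int = 0) -> dict:
    """Gene-expression and guide-capture matrices with planted cis effects.

    Baseline counts are negative binomial with gene-specific lognormal
    means and per-cell depth factors; perturbed cells scale their cis
    target genes' means by (1 - knockdown).  Capture UMIs place the
    cell's pair high with Poisson background on other guides; multiplets
    carry two pairs.  Gene coordinates are laid out every 100 kb on one
    synthetic chromosome so cis-window logic is exercisable.
    """
    cis_effects = cis_effects or {}
    rng = np.random.default_rng(seed)
    gene_names = [f"gene{i:04d}" for i in range(n_genes)]
    gene_ann = pd.DataFrame({
        "gene": gene_names, "chrom": "simchr",
        "start": 100_000 * np.arange(n_genes),
        "end": 100_000 * np.arange(n_genes) + 20_000})
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    base_mean *= mean_depth / base_mean.sum()

    labels: list[str] = []
    for t in targets:
        labels += [t] * cells_per_target
    labels += [control_pair] * n_control_cells
    n_cells = len(labels)
    cell_ids = [f"cell{i:06d}" for i in range(n_cells)]
    is_multiplet = rng.random(n_cells) < multiplet_rate
    all_pairs = list(targets) + [control_pair]
    second = []
    for lab in labels:  # a multiplet's second construct differs from the first
        others = [p for p in all_pairs if p != lab] or [lab]
        second.append(others[rng.integers(0, len(others))])

    depth = rng.lognormal(mean=0.0, sigma=0.3, size=n_cells)
    mean_mat = np.tile(base_mean[:, None], (1, n_cells))
    for target, per_gene in cis_effects.items():
        cols = [i for i, lab in enumerate(labels) if lab == target]
        for gene, kd in per_gene.items():
            gi = gene_names.index(gene)
            mean_mat[gi, cols] *= (1.0 - kd)
    mu = mean_mat * depth[None, :]
    lam = rng.gamma(shape=1.0 / gene_dispersion, scale=mu * gene_dispersion)
    expr = rng.poisson(lam)
    expression = pd.DataFrame(expr, index=gene_names, columns=cell_ids)

    features = [f"{p}_{side}" for p in all_pairs for side in ("u6", "h1")]
    capture = rng.poisson(capture_background, size=(len(features), n_cells))
    feat_idx = {f: i for i, f in enumerate(features)}
    for ci, lab in enumerate(labels):
        for side in ("u6", "h1"):
            capture[feat_idx[f"{lab}_{side}"], ci] += rng.poisson(capture_umi / 2) + 1
        if is_multiplet[ci] and second[ci] != lab:
            for side in ("u6", "h1"):
                capture[feat_idx[f"{second[ci]}_{side}"], ci] += (
                    rng.poisson(capture_umi / 2) + 1)
    capture_df = pd.DataFrame(capture, index=features, columns=cell_ids)
    pair_of_guide = {f: f.rsplit("_", 1)[0] for f in features}
    truth = {"seed": seed, "labels": dict(zip(cell_ids, labels)),
             "multiplet": dict(zip(cell_ids, map(bool, is_multiplet))),
             "cis_effects": cis_effects, "control_pair": control_pair}
    return {"expression": expression, "capture": capture_df,
            "pair_of_guide": pair_of_guide, "gene_annotations": gene_ann,
            "truth": truth}
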
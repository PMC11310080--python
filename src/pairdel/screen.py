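"""Region-level screen statistics.

Counts are normalized with median-ratio size factors, guide pairs are
scored by log2 fold change against the day-0 reference, and region-level
depletion is called with alpha-RRA: for a region whose k pairs sit at
global rank percentiles u(1) <= ... <= u(k), only percentiles below
``alpha`` are considered and

    rho = min_j  P( Beta(j, k - j + 1) <= u(j) )

i.e. the smallest tail probability of a uniform order statistic.  A small
rho means the region's pairs are jointly more depleted than chance.
Permutation p-values resample k percentiles without replacement; BH
controls the FDR across regions.

Per-condition selection coefficients ("beta scores") are robust median
log2-fold-change estimates relative to day 0; drug interactions are
called from the treated/untreated betas and their population spread.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def normalize_median_ratio(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-ratio size factors (computed over all-positive pairs).

    Returns (normalized counts, size factors).  The size factor of a
    sample is the median over pairs of count / geometric-mean(count
    across samples), restricted to pairs positive in every sample.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no pair has positive counts in every sample; add a pseudocount "
            "before normalizing")
    sub = mat[positive]
    log_gm = np.log(sub).mean(axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    size_factors = pd.Series(np.median(ratios, axis=0), index=counts.columns,
                             name="size_factor")
    norm = counts / size_factors
    return norm, size_factors


def score_guides(norm: pd.DataFrame, sample_a: str, sample_b: str,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-pair log2 fold change (b vs a) with ascending depletion ranks.

    Rank 1 is the most depleted pair; ties break by pair_id.  The
    percentile of a pair is rank / m.
    """
    for s in (sample_a, sample_b):
        if s not in norm.columns:
            raise ValueError(f"sample {s!r} absent from normalized counts")
    score = np.log2((norm[sample_b] + pseudocount) / (norm[sample_a] + pseudocount))
    df = pd.DataFrame({"score": score})
    df["_tie"] = df.index.astype(str)
    df = df.sort_values(["score", "_tie"]).drop(columns="_tie")
    df["rank"] = np.arange(1, len(df) + 1)
    df["percentile"] = df["rank"] / len(df)
    return df


def rra_rho(percentiles: np.ndarray, k: int, alpha: float) -> float:
    """alpha-RRA score for one region given its k sorted percentiles."""
    u = np.sort(np.asarray(percentiles, dtype=float))
    j = np.arange(1, k + 1)
    considered = u < alpha
    if not considered.any():
        return 1.0
    tails = stats.beta.cdf(u[considered], j[considered], k - j[considered] + 1)
    return float(tails.min())


def _null_rho(percentiles: np.ndarray, k: int, alpha: float, n_perm: int,
              rng: np.random.Generator) -> np.ndarray:
    """Null rho draws: random k-subsets of percentiles, without replacement."""
    percentiles = np.asarray(percentiles, dtype=float)
    m = len(percentiles)
    if m <= 2048:
        # argsort of uniform noise = uniform permutation; take the first k
        idx = np.argsort(rng.random((n_perm, m)), axis=1)[:, :k]
    else:
        # rejection sampling: redraw the few rows with duplicate indices
        idx = rng.integers(0, m, size=(n_perm, k))
        while k > 1:
            bad = (np.diff(np.sort(idx, axis=1), axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            idx[bad] = rng.integers(0, m, size=(int(bad.sum()), k))
    u = np.sort(percentiles[idx], axis=1)
    j = np.arange(1, k + 1)
    tails = stats.beta.cdf(u, j[None, :], (k - j + 1)[None, :])
    tails[u >= alpha] = 1.0
    out = tails.min(axis=1)
    out[(u >= alpha).all(axis=1)] = 1.0
    return out


def adaptive_alpha(scores: np.ndarray, z_cut: float = -1.645) -> float:
    """Fraction of guides significantly depleted, by robust z-score.

    The considered-percentile threshold of alpha-RRA is tied to the
    fraction of guides that look genuinely depleted (score below
    median + z_cut * 1.4826 MAD), the convention of the screen-analysis
    tool family this follows.  A fixed alpha admits coincidental mild
    joint depletion of a region's guides and cannot keep the region-level
    false-call rate low; the adaptive threshold restricts aggregation to
    the depleted tail.
    """
    scores = np.asarray(scores, dtype=float)
    mad = stats.median_abs_deviation(scores, scale="normal")
    if mad == 0:
        return 0.0
    z = (scores - np.median(scores)) / mad
    return float((z < z_cut).mean())


def alpha_rra(ranks: pd.DataFrame, region_map: dict[str, str],
              alpha: float | str = "adaptive", n_perm: int = 1000,
              seed: int = 0, cutoff: float = 0.01) -> pd.DataFrame:
    """Aggregate pair percentiles to region-level depletion calls.

    ``alpha`` may be a fixed fraction or ``"adaptive"`` (default), which
    derives the considered-percentile threshold from the fraction of
    significantly depleted guides.  Permutation p-values draw random
    k-subsets of all pair percentiles (shared across regions of equal
    size, add-one smoothed); fdr is the BH adjustment of p_perm across
    regions; ``significant`` applies the rho cutoff (default 0.01).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if alpha == "adaptive":
        alpha = adaptive_alpha(ranks["score"].to_numpy())
    percentiles_all = ranks["percentile"].to_numpy()
    groups: dict[str, np.ndarray] = {}
    for pair_id, u in ranks["percentile"].items():
        region = region_map.get(pair_id)
        if region is None:
            continue
        groups.setdefault(region, [])
        groups[region].append(u)
    rng = np.random.default_rng(seed)
    rows = []
    null_by_k: dict[int, np.ndarray] = {}
    for region in sorted(groups):
        u = np.asarray(groups[region])
        k = len(u)
        rho = rra_rho(u, k, alpha)
        if k not in null_by_k:
            null_by_k[k] = _null_rho(percentiles_all, k, alpha, n_perm, rng)
        p_perm = (1 + int((null_by_k[k] <= rho).sum())) / (n_perm + 1)
        rows.append((region, k, rho, p_perm))
    if not rows:
        return pd.DataFrame(columns=["region_id", "k", "rho", "p_perm", "fdr",
                                     "significant"]).set_index("region_id")
    out = pd.DataFrame(rows, columns=["region_id", "k", "rho", "p_perm"])
    out["fdr"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    out["significant"] = out["rho"] < cutoff
    return out.set_index("region_id")


def estimate_beta_scores(norm: pd.DataFrame, condition_map: dict[str, str],
                         region_map: dict[str, str], reference: str = "day0",
                         pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-region, per-condition selection coefficients.

    beta(region, condition) is the median over the region's pairs of the
    mean (over the condition's samples) log2 fold change versus the
    reference condition -- a robust selection coefficient relative to the
    initial population.  Regions without pairs in the matrix are excluded.
    """
    conditions = sorted(set(condition_map.values()) - {reference})
    ref_samples = [s for s, c in condition_map.items() if c == reference]
    if not ref_samples:
        raise ValueError(f"no sample maps to reference condition {reference!r}")
    if not conditions:
        raise ValueError("need at least one non-reference condition")
    ref = norm[ref_samples].mean(axis=1)
    lfc = {}
    for cond in conditions:
        samples = [s for s, c in condition_map.items() if c == cond]
        per_sample = [np.log2((norm[s] + pseudocount) / (ref + pseudocount))
                      for s in samples]
        lfc[cond] = pd.concat(per_sample, axis=1).mean(axis=1)
    lfc_df = pd.DataFrame(lfc)
    regions = pd.Series({p: region_map[p] for p in lfc_df.index if p in region_map},
                        name="region_id")
    betas = lfc_df.loc[regions.index].groupby(regions).median()
    betas.index.name = "region_id"
    return betas


def classify_drug_interactions(betas: pd.DataFrame, treated: str = "treated",
                               untreated: str = "untreated",
                               k_treated_sd: float = 2.0,
                               k_control_sd: float = 1.0,
                               k_diff_sd: float = 1.0) -> pd.DataFrame:
    """Call drug-resistant / drug-sensitizing regions from beta scores.

    A region is *resistant* when its treated beta exceeds the population
    mean by more than ``k_treated_sd`` s.d., its untreated beta stays
    within ``k_control_sd`` s.d. of the untreated mean, and its
    differential beta (treated - untreated) exceeds the differential mean
    by more than ``k_diff_sd`` s.d.; *sensitizing* is the mirror image.
    """
    for col in (treated, untreated):
        if col not in betas.columns:
            raise ValueError(f"condition {col!r} absent from beta table")
    bt, bu = betas[treated], betas[untreated]
    diff = bt - bu
    mt, st = bt.mean(), bt.std(ddof=1)
    mu, su = bu.mean(), bu.std(ddof=1)
    md, sd = diff.mean(), diff.std(ddof=1)
    control_ok = (bu - mu).abs() <= k_control_sd * su
    resistant = (bt > mt + k_treated_sd * st) & control_ok & (diff > md + k_diff_sd * sd)
    sensitizing = (bt < mt - k_treated_sd * st) & control_ok & (diff < md - k_diff_sd * sd)
    call = pd.Series("none", index=betas.index, name="call")
    call[resistant] = "resistant"
    call[sensitizing] = "sensitizing"
    out = pd.DataFrame({"beta_treated": bt, "beta_untreated": bu,
                        "differential": diff, "call": call})
    out.attrs["thresholds"] = {
        "k_treated_sd": k_treated_sd, "k_control_sd": k_control_sd,
        "k_diff_sd": k_diff_sd, "mean_treated": mt, "sd_treated": st,
        "mean_untreated": mu, "sd_untreated": su,
        "mean_diff": md, "sd_diff": sd}
    return out
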
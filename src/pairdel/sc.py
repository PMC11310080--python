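"""Single-cell deletion-perturbation analysis.

Cells are assigned a deletion perturbation from dual-guide capture UMIs
(dominant-pair rule with multiplet filtering), expression is depth
normalized (LogNormalize, scale factor 10,000), and NCRE-gene regulation
is tested with a two-part hurdle model: a logistic detection component
and a Gaussian component on log-normalized expression among detected
cells, both adjusted for the per-cell log number of expressed genes and
log number of guides detected.  The two deviance drops from removing the
group term are summed and referred to a chi-square with 2 df.  Cis
windows (TAD or +/-1 Mb) narrow the genes reported per region.
"""

from __future__ import annotations

import logging
import warnings as _warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import TargetRegion

logger = logging.getLogger(__name__)

SCALE_FACTOR = 10_000.0


def assign_perturbations(capture: pd.DataFrame, pair_of_guide: dict[str, str],
                         expression: pd.DataFrame, min_umi: int = 3,
                         dominance: float = 0.8) -> pd.DataFrame:
    """Per-cell perturbation identity from guide-capture UMIs.

    Pair-level UMI is the sum of the pair's guide UMIs.  A cell is
    assigned to its top pair when that pair reaches ``min_umi`` UMIs and
    holds at least a ``dominance`` fraction of all pair UMIs; two or more
    pairs above ``min_umi`` without dominance is a multiplet; otherwise
    the cell is unassigned.  Covariates (natural-log total expressed
    genes, natural-log total guides detected) come from the expression
    and capture matrices.
    """
    missing = [c for c in capture.columns if c not in expression.columns]
    if missing:
        raise ValueError(f"cell barcodes absent from expression matrix: {missing[:10]}")
    unknown = [g for g in capture.index if g not in pair_of_guide]
    if unknown:
        raise ValueError(f"capture features not in the design: {unknown[:10]}")
    pair_ids = pd.Index(sorted(set(pair_of_guide.values())))
    pair_umi = capture.groupby(capture.index.map(pair_of_guide)).sum()
    pair_umi = pair_umi.reindex(pair_ids, fill_value=0)

    rows = []
    for cell in capture.columns:
        umis = pair_umi[cell]
        total = umis.sum()
        n_pass = int((umis >= min_umi).sum())
        top = umis.idxmax() if total > 0 else None
        if total > 0 and umis[top] >= min_umi and umis[top] >= dominance * total:
            label = top
        elif n_pass >= 2:
            label = "multiplet"
        else:
            label = "unassigned"
        n_genes = int((expression[cell] > 0).sum())
        n_guides = int((capture[cell] > 0).sum())
        rows.append((cell, label,
                     float(np.log(max(n_genes, 1))),
                     float(np.log(max(n_guides, 1)))))
    return pd.DataFrame(rows, columns=["cell", "label", "log_genes",
                                       "log_guides"]).set_index("cell")


def lognormalize_cells(counts: pd.DataFrame) -> pd.DataFrame:
    """ln(1 + scale * count / cell_total), zero-total cells dropped."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index
    if len(zero):
        logger.warning("dropping %d zero-total cells", len(zero))
        counts = counts.drop(columns=zero)
        totals = totals.drop(zero)
    return np.log1p(counts * (SCALE_FACTOR / totals))


def _binomial_lrt(detected: np.ndarray, group: np.ndarray) -> float:
    """Closed-form 1-df LRT for a detection-rate difference (fallback)."""
    def loglik(k, n):
        if n == 0 or k == 0 or k == n:
            return 0.0
        p = k / n
        return k * np.log(p) + (n - k) * np.log(1 - p)
    n1, n0 = int(group.sum()), int((~group).sum())
    k1, k0 = int(detected[group].sum()), int(detected[~group].sum())
    full = loglik(k1, n1) + loglik(k0, n0)
    reduced = loglik(k1 + k0, n1 + n0)
    return 2.0 * (full - reduced)


def hurdle_de(norm: pd.DataFrame, assignment: pd.DataFrame, target: str,
              control_label: str, min_mean_expr: float = 0.01,
              min_detect_frac: float = 0.05) -> pd.DataFrame:
    """Two-part hurdle differential expression, perturbed vs control cells.

    Genes with mean normalized expression below ``min_mean_expr`` across
    the tested cells, or detected in fewer than ``min_detect_frac`` of
    cells in both groups, are skipped.  The LRT statistic is the sum of
    the detection-part and continuous-part deviance drops (chi-square,
    2 df); on logistic separation or an unfittable continuous part the
    detection-only fallback (1 df) is used and flagged.  Log2 fold change
    compares group means of normalized expression.  BH adjusts across
    the tested genes.
    """
    perturbed = assignment.index[assignment["label"] == target]
    control = assignment.index[assignment["label"] == control_label]
    if len(perturbed) < 2 or len(control) < 2:
        raise ValueError("need at least two cells in each group")
    cells = perturbed.append(control)
    group = np.concatenate([np.ones(len(perturbed), bool),
                            np.zeros(len(control), bool)])
    covs = assignment.loc[cells, ["log_genes", "log_guides"]].to_numpy()
    covs = covs - covs.mean(axis=0)  # centering stabilizes the logistic fit
    sub = norm[cells]

    x_full = np.column_stack([np.ones(len(cells)), group.astype(float), covs])
    x_red = x_full[:, [0, 2, 3]]
    rows = []
    for gene in sub.index:
        y = sub.loc[gene].to_numpy(dtype=float)
        if y.mean() < min_mean_expr:
            continue
        det = y > 0
        frac_p = det[group].mean()
        frac_c = det[~group].mean()
        if frac_p < min_detect_frac and frac_c < min_detect_frac:
            continue
        lrt, df, fallback = _fit_gene(y, det, group, x_full, x_red)
        p = float(stats.chi2.sf(lrt, df))
        mean_p = y[group].mean()
        mean_c = y[~group].mean()
        eps = 1e-9
        lfc = float(np.log2((mean_p + eps) / (mean_c + eps)))
        rows.append((gene, lrt, df, p, lfc, mean_p, mean_c, fallback))
    out = pd.DataFrame(rows, columns=["gene", "lrt", "df", "p", "lfc",
                                      "mean_perturbed", "mean_control",
                                      "fallback"]).set_index("gene")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out


def _fit_gene(y, det, group, x_full, x_red):
    """Detection + continuous LRT for one gene; returns (lrt, df, fallback)."""
    det_f = det.astype(float)
    all_detected = det.all()
    lrt_det = 0.0
    fallback = False
    if not all_detected:
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                full = sm.GLM(det_f, x_full, family=sm.families.Binomial()).fit(
                    maxiter=50, tol=1e-8)
                red = sm.GLM(det_f, x_red, family=sm.families.Binomial()).fit(
                    maxiter=50, tol=1e-8)
            lrt_det = max(red.deviance - full.deviance, 0.0)
            if not np.isfinite(lrt_det) or abs(full.params[1]) > 30:
                raise np.linalg.LinAlgError("separation")
        except Exception:
            return _binomial_lrt(det, group), 1, True
    # continuous part among detected cells
    n_det = int(det.sum())
    if n_det < 6 or det[group].sum() < 2 or det[~group].sum() < 2:
        if all_detected:
            return 0.0, 1, True
        return _binomial_lrt(det, group), 1, True
    yc = y[det]
    xf, xr = x_full[det], x_red[det]
    beta_f, rss_f = _ols_rss(xf, yc)
    beta_r, rss_r = _ols_rss(xr, yc)
    rss_f = max(rss_f, 1e-12)
    lrt_cont = max(n_det * np.log(rss_r / rss_f), 0.0)
    return float(lrt_det + lrt_cont), 2, fallback


def _ols_rss(x, y):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float(resid @ resid)


def cis_window_report(results: pd.DataFrame, region: TargetRegion,
                      gene_annotations: pd.DataFrame,
                      tads: list[tuple[str, int, int]] | None = None,
                      window_bp: int = 1_000_000) -> pd.DataFrame:
    """Genes near the region (TAD if available, else +/-window) with DE results.

    ``gene_annotations`` needs columns gene, chrom, start, end.  A gene is
    in scope when its body intersects the window.  Output is ordered by
    genomic position and carries lfc/p/p_adj where tested (NaN otherwise).
    """
    window = None
    if tads:
        mid = region.midpoint
        for chrom, s, e in tads:
            if chrom == region.chrom and s <= mid < e:
                window = (s, e)
                break
        if window is None:
            logger.warning("region %s outside all TADs; falling back to +/-%d bp",
                           region.region_id, window_bp)
    if window is None:
        window = (max(0, region.start - window_bp), region.end + window_bp)
    genes = gene_annotations[
        (gene_annotations["chrom"] == region.chrom)
        & (gene_annotations["start"] < window[1])
        & (gene_annotations["end"] > window[0])].copy()
    genes = genes.sort_values(["start", "gene"]).set_index("gene")
    for col in ("lfc", "p", "p_adj"):
        genes[col] = results[col] if col in results.columns else np.nan
    genes["region_id"] = region.region_id
    return genes
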
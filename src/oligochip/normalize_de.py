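"""MA transformation, loess normalization, and differential expression.

Two-color data are analyzed on the MA scale: M = log2(R/G),
A = ½·log2(R·G).  Intensity-dependent dye bias is removed per slide by
subtracting a loess fit of M on A (tricube-weighted local linear
regression with robustness iterations; control spots are excluded from
the fit).  Differential expression between the two co-hybridized samples
is a one-sample problem on dye-corrected log ratios: a per-gene linear
model (ordinary t test of the mean ratio against 0) and a SAM-style
permutation test with a variance-stabilized statistic
d = mean/(s + s0) whose null distribution comes from sign-flips of whole
hybridizations.  The per-gene FDR is the median permuted exceedance
count over the observed exceedance count, capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MAValue",
    "GeneExpressionMatrix",
    "SAMResult",
    "DEGeneList",
    "ma_transform",
    "loess_normalize",
    "normalize_slide",
    "build_expression_matrix",
    "per_gene_linear_fit",
    "sam_test",
    "bh_adjust",
    "consensus_lists",
]


@dataclass(frozen=True)
class MAValue:
    M: float  # log2(R/G)
    A: float  # mean log2 intensity


@dataclass(frozen=True)
class GeneExpressionMatrix:
    """Genes × hybridizations matrix of normalized M values.

    ``dye_orientation`` maps hybridization id to 'forward' or 'swapped';
    swapped hybridizations enter contrasts with sign −1.  Missing entries
    (NaN) arise only from filtered or flagged spots.
    """

    values: pd.DataFrame                  # genes × hybridizations
    dye_orientation: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.values.columns) - set(self.dye_orientation)
        if unknown:
            raise ValueError(f"hybridizations without dye orientation: {sorted(unknown)}")
        bad = set(self.dye_orientation.values()) - {"forward", "swapped"}
        if bad:
            raise ValueError(f"bad orientations: {sorted(bad)}")

    def corrected(self) -> pd.DataFrame:
        """Dye-corrected ratios: swapped hybridizations negated."""
        signs = pd.Series(
            {h: 1.0 if self.dye_orientation[h] == "forward" else -1.0
             for h in self.values.columns}
        )
        return self.values * signs


@dataclass(frozen=True)
class SAMResult:
    table: pd.DataFrame      # gene, mean, s, d, fdr, significant
    s0: float
    n_permutations: int
    threshold: float


@dataclass(frozen=True)
class DEGeneList:
    comparison: str
    genes: frozenset[str]
    direction: dict          # gene -> 'up' condition label
    method: str              # linear_model | permutation | consensus
    threshold: float


def ma_transform(r: float, g: float) -> MAValue:
    """MA coordinates of one spot; requires positive intensities."""
    r = float(r)
    g = float(g)
    if r <= 0 or g <= 0:
        raise ValueError("intensities must be positive (filter first)")
    return MAValue(M=float(np.log2(r / g)), A=float(0.5 * np.log2(r * g)))


def loess_normalize(m: np.ndarray, a: np.ndarray, span: float = 0.4,
                    iterations: int = 2) -> np.ndarray:
    """M minus the tricube local-linear fit of M on A.

    ``span`` is the fraction of points in each local neighborhood;
    ``iterations`` are robustness reweighting passes.  Requires at least
    20 points.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape:
        raise ValueError("M and A must have equal length")
    if m.size < 20:
        raise ValueError("need >= 20 points for loess normalization")
    fit = lowess(m, a, frac=span, it=iterations, delta=0.0, return_sorted=False)
    return m - fit


def normalize_slide(spots: pd.DataFrame, span: float = 0.4, iterations: int = 2) -> pd.DataFrame:
    """Per-slide normalization of filtered probe spots.

    Input rows must be retained probe spots (controls are excluded from
    normalization by construction).  Returns a copy with M, A and
    normalized M columns.
    """
    out = spots.copy()
    r = out["F_red"].to_numpy(dtype=float)
    g = out["F_green"].to_numpy(dtype=float)
    if np.any(r <= 0) or np.any(g <= 0):
        raise ValueError("nonpositive intensities in normalization input")
    m = np.log2(r / g)
    a = 0.5 * np.log2(r * g)
    out["M"] = m
    out["A"] = a
    out["M_norm"] = loess_normalize(m, a, span=span, iterations=iterations)
    return out


def build_expression_matrix(normalized_slides: dict[str, pd.DataFrame],
                            layout: pd.DataFrame) -> GeneExpressionMatrix:
    """Assemble per-slide normalized M into a genes × hybridizations
    matrix; genes absent from a slide (filtered spots) become NaN."""
    orient = dict(zip(layout["slide_id"], layout["orientation"]))
    cols = {}
    for slide_id, df in normalized_slides.items():
        if slide_id not in orient:
            raise ValueError(f"slide {slide_id!r} missing from layout")
        cols[slide_id] = df.set_index("ID")["M_norm"]
    values = pd.DataFrame(cols)
    return GeneExpressionMatrix(values=values, dye_orientation=orient)


# ---------------------------------------------------------------------------
# Per-gene linear model
# ---------------------------------------------------------------------------

def per_gene_linear_fit(mat: GeneExpressionMatrix) -> pd.DataFrame:
    """Ordinary one-sample t test of the dye-corrected mean ratio vs 0.

    Genes with fewer than 2 observations are reported untestable
    (p = NaN) and excluded from multiplicity correction.  A zero SD with
    nonzero mean yields t = +/-inf with p = NaN (permutation only).
    """
    corrected = mat.corrected()
    rows = []
    for gene, row in corrected.iterrows():
        obs = row.dropna().to_numpy(dtype=float)
        n = obs.size
        if n < 2:
            rows.append({"gene": gene, "n_obs": n, "estimate": np.nan,
                         "t": np.nan, "p": np.nan, "testable": False})
            continue
        est = obs.mean()
        sd = obs.std(ddof=1)
        if sd == 0.0:
            if est == 0.0:
                rows.append({"gene": gene, "n_obs": n, "estimate": 0.0,
                             "t": 0.0, "p": 1.0, "testable": True})
            else:
                rows.append({"gene": gene, "n_obs": n, "estimate": est,
                             "t": np.inf * np.sign(est), "p": np.nan,
                             "testable": False})
            continue
        t = est / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        rows.append({"gene": gene, "n_obs": n, "estimate": est, "t": t,
                     "p": p, "testable": True})
    out = pd.DataFrame(rows).set_index("gene")
    testable = out["testable"] & out["p"].notna()
    out["p_adj"] = np.nan
    if testable.any():
        out.loc[testable, "p_adj"] = bh_adjust(out.loc[testable, "p"].to_numpy())
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# SAM-style permutation test
# ---------------------------------------------------------------------------

def sam_test(mat: GeneExpressionMatrix, n_permutations: int = 200,
             seed: int = 0, s0: float | None = None,
             s0_percentile: float = 5.0, fdr_threshold: float = 0.05) -> SAMResult:
    """Sign-flip permutation test with d = mean/(s + s0).

    s is the per-gene sample SD of dye-corrected ratios; s0 defaults to
    the ``s0_percentile`` percentile of the s distribution.  Each
    permutation flips the signs of whole hybridizations (the self-self
    null for a one-sample dye-swap design).  Per-gene
    FDR = median over permutations of #{|d*| >= |d_i|} divided by the
    observed #{|d| >= |d_i|}, capped at 1.
    """
    if n_permutations < 10:
        raise ValueError("need at least 10 permutations")
    corrected = mat.corrected()
    x = corrected.to_numpy(dtype=float)
    genes = corrected.index
    n_obs = np.sum(~np.isnan(x), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(x, axis=1)
        s = np.nanstd(x, axis=1, ddof=1)
    ok = n_obs >= 2
    if s0 is None:
        s0 = float(np.percentile(s[ok], s0_percentile)) if ok.any() else 0.0
    d = np.full(x.shape[0], np.nan)
    d[ok] = mean[ok] / (s[ok] + s0)

    rng = np.random.default_rng(seed)
    abs_d = np.abs(d[ok])
    order = np.sort(abs_d)
    # observed exceedance count per gene
    obs_count = abs_d.size - np.searchsorted(order, abs_d, side="left")
    perm_counts = np.empty((n_permutations, abs_d.size), dtype=np.int64)
    xo = x[ok]
    n_hyb = x.shape[1]
    for b in range(n_permutations):
        signs = rng.choice([-1.0, 1.0], size=n_hyb)
        xp = xo * signs
        with np.errstate(invalid="ignore"):
            mp = np.nanmean(xp, axis=1)
            sp = np.nanstd(xp, axis=1, ddof=1)
        dp = np.abs(mp / (sp + s0))
        dp_sorted = np.sort(dp)
        perm_counts[b] = dp.size - np.searchsorted(dp_sorted, abs_d, side="left")
    med_perm = np.median(perm_counts, axis=0)
    fdr_ok = np.minimum(med_perm / np.maximum(obs_count, 1), 1.0)
    # q-value-style monotonization: each gene reports the best (lowest)
    # FDR achievable at its cutoff or any weaker one, which makes FDR
    # non-decreasing as |d| decreases (suffix minimum over the ranking)
    order_desc = np.argsort(-abs_d, kind="mergesort")
    fdr_ok[order_desc] = np.minimum.accumulate(fdr_ok[order_desc][::-1])[::-1]
    fdr = np.full(x.shape[0], np.nan)
    fdr[ok] = fdr_ok
    table = pd.DataFrame(
        {
            "mean": mean, "s": s, "d": d, "fdr": fdr,
            "significant": fdr <= fdr_threshold,
        },
        index=genes,
    )
    table.loc[~ok, "significant"] = False
    return SAMResult(table=table, s0=s0, n_permutations=n_permutations,
                     threshold=fdr_threshold)


# ---------------------------------------------------------------------------
# Method consensus
# ---------------------------------------------------------------------------

def de_list_from_linear(fit: pd.DataFrame, comparison: str, alpha: float,
                        up_label: str, down_label: str) -> DEGeneList:
    sig = fit[(fit["p_adj"].notna()) & (fit["p_adj"] <= alpha)]
    direction = {
        g: (up_label if row["estimate"] > 0 else down_label)
        for g, row in sig.iterrows()
    }
    return DEGeneList(comparison=comparison, genes=frozenset(sig.index),
                      direction=direction, method="linear_model", threshold=alpha)


def de_list_from_sam(sam: SAMResult, comparison: str, alpha: float,
                     up_label: str, down_label: str) -> DEGeneList:
    t = sam.table
    sig = t[(t["fdr"].notna()) & (t["fdr"] <= alpha)]
    direction = {
        g: (up_label if row["mean"] > 0 else down_label)
        for g, row in sig.iterrows()
    }
    return DEGeneList(comparison=comparison, genes=frozenset(sig.index),
                      direction=direction, method="permutation", threshold=alpha)


def consensus_lists(linear_list: DEGeneList, sam_list: DEGeneList) -> DEGeneList:
    """Genes called by both methods, with per-method provenance retained
    in the direction map (direction from the linear fit)."""
    if linear_list.comparison != sam_list.comparison:
        raise ValueError(
            f"comparison mismatch: {linear_list.comparison!r} vs {sam_list.comparison!r}"
        )
    genes = linear_list.genes & sam_list.genes
    direction = {g: linear_list.direction[g] for g in genes}
    return DEGeneList(
        comparison=linear_list.comparison, genes=frozenset(genes),
        direction=direction, method="consensus",
        threshold=max(linear_list.threshold, sam_list.threshold),
    )
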
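"""Relative qPCR quantification and reference-gene stability.

Expression of a target gene X is normalized to the geometric mean of a
panel of reference genes.  On the Ct scale the geometric mean of
reference expression corresponds to the arithmetic mean of reference
Cts, so under the standard convention

    rel(X) = 2^(−(Ct(X) − mean(Ct refs)))

one extra cycle halves the reported expression.  Some write-ups render
the exponent with a positive sign; that 'as_printed' convention is kept
selectable but inverts the usual Ct-expression relationship, so
'standard' is the default.  Amplification efficiency defaults to a base
of 2 (100% efficiency) and is configurable.

Reference stability follows the geNorm idea: for each candidate, the
stability value M is the average, over every other candidate, of the SD
across samples of their pairwise log2 expression ratio (equivalently the
pairwise Ct difference); lower M is more stable, and the top panel is
ranked in ascending M.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "relative_expression",
    "relative_expression_table",
    "reference_stability",
    "platform_agreement",
]

CONVENTIONS = ("standard_negative_exponent", "as_printed_positive_exponent")


def relative_expression(ct_x: float, ct_refs,
                        convention: str = "standard_negative_exponent",
                        base: float = 2.0) -> float:
    """Fold expression of X relative to the reference geometric mean."""
    refs = np.asarray(list(ct_refs), dtype=float)
    if refs.size < 2:
        raise ValueError("need >= 2 reference Cts")
    if ct_x <= 0 or np.any(refs <= 0):
        raise ValueError("Ct values must be positive")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    sign = -1.0 if convention == "standard_negative_exponent" else 1.0
    return float(base ** (sign * (float(ct_x) - refs.mean())))


def relative_expression_table(ct: pd.DataFrame,
                              convention: str = "standard_negative_exponent",
                              base: float = 2.0) -> pd.DataFrame:
    """Per (gene, sample) relative expression from a long Ct table.

    Columns required: gene_id, sample_id, ct, is_reference,
    technical_replicate.  Technical replicates are averaged first; each
    sample is normalized to the mean Ct of its own reference genes.
    """
    required = {"gene_id", "sample_id", "ct", "is_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    avg = (
        ct.groupby(["gene_id", "sample_id", "is_reference"], as_index=False)["ct"]
        .mean()
    )
    rows = []
    for sample, sub in avg.groupby("sample_id"):
        refs = sub[sub["is_reference"]]["ct"].to_numpy()
        if refs.size < 2:
            raise ValueError(f"sample {sample!r}: need >= 2 reference genes")
        for _, row in sub[~sub["is_reference"]].iterrows():
            rows.append(
                {
                    "gene_id": row["gene_id"],
                    "sample_id": sample,
                    "value": relative_expression(row["ct"], refs,
                                                 convention=convention, base=base),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "value"])


def reference_stability(ct_matrix: pd.DataFrame, iterative: bool = False) -> pd.DataFrame:
    """geNorm-style stability M per candidate reference.

    ``ct_matrix``: candidates (rows) × samples (columns) of Ct values.
    M(j) = mean over other candidates k of SD across samples of
    (Ct_j − Ct_k).  Returns candidates sorted by ascending M with a
    ``rank`` column; the top 3 form the reference panel.  With
    ``iterative``, the worst candidate is dropped and M recomputed until
    3 remain (eliminated candidates keep the M at which they were
    dropped).
    """
    if ct_matrix.shape[0] < 3:
        raise ValueError("need >= 3 candidate reference genes")
    if ct_matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")

    def m_values(frame: pd.DataFrame) -> pd.Series:
        x = frame.to_numpy(dtype=float)
        diffs = x[:, None, :] - x[None, :, :]        # (j, k, samples)
        sds = diffs.std(axis=2, ddof=1)              # pairwise SD across samples
        k = x.shape[0]
        m = (sds.sum(axis=1)) / (k - 1)              # exclude self (SD 0)
        return pd.Series(m, index=frame.index)

    if not iterative:
        m = m_values(ct_matrix)
    else:
        remaining = ct_matrix.copy()
        dropped: dict = {}
        while remaining.shape[0] > 3:
            cur = m_values(remaining)
            worst = cur.idxmax()
            dropped[worst] = float(cur[worst])
            remaining = remaining.drop(index=worst)
        final = m_values(remaining)
        m = pd.concat([final, pd.Series(dropped)])
    out = pd.DataFrame({"M": m}).sort_values("M", kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def platform_agreement(array_log2: pd.Series, qpcr_log2: pd.Series):
    """Pearson r on paired per-gene log2 ratios plus sign concordance.

    Returns (r, p_value, concordance_pct) over the genes shared by both
    series; requires >= 3 shared genes and nonzero variance in each.
    """
    shared = array_log2.index.intersection(qpcr_log2.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    a = array_log2.loc[shared].to_numpy(dtype=float)
    q = qpcr_log2.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(q) == 0:
        raise ValueError("zero variance in one platform's log ratios")
    r, p = stats.pearsonr(a, q)
    concordance = 100.0 * float(np.mean(np.sign(a) == np.sign(q)))
    return float(r), float(p), concordance
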
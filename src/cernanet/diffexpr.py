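"""Differential expression scoring and the fold-change / p-value gate.

The analysis contrasts stretched vs. control samples gene-by-gene with a
two-sample Student t-test on log2-normalized values.  A gene is called
differentially expressed when its linear fold change is at least
``fc_threshold`` (default 1.5, applied as ``|log2FC| >= log2(1.5)``) and
its raw p-value is at most ``p_threshold`` (default 0.05).  Benjamini-
Hochberg FDR is computed jointly across all tested genes and reported,
but does not gate by default — network inclusion rests on the raw P.

Note the FC columns of published top-DE tables in this domain are
routinely printed on the log2 scale even though the selection criterion
is quoted on the linear scale; thresholds here therefore act on
``2^|log2FC|``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix

DE_COLUMNS = ["gene_id", "biotype", "mean_control", "mean_stretch",
              "log2fc", "t_stat", "p_value", "fdr", "direction"]


def normalize_log2(matrix: ExpressionMatrix, pseudocount: float = 1.0,
                   already_log: bool = False) -> ExpressionMatrix:
    """Counts-per-million scaling followed by ``log2(x + pseudocount)``.

    Raw values must be non-negative; each sample (column) is scaled to a
    library size of one million before the log transform, which makes the
    result invariant to proportional rescaling of a column.  Data already
    on the log scale passes through unchanged when ``already_log`` is set.
    """
    if already_log:
        return matrix
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = matrix.values.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("normalize_log2 requires non-negative raw values")
    libsize = vals.sum(axis=0)
    if (libsize == 0).any():
        bad = [matrix.samples[j] for j in np.flatnonzero(libsize == 0)]
        raise ValueError(f"samples with zero total counts: {bad}")
    cpm = vals / libsize * 1e6
    out = pd.DataFrame(np.log2(cpm + pseudocount),
                       index=matrix.values.index,
                       columns=matrix.values.columns)
    return ExpressionMatrix(out, matrix.biotype.copy(), matrix.group.copy())


def _t_test(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    """Two-sided t-test for mean(a) - mean(b); pooled variance by default."""
    n1, n2 = len(a), len(b)
    diff = a.mean() - b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return np.sign(diff) * np.inf, 0.0
    if welch:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def differential_expression(matrix: ExpressionMatrix,
                            welch: bool = False,
                            fdr_per_biotype: bool = False) -> pd.DataFrame:
    """Score every gene: log2FC (stretch - control), t, p, BH FDR, direction.

    Requires at least two samples per group.  Genes with zero variance in
    both groups and equal means get ``t = 0, p = 1``.  Direction is ``Up``
    iff ``log2fc > 0`` (a zero fold change is classed ``Down``; such rows
    can never pass the fold-change gate).  Rows come back sorted stably by
    p-value ascending.
    """
    ctrl = matrix.samples_in("control")
    stretch = matrix.samples_in("stretch")
    if len(ctrl) < 2 or len(stretch) < 2:
        raise ValueError("each group needs at least 2 samples "
                         f"(control={len(ctrl)}, stretch={len(stretch)})")
    a = matrix.values[stretch].to_numpy(dtype=float)
    b = matrix.values[ctrl].to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(matrix.gene_ids):
        t, p = _t_test(a[i], b[i], welch)
        log2fc = float(a[i].mean() - b[i].mean())
        rows.append((gene, matrix.biotype[gene], float(b[i].mean()),
                     float(a[i].mean()), log2fc, t, p,
                     "Up" if log2fc > 0 else "Down"))
    table = pd.DataFrame(rows, columns=["gene_id", "biotype", "mean_control",
                                        "mean_stretch", "log2fc", "t_stat",
                                        "p_value", "direction"])
    if fdr_per_biotype:
        table["fdr"] = np.nan
        for bt in table["biotype"].unique():
            mask = table["biotype"] == bt
            table.loc[mask, "fdr"] = adjust_bh(
                table.loc[mask, "p_value"].tolist())
    else:
        table["fdr"] = adjust_bh(table["p_value"].tolist())
    table = table[DE_COLUMNS]
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


def adjust_bh(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        raise ValueError("adjust_bh needs a non-empty list")
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return [float(x) for x in adj]


def apply_de_filter(table: pd.DataFrame, fc_threshold: float = 1.5,
                    p_threshold: float = 0.05,
                    use_fdr: bool = False) -> pd.DataFrame:
    """Retain genes with ``|log2fc| >= log2(fc_threshold)`` and ``p <= p_threshold``.

    ``fc_threshold`` is on the linear scale and must be >= 1.  With
    ``use_fdr`` the BH-adjusted value gates instead of the raw p-value.
    The filter is monotone: tightening either threshold never adds rows.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear scale)")
    if table.empty:
        return table.copy()
    stat = table["fdr"] if use_fdr else table["p_value"]
    keep = (table["log2fc"].abs() >= np.log2(fc_threshold)) & \
        (stat <= p_threshold)
    return table.loc[keep].copy()


def write_de_table(table: pd.DataFrame, path) -> None:
    """Write a DE table as TSV with the conventional published column names."""
    out = table.rename(columns={"gene_id": "Gene", "biotype": "Biotype",
                                "p_value": "P", "log2fc": "log2FC",
                                "fdr": "FDR", "direction": "Regulation"})
    out.to_csv(path, sep="\t", index=False)
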
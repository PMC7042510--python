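"""ceRNA pair inference under the competing-endogenous-RNA hypothesis.

A lncRNA and an mRNA form a candidate ceRNA pair when (i) they respond to
stretch in the same direction while at least one miRNA targeting both
responds in the opposite direction (the sponge logic: less lncRNA frees
miRNA, which represses the mRNA), and (ii) the two transcripts share more
interacting miRNAs than expected by chance, scored with an upper-tail
hypergeometric test over a miRNA background universe.  Optional
co-expression and sensitivity-correlation filters tighten the selection
the way integrative ceRNA toolkits do; they are off by default because
the core selection rests on directions plus shared miRNAs.

Symbols: ``N`` background miRNAs, ``K`` miRNAs of the lncRNA, ``n``
miRNAs of the mRNA, ``k`` shared; ``p = P(X >= k)`` for hypergeometric X.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, InteractionSet
from .diffexpr import adjust_bh

logger = logging.getLogger("cernanet")

PAIR_COLUMNS = ["lncrna", "mrna", "shared_mirnas", "k", "K", "n", "N",
                "p_hypergeom", "fdr_hypergeom", "pearson_r", "corr_p",
                "senscor"]


@dataclass(frozen=True)
class HypergeomResult:
    """Shared-miRNA overlap test: P(X >= k) with X ~ Hypergeom(N, K, n)."""

    N: int
    K: int
    n: int
    k: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= self.N):
            raise ValueError(
                f"inconsistent hypergeometric counts N={self.N} K={self.K} "
                f"n={self.n} k={self.k}")


def directional_candidates(de_lnc: pd.DataFrame, de_mir: pd.DataFrame,
                           de_mrna: pd.DataFrame,
                           interactions: InteractionSet,
                           orientation: str = "both") -> pd.DataFrame:
    """Enumerate (lncRNA, miRNA, mRNA) triples obeying the sponge sign rule.

    Inputs are post-filter DE tables.  A triple is kept when both edges
    (miRNA, lncRNA) and (miRNA, mRNA) exist in the interaction set and
    ``sign(lncRNA) = sign(mRNA) = -sign(miRNA)``.  With
    ``orientation="down_up_down"`` only the stretch-typical case
    (lncRNA Down, miRNA Up, mRNA Down) is kept.
    """
    if orientation not in ("both", "down_up_down"):
        raise ValueError(f"unknown orientation {orientation!r}")
    dir_lnc = dict(zip(de_lnc["gene_id"], de_lnc["direction"]))
    dir_mir = dict(zip(de_mir["gene_id"], de_mir["direction"]))
    dir_mrna = dict(zip(de_mrna["gene_id"], de_mrna["direction"]))
    rows = []
    for mir, d_mir in dir_mir.items():
        lnc_partners = interactions.targets_of(mir, "lncRNA") & dir_lnc.keys()
        mrna_partners = interactions.targets_of(mir, "mRNA") & dir_mrna.keys()
        for lnc in lnc_partners:
            d_lnc = dir_lnc[lnc]
            if d_lnc == d_mir:
                continue
            if orientation == "down_up_down" and d_lnc != "Down":
                continue
            for mrna in mrna_partners:
                if dir_mrna[mrna] != d_lnc:
                    continue
                rows.append((lnc, mir, mrna, d_lnc, d_mir, dir_mrna[mrna]))
    out = pd.DataFrame(rows, columns=["lncrna", "mirna", "mrna",
                                      "lnc_direction", "mir_direction",
                                      "mrna_direction"])
    return out.sort_values(["lncrna", "mirna", "mrna"],
                           kind="stable").reset_index(drop=True)


def shared_mirna_test(lncrna_id: str, mrna_id: str,
                      interactions: InteractionSet,
                      background: set[str]) -> HypergeomResult:
    """Upper-tail hypergeometric test for the shared-miRNA count of a pair.

    ``background`` is the miRNA universe (must cover every miRNA in the
    interaction set); counts are intersected with it before testing.
    """
    if not background:
        raise ValueError("background miRNA set is empty")
    mirs_l = interactions.mirnas_of(lncrna_id) & background
    mirs_m = interactions.mirnas_of(mrna_id) & background
    k = len(mirs_l & mirs_m)
    K, n, N = len(mirs_l), len(mirs_m), len(background)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    return HypergeomResult(N=N, K=K, n=n, k=k, p_value=min(p, 1.0))


def coexpression(lncrna_id: str, mrna_id: str,
                 matrix: ExpressionMatrix) -> tuple[float, float]:
    """Pearson correlation of two genes across all samples, with t-test p.

    Zero variance in either profile makes r undefined; it is reported as
    ``(0.0, 1.0)`` with a warning.
    """
    x = matrix.values.loc[lncrna_id].to_numpy(dtype=float)
    y = matrix.values.loc[mrna_id].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("coexpression needs at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(f"zero variance for {lncrna_id!r} or {mrna_id!r}; "
                      "correlation undefined, reporting r=0")
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def sensitivity_correlation(lncrna_id: str, mrna_id: str,
                            shared_mirnas: set[str],
                            matrix: ExpressionMatrix) -> float:
    """Mean drop of the lncRNA-mRNA correlation after partialling out miRNAs.

    For each shared miRNA mu the sensitivity is
    ``r(l,m) - partial_r(l,m | mu)`` where the first-order partial
    correlation is ``(r(l,m) - r(l,mu)*r(m,mu)) /
    sqrt((1-r(l,mu)^2)(1-r(m,mu)^2))``.  A large positive value means the
    miRNA accounts for much of the co-expression, as the ceRNA mechanism
    predicts.  miRNAs perfectly correlated with either partner are
    skipped with a warning; all skipped is an error.
    """
    if not shared_mirnas:
        raise ValueError("shared miRNA set is empty")
    x = matrix.values.loc[lncrna_id].to_numpy(dtype=float)
    y = matrix.values.loc[mrna_id].to_numpy(dtype=float)
    r_lm = _pearson(x, y)
    vals = []
    for mu in sorted(shared_mirnas):
        z = matrix.values.loc[mu].to_numpy(dtype=float)
        r_lz, r_mz = _pearson(x, z), _pearson(y, z)
        if abs(r_lz) == 1.0 or abs(r_mz) == 1.0:
            warnings.warn(f"miRNA {mu!r} perfectly correlated with a "
                          "partner; skipped in sensitivity correlation")
            continue
        partial = (r_lm - r_lz * r_mz) / np.sqrt(
            (1 - r_lz ** 2) * (1 - r_mz ** 2))
        vals.append(r_lm - partial)
    if not vals:
        raise ValueError("all shared miRNAs skipped; sensitivity "
                         "correlation undefined")
    return float(np.mean(vals))


def infer_cerna_pairs(candidates: pd.DataFrame,
                      interactions: InteractionSet,
                      matrix: ExpressionMatrix | None = None,
                      background: set[str] | None = None,
                      hypergeom_p: float = 0.01,
                      min_shared: int = 1,
                      require_positive_corr: bool = False,
                      corr_p: float = 0.05,
                      min_senscor: float | None = None) -> pd.DataFrame:
    """Collapse directional triples into scored, filtered ceRNA pairs.

    Triples from :func:`directional_candidates` are grouped by
    (lncRNA, mRNA); each pair records its direction-consistent shared
    miRNAs (the evidence set, gated by ``min_shared``) and the
    hypergeometric overlap of the full interaction sets (gated by
    ``hypergeom_p``).  Optional gates: positive Pearson co-expression
    with p <= ``corr_p``, and mean sensitivity correlation >=
    ``min_senscor``; both need ``matrix``.  BH FDR across tested pairs is
    reported but never gates.  Output is sorted by hypergeometric p
    ascending, then k descending, then (lncRNA, mRNA) lexicographically.
    """
    if not (0 < hypergeom_p <= 1):
        raise ValueError("hypergeom_p must lie in (0, 1]")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if not (0 < corr_p <= 1):
        raise ValueError("corr_p must lie in (0, 1]")
    if background is None:
        background = interactions.mirna_universe
    needs_expr = require_positive_corr or min_senscor is not None
    if needs_expr and matrix is None:
        raise ValueError("expression matrix required for correlation or "
                         "sensitivity-correlation filters")

    rows = []
    if not candidates.empty:
        grouped = candidates.groupby(["lncrna", "mrna"], sort=True)
        for (lnc, mrna), sub in grouped:
            shared = sorted(set(sub["mirna"]))
            if len(shared) < min_shared:
                continue
            hg = shared_mirna_test(lnc, mrna, interactions, background)
            r = p_r = senscor = np.nan
            if needs_expr:
                r, p_r = coexpression(lnc, mrna, matrix)
                if require_positive_corr and not (r > 0 and p_r <= corr_p):
                    continue
                if min_senscor is not None:
                    senscor = sensitivity_correlation(lnc, mrna, set(shared),
                                                      matrix)
                    if senscor < min_senscor:
                        continue
            if hg.p_value > hypergeom_p:
                continue
            rows.append((lnc, mrna, ";".join(shared), hg.k, hg.K, hg.n,
                         hg.N, hg.p_value, np.nan, r, p_r, senscor))
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if not out.empty:
        out["fdr_hypergeom"] = adjust_bh(out["p_hypergeom"].tolist())
        out = out.sort_values(["p_hypergeom", "k", "lncrna", "mrna"],
                              ascending=[True, False, True, True],
                              kind="stable").reset_index(drop=True)
    logger.info("infer_cerna_pairs: %d pairs retained", len(out))
    return out
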
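"""Differential-expression stand-in and hypergeometric enrichment of DEGs
among edited genes.

The DE engine here is deliberately simple — Welch's t-test on log2(x+1)
with Benjamini-Hochberg correction and a fold-change floor — because the
scientific question downstream is the enrichment one; an externally
computed DEG list is accepted equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail enrichment of DEGs among edited genes."""

    N: int          # universe size
    K: int          # DEGs in universe
    n: int          # edited genes in universe
    k: int          # edited DEGs
    p_value: float  # P(X >= k)
    fold_enrichment: float  # (k/n) / (K/N)

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")


def samples_of_line(sample_map: Mapping[str, tuple[str, int]], line: str) -> list[str]:
    return sorted(s for s, (ln, _) in sample_map.items() if ln == line)


def simple_deg(expr: pd.DataFrame, sample_map: Mapping[str, tuple[str, int]],
               line_a: str, line_b: str, fc_threshold: float = 2.0,
               alpha: float = 0.05) -> set[str]:
    """DEGs between two cell lines.

    Welch t-test per gene on log2(expr+1), Benjamini-Hochberg across genes;
    a gene is a DEG when adjusted p <= alpha and |log2 fold change| >=
    log2(fc_threshold).
    """
    cols_a = samples_of_line(sample_map, line_a)
    cols_b = samples_of_line(sample_map, line_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each cell line needs >=2 replicates for the t-test")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    la = np.log2(expr[cols_a].to_numpy() + 1.0)
    lb = np.log2(expr[cols_b].to_numpy() + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    mask = (p_adj <= alpha) & (np.abs(log2fc) >= np.log2(fc_threshold))
    return set(expr.index[mask])


def expressed_universe(expr: pd.DataFrame,
                       sample_map: Mapping[str, tuple[str, int]]) -> set[str]:
    """Genes with nonzero mean expression in at least one cell line."""
    lines = {ln for ln, _ in sample_map.values()}
    universe: set[str] = set()
    for line in lines:
        cols = samples_of_line(sample_map, line)
        means = expr[cols].mean(axis=1)
        universe |= set(expr.index[means > 0])
    return universe


def hypergeom_enrichment(universe: set[str], deg_set: set[str],
                         edited_set: set[str]) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test.

    With N genes in the universe, K of them DEGs and n of them edited,
    the p-value is P(X >= k) for the observed k edited DEGs, where X is
    hypergeometric(N, K, n).
    """
    if not deg_set <= universe:
        raise ValueError("deg_set must be a subset of the universe")
    if not edited_set <= universe:
        raise ValueError("edited_set must be a subset of the universe")
    N, K, n = len(universe), len(deg_set), len(edited_set)
    if n == 0:
        raise ValueError("no edited genes in the universe")
    k = len(deg_set & edited_set)
    # sf(k-1) = P(X >= k); exact in scipy's log-space implementation
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    fold = (k / n) / (K / N) if K else float("nan")
    return EnrichmentResult(N, K, n, k, p, fold)


def load_deg_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def load_expression(path: str) -> tuple[pd.DataFrame, dict[str, tuple[str, int]]]:
    """Read an expression TSV (gene_id + one column per sample).

    Sample columns are expected as ``<line>_rep<k>``; the parsed mapping is
    returned alongside the matrix.
    """
    expr = pd.read_csv(path, sep="\t", index_col=0)
    sample_map = {}
    for col in expr.columns:
        line, _, rep = col.rpartition("_rep")
        if not line or not rep.isdigit():
            raise ValueError(f"sample column {col!r} not of the form <line>_rep<k>")
        sample_map[col] = (line, int(rep))
    return expr, sample_map
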
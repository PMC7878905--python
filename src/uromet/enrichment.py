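"""Expression-derived gene sets and Monte-Carlo gene-set enrichment.

Tissue/cell-type specific-expression sets are the top decile of genes ranked
by the t-statistic of a tissue-indicator coefficient in a per-gene linear
model of log-transformed expression.  Enrichment of a query gene set in a
named set is assessed by comparing the observed overlap to overlaps of
uniformly drawn random gene lists of the same size (add-one Monte-Carlo
p-value), with a 2x2 odds ratio over the gene universe, Bonferroni or
Benjamini-Hochberg adjusted across sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionData",
    "GeneSetDB",
    "EnrichmentResult",
    "specific_expression_sets",
    "zscore_profile",
    "mc_enrichment",
    "enrichment_odds_ratio",
    "adjust_pvalues",
    "read_gmt",
    "write_gmt",
]


@dataclass
class ExpressionData:
    """Genes x samples expression matrix with one tissue/cell-type label per sample."""

    values: pd.DataFrame  # rows = genes, columns = samples, TPM-like
    labels: pd.Series  # sample -> tissue/cell-type label

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise ValueError("every sample needs exactly one label")
        if self.labels.nunique() < 2:
            raise ValueError("need at least two distinct labels")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class GeneSetDB:
    """Named gene sets over a common universe; undersized sets are removed."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    min_set_size: int = 5

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        cleaned = {}
        for name, genes in self.sets.items():
            genes = frozenset(genes)
            if not genes <= self.universe:
                raise ValueError(f"set {name!r} contains genes outside the universe")
            if len(genes) >= self.min_set_size:
                cleaned[name] = genes
        self.sets = cleaned


@dataclass
class EnrichmentResult:
    set_name: str
    observed: int
    expected: float
    odds_ratio: float
    or_corrected: bool
    p: float
    p_adjusted: float | None
    n_draws: int
    seed: int


def _log_tpm(values: pd.DataFrame) -> np.ndarray:
    return np.log10(values.to_numpy(dtype=float) + 1.0)


def specific_expression_sets(
    expr: ExpressionData, fraction: float = 0.10
) -> dict[str, list[str]]:
    """Top ``ceil(fraction * G)`` genes per label, ranked by indicator t-statistic.

    Per gene and label, expression (log10(x+1)) is regressed on a focal-label
    indicator across all samples; the coefficient's t-statistic (the pooled
    two-group t) ranks genes.  Ties at the decile boundary are broken by gene
    id so set sizes are exactly ceil(fraction * G).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    X = _log_tpm(expr.values)
    genes = expr.genes
    n_top = math.ceil(fraction * len(genes))
    out: dict[str, list[str]] = {}
    for label in sorted(expr.labels.unique()):
        t = _indicator_tstats(X, (expr.labels == label).to_numpy())
        order = pd.DataFrame({"t": t, "gene": genes}).sort_values(
            ["t", "gene"], ascending=[False, True]
        )
        out[label] = sorted(order["gene"].head(n_top))
    return out


def _indicator_tstats(X: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled-variance two-group t-statistics, vectorized over genes (rows)."""
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 samples inside and outside each label")
    x1, x0 = X[:, mask], X[:, ~mask]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x0 - m0[:, None]) ** 2).sum(axis=1)
    sp2 = ss / (n1 + n0 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    return np.where(denom == 0, 0.0, t)  # constant gene: no specificity signal


def zscore_profile(expr: ExpressionData, genes: Sequence[str]) -> pd.DataFrame:
    """Per-gene mean log-expression per label, standardized across labels.

    Rows have mean 0 and SD 1 (population SD across labels); genes constant
    across labels get an all-zero row.  This is the heatmap convention for
    displaying where a gene is highly expressed.
    """
    missing = [g for g in genes if g not in expr.genes]
    if missing:
        raise ValueError(f"genes absent from expression data: {missing[:5]}")
    labels = sorted(expr.labels.unique())
    if len(labels) < 2:
        raise ValueError("need at least two labels")
    log = pd.DataFrame(_log_tpm(expr.values), index=expr.genes, columns=expr.values.columns)
    means = pd.DataFrame(
        {lab: log.loc[list(genes), expr.labels.index[expr.labels == lab]].mean(axis=1)
         for lab in labels}
    )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
    return z


def mc_enrichment(
    query: Iterable[str],
    db: GeneSetDB,
    n_draws: int = 100_000,
    seed: int = 0,
    adjust: str | None = None,
) -> list[EnrichmentResult]:
    """Monte-Carlo enrichment of a query gene list in every set of the database.

    Draws ``n_draws`` uniform k-subsets of the universe without replacement
    (k = query size) and compares each set's observed overlap to the drawn
    overlaps:  p = (1 + #draws with overlap >= observed) / (1 + n_draws), so
    p is never zero.  Optionally adjusts p-values across sets ("bonferroni"
    or "bh").
    """
    query = sorted(set(query))
    k = len(query)
    if k < 1:
        raise ValueError("query must contain at least one gene")
    universe = sorted(db.universe)
    absent = [g for g in query if g not in db.universe]
    if absent:
        raise ValueError(f"query genes absent from universe: {absent[:5]}")
    N = len(universe)
    gene_idx = {g: i for i, g in enumerate(universe)}
    membership = {
        name: np.isin(np.arange(N), [gene_idx[g] for g in genes])
        for name, genes in db.sets.items()
    }
    query_idx = np.array([gene_idx[g] for g in query])
    rng = np.random.default_rng(seed)

    names = sorted(db.sets)
    observed = {n: int(membership[n][query_idx].sum()) for n in names}
    exceed = {n: 0 for n in names}
    chunk = 10_000
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        # vectorized without-replacement draws: argpartition of random keys
        keys = rng.random((b, N))
        draws = np.argpartition(keys, k - 1, axis=1)[:, :k]
        for n in names:
            ov = membership[n][draws].sum(axis=1)
            exceed[n] += int((ov >= observed[n]).sum())
        done += b

    raw_p = {n: (1 + exceed[n]) / (1 + n_draws) for n in names}
    adj = None
    if adjust is not None:
        adj_vals = adjust_pvalues(np.array([raw_p[n] for n in names]), adjust, len(names))
        adj = dict(zip(names, adj_vals))
    results = []
    for n in names:
        K = len(db.sets[n])
        orat, corrected = enrichment_odds_ratio(observed[n], k, K, N)
        results.append(
            EnrichmentResult(
                set_name=n,
                observed=observed[n],
                expected=k * K / N,
                odds_ratio=orat,
                or_corrected=corrected,
                p=raw_p[n],
                p_adjusted=None if adj is None else float(adj[n]),
                n_draws=n_draws,
                seed=seed,
            )
        )
    return results


def enrichment_odds_ratio(
    observed: int, query_size: int, set_size: int, universe_size: int
) -> tuple[float, bool]:
    """Odds ratio of the 2x2 membership table over the universe.

    Table cells: a = overlap, b = query not in set, c = set not in query,
    d = neither; OR = a*d / (b*c).  When any cell is zero, 0.5 is added to
    every cell (Haldane-Anscombe) and the correction is flagged.
    """
    a = observed
    b = query_size - a
    c = set_size - a
    d = universe_size - set_size - query_size + a
    if min(a, b, c, d) < 0:
        raise ValueError("impossible 2x2 table")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return (a * d) / (b * c), corrected


def adjust_pvalues(pvalues: np.ndarray, method: str, m: int | None = None) -> np.ndarray:
    """Bonferroni (min(1, m*p)) or Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(1.0, ranked)
        return out
    raise ValueError(f"unknown method {method!r}")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = parts[2:]
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, description, *sorted(sets[name])]) + "\n")
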
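"""Metabolite quality control and transformation.

Urine metabolite intensities are confounded by inter-individual differences in
urine dilution and carry occasional extreme values and missing measurements.
The cleaning pipeline applied here is, in order:

1. per-metabolite outlier masking (values more than ``k`` SD from the mean are
   set to missing),
2. probabilistic quotient normalization (PQN) against a reference spectrum of
   well-measured endogenous metabolites, which removes per-sample dilution,
3. removal of metabolites (or ratios) quantified in too few samples,
4. pairwise ratio construction within selected super-pathways,
5. rank-based inverse normal transformation (INT) of each analyte.

Masking precedes PQN so that outliers cannot corrupt the quotients; ratios are
taken on normalized concentrations (pre-INT) because INT is rank-only and
ratios of ranks carry no meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaboliteMatrix",
    "RatioMatrix",
    "mask_outliers",
    "pqn_normalize",
    "filter_min_observations",
    "inverse_normal_transform",
    "transform_matrix",
    "build_ratio_matrix",
    "read_metabolite_tsv",
    "write_metabolite_tsv",
]

#: forward-only processing states
_STATES = ("raw", "outlier-masked", "pqn-normalized", "transformed")


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity matrix with a processing-state flag.

    ``values`` is a pandas DataFrame (rows = samples, columns = metabolites,
    NaN = missing).  ``pathways`` maps metabolite id -> super-pathway label
    (e.g. "amino acid", "peptide", "lipid-fatty acid", "other").
    """

    values: pd.DataFrame
    pathways: dict[str, str] = field(default_factory=dict)
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state != "transformed":
            with np.errstate(invalid="ignore"):
                if (self.values.to_numpy(dtype=float) < 0).any():
                    raise ValueError("intensities must be non-negative before transformation")

    def _require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise ValueError(f"operation requires state in {allowed}, got {self.state!r}")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns


@dataclass
class RatioMatrix:
    """Per-sample pairwise metabolite ratios.

    Columns are named ``"A/B"`` with A < B lexicographically; a ratio is
    missing wherever either member is missing or the denominator is zero.
    """

    values: pd.DataFrame
    pairs: pd.DataFrame  # columns: ratio_id, numerator, denominator, pathway_a, pathway_b
    state: str = "pqn-normalized"


def mask_outliers(matrix: MetaboliteMatrix, k: float = 5.0) -> MetaboliteMatrix:
    """Set values more than ``k`` SD away from the per-metabolite mean to missing.

    Mean and SD are computed over observed values in a single pass (the
    candidate value included); the inequality is strict, so a value at exactly
    ``k`` SD is retained.  Metabolites with zero SD mask nothing.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    matrix._require_state("raw", "outlier-masked")
    x = matrix.values
    mean = x.mean(axis=0, skipna=True)
    sd = x.std(axis=0, ddof=1, skipna=True)
    sd = sd.where(sd > 0)  # zero/undefined SD -> no masking
    z = (x - mean).abs().div(sd, axis=1)
    masked = x.where(~(z > k))
    return MetaboliteMatrix(masked, dict(matrix.pathways), "outlier-masked")


def pqn_normalize(
    matrix: MetaboliteMatrix, ref_missing_max: float = 0.01
) -> MetaboliteMatrix:
    """Probabilistic quotient normalization against well-measured metabolites.

    The reference spectrum is the per-metabolite median over samples,
    restricted to metabolites with a missing fraction below
    ``ref_missing_max``.  Each sample's quotient is the median of
    ``x_im / ref_m`` over the reference metabolites, and every value in the
    sample's row is divided by that quotient.  For data generated as a common
    profile times a per-sample dilution factor, the quotient recovers the
    dilution factor exactly.
    """
    matrix._require_state("outlier-masked")
    x = matrix.values
    miss_frac = x.isna().mean(axis=0)
    ref_cols = miss_frac.index[miss_frac < ref_missing_max]
    if len(ref_cols) == 0:
        raise ValueError(
            f"no metabolite has missing fraction < {ref_missing_max}; "
            "cannot build a PQN reference spectrum"
        )
    ref = x[ref_cols].median(axis=0, skipna=True)
    if (ref <= 0).any():
        raise ValueError("reference spectrum contains non-positive medians")
    quotients = x[ref_cols].div(ref, axis=1).median(axis=1, skipna=True)
    if (quotients <= 0).any() or quotients.isna().any():
        raise ValueError("non-positive or undefined probabilistic quotient")
    normalized = x.div(quotients, axis=0)
    return MetaboliteMatrix(normalized, dict(matrix.pathways), "pqn-normalized")


def filter_min_observations(matrix, min_n: int = 300):
    """Drop columns quantified in fewer than ``min_n`` samples (boundary inclusive).

    Works on either a :class:`MetaboliteMatrix` or a :class:`RatioMatrix`;
    column order is otherwise preserved.
    """
    keep = matrix.values.notna().sum(axis=0) >= min_n
    kept = matrix.values.loc[:, keep]
    if isinstance(matrix, RatioMatrix):
        pairs = matrix.pairs[matrix.pairs["ratio_id"].isin(kept.columns)].reset_index(drop=True)
        return RatioMatrix(kept, pairs, matrix.state)
    pathways = {m: p for m, p in matrix.pathways.items() if m in kept.columns}
    return MetaboliteMatrix(kept, pathways, matrix.state)


def inverse_normal_transform(values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Rank-based inverse normal transform, ``Phi^-1((rank - 0.5) / n_obs)``.

    Ties receive the average rank (so tied values map to identical
    transformed values); missing values stay missing.  The (rank - 0.5)/n
    offset is symmetric, hence the transformed mean of tie-free data is 0 up
    to floating point.
    """
    arr = np.asarray(values, dtype=float)
    obs = ~np.isnan(arr)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("inverse normal transform requires >= 2 observed values")
    ranks = stats.rankdata(arr[obs], method="average")
    out = np.full(arr.shape, np.nan)
    out[obs] = stats.norm.ppf((ranks - 0.5) / n)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def transform_matrix(matrix) -> "MetaboliteMatrix | RatioMatrix":
    """Apply the inverse normal transform to every column of a matrix."""
    transformed = matrix.values.apply(inverse_normal_transform, axis=0)
    if isinstance(matrix, RatioMatrix):
        return RatioMatrix(transformed, matrix.pairs, "transformed")
    return MetaboliteMatrix(transformed, dict(matrix.pathways), "transformed")


def build_ratio_matrix(
    matrix: MetaboliteMatrix,
    include_pathways: Iterable[str] = ("amino acid", "peptide", "lipid-fatty acid"),
) -> RatioMatrix:
    """All pairwise ratios of metabolites in the selected super-pathways.

    One ratio per unordered pair of eligible metabolites, oriented
    lexicographically (numerator < denominator); ``C(m, 2)`` ratios for ``m``
    eligible metabolites.  A ratio value is missing whenever either member is
    missing or the denominator is zero.
    """
    matrix._require_state("pqn-normalized")
    include = set(include_pathways)
    if not include:
        raise ValueError("include_pathways must not be empty")
    eligible = sorted(
        m for m in matrix.metabolites if matrix.pathways.get(m, "other") in include
    )
    cols: dict[str, np.ndarray] = {}
    records = []
    vals = matrix.values
    for a, b in combinations(eligible, 2):
        denom = vals[b].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = vals[a].to_numpy(dtype=float) / denom
        ratio[denom == 0] = np.nan
        rid = f"{a}/{b}"
        cols[rid] = ratio
        records.append(
            {
                "ratio_id": rid,
                "numerator": a,
                "denominator": b,
                "pathway_a": matrix.pathways.get(a, "other"),
                "pathway_b": matrix.pathways.get(b, "other"),
            }
        )
    values = pd.DataFrame(cols, index=matrix.samples)
    pairs = pd.DataFrame(
        records, columns=["ratio_id", "numerator", "denominator", "pathway_a", "pathway_b"]
    )
    return RatioMatrix(values, pairs, "pqn-normalized")


def write_metabolite_tsv(matrix: MetaboliteMatrix, path: str | Path) -> None:
    """Write samples x metabolites TSV (empty cell = missing)."""
    matrix.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def read_metabolite_tsv(
    path: str | Path, pathways: dict[str, str] | None = None, state: str = "raw"
) -> MetaboliteMatrix:
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    return MetaboliteMatrix(values, pathways or {}, state)
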
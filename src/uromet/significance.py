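"""Multiple-testing thresholds, the p-gain statistic, and result assembly.

Discovery is Bonferroni-based: the family-wise error rate alpha is divided by
(number of genes) x (number of phenotypes) x (number of aggregation tests).
For metabolite ratios, results are additionally filtered by the p-gain — the
lower of the two component metabolites' p-values divided by the ratio's
p-value — which measures the information a ratio adds beyond its members.  A
ratio is retained when its p-gain is at least 10 times the number of
evaluated ratios.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ThresholdSpec",
    "bonferroni_threshold",
    "p_gain",
    "log10_p_gain",
    "p_gain_retention_threshold",
    "round_sig",
    "assemble_results",
    "write_run_summary",
]


@dataclass
class ThresholdSpec:
    alpha: float = 0.05
    n_genes: int = 1
    n_phenotypes: int = 1
    n_tests: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if min(self.n_genes, self.n_phenotypes, self.n_tests) < 1:
            raise ValueError("all counts must be >= 1")


def bonferroni_threshold(spec: ThresholdSpec) -> float:
    """alpha / (n_genes * n_phenotypes * n_tests), at full precision."""
    return spec.alpha / (spec.n_genes * spec.n_phenotypes * spec.n_tests)


def round_sig(x: float, digits: int) -> float:
    """Round to ``digits`` significant digits, half away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - digits + 1)
    return math.floor(abs(x) / scale + 0.5) * scale * (1 if x > 0 else -1)


def log10_p_gain(p_a: float, p_b: float, p_ratio: float) -> float:
    """log10 of the p-gain; overflow-safe for subnormal p-values."""
    for p in (p_a, p_b, p_ratio):
        if not (0 < p <= 1):
            raise ValueError("p-values must be in (0, 1]")
    return math.log10(min(p_a, p_b)) - math.log10(p_ratio)


def p_gain(p_a: float, p_b: float, p_ratio: float) -> float:
    """min(p_A, p_B) / p_ratio, computed in log space.

    Invariant to which member is labeled A or B.  Values beyond float range
    are returned as inf (the log10 value is available separately).
    """
    lg = log10_p_gain(p_a, p_b, p_ratio)
    try:
        return 10.0 ** lg
    except OverflowError:
        return math.inf


def p_gain_retention_threshold(n_ratios: int) -> float:
    """Retain ratios with a p-gain of at least 10 times the number evaluated."""
    if n_ratios < 1:
        raise ValueError("n_ratios must be >= 1")
    return 10.0 * n_ratios


def _label(p_burden: float, p_skat: float, threshold: float) -> str:
    b = p_burden < threshold
    s = p_skat < threshold
    if b and s:
        return "Both"
    if b:
        return "B"
    if s:
        return "S"
    return ""


def assemble_results(
    results: pd.DataFrame,
    threshold: float,
    suggestive_threshold: float | None = None,
    pgain_retention: float | None = None,
) -> dict[str, pd.DataFrame]:
    """Split gene x phenotype results into significant / suggestive tables.

    ``results`` needs columns ``p_burden`` and ``p_skat`` (plus, for ratio
    phenotypes, ``log10_p_gain_burden`` / ``log10_p_gain_skat`` when a p-gain
    retention filter is applied).  Significant rows are labeled "B", "S" or
    "Both" by which test falls below the threshold; ratio rows must also
    exceed the p-gain retention threshold in the corresponding test.
    """
    df = results.copy()
    df["significant_test"] = [
        _label(b, s, threshold) for b, s in zip(df["p_burden"], df["p_skat"])
    ]
    sig = df[df["significant_test"] != ""].copy()
    if pgain_retention is not None and len(sig):
        log10_thr = math.log10(pgain_retention)
        keep = []
        for row in sig.itertuples():
            gains = []
            if row.significant_test in ("B", "Both"):
                gains.append(getattr(row, "log10_p_gain_burden"))
            if row.significant_test in ("S", "Both"):
                gains.append(getattr(row, "log10_p_gain_skat"))
            keep.append(any(g >= log10_thr for g in gains))
        sig = sig[keep]
    out = {"significant": sig.reset_index(drop=True)}
    if suggestive_threshold is not None:
        below = (df["p_burden"] < suggestive_threshold) | (df["p_skat"] < suggestive_threshold)
        out["suggestive"] = df[below & (df["significant_test"] == "")].reset_index(drop=True)
    return out


def write_run_summary(path: str | Path, **fields) -> None:
    """Machine-readable JSON summary of thresholds and counts."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
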
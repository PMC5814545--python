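"""Truncation selection: rankings, top-k persistence and response R = h2 * S.

Compares how two evaluation models (e.g. pedigree-based vs genomic-based)
rank candidates, how much of the top fraction persists between them, and
how the expected response to selection differs. The selection differential
S is the mean standardized phenotype of the selected group (optionally the
mean breeding value), and the response follows the breeder's equation
R = h2 * S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import VarianceReport
from .lmm import REMLFit

__all__ = [
    "SelectionReport",
    "rank_individuals",
    "top_k_overlap",
    "response_to_selection",
    "response_reduction",
    "compare_selection",
]


@dataclass
class SelectionReport:
    model_a: str
    model_b: str
    k: int
    overlap_percent: float
    response: dict[str, float]
    reduction_percent: float


def rank_individuals(fit: REMLFit) -> list[str]:
    """Ids ordered by additive breeding value, best first; ties by id."""
    if "a" not in fit.blup:
        raise ValueError("fit has no additive breeding values")
    bv = fit.blup["a"]
    order = sorted(bv.index, key=lambda i: (-bv[i], str(i)))
    return [str(i) for i in order]


def top_k_overlap(rank_a: list[str], rank_b: list[str], k: int = 50) -> float:
    """Percent of model A's top-k retained in model B's top-k."""
    if set(rank_a) != set(rank_b):
        raise ValueError("rankings cover different individuals")
    if k > len(rank_a):
        raise ValueError(f"k={k} exceeds population size {len(rank_a)}")
    return 100.0 * len(set(rank_a[:k]) & set(rank_b[:k])) / k


def response_to_selection(
    fit: REMLFit,
    report: VarianceReport,
    phenotypes: pd.Series,
    k: int | None = None,
    basis: str = "phenotype",
) -> float:
    """Response R = h2 * S for truncation selection of the top-k by BV.

    ``phenotypes`` maps individual id to the standardized phenotype. The
    selection differential S is the mean of the selected group minus the
    population mean — of the phenotype (default, the classical breeder's
    equation) or of the breeding values (``basis='bv'``).
    """
    if k is None:
        k = max(1, round(0.05 * len(phenotypes)))  # 5% selection intensity
    if k < 1:
        raise ValueError("k must be >= 1")
    selected = rank_individuals(fit)[:k]
    if basis == "phenotype":
        values = phenotypes
    elif basis == "bv":
        values = fit.blup["a"]
    else:
        raise ValueError(f"unknown basis {basis!r}")
    values = values.dropna()
    sel = values.reindex(selected).dropna()
    S = float(sel.mean() - values.mean())
    h2 = report.h2[0]
    return h2 * S


def response_reduction(r_ref: float, r_alt: float) -> float:
    """Percent reduction of response: 100 * (1 - r_alt / r_ref)."""
    if r_ref == 0:
        raise ValueError("reference response is zero; reduction undefined")
    return 100.0 * (1.0 - r_alt / r_ref)


def compare_selection(
    fit_a: REMLFit,
    report_a: VarianceReport,
    fit_b: REMLFit,
    report_b: VarianceReport,
    phenotypes: pd.Series,
    k: int | None = None,
    basis: str = "phenotype",
) -> SelectionReport:
    """Full two-model comparison: overlap, responses and reduction."""
    if k is None:
        k = max(1, round(0.05 * len(phenotypes)))
    rank_a = rank_individuals(fit_a)
    rank_b = rank_individuals(fit_b)
    r_a = response_to_selection(fit_a, report_a, phenotypes, k=k, basis=basis)
    r_b = response_to_selection(fit_b, report_b, phenotypes, k=k, basis=basis)
    return SelectionReport(
        model_a=fit_a.spec.name,
        model_b=fit_b.spec.name,
        k=k,
        overlap_percent=top_k_overlap(rank_a, rank_b, k=k),
        response={fit_a.spec.name: r_a, fit_b.spec.name: r_b},
        reduction_percent=response_reduction(r_a, r_b) if r_a != 0 else float("nan"),
    )
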
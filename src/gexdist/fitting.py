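"""Per-gene distribution selection: BIC ranking gated by the KS test.

For one expression vector, all sixteen candidate families are fitted; the
candidates are ranked by BIC = -2 ln L + k ln n (ascending) and the first
candidate whose one-sample Kolmogorov-Smirnov p-value clears the gate
(default P >= 0.01) is declared the gene's optimal distribution.  If no
candidate clears the gate the gene is UNFITTED.  KS p-values use the
asymptotic Kolmogorov distribution with the fitted parameters treated as
fixed, mirroring the classical test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .distributions import (
    FAMILY_ORDER,
    DegenerateDataError,
    Family,
    FitOptions,
    ParamVector,
    TooFewSamplesError,
    cdf as family_cdf,
    fit_parameters,
)
from .matrixio import ExpressionMatrix

__all__ = [
    "FitResult",
    "GeneAssignment",
    "SelectionOptions",
    "UNFITTED",
    "ecdf",
    "ks_statistic",
    "ks_pvalue",
    "ks_test",
    "replace_outliers",
    "select_optimal_distribution",
    "fit_matrix",
    "assignments_to_frame",
    "family_counts",
]

#: Sentinel used in tables for genes no candidate family fits.
UNFITTED = "UNFITTED"

_BIC_TIE_TOL = 1e-9


@dataclass
class FitResult:
    """One family's fit of one gene: likelihood, BIC, and KS gate values."""

    gene_id: str | None
    params: ParamVector
    loglik: float
    k: int
    n: int
    bic: float
    ks_D: float
    ks_p: float

    def __post_init__(self) -> None:
        expected = -2.0 * self.loglik + self.k * math.log(self.n)
        if math.isfinite(self.bic) and abs(self.bic - expected) > 1e-9 * max(
            1.0, abs(expected)
        ):
            raise ValueError("BIC inconsistent with loglik, k, n")


@dataclass
class GeneAssignment:
    """BIC-ranked candidate fits and the selected family (or UNFITTED)."""

    gene_id: str | None
    candidates: list[FitResult] = field(default_factory=list)
    selected: Family | None = None
    selected_ks_p: float | None = None
    skipped: list[tuple[Family, str]] = field(default_factory=list)
    reason: str | None = None

    @property
    def is_fitted(self) -> bool:
        return self.selected is not None

    @property
    def selected_result(self) -> FitResult | None:
        if self.selected is None:
            return None
        for c in self.candidates:
            if c.params.family is self.selected:
                return c
        return None


@dataclass(frozen=True)
class SelectionOptions(FitOptions):
    """Fitting options plus the selection-procedure knobs."""

    ks_gate: float = 0.01
    replace_outliers: bool = False
    z_threshold: float = 3.0
    families: tuple[Family, ...] = FAMILY_ORDER


def ecdf(values: Sequence[float], x) -> np.ndarray | float:
    """Right-continuous empirical CDF: fraction of observations <= x."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    srt = np.sort(v)
    xq = np.asarray(x, dtype=float)
    out = np.searchsorted(srt, np.atleast_1d(xq), side="right") / v.size
    return float(out[0]) if xq.ndim == 0 else out


def ks_statistic(values: Sequence[float], cdf: Callable[[np.ndarray], np.ndarray]) -> float:
    """Exact sup-distance between the sample ECDF and a theoretical CDF.

    Computed from the sorted sample as
    max_i max(|i/n - F(x_(i))|, |(i-1)/n - F(x_(i))|).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite observations")
    srt = np.sort(v)
    n = v.size
    f = np.clip(np.asarray(cdf(srt), dtype=float), 0.0, 1.0)
    i = np.arange(1, n + 1)
    d_plus = np.max(np.abs(i / n - f))
    d_minus = np.max(np.abs((i - 1) / n - f))
    return float(max(d_plus, d_minus))


def ks_pvalue(d: float, n: int) -> float:
    """Asymptotic two-sided KS p-value: P(K > sqrt(n) * D)."""
    return float(special.kolmogorov(math.sqrt(n) * d))


def ks_test(values: Sequence[float], params: ParamVector) -> tuple[float, float]:
    """KS statistic and asymptotic p-value against a fitted family's CDF."""
    v = np.asarray(values, dtype=float).ravel()
    d = ks_statistic(v, lambda x: family_cdf(params, x))
    return d, ks_pvalue(d, v.size)


def replace_outliers(values: Sequence[float], z_threshold: float = 3.0) -> np.ndarray:
    """Replace entries with |z-score| > threshold by the original median.

    Mean, standard deviation (1/n) and median are computed once, on the
    unmodified vector.  A constant vector is returned unchanged with a
    warning.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(v))
    if sd == 0:
        warnings.warn("constant vector: outlier replacement skipped")
        return v.copy()
    z = (v - float(np.mean(v))) / sd
    out = v.copy()
    out[np.abs(z) > z_threshold] = float(np.median(v))
    return out


def _rank_by_bic(results: list[FitResult]) -> list[FitResult]:
    """Ascending BIC; ties within 1e-9 broken by canonical family order."""
    order_idx = {f: i for i, f in enumerate(FAMILY_ORDER)}
    ranked = sorted(
        results, key=lambda r: (r.bic, order_idx[r.params.family])
    )
    # regroup near-ties deterministically by family order
    out: list[FitResult] = []
    i = 0
    while i < len(ranked):
        j = i + 1
        while j < len(ranked) and abs(ranked[j].bic - ranked[i].bic) < _BIC_TIE_TOL:
            j += 1
        group = sorted(ranked[i:j], key=lambda r: order_idx[r.params.family])
        out.extend(group)
        i = j
    return out


def select_optimal_distribution(
    values: Sequence[float],
    options: SelectionOptions | None = None,
    gene_id: str | None = None,
) -> GeneAssignment:
    """Fit all candidate families and select by BIC rank + KS gate.

    Families whose fit degenerates are skipped (recorded, never fatal).
    The first BIC-ranked candidate with KS p >= the gate is selected; if
    none qualifies the gene is UNFITTED with the full candidate table
    retained.
    """
    opt = options or SelectionOptions()
    v = np.asarray(values, dtype=float).ravel()
    if len(v) < opt.min_obs:
        raise TooFewSamplesError(f"need >= {opt.min_obs} observations, got {len(v)}")
    if opt.replace_outliers:
        v = replace_outliers(v, opt.z_threshold)
    assignment = GeneAssignment(gene_id=gene_id)
    results: list[FitResult] = []
    for fam in opt.families:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = fit_parameters(fam, v, opt)
            d, p = ks_test(v, out.params)
            bic = -2.0 * out.loglik + out.k * math.log(out.n)
            results.append(
                FitResult(
                    gene_id=gene_id,
                    params=out.params,
                    loglik=out.loglik,
                    k=out.k,
                    n=out.n,
                    bic=bic,
                    ks_D=d,
                    ks_p=p,
                )
            )
        except DegenerateDataError as e:
            assignment.skipped.append((fam, str(e)))
        except Exception as e:  # a misbehaving family must not block selection
            assignment.skipped.append((fam, f"{type(e).__name__}: {e}"))
    assignment.candidates = _rank_by_bic(results)
    for cand in assignment.candidates:
        if cand.ks_p >= opt.ks_gate:
            assignment.selected = cand.params.family
            assignment.selected_ks_p = cand.ks_p
            break
    if assignment.selected is None:
        if not assignment.candidates and assignment.skipped:
            assignment.reason = (
                f"all families skipped ({assignment.skipped[0][1]})"
            )
        else:
            assignment.reason = "no candidate passed the KS gate"
    return assignment


def fit_matrix(
    matrix: ExpressionMatrix, options: SelectionOptions | None = None
) -> list[GeneAssignment]:
    """Run the selection procedure independently for every gene.

    Per-gene failures (constant vectors, too-few samples) yield an
    UNFITTED-with-reason assignment; they never abort the matrix.
    """
    opt = options or SelectionOptions()
    out: list[GeneAssignment] = []
    for gene_id in matrix.gene_ids:
        v = matrix.gene(gene_id)
        try:
            out.append(select_optimal_distribution(v, opt, gene_id=gene_id))
        except (DegenerateDataError, TooFewSamplesError, ValueError) as e:
            out.append(GeneAssignment(gene_id=gene_id, reason=str(e)))
    return out


_TABLE_COLUMNS = [
    "gene_id",
    "selected_family",
    "params_json",
    "loglik",
    "k",
    "n",
    "bic",
    "ks_D",
    "ks_p",
    "status",
]


def assignments_to_frame(assignments: list[GeneAssignment]) -> pd.DataFrame:
    """Fixed-column table of selected fits (one row per gene)."""
    rows = []
    for a in assignments:
        sel = a.selected_result
        if sel is not None:
            rows.append(
                {
                    "gene_id": a.gene_id,
                    "selected_family": a.selected.value,
                    "params_json": sel.params.to_json(),
                    "loglik": sel.loglik,
                    "k": sel.k,
                    "n": sel.n,
                    "bic": sel.bic,
                    "ks_D": sel.ks_D,
                    "ks_p": sel.ks_p,
                    "status": "ok",
                }
            )
        else:
            rows.append(
                {
                    "gene_id": a.gene_id,
                    "selected_family": UNFITTED,
                    "params_json": "",
                    "loglik": np.nan,
                    "k": np.nan,
                    "n": np.nan,
                    "bic": np.nan,
                    "ks_D": np.nan,
                    "ks_p": np.nan,
                    "status": a.reason or "unfitted",
                }
            )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def family_counts(assignments: list[GeneAssignment]) -> pd.Series:
    """Number of genes per selected family (UNFITTED included)."""
    names = [a.selected.value if a.selected else UNFITTED for a in assignments]
    idx = [f.value for f in FAMILY_ORDER] + [UNFITTED]
    return pd.Series(names).value_counts().reindex(idx, fill_value=0)
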
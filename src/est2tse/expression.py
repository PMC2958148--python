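"""Relative quantification of qPCR data and contingency-table statistics.

Implements the 2^-ddCt method: replicate cycle-threshold (Ct) values are
averaged per (sample, gene); dCt = Ct(gene) - Ct(endogenous control, e.g.
TBP); ddCt = dCt - dCt(reference); relative quantity RQ = 2^-ddCt.  Two
reference conventions are supported, matching common practice:

* ``"min"`` — the sample with the lowest normalized Ct (highest expressor)
  is the reference, so every RQ is <= 1;
* an explicit collection of reference sample IDs (e.g. all benign-lesion
  samples), whose mean dCt is the reference, per gene.

Also implements the likelihood-ratio chi-square (G-test) for r x c
contingency tables, G = 2 * sum O * ln(O/E) with the 0*ln(0) = 0
convention, referred to a chi-square distribution on (r-1)(c-1) df.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

CT_COLUMNS = ("sample_id", "gene", "ct")


@dataclass(frozen=True)
class RelativeExpression:
    """One sample/gene relative-expression result (RQ = 2^-ddCt)."""

    sample_id: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    rq: float


def _mean_ct(ct: pd.DataFrame) -> pd.Series:
    """Replicate Ct values averaged per (sample, gene)."""
    for col in CT_COLUMNS:
        if col not in ct.columns:
            raise DataError(f"Ct table lacks required column {col!r}")
    vals = pd.to_numeric(ct["ct"], errors="coerce")
    if vals.isna().any() or not np.isfinite(vals).all() or (vals <= 0).any():
        raise DataError("Ct values must be positive finite numbers")
    return ct.assign(ct=vals).groupby(["sample_id", "gene"])["ct"].mean()


def relative_expression(
    ct: pd.DataFrame,
    control_gene: str,
    reference: str | Iterable[str] = "min",
) -> list[RelativeExpression]:
    """Convert a replicate Ct table to relative expression via 2^-ddCt.

    ``ct`` has one row per replicate measurement with columns
    ``sample_id``, ``gene``, ``ct``.  Every sample must include the
    endogenous control gene.  ``reference`` is ``"min"`` or a collection of
    sample IDs whose mean dCt defines the per-gene reference.
    """
    mean_ct = _mean_ct(ct)
    samples = mean_ct.index.get_level_values("sample_id").unique()
    genes = [
        g for g in mean_ct.index.get_level_values("gene").unique()
        if g != control_gene
    ]
    if not genes:
        raise DataError("Ct table contains only the control gene")

    control = {}
    for s in samples:
        if (s, control_gene) not in mean_ct.index:
            raise DataError(
                f"sample {s!r} lacks the endogenous control {control_gene!r}"
            )
        control[s] = mean_ct[(s, control_gene)]

    # per-gene dCt over the samples measured for that gene
    dct: dict[str, dict[str, float]] = {
        g: {
            s: mean_ct[(s, g)] - control[s]
            for s in samples
            if (s, g) in mean_ct.index
        }
        for g in genes
    }

    out: list[RelativeExpression] = []
    for g in genes:
        if not dct[g]:
            continue
        if isinstance(reference, str) and reference == "min":
            ref_dct = min(dct[g].values())
        else:
            ref_ids = [s for s in reference]
            missing = [s for s in ref_ids if s not in dct[g]]
            if not ref_ids or missing:
                raise DataError(
                    f"reference samples {missing or ref_ids} not measured "
                    f"for gene {g!r}"
                )
            ref_dct = float(np.mean([dct[g][s] for s in ref_ids]))
        for s, d in dct[g].items():
            ddct = d - ref_dct
            out.append(
                RelativeExpression(
                    sample_id=s, gene=g,
                    delta_ct=float(d),
                    delta_delta_ct=float(ddct),
                    rq=float(2.0 ** (-ddct)),
                )
            )
    return out


def relative_expression_frame(
    ct: pd.DataFrame, control_gene: str,
    reference: str | Iterable[str] = "min",
) -> pd.DataFrame:
    """:func:`relative_expression` as a tidy DataFrame."""
    return pd.DataFrame(
        [vars(r) for r in relative_expression(ct, control_gene, reference)]
    )


# ---------------------------------------------------------------------------
# Likelihood-ratio chi-square (G-test)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GTestResult:
    statistic: float   # G
    df: int
    pvalue: float
    expected: np.ndarray

    def __iter__(self):  # (G, df, p) unpacking
        return iter((self.statistic, self.df, self.pvalue))


def lr_chisq(table: Sequence[Sequence[float]]) -> GTestResult:
    """Likelihood-ratio chi-square test of independence on an r x c table.

    G = 2 * sum_ij O_ij * ln(O_ij / E_ij) with E from the margins and
    0*ln(0) := 0; df = (r-1)(c-1); p is the upper chi-square tail.
    A zero row or column total makes the test degenerate and raises.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError("contingency table must be at least 2x2")
    if (obs < 0).any() or not np.isfinite(obs).all():
        raise DataError("observed counts must be finite and non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if n <= 0 or (row == 0).any() or (col == 0).any():
        raise DataError("degenerate table: zero grand, row, or column total")
    expected = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    g = float(2.0 * terms.sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return GTestResult(g, df, float(stats.chi2.sf(g, df)), expected)


# ---------------------------------------------------------------------------
# Group-comparison pass-throughs (plumbing, not reimplemented)
# ---------------------------------------------------------------------------

def anova_log(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA on natural-log-transformed positive expression values."""
    logged = []
    for g in groups:
        arr = np.asarray(g, dtype=float)
        if (arr <= 0).any():
            raise DataError("ANOVA-on-log requires strictly positive values")
        logged.append(np.log(arr))
    f, p = stats.f_oneway(*logged)
    return float(f), float(p)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (rank-based group comparison)."""
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)
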
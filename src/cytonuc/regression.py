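"""Compensatory-substitution linear model for aaRS / mt-tRNA rates.

For each amino-acid specificity i, let Y_i be the substitution rate of an
aminoacyl-tRNA synthetase (mean pairwise WAG distance to an outgroup), X_i
the substitution rate of the mitochondrial tRNA of the same specificity
(mean pairwise K80 distance), and delta_mt an indicator for the synthetase
functioning in the mitochondrion.  The full model is

    Y_i = b0 + b1*delta_mt + b2*X_i + b3*X_i*delta_mt + e_i

where b1 captures rate acceleration under relaxed selection on
mitochondrial translation, b2 the shared-specificity coupling between
synthetase and tRNA rates, and b3 the interaction attributable to
compensatory substitutions.  Nested sub-models fix b3 = 0 ("no_interaction")
or b3 = b2 = 0 ("intercepts_only"); relative fit is judged by nested F
tests.  Fitting is ordinary least squares (statsmodels OLS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MODEL_TAGS = ("full", "no_interaction", "intercepts_only")

#: design columns per model tag (intercept always included)
_MODEL_COLUMNS = {
    "full": ("delta_mt", "X", "X_mt"),
    "no_interaction": ("delta_mt", "X"),
    "intercepts_only": ("delta_mt",),
}

_COEF_NAMES = {
    "full": ("b0", "b1", "b2", "b3"),
    "no_interaction": ("b0", "b1", "b2"),
    "intercepts_only": ("b0", "b1"),
}


def assemble_rate_table(aars_distances: dict[tuple[str, str], float],
                        trna_distances: dict[str, float]) -> pd.DataFrame:
    """Join synthetase and tRNA rates into the regression table.

    ``aars_distances`` maps (specificity letter, lineage in {mt, cy}) to the
    synthetase rate; ``trna_distances`` maps specificity to the mt-tRNA
    rate, which is shared across the mt and cy rows of that specificity.
    """
    rows = []
    for (spec, lineage), y in sorted(aars_distances.items()):
        if lineage not in ("mt", "cy"):
            raise ValueError(f"lineage must be 'mt' or 'cy', got {lineage!r}")
        if spec not in trna_distances:
            raise ValueError(f"no mt-tRNA rate for specificity {spec!r}")
        if not (math.isfinite(y) and y >= 0):
            raise ValueError(f"non-finite aaRS rate for {spec}/{lineage}")
        rows.append({"specificity": spec, "delta_mt": int(lineage == "mt"),
                     "X": float(trna_distances[spec]), "Y": float(y)})
    df = pd.DataFrame(rows, columns=["specificity", "delta_mt", "X", "Y"])
    if df.duplicated(["specificity", "delta_mt"]).any():
        raise ValueError("duplicate (specificity, lineage) rows")
    return df


@dataclass
class LinearFit:
    model_tag: str
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_statistics: dict[str, float]
    p_values: dict[str, float]
    residual_df: int
    sse: float
    r_squared: float
    n: int

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


def _design(table: pd.DataFrame, model_tag: str) -> np.ndarray:
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    tab = table.assign(X_mt=table["X"] * table["delta_mt"])
    cols = [np.ones(len(tab))] + [tab[c].to_numpy(float) for c in _MODEL_COLUMNS[model_tag]]
    return np.column_stack(cols)


def fit_linear_model(table: pd.DataFrame, model_tag: str = "full") -> LinearFit:
    """OLS fit of the compensatory model or one of its nested cases."""
    D = _design(table, model_tag)
    y = table["Y"].to_numpy(float)
    n, p = D.shape
    if n <= p:
        raise ValueError(f"need more than {p} rows to fit {model_tag!r}")
    if np.linalg.matrix_rank(D) < p:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, D).fit()
    names = _COEF_NAMES[model_tag]
    return LinearFit(
        model_tag=model_tag,
        coefficients=dict(zip(names, res.params)),
        standard_errors=dict(zip(names, res.bse)),
        t_statistics=dict(zip(names, res.tvalues)),
        p_values=dict(zip(names, res.pvalues)),
        residual_df=int(res.df_resid),
        sse=float(res.ssr),
        r_squared=float(res.rsquared) if np.isfinite(res.rsquared) else 0.0,
        n=n,
    )


@dataclass
class NestedComparison:
    restricted_tag: str
    full_tag: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float


def nested_f_test(restricted: LinearFit, full: LinearFit) -> NestedComparison:
    """F = [(SSE_r - SSE_f)/d_num] / [SSE_f/d_den] with p from F(d_num, d_den)."""
    order = {tag: i for i, tag in enumerate(MODEL_TAGS)}
    if order[restricted.model_tag] <= order[full.model_tag]:
        raise ValueError("models are not properly nested")
    if restricted.n != full.n:
        raise ValueError("fits use different data")
    df_num = full.n_params - restricted.n_params
    df_den = full.residual_df
    num = max(restricted.sse - full.sse, 0.0) / df_num
    den = full.sse / df_den
    if den == 0:
        f = math.inf if num > 0 else 0.0
    else:
        f = num / den
    p = float(stats.f.sf(f, df_num, df_den)) if math.isfinite(f) else 0.0
    return NestedComparison(restricted.model_tag, full.model_tag, f,
                            df_num, df_den, p)


def select_most_parsimonious(table: pd.DataFrame, alpha: float = 0.05
                             ) -> tuple[LinearFit, dict[str, LinearFit]]:
    """Backward selection by nested F tests from the full model.

    Drops the interaction, then the slope, whenever the reduction is not
    rejected at ``alpha``; returns the selected fit plus all three fits.
    """
    fits = {tag: fit_linear_model(table, tag) for tag in MODEL_TAGS}
    selected = fits["full"]
    cmp1 = nested_f_test(fits["no_interaction"], fits["full"])
    if cmp1.p_value >= alpha:
        selected = fits["no_interaction"]
        cmp2 = nested_f_test(fits["intercepts_only"], fits["no_interaction"])
        if cmp2.p_value >= alpha:
            selected = fits["intercepts_only"]
    return selected, fits


def mt_cy_rate_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between paired mt and cy synthetase rates.

    Pairs Y_mt with Y_cy across specificities having both lineages; returns
    (r, two-sided t-based p-value).  Requires at least 3 pairs.
    """
    mt = table[table["delta_mt"] == 1].set_index("specificity")["Y"]
    cy = table[table["delta_mt"] == 0].set_index("specificity")["Y"]
    shared = mt.index.intersection(cy.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 specificities with both mt and cy rates")
    r, p = stats.pearsonr(mt.loc[shared], cy.loc[shared])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Tab-separated I/O
# ---------------------------------------------------------------------------

def read_rate_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"specificity", "delta_mt", "X", "Y"}
    if not required <= set(df.columns):
        raise ValueError(f"rate table must have columns {sorted(required)}")
    return df


def write_rate_table(table: pd.DataFrame, path: str, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write(f"# n_rows={len(table)}\n")
        table.to_csv(fh, sep="\t", index=False)


def fit_summary(fit: LinearFit) -> str:
    lines = [f"model\t{fit.model_tag}", f"n\t{fit.n}",
             f"sse\t{fit.sse:.8g}", f"r_squared\t{fit.r_squared:.6f}",
             f"residual_df\t{fit.residual_df}",
             "coef\testimate\tse\tt\tp"]
    for name in fit.coefficients:
        lines.append(f"{name}\t{fit.coefficients[name]:.6g}\t"
                     f"{fit.standard_errors[name]:.6g}\t"
                     f"{fit.t_statistics[name]:.4g}\t{fit.p_values[name]:.4g}")
    return "\n".join(lines)
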
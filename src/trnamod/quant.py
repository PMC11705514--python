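"""Relative quantification of tRNA modifications from XIC peak areas.

Nucleoside extracted-ion-chromatogram peak areas are normalized per sample
by the summed peak area of the four canonical nucleosides (A, G, C, U),
which cancels sample-to-sample differences in tRNA input and matrix effects.
Fold changes across a blood-feeding time course are taken relative to the
mean non-blood-fed (NBF) level.  Significance of a time-course effect per
nucleoside uses an ordinary least squares model with time point as a
categorical factor (overall F-test); modification–enzyme interactions are
assessed with per-pair OLS fits carrying enzyme expression, treatment and
time terms, reporting a type-II F and p per term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

CANONICAL = ("A", "G", "C", "U")
TIME_ORDER = ("NBF", "6H", "12H", "24H", "48H", "72H")

__all__ = ["CANONICAL", "TIME_ORDER", "ModelResult", "normalize", "fold_change",
           "per_nucleoside_model", "interaction_model", "interaction_screen",
           "microarray_fold_change", "fold_change_heatmap"]


@dataclass(frozen=True)
class ModelResult:
    """Per-term F statistics from one modification–enzyme regression."""

    modification: str
    enzyme: str
    terms: pd.DataFrame  # index: term; columns: F, p


def _require_columns(table: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")


def normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized`` column: area / Σ(canonical areas of the sample).

    Long format in, long format out (columns sample, time, nucleoside, area;
    a tissue column is carried through if present).  Every sample must carry
    positive areas for all four canonical nucleosides.  Modifications absent
    from a sample simply have no row — never a zero.

    Closure is exact: within each sample the last canonical fraction is set
    to the correctly rounded complement of the other three, so the exact
    (fsum) total of the four canonical normalized abundances is 1.0.
    """
    _require_columns(table, ("sample", "nucleoside", "area"))
    out = table.copy()
    sums = {}
    for sample, grp in out.groupby("sample"):
        canon = grp[grp["nucleoside"].isin(CANONICAL)]
        present = set(canon["nucleoside"])
        if present != set(CANONICAL):
            raise ValueError(
                f"sample {sample!r}: canonical nucleosides missing: "
                f"{sorted(set(CANONICAL) - present)}"
            )
        if (canon["area"] <= 0).any():
            raise ValueError(f"sample {sample!r}: non-positive canonical peak area")
        total = float(canon.groupby("nucleoside")["area"].mean().sum())
        if total <= 0:
            raise ValueError(f"sample {sample!r}: canonical area sum is not positive")
        sums[sample] = total
    out["normalized"] = out["area"] / out["sample"].map(sums)
    # exact closure: the largest canonical fraction absorbs rounding error
    canon_mask = out["nucleoside"].isin(CANONICAL)
    for sample, grp in out[canon_mask].groupby("sample"):
        idx_last = grp.index[-1]
        others = grp.drop(index=idx_last)["normalized"]
        out.loc[idx_last, "normalized"] = math.fsum([1.0, *(-v for v in others)])
    return out


def fold_change(
    table: pd.DataFrame, reference: str = "NBF", value_col: str = "normalized"
) -> pd.DataFrame:
    """Per-(nucleoside, time) fold change of mean normalized abundance vs the
    reference time point.  The reference row is 1 by construction; a zero
    reference mean yields NaN with an ``undefined`` flag."""
    _require_columns(table, ("time", "nucleoside", value_col))
    if reference not in set(table["time"]):
        raise ValueError(f"reference time point {reference!r} absent from table")
    means = (
        table.groupby(["nucleoside", "time"], sort=False)[value_col]
        .mean()
        .rename("mean")
        .reset_index()
    )
    ref = means[means["time"] == reference].set_index("nucleoside")["mean"]
    means["ref_mean"] = means["nucleoside"].map(ref)
    means["fold_change"] = np.where(
        means["ref_mean"] > 0, means["mean"] / means["ref_mean"], np.nan
    )
    means["undefined"] = ~(means["ref_mean"] > 0)
    order = {t: i for i, t in enumerate(TIME_ORDER)}
    means = means.sort_values(
        ["nucleoside", "time"], key=lambda s: s.map(lambda v: order.get(v, v))
    )
    return means.reset_index(drop=True)


def per_nucleoside_model(
    table: pd.DataFrame,
    value_col: str = "normalized",
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Overall F-test of a time-point effect per nucleoside (OLS, categorical
    time).  Returns one row per nucleoside with F, p and a significance call
    at ``alpha``; ``adjust=True`` adds Benjamini–Hochberg adjusted p-values.
    """
    _require_columns(table, ("time", "nucleoside", value_col))
    rows = []
    for nuc, grp in table.groupby("nucleoside", sort=False):
        grp = grp.dropna(subset=[value_col])
        n_times = grp["time"].nunique()
        if n_times < 2:
            raise ValueError(f"nucleoside {nuc!r}: need >=2 time points, got {n_times}")
        counts = grp.groupby("time").size()
        if (counts < 2).any():
            raise ValueError(
                f"nucleoside {nuc!r}: need >=2 replicates per time point "
                f"(factor 'time' level(s) {list(counts[counts < 2].index)})"
            )
        if grp[value_col].nunique() <= 1:  # identical values everywhere
            fval, pval = 0.0, 1.0
        else:
            fit = smf.ols(f"Q('{value_col}') ~ C(time)", data=grp).fit()
            fval = float(fit.fvalue)
            pval = float(fit.f_pvalue)
            if not np.isfinite(fval):
                fval, pval = 0.0, 1.0
        rows.append({"nucleoside": nuc, "F": fval, "p": pval})
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out


def interaction_model(
    modification: pd.Series | Sequence[float],
    enzyme_expression: pd.Series | Sequence[float],
    treatment: Sequence,
    time: Optional[Sequence] = None,
    modification_name: str = "modification",
    enzyme_name: str = "enzyme",
) -> ModelResult:
    """Per-pair regression of a modification level on a single enzyme's
    expression with treatment (and optionally time) factors.

    Inputs must be sample-matched, equal-length vectors.  Terms with no
    information (constant expression, single-level factors) are dropped;
    the remaining terms get type-II F and p values.  With constant enzyme
    expression and no time factor this reduces to a one-way ANOVA of the
    modification on treatment.
    """
    mod = np.asarray(modification, dtype=float)
    expr = np.asarray(enzyme_expression, dtype=float)
    treat = np.asarray(treatment)
    if not (len(mod) == len(expr) == len(treat)):
        raise ValueError("modification, enzyme expression and treatment must be sample-matched")
    data = pd.DataFrame({"mod": mod, "expr": expr, "treatment": treat})
    terms = []
    if np.nanstd(expr) > 0:
        terms.append("expr")
    if data["treatment"].nunique() > 1:
        terms.append("C(treatment)")
    if time is not None:
        t = np.asarray(time)
        if len(t) != len(mod):
            raise ValueError("time must be sample-matched")
        data["time"] = t
        if data["time"].nunique() > 1:
            terms.append("C(time)")
    if not terms:
        raise ValueError("no informative terms: expression constant and factors single-level")
    fit = smf.ols("mod ~ " + " + ".join(terms), data=data.dropna()).fit()
    table = anova_lm(fit, typ=2)
    table = table.drop(index="Residual")
    rename = {"expr": "expression", "C(treatment)": "treatment", "C(time)": "time"}
    out = pd.DataFrame(
        {"F": table["F"].values, "p": table["PR(>F)"].values},
        index=[rename.get(i, i) for i in table.index],
    )
    return ModelResult(modification_name, enzyme_name, out)


def interaction_screen(
    mod_table: pd.DataFrame,
    expr_table: pd.DataFrame,
    pairs: Optional[Iterable[tuple]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`interaction_model` over modification–enzyme pairs.

    ``mod_table``: columns sample, treatment, time, nucleoside, normalized.
    ``expr_table``: columns sample, gene, value (sample ids shared).
    Returns one row per (modification, enzyme, term) with F, p and the
    significance call — the layout of a per-pair interaction table.
    """
    _require_columns(mod_table, ("sample", "treatment", "time", "nucleoside", "normalized"))
    _require_columns(expr_table, ("sample", "gene", "value"))
    if pairs is None:
        pairs = [
            (nuc, gene)
            for nuc in mod_table["nucleoside"].unique()
            if nuc not in CANONICAL
            for gene in expr_table["gene"].unique()
        ]
    rows = []
    for nuc, gene in pairs:
        m = mod_table[mod_table["nucleoside"] == nuc].set_index("sample")
        e = expr_table[expr_table["gene"] == gene].set_index("sample")
        shared = m.index.intersection(e.index)
        if len(shared) == 0:
            raise ValueError(f"no shared samples for pair ({nuc}, {gene})")
        m = m.loc[shared]
        res = interaction_model(
            m["normalized"], e.loc[shared, "value"], m["treatment"], m["time"],
            modification_name=nuc, enzyme_name=gene,
        )
        for term, row in res.terms.iterrows():
            rows.append({
                "modification": nuc, "enzyme": gene, "term": term,
                "F": row["F"], "p": row["p"], "significant": row["p"] < alpha,
            })
    return pd.DataFrame(rows)


def microarray_fold_change(
    expression: pd.DataFrame,
    probe_map: pd.DataFrame,
    reference: str = "NBF",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-level fold change vs the reference time point from probe-level
    microarray values, plus a per-gene time-course F-test.

    ``expression``: columns probe, sample, time, value.  ``probe_map``:
    columns probe, gene (a gene may have several probes; probe values are
    averaged per gene per sample before anything else).
    """
    _require_columns(expression, ("probe", "sample", "time", "value"))
    _require_columns(probe_map, ("probe", "gene"))
    merged = expression.merge(probe_map, on="probe", how="left")
    if merged["gene"].isna().any():
        orphans = merged.loc[merged["gene"].isna(), "probe"].unique()
        raise ValueError(f"probes without a gene mapping: {list(orphans)[:5]}")
    genes_without = set(probe_map["gene"]) - set(merged["gene"])
    if genes_without:
        raise ValueError(f"genes with no probes measured: {sorted(genes_without)}")
    per_gene = (
        merged.groupby(["gene", "sample", "time"], sort=False)["value"].mean().reset_index()
    )
    rows = []
    for gene, grp in per_gene.groupby("gene", sort=False):
        means = grp.groupby("time")["value"].mean()
        if reference not in means.index:
            raise ValueError(f"gene {gene!r}: reference {reference!r} missing")
        ref = means[reference]
        if grp["value"].nunique() <= 1:
            fval, pval = 0.0, 1.0
        else:
            fit = smf.ols("value ~ C(time)", data=grp).fit()
            fval, pval = float(fit.fvalue), float(fit.f_pvalue)
            if not np.isfinite(fval):
                fval, pval = 0.0, 1.0
        for t, m in means.items():
            rows.append({
                "gene": gene, "time": t,
                "fold_change": m / ref if ref > 0 else np.nan,
                "F": fval, "p": pval, "significant": pval < alpha,
            })
    order = {t: i for i, t in enumerate(TIME_ORDER)}
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["gene", "time"], key=lambda s: s.map(lambda v: order.get(v, v))
    ).reset_index(drop=True)


def fold_change_heatmap(fc: pd.DataFrame, significance: Optional[pd.DataFrame] = None,
                        ax=None):
    """log2 fold-change heatmap (nucleosides × time points), significance
    marked with '*'.  Display only; returns the matplotlib Axes."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    mat = fc.pivot(index="nucleoside", columns="time", values="fold_change")
    cols = [t for t in TIME_ORDER if t in mat.columns]
    mat = mat[cols]
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(cols), 1 + 0.3 * len(mat)))
    with np.errstate(divide="ignore"):
        img = ax.imshow(np.log2(mat.values), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(cols)), cols)
    ax.set_yticks(range(len(mat)), mat.index)
    ax.figure.colorbar(img, ax=ax, label="log2 fold change vs NBF")
    if significance is not None:
        sig = significance.set_index("nucleoside")["significant"]
        for i, nuc in enumerate(mat.index):
            if sig.get(nuc, False):
                ax.text(len(cols) - 0.4, i, "*", va="center", fontsize=12)
    return ax
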
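"""Significant/specific phenotype calls and cohort statistics.

A gene has a *significant* phenotype in a condition when |fitness| > 1 and
|t| > 4 (strict inequalities, configurable). It is *specific* for the
fatty/dicarboxylic-acid conditions when it is significant in at least one
experimental (non-control) condition while showing |fitness| < 1 on the
glucose (or lactate) control. Calls are then classified by substrate class
(DA/FA), chain-length parity, and chain-length range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "call_significant",
    "call_specific",
    "classify_matrix",
    "summarize_cohort",
    "CohortSummary",
]

FITNESS_THRESHOLD = 1.0
T_THRESHOLD = 4.0
DIRECT_CATEGORIES = ("β-oxidation", "transporter", "regulator")


def call_significant(fitness, t, thresholds=(FITNESS_THRESHOLD, T_THRESHOLD)):
    """|fitness| > 1 and |t| > 4, strict; masked (NaN) cells are False.

    Vectorized over arrays.
    """
    f_thr, t_thr = thresholds
    f = np.asarray(fitness, dtype=float)
    tt = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        out = (np.abs(f) > f_thr) & (np.abs(tt) > t_thr)
    return out & ~np.isnan(f) & ~np.isnan(tt)


def call_specific(
    significant_experimental: np.ndarray,
    control_fitness: float,
    control_t: float = np.nan,
    thresholds=(FITNESS_THRESHOLD, T_THRESHOLD),
    control_rule: str = "fitness_lt_1",
) -> bool:
    """Specificity screen for one gene.

    ``control_rule="fitness_lt_1"`` (default): |control fitness| < 1; a
    masked control cell fails conservatively. The alternative
    ``"no_significant"`` requires only that the control condition is not
    itself significant.
    """
    if not np.asarray(significant_experimental, dtype=bool).any():
        return False
    if control_rule == "fitness_lt_1":
        if np.isnan(control_fitness):
            return False
        return bool(abs(control_fitness) < thresholds[0])
    if control_rule == "no_significant":
        return not bool(call_significant(control_fitness, control_t, thresholds))
    raise ValueError(f"unknown control_rule {control_rule!r}")


def classify_matrix(
    fitness_matrix: pd.DataFrame,
    t_matrix: pd.DataFrame,
    conditions: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    thresholds=(FITNESS_THRESHOLD, T_THRESHOLD),
    control_rule: str = "fitness_lt_1",
) -> pd.DataFrame:
    """Per-locus phenotype call table from replicate-averaged matrices.

    Returns one row per locus with columns: significant, specific, classes
    (subset of "DA,FA" as a comma-joined string), parity ("odd,even"
    subset), min_len, max_len, category.
    """
    if not fitness_matrix.columns.equals(t_matrix.columns) or not fitness_matrix.index.equals(t_matrix.index):
        raise ValueError("fitness and t matrices must be aligned")
    cond = conditions.set_index("condition_name").reindex(fitness_matrix.columns)
    if cond["condition_class"].isna().any():
        missing = cond.index[cond["condition_class"].isna()].tolist()
        raise ValueError(f"conditions missing from taxonomy: {missing}")
    controls = cond.index[cond["condition_class"] == "control"]
    if len(controls) != 1:
        raise ValueError(f"expected exactly one control condition, found {list(controls)}")
    control = controls[0]
    experimental = [c for c in fitness_matrix.columns if c != control]

    sig = pd.DataFrame(
        call_significant(fitness_matrix.to_numpy(), t_matrix.to_numpy(), thresholds),
        index=fitness_matrix.index,
        columns=fitness_matrix.columns,
    )

    if annotations is not None:
        unknown = set(annotations["locus"]) - set(fitness_matrix.index)
        if unknown:
            logger.warning("%d annotation loci absent from matrix (ignored)", len(unknown))
        cat_of = annotations.set_index("locus")["category"]
    else:
        cat_of = pd.Series(dtype=object)

    rows = []
    for locus in fitness_matrix.index:
        sig_exp = sig.loc[locus, experimental]
        significant = bool(sig_exp.any())
        specific = call_specific(
            sig_exp.to_numpy(),
            fitness_matrix.at[locus, control],
            t_matrix.at[locus, control],
            thresholds,
            control_rule,
        )
        sig_conds = cond.loc[sig_exp.index[sig_exp]]
        dafa = sig_conds[sig_conds["condition_class"].isin(["DA", "FA"])]
        classes = sorted(dafa["condition_class"].unique())
        lens = dafa["chain_length"].dropna().astype(int)
        parity = sorted({"odd" if l % 2 else "even" for l in lens}, reverse=True)
        rows.append(
            {
                "locus": locus,
                "significant": significant,
                "specific": specific,
                "classes": ",".join(classes),
                "parity": ",".join(parity),
                "min_len": int(lens.min()) if len(lens) else pd.NA,
                "max_len": int(lens.max()) if len(lens) else pd.NA,
                "category": cat_of.get(locus, "other"),
            }
        )
    calls = pd.DataFrame(rows).set_index("locus")
    # invariant: specific implies significant
    assert not (calls["specific"] & ~calls["significant"]).any()
    return calls


@dataclass
class CohortSummary:
    """Counts and percentages over the significant+specific gene cohort."""

    n_significant_specific: int
    n_da_only: int
    n_fa_only: int
    n_both: int
    pct_da_only: float
    pct_fa_only: float
    pct_both: float
    pct_direct_categories: float
    category_counts: dict = field(default_factory=dict)
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "n_significant_specific": self.n_significant_specific,
            "n_da_only": self.n_da_only,
            "n_fa_only": self.n_fa_only,
            "n_both": self.n_both,
            "pct_da_only": self.pct_da_only,
            "pct_fa_only": self.pct_fa_only,
            "pct_both": self.pct_both,
            "pct_direct_categories": self.pct_direct_categories,
            "category_counts": dict(self.category_counts),
            "empty": self.empty,
        }


def summarize_cohort(calls: pd.DataFrame) -> CohortSummary:
    """Cohort statistics over the significant+specific set.

    Percentages are rounded to one decimal; DA-only/FA-only/both need not sum
    to 100 (the remainder had calls only in control/aromatic/other
    conditions).
    """
    cohort = calls[calls["significant"] & calls["specific"]]
    n = len(cohort)
    if n == 0:
        return CohortSummary(0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, {}, empty=True)
    da_only = int((cohort["classes"] == "DA").sum())
    fa_only = int((cohort["classes"] == "FA").sum())
    both = int((cohort["classes"] == "DA,FA").sum())
    direct = int(cohort["category"].isin(DIRECT_CATEGORIES).sum())
    cats = cohort["category"].value_counts().to_dict()
    pct = lambda k: round(100.0 * k / n, 1)
    return CohortSummary(
        n_significant_specific=n,
        n_da_only=da_only,
        n_fa_only=fa_only,
        n_both=both,
        pct_da_only=pct(da_only),
        pct_fa_only=pct(fa_only),
        pct_both=pct(both),
        pct_direct_categories=pct(direct),
        category_counts=cats,
    )
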
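"""Translation-efficiency statistics for a two-condition, two-replicate design.

Works on FPKM tables from matched mRNA-input and ribosome-footprint libraries
(wild type vs mutant, two biological replicates each). Per replicate,
translation efficiency (TE) is the ratio of CDS-restricted footprint FPKM
(RPF) to input FPKM; the per-condition TE is the geometric mean over
replicates, and the quantity compared across codon-defined gene groups is the
TE fold change mutant/wild-type.

Differential-expression calls use the three-way conjunction: |fold change|
beyond 2x, adjusted p < 0.05, and replicate signal-to-noise ratio

    SNR = |X - Y| / (|x1 - x2| + |y1 - y2|)  > 1

where X, Y are condition means and x_i, y_i the replicate FPKMs. The SNR
filter discards genes whose between-condition difference is no larger than
the within-condition replicate scatter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SnrRecord",
    "compute_snr",
    "ExpressionTable",
    "compute_te",
    "te_fold_change",
    "call_de",
    "compare_groups",
    "GroupComparison",
    "cumulative_summary",
]

REQUIRED_SHEET_COLUMNS = ("sample", "assay", "condition", "replicate")
ASSAYS = ("input_mrna", "ribo_footprint")


@dataclass(frozen=True)
class SnrRecord:
    x1: float
    x2: float
    y1: float
    y2: float

    @property
    def X(self) -> float:
        return (self.x1 + self.x2) / 2.0

    @property
    def Y(self) -> float:
        return (self.y1 + self.y2) / 2.0

    @property
    def snr(self) -> float:
        num = abs(self.X - self.Y)
        den = abs(self.x1 - self.x2) + abs(self.y1 - self.y2)
        if den == 0.0:
            return math.inf if num > 0.0 else 0.0
        return num / den


def compute_snr(x1: float, x2: float, y1: float, y2: float) -> SnrRecord:
    """Replicate signal-to-noise ratio of a 2x2 FPKM design.

    Zero-denominator convention: identical replicates within both conditions
    give SNR = +inf when the condition means differ (perfectly reproducible
    difference) and 0 when they do not.
    """
    vals = (x1, x2, y1, y2)
    if any(v < 0 for v in vals):
        raise ValueError(f"FPKM values must be non-negative, got {vals}")
    return SnrRecord(x1, x2, y1, y2)


class ExpressionTable:
    """Gene x sample FPKM matrix plus a sample sheet.

    ``values``: DataFrame indexed by gene_id, one column per sample.
    ``samples``: DataFrame with columns sample/assay/condition/replicate.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if samples["sample"].duplicated().any():
            dups = samples.loc[samples["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample names: {dups}")
        unknown = set(samples["sample"]) - set(values.columns)
        if unknown:
            raise ValueError(f"samples absent from the value table: {sorted(unknown)}")
        bad_assay = set(samples["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ValueError(f"unknown assay labels: {sorted(bad_assay)}")
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression table")
        if (values[samples["sample"]] < 0).any().any():
            raise ValueError("negative FPKM values")
        self.values = values
        self.samples = samples.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    def column(self, assay: str, condition: str, replicate: int) -> pd.Series:
        sel = self.samples[
            (self.samples["assay"] == assay)
            & (self.samples["condition"] == condition)
            & (self.samples["replicate"] == replicate)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"need exactly one sample for ({assay}, {condition}, rep {replicate}), "
                f"found {len(sel)}"
            )
        return self.values[sel["sample"].iloc[0]]

    def replicates(self, assay: str, condition: str) -> list[int]:
        sel = self.samples[
            (self.samples["assay"] == assay) & (self.samples["condition"] == condition)
        ]
        return sorted(sel["replicate"].tolist())

    def validate_design(self) -> None:
        """Require the full factorial assay x condition design with matched
        replicate indices, >= 2 replicates each."""
        unmatched = []
        for cond in self.conditions:
            reps_by_assay = {a: self.replicates(a, cond) for a in ASSAYS}
            reps = set(reps_by_assay[ASSAYS[0]])
            for a in ASSAYS:
                if len(reps_by_assay[a]) < 2:
                    unmatched.append(f"{a}/{cond}: fewer than 2 replicates")
                if set(reps_by_assay[a]) != reps:
                    unmatched.append(f"{a}/{cond}: replicate mismatch {reps_by_assay}")
        if unmatched:
            raise ValueError("unmatched design: " + "; ".join(unmatched))


def compute_te(
    expr: ExpressionTable,
    min_fpkm: float = 0.0,
    min_rpf: float = 0.0,
    wildtype: str = "wildtype",
    mutant: str = "mutant",
) -> pd.DataFrame:
    """Per-gene TE per replicate and condition, with a ``translated`` flag.

    A gene is ``translated`` only if input FPKM > min_fpkm and RPF > min_rpf
    in every replicate of both conditions; otherwise its TEs are NaN and it
    is excluded from downstream group tests. Condition TE is the geometric
    mean of replicate TEs. Returns a DataFrame indexed by gene_id with
    columns te_<cond>_rep<k>, te_<cond>, te_fold_change, translated.
    """
    expr.validate_design()
    conds = expr.conditions
    if not {wildtype, mutant} <= set(conds):
        raise ValueError(
            f"conditions {wildtype!r}/{mutant!r} not both present in {conds}"
        )
    out = pd.DataFrame(index=expr.values.index)
    translated = pd.Series(True, index=expr.values.index)
    for cond in (wildtype, mutant):
        reps = expr.replicates("input_mrna", cond)
        te_cols = []
        for rep in reps:
            inp = expr.column("input_mrna", cond, rep)
            rpf = expr.column("ribo_footprint", cond, rep)
            ok = (inp > min_fpkm) & (rpf > min_rpf)
            translated &= ok
            te = pd.Series(np.nan, index=inp.index)
            te[ok] = rpf[ok] / inp[ok]
            col = f"te_{cond}_rep{rep}"
            out[col] = te
            te_cols.append(col)
        # geometric mean over replicates
        out[f"te_{cond}"] = np.exp(np.log(out[te_cols]).mean(axis=1))
    out["translated"] = translated
    out.loc[~translated, [c for c in out.columns if c.startswith("te_")]] = np.nan
    out["te_fold_change"] = out[f"te_{mutant}"] / out[f"te_{wildtype}"]
    return out


def te_fold_change(te_table: pd.DataFrame) -> pd.Series:
    """Mutant/wild-type TE ratio for translated genes; undefined genes dropped."""
    fc = te_table.loc[te_table["translated"], "te_fold_change"]
    return fc.dropna()


def call_de(
    expr: ExpressionTable,
    fc_cutoff: float = 2.0,
    alpha: float = 0.05,
    snr_cutoff: float = 1.0,
    assay: str = "input_mrna",
    wildtype: str = "wildtype",
    mutant: str = "mutant",
    pseudocount: float = 1.0,
    test: Callable[..., object] | None = None,
) -> pd.DataFrame:
    """Differential-expression calls under the three-way conjunction.

    Fold change is mutant/wild-type mean FPKM; the p-value comes from a
    two-sided Welch t-test on log2(FPKM + pseudocount) across replicates
    (swappable via ``test``), BH-adjusted; SNR per the replicate filter.
    ``called`` requires fold change > fc_cutoff or < 1/fc_cutoff, adjusted
    p < alpha, and SNR > snr_cutoff simultaneously. Genes with all-zero rows
    are excluded.
    """
    expr.validate_design()
    x = np.column_stack(
        [expr.column(assay, wildtype, r) for r in expr.replicates(assay, wildtype)]
    )
    y = np.column_stack(
        [expr.column(assay, mutant, r) for r in expr.replicates(assay, mutant)]
    )
    genes = expr.values.index
    nonzero = (x.sum(axis=1) + y.sum(axis=1)) > 0
    x, y, genes = x[nonzero], y[nonzero], genes[nonzero]

    xm, ym = x.mean(axis=1), y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(xm > 0, ym / xm, np.inf)
    lx = np.log2(x + pseudocount)
    ly = np.log2(y + pseudocount)
    if test is None:
        pvals = stats.ttest_ind(ly, lx, axis=1, equal_var=False).pvalue
    else:
        pvals = np.array([test(ly[i], lx[i]).pvalue for i in range(len(genes))])
    # zero-variance rows (identical values) have undefined t p-values; they
    # cannot be evidence of change, so assign p = 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]
    snr = np.array(
        [compute_snr(x[i, 0], x[i, 1], y[i, 0], y[i, 1]).snr for i in range(len(genes))]
    )
    called = (
        ((fold > fc_cutoff) | (fold < 1.0 / fc_cutoff))
        & (padj < alpha)
        & (snr > snr_cutoff)
    )
    return pd.DataFrame(
        {
            "fold_change": fold,
            "p_value": pvals,
            "p_adjusted": padj,
            "snr": snr,
            "called": called,
        },
        index=genes,
    )


@dataclass
class GroupComparison:
    """Omnibus + pairwise nonparametric comparison across gene groups."""

    statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p_value, p_adjusted
    letters: dict[str, str]
    summary: pd.DataFrame  # n, median, mean, q1, q3 per group
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "kruskal_statistic": self.statistic,
            "kruskal_p": self.p_value,
            "pairwise": self.pairwise.to_dict(orient="records"),
            "letters": self.letters,
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "degenerate": self.degenerate,
        }


def _compact_letter_display(
    groups: Sequence[str], distinct: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups not significantly different share at least one letter; each pair
    in ``distinct`` shares none.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in distinct:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for t in (sa, sb):
                    if not any(t <= u for u in letter_sets):
                        letter_sets.append(t)
    # deterministic letter order: by first group appearance
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def compare_groups(
    fold_changes: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    min_group_size: int = 3,
) -> GroupComparison:
    """Kruskal-Wallis omnibus plus pairwise rank-sum tests with BH adjustment.

    The compact-letter display assigns shared letters to groups that do not
    differ at adjusted p < alpha. Groups smaller than ``min_group_size`` are
    dropped with a warning. All-identical values are reported as degenerate.
    """
    fc = pd.Series(fold_changes, dtype=float).dropna()
    grp = pd.Series(groups).reindex(fc.index).dropna()
    fc = fc.reindex(grp.index)
    by_group = {g: fc[grp == g].to_numpy() for g in pd.unique(grp)}
    small = [g for g, v in by_group.items() if len(v) < min_group_size]
    if small:
        import warnings

        warnings.warn(f"groups below size {min_group_size} excluded: {small}",
                      stacklevel=2)
        by_group = {g: v for g, v in by_group.items() if g not in small}
    if len(by_group) < 2:
        raise ValueError("need at least two groups of sufficient size")
    names = list(by_group)
    summary = pd.DataFrame(
        {
            "n": [len(by_group[g]) for g in names],
            "median": [float(np.median(by_group[g])) for g in names],
            "mean": [float(np.mean(by_group[g])) for g in names],
            "q1": [float(np.quantile(by_group[g], 0.25)) for g in names],
            "q3": [float(np.quantile(by_group[g], 0.75)) for g in names],
        },
        index=pd.Index(names, name="group"),
    )
    pooled = np.concatenate(list(by_group.values()))
    if np.all(pooled == pooled[0]):
        pairwise = pd.DataFrame(
            columns=["group_a", "group_b", "statistic", "p_value", "p_adjusted"]
        )
        return GroupComparison(
            statistic=float("nan"),
            p_value=float("nan"),
            pairwise=pairwise,
            letters={g: "a" for g in names},
            summary=summary,
            degenerate=True,
        )
    stat, p = stats.kruskal(*by_group.values())
    rows = []
    for a, b in combinations(names, 2):
        u, pu = stats.mannwhitneyu(by_group[a], by_group[b], alternative="two-sided")
        rows.append((a, b, float(u), float(pu)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])
    pairwise["p_adjusted"] = multipletests(pairwise["p_value"], method="fdr_bh")[1]
    distinct = {
        (r.group_a, r.group_b)
        for r in pairwise.itertuples()
        if r.p_adjusted < alpha
    }
    letters = _compact_letter_display(names, distinct)
    return GroupComparison(
        statistic=float(stat),
        p_value=float(p),
        pairwise=pairwise,
        letters=letters,
        summary=summary,
    )


def cumulative_summary(
    fold_changes: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Empirical CDF points per group (no smoothing), for cumulative plots.

    Returns columns group, value, cum_fraction with values sorted ascending
    within each group and cum_fraction = rank/n.
    """
    fc = pd.Series(fold_changes, dtype=float).dropna()
    grp = pd.Series(groups).reindex(fc.index).dropna()
    fc = fc.reindex(grp.index)
    frames = []
    for g in pd.unique(grp):
        vals = np.sort(fc[grp == g].to_numpy())
        if len(vals) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "value": vals,
                    "cum_fraction": np.arange(1, len(vals) + 1) / len(vals),
                }
            )
        )
    if not frames:
        raise ValueError("no non-empty groups")
    return pd.concat(frames, ignore_index=True)
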
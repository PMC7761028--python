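"""Relative qPCR expression by the comparative 2^-ddCt (Livak) method.

Per sample, dCt = Ct(target) - Ct(reference housekeeping gene); ddCt
subtracts the mean dCt of the calibrator condition at the same timepoint;
fold change = 2^-ddCt, so the calibrator averages to 1 by construction.
Group differences are assessed by one-way ANOVA with Tukey's HSD post-hoc
test, summarized as compact letter display (groups sharing a letter are not
significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "condition", "timepoint", "gene", "replicate", "ct"]


@dataclass
class CtTable:
    """Replicate Ct measurements in long format."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing column(s) {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be > 0")

    @classmethod
    def read(cls, path: str | Path) -> "CtTable":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())


@dataclass
class FoldChangeResult:
    """Mean fold change, sd, and Tukey group letter per (condition, timepoint)."""

    target: str
    reference: str
    calibrator: str
    table: pd.DataFrame  # condition, timepoint, mean_fold, sd_fold, letter
    replicate_folds: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def delta_delta_ct(ct: CtTable, target: str, reference: str,
                   calibrator: str, alpha: float = 0.05,
                   letters_on: str = "fold") -> FoldChangeResult:
    """Livak fold changes with replicate statistics and Tukey letters.

    The calibrator mean dCt is taken per timepoint from the ``calibrator``
    condition; per-replicate folds are then averaged.  ``letters_on`` selects
    whether ANOVA/Tukey runs on the fold or the dCt scale.
    """
    df = ct.data
    piv = df[df["gene"].isin([target, reference])].pivot_table(
        index=["condition", "timepoint", "replicate"], columns="gene",
        values="ct", aggfunc="mean")
    for gene in (target, reference):
        if gene not in piv.columns or piv[gene].isna().any():
            missing = (piv.index[piv[gene].isna()].tolist()
                       if gene in piv.columns else "all samples")
            raise ValueError(f"missing Ct for gene {gene!r} in: {missing}")
    dct = piv[target] - piv[reference]

    if calibrator not in df["condition"].unique():
        raise ValueError(f"calibrator condition {calibrator!r} absent")

    rows = []
    rep_folds: dict[tuple[str, str], np.ndarray] = {}
    rep_dct: dict[tuple[str, str], np.ndarray] = {}
    timepoints = list(dict.fromkeys(df["timepoint"]))
    conditions = list(dict.fromkeys(df["condition"]))
    for tp in timepoints:
        cal = dct.loc[(calibrator, tp)]
        cal_mean = float(np.mean(cal))
        for cond in conditions:
            try:
                d = dct.loc[(cond, tp)]
            except KeyError:
                continue
            d_arr = np.asarray(d, dtype=float)
            ddct = d_arr - cal_mean
            folds = np.power(2.0, -ddct)
            rep_folds[(cond, str(tp))] = folds
            rep_dct[(cond, str(tp))] = d_arr
            # geometric mean = 2^-(mean ddCt); computing the mean as
            # mean(dCt) - cal_mean makes the calibrator fold exactly 1
            mean_ddct = float(np.mean(d_arr)) - cal_mean
            rows.append({"condition": cond, "timepoint": tp,
                         "mean_fold": float(2.0 ** (-mean_ddct)),
                         "sd_fold": float(folds.std(ddof=1))
                         if len(folds) > 1 else 0.0})

    groups = rep_folds if letters_on == "fold" else rep_dct
    letters = anova_tukey({f"{c}@{t}": v for (c, t), v in groups.items()},
                          alpha=alpha).letters
    table = pd.DataFrame(rows)
    table["letter"] = [letters[f"{r.condition}@{r.timepoint}"]
                       for r in table.itertuples()]
    return FoldChangeResult(target, reference, calibrator, table, rep_folds)


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]
    tukey_p: dict[tuple[str, str], float]


def anova_tukey(groups: dict[str, np.ndarray],
                alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA F test plus Tukey HSD compact letter display.

    Groups sharing a letter are not significantly different at ``alpha``.
    When the omnibus F test is not significant, all groups share one letter.
    """
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for n, v in zip(names, values):
        if len(v) < 2:
            raise ValueError(f"group {n!r} has a single replicate")

    if np.ptp(np.concatenate(values)) == 0:
        # all observations identical: no variance anywhere
        return AnovaTukeyResult(0.0, 1.0, {n: "a" for n in names},
                                {(a, b): 1.0 for a in names for b in names
                                 if a < b})

    f_stat, p = stats.f_oneway(*values)
    tukey_p: dict[tuple[str, str], float] = {}
    if p < alpha:
        res = stats.tukey_hsd(*values)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    tukey_p[(a, b)] = float(res.pvalue[i, j])
    else:
        tukey_p = {(a, b): 1.0 for i, a in enumerate(names)
                   for j, b in enumerate(names) if i < j}

    distinct = {pair for pair, pv in tukey_p.items() if pv < alpha}
    letters = _compact_letter_display(names, distinct,
                                      means=[float(v.mean()) for v in values])
    return AnovaTukeyResult(float(f_stat), float(p), letters, tukey_p)


def _compact_letter_display(names: list[str],
                            distinct: set[tuple[str, str]],
                            means: list[float]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Each letter marks a maximal set of mutually non-different groups; groups
    are processed in descending mean order so 'a' labels the largest mean.
    """
    order = [n for _, n in sorted(zip(means, names), key=lambda t: -t[0])]

    def differ(a: str, b: str) -> bool:
        return (a, b) in distinct or (b, a) in distinct

    letter_sets: list[set[str]] = []
    for name in order:
        placed = False
        for s in letter_sets:
            if not any(differ(name, other) for other in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # absorb sets fully contained in another
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets)
                              if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {n: "" for n in names}
    for letter, s in zip(alphabet, letter_sets):
        for n in order:
            if n in s:
                out[n] += letter
    return out
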
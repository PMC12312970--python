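"""Group statistics and expression math.

Comparative-Cq (ΔΔCq) fold induction for qPCR with reference-gene
(GAPDH) normalization, blank-corrected percent-of-control normalization
for cDNA plate arrays, and two-sample Student's t-tests with the
significance-star convention *p ≤ 0.05, **p ≤ 0.01, ***p ≤ 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: star thresholds, inclusive (legends print "p ≤ 0.05")
STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the figure-legend star convention."""
    for level, stars in STAR_LEVELS:
        if p <= level:
            return stars
    return ""


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison summary (Student's t-test)."""

    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    p_value: float
    stars: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")
        if self.stars != significance_stars(self.p_value):
            raise ValueError("stars inconsistent with p-value")


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> GroupComparison:
    """Two-sided two-sample t-test between two groups of measurements.

    Uses the classic pooled-variance Student's t-test by default (matching
    the study's stated method); set ``welch=True`` for unequal variances.
    Each group needs at least two values.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    t, p = float(t), float(p)
    if np.isnan(p):  # both groups constant and equal
        t, p = 0.0, 1.0
    return GroupComparison(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=int(a.size),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=int(b.size),
        t_statistic=t, p_value=p, stars=significance_stars(p),
    )


def _check_cq(cq: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "group", "gene", "cq"}
    missing = required - set(cq.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    return cq


def fold_induction(
    cq: pd.DataFrame,
    target_gene: str,
    ref_gene: str = "GAPDH",
    control_group: str = "Mock",
) -> pd.Series:
    """Comparative-Cq (ΔΔCq) fold induction per group, control ≡ 1.

    Per sample, replicate Cq values are averaged and
    ΔCq = Cq(target) − Cq(reference); per group,
    ΔΔCq = mean ΔCq(group) − mean ΔCq(control) and
    fold = 2^(−ΔΔCq).  Reference-gene normalization makes the result
    invariant to any constant shift of the whole Cq table.

    Returns a Series of fold inductions indexed by group.
    """
    cq = _check_cq(cq)
    genes = set(cq["gene"])
    for gene in (target_gene, ref_gene):
        if gene not in genes:
            raise ValueError(f"gene {gene!r} not present in the Cq table")
    if control_group not in set(cq["group"]):
        raise ValueError(f"control group {control_group!r} not in the table")
    # average technical replicates per (sample, gene)
    per_sample = (
        cq.groupby(["group", "sample", "gene"])["cq"].mean().unstack("gene")
    )
    for gene in (target_gene, ref_gene):
        if per_sample[gene].isna().any():
            bad = per_sample[per_sample[gene].isna()].index.tolist()
            raise ValueError(f"missing {gene} Cq for samples {bad}")
    dcq = per_sample[target_gene] - per_sample[ref_gene]
    mean_dcq = dcq.groupby(level="group").mean()
    ddcq = mean_dcq - mean_dcq[control_group]
    return np.power(2.0, -ddcq).rename("fold_induction")


def plate_normalize(
    plate: pd.DataFrame,
    blank: float,
    ref_gene: str = "GAPDH",
    control_group: str = "Mock",
) -> pd.DataFrame:
    """Blank-corrected, GAPDH-normalized percent-of-control per gene.

    Each gene's luminescence is background-corrected with the blank well
    and divided by the blank-corrected reference-gene signal of its group;
    the result is expressed as percent of the control group's normalized
    value (control ≡ 100%).  Invariant to rescaling all luminescence
    values (blank included).

    Returns a DataFrame indexed by gene with one percent column per group.
    """
    required = {"gene", "group", "luminescence"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    if (plate["luminescence"] < 0).any():
        raise ValueError("luminescence values must be >= 0")
    groups = list(dict.fromkeys(plate["group"]))
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in the table")
    lum = plate.groupby(["group", "gene"])["luminescence"].mean()
    norm: Dict[str, pd.Series] = {}
    for group in groups:
        g = lum.loc[group]
        if ref_gene not in g.index:
            raise ValueError(f"reference gene {ref_gene!r} missing in {group!r}")
        ref = g[ref_gene] - blank
        if ref <= 0:
            raise ValueError(
                f"reference-gene signal does not exceed blank in {group!r}"
            )
        norm[group] = (g - blank) / ref
    out = pd.DataFrame(norm)
    control = out[control_group]
    percent = out.div(control, axis=0) * 100.0
    percent.columns = [f"{g}_percent_of_control" for g in percent.columns]
    return percent


def morphometry_group_tests(
    table: pd.DataFrame,
    group_col: str = "group",
    value_cols: Sequence[str] = ("volume_um3", "elongation", "compactness_norm",
                                "chromatin_density"),
    welch: bool = False,
) -> pd.DataFrame:
    """Student's t-tests between the two groups of a morphometry table.

    Returns one row per measurement column with group means ± SD, t, p and
    significance stars.
    """
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    ga, gb = groups
    rows = []
    for col in value_cols:
        cmp_ = compare_groups(
            table.loc[table[group_col] == ga, col],
            table.loc[table[group_col] == gb, col],
            welch=welch,
        )
        rows.append({
            "measure": col,
            f"mean_{ga}": cmp_.mean_a, f"sd_{ga}": cmp_.sd_a,
            f"mean_{gb}": cmp_.mean_b, f"sd_{gb}": cmp_.sd_b,
            "t": cmp_.t_statistic, "p": cmp_.p_value, "stars": cmp_.stars,
        })
    return pd.DataFrame(rows).set_index("measure")
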
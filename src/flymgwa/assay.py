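"""Colony-count assay processing and phenotype statistics.

The persistence assay measures, per fly, the number of colony-forming units
(CFU) remaining after serial transfers to sterile diet.  Colonies on a
dilution plate are converted to CFU per fly at a fixed scale (800 CFU per
colony at defaults); plates too dense to count are right-censored at the
ceiling of 160 colonies = 128,000 CFU per fly and recorded at that point
value.  Whole vials are excluded when the fly density is below 30 or when
undiluted aliquots showed more than 5 CFU of an unexpected colony
morphology (contamination).

Group comparisons of log2(CFU+1) use Kruskal-Wallis omnibus tests, Dunn's
post hoc test with a compact letter display, pairwise two-group tests
against a control strain, and per-strain Wilcoxon comparisons between
sexes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .ranktests import (
    compact_letter_display,
    dunn_z_matrix,
    kruskal_p,
    rank_sum_test,
)
from scipy import stats as _sps

#: colony-count ceiling above which plates are uncountable
DEFAULT_CEILING_COLONIES = 160
#: CFU per counted colony implied by the dilution scheme (128,000 / 160)
DEFAULT_COLONY_SCALE = 800
#: vials with fewer flies than this are discarded
MIN_VIAL_DENSITY = 30
#: vials whose undiluted aliquots bear more than this many foreign CFU
#: are considered contaminated
MAX_UNEXPECTED_CFU = 5

#: canonical column order of the tidy CFU table
CFU_COLUMNS = [
    "strain",
    "experiment",
    "vial",
    "fly",
    "sex",
    "colony_count",
    "too_dense",
    "contaminated_vial",
    "unexpected_colony_count",
    "vial_density",
]


@dataclass
class FlyCfuRecord:
    """One fly's plate count and its vial-level context."""

    strain: str
    experiment: str = "E1"
    vial: str = "V1"
    fly: int = 1
    sex: str = "female"
    colony_count: int = 0
    too_dense: bool = False
    contaminated_vial: bool = False
    unexpected_colony_count: int = 0
    vial_density: int = 40

    def cfu_per_fly(
        self,
        colony_scale: int = DEFAULT_COLONY_SCALE,
        ceiling_colonies: int = DEFAULT_CEILING_COLONIES,
    ) -> int:
        return int(
            colonies_to_cfu(
                self.colony_count,
                self.too_dense,
                colony_scale=colony_scale,
                ceiling_colonies=ceiling_colonies,
            )
        )

    def log_cfu(self, **kwargs) -> float:
        return float(np.log2(self.cfu_per_fly(**kwargs) + 1))


@dataclass
class GroupTestResult:
    """Omnibus rank test over two or more groups."""

    statistic: float
    df: int
    p: float
    groups: list
    method: str = "chi2"
    letters: dict | None = None


def colonies_to_cfu(
    colony_count,
    too_dense=False,
    *,
    colony_scale: int = DEFAULT_COLONY_SCALE,
    ceiling_colonies: int = DEFAULT_CEILING_COLONIES,
):
    """Convert plate colony counts to CFU per fly.

    Too-dense plates are assigned the censoring point
    ``ceiling_colonies * colony_scale`` (128,000 at defaults); countable
    plates scale linearly.  Accepts scalars or arrays.
    """
    if colony_scale <= 0:
        raise ValueError("colony_scale must be positive")
    counts = np.asarray(colony_count)
    if np.any(counts < 0):
        raise ValueError("colony_count must be nonnegative")
    dense = np.asarray(too_dense, dtype=bool)
    out = np.where(dense, ceiling_colonies * colony_scale, counts * colony_scale)
    if np.isscalar(colony_count) and np.isscalar(too_dense):
        return int(out)
    return out.astype(np.int64)


def add_cfu_columns(
    records: pd.DataFrame,
    *,
    colony_scale: int = DEFAULT_COLONY_SCALE,
    ceiling_colonies: int = DEFAULT_CEILING_COLONIES,
) -> pd.DataFrame:
    """Return a copy with derived ``cfu_per_fly`` and ``log_cfu`` columns."""
    out = records.copy()
    out["cfu_per_fly"] = colonies_to_cfu(
        out["colony_count"].to_numpy(),
        out["too_dense"].to_numpy(),
        colony_scale=colony_scale,
        ceiling_colonies=ceiling_colonies,
    )
    out["log_cfu"] = np.log2(out["cfu_per_fly"].astype(float) + 1.0)
    return out


def filter_vials(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the vial-level exclusion rules.

    A vial is dropped when its density is below 30 flies or when its
    undiluted aliquots bore more than 5 CFU of an unexpected morphology.
    Returns ``(retained, exclusion_log)``; the exclusion log has one row
    per dropped vial with the reason.  Retained + excluded rows partition
    the input.
    """
    key_cols = ["strain", "experiment", "vial"]
    excluded = []
    bad_keys = set()
    for key, grp in records.groupby(key_cols, sort=True):
        density = int(grp["vial_density"].iloc[0])
        unexpected = int(grp["unexpected_colony_count"].max())
        contaminated = (
            bool(grp["contaminated_vial"].any())
            if "contaminated_vial" in grp.columns
            else False
        )
        reasons = []
        if density < MIN_VIAL_DENSITY:
            reasons.append("density")
        if unexpected > MAX_UNEXPECTED_CFU or contaminated:
            reasons.append("contamination")
        if reasons:
            bad_keys.add(key)
            excluded.append(dict(zip(key_cols, key), reason="+".join(reasons)))
    keys = list(zip(records["strain"], records["experiment"], records["vial"]))
    keep_mask = np.array([k not in bad_keys for k in keys], dtype=bool)
    retained = records.loc[keep_mask].copy()
    log = pd.DataFrame(excluded, columns=key_cols + ["reason"])
    return retained, log


def _as_groups(values_by_group: Mapping) -> tuple[list, list[np.ndarray]]:
    labels = sorted(values_by_group, key=str)
    groups = [np.asarray(values_by_group[lab], dtype=float) for lab in labels]
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be nonempty")
    return labels, groups


def kruskal_wallis(values_by_group: Mapping) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis test over labelled groups."""
    labels, groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least two groups")
    h, df, p, method = kruskal_p(groups)
    return GroupTestResult(h, df, p, labels, method)


def dunn_posthoc(
    values_by_group: Mapping,
    *,
    adjust: str = "bh",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Dunn's post hoc test with multiplicity adjustment and letters.

    Pairwise z statistics come from pooled tie-corrected midranks over all
    groups.  P-values are adjusted by Benjamini-Hochberg (``adjust="bh"``)
    or Bonferroni (``adjust="bonferroni"``).  For the two-group case the
    p-value is the exact rank-sum permutation p when the combined sample
    is small.  Letters follow the insert-and-absorb compact letter
    display: two groups share a letter iff their adjusted p >= alpha.
    """
    labels, groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("dunn_posthoc needs at least two groups")
    z = dunn_z_matrix(groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            if len(groups) == 2:
                p_raw = rank_sum_test(groups[i], groups[j]).p
            else:
                p_raw = float(2.0 * _sps.norm.sf(abs(z[i, j])))
            rows.append(
                {"group1": labels[i], "group2": labels[j], "z": z[i, j], "p_raw": min(1.0, p_raw)}
            )
    table = pd.DataFrame(rows)
    method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(adjust)
    if method is None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table["p_adj"] = multipletests(table["p_raw"].to_numpy(), method=method)[1]
    different = {
        (row.group1, row.group2)
        for row in table.itertuples()
        if row.p_adj < alpha
    }
    letters = compact_letter_display(labels, different)
    return table, letters


def pairwise_vs_control(
    values_by_group: Mapping,
    control_label,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group rank test of every non-control group against the control.

    Each comparison is a two-group Kruskal-Wallis test, equivalently a
    two-sided Wilcoxon rank-sum test.  ``direction`` reports whether the
    group median lies above or below the control median.
    """
    if control_label not in values_by_group:
        raise ValueError(f"control group {control_label!r} missing")
    control = np.asarray(values_by_group[control_label], dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    rows = []
    for label in sorted(values_by_group, key=str):
        if label == control_label:
            continue
        values = np.asarray(values_by_group[label], dtype=float)
        res = rank_sum_test(values, control)
        med, med_c = np.median(values), np.median(control)
        direction = "lower" if med < med_c else ("higher" if med > med_c else "equal")
        rows.append(
            {
                "group": label,
                "W": res.statistic,
                "p": res.p,
                "significant": res.p < alpha,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def sex_comparison(records: pd.DataFrame, value_col: str = "log_cfu") -> pd.DataFrame:
    """Per-strain two-sided Wilcoxon rank-sum test between sexes.

    Strains missing either sex are skipped with a warning.
    """
    rows = []
    for strain, grp in records.groupby("strain", sort=True):
        females = grp.loc[grp["sex"] == "female", value_col].to_numpy(dtype=float)
        males = grp.loc[grp["sex"] == "male", value_col].to_numpy(dtype=float)
        if females.size == 0 or males.size == 0:
            warnings.warn(f"strain {strain}: missing one sex, skipped", stacklevel=2)
            continue
        res = rank_sum_test(females, males)
        rows.append(
            {
                "strain": strain,
                "n_female": females.size,
                "n_male": males.size,
                "W": res.statistic,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def phenotype_by_strain(
    records: pd.DataFrame,
    *,
    sex: str | None = "female",
    apply_filters: bool = True,
    colony_scale: int = DEFAULT_COLONY_SCALE,
    ceiling_colonies: int = DEFAULT_CEILING_COLONIES,
) -> pd.Series:
    """Strain-level persistence summary: mean log2(CFU+1) per strain.

    Applies the vial filters and (by default) restricts to female flies
    before averaging, matching the downstream association's unit of
    analysis.
    """
    df = records
    if apply_filters and {"vial_density", "unexpected_colony_count"} <= set(df.columns):
        df, _ = filter_vials(df)
    if sex is not None and "sex" in df.columns:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError("no records left after filtering")
    df = add_cfu_columns(df, colony_scale=colony_scale, ceiling_colonies=ceiling_colonies)
    return df.groupby("strain")["log_cfu"].mean()


def write_cfu_tsv(records: pd.DataFrame, path) -> None:
    records.loc[:, CFU_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cfu_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CFU_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CFU table missing columns: {sorted(missing)}")
    df["too_dense"] = df["too_dense"].astype(bool)
    df["contaminated_vial"] = df["contaminated_vial"].astype(bool)
    return df
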
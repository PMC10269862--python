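"""Gene presence/absence association with persistence (the MGWA stage).

Orthologous groups (OGs) sharing one exact strain presence/absence pattern
carry identical information, so they are collapsed into phylogenetic
distribution groups (PDGs) before testing.  Each testable PDG (present in
some but not all phenotyped strains) is tested with a two-sided Wilcoxon
rank-sum comparison of the persistence phenotype between carrier and
non-carrier strains, and p-values are Bonferroni-corrected over the number
of tested PDGs.  PDG p-values propagate unchanged to their member OGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assay
from .ranktests import RankSumResult, rank_sum_test


@dataclass
class GenePresenceMatrix:
    """Binary OG x strain matrix with provenance.

    ``data`` is indexed by OG id with one column per strain; values are
    strictly 0/1.
    """

    data: pd.DataFrame
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("presence matrix must be strictly binary")
        self.data = self.data.astype(np.int8)

    @property
    def og_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def strains(self) -> list[str]:
        return list(self.data.columns)

    def frequencies(self) -> pd.Series:
        """Strain frequency of each OG."""
        return self.data.mean(axis=1)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="og_id")

    @classmethod
    def from_tsv(cls, path, provenance: str = "tsv") -> "GenePresenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="og_id"), provenance)


@dataclass
class PDG:
    """A unique strain presence/absence pattern and its member OGs."""

    pdg_id: str
    strains: tuple[str, ...]
    pattern: np.ndarray  # boolean, aligned with ``strains``
    member_ogs: tuple[str, ...]
    testable: bool = True

    @property
    def n_present(self) -> int:
        return int(self.pattern.sum())

    @property
    def n_absent(self) -> int:
        return int(len(self.pattern) - self.pattern.sum())

    def pattern_string(self) -> str:
        return "".join("1" if v else "0" for v in self.pattern)


@dataclass
class AssociationResult:
    """Wilcoxon association of one PDG with the phenotype."""

    pdg: PDG
    statistic: float
    raw_p: float
    method: str
    bonferroni_p: float = field(default=np.nan)
    significant: bool = field(default=False)


@dataclass
class MgwaResult:
    """Full association scan: per-OG table plus per-PDG results."""

    table: pd.DataFrame
    pdg_results: list[AssociationResult]
    m: int
    n_untestable: int
    phenotype: pd.Series
    unit: str
    alpha: float


def build_pdgs(matrix: GenePresenceMatrix) -> list[PDG]:
    """Collapse OGs into PDGs by identical presence vectors.

    All-present and all-absent patterns are retained but flagged
    untestable.  PDG ids are assigned in order of each pattern's first
    member OG; every OG lands in exactly one PDG.
    """
    if not matrix.og_ids:
        raise ValueError("empty presence matrix")
    strains = tuple(matrix.strains)
    patterns: dict[bytes, list[str]] = {}
    arr = matrix.data.to_numpy(dtype=bool)
    for og, row in zip(matrix.og_ids, arr):
        patterns.setdefault(row.tobytes(), []).append(og)
    ordered = sorted(patterns.items(), key=lambda kv: sorted(kv[1])[0])
    width = max(4, len(str(len(ordered))))
    pdgs = []
    for i, (key, ogs) in enumerate(ordered, start=1):
        pattern = np.frombuffer(key, dtype=bool).copy()
        n_present = int(pattern.sum())
        pdgs.append(
            PDG(
                pdg_id=f"PDG_{i:0{width}d}",
                strains=strains,
                pattern=pattern,
                member_ogs=tuple(sorted(ogs)),
                testable=0 < n_present < len(strains),
            )
        )
    return pdgs


def _split_phenotype(
    pdg: PDG, values: np.ndarray, strain_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    present_strains = {s for s, keep in zip(pdg.strains, pdg.pattern) if keep}
    mask = np.isin(strain_labels, sorted(present_strains))
    return values[mask], values[~mask]


def associate(pdg: PDG, phenotype: pd.Series) -> AssociationResult:
    """Two-sided Wilcoxon rank-sum test of one PDG against the phenotype.

    ``phenotype`` maps strain id to a persistence summary (one value per
    strain) or, for fly-level analyses, holds repeated strain ids in its
    index.  Strains absent from the phenotype are ignored; a PDG whose
    carriers or non-carriers vanish after that restriction is untestable.
    """
    strain_labels = phenotype.index.to_numpy()
    known = np.isin(strain_labels, np.asarray(pdg.strains))
    values = phenotype.to_numpy(dtype=float)[known]
    labels = strain_labels[known]
    carriers, others = _split_phenotype(pdg, values, labels)
    if carriers.size == 0 or others.size == 0:
        raise ValueError(f"{pdg.pdg_id} is untestable: one side has no phenotyped strains")
    res: RankSumResult = rank_sum_test(carriers, others)
    return AssociationResult(pdg, res.statistic, res.p, res.method)


def bonferroni(raw_p, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p -> min(1, p * m); order-preserving."""
    p = np.asarray(raw_p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)


def run_mgwa(
    matrix: GenePresenceMatrix,
    cfu_records: pd.DataFrame,
    *,
    unit: str = "strain",
    alpha: float = 0.01,
    correct_over: str = "pdg",
    sex: str | None = "female",
    apply_filters: bool = True,
    colony_scale: int = assay.DEFAULT_COLONY_SCALE,
    ceiling_colonies: int = assay.DEFAULT_CEILING_COLONIES,
) -> MgwaResult:
    """Run the full association scan and return a ranked per-OG table.

    The phenotype is the mean log2(CFU+1) of retained female flies per
    strain (``unit="strain"``, the default, avoiding pseudoreplication) or
    the pooled fly-level values (``unit="fly"``).  Bonferroni correction is
    over the number of tested PDGs (``correct_over="pdg"``) or over member
    OGs (``correct_over="og"``).  Output rows are one per OG, sorted by
    corrected p then OG id.
    """
    if unit not in ("strain", "fly"):
        raise ValueError("unit must be 'strain' or 'fly'")
    if correct_over not in ("pdg", "og"):
        raise ValueError("correct_over must be 'pdg' or 'og'")

    df = cfu_records
    if apply_filters and {"vial_density", "unexpected_colony_count"} <= set(df.columns):
        df, _ = assay.filter_vials(df)
    if sex is not None and "sex" in df.columns:
        df = df[df["sex"] == sex]
    df = assay.add_cfu_columns(
        df, colony_scale=colony_scale, ceiling_colonies=ceiling_colonies
    )
    if unit == "strain":
        phenotype = df.groupby("strain")["log_cfu"].mean()
    else:
        phenotype = pd.Series(
            df["log_cfu"].to_numpy(), index=pd.Index(df["strain"], name="strain")
        )

    phenotyped = set(phenotype.index)
    missing = set(matrix.strains) - phenotyped
    if missing:
        warnings.warn(
            f"{len(missing)} strain(s) in the matrix lack phenotype data "
            "and are ignored",
            stacklevel=2,
        )

    pdgs = build_pdgs(matrix)
    results: list[AssociationResult] = []
    n_untestable = 0
    for pdg in pdgs:
        if not pdg.testable:
            n_untestable += 1
            continue
        try:
            results.append(associate(pdg, phenotype))
        except ValueError:
            n_untestable += 1

    if not results:
        warnings.warn("no testable PDG; returning empty table", stacklevel=2)
        empty = pd.DataFrame(
            columns=[
                "og_id", "pdg_id", "pattern", "n_present", "n_absent",
                "W", "raw_p", "bonferroni_p", "significant",
            ]
        )
        return MgwaResult(empty, [], 0, n_untestable, phenotype, unit, alpha)

    m = (
        len(results)
        if correct_over == "pdg"
        else sum(len(r.pdg.member_ogs) for r in results)
    )
    corrected = bonferroni([r.raw_p for r in results], m)
    for r, cp in zip(results, corrected):
        r.bonferroni_p = float(cp)
        r.significant = bool(cp < alpha)

    rows = []
    for r in results:
        for og in r.pdg.member_ogs:
            rows.append(
                {
                    "og_id": og,
                    "pdg_id": r.pdg.pdg_id,
                    "pattern": r.pdg.pattern_string(),
                    "n_present": r.pdg.n_present,
                    "n_absent": r.pdg.n_absent,
                    "W": r.statistic,
                    "raw_p": r.raw_p,
                    "bonferroni_p": r.bonferroni_p,
                    "significant": r.significant,
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["bonferroni_p", "og_id"], kind="mergesort"
    ).reset_index(drop=True)
    return MgwaResult(table, results, m, n_untestable, phenotype, unit, alpha)


def significant_ogs(result: MgwaResult) -> set[str]:
    """OG ids whose PDG passed the Bonferroni threshold."""
    if result.table.empty:
        return set()
    return set(result.table.loc[result.table["significant"], "og_id"])
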
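"""KEGG pathway enrichment of the significant OG set.

Each pathway is tested with a 2x2 Pearson chi-square (no continuity
correction) of significant/nonsignificant membership against the
background, followed by Benjamini-Hochberg FDR control.  The background
defaults to all OGs carrying at least one pathway annotation; unannotated
OGs say nothing about pathway membership (``background="all"`` overrides).
A pathway is called enriched when q < alpha and the significant overlap
exceeds its expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """OG -> KO -> pathway lookup built from an annotation table."""

    og_to_ko: dict[str, str]
    ko_to_pathways: dict[str, set[str]]
    pathway_labels: dict[str, str] = field(default_factory=dict)

    def og_pathways(self, og: str) -> set[str]:
        ko = self.og_to_ko.get(og)
        if ko is None:
            return set()
        return self.ko_to_pathways.get(ko, set())

    @property
    def pathways(self) -> set[str]:
        out: set[str] = set()
        for paths in self.ko_to_pathways.values():
            out |= paths
        return out

    def annotated_ogs(self) -> set[str]:
        return {og for og in self.og_to_ko if self.og_pathways(og)}

    def pathway_members(self) -> dict[str, set[str]]:
        members: dict[str, set[str]] = {p: set() for p in self.pathways}
        for og in self.og_to_ko:
            for p in self.og_pathways(og):
                members[p].add(og)
        return members


def assign_pathways(table: pd.DataFrame) -> AnnotationMap:
    """Build an :class:`AnnotationMap` from an (og_id, ko_id, pathway_id) table.

    An OG listed with two different KOs is a conflict and raises; an OG's
    KO may map to several pathways (the OG then counts once per pathway).
    An optional ``pathway_label`` column supplies display names.
    """
    required = {"og_id", "ko_id", "pathway_id"}
    if not required <= set(table.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    og_to_ko: dict[str, str] = {}
    ko_to_pathways: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for row in table.itertuples():
        og, ko, pathway = str(row.og_id), str(row.ko_id), str(row.pathway_id)
        if og in og_to_ko and og_to_ko[og] != ko:
            raise ValueError(f"OG {og} assigned conflicting KOs {og_to_ko[og]} and {ko}")
        og_to_ko[og] = ko
        ko_to_pathways.setdefault(ko, set()).add(pathway)
        if "pathway_label" in table.columns:
            labels[pathway] = str(row.pathway_label)
    return AnnotationMap(og_to_ko, ko_to_pathways, labels)


def pearson_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df=1, no Yates correction) for a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        raise ValueError("empty table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0  # degenerate margin: no evidence of association
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def bh_fdr(raw_p) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, in the input order."""
    p = np.asarray(raw_p, dtype=float)
    if p.size == 0:
        return p
    if np.min(p) < 0 or np.max(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    significant: Iterable[str],
    annotation: AnnotationMap,
    background: Iterable[str] | None = None,
    *,
    alpha: float = 0.05,
    fisher_fallback: bool = False,
) -> pd.DataFrame:
    """Per-pathway chi-square enrichment of ``significant`` OGs.

    2x2 counts per pathway: a = significant OGs in the pathway, b =
    significant OGs outside it, c/d likewise for nonsignificant background
    OGs.  ``background`` defaults to all pathway-annotated OGs and must
    contain the significant set.  Rows with any expected cell below 1 get
    ``low_expected=True`` (and, with ``fisher_fallback``, a Fisher exact
    p instead).  Output is sorted by q then raw p then pathway id.
    """
    significant = set(significant)
    if background is None:
        background = annotation.annotated_ogs()
    background = set(background)
    if not significant <= background:
        raise ValueError("significant OGs must be a subset of the background")
    members = annotation.pathway_members()
    n_sig = len(significant)
    n_bg = len(background)
    rows = []
    for pathway in sorted(members):
        in_path = members[pathway] & background
        if not in_path:
            continue  # no background members: untestable
        a = len(in_path & significant)
        b = n_sig - a
        c = len(in_path) - a
        d = n_bg - a - b - c
        expected_a = n_sig * len(in_path) / n_bg
        expected = np.outer(
            [a + b, c + d], [a + c, b + d]
        ) / max(1, n_bg)
        low_expected = bool((expected < 1).any())
        if fisher_fallback and low_expected:
            _, p = fisher_exact([[a, b], [c, d]])
            chi2 = np.nan
        else:
            chi2, p = pearson_chi2(a, b, c, d)
        rows.append(
            {
                "pathway_id": pathway,
                "pathway_label": annotation.pathway_labels.get(pathway, pathway),
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "expected_a": expected_a,
                "chi2": chi2,
                "raw_p": float(p),
                "low_expected": low_expected,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "pathway_id", "pathway_label", "a", "b", "c", "d",
                "expected_a", "chi2", "raw_p", "low_expected", "fdr_q", "enriched",
            ]
        )
    out = pd.DataFrame(rows)
    out["fdr_q"] = bh_fdr(out["raw_p"].to_numpy())
    out["enriched"] = (out["fdr_q"] < alpha) & (out["a"] > out["expected_a"])
    return out.sort_values(
        ["fdr_q", "raw_p", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
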
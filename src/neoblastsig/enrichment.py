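"""Fold enrichment of annotation terms in cluster sets, with Yates chi-squared.

For a term annotated on ``m`` of ``N`` clusters and a set of ``n`` clusters of
which ``k`` carry the term, the fold enrichment over random expectation is
``(k/m) / (n/N)`` and significance comes from Pearson's chi-squared test with
Yates' continuity correction on the 2x2 table ``[[k, n-k], [m-k, N-n-m+k]]``.
The universe N is the set of annotated clusters of the relevant term type,
optionally intersected with an expression-filtered cluster universe.  P-values
are BH-adjusted across the terms of one term type.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import SchemaError

ENRICHMENT_COLUMNS = ["term_type", "term", "category", "k", "m", "n", "N", "fold", "chi2", "p", "fdr"]


class AnnotationMap:
    """cluster_id -> set of (term_type, term) assignments."""

    def __init__(self, table: pd.DataFrame):
        table = table[["cluster_id", "term_type", "term"]].drop_duplicates()
        self.table = table.reset_index(drop=True)

    def term_types(self) -> list[str]:
        return sorted(self.table["term_type"].unique())

    def universe(self, term_type: str) -> set[str]:
        sub = self.table[self.table["term_type"] == term_type]
        return set(sub["cluster_id"])

    def terms(self, term_type: str) -> list[str]:
        sub = self.table[self.table["term_type"] == term_type]
        return sorted(sub["term"].unique())

    def clusters_with(self, term_type: str, term: str) -> set[str]:
        sub = self.table[(self.table["term_type"] == term_type) & (self.table["term"] == term)]
        return set(sub["cluster_id"])

    def __len__(self) -> int:
        return len(self.table)


def read_annotation(path: str | Path) -> AnnotationMap:
    """Annotation TSV with columns cluster_id, term_type, term."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cluster_id", "term_type", "term"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    bad = df[df[["cluster_id", "term_type", "term"]].isna().any(axis=1)]
    if len(bad):
        raise SchemaError(f"{path}: malformed row at line {bad.index[0] + 2}")
    return AnnotationMap(df)


def yates_chi2(k: int, n: int, m: int, big_n: int) -> tuple[float, float]:
    """Yates-corrected chi-squared statistic and p for the 2x2 membership table."""
    table = np.array([[k, n - k], [m - k, big_n - n - m + k]])
    if (table < 0).any():
        raise ValueError("inconsistent 2x2 table (k > n, k > m, or N too small)")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def fold_enrichment(
    cluster_set: set[str],
    annotation: AnnotationMap,
    term_type: str,
    universe: set[str] | None = None,
    yates: bool = True,
) -> pd.DataFrame:
    """Per-term fold enrichment of ``cluster_set`` within the annotated universe.

    Set members outside the universe are dropped (the set must be assessed
    against clusters that could have carried the term).  Terms with m = 0 or
    an empty effective set yield a missing fold rather than an error.
    """
    ann_universe = annotation.universe(term_type)
    big = ann_universe if universe is None else (ann_universe & set(universe))
    eff_set = set(cluster_set) & big
    n, big_n = len(eff_set), len(big)
    rows = []
    for term in annotation.terms(term_type):
        with_term = annotation.clusters_with(term_type, term) & big
        m = len(with_term)
        k = len(with_term & eff_set)
        if m == 0 or n == 0:
            fold, chi2, p = np.nan, np.nan, np.nan
        else:
            fold = (k / m) / (n / big_n)
            tbl = np.array([[k, n - k], [m - k, big_n - n - m + k]])
            if tbl.sum(axis=0).min() == 0 or tbl.sum(axis=1).min() == 0:
                chi2, p = 0.0, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(tbl, correction=yates)
                chi2, p = float(chi2), float(p)
        rows.append((term_type, term, k, m, n, big_n, fold, chi2, p))
    df = pd.DataFrame(
        rows, columns=["term_type", "term", "k", "m", "n", "N", "fold", "chi2", "p"]
    )
    tested = df["p"].notna()
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p"].to_numpy())
    return df


def enrichment_report(
    categories,
    annotation: AnnotationMap,
    universe: set[str] | None = None,
    yates: bool = True,
) -> pd.DataFrame:
    """Long-format enrichment table over every (category, term_type) pair."""
    frames = []
    for name, members in categories.as_dict().items():
        for term_type in annotation.term_types():
            sub = fold_enrichment(members, annotation, term_type, universe, yates)
            sub.insert(2, "category", name)
            frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[ENRICHMENT_COLUMNS]
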
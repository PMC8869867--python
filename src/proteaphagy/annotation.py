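"""Functional-category summaries and Fisher's-exact enrichment.

Summarizes per-protein values by functional category — proteasome
subcomplexes (20S alpha/beta rings, 19S base and lid) and
autophagy-lysosome stages (early signaling, autophagosome formation,
lysosome fusion) — and tests whether a differential set is enriched in
a category via the two-sided Fisher's exact test on the 2x2
cross-classification.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UPS_SUBCATEGORIES = ("20S alpha", "20S beta", "19S base", "19S lid")
ALS_SUBCATEGORIES = ("early signaling", "autophagosome formation", "lysosome fusion")


@dataclasses.dataclass
class AnnotationMap:
    """Protein -> (category, subcategory) assignments; many-to-many allowed."""

    table: pd.DataFrame  # columns: protein_id, category, subcategory

    def __post_init__(self) -> None:
        required = {"protein_id", "category", "subcategory"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        if (self.table["category"].astype(str).str.len() == 0).any():
            raise ValueError("empty category labels")

    @classmethod
    def from_tsv(cls, path) -> "AnnotationMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def bundled(cls) -> "AnnotationMap":
        """The shipped UPS/ALS scheme (human gene symbols)."""
        ref = importlib.resources.files("proteaphagy.data") / "ups_als_annotation.tsv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def members(self, label: str, by: str = "subcategory") -> set[str]:
        sel = self.table[self.table[by] == label]
        return set(sel["protein_id"])

    def labels(self, by: str = "subcategory") -> list[str]:
        return list(dict.fromkeys(self.table[by]))

    def proteins(self) -> set[str]:
        return set(self.table["protein_id"])


@dataclasses.dataclass
class CategoryMatrix:
    """Category x condition means with member counts."""

    means: pd.DataFrame
    counts: pd.Series

    def difference(self, condition_b: str, condition_a: str) -> pd.Series:
        """Per-category mean difference (B - A)."""
        return self.means[condition_b] - self.means[condition_a]


def category_summary(
    values: pd.DataFrame, ann: AnnotationMap, by: str = "subcategory"
) -> CategoryMatrix:
    """Mean per-category value per condition ("the means of all single values").

    ``values`` is a proteins x conditions frame.  A protein annotated to
    several categories contributes to each.  Categories with no
    annotated protein present in the data are omitted with a warning.
    """
    rows = {}
    counts = {}
    for label in ann.labels(by):
        members = sorted(ann.members(label, by) & set(values.index))
        if not members:
            logger.warning("category %r has no annotated protein in the data; omitted", label)
            continue
        rows[label] = values.loc[members].mean(axis=0)
        counts[label] = len(members)
    if not rows:
        raise ValueError("no category has members in the data")
    means = pd.DataFrame(rows).T
    means.index.name = by
    return CategoryMatrix(means=means, counts=pd.Series(counts))


@dataclasses.dataclass
class EnrichmentResult:
    """2x2 Fisher's-exact result for one category."""

    table: tuple[int, int, int, int]  # a, b, c, d
    odds_ratio: float
    p_value: float
    haldane_corrected: bool

    def as_dict(self) -> dict:
        a, b, c, d = self.table
        return {
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "haldane_corrected": self.haldane_corrected,
        }


def fisher_enrichment(
    differential_set: set[str],
    category_members: set[str],
    universe: set[str],
) -> EnrichmentResult:
    """Two-sided Fisher's exact test for category enrichment.

    Cross-classifies the universe by (differential vs not) x (in
    category vs not).  The reported odds ratio uses the Haldane 0.5
    continuity correction when any cell is zero (the p-value never
    does).
    """
    if not differential_set <= universe:
        raise ValueError("differential set not contained in universe")
    if not category_members <= universe:
        raise ValueError("category members not contained in universe")
    a = len(differential_set & category_members)
    b = len(differential_set - category_members)
    c = len(category_members - differential_set)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        oa, ob, oc, od = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (oa * od) / (ob * oc)
        corrected = True
    else:
        odds = (a * d) / (b * c)
        corrected = False
    return EnrichmentResult(
        table=(a, b, c, d),
        odds_ratio=float(odds),
        p_value=float(min(p, 1.0)),
        haldane_corrected=corrected,
    )


def enrichment_table(
    differential_set: set[str],
    ann: AnnotationMap,
    universe: set[str],
    by: str = "subcategory",
) -> pd.DataFrame:
    """Fisher enrichment for every category label, as one frame."""
    rows = []
    for label in ann.labels(by):
        members = ann.members(label, by) & universe
        if not members:
            continue
        res = fisher_enrichment(differential_set, members, universe)
        rows.append({by: label, **res.as_dict()})
    return pd.DataFrame(rows)


def heatmap_matrix(
    cm: CategoryMatrix,
    scale: str = "row_z",
    figure_path=None,
):
    """Matrix behind the category heat map; optionally render it.

    ``row_z`` centers and scales each category row by its sample
    standard deviation, the convention of the usual heat-map row
    scaling (constant rows map to zeros rather than NaN); ``none``
    passes the means through unchanged.
    """
    if cm.means.empty:
        raise ValueError("empty category matrix")
    if scale == "row_z":
        arr = cm.means.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out = pd.DataFrame(z, index=cm.means.index, columns=cm.means.columns)
    elif scale == "none":
        out = cm.means.copy()
    else:
        raise ValueError("scale must be 'row_z' or 'none'")
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(
            figsize=(2 + 0.6 * out.shape[1], 1 + 0.4 * out.shape[0])
        )
        im = ax.imshow(out.to_numpy(), aspect="auto", cmap="RdYlGn")
        ax.set_xticks(range(out.shape[1]), out.columns)
        ax.set_yticks(range(out.shape[0]), out.index)
        fig.colorbar(im, ax=ax, label="enrichment" if scale == "none" else "row z")
        fig.tight_layout()
        fig.savefig(figure_path)
        plt.close(fig)
    return out
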
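"""Reproducible two-fold differential filter.

Classifies proteins as enriched or reduced in the resistant condition
by requiring a more-than-two-fold difference (|log2 difference| > 1 by
default) in *every* replicate pair — a reproducibility criterion, not a
p-value test.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .quant import SpectralCountMatrix

STATUS_ENRICHED = "enriched_in_B"
STATUS_REDUCED = "reduced_in_B"
STATUS_NULL = "not_differential"


@dataclasses.dataclass
class FoldChangeTable:
    """Per-protein log2 differences (condition B - condition A) per replicate pair."""

    diffs: pd.DataFrame
    pairing: str
    condition_a: str
    condition_b: str


@dataclasses.dataclass
class DifferentialResult:
    """Per-protein status plus the pair differences that produced it."""

    status: pd.Series
    diffs: pd.DataFrame
    log2_threshold: float
    strict: bool

    @property
    def enriched(self) -> set[str]:
        return set(self.status.index[self.status == STATUS_ENRICHED])

    @property
    def reduced(self) -> set[str]:
        return set(self.status.index[self.status == STATUS_REDUCED])

    @property
    def differential(self) -> set[str]:
        return self.enriched | self.reduced

    def summary(self) -> dict[str, int]:
        n_up = len(self.enriched)
        n_down = len(self.reduced)
        return {
            "n_enriched": n_up,
            "n_reduced": n_down,
            "n_total_differential": n_up + n_down,
        }

    def to_frame(self) -> pd.DataFrame:
        out = self.diffs.copy()
        out.insert(0, "status", self.status)
        return out


def replicate_fold_changes(
    m: SpectralCountMatrix,
    condition_a: str | None = None,
    condition_b: str | None = None,
    pairing: str = "by_index",
) -> FoldChangeTable:
    """Compute per-replicate log2 differences between two conditions.

    ``by_index`` pairs replicate *j* of B with replicate *j* of A (one
    column per replicate; replicate counts must match); ``all_pairs``
    emits one column per ordered (A_i, B_j) pair.
    """
    m.require_stage("normalized", "log2")
    conds = m.conditions()
    if condition_a is None or condition_b is None:
        if len(conds) != 2:
            raise ValueError(
                f"conditions must be named explicitly when there are {len(conds)}"
            )
        condition_a, condition_b = conds
    cols_a = m.condition_columns(condition_a)
    cols_b = m.condition_columns(condition_b)
    if not cols_a or not cols_b:
        raise ValueError("both conditions need at least one replicate")
    if pairing == "by_index":
        if len(cols_a) != len(cols_b):
            raise ValueError(
                "by_index pairing needs equal replicate counts "
                f"({len(cols_a)} vs {len(cols_b)})"
            )
        diffs = {}
        for j, (ca, cb) in enumerate(zip(cols_a, cols_b), start=1):
            diffs[f"r{j}"] = m.data[cb] - m.data[ca]
    elif pairing == "all_pairs":
        diffs = {}
        for (i, ca), (j, cb) in itertools.product(
            enumerate(cols_a, start=1), enumerate(cols_b, start=1)
        ):
            diffs[f"b{j}-a{i}"] = m.data[cb] - m.data[ca]
    else:
        raise ValueError("pairing must be 'by_index' or 'all_pairs'")
    table = pd.DataFrame(diffs)
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("non-finite log2 differences")
    return FoldChangeTable(
        diffs=table, pairing=pairing, condition_a=condition_a, condition_b=condition_b
    )


def reproducible_differential(
    fc: FoldChangeTable,
    log2_threshold: float = 1.0,
    strict: bool = True,
) -> DifferentialResult:
    """Keep proteins whose fold change is reproduced in every replicate pair.

    A protein is ``enriched_in_B`` iff every pair column exceeds
    ``+log2_threshold`` and ``reduced_in_B`` iff every column is below
    ``-log2_threshold``; "more than two-fold" means strict inequality
    by default (a difference of exactly the threshold fails).
    """
    if log2_threshold <= 0:
        raise ValueError("log2_threshold must be > 0")
    if fc.diffs.empty:
        raise ValueError("empty fold-change table")
    arr = fc.diffs.to_numpy(dtype=float)
    if strict:
        up = (arr > log2_threshold).all(axis=1)
        down = (arr < -log2_threshold).all(axis=1)
    else:
        up = (arr >= log2_threshold).all(axis=1)
        down = (arr <= -log2_threshold).all(axis=1)
    status = pd.Series(STATUS_NULL, index=fc.diffs.index, dtype=object)
    status[up] = STATUS_ENRICHED
    status[down] = STATUS_REDUCED
    return DifferentialResult(
        status=status, diffs=fc.diffs, log2_threshold=log2_threshold, strict=strict
    )


def recovery_report(result: DifferentialResult, truth: pd.DataFrame) -> dict[str, float]:
    """Score a differential call against planted ground truth.

    ``truth`` is the generator's per-protein frame with a ``direction``
    column in {up, down, null} (up/down meaning higher/lower in
    condition B).  Sensitivity is direction-aware: a planted 'up'
    protein counts as recovered only if called enriched.
    """
    if set(result.status.index) != set(truth.index):
        raise ValueError("differential result and ground truth cover different proteins")
    truth = truth.loc[result.status.index]
    direction = truth["direction"]
    planted = direction != "null"
    called = result.status != STATUS_NULL
    match_up = (direction == "up") & (result.status == STATUS_ENRICHED)
    match_down = (direction == "down") & (result.status == STATUS_REDUCED)
    recovered = match_up | match_down
    n_planted = int(planted.sum())
    n_called = int(called.sum())
    true_pos = int((recovered & planted).sum())
    false_pos = n_called - int((called & planted & recovered).sum())
    n_null = int((~planted).sum())
    true_neg = int((~called & ~planted).sum())
    return {
        "n_planted": n_planted,
        "n_called": n_called,
        "sensitivity": true_pos / n_planted if n_planted else float("nan"),
        "specificity": true_neg / n_null if n_null else float("nan"),
        "false_discovery_proportion": false_pos / n_called if n_called else 0.0,
    }
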
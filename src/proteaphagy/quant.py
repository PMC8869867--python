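"""Spectral-count quantification of affinity-purified ubiquitome samples.

Implements the label-free processing chain used for TUBE pull-down
proteomics: per-protein summation of peptide spectral counts, subtraction
of the nonspecific (GST resin) background, flooring of non-positive
values to one, log2 transformation, and quantile normalization across
samples.  The chain is modelled as an explicit stage machine
(``raw -> subtracted -> floored -> log2 -> normalized``) so that stages
cannot be applied out of order.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

STAGES = ("raw", "subtracted", "floored", "log2", "normalized")

CONTROL_CONDITION = "control"


class StageError(RuntimeError):
    """Raised when a processing stage is applied out of order."""


@dataclasses.dataclass
class SpectralCountMatrix:
    """Protein x sample matrix with sample metadata and a processing stage.

    Parameters
    ----------
    data
        Proteins (rows, indexed by protein id) by samples (columns,
        sample ids) matrix.  Integer counts at stage ``raw``, real
        values afterwards.
    samples
        Sample metadata indexed by sample id with columns ``condition``
        (a condition label, or ``"control"`` for resin-only pull-downs),
        ``replicate`` (integer) and ``is_control`` (bool).
    stage
        One of ``raw, subtracted, floored, log2, normalized``.
    controls
        Raw control columns retained for audit after background
        subtraction drops them from ``data``.
    """

    data: pd.DataFrame
    samples: pd.DataFrame
    stage: str = "raw"
    controls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        required = {"condition", "replicate", "is_control"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        unknown = set(self.data.columns) - set(self.samples.index)
        if unknown:
            raise ValueError(f"samples absent from metadata: {sorted(unknown)}")

    # -- convenience -------------------------------------------------
    @property
    def control_columns(self) -> list[str]:
        cols = self.samples.index[self.samples["is_control"]]
        return [c for c in cols if c in self.data.columns]

    @property
    def experimental_columns(self) -> list[str]:
        cols = self.samples.index[~self.samples["is_control"]]
        return [c for c in cols if c in self.data.columns]

    def conditions(self) -> list[str]:
        meta = self.samples.loc[self.experimental_columns]
        return sorted(meta["condition"].unique())

    def condition_columns(self, condition: str) -> list[str]:
        meta = self.samples.loc[self.experimental_columns]
        sub = meta[meta["condition"] == condition]
        return list(sub.sort_values("replicate").index)

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, matrix is at {self.stage!r}"
            )

    def copy_with(self, data: pd.DataFrame, stage: str, **kw) -> "SpectralCountMatrix":
        return SpectralCountMatrix(
            data=data,
            samples=kw.pop("samples", self.samples),
            stage=stage,
            controls=kw.pop("controls", self.controls),
        )


def make_sample_metadata(
    conditions: dict[str, int], n_controls: int = 0
) -> pd.DataFrame:
    """Build a sample-metadata frame: ``{condition: n_replicates}`` plus controls.

    Sample ids follow the pattern ``<condition>_r<replicate>`` and
    ``control_r<replicate>``.
    """
    rows = []
    for cond, n in conditions.items():
        for r in range(1, n + 1):
            rows.append((f"{cond}_r{r}", cond, r, False))
    for r in range(1, n_controls + 1):
        rows.append((f"control_r{r}", CONTROL_CONDITION, r, True))
    meta = pd.DataFrame(rows, columns=["sample_id", "condition", "replicate", "is_control"])
    return meta.set_index("sample_id")


def aggregate_psm_counts(
    psm: pd.DataFrame,
    samples: pd.DataFrame,
    shared_peptides: str = "all",
) -> SpectralCountMatrix:
    """Sum peptide spectral counts per protein per sample.

    ``psm`` is a long table with columns ``protein_id, peptide_id,
    sample_id, spectral_count``.  Counts are summed for each matching
    peptide of a protein; a peptide listed under several proteins
    contributes to every one of them (``shared_peptides="all"``), or is
    discarded entirely (``"unique"``).
    """
    required = {"protein_id", "peptide_id", "sample_id", "spectral_count"}
    missing = required - set(psm.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    if shared_peptides not in ("all", "unique"):
        raise ValueError("shared_peptides must be 'all' or 'unique'")
    if len(psm):
        if (psm["spectral_count"] < 0).any():
            raise ValueError("negative spectral counts")
        unknown = set(psm["sample_id"]) - set(samples.index)
        if unknown:
            raise ValueError(f"unknown sample ids in PSM table: {sorted(unknown)}")
    table = psm
    if shared_peptides == "unique" and len(table):
        n_owners = table.groupby("peptide_id")["protein_id"].transform("nunique")
        table = table[n_owners == 1]
    if len(table):
        wide = table.pivot_table(
            index="protein_id",
            columns="sample_id",
            values="spectral_count",
            aggfunc="sum",
            fill_value=0,
        )
    else:
        wide = pd.DataFrame()
    wide = wide.reindex(columns=samples.index, fill_value=0)
    wide.columns.name = None
    wide.index.name = None
    return SpectralCountMatrix(data=wide.astype(float), samples=samples, stage="raw")


def subtract_background(
    m: SpectralCountMatrix, control_mode: str = "mean"
) -> SpectralCountMatrix:
    """Subtract resin-only (GST) control counts from experimental samples.

    ``control_mode="mean"`` subtracts the per-protein mean over control
    samples from every experimental column; ``"paired"`` subtracts
    control replicate *i* from experimental replicate *i*.  Control
    columns are dropped from the working matrix but retained in
    ``.controls`` for audit.  Values may become negative.
    """
    m.require_stage("raw")
    ctrl_cols = m.control_columns
    if not ctrl_cols:
        raise ValueError("background subtraction requires at least one control sample")
    exp_cols = m.experimental_columns
    ctrl = m.data[ctrl_cols]
    exp = m.data[exp_cols]
    if control_mode == "mean":
        out = exp.sub(ctrl.mean(axis=1), axis=0)
    elif control_mode == "paired":
        ctrl_by_rep = {
            int(m.samples.loc[c, "replicate"]): c for c in ctrl_cols
        }
        out = exp.copy()
        for col in exp_cols:
            rep = int(m.samples.loc[col, "replicate"])
            if rep not in ctrl_by_rep:
                raise ValueError(f"no control replicate matching replicate {rep}")
            out[col] = exp[col] - ctrl[ctrl_by_rep[rep]]
    else:
        raise ValueError("control_mode must be 'mean' or 'paired'")
    samples = m.samples.loc[exp_cols + ctrl_cols]
    return SpectralCountMatrix(
        data=out, samples=samples, stage="subtracted", controls=ctrl
    )


def floor_to_one(m: SpectralCountMatrix) -> SpectralCountMatrix:
    """Replace every value below one by one (pre-log2 floor).

    Integer counts only ever fall below one by going to zero or
    negative after background subtraction; flooring the whole interval
    below one keeps the floored stage >= 1 (and the log2 stage >= 0)
    for fractional values too, which arise when the subtracted control
    is a mean.
    """
    m.require_stage("subtracted")
    data = m.data.where(m.data >= 1, 1.0)
    return m.copy_with(data, "floored")


def log2_with_floor(m: SpectralCountMatrix) -> SpectralCountMatrix:
    """Floor sub-unity values to one, then apply log2.

    Accepts a ``subtracted`` matrix (applies the floor itself) or an
    already ``floored`` one.  Output values are all >= 0.
    """
    m.require_stage("subtracted", "floored")
    if m.stage == "subtracted":
        m = floor_to_one(m)
    data = pd.DataFrame(
        np.log2(m.data.to_numpy(dtype=float)),
        index=m.data.index,
        columns=m.data.columns,
    )
    return m.copy_with(data, "log2")


def _quantile_normalize_array(arr: np.ndarray) -> np.ndarray:
    """Classical quantile normalization with tie-averaged ranks."""
    n, k = arr.shape
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    for j in range(k):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n, dtype=float)
        mapped[order] = ref
        sorted_col = col[order]
        # ties share the mean of the reference values they span
        if n > 1 and (sorted_col[1:] == sorted_col[:-1]).any():
            uniq, inv = np.unique(col, return_inverse=True)
            sums = np.bincount(inv, weights=mapped, minlength=len(uniq))
            counts = np.bincount(inv, minlength=len(uniq))
            mapped = (sums / counts)[inv]
        out[:, j] = mapped
    return out


def quantile_normalize(m: SpectralCountMatrix) -> SpectralCountMatrix:
    """Force all experimental columns onto the common rank-mean distribution.

    Each column's ranked values are replaced by the across-column mean
    of the values at that rank; afterwards every column shares one
    multiset of values (ties averaged).  Controls are excluded — they
    exist only to define background.
    """
    m.require_stage("log2")
    cols = m.experimental_columns
    if len(cols) < 2:
        raise ValueError("quantile normalization needs at least two experimental columns")
    arr = m.data[cols].to_numpy(dtype=float)
    out = pd.DataFrame(_quantile_normalize_array(arr), index=m.data.index, columns=cols)
    return m.copy_with(out, "normalized")


@dataclasses.dataclass
class DetectionCall:
    """Per-protein, per-condition detection flags.

    ``detected`` is proteins x conditions booleans; ``support`` counts
    replicates meeting the threshold; ``sizes`` maps condition ->
    number of detected proteins.
    """

    detected: pd.DataFrame
    support: pd.DataFrame
    min_value: float
    min_replicates: int
    sizes: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            self.sizes = {c: int(self.detected[c].sum()) for c in self.detected.columns}


def call_detected_proteins(
    m: SpectralCountMatrix,
    min_value: float = 1.0,
    min_replicates: int | None = None,
) -> DetectionCall:
    """Flag proteins specifically bound in each condition.

    A protein is detected in a condition iff its post-subtraction value
    is >= ``min_value`` in at least ``min_replicates`` replicates of
    that condition (default: all replicates).
    """
    m.require_stage("subtracted")
    conditions = m.conditions()
    support = {}
    detected = {}
    for cond in conditions:
        cols = m.condition_columns(cond)
        need = len(cols) if min_replicates is None else min_replicates
        if need > len(cols):
            raise ValueError(
                f"min_replicates={need} exceeds the {len(cols)} replicates of {cond!r}"
            )
        sup = (m.data[cols] >= min_value).sum(axis=1)
        support[cond] = sup
        detected[cond] = sup >= need
    need_out = min_replicates if min_replicates is not None else -1
    return DetectionCall(
        detected=pd.DataFrame(detected),
        support=pd.DataFrame(support),
        min_value=min_value,
        min_replicates=need_out,
    )


def densitometry_relative_level(
    band: float,
    housekeeping: float,
    control_band: float,
    control_housekeeping: float,
) -> float:
    """Housekeeping-normalized band density relative to the control lane.

    Returns ``(band/housekeeping) / (control_band/control_housekeeping)``,
    the standard western-blot relative quantification against beta-actin
    or GAPDH.
    """
    densities = (band, housekeeping, control_band, control_housekeeping)
    if any(d <= 0 for d in densities):
        raise ValueError("densitometry requires strictly positive densities")
    return (band / housekeeping) / (control_band / control_housekeeping)
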
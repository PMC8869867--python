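"""Median-effect dose-response fitting and Chou-Talalay combination index.

Quantifies cooperativity between two agents (e.g. a proteasome
inhibitor and an autophagy inhibitor) tested alone and in a
constant-ratio combination.  The median-effect model
``fa/fu = (D/Dm)^m`` is fitted by least squares on the linearized form
``log10(fa/(1-fa)) = m*log10(D) - m*log10(Dm)``; the combination index
at effect level fa is

    CI = dA/DxA + dB/DxB        (mutually exclusive form)

where (dA, dB) split the combination's equi-effective total dose by the
fixed mixing ratio and DxA, DxB are the single-agent doses producing
the same effect.  CI < 1 indicates cooperativity, 1 additivity, > 1
antagonism.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

COMBO = "combo"


@dataclasses.dataclass
class MedianEffectFit:
    """Parameters of one median-effect fit."""

    m: float
    dm: float
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a median-effect fit needs at least 2 points")
        if not (self.m > 0 and self.dm > 0):
            raise ValueError("invalid fit: m and Dm must be positive")

    def dose_for(self, fa: float) -> float:
        """Dose producing fraction affected ``fa`` (Dx)."""
        if not 0 < fa < 1:
            raise ValueError("fa must lie strictly in (0, 1)")
        return self.dm * (fa / (1 - fa)) ** (1 / self.m)

    def fa_at(self, dose: float) -> float:
        x = (dose / self.dm) ** self.m
        return x / (1 + x)


@dataclasses.dataclass
class CIResult:
    """Combination indexes at requested effect levels."""

    fa_levels: list[float]
    ci: list[float]                 # point values (or replicate means)
    ci_sd: list[float] | None       # across-replicate SD, if replicates fitted
    form: str

    def cooperative(self, fa: float) -> bool:
        """CI < 1 flags a cooperative (synergistic) combination."""
        return self.ci[self.fa_levels.index(fa)] < 1.0


def gate_apoptosis(events: pd.DataFrame, gate_threshold: float) -> dict:
    """Fraction of flow-cytometry events above the annexin-V gate."""
    if "intensity" not in events.columns:
        raise ValueError("event table needs an 'intensity' column")
    n = len(events)
    if n < 1:
        raise ValueError("empty event table")
    k = int((events["intensity"] > gate_threshold).sum())
    return {"n_events": n, "n_positive": k, "fraction": k / n}


def fit_median_effect(
    dr: pd.DataFrame,
    agent: str,
    replicate: int | None = None,
) -> MedianEffectFit:
    """Fit the median-effect line for one agent.

    ``dr`` has columns ``agent, dose, fa, replicate``.  Rows with fa
    outside the open interval (0, 1) are rejected with a warning;
    fewer than two usable points is an error.
    """
    sub = dr[dr["agent"] == agent]
    if replicate is not None:
        sub = sub[sub["replicate"] == replicate]
    if sub.empty:
        raise ValueError(f"no rows for agent {agent!r}")
    if (sub["dose"] <= 0).any():
        raise ValueError("doses must be positive")
    usable = sub[(sub["fa"] > 0) & (sub["fa"] < 1)]
    n_dropped = len(sub) - len(usable)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} rows with fa outside (0, 1)")
    if len(usable) < 2 or usable["dose"].nunique() < 2:
        raise ValueError("need at least two usable points at distinct doses")
    x = np.log10(usable["dose"].to_numpy(dtype=float))
    y = np.log10(usable["fa"] / (1 - usable["fa"])).to_numpy(dtype=float)
    fit = sps.linregress(x, y)
    m = float(fit.slope)
    if m <= 0:
        raise ValueError("non-positive fitted slope: not a valid dose response")
    dm = float(10 ** (-fit.intercept / m))
    return MedianEffectFit(m=m, dm=dm, r=float(fit.rvalue), n_points=len(usable))


def ic50(fit: MedianEffectFit) -> float:
    """Dose for 50% effect; under the median-effect model this is Dm."""
    return fit.dm


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: float,
    fa_levels,
    form: str = "exclusive",
) -> CIResult:
    """Combination index at each effect level, for a fixed ratio doseA:doseB.

    The combination's equi-effective total dose is split into components
    dA = Dx_combo * r/(1+r), dB = Dx_combo / (1+r); the mutually
    exclusive form is dA/DxA + dB/DxB, the non-exclusive form adds the
    cross term (dA*dB)/(DxA*DxB).
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if form not in ("exclusive", "nonexclusive"):
        raise ValueError("form must be 'exclusive' or 'nonexclusive'")
    cis = []
    for fa in fa_levels:
        if not 0 < fa < 1:
            raise ValueError("fa levels must lie strictly in (0, 1)")
        dx_combo = fit_combo.dose_for(fa)
        d_a = dx_combo * ratio / (1 + ratio)
        d_b = dx_combo / (1 + ratio)
        term_a = d_a / fit_a.dose_for(fa)
        term_b = d_b / fit_b.dose_for(fa)
        ci = term_a + term_b
        if form == "nonexclusive":
            ci += term_a * term_b
        cis.append(float(ci))
    return CIResult(fa_levels=list(fa_levels), ci=cis, ci_sd=None, form=form)


def ci_analysis(
    dr: pd.DataFrame,
    ratio: float,
    fa_levels=(0.5,),
    agent_a: str = "A",
    agent_b: str = "B",
    form: str = "exclusive",
) -> CIResult:
    """Replicate-resolved CI: fit per replicate, CI per replicate, then mean +/- SD.

    Falls back to a single pooled fit when the table carries no
    replicate structure (a single replicate index).
    """
    reps = sorted(dr["replicate"].unique())
    if len(reps) < 2:
        fits = [
            (
                fit_median_effect(dr, agent_a),
                fit_median_effect(dr, agent_b),
                fit_median_effect(dr, COMBO),
            )
        ]
    else:
        fits = [
            (
                fit_median_effect(dr, agent_a, rep),
                fit_median_effect(dr, agent_b, rep),
                fit_median_effect(dr, COMBO, rep),
            )
            for rep in reps
        ]
    per_rep = np.array(
        [
            combination_index(fa_, fb_, fc_, ratio, fa_levels, form=form).ci
            for fa_, fb_, fc_ in fits
        ]
    )
    mean = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if len(fits) > 1 else np.zeros(len(list(fa_levels)))
    return CIResult(
        fa_levels=list(fa_levels),
        ci=[float(v) for v in mean],
        ci_sd=[float(v) for v in sd],
        form=form,
    )
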
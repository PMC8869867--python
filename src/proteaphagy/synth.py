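"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the statistical structure of the study design: a TUBE
pull-down spectral-count experiment with two cell lines, three
replicates and matched GST (resin-only) controls; two-channel punctate
fluorescence images; constant-ratio dose-response series under the
median-effect model; and annexin-V flow-cytometry event tables drawn
from a two-component intensity mixture.

Counts follow a gamma-Poisson (negative-binomial) model,
``var = mu + dispersion * mu**2``; spectral counts are overdispersed
integers and Poisson is recovered as dispersion -> 0.  Nonspecific
(resin) background counts are added to the specific samples as well,
and appear alone in the control samples, so that background
subtraction is meaningful.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .annotation import ALS_SUBCATEGORIES, UPS_SUBCATEGORIES
from .coloc import TwoChannelImage
from .quant import SpectralCountMatrix, make_sample_metadata


def _round_half_away(x: float) -> int:
    """Round half away from zero (documented planted-set rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# spectral counts


@dataclasses.dataclass(frozen=True)
class SynthCountConfig:
    """Study conditions for the synthetic TUBE count experiment.

    Defaults model two conditions x three replicates with matched
    resin controls, ~10**3 proteins around 100 specific counts
    (count CV ~ 0.2 at baseline), a modest nonspecific background,
    and a planted four-fold regulated subset (5% up + 5% down).
    """

    n_proteins: int = 1000
    n_replicates: int = 3
    frac_up: float = 0.05
    frac_down: float = 0.05
    planted_log2fc: float = 2.0
    baseline_mean: float = 100.0
    dispersion: float = 0.03
    background_mean: float = 5.0
    seed: int = 0
    condition_a: str = "A"
    condition_b: str = "B"
    categorize: bool = False

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be positive")
        if not (0 <= self.frac_up <= 1 and 0 <= self.frac_down <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if self.planted_log2fc <= 0:
            raise ValueError("planted_log2fc must be > 0")
        if self.baseline_mean <= 0 or self.background_mean < 0 or self.dispersion < 0:
            raise ValueError("means must be >= 0 (baseline > 0), dispersion >= 0")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and var mu + dispersion*mu^2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def generate_tube_counts(
    config: SynthCountConfig,
) -> tuple[SpectralCountMatrix, pd.DataFrame]:
    """Generate a raw count matrix plus per-protein ground truth.

    The planted B-vs-A fold change is ``2**planted_log2fc`` for up
    proteins (elevated specific counts in condition B) and
    ``2**-planted_log2fc`` for down proteins (elevated in condition A —
    a protein less abundant in the resistant line is one that was
    abundant in the parental line).  With equal up/down fractions the
    two conditions then share one marginal count distribution, the
    regime quantile normalization assumes.  Control samples carry only
    background counts.  The returned truth frame has
    columns ``direction`` (up/down/null, B vs A), ``true_log2fc`` and,
    when ``categorize`` is set, UPS/ALS ``category``/``subcategory``
    labels (down proteins cycle through the proteasome subcomplexes, up
    proteins through the autophagy stages).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    n_up = _round_half_away(cfg.frac_up * n)
    n_down = _round_half_away(cfg.frac_down * n)
    if n_up + n_down > n:
        raise ValueError("planted sets exceed protein universe after rounding")
    proteins = [f"P{i:05d}" for i in range(1, n + 1)]
    direction = np.array(["null"] * n, dtype=object)
    regulated = rng.permutation(n)[: n_up + n_down]
    direction[regulated[:n_up]] = "up"
    direction[regulated[n_up:]] = "down"
    fc = np.zeros(n)
    fc[direction == "up"] = cfg.planted_log2fc
    fc[direction == "down"] = -cfg.planted_log2fc

    samples = make_sample_metadata(
        {cfg.condition_a: cfg.n_replicates, cfg.condition_b: cfg.n_replicates},
        n_controls=cfg.n_replicates,
    )
    mu_a = cfg.baseline_mean * 2.0 ** np.where(fc < 0, -fc, 0.0)
    mu_b = cfg.baseline_mean * 2.0 ** np.where(fc > 0, fc, 0.0)
    data = {}
    for sid, row in samples.iterrows():
        if row["is_control"]:
            mu = np.full(n, float(cfg.background_mean))
        elif row["condition"] == cfg.condition_a:
            mu = mu_a + cfg.background_mean
        else:
            mu = mu_b + cfg.background_mean
        data[sid] = _nb_counts(rng, mu, cfg.dispersion)
    matrix = pd.DataFrame(data, index=proteins, dtype=float)

    truth = pd.DataFrame(
        {"direction": direction, "true_log2fc": fc}, index=pd.Index(proteins, name="protein_id")
    )
    if cfg.categorize:
        cat = np.array([""] * n, dtype=object)
        sub = np.array([""] * n, dtype=object)
        ups = list(UPS_SUBCATEGORIES)
        als = list(ALS_SUBCATEGORIES)
        for k, i in enumerate(np.flatnonzero(direction == "up")):
            cat[i], sub[i] = "ALS", als[k % len(als)]
        for k, i in enumerate(np.flatnonzero(direction == "down")):
            cat[i], sub[i] = "UPS", ups[k % len(ups)]
        truth["category"] = cat
        truth["subcategory"] = sub
    scm = SpectralCountMatrix(data=matrix, samples=samples, stage="raw")
    return scm, truth


def truth_annotation(truth: pd.DataFrame):
    """Build an AnnotationMap from a categorized ground-truth frame."""
    from .annotation import AnnotationMap

    if "category" not in truth.columns:
        raise ValueError("ground truth carries no category labels (categorize=False?)")
    sel = truth[truth["category"] != ""]
    table = pd.DataFrame(
        {
            "protein_id": sel.index,
            "category": sel["category"].to_numpy(),
            "subcategory": sel["subcategory"].to_numpy(),
        }
    ).reset_index(drop=True)
    return AnnotationMap(table)


# ---------------------------------------------------------------------------
# two-channel images


@dataclasses.dataclass
class ImageGroundTruth:
    """Planted spot bookkeeping for one synthetic two-channel image."""

    centers_both: np.ndarray        # (k, 2) row/col centers present in both channels
    centers_reference_only: np.ndarray
    centers_partner_only: np.ndarray
    amplitude: float
    overlap_fraction: float         # |both| / |reference-channel spots|


def generate_two_channel_image(
    n_spots: int,
    overlap_fraction: float,
    spot_sigma: float = 2.0,
    noise_sd: float = 5.0,
    size: tuple[int, int] = (256, 256),
    amplitude: float = 1000.0,
    background: float = 100.0,
    seed: int = 0,
    min_sep_factor: float = 3.0,
) -> tuple[TwoChannelImage, ImageGroundTruth]:
    """Render Gaussian puncta on a noisy background in two channels.

    ``round(overlap_fraction * n_spots)`` spots share a center in both
    channels; the remaining reference spots appear only there, and the
    partner channel receives the same number of its own distinct spots
    so both channels carry ``n_spots`` puncta.  All centers (both
    channels pooled) are separated by at least
    ``min_sep_factor * spot_sigma`` via rejection sampling, and kept
    ``4 * spot_sigma`` away from the borders.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if n_spots < 1:
        raise ValueError("n_spots must be positive")
    rng = np.random.default_rng(seed)
    n_both = _round_half_away(overlap_fraction * n_spots)
    n_ref_only = n_spots - n_both
    n_partner_only = n_ref_only
    total = n_both + n_ref_only + n_partner_only
    margin = 4.0 * spot_sigma
    nrow, ncol = size
    if nrow - 2 * margin <= 0 or ncol - 2 * margin <= 0:
        raise ValueError("spots do not fit inside the image")
    min_sep = min_sep_factor * spot_sigma
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < total:
        attempts += 1
        if attempts > 1000 * total:
            raise RuntimeError(
                "could not place all spots at the requested separation; "
                "reduce n_spots or enlarge the image"
            )
        r = rng.uniform(margin, nrow - margin)
        c = rng.uniform(margin, ncol - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    centers_arr = np.array(centers)
    both = centers_arr[:n_both]
    ref_only = centers_arr[n_both : n_both + n_ref_only]
    partner_only = centers_arr[n_both + n_ref_only :]

    rows = np.arange(nrow)[:, None]
    cols = np.arange(ncol)[None, :]

    def _render(spot_centers: np.ndarray) -> np.ndarray:
        img = np.zeros(size, dtype=float)
        for r0, c0 in spot_centers:
            img += amplitude * np.exp(
                -((rows - r0) ** 2 + (cols - c0) ** 2) / (2.0 * spot_sigma**2)
            )
        return img

    ref = _render(np.vstack([both, ref_only]) if len(both) + len(ref_only) else np.empty((0, 2)))
    par = _render(
        np.vstack([both, partner_only]) if len(both) + len(partner_only) else np.empty((0, 2))
    )
    ref = np.clip(ref + background + rng.normal(0, noise_sd, size), 0, None)
    par = np.clip(par + background + rng.normal(0, noise_sd, size), 0, None)
    image = TwoChannelImage(reference=ref, partner=par)
    truth = ImageGroundTruth(
        centers_both=both,
        centers_reference_only=ref_only,
        centers_partner_only=partner_only,
        amplitude=amplitude,
        overlap_fraction=n_both / n_spots,
    )
    return image, truth


# ---------------------------------------------------------------------------
# dose response


@dataclasses.dataclass(frozen=True)
class DoseResponseTruth:
    """True median-effect parameters and the planted interaction.

    ``alpha`` scales the Loewe interaction sum: the combination row at
    total dose D has the effect level fa solving
    ``dA/DxA(fa) + dB/DxB(fa) = alpha`` with (dA, dB) split by
    ``ratio`` (doseA:doseB).  alpha = 1 is exactly Loewe-additive
    (downstream CI = 1); alpha < 1 plants synergy.
    """

    m_a: float
    dm_a: float
    m_b: float
    dm_b: float
    alpha: float = 1.0
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if min(self.m_a, self.dm_a, self.m_b, self.dm_b) <= 0:
            raise ValueError("m and Dm must be positive for both agents")
        if self.alpha <= 0 or self.ratio <= 0:
            raise ValueError("alpha and ratio must be positive")


def _combo_fa(truth: DoseResponseTruth, total_dose: float) -> float:
    """Effect level of the combination at one total dose (brentq on fa)."""
    from scipy.optimize import brentq

    r = truth.ratio
    d_a = total_dose * r / (1 + r)
    d_b = total_dose / (1 + r)

    def interaction(fa: float) -> float:
        dx_a = truth.dm_a * (fa / (1 - fa)) ** (1 / truth.m_a)
        dx_b = truth.dm_b * (fa / (1 - fa)) ** (1 / truth.m_b)
        return d_a / dx_a + d_b / dx_b - truth.alpha

    # interaction() decreases in fa; clamp extreme doses whose solution
    # falls outside the bracket (the generated fa is clipped anyway)
    lo, hi = 1e-6, 1 - 1e-6
    if interaction(lo) <= 0:
        return lo
    if interaction(hi) >= 0:
        return hi
    return brentq(interaction, lo, hi)


FA_CLIP = (0.005, 0.995)  # the median-effect linearization is undefined at 0/1


def generate_dose_response(
    truth: DoseResponseTruth,
    doses,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    agent_a: str = "A",
    agent_b: str = "B",
) -> pd.DataFrame:
    """Simulate single-agent and constant-ratio combination fa series.

    Single agents follow ``fa = (D/Dm)^m / (1 + (D/Dm)^m)``; combination
    rows use the planted interaction (see DoseResponseTruth).  Gaussian
    noise is added to fa and the result clipped to [0.005, 0.995].
    Returns a long frame with columns ``agent, dose, fa, replicate``;
    combination rows carry the *total* dose and agent label ``combo``.
    """
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        fa_a = (dose / truth.dm_a) ** truth.m_a / (1 + (dose / truth.dm_a) ** truth.m_a)
        fa_b = (dose / truth.dm_b) ** truth.m_b / (1 + (dose / truth.dm_b) ** truth.m_b)
        fa_c = _combo_fa(truth, dose)
        for rep in range(1, replicates + 1):
            for agent, fa in ((agent_a, fa_a), (agent_b, fa_b), ("combo", fa_c)):
                value = fa + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append((agent, dose, float(np.clip(value, *FA_CLIP)), rep))
    out = pd.DataFrame(rows, columns=["agent", "dose", "fa", "replicate"])
    out.attrs["ratio"] = truth.ratio
    return out


# ---------------------------------------------------------------------------
# flow cytometry events


def generate_flow_events(
    n_events: int = 10_000,
    positive_fraction: float = 0.3,
    seed: int = 0,
    negative_mean: float = 100.0,
    negative_sd: float = 25.0,
    positive_mean: float = 1000.0,
    positive_sd: float = 200.0,
) -> pd.DataFrame:
    """Annexin-V-like event intensities from a two-component mixture.

    Exactly ``round(positive_fraction * n_events)`` events come from the
    positive (apoptotic) component; labels are kept as ground truth.
    The default of 10^4 events matches a typical acquisition.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0 <= positive_fraction <= 1:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pos = _round_half_away(positive_fraction * n_events)
    labels = np.array([1] * n_pos + [0] * (n_events - n_pos))
    rng.shuffle(labels)
    intensity = np.where(
        labels == 1,
        rng.normal(positive_mean, positive_sd, n_events),
        rng.normal(negative_mean, negative_sd, n_events),
    )
    return pd.DataFrame({"intensity": np.clip(intensity, 0, None), "label": labels})
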
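"""Readers and writers for the plain-text and TIFF formats the pipeline uses."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .coloc import TwoChannelImage
from .quant import SpectralCountMatrix


# -- spectral counts -------------------------------------------------------

def write_counts_tsv(m: SpectralCountMatrix, counts_path, samples_path) -> None:
    """Write a count matrix as protein/peptide TSV plus a sample sidecar.

    The count file has columns ``protein_id, peptide_id`` then one
    column per sample; matrix-level data are written as a single
    synthetic peptide per protein.
    """
    out = m.data.copy()
    out.insert(0, "peptide_id", [f"{p}_pep1" for p in m.data.index])
    out.index.name = "protein_id"
    out.reset_index().to_csv(counts_path, sep="\t", index=False)
    m.samples.reset_index().to_csv(samples_path, sep="\t", index=False)


def read_psm_table(path) -> pd.DataFrame:
    """Long PSM table: protein_id, peptide_id, sample_id, spectral_count."""
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide_id": str, "sample_id": str})


def read_counts_tsv(counts_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the wide count TSV into a long PSM table plus sample metadata."""
    wide = pd.read_csv(counts_path, sep="\t", dtype={"protein_id": str, "peptide_id": str})
    samples = read_sample_metadata(samples_path)
    long = wide.melt(
        id_vars=["protein_id", "peptide_id"],
        var_name="sample_id",
        value_name="spectral_count",
    )
    return long, samples


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    meta["is_control"] = meta["is_control"].astype(bool)
    meta["replicate"] = meta["replicate"].astype(int)
    return meta.set_index("sample_id")


def write_matrix_tsv(m: SpectralCountMatrix, path) -> None:
    out = m.data.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


# -- images ----------------------------------------------------------------

def write_two_channel_tiff(image: TwoChannelImage, reference_path, partner_path) -> None:
    """One 16-bit grayscale TIFF per channel (values clipped to uint16)."""
    for arr, path in ((image.reference, reference_path), (image.partner, partner_path)):
        tifffile.imwrite(path, np.clip(np.round(arr), 0, 65535).astype(np.uint16))


def read_two_channel_tiff(reference_path, partner_path=None) -> TwoChannelImage:
    """Read two single-channel TIFFs, or a single 2-page TIFF."""
    if partner_path is None:
        pages = tifffile.imread(reference_path)
        if pages.ndim != 3 or pages.shape[0] != 2:
            raise ValueError("single-file mode expects a 2-page TIFF")
        ref, par = pages[0], pages[1]
    else:
        ref = tifffile.imread(reference_path)
        par = tifffile.imread(partner_path)
    return TwoChannelImage(reference=np.asarray(ref, float), partner=np.asarray(par, float))


# -- dose response and events ---------------------------------------------

def write_dose_response_csv(dr: pd.DataFrame, path) -> None:
    dr.to_csv(path, index=False)


def read_dose_response_csv(path, ratio: float | None = None) -> pd.DataFrame:
    dr = pd.read_csv(path, dtype={"agent": str})
    if ratio is not None:
        dr.attrs["ratio"] = float(ratio)
    return dr


def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
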
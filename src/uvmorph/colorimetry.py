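"""Colorimetric variables and the UV+white / UV-white threshold classification.

Four per-spectrum variables summarise a ventral reflectance trace:

* **luminance** — the plain sum of percent reflectance over 300-700 nm;
* **UV chroma** ``C_UV`` — the sum over 300-400 nm divided by the total sum;
* **hue** — the wavelength of peak reflectance;
* **R_mid** — the wavelength at which reflectance is halfway between its
  minimum and maximum within the 300-450 nm window, locating the position of
  the near-UV spectral cut-off.

White ventral colorations fall into two discrete classes indistinguishable to
a human observer: UV+white spectra keep reflecting into the near UV (early
cut-off) while UV-white spectra absorb it (late cut-off).  Classification is
by thresholds on R_mid: at or below 345 nm is UV+white, at or above 365 nm is
UV-white, strictly between (or with R_mid undefined) is ambiguous.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

LO_THRESHOLD_NM = 345.0
HI_THRESHOLD_NM = 365.0
RMID_WINDOW_NM = (300.0, 450.0)
FLAT_TOL = 1e-6  # reflectance-percent range below which R_mid is undefined


class MorphLabel(str, enum.Enum):
    UVPLUS_WHITE = "UVplus_white"
    UVMINUS_WHITE = "UVminus_white"
    AMBIGUOUS = "ambiguous"


@dataclass
class ColourFeatures:
    specimen_id: str
    patch: str
    luminance: float
    c_uv: float
    hue_peak: float
    hue_tie: bool
    r_mid: float  # nan when undefined
    label: MorphLabel


def r_mid(
    spectrum: Spectrum,
    window: tuple[float, float] = RMID_WINDOW_NM,
    minmax: str = "window",
    tol: float = FLAT_TOL,
) -> float:
    """Wavelength where reflectance first crosses halfway between min and max.

    The half-height H = (Rmin + Rmax) / 2 is computed from the extrema inside
    ``window`` (``minmax="window"``, the default) or over the whole spectrum
    (``minmax="full"``); the first upward crossing of H inside the window is
    located by linear interpolation between the bracketing grid samples.
    Returns nan when the dynamic range is below ``tol`` or no upward crossing
    exists in the window.
    """
    wl = spectrum.wavelengths
    if window[0] < wl[0] - 1e-9 or window[1] > wl[-1] + 1e-9:
        raise ValueError(f"window {window} outside grid {wl[0]}-{wl[-1]} nm")
    in_win = (wl >= window[0] - 1e-9) & (wl <= window[1] + 1e-9)
    r_win = spectrum.reflectance[in_win]
    wl_win = wl[in_win]
    if minmax == "window":
        rmin, rmax = float(r_win.min()), float(r_win.max())
    elif minmax == "full":
        rmin, rmax = float(spectrum.reflectance.min()), float(spectrum.reflectance.max())
    else:
        raise ValueError(f"minmax must be 'window' or 'full', got {minmax!r}")
    if rmax - rmin < tol:
        return math.nan
    half = 0.5 * (rmin + rmax)
    below = r_win < half
    # first upward crossing: sample below H followed by a sample at/above H
    cross = np.flatnonzero(below[:-1] & ~below[1:])
    if cross.size == 0:
        return math.nan
    i = int(cross[0])
    r0, r1 = r_win[i], r_win[i + 1]
    return float(wl_win[i] + (half - r0) / (r1 - r0) * (wl_win[i + 1] - wl_win[i]))


def classify_white(
    r: float, lo: float = LO_THRESHOLD_NM, hi: float = HI_THRESHOLD_NM
) -> MorphLabel:
    """Threshold classification of a spectral cut-off position.

    Boundary values are inclusive: R_mid <= ``lo`` is UV+white, >= ``hi`` is
    UV-white; anything strictly between, or an undefined R_mid, is ambiguous.
    """
    if not lo < hi:
        raise ValueError(f"lo threshold {lo} must be < hi threshold {hi}")
    if r is None or math.isnan(r):
        return MorphLabel.AMBIGUOUS
    if r <= lo:
        return MorphLabel.UVPLUS_WHITE
    if r >= hi:
        return MorphLabel.UVMINUS_WHITE
    return MorphLabel.AMBIGUOUS


def luminance(spectrum: Spectrum) -> float:
    """Total brightness: plain sum of reflectance over all grid samples."""
    return float(spectrum.reflectance.sum())


def uv_chroma(spectrum: Spectrum, uv_limit: float = 400.0) -> float:
    """Proportion of total reflectance in the near UV (300-400 nm inclusive)."""
    total = spectrum.reflectance.sum()
    if total <= 0:
        raise ValueError(
            f"zero total reflectance in {spectrum.specimen_id}:{spectrum.patch}"
        )
    uv = spectrum.reflectance[spectrum.wavelengths <= uv_limit + 1e-9].sum()
    return float(uv / total)


def hue_peak(spectrum: Spectrum) -> tuple[float, bool]:
    """Wavelength of maximum reflectance; ties broken to the shortest
    wavelength, with the tie reported in the second return value."""
    r = spectrum.reflectance
    peak = r.max()
    at_peak = np.flatnonzero(np.isclose(r, peak, rtol=0, atol=1e-12))
    return float(spectrum.wavelengths[at_peak[0]]), bool(at_peak.size > 1)


def extract_features(
    sset: SpectrumSet,
    lo: float = LO_THRESHOLD_NM,
    hi: float = HI_THRESHOLD_NM,
    minmax: str = "window",
) -> pd.DataFrame:
    """Per-spectrum feature table: luminance, C_UV, hue, R_mid and label.

    One row per (id, patch), joined with the set's metadata, suitable for
    export to external mixed-model packages.
    """
    rows = []
    for spec in sset.iter_spectra():
        r = r_mid(spec, minmax=minmax)
        hp, tie = hue_peak(spec)
        rows.append(
            {
                "id": spec.specimen_id,
                "patch": spec.patch,
                "luminance": luminance(spec),
                "c_uv": uv_chroma(spec) if spec.reflectance.sum() > 0 else math.nan,
                "hue_peak": hp,
                "hue_tie": tie,
                "r_mid": r,
                "label": classify_white(r, lo, hi).value,
            }
        )
    feats = pd.DataFrame(rows)
    return feats.merge(
        sset.metadata.drop(columns=[c for c in ("wl",) if c in sset.metadata]),
        on=["id", "patch"],
        how="left",
    )


def group_mean_spectra(
    sset: SpectrumSet,
    labels: pd.Series | np.ndarray | list,
    normalize: bool = False,
    by_patch: bool = True,
) -> pd.DataFrame:
    """Pointwise mean and SEM spectrum per label (and per patch).

    With ``normalize`` the mean spectrum is divided by its own maximum after
    averaging, so each group mean peaks at 1.  Long-format output with
    columns ``label, patch, wl, mean, sem, n``.
    """
    labels = np.asarray([l.value if isinstance(l, MorphLabel) else str(l) for l in labels])
    if labels.size != len(sset):
        raise ValueError("one label per spectrum required")
    patches = sset.metadata["patch"].to_numpy() if by_patch else np.array(["all"] * len(sset))
    wl = sset.wavelengths
    out = []
    for lab in np.unique(labels):
        for patch in np.unique(patches):
            mask = (labels == lab) & (patches == patch)
            n = int(mask.sum())
            if n == 0:
                continue
            block = sset.reflectance[mask]
            mean = block.mean(axis=0)
            sem = block.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
            if normalize:
                peak = mean.max()
                if peak <= 0:
                    raise ValueError(f"cannot normalize non-positive mean for {lab}/{patch}")
                mean = mean / peak
                sem = sem / peak
            out.append(
                pd.DataFrame(
                    {"label": lab, "patch": patch, "wl": wl, "mean": mean, "sem": sem, "n": n}
                )
            )
    if not out:
        raise ValueError("no non-empty groups")
    return pd.concat(out, ignore_index=True)


def tabulate_frequencies(
    features: pd.DataFrame,
    by: tuple[str, ...] = ("locality", "sex", "patch"),
) -> dict[str, pd.DataFrame]:
    """Counts and within-stratum proportions of each label, plus the four
    throat x belly combination classes per sex.

    ``features`` must carry ``label`` plus the stratifier columns.  Strata
    with zero specimens are omitted with a warning rather than producing a
    zero division.  Returns ``{"strata": ..., "combinations": ...}``.
    """
    feats = features.copy()
    feats["label"] = feats["label"].astype(str)

    counts = (
        feats.groupby(list(by) + ["label"], observed=True).size().rename("count").reset_index()
    )
    totals = counts.groupby(list(by), observed=True)["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals

    all_strata = feats[list(by)].drop_duplicates()
    present = counts[list(by)].drop_duplicates()
    n_empty = len(all_strata.merge(present, how="left", indicator=True).query("_merge == 'left_only'"))
    if n_empty:
        warnings.warn(f"{n_empty} empty strata omitted from frequency table")

    # throat x belly combination classes per specimen, per sex
    wide = feats.pivot_table(
        index=["id", "sex"], columns="patch", values="label", aggfunc="first", observed=True
    )
    combos = pd.DataFrame()
    if {"throat", "belly"}.issubset(wide.columns):
        both = wide.dropna(subset=["throat", "belly"]).reset_index()
        both["combination"] = both["throat"] + "_throat/" + both["belly"] + "_belly"
        combos = (
            both.groupby(["sex", "combination"], observed=True).size().rename("count").reset_index()
        )
        combos["proportion"] = combos["count"] / combos.groupby("sex", observed=True)[
            "count"
        ].transform("sum")
    return {"strata": counts, "combinations": combos}
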
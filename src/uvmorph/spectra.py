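"""Reflectance spectra on a common wavelength grid, with specimen metadata.

The working objects are :class:`WavelengthGrid`, :class:`Spectrum` and
:class:`SpectrumSet`.  A ``SpectrumSet`` stores all reflectance traces as a
single ``(n_spectra, n_wavelengths)`` array plus a pandas metadata table keyed
by ``(specimen_id, patch)``.  Files are plain UTF-8 CSV: a wide spectra table
whose first column is the wavelength (``wl``) with one column per spectrum
named ``<id>:<patch>``, and a metadata table with columns
``id, patch, sex, locality, human_morph`` (optionally ``svl``).

Reflectance is percent reflectance relative to a diffuse white standard.
All downstream colorimetric sums are plain sums over grid samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PATCHES = ("throat", "belly")
METADATA_COLUMNS = ("id", "patch", "sex", "locality", "human_morph")


class SpectraError(ValueError):
    """Raised for malformed spectra or metadata input."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm, endpoints inclusive.

    The canonical grid is 300-700 nm at 1 nm (401 samples), the range over
    which ventral reflectance is measured and summed.
    """

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise SpectraError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise SpectraError(f"grid step must be positive, got {self.step}")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @classmethod
    def from_wavelengths(cls, wl: np.ndarray) -> "WavelengthGrid":
        wl = np.asarray(wl, dtype=float)
        if wl.size < 2:
            raise SpectraError("need at least two wavelength samples")
        steps = np.diff(wl)
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * max(1.0, steps[0])):
            raise SpectraError("wavelength samples are not uniformly spaced")
        return cls(float(wl[0]), float(wl[-1]), float(steps[0]))


@dataclass
class Spectrum:
    """One reflectance trace for one body patch of one specimen."""

    specimen_id: str
    patch: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise SpectraError(
                f"wavelength/reflectance length mismatch for {self.specimen_id}:{self.patch}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise SpectraError(
                f"non-finite reflectance in {self.specimen_id}:{self.patch}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.specimen_id, self.patch)


@dataclass
class SpectrumSet:
    """An ordered collection of spectra on one shared grid, with metadata.

    ``reflectance`` is ``(n_spectra, n_wavelengths)``; row order matches
    ``metadata`` (indexed by ``(id, patch)``).  ``provenance`` accumulates a
    human-readable log of cleaning operations applied.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray
    metadata: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.reflectance.size == 0:
            self.reflectance = self.reflectance.reshape(0, self.grid.n_points)
        if self.reflectance.shape[1] != self.grid.n_points:
            raise SpectraError(
                f"reflectance has {self.reflectance.shape[1]} columns, "
                f"grid has {self.grid.n_points} points"
            )
        if len(self.metadata) != self.reflectance.shape[0]:
            raise SpectraError(
                f"{self.reflectance.shape[0]} spectra but {len(self.metadata)} metadata rows"
            )
        keys = list(zip(self.metadata["id"], self.metadata["patch"]))
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise SpectraError(f"duplicate (id, patch) keys: {dupes}")

    def __len__(self) -> int:
        return self.reflectance.shape[0]

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths()

    @property
    def keys(self) -> list[tuple[str, str]]:
        return list(zip(self.metadata["id"], self.metadata["patch"]))

    def spectrum(self, specimen_id: str, patch: str) -> Spectrum:
        mask = (self.metadata["id"] == specimen_id) & (self.metadata["patch"] == patch)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError((specimen_id, patch))
        return Spectrum(specimen_id, patch, self.wavelengths, self.reflectance[idx[0]])

    def iter_spectra(self):
        wl = self.wavelengths
        for i, (sid, patch) in enumerate(self.keys):
            yield Spectrum(sid, patch, wl, self.reflectance[i])

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.grid,
            self.reflectance.copy(),
            self.metadata.copy(),
            list(self.provenance),
        )


def from_spectra(spectra: list[Spectrum], metadata: pd.DataFrame) -> SpectrumSet:
    """Assemble a SpectrumSet from individual spectra sharing one grid."""
    if not spectra:
        raise SpectraError("empty spectrum list")
    grid = WavelengthGrid.from_wavelengths(spectra[0].wavelengths)
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, spectra[0].wavelengths):
            raise SpectraError(f"{s.key} is not on the shared grid")
    meta = metadata.set_index(["id", "patch"], drop=False)
    rows, meta_rows = [], []
    for s in spectra:
        if s.key not in meta.index:
            raise SpectraError(f"no metadata row for spectrum {s.key}")
        rows.append(s.reflectance)
        meta_rows.append(meta.loc[[s.key]])
    return SpectrumSet(grid, np.vstack(rows), pd.concat(meta_rows).reset_index(drop=True))


def read_spectra(spectra_path, metadata_path) -> SpectrumSet:
    """Read a wide spectra CSV plus its metadata CSV.

    The spectra file keeps its native grid; no resampling is performed here.
    Raises :class:`SpectraError` for a missing ``wl`` column, duplicate
    ``(id, patch)`` keys, non-numeric reflectance, or metadata rows without a
    matching spectrum column (orphans are named in the message).
    """
    spec_df = pd.read_csv(spectra_path)
    if "wl" not in spec_df.columns:
        raise SpectraError(f"{spectra_path}: missing wavelength column 'wl'")
    meta = pd.read_csv(metadata_path, dtype={"id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise SpectraError(f"{metadata_path}: missing metadata columns {missing}")
    meta["patch"] = meta["patch"].astype(str)

    wl = spec_df["wl"].to_numpy(dtype=float)
    grid = WavelengthGrid.from_wavelengths(wl)

    col_keys = []
    for col in spec_df.columns:
        if col == "wl":
            continue
        if ":" not in col:
            raise SpectraError(f"spectrum column {col!r} is not '<id>:<patch>'")
        sid, patch = col.rsplit(":", 1)
        col_keys.append((col, sid, patch))
        if not pd.api.types.is_numeric_dtype(spec_df[col]):
            raise SpectraError(f"non-numeric reflectance in column {col!r}")

    keys = [(sid, patch) for _, sid, patch in col_keys]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise SpectraError(f"duplicate (id, patch) spectrum columns: {dupes}")

    meta_keys = set(zip(meta["id"], meta["patch"]))
    orphans = sorted(set(meta_keys) - set(keys))
    if orphans:
        raise SpectraError(f"metadata rows with no spectrum column: {orphans}")
    unmatched_cols = sorted(set(keys) - meta_keys)
    if unmatched_cols:
        raise SpectraError(f"spectrum columns with no metadata row: {unmatched_cols}")

    meta_indexed = meta.set_index(["id", "patch"], drop=False)
    refl = np.empty((len(keys), wl.size))
    meta_rows = []
    for i, (col, sid, patch) in enumerate(col_keys):
        refl[i] = spec_df[col].to_numpy(dtype=float)
        meta_rows.append(meta_indexed.loc[[(sid, patch)]])
    if not np.all(np.isfinite(refl)):
        raise SpectraError("non-finite reflectance values in spectra file")
    if meta_rows:
        metadata = pd.concat(meta_rows).reset_index(drop=True)
    else:
        metadata = meta.iloc[0:0].reset_index(drop=True)
    return SpectrumSet(grid, refl.reshape(len(keys), wl.size), metadata)


def write_spectra(sset: SpectrumSet, spectra_path, metadata_path) -> None:
    """Write the wide spectra CSV and metadata CSV; inverse of read_spectra."""
    cols = {"wl": sset.wavelengths}
    for i, (sid, patch) in enumerate(sset.keys):
        cols[f"{sid}:{patch}"] = sset.reflectance[i]
    pd.DataFrame(cols).to_csv(spectra_path, index=False, float_format="%.10g")
    sset.metadata.to_csv(metadata_path, index=False)


def resample(sset: SpectrumSet, grid: WavelengthGrid) -> SpectrumSet:
    """Linearly interpolate every spectrum onto ``grid``.

    The target grid must lie within the native wavelength coverage;
    extrapolation is an error, never silent.
    """
    native = sset.wavelengths
    target = grid.wavelengths()
    if target[0] < native[0] - 1e-9 or target[-1] > native[-1] + 1e-9:
        raise SpectraError(
            f"target grid {target[0]}-{target[-1]} nm exceeds native "
            f"coverage {native[0]}-{native[-1]} nm; refusing to extrapolate"
        )
    out = np.empty((len(sset), target.size))
    for i in range(len(sset)):
        out[i] = np.interp(target, native, sset.reflectance[i])
    return SpectrumSet(
        grid,
        out.reshape(len(sset), target.size),
        sset.metadata.copy(),
        sset.provenance + [f"resample:{grid.start}:{grid.stop}:{grid.step}"],
    )


def clean(
    sset: SpectrumSet,
    clip_negative: bool = True,
    smooth_span: float | None = None,
) -> SpectrumSet:
    """Clip negative reflectance and optionally smooth each spectrum.

    Negative raw reflectance is an instrument artefact near the white
    standard; ``clip_negative`` floors it at 0.  ``smooth_span`` (fraction of
    the grid in (0, 1]) applies local quadratic regression (Savitzky-Golay)
    per spectrum.  With both options off the output equals the input.
    """
    refl = sset.reflectance.copy()
    prov = list(sset.provenance)
    if smooth_span is not None:
        if not 0 < smooth_span <= 1:
            raise SpectraError(f"smooth_span must be in (0, 1], got {smooth_span}")
        from scipy.signal import savgol_filter

        window = int(round(smooth_span * sset.grid.n_points))
        window = max(5, window + (window % 2 == 0))  # odd, >= 5
        window = min(window, sset.grid.n_points - (sset.grid.n_points % 2 == 0))
        refl = savgol_filter(refl, window_length=window, polyorder=2, axis=1)
        prov.append(f"smooth:savgol:span={smooth_span}:window={window}")
    if clip_negative:
        n_clipped = int(np.sum(refl < 0))
        refl = np.clip(refl, 0.0, None)
        prov.append(f"clip_negative:{n_clipped} samples floored at 0")
    return SpectrumSet(sset.grid, refl, sset.metadata.copy(), prov)
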
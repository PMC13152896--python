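"""Synthetic spectral cohorts with the structure the pipeline assumes.

Ventral reflectance of white patches is well described by a long-pass
sigmoid: low reflectance below a cut-off wavelength lambda0, rising to a
plateau above it.  The two white classes differ only in where the cut-off
sits — UV+white cuts off in the near UV (default lambda0 ~ Normal(330, 5)
nm, so the patch still reflects UV) and UV-white past it (Normal(390, 5)
nm).  Yellow and orange morph spectra are the same long-pass shape with
cut-offs in the human-visible range (Normal(460, 8) and Normal(520, 10)
nm), which gives them negligible UV reflectance.  The default class cut-off
means sit symmetric about the 345-365 nm classification gap so both white
classes are unambiguous at default noise.

Each simulated spectrum is

    R(wl) = [base + amplitude / (1 + exp(-(wl - lambda0) / s))] * eps_mult + eps_add

with per-sample lognormal multiplicative noise and additive Gaussian noise,
clipped at zero.  Cohorts carry sex, locality (with locality-specific class
frequencies) and the TRUE generating class per spectrum, so classification
recovery is measurable.  Throat and belly are generated per specimen with a
configurable probability that the belly class differs from the throat class
(discordant mosaic-like individuals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectrumSet, Spectrum, WavelengthGrid

CLASS_NAMES = ("UVplus_white", "UVminus_white", "yellow", "orange")

# per-class sigmoid midpoint: mean and SD in nm
DEFAULT_CUTOFFS: dict[str, tuple[float, float]] = {
    "UVplus_white": (330.0, 5.0),
    "UVminus_white": (390.0, 5.0),
    "yellow": (460.0, 8.0),
    "orange": (520.0, 10.0),
}


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults give a 400-specimen, 50:50 UV+white/UV-white cohort with
    well-separated classes at realistic measurement noise; localities, when
    given, carry their own class mixes (Tor-de-Querol-like extremes are
    expressible by setting a locality's mix to nearly one class).
    """

    n_specimens: int = 400
    class_mix: dict[str, float] = field(
        default_factory=lambda: {"UVplus_white": 0.5, "UVminus_white": 0.5}
    )
    localities: list[dict] | None = None  # [{"name", "weight", "class_mix"}, ...]
    sex_ratio: float = 0.5  # P(male)
    cutoff_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CUTOFFS)
    )
    sigmoid_slope_nm: float = 8.0
    base_reflectance: float = 3.0  # percent
    amplitude: float = 40.0  # percent
    mult_noise_sd: float = 0.05  # SD of log multiplicative noise, per sample
    add_noise_sd: float = 0.5  # percent, per sample
    discordance_prob: float = 0.1  # P(belly class != throat class)
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in self._all_mixes():
            if any(v < 0 for v in mix.values()) or not np.isclose(sum(mix.values()), 1.0):
                raise ValueError(f"class mix for {name} must be non-negative and sum to 1")
            unknown = set(mix) - set(CLASS_NAMES)
            if unknown:
                raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
        if any(sd < 0 for _, sd in self.cutoff_params.values()):
            raise ValueError("cut-off SDs must be non-negative")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0 <= self.discordance_prob <= 1:
            raise ValueError("discordance_prob must be a probability")

    def _all_mixes(self):
        yield ("cohort", self.class_mix)
        for loc in self.localities or []:
            yield (loc["name"], loc.get("class_mix", self.class_mix))


def simulate_spectrum(
    cls: str,
    config: CohortConfig,
    rng: np.random.Generator,
    lambda0: float | None = None,
) -> np.ndarray:
    """One noisy long-pass reflectance trace for a generating class.

    ``lambda0`` overrides the class draw (used when throat and belly of one
    specimen share a cut-off realisation).  Returns percent reflectance on
    the config grid, clipped at zero.
    """
    if cls not in config.cutoff_params:
        raise ValueError(f"no cut-off parameters for class {cls!r}")
    if lambda0 is None:
        mu, sd = config.cutoff_params[cls]
        lambda0 = rng.normal(mu, sd)
    wl = config.grid.wavelengths()
    clean = config.base_reflectance + config.amplitude / (
        1.0 + np.exp(-(wl - lambda0) / config.sigmoid_slope_nm)
    )
    noisy = clean * rng.lognormal(0.0, config.mult_noise_sd, wl.size) if config.mult_noise_sd > 0 else clean
    if config.add_noise_sd > 0:
        noisy = noisy + rng.normal(0.0, config.add_noise_sd, wl.size)
    return np.clip(noisy, 0.0, None)


def _draw_class(mix: dict[str, float], rng: np.random.Generator) -> str:
    names = sorted(mix)
    probs = np.array([mix[n] for n in names])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def simulate_cohort(config: CohortConfig) -> tuple[SpectrumSet, pd.DataFrame]:
    """Generate a full cohort: one throat and one belly spectrum per specimen.

    Returns the SpectrumSet (metadata carries sex, locality and human_morph)
    and a truth table with the TRUE generating class and cut-off per
    spectrum.  Reproducible: the same config (including seed) gives
    byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    locs = config.localities or [
        {"name": "locA", "weight": 1.0, "class_mix": config.class_mix}
    ]
    weights = np.array([loc.get("weight", 1.0) for loc in locs], dtype=float)
    weights = weights / weights.sum()

    refl, meta_rows, truth_rows = [], [], []
    for i in range(config.n_specimens):
        sid = f"S{i:04d}"
        loc = locs[rng.choice(len(locs), p=weights)]
        mix = loc.get("class_mix", config.class_mix)
        sex = "male" if rng.random() < config.sex_ratio else "female"
        throat_cls = _draw_class(mix, rng)
        if rng.random() < config.discordance_prob:
            belly_cls = _draw_class(mix, rng)
        else:
            belly_cls = throat_cls
        human = "white" if {throat_cls, belly_cls} <= {"UVplus_white", "UVminus_white"} else (
            "yellow" if "yellow" in (throat_cls, belly_cls) else "orange"
        )
        for patch, cls in (("throat", throat_cls), ("belly", belly_cls)):
            mu, sd = config.cutoff_params[cls]
            lam0 = rng.normal(mu, sd)
            refl.append(simulate_spectrum(cls, config, rng, lambda0=lam0))
            meta_rows.append(
                {
                    "id": sid,
                    "patch": patch,
                    "sex": sex,
                    "locality": loc["name"],
                    "human_morph": human,
                }
            )
            truth_rows.append(
                {"id": sid, "patch": patch, "true_class": cls, "lambda0": lam0}
            )
    sset = SpectrumSet(
        config.grid,
        np.vstack(refl),
        pd.DataFrame(meta_rows),
        provenance=[f"simulate_cohort:seed={config.seed}"],
    )
    return sset, pd.DataFrame(truth_rows)


def template_spectrum(cls: str, config: CohortConfig | None = None) -> Spectrum:
    """Noise-free class template at the class mean cut-off."""
    config = config or CohortConfig()
    mu, _ = config.cutoff_params[cls]
    wl = config.grid.wavelengths()
    r = config.base_reflectance + config.amplitude / (
        1.0 + np.exp(-(wl - mu) / config.sigmoid_slope_nm)
    )
    return Spectrum(f"template_{cls}", "throat", wl, r)
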
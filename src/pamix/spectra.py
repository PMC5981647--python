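"""Synthetic photoacoustic spectra of volatile organic compounds.

The forward model is the standard linear photoacoustic relation: for an
N-component gas mixture in the unsaturated-absorption regime the signal at
wavelength lambda is

    S(lambda) = C * P(lambda) * N_tot * sum_i c_i * sigma_i(lambda)

where ``C`` is the cell constant (geometry, microphone placement, acoustic
resonance amplification), ``P`` the optical power, ``N_tot`` the total
molecular density, ``c_i`` the molar fraction of component i and
``sigma_i`` its absorption cross-section.  All multiplicative constants are
in arbitrary units; a multivariate calibration absorbs them, so the defaults
are 1.

Because measured cross-sections of the six breath-biomarker VOCs studied
here (2-butanone, 1-propanol, isoprene, ethylbenzene, styrene, hexanal) are
not deposited anywhere machine-readable, :func:`default_voc_library`
synthesises six cross-section curves with the qualitative features that make
this calibration problem hard: broad, mutually overlapping bands across the
whole 3250-3550 nm scan window, no exclusive marker wavelength for any
single component, and peak strengths spread over roughly a decade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "WavelengthGrid",
    "BandShape",
    "CrossSectionModel",
    "InstrumentModel",
    "GasMixture",
    "Spectrum",
    "VOCProperties",
    "evaluate_cross_section",
    "pa_signal",
    "normalize_by_power",
    "add_noise",
    "required_liquid_volume",
    "default_voc_library",
    "DEFAULT_VOC_NAMES",
    "MOLAR_VOLUME_NORMAL_L_PER_MOL",
]

#: The six candidate lung-cancer breath biomarkers the analyzer targets.
DEFAULT_VOC_NAMES = (
    "2-butanone",
    "1-propanol",
    "isoprene",
    "ethylbenzene",
    "styrene",
    "hexanal",
)

#: Molar volume of an ideal gas at normal pressure, L/mol.
MOLAR_VOLUME_NORMAL_L_PER_MOL = 22.414


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres.

    The default matches the mid-IR idler scan of the optical parametric
    oscillator used for the measurements: 301 points from 3250 to 3550 nm.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
        if not np.all(np.isfinite(v)):
            raise ValueError("wavelength grid contains non-finite values")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "values", v)

    @classmethod
    def default(cls, start: float = 3250.0, stop: float = 3550.0, n: int = 301) -> "WavelengthGrid":
        return cls(np.linspace(start, stop, n))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


@dataclass(frozen=True)
class BandShape:
    """A single absorption band: Gaussian or Lorentzian profile.

    ``width`` is the full width at half maximum (FWHM) in nm, ``amplitude``
    the peak cross-section contribution in arbitrary units.
    """

    center: float
    width: float
    amplitude: float
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width (FWHM) must be positive")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be nonnegative")
        if self.profile not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band profile {self.profile!r}")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        x = np.asarray(wavelengths, dtype=float) - self.center
        if self.profile == "gaussian":
            # FWHM = 2*sqrt(2*ln 2)*s
            s = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.amplitude * np.exp(-0.5 * (x / s) ** 2)
        hwhm = self.width / 2.0
        return self.amplitude * hwhm**2 / (x**2 + hwhm**2)


@dataclass(frozen=True)
class CrossSectionModel:
    """Parametric absorption cross-section sigma(lambda) of one component."""

    component_name: str
    bands: tuple[BandShape, ...]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        if self.baseline < 0:
            raise ValueError("baseline must be nonnegative")

    def scaled(self, factor: float) -> "CrossSectionModel":
        """Return a copy with every band amplitude and the baseline scaled."""
        if factor < 0:
            raise ValueError("scale factor must be nonnegative")
        bands = tuple(replace(b, amplitude=b.amplitude * factor) for b in self.bands)
        return replace(self, bands=bands, baseline=self.baseline * factor)


@dataclass(frozen=True)
class InstrumentModel:
    """Multiplicative instrument terms of the photoacoustic forward model.

    ``cell_constant`` (C), ``power_curve`` (P(lambda), per grid point) and
    ``total_density`` (N_tot) default to 1: they cancel out of any
    calibration that is trained and evaluated on the same instrument.
    ``noise_fraction`` is the ratio of the added Gaussian noise standard
    deviation to the RMS of the clean spectrum (default 0.10).
    """

    cell_constant: float = 1.0
    power_curve: np.ndarray | float = 1.0
    total_density: float = 1.0
    noise_fraction: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be nonnegative")

    def power_at(self, grid: WavelengthGrid) -> np.ndarray:
        p = np.asarray(self.power_curve, dtype=float)
        if p.ndim == 0:
            p = np.full(len(grid), float(p))
        if p.size != len(grid):
            raise ValueError("power_curve length does not match wavelength grid")
        return p


@dataclass(frozen=True)
class GasMixture:
    """Component concentrations in ppm (molar parts per million)."""

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for name, ppm in self.concentrations.items():
            ppm = float(ppm)
            if not np.isfinite(ppm):
                raise ValueError(f"non-finite concentration for {name!r}")
            if ppm < 0:
                raise ValueError(
                    f"negative concentration {ppm} ppm for {name!r}; physical "
                    "mixtures are nonnegative (negative *predictions* belong in "
                    "PredictionResult)"
                )
            clean[name] = ppm
        object.__setattr__(self, "concentrations", clean)

    def __getitem__(self, name: str) -> float:
        return self.concentrations[name]


@dataclass(frozen=True)
class Spectrum:
    """A signal sampled on a wavelength grid, in arbitrary units."""

    grid: WavelengthGrid
    signal: np.ndarray
    normalized: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.signal, dtype=float)
        if s.shape != (len(self.grid),):
            raise ValueError("signal length does not match wavelength grid")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "signal", s)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.signal**2)))


@dataclass(frozen=True)
class VOCProperties:
    """Physical constants needed for Tedlar-bag standard preparation."""

    name: str
    molar_mass: float  # g/mol
    liquid_density: float  # g/mL

    def __post_init__(self) -> None:
        if self.molar_mass <= 0 or self.liquid_density <= 0:
            raise ValueError("molar mass and liquid density must be positive")


def evaluate_cross_section(model: CrossSectionModel, grid: WavelengthGrid) -> np.ndarray:
    """Evaluate sigma(lambda) on the grid: sum of band profiles plus baseline."""
    lo, hi = grid.span
    sigma = np.full(len(grid), model.baseline, dtype=float)
    for band in model.bands:
        if not (lo - 2 * band.width <= band.center <= hi + 2 * band.width):
            warnings.warn(
                f"band center {band.center} nm of {model.component_name!r} lies far "
                f"outside the grid [{lo}, {hi}] nm; only its tail contributes",
                stacklevel=2,
            )
        sigma += band(grid.values)
    return sigma


def pa_signal(
    instrument: InstrumentModel,
    components: list[CrossSectionModel],
    mixture: GasMixture,
    grid: WavelengthGrid,
) -> Spectrum:
    """Noiseless raw photoacoustic spectrum of a mixture.

    S(lambda) = C * P(lambda) * N_tot * sum_i c_i sigma_i(lambda), with the
    ppm concentrations converted to absolute molar fractions (ppm * 1e-6).
    """
    by_name = {m.component_name: m for m in components}
    total = np.zeros(len(grid))
    for name, ppm in mixture.concentrations.items():
        if name not in by_name:
            raise KeyError(f"no cross-section model for mixture component {name!r}")
        total += (ppm * 1e-6) * evaluate_cross_section(by_name[name], grid)
    signal = instrument.cell_constant * instrument.total_density * instrument.power_at(grid) * total
    return Spectrum(grid=grid, signal=signal, normalized=False)


def normalize_by_power(raw: Spectrum, instrument: InstrumentModel) -> Spectrum:
    """Divide the raw signal by the optical power at each wavelength.

    Mirrors the measurement protocol in which each wavelength's averaged
    photoacoustic amplitude is divided by the averaged optical power, which
    removes the source's wavelength-dependent emission curve.
    """
    power = instrument.power_at(raw.grid)
    if np.any(power <= 0):
        raise ValueError("power curve must be strictly positive for normalization")
    return Spectrum(
        grid=raw.grid, signal=raw.signal / power, normalized=True, name=raw.name
    )


def add_noise(s: Spectrum, noise_fraction: float, seed: int) -> Spectrum:
    """Add i.i.d. zero-mean Gaussian noise scaled to the spectrum RMS.

    The noise standard deviation is ``noise_fraction * RMS(signal)``: "noise
    power" is read on the RMS amplitude scale, so 0.10 means noise whose RMS
    is 10% of the spectrum RMS.  Negative resulting values are kept; digital
    microphone data can dip below baseline.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be nonnegative")
    if noise_fraction == 0:
        return s
    rng = np.random.default_rng(seed)
    sigma = noise_fraction * s.rms()
    noisy = s.signal + rng.normal(0.0, sigma, size=s.signal.shape)
    return Spectrum(grid=s.grid, signal=noisy, normalized=s.normalized, name=s.name)


def required_liquid_volume(
    v_n2_l: float,
    c_voc_ppm: float,
    props: VOCProperties,
    v_ideal_l_per_mol: float = MOLAR_VOLUME_NORMAL_L_PER_MOL,
) -> float:
    """Liquid VOC volume (mL) to evaporate into a nitrogen-filled bag.

    V_VOC = V_N2 * c_VOC * M_VOC / (V_ideal * rho_VOC), with the ppm
    concentration converted to an absolute molar fraction.  ``v_n2_l`` is the
    bag volume in litres and the result is in millilitres (the L/L ratio of
    the gas terms leaves g / (g/mL) = mL).
    """
    if v_ideal_l_per_mol <= 0:
        raise ValueError("molar volume must be positive")
    if v_n2_l <= 0:
        raise ValueError("nitrogen volume must be positive")
    if c_voc_ppm < 0:
        raise ValueError("concentration must be nonnegative")
    return (
        v_n2_l * (c_voc_ppm * 1e-6) * props.molar_mass
        / (v_ideal_l_per_mol * props.liquid_density)
    )


def _cosine_similarity_matrix(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    unit = m / norms
    return unit @ unit.T


def _draw_candidate_library(
    rng: np.random.Generator, grid: WavelengthGrid, names: tuple[str, ...]
) -> list[CrossSectionModel]:
    """One random library draw: shared broad backbone + component bands.

    Every component gets a broad band near the centre of the window (this is
    what makes the spectra overlap everywhere, as C-H stretch envelopes of
    mid-size organics do in the 3.3 um region) plus 2-4 narrower bands at
    random positions that carry its distinguishing structure.  Peak
    amplitudes are drawn log-uniformly over one decade and rescaled so a
    100 ppm single-component spectrum peaks at order 1 a.u.
    """
    lo, hi = grid.span
    span = hi - lo
    models = []
    for name in names:
        bands = [
            BandShape(
                center=rng.uniform(lo + 0.3 * span, lo + 0.7 * span),
                width=rng.uniform(0.5 * span, 0.9 * span),
                amplitude=rng.uniform(0.4, 0.8),
                profile="gaussian",
            )
        ]
        for _ in range(rng.integers(2, 5)):
            bands.append(
                BandShape(
                    center=rng.uniform(lo + 0.05 * span, hi - 0.05 * span),
                    width=rng.uniform(0.05 * span, 0.25 * span),
                    amplitude=rng.uniform(0.3, 1.0),
                    profile=str(rng.choice(["gaussian", "lorentzian"])),
                )
            )
        model = CrossSectionModel(component_name=name, bands=tuple(bands), baseline=0.0)
        # Rescale: 100 ppm of the strongest component peaks at ~1 a.u.,
        # weaker ones spread log-uniformly down to ~0.1 a.u. (a decade of
        # peak strengths emulates the differing per-component SNRs).
        target_peak = 10.0 ** rng.uniform(-1.0, 0.0) / 100e-6
        peak = float(np.max(evaluate_cross_section(model, grid)))
        models.append(model.scaled(target_peak / peak))
    return models


def default_voc_library(seed: int = 0, grid: WavelengthGrid | None = None) -> list[CrossSectionModel]:
    """Six synthetic VOC cross-section models with realistic overlap.

    Contract, enforced by deterministic rejection sampling on the seeded
    RNG stream:

    * the 6 x n_wavelengths matrix of sigma values has rank 6 (the spectra
      are linearly independent, so a calibration can separate them);
    * every pair of components has cosine similarity between 0.3 and 0.95
      (strong overlap, yet no near-duplicates);
    * peak signals at 100 ppm span roughly one order of magnitude.

    The same seed always returns the same library.
    """
    if grid is None:
        grid = WavelengthGrid.default()
    rng = np.random.default_rng(seed)
    for _ in range(200):
        models = _draw_candidate_library(rng, grid, DEFAULT_VOC_NAMES)
        sigma = np.vstack([evaluate_cross_section(m, grid) for m in models])
        cos = _cosine_similarity_matrix(sigma)
        off = cos[~np.eye(len(models), dtype=bool)]
        if not (off.min() > 0.3 and off.max() < 0.95):
            continue
        if np.linalg.matrix_rank(sigma) != len(models):
            continue
        return models
    raise RuntimeError("could not draw a library meeting the overlap contract")
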
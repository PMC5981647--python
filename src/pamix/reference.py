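"""Factorial construction of the multivariate calibration corpus.

Starting from one measured (here: simulated) spectrum per component at a
common base concentration (default 100 ppm), every reference spectrum is a
scaled sum of the singles with per-component scale factors drawn from a
fixed level set (default {0, 0.3, 0.7, 1}).  Enumerating all factor
combinations for six components gives the full-factorial 4^6 = 4096-row
calibration corpus, with "generated" concentration levels of 0/30/70/100
ppm per component.

Gaussian noise emulating photoacoustic amplitude fluctuation can be placed
either on the base spectra before combination (``originals`` mode, the
literal laboratory protocol, which makes noise correlated across rows built
from the same original) or independently on every generated row
(``per_reference``, the default; see the methods note for why).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import Spectrum, WavelengthGrid, add_noise

__all__ = ["AugmentationConfig", "ReferenceSet", "build_reference_set", "concentration_grid", "inject_noise"]

NOISE_PLACEMENTS = ("originals", "per_reference")


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the factorial reference-set synthesis."""

    scale_factors: tuple[float, ...] = (0.0, 0.3, 0.7, 1.0)
    base_concentration: float = 100.0  # ppm
    noise_fraction: float = 0.10
    noise_placement: str = "per_reference"
    seed: int = 0

    def __post_init__(self) -> None:
        factors = tuple(float(f) for f in self.scale_factors)
        if len(set(factors)) != len(factors):
            raise ValueError("scale factors must be distinct")
        if any(f < 0 or f > 1 for f in factors):
            raise ValueError("scale factors must lie in [0, 1]")
        if self.base_concentration <= 0:
            raise ValueError("base concentration must be positive")
        if self.noise_fraction < 0:
            raise ValueError("noise fraction must be nonnegative")
        if self.noise_placement not in NOISE_PLACEMENTS:
            raise ValueError(
                f"unknown noise placement {self.noise_placement!r}; "
                f"expected one of {NOISE_PLACEMENTS}"
            )
        object.__setattr__(self, "scale_factors", factors)


@dataclass(frozen=True)
class ReferenceSet:
    """Calibration corpus: spectra matrix X paired with concentrations Y.

    Rows of ``X`` (n_samples x n_wavelengths, a.u.) are reference spectra;
    rows of ``Y`` (n_samples x n_components, ppm) the associated known
    concentrations.  Row order is the lexicographic product of the scale
    factors over components with the **last component varying fastest**.
    ``singles`` optionally keeps the clean base spectra the set was built
    from (needed to re-inject noise in ``originals`` mode).
    """

    X: np.ndarray
    Y: np.ndarray
    component_names: tuple[str, ...]
    grid: WavelengthGrid
    singles: tuple[Spectrum, ...] | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if Y.shape[1] != len(self.component_names):
            raise ValueError("Y column count must match component_names")
        if X.shape[1] != len(self.grid):
            raise ValueError("X column count must match the wavelength grid")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "component_names", tuple(self.component_names))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_components(self) -> int:
        return len(self.component_names)

    def check_fittable(self) -> None:
        """A calibration needs more reference spectra than components."""
        if self.n_samples <= self.n_components:
            raise ValueError(
                f"only {self.n_samples} reference spectra for "
                f"{self.n_components} components; need strictly more"
            )


def concentration_grid(config: AugmentationConfig, n_components: int) -> np.ndarray:
    """All rows of the factorial concentration design, in ppm.

    Enumerates ``scale_factors ** n_components`` combinations
    lexicographically (last component fastest) and multiplies by the base
    concentration; the design is balanced, every component taking each
    level equally often.
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    rows = np.array(
        list(itertools.product(config.scale_factors, repeat=n_components)), dtype=float
    )
    return rows * config.base_concentration


def build_reference_set(
    singles: list[Spectrum], config: AugmentationConfig, component_names: list[str] | None = None
) -> ReferenceSet:
    """Build the full-factorial calibration corpus from single-component spectra.

    Each row for a factor tuple (f_1 ... f_N) is ``sum_i f_i * single_i``
    plus noise as configured; the matching Y row is the factor tuple times
    the base concentration.  With six components and four factor levels this
    yields the 4096-spectrum reference set.
    """
    if not singles:
        raise ValueError("need at least one single-component spectrum")
    grid = singles[0].grid
    for s in singles[1:]:
        if not np.array_equal(s.grid.values, grid.values):
            raise ValueError("all single-component spectra must share one wavelength grid")
    if component_names is None:
        component_names = [s.name or f"component_{i}" for i, s in enumerate(singles)]
    if len(component_names) != len(singles):
        raise ValueError("one name per single-component spectrum required")

    n = len(singles)
    Y = concentration_grid(config, n)
    F = Y / config.base_concentration
    S = np.vstack([s.signal for s in singles])
    clean = ReferenceSet(
        X=F @ S,
        Y=Y,
        component_names=tuple(component_names),
        grid=grid,
        singles=tuple(singles),
    )
    if config.noise_fraction == 0:
        return clean
    return inject_noise(clean, config)


def inject_noise(ref: ReferenceSet, config: AugmentationConfig) -> ReferenceSet:
    """Apply the Gaussian noise model to a (clean) reference set.

    ``per_reference``: each row gets independent noise with standard
    deviation ``noise_fraction * RMS(row)``.  ``originals``: each base
    spectrum is perturbed once (std ``noise_fraction * RMS(single)``) and
    the rows are rebuilt as factor-weighted sums of the noisy singles, so
    rows sharing a factor share the identical noise realisation.
    """
    if config.noise_fraction == 0:
        return ref
    if config.noise_placement == "per_reference":
        rng = np.random.default_rng(config.seed)
        rms = np.sqrt(np.mean(ref.X**2, axis=1, keepdims=True))
        noisy = ref.X + rng.normal(size=ref.X.shape) * (config.noise_fraction * rms)
        return replace(ref, X=noisy)
    # originals mode: perturb the base spectra, then recombine.
    if ref.singles is None:
        raise ValueError(
            "originals-mode noise needs the base spectra; build the set with "
            "build_reference_set or attach `singles`"
        )
    noisy_singles = tuple(
        add_noise(s, config.noise_fraction, seed=config.seed + i)
        for i, s in enumerate(ref.singles)
    )
    F = ref.Y / config.base_concentration
    S = np.vstack([s.signal for s in noisy_singles])
    return replace(ref, X=F @ S, singles=noisy_singles)
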
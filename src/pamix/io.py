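"""File formats and run configuration.

Spectra travel as wide CSV: first column ``wavelength_nm``, one column per
sample, header row with sample identifiers, '.' decimal separator.  Values
are written with 12 significant digits so a write -> read round trip is
faithful at that precision.  Component libraries (band parameters per VOC)
are JSON or YAML.  A reference set is persisted as paired CSVs (``X.csv``
wide spectra, ``Y.csv`` concentrations) plus a JSON sidecar recording the
configuration, seed and row-ordering convention.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .reference import AugmentationConfig, ReferenceSet
from .spectra import BandShape, CrossSectionModel, Spectrum, WavelengthGrid

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_library",
    "write_library",
    "save_reference_set",
    "load_reference_set",
    "RunConfig",
    "config_digest",
]

_FMT = "{:.12g}"


class SpectraCSVError(ValueError):
    """Malformed wide-format spectra CSV (message carries the line number)."""


def write_spectra_csv(path: str | Path, grid: WavelengthGrid, spectra: dict[str, np.ndarray]) -> None:
    """Write named signals sharing one grid as a wide CSV."""
    names = list(spectra)
    cols = []
    for name in names:
        s = np.asarray(spectra[name], dtype=float)
        if s.shape != (len(grid),):
            raise ValueError(f"signal {name!r} does not match the wavelength grid")
        cols.append(s)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["wavelength_nm", *names])
        for i, wl in enumerate(grid.values):
            w.writerow([_FMT.format(wl), *(_FMT.format(c[i]) for c in cols)])


def read_spectra_csv(path: str | Path) -> tuple[WavelengthGrid, dict[str, Spectrum]]:
    """Read a wide spectra CSV back into named :class:`Spectrum` objects.

    Raises :class:`SpectraCSVError` with the offending line number for
    ragged rows, non-numeric cells, or non-increasing wavelengths.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise SpectraCSVError(f"{path}: empty file")
    header = rows[0]
    if not header or header[0] != "wavelength_nm":
        raise SpectraCSVError(f"{path}, line 1: first column must be 'wavelength_nm'")
    names = header[1:]
    if len(set(names)) != len(names):
        raise SpectraCSVError(f"{path}, line 1: duplicate sample identifiers")
    ncol = len(header)
    wavelengths: list[float] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != ncol:
            raise SpectraCSVError(
                f"{path}, line {lineno}: expected {ncol} cells, got {len(row)}"
            )
        try:
            values = [float(c) for c in row]
        except ValueError as exc:
            raise SpectraCSVError(f"{path}, line {lineno}: non-numeric cell ({exc})") from None
        if wavelengths and values[0] <= wavelengths[-1]:
            raise SpectraCSVError(
                f"{path}, line {lineno}: wavelengths must be strictly increasing "
                f"({values[0]} after {wavelengths[-1]})"
            )
        wavelengths.append(values[0])
        data.append(values[1:])
    grid = WavelengthGrid(np.asarray(wavelengths))
    mat = np.asarray(data, dtype=float)
    spectra = {
        name: Spectrum(grid=grid, signal=mat[:, j], normalized=True, name=name)
        for j, name in enumerate(names)
    }
    return grid, spectra


# -- component libraries --------------------------------------------------


def write_library(path: str | Path, models: list[CrossSectionModel]) -> None:
    """Serialize cross-section models (band parameters) to JSON or YAML."""
    doc = {
        "format": "pamix-component-library",
        "components": [
            {
                "name": m.component_name,
                "baseline": m.baseline,
                "bands": [
                    {
                        "center_nm": b.center,
                        "fwhm_nm": b.width,
                        "amplitude": b.amplitude,
                        "profile": b.profile,
                    }
                    for b in m.bands
                ],
            }
            for m in models
        ],
    }
    path = Path(path)
    text = (
        yaml.safe_dump(doc, sort_keys=False)
        if path.suffix in (".yml", ".yaml")
        else json.dumps(doc, indent=1)
    )
    path.write_text(text, encoding="utf-8")


def read_library(path: str | Path) -> list[CrossSectionModel]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    if not isinstance(doc, dict) or doc.get("format") != "pamix-component-library":
        raise ValueError(f"{path}: not a component-library file")
    models = []
    for comp in doc["components"]:
        bands = tuple(
            BandShape(
                center=float(b["center_nm"]),
                width=float(b["fwhm_nm"]),
                amplitude=float(b["amplitude"]),
                profile=b.get("profile", "gaussian"),
            )
            for b in comp["bands"]
        )
        models.append(
            CrossSectionModel(
                component_name=comp["name"], bands=bands, baseline=float(comp.get("baseline", 0.0))
            )
        )
    return models


# -- reference sets -------------------------------------------------------


def save_reference_set(out_dir: str | Path, ref: ReferenceSet, config: AugmentationConfig) -> None:
    """Persist a reference set as X.csv / Y.csv / meta.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sample_names = [f"ref_{i:05d}" for i in range(ref.n_samples)]
    write_spectra_csv(out / "X.csv", ref.grid, dict(zip(sample_names, ref.X)))
    with open(out / "Y.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", *[f"{n}_ppm" for n in ref.component_names]])
        for name, row in zip(sample_names, ref.Y):
            w.writerow([name, *(_FMT.format(v) for v in row)])
    meta = {
        "format": "pamix-reference-set",
        "config": dataclasses.asdict(config),
        "config_digest": config_digest(dataclasses.asdict(config)),
        "component_names": list(ref.component_names),
        "row_order": "lexicographic product of scale factors, last component fastest",
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def load_reference_set(in_dir: str | Path) -> tuple[ReferenceSet, AugmentationConfig]:
    out = Path(in_dir)
    meta = json.loads((out / "meta.json").read_text(encoding="utf-8"))
    if meta.get("format") != "pamix-reference-set":
        raise ValueError(f"{out}: not a reference-set directory")
    config = AugmentationConfig(**{
        **meta["config"],
        "scale_factors": tuple(meta["config"]["scale_factors"]),
    })
    grid, spectra = read_spectra_csv(out / "X.csv")
    X = np.vstack([spectra[n].signal for n in spectra])
    names = list(meta["component_names"])
    with open(out / "Y.csv", newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    Y = np.asarray([[float(c) for c in row[1:]] for row in rows[1:]], dtype=float)
    ref = ReferenceSet(X=X, Y=Y, component_names=tuple(names), grid=grid)
    return ref, config


# -- run configuration ----------------------------------------------------


def config_digest(doc: dict) -> str:
    """Short stable digest identifying a configuration."""
    blob = json.dumps(doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


_GRID_KEYS = {"start_nm", "stop_nm", "n_points"}
_AUG_KEYS = {"scale_factors", "base_concentration", "noise_fraction", "noise_placement", "seed"}
_PLS_KEYS = {"n_factors", "scale"}
_CV_KEYS = {"k", "n_factors", "seed"}
_TOP_KEYS = {"grid", "library", "augmentation", "pls", "cv", "seed"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration (YAML or JSON).

    Unknown keys anywhere in the document are rejected with a message
    naming them, so typos cannot silently fall back to defaults.
    """

    grid: dict
    library: str | None
    augmentation: dict
    pls: dict
    cv: dict
    seed: int

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc or {})
        unknown = set(doc) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in (
            ("grid", _GRID_KEYS),
            ("augmentation", _AUG_KEYS),
            ("pls", _PLS_KEYS),
            ("cv", _CV_KEYS),
        ):
            extra = set(doc.get(section) or {}) - allowed
            if extra:
                raise ValueError(f"unknown keys in config section {section!r}: {sorted(extra)}")
        return cls(
            grid=dict(doc.get("grid") or {}),
            library=doc.get("library"),
            augmentation=dict(doc.get("augmentation") or {}),
            pls=dict(doc.get("pls") or {}),
            cv=dict(doc.get("cv") or {}),
            seed=int(doc.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        doc = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(doc)

    def make_grid(self) -> WavelengthGrid:
        return WavelengthGrid.default(
            start=float(self.grid.get("start_nm", 3250.0)),
            stop=float(self.grid.get("stop_nm", 3550.0)),
            n=int(self.grid.get("n_points", 301)),
        )

    def make_augmentation(self, seed: int | None = None) -> AugmentationConfig:
        kw = dict(self.augmentation)
        if "scale_factors" in kw:
            kw["scale_factors"] = tuple(kw["scale_factors"])
        if seed is not None:
            kw["seed"] = seed
        return AugmentationConfig(**kw)

    def digest(self) -> str:
        return config_digest(dataclasses.asdict(self))
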
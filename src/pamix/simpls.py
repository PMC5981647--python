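"""SIMPLS partial least squares regression, implemented from scratch.

Partial least squares models the linear relation ``Y = X @ B + G`` between a
predictor matrix X (spectra as rows) and a response matrix Y (known
concentrations) through a small number of latent factors, which makes it
robust for spectroscopic data whose thousands of wavelength channels are
strongly collinear.  SIMPLS (de Jong, 1993) computes the factors directly
from the cross-product matrix S = Xc' Yc of the column-centered data:

1. take the dominant left singular vector of the (deflated) cross-product
   as the next weight vector r_a;
2. form the score t_a = Xc r_a, normalise it to unit length;
3. compute loadings p_a = Xc' t_a and q_a = Yc' t_a;
4. deflate S against an orthonormal basis of the x-loadings so the next
   weight is orthogonal to everything already explained.

The regression coefficients are B = R Q' and prediction is the single
matrix product ``y_mean + (x - x_mean) @ B``.  Successive score vectors are
mutually orthogonal by construction.

No randomness is involved; a fixed sign convention on the weight vectors
(largest-magnitude entry positive) removes the SVD sign ambiguity so
repeated fits are bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PLSModel", "PredictionResult", "fit_simpls", "predict", "variance_explained"]

SERIAL_VERSION = 1


@dataclass(frozen=True)
class PredictionResult:
    """Raw and nonnegativity-clamped concentration predictions, ppm.

    PLS is an unconstrained linear map, so raw predictions can come out
    negative; ``clamped`` applies the physical prior that concentrations
    are nonnegative (elementwise ``max(raw, 0)``).  Clamping is a
    presentation-level step, never fed back into fitting.
    """

    raw: np.ndarray
    clamped: np.ndarray
    component_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", np.asarray(self.raw, dtype=float))
        object.__setattr__(self, "clamped", np.asarray(self.clamped, dtype=float))
        if self.raw.shape != self.clamped.shape:
            raise ValueError("raw and clamped shapes differ")
        if self.raw.shape[-1] != len(self.component_names):
            raise ValueError("prediction width does not match component names")


@dataclass(frozen=True)
class PLSModel:
    """Fitted SIMPLS state.

    ``coefficients`` is the n_wavelengths x n_components regression matrix
    B (ppm per a.u.); ``weights``, ``x_loadings``, ``y_loadings`` the
    per-factor SIMPLS quantities; the variance-explained arrays give the
    fraction of centered sum-of-squares of X and Y captured by each factor.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    n_factors: int
    weights: np.ndarray  # n_wavelengths x n_factors
    x_loadings: np.ndarray  # n_wavelengths x n_factors
    y_loadings: np.ndarray  # n_components x n_factors
    coefficients: np.ndarray  # n_wavelengths x n_components
    x_variance_explained: np.ndarray  # per-factor fractions
    y_variance_explained: np.ndarray
    component_names: tuple[str, ...] = ()
    x_scale: np.ndarray | None = None  # column stds if scale=True at fit

    def __post_init__(self) -> None:
        if self.coefficients.shape[1] != self.y_mean.shape[0]:
            raise ValueError("coefficient columns must match response dimension")

    @property
    def n_wavelengths(self) -> int:
        return int(self.x_mean.size)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "format": "pamix-pls-model",
            "version": SERIAL_VERSION,
            "n_factors": int(self.n_factors),
            "component_names": list(self.component_names),
            "dims": {
                "n_wavelengths": self.n_wavelengths,
                "n_components": int(self.y_mean.size),
            },
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean.tolist(),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "x_variance_explained": self.x_variance_explained.tolist(),
            "y_variance_explained": self.y_variance_explained.tolist(),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        if d.get("format") != "pamix-pls-model":
            raise ValueError("not a pamix PLS model container")
        if d.get("version") != SERIAL_VERSION:
            raise ValueError(f"unsupported model version {d.get('version')!r}")
        arr = lambda k: np.asarray(d[k], dtype=float)
        return cls(
            x_mean=arr("x_mean"),
            y_mean=arr("y_mean"),
            n_factors=int(d["n_factors"]),
            weights=arr("weights"),
            x_loadings=arr("x_loadings"),
            y_loadings=arr("y_loadings"),
            coefficients=arr("coefficients"),
            x_variance_explained=arr("x_variance_explained"),
            y_variance_explained=arr("y_variance_explained"),
            component_names=tuple(d.get("component_names", ())),
            x_scale=None if d.get("x_scale") is None else np.asarray(d["x_scale"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit_simpls(
    X: np.ndarray,
    Y: np.ndarray,
    n_factors: int = 6,
    component_names: tuple[str, ...] | None = None,
    scale: bool = False,
) -> PLSModel:
    """Calibrate a PLS model with the SIMPLS algorithm.

    Parameters
    ----------
    X : (n_samples, n_wavelengths)
        Predictor matrix, spectra as rows.
    Y : (n_samples, n_components) or (n_samples,)
        Known concentrations, ppm.
    n_factors : int
        Number of latent factors to extract (default 6, one per component
        in the six-VOC problem).  Must satisfy
        ``n_factors <= min(n_samples - 1, n_wavelengths)``.
    scale : bool
        If True, columns of X are additionally divided by their standard
        deviation after centering (autoscaling).  Default False: plain
        mean-centering, the common default for spectral calibration.

    If the residual cross-product vanishes before ``n_factors`` factors are
    extracted (rank deficiency), fitting stops early with a warning and the
    model reports the achieved factor count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    m = Y.shape[1]
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n <= n_factors:
        raise ValueError(
            f"need more than n_factors={n_factors} samples, got {n} "
            "(the number of reference spectra must exceed the factor count)"
        )
    if n_factors > p:
        raise ValueError(f"n_factors={n_factors} exceeds {p} predictor channels")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    if not np.any(Xc):
        raise ValueError("X has zero variance; cannot calibrate")
    x_scale = None
    if scale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xc = Xc / x_scale

    ss_x = float(np.sum(Xc**2))
    ss_y = float(np.sum(Yc**2))

    S = Xc.T @ Yc  # p x m cross-product
    s0_norm = np.linalg.norm(S)

    R = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    Q = np.zeros((m, n_factors))
    V = np.zeros((p, n_factors))
    xvar = np.zeros(n_factors)
    yvar = np.zeros(n_factors)

    achieved = 0
    for a in range(n_factors):
        if np.linalg.norm(S) <= 1e-12 * max(1.0, s0_norm):
            warnings.warn(
                f"cross-product exhausted after {achieved} factors "
                f"(requested {n_factors}); stopping early",
                stacklevel=2,
            )
            break
        # dominant left singular vector of the deflated cross-product
        u, _, _ = np.linalg.svd(S, full_matrices=False)
        r = u[:, 0]
        # fixed sign convention: largest-magnitude weight entry positive
        if r[np.argmax(np.abs(r))] < 0:
            r = -r
        t = Xc @ r
        normt = np.linalg.norm(t)
        if normt <= 1e-12:
            warnings.warn(
                f"degenerate score at factor {a + 1}; stopping early", stacklevel=2
            )
            break
        t = t / normt
        r = r / normt
        pa = Xc.T @ t
        qa = Yc.T @ t
        # orthonormal basis of x-loadings, Gram-Schmidt with re-orthogonalization
        v = pa.copy()
        for _ in range(2):
            v -= V[:, :a] @ (V[:, :a].T @ v)
        vnorm = np.linalg.norm(v)
        if vnorm <= 1e-12:
            warnings.warn(
                f"loading basis degenerate at factor {a + 1}; stopping early",
                stacklevel=2,
            )
            break
        v /= vnorm
        S = S - np.outer(v, v @ S)

        R[:, a], P[:, a], Q[:, a], V[:, a] = r, pa, qa, v
        # scores are orthonormal, so each factor explains ||p||^2 of SS(Xc)
        xvar[a] = float(pa @ pa) / ss_x if ss_x > 0 else 0.0
        yvar[a] = float(qa @ qa) / ss_y if ss_y > 0 else 0.0
        achieved = a + 1

    if achieved == 0:
        raise ValueError("could not extract any PLS factor (degenerate input)")

    R, P, Q = R[:, :achieved], P[:, :achieved], Q[:, :achieved]
    B = R @ Q.T
    if x_scale is not None:
        B = B / x_scale[:, None]

    if component_names is None:
        component_names = tuple(f"component_{j}" for j in range(m))
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        n_factors=achieved,
        weights=R,
        x_loadings=P,
        y_loadings=Q,
        coefficients=B,
        x_variance_explained=xvar[:achieved],
        y_variance_explained=yvar[:achieved],
        component_names=tuple(component_names),
        x_scale=x_scale,
    )


def predict(model: PLSModel, x: np.ndarray) -> PredictionResult:
    """Predict concentrations for one spectrum or a matrix of spectra.

    ``raw = y_mean + (x - x_mean) @ B``; ``clamped`` zeroes negative
    entries.  A 1-D input yields 1-D outputs.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_wavelengths:
        raise ValueError(
            f"spectrum length {X.shape[1]} does not match model "
            f"({model.n_wavelengths} wavelengths)"
        )
    raw = model.y_mean + (X - model.x_mean) @ model.coefficients
    if single:
        raw = raw[0]
    return PredictionResult(
        raw=raw, clamped=np.maximum(raw, 0.0), component_names=model.component_names
    )


def variance_explained(model: PLSModel) -> dict[str, np.ndarray]:
    """Per-factor and cumulative variance-explained fractions for X and Y."""
    return {
        "x": model.x_variance_explained,
        "y": model.y_variance_explained,
        "x_cumulative": np.cumsum(model.x_variance_explained),
        "y_cumulative": np.cumsum(model.y_variance_explained),
    }
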
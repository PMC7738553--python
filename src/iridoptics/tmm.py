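"""Characteristic-matrix reflectivity of guanine/cytoplasm multilayers.

Each dielectric layer *j* with refractive index ``n_j`` and thickness
``d_j`` carries the 2x2 characteristic matrix

    m_j = [[cos b_j, -(i/eta_j) sin b_j],
           [-i eta_j sin b_j,  cos b_j]],   b_j = (2 pi / lambda) n_j d_j cos t_j,

where ``t_j`` is the propagation angle inside the layer (Snell's law
from ambient index 1.0) and ``eta_j`` the polarization-dependent
effective index (``eta = n`` at normal incidence).  The stack matrix is
the ordered product over the 2k layers of k crystal/cytoplasm double
layers, and the reflectance follows from the matrix elements with air
on both sides.  The default reflectance convention is the amplitude
modulus

    R = | ((m11 + m12) - (m21 + m22)) / ((m11 + m12) + (m21 + m22)) |

(unity ambient/exit media at normal incidence); a conventional
intensity reflectance |r|^2 is available behind a flag.  Peak positions
are identical under both conventions.

Disordered stacks are handled by Monte Carlo: reflectance is averaged
over many stacks whose layer thicknesses are drawn from the measured
crystallotype distributions (500 runs by default), either at normal
incidence or across 0-70 degrees for angle-dependence studies.
Refractive-index dispersion is neglected and interfaces are taken as
parallel; disorder enters only through the thickness distributions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import NumericalError, ParameterError
from .presets import CrystallotypePreset, LayerStack
from .stack_synth import sample_stack_batch

Polarization = Literal["s", "p", "unpolarized"]
Convention = Literal["paper_eq3", "standard_intensity"]

DEFAULT_WAVELENGTH_MIN = 380.0
DEFAULT_WAVELENGTH_MAX = 780.0
DEFAULT_WAVELENGTH_STEP = 1.0
DEFAULT_N_RUNS = 500


@dataclass(frozen=True)
class CharacteristicMatrix:
    """2x2 complex characteristic matrix of a layer or stack."""

    m11: complex
    m12: complex
    m21: complex
    m22: complex

    @classmethod
    def identity(cls) -> "CharacteristicMatrix":
        return cls(1.0 + 0j, 0j, 0j, 1.0 + 0j)

    def det(self) -> complex:
        return self.m11 * self.m22 - self.m12 * self.m21

    def __matmul__(self, other: "CharacteristicMatrix") -> "CharacteristicMatrix":
        return CharacteristicMatrix(
            self.m11 * other.m11 + self.m12 * other.m21,
            self.m11 * other.m12 + self.m12 * other.m22,
            self.m21 * other.m11 + self.m22 * other.m21,
            self.m21 * other.m12 + self.m22 * other.m22,
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.m11, self.m12], [self.m21, self.m22]], dtype=complex)


@dataclass(frozen=True)
class Spectrum:
    """Reflectance sampled on an ascending wavelength grid (nm)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if wl.shape != r.shape:
            raise ParameterError("wavelengths and reflectance must have equal length")
        if wl.size > 1 and not (np.diff(wl) > 0).all():
            raise ParameterError("wavelengths must be strictly ascending")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_reflectance(self, r: np.ndarray, **meta) -> "Spectrum":
        return Spectrum(self.wavelengths, r, {**self.metadata, **meta})


@dataclass(frozen=True)
class MonteCarloConfig:
    """Wavelength grid, incidence and averaging settings for simulations."""

    n_runs: int = DEFAULT_N_RUNS
    wavelength_min: float = DEFAULT_WAVELENGTH_MIN
    wavelength_max: float = DEFAULT_WAVELENGTH_MAX
    wavelength_step: float = DEFAULT_WAVELENGTH_STEP
    angle: float = 0.0  # degrees from the normal
    polarization: Polarization = "unpolarized"
    convention: Convention = "paper_eq3"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ParameterError("n_runs must be >= 1")
        if self.wavelength_min <= 0 or self.wavelength_max <= self.wavelength_min:
            raise ParameterError("invalid wavelength band")
        if self.wavelength_step <= 0:
            raise ParameterError("wavelength_step must be > 0")
        if not (0.0 <= self.angle <= 70.0):
            raise ParameterError("incidence angle must be within [0, 70] degrees")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(
            self.wavelength_min, self.wavelength_max + 0.5 * self.wavelength_step,
            self.wavelength_step,
        )


def _effective_index(n: float | np.ndarray, cos_t, polarization: str):
    if polarization == "s":
        return n * cos_t
    if polarization == "p":
        return n / cos_t
    raise ParameterError(f"unknown polarization {polarization!r}")


def layer_matrix(
    n: float,
    d: float,
    wavelength: float,
    angle_in_layer: float = 0.0,
    polarization: str = "s",
) -> CharacteristicMatrix:
    """Characteristic matrix of a single lossless layer.

    ``angle_in_layer`` is the propagation angle *inside* the layer in
    radians (0 for normal incidence, where s and p coincide).
    """
    if wavelength <= 0:
        raise ParameterError("wavelength must be > 0")
    if n < 1:
        raise ParameterError("refractive index must be >= 1")
    if d < 0:
        raise ParameterError("thickness must be >= 0")
    cos_t = np.cos(angle_in_layer)
    eta = _effective_index(n, cos_t, polarization)
    beta = 2.0 * np.pi / wavelength * n * d * cos_t
    cb, sb = np.cos(beta), np.sin(beta)
    return CharacteristicMatrix(cb, -1j / eta * sb, -1j * eta * sb, cb)


def snell_angle(n: float, angle_deg: float, n_ambient: float = 1.0) -> float:
    """Propagation angle (radians) inside a layer of index ``n``."""
    s = n_ambient * np.sin(np.deg2rad(angle_deg)) / n
    return float(np.arcsin(s))


def stack_matrix(
    stack: LayerStack,
    wavelength: float,
    angle: float = 0.0,
    polarization: str = "s",
) -> CharacteristicMatrix:
    """Ordered product of layer matrices over the whole stack.

    ``angle`` is the incidence angle in degrees in the ambient medium
    (index 1.0); per-layer angles follow Snell's law.  An empty stack
    returns the identity matrix.
    """
    m = CharacteristicMatrix.identity()
    for layer in stack.layers:
        t = snell_angle(layer.refractive_index, angle)
        m = m @ layer_matrix(
            layer.refractive_index, layer.thickness, wavelength, t, polarization
        )
    return m


def reflectivity(
    m: CharacteristicMatrix,
    convention: Convention = "paper_eq3",
    eta_in: float = 1.0,
    eta_out: float = 1.0,
) -> float:
    """Reflectance from a characteristic matrix.

    ``paper_eq3`` returns the amplitude modulus |r|; with the default
    unity ambient/exit admittances this is exactly
    ``|((m11+m12)-(m21+m22)) / ((m11+m12)+(m21+m22))|``.
    ``standard_intensity`` returns |r|^2.  ``eta_in``/``eta_out`` are
    the ambient and exit-medium effective indices (admittances).
    """
    b = m.m11 + m.m12 * eta_out
    c = m.m21 + m.m22 * eta_out
    denom = eta_in * b + c
    if denom == 0:
        raise NumericalError("zero denominator in reflectance (singular stack matrix)")
    r = (eta_in * b - c) / denom
    mag = abs(r)
    if convention == "paper_eq3":
        return float(mag)
    if convention == "standard_intensity":
        return float(mag * mag)
    raise ParameterError(f"unknown convention {convention!r}")


def _reflectance_batch(
    thicknesses: np.ndarray,
    indices: np.ndarray,
    wavelengths: np.ndarray,
    angle_deg: float,
    polarization: str,
    convention: Convention,
) -> np.ndarray:
    """Reflectance of many stacks at once; shape (n_stacks, n_wavelengths).

    ``thicknesses``: (n_stacks, L) with zero-padding allowed (a
    zero-thickness layer contributes an identity matrix exactly);
    ``indices``: (L,) per-position refractive index.
    """
    d = np.atleast_2d(np.asarray(thicknesses, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    sin0 = np.sin(np.deg2rad(angle_deg))
    cos0 = np.cos(np.deg2rad(angle_deg))
    n_stacks = d.shape[0]
    m11 = np.ones((n_stacks, wl.size), dtype=complex)
    m22 = np.ones_like(m11)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    for j in range(d.shape[1]):
        n = indices[j]
        cos_t = np.sqrt(1.0 - (sin0 / n) ** 2)
        eta = _effective_index(n, cos_t, polarization)
        beta = (2.0 * np.pi / wl)[None, :] * n * d[:, j : j + 1] * cos_t
        cb = np.cos(beta)
        sb = np.sin(beta)
        a12 = -1j / eta * sb
        a21 = -1j * eta * sb
        m11, m12, m21, m22 = (
            m11 * cb + m12 * a21,
            m11 * a12 + m12 * cb,
            m21 * cb + m22 * a21,
            m21 * a12 + m22 * cb,
        )
    eta0 = _effective_index(1.0, cos0, polarization)
    b = m11 + m12 * eta0
    c = m21 + m22 * eta0
    r = np.abs((eta0 * b - c) / (eta0 * b + c))
    return r if convention == "paper_eq3" else r**2


def _reflectance_grid(
    thicknesses: np.ndarray,
    indices: np.ndarray,
    cfg: MonteCarloConfig,
    angle: float | None = None,
) -> np.ndarray:
    """Per-stack reflectance on cfg's grid, averaging s/p if unpolarized."""
    ang = cfg.angle if angle is None else angle
    if cfg.polarization == "unpolarized":
        if ang == 0.0:
            # s and p coincide at normal incidence
            return _reflectance_batch(thicknesses, indices, cfg.grid, ang, "s", cfg.convention)
        rs = _reflectance_batch(thicknesses, indices, cfg.grid, ang, "s", cfg.convention)
        rp = _reflectance_batch(thicknesses, indices, cfg.grid, ang, "p", cfg.convention)
        return 0.5 * (rs + rp)
    return _reflectance_batch(thicknesses, indices, cfg.grid, ang, cfg.polarization, cfg.convention)


def spectrum(stack: LayerStack, cfg: MonteCarloConfig | None = None) -> Spectrum:
    """Deterministic reflectance spectrum of one fixed stack."""
    cfg = cfg or MonteCarloConfig(n_runs=1)
    if len(stack.layers) == 0:
        wl = cfg.grid
        return Spectrum(wl, np.zeros_like(wl), {"angle": cfg.angle, "n_runs": 1})
    r = _reflectance_grid(stack.thicknesses[None, :], stack.indices, cfg)[0]
    return Spectrum(
        cfg.grid, r,
        {"angle": cfg.angle, "polarization": cfg.polarization,
         "convention": cfg.convention, "n_runs": 1},
    )


def monte_carlo_spectrum(
    preset: CrystallotypePreset, cfg: MonteCarloConfig
) -> Spectrum:
    """Mean reflectance over ``cfg.n_runs`` independently sampled stacks."""
    d, indices = sample_stack_batch(preset, cfg.n_runs, cfg.rng_seed)
    r = _reflectance_grid(d, indices, cfg).mean(axis=0)
    return Spectrum(
        cfg.grid, r,
        {"preset": preset.name, "angle": cfg.angle, "polarization": cfg.polarization,
         "convention": cfg.convention, "n_runs": cfg.n_runs, "seed": cfg.rng_seed},
    )


def angular_scan(
    preset: CrystallotypePreset,
    cfg: MonteCarloConfig,
    angles: Sequence[float] | Iterable[float],
) -> list[Spectrum]:
    """Averaged spectra at several incidence angles, same stacks per angle.

    The same seeded stack ensemble is reused across angles (the physical
    picture: identical cells viewed at different angles), so the 0-degree
    result is identical to :func:`monte_carlo_spectrum` at the same seed.
    """
    angles = list(angles)
    for a in angles:
        if not (0.0 <= a <= 70.0):
            raise ParameterError("angles must lie within [0, 70] degrees")
    d, indices = sample_stack_batch(preset, cfg.n_runs, cfg.rng_seed)
    out = []
    for a in angles:
        r = _reflectance_grid(d, indices, cfg, angle=a).mean(axis=0)
        out.append(
            Spectrum(
                cfg.grid, r,
                {"preset": preset.name, "angle": a, "polarization": cfg.polarization,
                 "convention": cfg.convention, "n_runs": cfg.n_runs, "seed": cfg.rng_seed},
            )
        )
    return out


def config_for_preset(cfg: MonteCarloConfig, **overrides) -> MonteCarloConfig:
    """Convenience copy-with-overrides for MonteCarloConfig."""
    return replace(cfg, **overrides)
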
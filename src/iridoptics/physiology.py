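"""Quarter-wave relations and the norepinephrine spacing-response model.

An ideal two-material multilayer reflects maximally at the first-order
Bragg wavelength ``lambda = 2 (n1 d1 + n2 d2)``; for the mean ordered
crystallotype (27 nm guanine / 131 nm cytoplasm) this is 447.2 nm,
consistent with the simulated blue peak.  Norepinephrine (NE) shifts
the reflectance peak of stripe (ordered-crystallotype) iridophores from
about 450 to about 570 nm while interstripe (disordered) iridophores
are refractory.  The model here encodes that observation as a
multiplicative dilation of the cytoplasm spacing: the default factor
1.35 is *calibrated* — chosen so the analytic quarter-wave peak moves
from ~447 to ~570 nm (177.1 / 131.0 ~ 1.351) — not a measured spacing.
Crystal thicknesses are unchanged and SDs scale with the mean (constant
coefficient of variation).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import colorimetry
from .errors import ParameterError
from .presets import CrystallotypePreset
from .tmm import MonteCarloConfig, Spectrum, monte_carlo_spectrum


@dataclass(frozen=True)
class NEModel:
    """Cytoplasm-spacing dilation factors applied under NE treatment."""

    dilation_ordered: float = 1.35
    dilation_disordered: float = 1.0  # refractory

    def __post_init__(self) -> None:
        if self.dilation_ordered <= 0 or self.dilation_disordered <= 0:
            raise ParameterError("dilation factors must be > 0")


def quarter_wave_peak(
    d_crystal: float, d_cytoplasm: float, n_crystal: float, n_cytoplasm: float
) -> float:
    """First-order Bragg peak 2(n1 d1 + n2 d2) of the ideal multilayer (nm)."""
    if min(d_crystal, d_cytoplasm, n_crystal, n_cytoplasm) <= 0:
        raise ParameterError("all inputs must be > 0")
    return 2.0 * (n_crystal * d_crystal + n_cytoplasm * d_cytoplasm)


def invert_spacing_for_peak(
    target_peak: float, d_crystal: float, n_crystal: float, n_cytoplasm: float
) -> float:
    """Cytoplasm spacing (nm) that places the Bragg peak at ``target_peak``."""
    if min(target_peak, d_crystal, n_crystal, n_cytoplasm) <= 0:
        raise ParameterError("all inputs must be > 0")
    floor = 2.0 * n_crystal * d_crystal
    if target_peak <= floor:
        raise ParameterError(
            f"target peak {target_peak} nm is below the crystal-only floor {floor} nm"
        )
    return (target_peak / 2.0 - n_crystal * d_crystal) / n_cytoplasm


@dataclass(frozen=True)
class CrystallotypeResponse:
    """Pre/post-NE optical readout for one crystallotype."""

    name: str
    peak_pre_nm: float
    peak_post_nm: float
    xy_pre: colorimetry.ChromaticityPoint
    xy_post: colorimetry.ChromaticityPoint
    spectrum_pre: Spectrum
    spectrum_post: Spectrum

    @property
    def peak_shift_nm(self) -> float:
        return self.peak_post_nm - self.peak_pre_nm


@dataclass(frozen=True)
class NEReport:
    ordered: CrystallotypeResponse
    disordered: CrystallotypeResponse
    contrast_pre: float
    contrast_post: float

    def to_dict(self) -> dict:
        def _side(r: CrystallotypeResponse) -> dict:
            return {
                "peak_pre_nm": r.peak_pre_nm,
                "peak_post_nm": r.peak_post_nm,
                "peak_shift_nm": r.peak_shift_nm,
                "cie_pre": [r.xy_pre.x, r.xy_pre.y],
                "cie_post": [r.xy_post.x, r.xy_post.y],
            }

        return {
            "ordered": _side(self.ordered),
            "disordered": _side(self.disordered),
            "contrast_pre": self.contrast_pre,
            "contrast_post": self.contrast_post,
        }


def _respond(
    name: str,
    preset: CrystallotypePreset,
    dilation: float,
    cfg: MonteCarloConfig,
) -> CrystallotypeResponse:
    pre = monte_carlo_spectrum(preset, cfg)
    post_preset = preset.with_cytoplasm_scaled(dilation) if dilation != 1.0 else preset
    post = monte_carlo_spectrum(post_preset, cfg)
    return CrystallotypeResponse(
        name=name,
        peak_pre_nm=colorimetry.peak_wavelength(pre),
        peak_post_nm=colorimetry.peak_wavelength(post),
        xy_pre=colorimetry.cie_xy(pre),
        xy_post=colorimetry.cie_xy(post),
        spectrum_pre=pre,
        spectrum_post=post,
    )


def ne_response(
    preset_ordered: CrystallotypePreset,
    preset_disordered: CrystallotypePreset,
    model: NEModel | None = None,
    cfg: MonteCarloConfig | None = None,
) -> NEReport:
    """Simulate both crystallotypes before and after NE treatment.

    Reuses the same stack ensemble (same seed) pre and post so the
    reported shift isolates the spacing dilation; reports per-type peak
    shifts, chromaticities and the stripe/interstripe contrast.
    """
    model = model or NEModel()
    cfg = cfg or MonteCarloConfig()
    # decorrelate the two crystallotype ensembles deterministically
    seed_o = int(np.random.SeedSequence([cfg.rng_seed, 0]).generate_state(1)[0] % 2**31)
    seed_d = int(np.random.SeedSequence([cfg.rng_seed, 1]).generate_state(1)[0] % 2**31)
    from dataclasses import replace

    ordered = _respond(
        "ordered", preset_ordered, model.dilation_ordered, replace(cfg, rng_seed=seed_o)
    )
    disordered = _respond(
        "disordered", preset_disordered, model.dilation_disordered,
        replace(cfg, rng_seed=seed_d),
    )
    return NEReport(
        ordered=ordered,
        disordered=disordered,
        contrast_pre=colorimetry.contrast(ordered.xy_pre, disordered.xy_pre),
        contrast_post=colorimetry.contrast(ordered.xy_post, disordered.xy_post),
    )
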
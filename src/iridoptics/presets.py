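"""Crystallotype parameter presets and the layer-stack container.

Adult zebrafish iridophores come in two architectures: the *ordered*
crystallotype of loose stripe iridophores (thin guanine platelets in
20-30 parallel layers with narrow cytoplasm gaps) and the *disordered*
crystallotype of dense interstripe iridophores (similar platelets, but
with broadly varying cytoplasm spacings).  A :class:`CrystallotypePreset`
bundles the measured thickness/spacing distributions, layer-count range
and refractive indices for one crystallotype; :class:`LayerStack` is one
concrete realisation — an alternating crystal/cytoplasm multilayer — fed
to the transfer-matrix engine.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import ParameterError

Material = Literal["crystal", "cytoplasm"]

#: Refractive index of crystalline beta-guanine platelets.
N_GUANINE = 1.83
#: Refractive index assumed for aqueous cytoplasm (not measured in situ;
#: the standard value used throughout the structural-colour literature).
N_CYTOPLASM = 1.33

#: Minimum physical layer thickness (nm); Gaussian draws below this are
#: rejection-resampled.
MIN_THICKNESS_NM = 5.0


@dataclass(frozen=True)
class CrystallotypePreset:
    """Distributional description of one iridophore crystallotype.

    Thicknesses are normal distributions (mean, SD) in nm, truncated at
    ``MIN_THICKNESS_NM`` when sampled; the crystal-layer count is uniform
    over ``[layer_count_min, layer_count_max]``.
    """

    name: str
    crystal_thickness_mean: float
    crystal_thickness_sd: float
    cytoplasm_mean: float
    cytoplasm_sd: float
    layer_count_min: int
    layer_count_max: int
    n_crystal: float = N_GUANINE
    n_cytoplasm: float = N_CYTOPLASM

    def __post_init__(self) -> None:
        if self.crystal_thickness_mean <= 0 or self.cytoplasm_mean <= 0:
            raise ParameterError("thickness means must be > 0")
        if self.crystal_thickness_sd < 0 or self.cytoplasm_sd < 0:
            raise ParameterError("thickness SDs must be >= 0")
        if self.layer_count_min > self.layer_count_max:
            raise ParameterError("layer_count_min must be <= layer_count_max")
        if self.layer_count_min < 1:
            raise ParameterError("need at least one double layer")
        if not (self.n_crystal > self.n_cytoplasm >= 1.0):
            raise ParameterError("require n_crystal > n_cytoplasm >= 1")

    def with_cytoplasm_scaled(self, factor: float) -> "CrystallotypePreset":
        """Preset with cytoplasm mean and SD multiplied by ``factor``.

        SD scales with the mean (constant coefficient of variation).
        """
        if factor <= 0:
            raise ParameterError("scale factor must be > 0")
        return replace(
            self,
            cytoplasm_mean=self.cytoplasm_mean * factor,
            cytoplasm_sd=self.cytoplasm_sd * factor,
        )


#: Ordered crystallotype (loose iridophores, stripe): 20-30 parallel
#: crystals of 27 +/- 7 nm separated by 131 +/- 24 nm cytoplasm.
ORDERED = CrystallotypePreset(
    name="ordered",
    crystal_thickness_mean=27.0,
    crystal_thickness_sd=7.0,
    cytoplasm_mean=131.0,
    cytoplasm_sd=24.0,
    layer_count_min=20,
    layer_count_max=30,
)

#: Disordered crystallotype (dense iridophores, interstripe): 30-40
#: crystals of 25 +/- 8 nm with highly variable 186 +/- 81 nm spacings.
DISORDERED = CrystallotypePreset(
    name="disordered",
    crystal_thickness_mean=25.0,
    crystal_thickness_sd=8.0,
    cytoplasm_mean=186.0,
    cytoplasm_sd=81.0,
    layer_count_min=30,
    layer_count_max=40,
)

PRESETS = {"ordered": ORDERED, "disordered": DISORDERED}


@dataclass(frozen=True)
class Layer:
    material: Material
    refractive_index: float
    thickness: float  # nm


@dataclass(frozen=True)
class LayerStack:
    """An alternating crystal/cytoplasm multilayer.

    The stack consists of ``k`` double layers: (crystal, cytoplasm)
    repeated ``k`` times, so the matrix product runs over ``2k`` layers
    starting with a crystal layer.
    """

    layers: tuple[Layer, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for i, layer in enumerate(self.layers):
            if layer.thickness < 0:
                raise ParameterError("layer thicknesses must be >= 0")
            expected: Material = "crystal" if i % 2 == 0 else "cytoplasm"
            if layer.material != expected:
                raise ParameterError(
                    "layers must alternate crystal/cytoplasm starting with crystal"
                )

    @property
    def k(self) -> int:
        """Number of double layers (crystal layers)."""
        return (len(self.layers) + 1) // 2

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([l.thickness for l in self.layers], dtype=float)

    @property
    def indices(self) -> np.ndarray:
        return np.array([l.refractive_index for l in self.layers], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        crystal_thicknesses: Sequence[float],
        cytoplasm_thicknesses: Sequence[float],
        n_crystal: float = N_GUANINE,
        n_cytoplasm: float = N_CYTOPLASM,
    ) -> "LayerStack":
        """Interleave per-material thickness arrays into a stack.

        ``cytoplasm_thicknesses`` must have the same length as
        ``crystal_thicknesses`` (k double layers).
        """
        cry = list(crystal_thicknesses)
        cyt = list(cytoplasm_thicknesses)
        if len(cry) != len(cyt):
            raise ParameterError("need equal numbers of crystal and cytoplasm layers")
        layers: list[Layer] = []
        for dc, dy in zip(cry, cyt):
            layers.append(Layer("crystal", n_crystal, float(dc)))
            layers.append(Layer("cytoplasm", n_cytoplasm, float(dy)))
        return cls(tuple(layers))

    @classmethod
    def uniform(
        cls,
        k: int,
        d_crystal: float,
        d_cytoplasm: float,
        n_crystal: float = N_GUANINE,
        n_cytoplasm: float = N_CYTOPLASM,
    ) -> "LayerStack":
        """Zero-variance stack: k identical double layers."""
        return cls.from_arrays([d_crystal] * k, [d_cytoplasm] * k, n_crystal, n_cytoplasm)
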
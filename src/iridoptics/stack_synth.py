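"""Seeded synthetic generators for layer stacks and crystal morphometry.

Layer thicknesses are drawn from the normal distributions summarising
the cryo-SEM measurements of each crystallotype, rejection-resampled
against a 5 nm physical floor; crystal lengths and aspect ratios mimic
the TEM measurements of isolated platelets.  Every generator takes an
explicit seed and is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, ParameterError
from .presets import MIN_THICKNESS_NM, CrystallotypePreset, LayerStack


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, floor: float
) -> np.ndarray:
    """Normal(mean, sd) draws rejection-resampled until all >= floor."""
    if sd == 0.0:
        if mean < floor:
            raise ParameterError(f"degenerate mean {mean} below floor {floor}")
        return np.full(size, mean, dtype=float)
    out = rng.normal(mean, sd, size)
    bad = out < floor
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < floor
    return out


def sample_stack(
    preset: CrystallotypePreset,
    rng_seed: int | np.random.Generator,
) -> LayerStack:
    """Draw one random multilayer realisation from a crystallotype preset.

    The crystal-layer count is uniform over the preset's range; each
    crystal and cytoplasm thickness is an independent truncated-normal
    draw (floor 5 nm).
    """
    rng = np.random.default_rng(rng_seed)
    k = int(rng.integers(preset.layer_count_min, preset.layer_count_max + 1))
    cry = _truncated_normal(
        rng, preset.crystal_thickness_mean, preset.crystal_thickness_sd, k, MIN_THICKNESS_NM
    )
    cyt = _truncated_normal(
        rng, preset.cytoplasm_mean, preset.cytoplasm_sd, k, MIN_THICKNESS_NM
    )
    return LayerStack.from_arrays(cry, cyt, preset.n_crystal, preset.n_cytoplasm)


def sample_stack_batch(
    preset: CrystallotypePreset,
    n_stacks: int,
    rng_seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample many stacks at once in padded-array form.

    Returns ``(thicknesses, indices)`` where ``thicknesses`` has shape
    ``(n_stacks, 2*k_max)``; rows of stacks with fewer than ``k_max``
    double layers are zero-padded (zero-thickness layers are optical
    identities, so padding is exact).  ``indices`` is the per-position
    refractive index, alternating crystal/cytoplasm.
    """
    if n_stacks < 1:
        raise ParameterError("n_stacks must be >= 1")
    rng = np.random.default_rng(rng_seed)
    ks = rng.integers(preset.layer_count_min, preset.layer_count_max + 1, n_stacks)
    k_max = int(ks.max())
    d = np.zeros((n_stacks, 2 * k_max), dtype=float)
    for i, k in enumerate(ks):
        k = int(k)
        d[i, 0 : 2 * k : 2] = _truncated_normal(
            rng, preset.crystal_thickness_mean, preset.crystal_thickness_sd, k, MIN_THICKNESS_NM
        )
        d[i, 1 : 2 * k : 2] = _truncated_normal(
            rng, preset.cytoplasm_mean, preset.cytoplasm_sd, k, MIN_THICKNESS_NM
        )
    indices = np.tile([preset.n_crystal, preset.n_cytoplasm], k_max)
    return d, indices


def truncation_bias(mean: float, sd: float, floor: float = MIN_THICKNESS_NM) -> float:
    """Shift of the truncated-normal mean above the nominal mean (nm).

    Closed form via :func:`scipy.stats.truncnorm`; used to bound the
    systematic bias the 5 nm floor introduces.
    """
    if sd == 0:
        return 0.0
    a = (floor - mean) / sd
    return float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd) - mean)


@dataclass(frozen=True)
class MorphometrySample:
    """Lengths, widths and aspect ratios of isolated guanine platelets."""

    lengths: np.ndarray  # um
    widths: np.ndarray  # um
    aspect_ratios: np.ndarray  # dimensionless, length/width >= 1
    crystallotype: str

    def __post_init__(self) -> None:
        if len(self.lengths) == 0:
            raise DataError("empty morphometry sample")
        if not (np.asarray(self.widths) > 0).all():
            raise DataError("widths must be > 0")
        if not (np.asarray(self.lengths) >= np.asarray(self.widths)).all():
            raise DataError("lengths must be >= widths")

    @property
    def n(self) -> int:
        return len(self.lengths)


def sample_morphometry(
    mean_len: float,
    sd_len: float,
    mean_ar: float,
    sd_ar: float,
    n: int,
    rng_seed: int | np.random.Generator,
    crystallotype: str = "unspecified",
) -> MorphometrySample:
    """Synthetic platelet morphometry for one crystallotype.

    Lengths ~ Normal(mean_len, sd_len) truncated > 0; aspect ratios
    (length/width) ~ Normal(mean_ar, sd_ar) truncated >= 1; widths are
    derived as length / aspect_ratio so the printed ratio definition
    holds exactly.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if mean_len <= 0 or mean_ar < 1:
        raise ParameterError("mean length must be > 0 and mean aspect ratio >= 1")
    rng = np.random.default_rng(rng_seed)
    tiny = np.finfo(float).tiny
    lengths = _truncated_normal(rng, mean_len, sd_len, n, tiny)
    ars = _truncated_normal(rng, mean_ar, sd_ar, n, 1.0)
    widths = lengths / ars
    return MorphometrySample(lengths, widths, ars, crystallotype)


# TEM parameters for isolated crystals: (mean length um, SD, mean aspect
# ratio, SD, n measured).
STRIPE_MORPHOMETRY = dict(mean_len=3.9, sd_len=0.4, mean_ar=1.9, sd_ar=0.2, n=60)
INTERSTRIPE_MORPHOMETRY = dict(mean_len=5.3, sd_len=0.9, mean_ar=2.5, sd_ar=0.3, n=57)


def summarize_morphometry(a: MorphometrySample, b: MorphometrySample) -> dict:
    """Compare two platelet samples the way the TEM data were compared.

    Returns per-group mean +/- SEM for lengths and aspect ratios and a
    two-sided Mann-Whitney (rank-sum) p-value on the aspect ratios.
    The exact null distribution is used for small samples (both n <= 20),
    the normal approximation otherwise.
    """
    method = "exact" if max(a.n, b.n) <= 20 else "asymptotic"
    test = stats.mannwhitneyu(a.aspect_ratios, b.aspect_ratios, method=method)

    def _grp(s: MorphometrySample) -> dict:
        return {
            "crystallotype": s.crystallotype,
            "n": s.n,
            "length_mean_um": float(np.mean(s.lengths)),
            "length_sem_um": float(stats.sem(s.lengths)) if s.n > 1 else 0.0,
            "aspect_ratio_mean": float(np.mean(s.aspect_ratios)),
            "aspect_ratio_sem": float(stats.sem(s.aspect_ratios)) if s.n > 1 else 0.0,
        }

    return {
        "group_a": _grp(a),
        "group_b": _grp(b),
        "mannwhitney_u": float(test.statistic),
        "p_value": float(test.pvalue),
        "method": method,
    }
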
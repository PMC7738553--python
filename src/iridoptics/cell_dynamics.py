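"""Time-lapse iridophore behaviour statistics on synthetic cell tracks.

Covers the three quantifications applied to membrane-labelled
iridophore movies — orientation of division planes (axial data, 0-180
degrees, measured from the anterior-posterior axis), net migration of
cells moving at least one cell diameter, and per-class proliferation
rates — together with a seeded track generator so every statistic can
be exercised and calibrated without imaging data.

Coordinate conventions: x increases toward posterior (AP axis), y
increases dorsally (DV axis).  Stripe iridophores sit ventral to the
first interstripe, so migration "away from the interstripe" means a
negative DV (y) component.  Iridophore classes: ``dense`` (interstripe,
tightly packed, near-static, divisions oriented along AP), ``loose``
(stripe, stellate, migratory with a ventral bias, divisions roughly
uniform) and ``edge`` (interstripe margin).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError

CLASSES = ("dense", "loose", "edge")

TRACK_COLUMNS = ["cell_id", "class", "t", "x_um", "y_um"]
DIVISION_COLUMNS = ["cell_id", "t", "angle_deg"]


@dataclass(frozen=True)
class TrackDataset:
    """Cell tracks plus division events.

    ``tracks``: one row per (cell, timepoint) with columns
    cell_id, class, t (minutes), x_um, y_um.
    ``divisions``: one row per division with cell_id, t, angle_deg
    (axial, [0, 180), from the AP axis).
    """

    tracks: pd.DataFrame
    divisions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=DIVISION_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = set(TRACK_COLUMNS) - set(self.tracks.columns)
        if missing:
            raise DataError(f"tracks missing columns: {sorted(missing)}")
        missing = set(DIVISION_COLUMNS) - set(self.divisions.columns)
        if missing:
            raise DataError(f"divisions missing columns: {sorted(missing)}")
        bad = set(self.tracks["class"].unique()) - set(CLASSES)
        if bad:
            raise DataError(f"unknown cell classes: {sorted(bad)}")
        if len(self.divisions):
            a = self.divisions["angle_deg"].to_numpy(float)
            if ((a < 0) | (a >= 180)).any():
                raise DataError("division angles must lie in [0, 180)")
        for _, g in self.tracks.groupby("cell_id"):
            if not g["t"].is_monotonic_increasing or g["t"].duplicated().any():
                raise DataError("timestamps must be strictly increasing per cell")

    @property
    def n_cells(self) -> int:
        return self.tracks["cell_id"].nunique()

    def cells_of_class(self, cls: str) -> pd.DataFrame:
        return self.tracks[self.tracks["class"] == cls]


@dataclass(frozen=True)
class TrackGeneratorParams:
    """Settings for the synthetic time-lapse generator.

    Defaults emulate a 15 h movie imaged every 5 min: dense cells are
    near-static jitter walks whose divisions concentrate on the AP axis
    (von Mises in doubled-angle space, concentration ``kappa_dense``);
    loose cells are random walks with a ventral drift and uniform
    division angles.  Division events are Poisson with class-specific
    rates (events per cell-hour); the loose default is twice the dense
    one.
    """

    dt_min: float = 5.0  # minutes between frames
    duration_h: float = 15.0
    dense_jitter_um: float = 0.3  # per-frame isotropic step SD
    loose_jitter_um: float = 1.5
    loose_drift_um_per_frame: tuple[float, float] = (0.0, -0.3)  # (AP, DV)
    dense_drift_um_per_frame: tuple[float, float] = (0.0, 0.0)
    kappa_dense: float = 4.0  # doubled-angle von Mises concentration
    division_rate_dense: float = 0.01  # divisions per cell-hour
    division_rate_loose: float = 0.02
    field_um: tuple[float, float] = (500.0, 300.0)

    def __post_init__(self) -> None:
        if self.dt_min <= 0 or self.duration_h <= 0:
            raise ParameterError("dt_min and duration_h must be > 0")
        if min(self.dense_jitter_um, self.loose_jitter_um) < 0:
            raise ParameterError("jitter SDs must be >= 0")
        if self.kappa_dense < 0:
            raise ParameterError("kappa must be >= 0")
        if min(self.division_rate_dense, self.division_rate_loose) < 0:
            raise ParameterError("division rates must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_h * 60.0 / self.dt_min)) + 1


def _sample_axial_angles(
    rng: np.random.Generator, n: int, kappa: float
) -> np.ndarray:
    """Axial angles in [0, 180): von Mises about the AP axis in doubled space."""
    if n == 0:
        return np.empty(0)
    if np.isinf(kappa):
        doubled = np.zeros(n)
    elif kappa == 0:
        doubled = rng.uniform(-np.pi, np.pi, n)
    else:
        doubled = rng.vonmises(0.0, kappa, n)
    return (np.rad2deg(doubled) / 2.0) % 180.0


def generate_tracks(
    n_dense: int,
    n_loose: int,
    params: TrackGeneratorParams | None = None,
    rng_seed: int = 0,
) -> TrackDataset:
    """Seeded synthetic time-lapse dataset of dense and loose iridophores."""
    if n_dense < 0 or n_loose < 0:
        raise ParameterError("cell counts must be >= 0")
    p = params or TrackGeneratorParams()
    rng = np.random.default_rng(rng_seed)
    nf = p.n_frames
    t = np.arange(nf) * p.dt_min

    frames_tracks: list[pd.DataFrame] = []
    frames_div: list[pd.DataFrame] = []
    specs = [
        ("dense", n_dense, p.dense_jitter_um, p.dense_drift_um_per_frame,
         p.division_rate_dense, p.kappa_dense),
        ("loose", n_loose, p.loose_jitter_um, p.loose_drift_um_per_frame,
         p.division_rate_loose, 0.0),
    ]
    cell0 = 0
    for cls, n_cells, jitter, drift, rate, kappa in specs:
        if n_cells == 0:
            continue
        start = np.column_stack([
            rng.uniform(0, p.field_um[0], n_cells),
            rng.uniform(0, p.field_um[1], n_cells),
        ])
        steps = rng.normal(0.0, jitter, (n_cells, nf - 1, 2)) if jitter > 0 else np.zeros(
            (n_cells, nf - 1, 2)
        )
        steps += np.asarray(drift)[None, None, :]
        pos = np.concatenate(
            [start[:, None, :], start[:, None, :] + np.cumsum(steps, axis=1)], axis=1
        )
        ids = np.arange(cell0, cell0 + n_cells)
        frames_tracks.append(
            pd.DataFrame({
                "cell_id": np.repeat(ids, nf),
                "class": cls,
                "t": np.tile(t, n_cells),
                "x_um": pos[:, :, 0].ravel(),
                "y_um": pos[:, :, 1].ravel(),
            })
        )
        # Poisson-thinned division events: per-frame probability rate*dt
        p_frame = rate * (p.dt_min / 60.0)
        events = rng.random((n_cells, nf - 1)) < p_frame
        ci, fi = np.nonzero(events)
        angles = _sample_axial_angles(rng, ci.size, kappa)
        frames_div.append(
            pd.DataFrame({
                "cell_id": ids[ci],
                "t": t[fi + 1],
                "angle_deg": angles,
            })
        )
        cell0 += n_cells
    tracks = (
        pd.concat(frames_tracks, ignore_index=True)
        if frames_tracks
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    divisions = (
        pd.concat(frames_div, ignore_index=True)
        if frames_div
        else pd.DataFrame(columns=DIVISION_COLUMNS)
    )
    return TrackDataset(tracks, divisions)


@dataclass(frozen=True)
class AxialStats:
    """Summary of axial (mod-180) orientation data."""

    mean_axis_deg: float  # in [0, 180)
    resultant_length: float  # of the doubled angles, in [0, 1]
    p_uniform: float  # Rayleigh test on doubled angles
    concentration: float  # von Mises kappa estimate in doubled space
    n: int


def _kappa_from_resultant(rbar: float, n: int) -> float:
    """Best-Fisher approximation to the von Mises concentration MLE."""
    if rbar >= 1.0:
        return float("inf")
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        denom = rbar**3 - 4 * rbar**2 + 3 * rbar  # cancels to 0 as rbar -> 1
        if denom <= 0:
            return float("inf")
        k = 1 / denom
    # small-sample correction (Fisher 1993)
    if n < 16 and k > 0:
        k = max(k - 2 / (n * k), 0.0) if k < 2 else k * (n - 1) ** 3 / (n**3 + n)
    return float(k)


def division_angle_stats(angles_deg) -> AxialStats:
    """Axial statistics of division-plane angles.

    Angles are doubled into circular space, where the mean direction,
    resultant length and Rayleigh uniformity test are computed; the
    mean is halved back to an axis in [0, 180).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise DataError("no angles supplied")
    doubled = np.deg2rad(2.0 * a)
    z = np.exp(1j * doubled).mean()
    rbar = float(np.abs(z))
    mean_axis = (np.rad2deg(np.angle(z)) / 2.0) % 180.0
    if a.size >= 2 and rbar > 1e-12:
        from pingouin import circ_rayleigh

        _, p = circ_rayleigh(doubled)
        p = float(min(p, 1.0))
    elif rbar <= 1e-12:
        p = 1.0
    else:
        p = 1.0
    return AxialStats(
        mean_axis_deg=float(mean_axis),
        resultant_length=rbar,
        p_uniform=p,
        concentration=_kappa_from_resultant(rbar, int(a.size)),
        n=int(a.size),
    )


@dataclass(frozen=True)
class MigrationReport:
    n_qualifying: int
    mean_dv_um: float
    ci_low_um: float
    ci_high_um: float
    fraction_away_from_interstripe: float
    empty: bool


def migration_bias(
    dataset: TrackDataset,
    cls: str = "loose",
    min_displacement_um: float = 20.0,
    rng_seed: int = 0,
    n_bootstrap: int = 2000,
) -> MigrationReport:
    """Net-displacement bias of cells that moved at least one cell diameter.

    A cell qualifies when the straight-line distance between its first
    and last position is >= ``min_displacement_um`` (default 20 um, a
    nominal iridophore diameter).  Reports the mean DV (y) component of
    qualifying net displacements with a percentile bootstrap CI, and the
    fraction moving ventrally (away from the first interstripe).
    """
    if cls not in CLASSES:
        raise ParameterError(f"unknown class {cls!r}")
    g = dataset.cells_of_class(cls)
    if len(g) == 0:
        return MigrationReport(0, np.nan, np.nan, np.nan, np.nan, True)
    first = g.groupby("cell_id").first()
    last = g.groupby("cell_id").last()
    dx = (last["x_um"] - first["x_um"]).to_numpy(float)
    dy = (last["y_um"] - first["y_um"]).to_numpy(float)
    dist = np.hypot(dx, dy)
    sel = dist >= min_displacement_um
    if not sel.any():
        return MigrationReport(0, np.nan, np.nan, np.nan, np.nan, True)
    dv = dy[sel]
    if dv.size >= 2:
        res = stats.bootstrap(
            (dv,), np.mean, n_resamples=n_bootstrap, method="percentile",
            rng=np.random.default_rng(rng_seed),
        )
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    else:
        lo = hi = float(dv.mean())
    return MigrationReport(
        n_qualifying=int(sel.sum()),
        mean_dv_um=float(dv.mean()),
        ci_low_um=lo,
        ci_high_um=hi,
        fraction_away_from_interstripe=float((dv < 0).mean()),
        empty=False,
    )


@dataclass(frozen=True)
class ClassRate:
    n_cells: int
    n_divisions: int
    cell_hours: float
    rate_per_cell_hour: float
    ci_low: float
    ci_high: float


def _exact_poisson_ci(k: int, exposure: float, alpha: float = 0.05) -> tuple[float, float]:
    from statsmodels.stats.rates import confint_poisson

    if exposure <= 0:
        raise DataError("zero observation time")
    if k == 0:
        lo = 0.0
        hi = float(stats.chi2.ppf(1 - alpha / 2, 2) / 2 / exposure)
        return lo, hi
    lo, hi = confint_poisson(k, exposure, method="exact-c", alpha=alpha)
    return float(lo), float(hi)


def proliferation_rates(dataset: TrackDataset) -> dict:
    """Divisions per cell-hour per class with exact Poisson CIs.

    When both dense and loose cells are present, also reports the
    loose/dense rate ratio with a two-sample Poisson rate test.
    """
    if len(dataset.tracks) == 0:
        raise DataError("empty dataset")
    out: dict = {"classes": {}}
    counts: dict[str, tuple[int, float]] = {}
    div_by_cell = dataset.divisions.groupby("cell_id").size() if len(dataset.divisions) else None
    for cls, g in dataset.tracks.groupby("class"):
        per_cell = g.groupby("cell_id")["t"].agg(["min", "max"])
        hours = float((per_cell["max"] - per_cell["min"]).sum() / 60.0)
        if hours <= 0:
            raise DataError(f"zero observation time for class {cls!r}")
        if div_by_cell is not None:
            k = int(div_by_cell.reindex(per_cell.index).fillna(0).sum())
        else:
            k = 0
        lo, hi = _exact_poisson_ci(k, hours)
        counts[str(cls)] = (k, hours)
        out["classes"][str(cls)] = ClassRate(
            n_cells=len(per_cell), n_divisions=k, cell_hours=hours,
            rate_per_cell_hour=k / hours, ci_low=lo, ci_high=hi,
        )
    if "loose" in counts and "dense" in counts:
        from statsmodels.stats.rates import confint_poisson_2indep, test_poisson_2indep

        (k1, e1), (k2, e2) = counts["loose"], counts["dense"]
        if k1 + k2 > 0:
            test = test_poisson_2indep(k1, e1, k2, e2, method="score")
            try:
                lo, hi = confint_poisson_2indep(k1, e1, k2, e2, method="score")
            except Exception:  # degenerate counts
                lo, hi = np.nan, np.nan
            rr = (k1 / e1) / (k2 / e2) if k2 > 0 else np.inf
            out["loose_vs_dense"] = {
                "rate_ratio": float(rr),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_value": float(test.pvalue),
            }
    return out
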
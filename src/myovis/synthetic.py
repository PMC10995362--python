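"""Synthetic study material: mosaics, choroid phantoms, observers, cohorts.

Every analysis stage can be exercised without clinical images:

* :func:`gen_mosaic` renders a jittered hexagonal cone mosaic as a sum of
  Gaussian spots with additive noise, keeping the ground-truth centers;
* :func:`gen_choroid_phantom` builds a two-compartment choroidal band
  (bright stroma, dark elliptical vessel lumens) between smooth boundaries,
  with per-pixel class labels and a controlled lumen fraction;
* :func:`gen_observer` instantiates a 2AFC observer whose contrast
  sensitivity follows a truncated log-parabola CSF and whose responses are
  drawn from the package's Weibull psychometric function;
* :func:`gen_cohort` draws a per-eye table with a myopia study's three-group
  structure (emmetropia / low-moderate myopia / simple high myopia), Table-1
  style biometry, and axial-length-coupled imaging and CSF outcomes.

All generators are deterministic under a fixed seed.

What the phantoms do *not* emulate: optical blur anisotropy, vessel
shadowing, motion artifacts, rods, or real OCT speckle statistics — passing
recovery tests on them demonstrates correctness of the measurement chain,
not clinical-grade robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .choroid import BScan, BoundarySet
from .cone_mosaic import AOImage
from .csf import DEFAULT_FREQUENCIES, PsychometricParams, psychometric

__all__ = [
    "MosaicSpec",
    "ChoroidPhantomSpec",
    "ObserverSpec",
    "CohortSpec",
    "SimulatedObserver",
    "gen_mosaic",
    "gen_choroid_phantom",
    "gen_observer",
    "gen_cohort",
    "hexagonal_lattice",
    "log_parabola_sensitivity",
]


# ---------------------------------------------------------------- cone mosaic

@dataclass(frozen=True)
class MosaicSpec:
    """Quasi-hexagonal cone mosaic rendered as Gaussian spots.

    ``density`` is cones/mm^2; ``jitter_sd`` is the positional jitter SD as a
    fraction of the lattice constant; ``dropout`` the Bernoulli cone-loss
    probability.  Default density matches healthy parafoveal values
    (~20,000/mm^2 at 0.6-1.2 mm eccentricity).
    """

    density: float = 20000.0
    jitter_sd: float = 0.08
    dropout: float = 0.0
    spot_sigma_um: float = 1.0
    pixel_scale: float = 0.5  # um/px
    noise_sd: float = 0.05  # spot peak amplitude is 1.0
    side_um: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    @property
    def lattice_constant_um(self) -> float:
        # hexagonal packing: density (per um^2) = 2 / (sqrt(3) s^2)
        return float(np.sqrt(2.0 / (np.sqrt(3.0) * self.density * 1e-6)))


def hexagonal_lattice(side_um: float, lattice_constant: float) -> np.ndarray:
    """Points of a hexagonal lattice covering [0, side)^2 (um, half-open)."""
    s = lattice_constant
    dy = s * np.sqrt(3.0) / 2.0
    pts = []
    row = 0
    y = 0.0
    while y < side_um:
        x0 = (s / 2.0) if (row % 2) else 0.0
        x = x0
        while x < side_um:
            pts.append((x, y))
            x += s
        row += 1
        y = row * dy
    return np.asarray(pts, dtype=float)


def gen_mosaic(spec: MosaicSpec) -> tuple[AOImage, np.ndarray]:
    """Render the mosaic; returns (image, ground-truth positions in um)."""
    rng = np.random.default_rng(spec.seed)
    s = spec.lattice_constant_um
    pts = hexagonal_lattice(spec.side_um, s)
    if spec.jitter_sd > 0:
        pts = pts + rng.normal(0.0, spec.jitter_sd * s, size=pts.shape)
    if spec.dropout > 0:
        pts = pts[rng.random(len(pts)) >= spec.dropout]
    inside = (
        (pts[:, 0] >= 0) & (pts[:, 0] <= spec.side_um)
        & (pts[:, 1] >= 0) & (pts[:, 1] <= spec.side_um)
    )
    pts = pts[inside]

    n_px = int(round(spec.side_um / spec.pixel_scale))
    img = np.zeros((n_px, n_px))
    sig_px = spec.spot_sigma_um / spec.pixel_scale
    r = max(2, int(np.ceil(4 * sig_px)))
    for x_um, y_um in pts:
        cx, cy = x_um / spec.pixel_scale, y_um / spec.pixel_scale
        x0, x1 = max(0, int(cx) - r), min(n_px, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(n_px, int(cy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sig_px**2)
        )
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = AOImage(pixels=img, pixel_scale=spec.pixel_scale, fovea_xy=(n_px / 2, n_px / 2))
    return image, pts


# ------------------------------------------------------------ choroid phantom

@dataclass(frozen=True)
class ChoroidPhantomSpec:
    """Two-compartment choroidal band with a controlled lumen fraction.

    Intensity levels mimic structural OCT: hyporeflective lumens (~60) inside
    bright stroma (~180), with Gaussian speckle.  The lumen fraction of
    choroid pixels is driven to ``lumen_fraction`` within +-0.01 by rejection
    sampling of elliptical vessels.
    """

    ct_um: float = 300.0
    lumen_fraction: float = 0.65
    vessel_radius_um: tuple[float, float] = (15.0, 60.0)
    lumen_mean: float = 60.0
    stroma_mean: float = 180.0
    retina_mean: float = 130.0
    sclera_mean: float = 110.0
    speckle_sd: float = 15.0
    lateral_scale: float = 6.0  # um/px
    axial_scale: float = 5.0  # um/px
    width_mm: float = 3.6
    boundary_wave_px: float = 6.0  # amplitude of the smooth RPE undulation
    include_retina_layers: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lumen_fraction < 1):
            raise ValueError("lumen_fraction must be in [0, 1)")
        if self.ct_um <= 0:
            raise ValueError("ct_um must be positive")


# nominal intraretinal boundary offsets above the RPE-Bruch complex, in um;
# shallow to deep, chosen near healthy parafoveal sublayer thicknesses
_RETINA_OFFSETS_UM = {
    "inl_opl": 230.0,
    "opl_hfl": 200.0,
    "elm": 115.0,
    "is_os": 88.0,
    "os_iz": 55.0,
}


def gen_choroid_phantom(
    spec: ChoroidPhantomSpec,
) -> tuple[BScan, BoundarySet, np.ndarray]:
    """Build the phantom; returns (scan, boundaries, labels).

    ``labels``: 0 outside the choroid, 1 stroma, 2 lumen.
    """
    rng = np.random.default_rng(spec.seed)
    w = int(round(spec.width_mm * 1000.0 / spec.lateral_scale))
    ct_px = spec.ct_um / spec.axial_scale
    top_margin = int(round(max(_RETINA_OFFSETS_UM.values()) / spec.axial_scale)) + 12
    h = int(round(top_margin + ct_px + 25 + 2 * spec.boundary_wave_px))

    x = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi)
    rpe = (
        top_margin
        + spec.boundary_wave_px * np.sin(2 * np.pi * x / w * 1.5 + phase)
        + spec.boundary_wave_px * 0.5 * np.sin(2 * np.pi * x / w * 3.7 + phase * 0.7)
    )
    cs = rpe + ct_px

    rows = np.arange(h)[:, None]
    choroid = (rows >= np.round(rpe)[None, :]) & (rows < np.round(cs)[None, :])
    n_choroid = int(choroid.sum())

    labels = np.where(choroid, 1, 0).astype(np.int8)
    target = spec.lumen_fraction
    if target > 0 and n_choroid > 0:
        lumen = np.zeros((h, w), dtype=bool)
        yy, xx = np.mgrid[0:h, 0:w]
        r_lo = spec.vessel_radius_um[0]
        r_hi = spec.vessel_radius_um[1]
        frac = 0.0
        for _ in range(20000):
            if frac >= target - 0.01:
                break
            cx = rng.uniform(0, w)
            cy = rng.uniform(rpe[int(cx) % w], cs[int(cx) % w])
            a = rng.uniform(r_lo, r_hi) / spec.lateral_scale
            b = rng.uniform(r_lo, r_hi) / spec.axial_scale
            theta = rng.uniform(0, np.pi)
            ct_, st_ = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct_ + (yy - cy) * st_
            v = -(xx - cx) * st_ + (yy - cy) * ct_
            ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            cand = lumen | (ell & choroid)
            new_frac = cand.sum() / n_choroid
            if new_frac <= target + 0.01:
                lumen = cand
                frac = new_frac
        labels[lumen] = 2

    img = np.full((h, w), float(spec.sclera_mean))
    img[rows < np.round(rpe)[None, :]] = spec.retina_mean
    img[labels == 1] = spec.stroma_mean
    img[labels == 2] = spec.lumen_mean
    if spec.speckle_sd > 0:
        img = img + rng.normal(0.0, spec.speckle_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    bset = {"rpe_bruch": rpe, "choroid_sclera": cs}
    if spec.include_retina_layers:
        for name, off_um in _RETINA_OFFSETS_UM.items():
            bset[name] = rpe - off_um / spec.axial_scale
    scan = BScan(
        pixels=img,
        lateral_scale=spec.lateral_scale,
        axial_scale=spec.axial_scale,
        fovea_column=w // 2,
        orientation="horizontal",
    )
    return scan, BoundarySet(bset), labels


# ------------------------------------------------------- simulated observers

@dataclass(frozen=True)
class ObserverSpec:
    """Truncated log-parabola CSF observer for 2AFC simulation.

    log10 S(f) = log10 G - 4 log10(2) ((log10 f - log10 f0)/w)^2, floored at
    log10 G - delta for f < f0.  Defaults give a young-adult CSF whose
    AULCSF over 1.5-24 cpd falls in the clinically observed adult range (1.5-1.9).
    """

    peak_gain: float = 100.0
    peak_frequency: float = 3.0
    bandwidth: float = 0.65
    truncation: float = 0.5
    slope: float = 3.0
    lapse_rate: float = 0.02
    guess_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_gain <= 1:
            raise ValueError("peak_gain must exceed 1")
        if self.peak_frequency <= 0 or self.bandwidth <= 0 or self.truncation < 0:
            raise ValueError("invalid CSF shape parameters")


def log_parabola_sensitivity(frequency, spec: ObserverSpec):
    """True log10 contrast sensitivity of the observer at ``frequency`` (cpd)."""
    f = np.asarray(frequency, dtype=float)
    lg = np.log10(spec.peak_gain)
    dev = (np.log10(f) - np.log10(spec.peak_frequency)) / spec.bandwidth
    y = lg - 4.0 * np.log10(2.0) * dev**2
    floor = lg - spec.truncation
    y = np.where((f < spec.peak_frequency) & (y < floor), floor, y)
    return y if y.shape else float(y)


class SimulatedObserver:
    """Stochastic 2AFC observer driven by a truncated log-parabola CSF."""

    def __init__(self, spec: ObserverSpec):
        self.spec = spec

    def true_threshold(self, frequency: float) -> float:
        s = 10.0 ** log_parabola_sensitivity(frequency, self.spec)
        return float(min(1.0, max(1e-6, 1.0 / s)))

    def true_params(self, frequency: float) -> PsychometricParams:
        return PsychometricParams(
            threshold=self.true_threshold(frequency),
            slope=self.spec.slope,
            guess_rate=self.spec.guess_rate,
            lapse_rate=self.spec.lapse_rate,
        )

    def respond(self, frequency: float, contrast: float, rng: np.random.Generator) -> bool:
        p = psychometric(contrast, self.true_params(frequency))
        return bool(rng.random() < p)


def gen_observer(
    spec: ObserverSpec, frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
) -> tuple[dict[float, float], SimulatedObserver]:
    """True thresholds at the tested frequencies plus the trial simulator."""
    obs = SimulatedObserver(spec)
    return {f: obs.true_threshold(f) for f in frequencies}, obs


# ---------------------------------------------------------------- cohort

@dataclass(frozen=True)
class GroupParams:
    """Per-group biometry distribution (truncated normals at printed ranges)."""

    n: int
    se_mean: float
    se_sd: float
    se_range: tuple[float, float]
    al_mean: float
    al_sd: float
    al_range: tuple[float, float]
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    iop_mean: float
    iop_sd: float
    iop_range: tuple[float, float]
    female_fraction: float


# study-cohort defaults: group sizes 20/26/35 and biometry means +- SD with
# printed ranges for EM, LM/MM, and SHM eyes
DEFAULT_GROUPS: dict[str, GroupParams] = {
    "EM": GroupParams(
        n=20,
        se_mean=-0.15, se_sd=0.35, se_range=(-0.75, 0.75),
        al_mean=23.64, al_sd=0.69, al_range=(22.45, 24.80),
        age_mean=23.35, age_sd=1.66, age_range=(22, 27),
        iop_mean=14.44, iop_sd=3.16, iop_range=(9.70, 20.0),
        female_fraction=11 / 20,
    ),
    "LM/MM": GroupParams(
        n=26,
        se_mean=-3.65, se_sd=1.60, se_range=(-5.99, -0.76),
        al_mean=24.76, al_sd=0.78, al_range=(23.31, 26.49),
        age_mean=23.27, age_sd=1.66, age_range=(22, 29),
        iop_mean=15.70, iop_sd=2.78, iop_range=(10.90, 20.50),
        female_fraction=10 / 26,
    ),
    "SHM": GroupParams(
        n=35,
        se_mean=-8.00, se_sd=1.50, se_range=(-10.50, -4.25),
        al_mean=26.77, al_sd=1.05, al_range=(25.03, 29.23),
        age_mean=23.57, age_sd=2.39, age_range=(19, 30),
        iop_mean=16.14, iop_sd=2.57, iop_range=(12.10, 21.0),
        female_fraction=11 / 35,
    ),
}


@dataclass(frozen=True)
class OutcomeCoupling:
    """Linear-Gaussian outcome: value = intercept_at_24 + slope*(AL-24) + noise."""

    intercept_at_24: float
    slope_per_mm: float
    noise_sd: float
    clip: tuple[float, float] | None = None


# AL-coupled outcome defaults; signs follow clinically reported associations
# (density/regularity/CT/CVI/TCA/AULCSF decrease with AL, spacing increases)
DEFAULT_COUPLINGS: dict[str, OutcomeCoupling] = {
    "cone_density_inner": OutcomeCoupling(20400.0, -1578.0, 2400.0, (8000.0, 30000.0)),
    "cone_density_outer": OutcomeCoupling(20500.0, -1435.0, 2500.0, (8000.0, 30000.0)),
    "cone_spacing_inner": OutcomeCoupling(5.28, 0.093, 0.25, (4.0, 7.5)),
    "cone_spacing_outer": OutcomeCoupling(5.29, 0.090, 0.30, (4.0, 7.5)),
    "cone_regularity": OutcomeCoupling(92.5, -2.2, 4.0, (60.0, 100.0)),
    "ct_um": OutcomeCoupling(280.0, -30.0, 55.0, (60.0, 500.0)),
    "cvi": OutcomeCoupling(0.66, -0.012, 0.03, (0.35, 0.85)),
    "tca_mm2": OutcomeCoupling(0.45, -0.04, 0.08, (0.1, 1.0)),
    "is_um": OutcomeCoupling(28.0, -0.8, 2.0, (18.0, 40.0)),
    "os_um": OutcomeCoupling(32.0, 0.7, 2.5, (20.0, 45.0)),
    "izrpe_um": OutcomeCoupling(55.0, -1.2, 4.0, (35.0, 75.0)),
    "opl_um": OutcomeCoupling(32.0, 0.0, 3.0, (20.0, 45.0)),
    "hflonl_um": OutcomeCoupling(85.0, 0.0, 7.0, (55.0, 115.0)),
    "superficial_vd": OutcomeCoupling(48.0, -0.5, 2.5, (30.0, 60.0)),
    "deep_vd": OutcomeCoupling(50.0, -0.6, 3.0, (30.0, 62.0)),
    "faz_mm2": OutcomeCoupling(0.32, 0.0, 0.08, (0.05, 0.8)),
    "aulcsf": OutcomeCoupling(1.85, -0.066, 0.24, (0.5, 2.6)),
    "cutoff_sf": OutcomeCoupling(1.42, -0.032, 0.12, (0.8, 1.7)),
}


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic study cohort: three groups with AL-coupled outcomes."""

    groups: dict[str, GroupParams] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    couplings: dict[str, OutcomeCoupling] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS)
    )
    seed: int = 0


def _classify(se: float, al: float) -> str:
    """Refractive-group rule: SHM iff SE <= -6.00 D or AL >= 26.5 mm."""
    if se <= -6.0 or al >= 26.5:
        return "SHM"
    if -1.0 < se < 1.0:
        return "EM"
    return "LM/MM"


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=size), out)
        bad = (out < lo) | (out > hi)
    return out


def gen_cohort(spec: CohortSpec = CohortSpec(), seed: int | None = None) -> pd.DataFrame:
    """Draw the per-eye table; group labels re-derived from the SE/AL rule.

    Biometry draws whose re-derived group disagrees with the intended group
    are resampled, so the emitted table respects the grouping rule exactly.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    idx = 0
    for gname, gp in spec.groups.items():
        for _ in range(gp.n):
            for _ in range(10000):
                se = float(_truncnorm(rng, gp.se_mean, gp.se_sd, *gp.se_range))
                al = float(_truncnorm(rng, gp.al_mean, gp.al_sd, *gp.al_range))
                if _classify(se, al) == gname:
                    break
            else:  # pragma: no cover - ranges guarantee convergence
                raise RuntimeError(f"could not sample biometry for group {gname}")
            idx += 1
            row = {
                "id": f"S{idx:03d}",
                "group": gname,
                "sex": "F" if rng.random() < gp.female_fraction else "M",
                "age": float(np.round(_truncnorm(rng, gp.age_mean, gp.age_sd, *gp.age_range))),
                "se_d": round(se, 2),
                "al_mm": round(al, 2),
                "iop": round(float(_truncnorm(rng, gp.iop_mean, gp.iop_sd, *gp.iop_range)), 1),
            }
            for name, cpl in spec.couplings.items():
                val = cpl.intercept_at_24 + cpl.slope_per_mm * (row["al_mm"] - 24.0)
                val += rng.normal(0.0, cpl.noise_sd)
                if cpl.clip is not None:
                    val = float(np.clip(val, *cpl.clip))
                row[name] = val
            rows.append(row)
    df = pd.DataFrame(rows)
    if "cvi" in df.columns and "tca_mm2" in df.columns:
        df["la_mm2"] = df["cvi"] * df["tca_mm2"]
        df["sa_mm2"] = df["tca_mm2"] - df["la_mm2"]
    return df
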
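"""Synthetic data generators for every pipeline stage.

Each generator emulates the statistical structure of one experimental data
stream from an aging *C. elegans* ferroptosis study:

* :func:`gen_lifespan` — replicated lifespan cohorts from a Weibull baseline
  hazard with per-animal Gamma frailty, with optional pure temporal scaling
  between treatment arms.
* :func:`gen_xanes_stack` — fluorescence-detected XANES image stacks over the
  Fe K-edge as noisy mixtures of Fe2+/Fe3+ endmember spectra, with a calcium
  channel and optional per-frame positional jitter.
* :func:`gen_xfm_scene` — X-ray fluorescence microscopy scenes with
  worm-shaped foregrounds distinguishable in Compton scatter.
* :func:`gen_dose_response` — Bernoulli lethality outcomes under a Hill
  dose-response with age-dependent LD50.

All randomness flows from an explicit integer seed in each config
(``numpy.random.default_rng``); there is no hidden global state, so a rerun
with the same config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .xanes import EnergyGrid, SpectrumStack, paper_energy_grid
from .xfm import ElementalScene

__all__ = [
    "ArmSpec",
    "LifespanSimConfig",
    "EndmemberSpec",
    "XanesSimConfig",
    "WormSpec",
    "XfmSimConfig",
    "DoseSimConfig",
    "gen_lifespan",
    "gen_xanes_stack",
    "gen_xfm_scene",
    "gen_dose_response",
    "default_lifespan_config",
    "default_endmembers",
]

COHORT_COLUMNS = ["animal_id", "replicate", "arm", "day", "event", "temperature_C"]


# ---------------------------------------------------------------------------
# Lifespan cohorts
# ---------------------------------------------------------------------------

@dataclass
class ArmSpec:
    """One treatment arm of a lifespan experiment.

    The arm's effective parameters are ``k_eff = k * exp(dlog_k)``,
    ``b_eff = b * lam`` (days) and ``sigma2_eff = sigma2 * exp(dlog_sigma2)``.
    ``lam`` is the temporal-scaling factor: a pure-scaling intervention
    changes only ``lam``.
    """

    name: str
    k: float = 4.0            # Weibull shape
    b: float = 7.4            # Weibull scale, days of adulthood
    sigma2: float = 0.4       # Gamma frailty variance (mean fixed at 1)
    lam: float = 1.0          # temporal scaling multiplier on the time axis
    dlog_k: float = 0.0       # shape departure, log scale
    dlog_sigma2: float = 0.0  # frailty departure, log scale

    def __post_init__(self) -> None:
        for fname in ("k", "b", "lam"):
            if getattr(self, fname) <= 0:
                raise ValueError(f"arm {self.name!r}: {fname} must be > 0")
        if self.sigma2 < 0:
            raise ValueError(f"arm {self.name!r}: sigma2 must be >= 0")

    @property
    def k_eff(self) -> float:
        return self.k * np.exp(self.dlog_k)

    @property
    def sigma2_eff(self) -> float:
        return self.sigma2 * np.exp(self.dlog_sigma2)


@dataclass
class LifespanSimConfig:
    arms: Sequence[ArmSpec]
    n_per_arm: int = 90
    n_replicates: int = 1
    replicate_jitter_sd: float = 0.0  # SD of per-replicate log-scale offsets
    censor_day: float | None = None
    discretize: bool = False          # round deaths up to whole scoring days
    temperature_C: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.arms:
            raise ValueError("at least one arm required")


def default_lifespan_config(seed: int = 0, **overrides) -> LifespanSimConfig:
    """Study-condition defaults: control / Lip-1 / SIH arms at 25 degC.

    The control arm is calibrated so the marginal model median is 7 days;
    Lip-1 and SIH scale time by 13/7 and 2 with negative frailty deltas,
    giving model medians of about 13 and 14 days.
    """
    arms = [
        ArmSpec("control"),
        ArmSpec("lip1", lam=13.0 / 7.0, dlog_k=0.3, dlog_sigma2=-1.0),
        ArmSpec("sih", lam=2.0, dlog_k=0.4, dlog_sigma2=-1.0),
    ]
    kwargs = dict(arms=arms, n_per_arm=90, n_replicates=8,
                  replicate_jitter_sd=0.05, seed=seed)
    kwargs.update(overrides)
    return LifespanSimConfig(**kwargs)


def gen_lifespan(config: LifespanSimConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a lifespan cohort under the Weibull–Gamma-frailty model.

    Per animal: frailty ``z ~ Gamma(mean 1, var sigma2_eff)`` multiplies the
    Weibull hazard ``(k/b')(t/b')^(k-1)`` with ``b' = b * lam * exp(replicate
    offset)``.  Inverting the conditional survival gives
    ``T = b' * (E / z)^(1/k)`` with ``E ~ Exp(1)``.

    Returns the event table (columns ``animal_id, replicate, arm, day, event,
    temperature_C``) and a truth record with all parameters and a
    ``pure_scaling`` flag (true iff arms differ only in ``lam``).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    rep_offsets = rng.normal(0.0, config.replicate_jitter_sd,
                             size=config.n_replicates)
    animal = 0
    for rep in range(config.n_replicates):
        for arm in config.arms:
            k = arm.k_eff
            s2 = arm.sigma2_eff
            bprime = arm.b * arm.lam * np.exp(rep_offsets[rep])
            n = config.n_per_arm
            if s2 > 0:
                z = rng.gamma(shape=1.0 / s2, scale=s2, size=n)
            else:
                z = np.ones(n)
            e = rng.exponential(size=n)
            t = bprime * (e / z) ** (1.0 / k)
            if config.discretize:
                t = np.ceil(t)
                t = np.maximum(t, 1.0)
            event = np.ones(n, dtype=int)
            if config.censor_day is not None:
                censored = t > config.censor_day
                t = np.where(censored, config.censor_day, t)
                event = np.where(censored, 0, 1)
            for ti, ev in zip(t, event):
                rows.append((animal, rep, arm.name, float(ti), int(ev),
                             config.temperature_C))
                animal += 1
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)

    k_effs = [a.k_eff for a in config.arms]
    s2_effs = [a.sigma2_eff for a in config.arms]
    bs = [a.b for a in config.arms]
    pure_scaling = (
        np.allclose(k_effs, k_effs[0])
        and np.allclose(s2_effs, s2_effs[0])
        and np.allclose(bs, bs[0])
    )
    truth = {
        "arms": [asdict(a) for a in config.arms],
        "replicate_offsets": rep_offsets.tolist(),
        "pure_scaling": bool(pure_scaling),
        "n_per_arm": config.n_per_arm,
        "n_replicates": config.n_replicates,
        "censor_day": config.censor_day,
        "discretize": config.discretize,
        "seed": config.seed,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# XANES stacks
# ---------------------------------------------------------------------------

@dataclass
class EndmemberSpec:
    """Parametric Fe K-edge endmember: arctangent edge step plus one
    pre-edge Gaussian (the 1s->3d feature)."""

    preedge_center: float   # eV
    preedge_amplitude: float
    preedge_width: float    # Gaussian sigma, eV
    edge_position: float    # arctan center, eV
    edge_width: float       # arctan scale, eV

    def mu(self, energies: np.ndarray) -> np.ndarray:
        e = np.asarray(energies, dtype=float)
        step = 0.5 + np.arctan((e - self.edge_position) / self.edge_width) / np.pi
        peak = self.preedge_amplitude * np.exp(
            -0.5 * ((e - self.preedge_center) / self.preedge_width) ** 2)
        return step + peak


def default_endmembers() -> tuple[EndmemberSpec, EndmemberSpec]:
    """Default Fe2+ / Fe3+ endmembers.

    Pre-edge centers 7112.1 eV (Fe2+) and 7113.5 eV (Fe3+); the oxidized
    species has its main edge shifted up a few eV, as in the pre-edge
    literature for ferrous vs ferric coordination environments.
    """
    fe2 = EndmemberSpec(preedge_center=7112.1, preedge_amplitude=0.12,
                        preedge_width=0.9, edge_position=7120.0, edge_width=2.0)
    fe3 = EndmemberSpec(preedge_center=7113.5, preedge_amplitude=0.12,
                        preedge_width=0.9, edge_position=7124.0, edge_width=2.0)
    return fe2, fe3


@dataclass
class XanesSimConfig:
    fe2_fraction_map: np.ndarray          # 2D, values in [0, 1]
    iron_density_map: np.ndarray          # 2D, >= 0
    ca_density_map: np.ndarray            # 2D, >= 0
    grid: EnergyGrid = field(default_factory=paper_energy_grid)
    endmembers: tuple[EndmemberSpec, EndmemberSpec] = field(
        default_factory=default_endmembers)
    counts_scale: float = 1e4             # expected photons per unit density
    frame_jitter_px: int = 0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fe2_fraction_map, dtype=float)
        if f.min() < 0 or f.max() > 1:
            raise ValueError("fe2_fraction_map values must lie in [0, 1]")
        if np.asarray(self.iron_density_map).min() < 0:
            raise ValueError("iron_density_map must be >= 0")
        fe2, fe3 = self.endmembers
        if fe2.preedge_center == fe3.preedge_center:
            raise ValueError("endmember pre-edge centers must be distinct")
        if f.shape != np.asarray(self.iron_density_map).shape:
            raise ValueError("fraction and density maps must share shape")


def gen_xanes_stack(config: XanesSimConfig) -> tuple[SpectrumStack, dict]:
    """Render a phi-XANES stack: one Fe-fluorescence frame per incident energy.

    Per-pixel expected spectrum is
    ``iron_density * [f * mu_Fe2(E) + (1 - f) * mu_Fe3(E)] * counts_scale``
    with Poisson counts.  Each energy frame (Fe and Ca together, so alignment
    is recoverable from Ca) may be translated by an integer jitter drawn
    uniformly from ``[-frame_jitter_px, frame_jitter_px]``.
    """
    rng = np.random.default_rng(config.seed)
    energies = config.grid.energies
    f = np.asarray(config.fe2_fraction_map, dtype=float)
    rho = np.asarray(config.iron_density_map, dtype=float)
    ca = np.asarray(config.ca_density_map, dtype=float)
    ny, nx = rho.shape
    jmax = int(config.frame_jitter_px)
    if jmax > 0:
        margin = min(ny, nx) // 4
        if jmax > margin:
            raise ValueError(
                f"frame_jitter_px={jmax} exceeds scene margin {margin}")

    fe2, fe3 = config.endmembers
    mu2 = fe2.mu(energies)
    mu3 = fe3.mu(energies)

    n_e = len(energies)
    frames = np.empty((n_e, ny, nx))
    ca_frames = np.empty((n_e, ny, nx))
    shifts = np.zeros((n_e, 2), dtype=int)
    ca_expected = ca * config.counts_scale
    for i in range(n_e):
        expected = rho * (f * mu2[i] + (1 - f) * mu3[i]) * config.counts_scale
        if jmax > 0 and i > 0:
            dy, dx = rng.integers(-jmax, jmax + 1, size=2)
        else:
            dy, dx = 0, 0
        shifts[i] = (dy, dx)
        exp_sh = np.roll(np.roll(expected, dy, axis=0), dx, axis=1)
        ca_sh = np.roll(np.roll(ca_expected, dy, axis=0), dx, axis=1)
        if config.poisson_noise:
            frames[i] = rng.poisson(exp_sh)
            ca_frames[i] = rng.poisson(ca_sh)
        else:
            frames[i] = exp_sh
            ca_frames[i] = ca_sh

    stack = SpectrumStack(frames=frames, grid=config.grid, ca_frames=ca_frames)
    truth = {
        "shifts": shifts.tolist(),
        "fe2_fraction_map": f.tolist(),
        "counts_scale": config.counts_scale,
        "endmembers": [asdict(fe2), asdict(fe3)],
        "seed": config.seed,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# XFM scenes
# ---------------------------------------------------------------------------

@dataclass
class WormSpec:
    centroid: tuple[float, float]       # (row, col) pixels
    axes: tuple[float, float]           # ellipse semi-axes, pixels
    orientation: float = 0.0            # radians
    fe_density: float = 0.02            # pg / um^2
    ca_density: float = 0.05            # pg / um^2


@dataclass
class XfmSimConfig:
    scene_shape: tuple[int, int]
    worm_specs: Sequence[WormSpec]
    background_rate: float = 2.0        # mean background counts / pixel
    compton_contrast: float = 20.0      # foreground / background scatter ratio
    pixel_area: float = 0.64            # um^2 per virtual pixel
    counts_per_density: float = 500.0   # Fe counts per (pg/um^2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.compton_contrast <= 1:
            raise ValueError("compton_contrast must be > 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        for w in self.worm_specs:
            if w.fe_density < 0 or w.ca_density < 0:
                raise ValueError("worm densities must be >= 0")


def _ellipse_mask(shape, spec: WormSpec) -> np.ndarray:
    from skimage.draw import ellipse
    rr, cc = ellipse(spec.centroid[0], spec.centroid[1],
                     spec.axes[0], spec.axes[1], shape=None,
                     rotation=spec.orientation)
    ny, nx = shape
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= ny or cc.max() >= nx:
        raise ValueError("worm footprint extends outside the scene")
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def gen_xfm_scene(config: XfmSimConfig) -> tuple[ElementalScene, dict]:
    """Render an XFM scene (Fe, Ca, Compton channels) with planted worms.

    Worms are ellipses of uniform areal density; channels are Poisson counts.
    The Compton foreground rate is ``compton_contrast * max(background_rate,
    1)`` so foreground stays separable even on zero background.  Truth lists
    per-worm pixel sets, densities and total masses
    (``density * n_pixels * pixel_area``).
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.scene_shape)
    masks = [_ellipse_mask(shape, w) for w in config.worm_specs]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError(
                    f"worm footprints {i} and {j} overlap; per-worm truth "
                    "would be ambiguous")

    fe_expected = np.zeros(shape)
    ca_expected = np.zeros(shape)
    fg = np.zeros(shape, dtype=bool)
    for mask, w in zip(masks, config.worm_specs):
        fe_expected[mask] = w.fe_density * config.counts_per_density
        ca_expected[mask] = w.ca_density * config.counts_per_density
        fg |= mask

    compton_fg_rate = config.compton_contrast * max(config.background_rate, 1.0)
    compton_expected = np.where(fg, compton_fg_rate, config.background_rate)
    fe_expected = fe_expected + np.where(fg, 0.0, config.background_rate)
    ca_expected = ca_expected + np.where(fg, 0.0, config.background_rate)

    fe = rng.poisson(fe_expected).astype(float)
    ca = rng.poisson(ca_expected).astype(float)
    compton = rng.poisson(compton_expected).astype(float)

    scene = ElementalScene(
        channels={"Fe": fe, "Ca": ca, "Compton": compton},
        pixel_area=config.pixel_area, units_state="raw_counts")
    truth = {
        "worms": [
            {
                "pixels": int(m.sum()),
                "fe_density": w.fe_density,
                "ca_density": w.ca_density,
                "fe_total_pg": w.fe_density * int(m.sum()) * config.pixel_area,
                "expected_fe_counts": float(
                    w.fe_density * config.counts_per_density * m.sum()),
            }
            for m, w in zip(masks, config.worm_specs)
        ],
        "masks": [np.flatnonzero(m.ravel()).tolist() for m in masks],
        "counts_per_density": config.counts_per_density,
        "background_rate": config.background_rate,
        "pixel_area": config.pixel_area,
        "seed": config.seed,
    }
    return scene, truth


# ---------------------------------------------------------------------------
# Dose-response tables
# ---------------------------------------------------------------------------

@dataclass
class DoseSimConfig:
    doses: Sequence[float] = (0.0, 1.0, 2.5, 5.0, 10.0, 20.0, 40.0)  # mM
    n_per_dose: int = 100
    ld50: float = 10.0          # mM at the reference age
    hill_slope: float = 3.0
    age_sensitivity: float = 0.0  # per-day shift of log-LD50
    age: float = 4.0              # days of adulthood
    reference_age: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")
        if self.n_per_dose < 1:
            raise ValueError("n_per_dose must be >= 1")
        if self.ld50 <= 0:
            raise ValueError("ld50 must be > 0")


def hill_death_probability(dose, ld50: float, hill_slope: float):
    """P(death | dose) = d^h / (d^h + LD50^h); 0 at dose 0."""
    d = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        p = np.where(d > 0, d ** hill_slope / (d ** hill_slope + ld50 ** hill_slope), 0.0)
    return p


def gen_dose_response(config: DoseSimConfig) -> pd.DataFrame:
    """Per-animal Bernoulli death outcomes under a Hill lethality curve.

    The effective LD50 shifts with age as
    ``LD50(age) = ld50 * exp(age_sensitivity * (age - reference_age))``, so a
    negative ``age_sensitivity`` makes older animals more sensitive.
    """
    rng = np.random.default_rng(config.seed)
    ld50_eff = config.ld50 * np.exp(
        config.age_sensitivity * (config.age - config.reference_age))
    rows = []
    for dose in config.doses:
        p = float(hill_death_probability(dose, ld50_eff, config.hill_slope))
        deaths = rng.random(config.n_per_dose) < p
        for dth in deaths:
            rows.append((float(dose), config.age, int(dth)))
    return pd.DataFrame(rows, columns=["dose_mM", "age_days", "death"])
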
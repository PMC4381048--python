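"""Synthetic scaffold-independent-analysis experiments with known ground truth.

The generator emulates the measurement design the analysis expects: for each
scanned RNA position, one free-protein ¹H{¹⁵N} correlation spectrum plus four
spectra of the protein in complex with the A/C/G/U pools. Binding is modelled
as a single effective 1:1 equilibrium per pool (one Kd standing in for the
pool's quasi-degenerate mixture average) in the fast-exchange regime, so each
responsive amide peak moves by ``fraction_bound × Δδ_max`` from its free
position. Adding an RNA pool dilutes the protein, so every bound plane is
scaled by a dilution factor; i.i.d. Gaussian noise is added to every plane.

Saturated-complex shifts (Δδ_max) are drawn once per peak and shared across
the four pools of every position: the pools then differ only in their bound
fraction, which is exactly the premise that lets shift magnitude report
average affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError, PlacementError
from .spectra import (
    BASES,
    AxisCalibration,
    EnsembleStack,
    PeakEntry,
    PeakList,
    PoolLabel,
    Spectrum2D,
    stack_ensemble,
)

__all__ = [
    "BindingModel",
    "SimulationConfig",
    "SimulationResult",
    "fraction_bound",
    "simulate_bound_peaklist",
    "render_spectrum",
    "simulate_sia_experiment",
    "default_config",
    "default_model",
]

#: Kd ladder (µM) assigned to a position's bases from most to least preferred.
DEFAULT_KD_LADDER = (2.0, 10.0, 50.0, 250.0)

#: Default per-position preference orders (most preferred base first).
DEFAULT_PROFILE: Dict[int, Tuple[str, str, str, str]] = {
    1: ("G", "U", "C", "A"),
    2: ("U", "G", "A", "C"),
    3: ("A", "C", "G", "U"),
    4: ("C", "A", "U", "G"),
    5: ("G", "A", "U", "C"),
}


def fraction_bound(protein_total: float, rna_total: float, kd: float) -> float:
    """Bound protein fraction for a 1:1 equilibrium at total concentrations.

    Solves ``P·f² − (P + R + K)·f + R = 0`` for the physical root

    .. math:: f = \\frac{(P + R + K) - \\sqrt{(P + R + K)^2 - 4 P R}}{2 P}

    with all quantities in consistent concentration units (µM here).
    Monotone increasing in ``rna_total`` and decreasing in ``kd``.
    """
    if protein_total <= 0:
        raise ValueError(f"protein_total must be > 0, got {protein_total}")
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if rna_total < 0:
        raise ValueError(f"rna_total must be >= 0, got {rna_total}")
    if rna_total == 0:
        return 0.0
    s = protein_total + rna_total + kd
    disc = s * s - 4.0 * protein_total * rna_total
    f = (s - math.sqrt(max(disc, 0.0))) / (2.0 * protein_total)
    return min(max(f, 0.0), 1.0)


@dataclass
class BindingModel:
    """Equilibrium parameters of one simulated experiment.

    ``kd_by_pool`` maps ``(position, base)`` to the pool's effective
    dissociation constant (µM). ``dmax_by_peak`` maps assignment ids of
    interface-responsive peaks to their saturated-complex shifts
    ``(Δδ_max_h, Δδ_max_n)`` in ppm, shared across all pools.
    """

    protein_conc: float
    rna_ratio: float
    kd_by_pool: Dict[Tuple[int, str], float]
    dmax_by_peak: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        if self.protein_conc <= 0:
            raise ConfigurationError("protein_conc must be > 0")
        if self.rna_ratio < 0:
            raise ConfigurationError("rna_ratio must be >= 0")
        for key, kd in self.kd_by_pool.items():
            if kd <= 0:
                raise ConfigurationError(f"Kd for pool {key} must be > 0, got {kd}")

    @property
    def rna_conc(self) -> float:
        return self.protein_conc * self.rna_ratio

    def fraction_bound(self, pool: PoolLabel) -> float:
        key = (pool.position, pool.base)
        if key not in self.kd_by_pool:
            raise ConfigurationError(f"no Kd configured for pool {key}")
        return fraction_bound(self.protein_conc, self.rna_conc, self.kd_by_pool[key])


def _default_grid_h() -> AxisCalibration:
    return AxisCalibration(n_points=290, spectral_width=5.0, ppm_first=11.0, obs_mhz=700.13)


def _default_grid_n() -> AxisCalibration:
    return AxisCalibration(n_points=256, spectral_width=30.0, ppm_first=135.0, obs_mhz=70.95)


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic experiment.

    Defaults reproduce the study conditions: a 290 × 256 frequency-domain
    grid, 100 amide peaks of which 30% respond to binding, per-peak
    saturated shifts drawn once with sd 0.05 ppm (¹H) / 0.25 ppm (¹⁵N),
    pool Kds {2, 10, 50, 250} µM at 25 µM protein with a 1:1 RNA ratio,
    a 0.9 dilution of every bound sample, and additive Gaussian noise of
    0.5% of the maximum free-spectrum intensity. Each bound sample is an
    independently prepared tube, so its overall intensity additionally
    carries a 2% relative error (``scale_jitter_sd``) on top of the
    nominal dilution — without it the first (intensity) principal
    component would be an artificially clean function of binding.
    """

    axis_h: AxisCalibration = field(default_factory=_default_grid_h)
    axis_n: AxisCalibration = field(default_factory=_default_grid_n)
    n_peaks: int = 100
    responsive_fraction: float = 0.3
    linewidth_h: float = 0.02  # Lorentzian HWHM, ppm
    linewidth_n: float = 0.15
    dmax_sd_h: float = 0.05  # sd of saturated-shift draws, ppm
    dmax_sd_n: float = 0.25
    dilution_factor: float = 0.9
    noise_sd: float = 0.005  # fraction of max noiseless free intensity
    scale_jitter_sd: float = 0.02  # relative per-sample intensity error
    seed: int = 42
    protein_conc: float = 25.0  # µM
    rna_ratio: float = 1.0
    kd_ladder: Tuple[float, ...] = DEFAULT_KD_LADDER
    profile: Dict[int, Tuple[str, str, str, str]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE)
    )
    rna_length: int = 5

    def __post_init__(self) -> None:
        if self.linewidth_h <= 0 or self.linewidth_n <= 0:
            raise ConfigurationError("linewidths must be > 0")
        if self.noise_sd < 0 or self.scale_jitter_sd < 0:
            raise ConfigurationError("noise_sd and scale_jitter_sd must be >= 0")
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ConfigurationError("responsive_fraction must lie in [0, 1]")
        if not 0.0 <= self.dilution_factor <= 1.0:
            raise ConfigurationError("dilution_factor must lie in [0, 1]")
        for pos, order in self.profile.items():
            if sorted(order) != sorted(BASES):
                raise ConfigurationError(
                    f"profile for position {pos} must permute {BASES}, got {order}"
                )
            if len(self.kd_ladder) != 4 or any(k <= 0 for k in self.kd_ladder):
                raise ConfigurationError("kd_ladder must hold four positive Kds")

    @property
    def grid(self) -> Tuple[int, int]:
        return (self.axis_h.n_points, self.axis_n.n_points)

    @property
    def positions(self) -> List[int]:
        return sorted(self.profile)

    def kd_by_pool(self) -> Dict[Tuple[int, str], float]:
        table: Dict[Tuple[int, str], float] = {}
        for pos, order in self.profile.items():
            for rank, base in enumerate(order):
                table[(pos, base)] = float(self.kd_ladder[rank])
        return table


def _plane_seed(seed: int, position: int, plane_index: int) -> np.random.SeedSequence:
    """Deterministic per-plane seed stream derived from the master seed."""
    return np.random.SeedSequence(entropy=(int(seed), int(position), int(plane_index)))


def _draw_free_peaks(config: SimulationConfig, rng: np.random.Generator) -> PeakList:
    # keep a margin so peaks stay on-grid after even extreme (~4 sd) shifts
    margin_h = 5 * config.dmax_sd_h + 2 * config.linewidth_h
    margin_n = 5 * config.dmax_sd_n + 2 * config.linewidth_n
    h_lo, h_hi = config.axis_h.ppm_last + margin_h, config.axis_h.ppm_first - margin_h
    n_lo, n_hi = config.axis_n.ppm_last + margin_n, config.axis_n.ppm_first - margin_n
    if h_lo >= h_hi or n_lo >= n_hi:
        raise ConfigurationError("grid too narrow for the configured shift range")
    entries = [
        PeakEntry(
            assignment_id=f"res{i + 1}",
            delta_h=float(rng.uniform(h_lo, h_hi)),
            delta_n=float(rng.uniform(n_lo, n_hi)),
            intensity=float(rng.uniform(0.5, 1.0)),
        )
        for i in range(config.n_peaks)
    ]
    return PeakList(entries=entries)


def default_model(config: SimulationConfig) -> Tuple[BindingModel, PeakList]:
    """Draw the free peak list and the binding model implied by ``config``.

    The first ``round(n_peaks × responsive_fraction)`` peaks are flagged
    responsive and receive signed Δδ_max draws; draws are deterministic in
    ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(config.seed), 0)))
    free_peaks = _draw_free_peaks(config, rng)
    n_responsive = int(round(config.n_peaks * config.responsive_fraction))
    dmax: Dict[str, Tuple[float, float]] = {}
    for entry in free_peaks.entries[:n_responsive]:
        dmax[entry.assignment_id] = (
            float(rng.normal(0.0, config.dmax_sd_h)),
            float(rng.normal(0.0, config.dmax_sd_n)),
        )
    model = BindingModel(
        protein_conc=config.protein_conc,
        rna_ratio=config.rna_ratio,
        kd_by_pool=config.kd_by_pool(),
        dmax_by_peak=dmax,
    )
    return model, free_peaks


def default_config(**overrides) -> SimulationConfig:
    """The study-condition configuration, with keyword overrides."""
    return SimulationConfig(**overrides)


def simulate_bound_peaklist(
    free_peaks: PeakList, model: BindingModel, pool: PoolLabel
) -> PeakList:
    """Peak positions of the protein–pool complex under fast exchange.

    Every peak listed in ``model.dmax_by_peak`` moves by
    ``f_bound × Δδ_max`` in both dimensions (the population-weighted
    average of free and saturated positions); all other peaks and all
    intensities are unchanged.
    """
    f = model.fraction_bound(pool)
    entries = []
    for e in free_peaks:
        dmax = model.dmax_by_peak.get(e.assignment_id)
        if dmax is None:
            entries.append(e)
        else:
            entries.append(
                PeakEntry(
                    assignment_id=e.assignment_id,
                    delta_h=e.delta_h + f * dmax[0],
                    delta_n=e.delta_n + f * dmax[1],
                    intensity=e.intensity,
                )
            )
    return PeakList(entries=entries)


def render_spectrum(
    peaks: PeakList,
    config: SimulationConfig,
    intensity_scale: float = 1.0,
    seed: Optional[object] = None,  # int or np.random.SeedSequence
    noise_reference: Optional[float] = None,
    label: str = "",
) -> Spectrum2D:
    """Render a peak list onto the configured grid.

    Each peak contributes a separable 2D Lorentzian (product of 1D
    Lorentzians with the configured HWHMs, unit height at the peak centre,
    scaled by the peak intensity). The whole noiseless plane is multiplied
    by ``intensity_scale``, then i.i.d. Gaussian noise with
    sd = ``config.noise_sd × noise_reference`` is added. ``noise_reference``
    defaults to the plane's own noiseless maximum; the experiment driver
    passes the free plane's maximum so the absolute noise floor is shared
    across all planes of an ensemble.
    """
    ax_h, ax_n = config.axis_h, config.axis_n
    ppm_h = ax_h.ppm_scale()
    ppm_n = ax_n.ppm_scale()
    plane = np.zeros((ax_h.n_points, ax_n.n_points))
    for e in peaks:
        if not (ax_h.contains(e.delta_h) and ax_n.contains(e.delta_n)):
            raise PlacementError(
                f"peak {e.assignment_id!r} at ({e.delta_h:.3f}, {e.delta_n:.3f}) ppm "
                "lies outside the grid"
            )
        lh = 1.0 / (1.0 + ((ppm_h - e.delta_h) / config.linewidth_h) ** 2)
        ln = 1.0 / (1.0 + ((ppm_n - e.delta_n) / config.linewidth_n) ** 2)
        plane += e.intensity * np.outer(lh, ln)
    plane *= intensity_scale
    if config.noise_sd > 0:
        ref = noise_reference if noise_reference is not None else float(np.max(np.abs(plane)))
        rng = np.random.default_rng(seed)
        plane = plane + rng.normal(0.0, config.noise_sd * ref, size=plane.shape)
    return Spectrum2D(intensities=plane, axis_h=ax_h, axis_n=ax_n, label=label)


@dataclass
class SimulationResult:
    """A full synthetic experiment plus its ground truth."""

    config: SimulationConfig
    model: BindingModel
    stacks: Dict[int, EnsembleStack]
    free_peaks: PeakList
    bound_peaks: Dict[int, Dict[str, PeakList]]  # position -> base -> list
    f_bound: Dict[Tuple[int, str], float]  # ground-truth bound fractions

    def true_ranking(self, position: int) -> List[str]:
        """Bases ordered by decreasing ground-truth bound fraction."""
        return sorted(BASES, key=lambda b: (-self.f_bound[(position, b)], b))


def simulate_sia_experiment(
    config: SimulationConfig, model: Optional[BindingModel] = None
) -> SimulationResult:
    """Simulate the full multi-position experiment.

    Per position: one free plane at full intensity and four pool-bound
    planes at ``dilution_factor`` intensity, each with independent noise
    seeded deterministically from ``(config.seed, position, plane_index)``
    with plane order [free, A, C, G, U]. The noise floor of every plane is
    set by the free plane's noiseless maximum. Ground truth (bound
    fractions and bound peak lists) is returned alongside the spectra.
    """
    if model is None:
        model, free_peaks = default_model(config)
    else:
        _, free_peaks = default_model(config)
        for key in config.kd_by_pool():
            if key not in model.kd_by_pool:
                raise ConfigurationError(f"model lacks a Kd for pool {key}")
    for pid in model.dmax_by_peak:
        if pid not in set(free_peaks.ids()):
            raise ConfigurationError(f"Δδ_max given for unknown peak {pid!r}")

    # shared noise floor: the free plane's noiseless maximum
    noiseless_free = render_spectrum(
        free_peaks, replace(config, noise_sd=0.0), intensity_scale=1.0
    )
    noise_ref = float(np.max(noiseless_free.intensities))

    stacks: Dict[int, EnsembleStack] = {}
    bound_lists: Dict[int, Dict[str, PeakList]] = {}
    f_bound: Dict[Tuple[int, str], float] = {}
    for position in config.positions:
        free_plane = render_spectrum(
            free_peaks,
            config,
            intensity_scale=1.0,
            seed=_plane_seed(config.seed, position, 0),
            noise_reference=noise_ref,
            label="free",
        )
        bound_planes: Dict[int, Spectrum2D] = {}
        bound_lists[position] = {}
        for plane_index, base in enumerate(BASES, start=1):
            pool = PoolLabel(position=position, base=base, length=config.rna_length)
            peaks = simulate_bound_peaklist(free_peaks, model, pool)
            bound_lists[position][base] = peaks
            f_bound[(position, base)] = model.fraction_bound(pool)
            scale = config.dilution_factor
            if config.scale_jitter_sd > 0:
                jitter_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=(int(config.seed), int(position), int(plane_index), 1)
                    )
                )
                scale *= 1.0 + jitter_rng.normal(0.0, config.scale_jitter_sd)
            bound_planes[base] = render_spectrum(
                peaks,
                config,
                intensity_scale=scale,
                seed=_plane_seed(config.seed, position, plane_index),
                noise_reference=noise_ref,
                label=pool.name,
            )
        stacks[position] = stack_ensemble(free_plane, bound_planes, position)
    return SimulationResult(
        config=config,
        model=model,
        stacks=stacks,
        free_peaks=free_peaks,
        bound_peaks=bound_lists,
        f_bound=f_bound,
    )
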
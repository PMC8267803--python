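"""Synthetic ground truth: trabecular phantoms and load-adaptive remodelling.

The phantom generator produces a connected trabecular structure (smoothed
Gaussian random field thresholded to a target bone volume fraction,
BV/TV ~ 0.12 by default) with a plausible mineral-density range, standing
in for baseline HR-pQCT geometries that cannot be redistributed.

The remodelling simulator adapts a geometry toward an applied load by
advecting the bone surface with an SED-dependent speed: cell sensing is
mimicked by dilating the SED field (50 um radius), the surface then moves
along its normal at v = gain * (SED - set point), zero inside a narrow
lazy zone around the homeostatic set point (0.02 MPa +- 2%) and clamped to
+- 12 um/month.  The greyscale density field itself is the implicit
surface representation: the binarisation threshold crossing is the
interface and a first-order upwind (Godunov) level-set update moves it.
Formation raises densities toward full mineralisation, resorption erodes
them; a density regularisation pass before each FE solve sets interior
bone to full density while preserving the greyscale of the surface, so
the FE moduli follow the (sub-voxel) interface position.

Applied loads use the package's time-sharing convention: a scenario with
composition c and magnitude m produces s_i = c_i * m^2 / 6 and a
compounded field sum_i s_i U_i,unit, i.e. the magnitude alpha_i recovered
by the estimators for a pure scenario equals m * sqrt(c_i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .images import (
    BinaryMask,
    DensityImage,
    RemodelingRates,
    binarise,
    extract_surface,
    intensity_correlation,
    overlay_remodeling,
    remodeling_rates,
)
from .microfe import build_mesh, scenario_load, solve_unit_loads, superpose

__all__ = [
    "AdvectionConfig",
    "SimulationSeries",
    "ConfigurationError",
    "BracketingError",
    "generate_phantom",
    "regularise_density",
    "advection_step",
    "run_simulation",
    "homeostatic_magnitude",
    "subsample_series",
    "trabecular_region",
]

#: Default binarisation threshold (mg HA/cm^3) and fully mineralised
#: tissue density for the synthetic (radius-like) phantoms.
DEFAULT_THRESHOLD = 320.0
FULL_DENSITY = 720.0


class ConfigurationError(ValueError):
    """Simulator configuration violates a stability constraint."""


class BracketingError(RuntimeError):
    """The magnitude bracket does not contain a homeostatic point."""


@dataclass(frozen=True)
class AdvectionConfig:
    """Parameters of the advection remodelling model.

    set_point : MPa, homeostatic tissue load (0.02).
    lazy_half_width : half-width of the lazy zone as a fraction of the set
        point (0.02, i.e. a 4%-wide zone where nothing moves).
    velocity_gain : um/year/MPa, slope of speed vs SED deviation (8,000).
    velocity_cap : um/month, speed clamp (12).
    dilation_radius : um, spherical maximum-filter radius mimicking the
        sensing reach of osteocytes (50); at least one voxel.
    step_months : months per remodelling step (1).
    steps : number of remodelling steps (40); the first eight are the
        initialisation transient and excluded from analysis windows.
    tissue_modulus : MPa, modulus of fully mineralised tissue (6,800).
    density_slope : MPa per mg/cm^3, linear density-to-modulus mapping;
        defaults to tissue_modulus / FULL_DENSITY so full density maps to
        the tissue modulus.
    threshold : mg/cm^3, bone binarisation threshold.
    frozen_end_layers : axial voxel layers at each end where the surface
        is pinned (the solid end plates of the phantom).
    """

    set_point: float = 0.02
    lazy_half_width: float = 0.02
    velocity_gain: float = 8000.0
    velocity_cap: float = 12.0
    dilation_radius: float = 50.0
    step_months: float = 1.0
    steps: int = 40
    tissue_modulus: float = 6800.0
    soft_modulus: float = 2.0
    poisson: float = 0.3
    density_slope: float | None = None
    threshold: float = DEFAULT_THRESHOLD
    full_density: float = FULL_DENSITY
    frozen_end_layers: int = 1

    def __post_init__(self) -> None:
        for name in ("set_point", "velocity_gain", "velocity_cap", "dilation_radius",
                     "step_months", "steps"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def slope(self) -> float:
        return self.density_slope if self.density_slope is not None else (
            self.tissue_modulus / self.full_density
        )


@dataclass
class SimulationSeries:
    """Ordered greyscale volumes from one remodelling simulation.

    ``images[k]`` is the density after k steps (index 0 is the baseline
    phantom); ``rates[k]`` the formation/resorption rates of step k+1.
    ``magnitude`` is the applied scenario magnitude (ground truth), in N.
    """

    images: list[DensityImage]
    scenario: str
    magnitude: float
    rates: list[RemodelingRates]
    config: AdvectionConfig
    selected_indices: np.ndarray | None = None

    @property
    def n_steps(self) -> int:
        return len(self.images) - 1

    def mask(self, index: int) -> BinaryMask:
        return binarise(self.images[index], self.config.threshold)


def trabecular_region(shape: tuple[int, int, int], end_layers: int = 1) -> np.ndarray:
    """Boolean region mask excluding the solid plates at the axial ends.

    Remodelling analysis (and the simulator's own surface motion) is
    limited to this trabecular compartment; the plates are load-transfer
    plumbing, not bone that adapts."""
    region = np.ones(shape, dtype=bool)
    n = int(end_layers)
    if n > 0:
        region[:, :, :n] = False
        region[:, :, shape[2] - n :] = False
    return region


def _spherical_footprint(radius_vox: int) -> np.ndarray:
    r = int(radius_vox)
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r * r


def generate_phantom(
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: float = 0.0305,
    target_bvtv: float = 0.12,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    full_density: float = FULL_DENSITY,
    smoothing: tuple[float, float, float] = (1.6, 1.6, 3.0),
    tolerance: float = 0.005,
) -> DensityImage:
    """Generate a seeded trabecular phantom density volume.

    A Gaussian random field (anisotropically smoothed so trabeculae
    elongate along the loading axis, as they do in load-adapted bone) is
    thresholded at the level that gives ``target_bvtv`` in the trabecular
    interior after keeping only structure that percolates between the two
    end faces.  One solid layer is added at each axial end (the "platen"
    plates), so the FE model is always well posed; BV/TV is measured on
    the interior slices, excluding those plates.  Densities are mapped
    into a plausible mineral range: bone voxels between roughly
    0.6*full_density and full_density, background below the binarisation
    threshold, with a smooth ramp across the interface so the implicit
    surface has a well-defined sub-voxel position.  Deterministic for a
    given seed.
    """
    shape = tuple(int(n) for n in shape)
    if min(shape) < 24:
        raise ValueError(f"shape must be >= 24 in every axis, got {shape}")
    if not 0.0 < target_bvtv < 0.5:
        raise ValueError(f"target_bvtv must be in (0, 0.5), got {target_bvtv}")

    interior = (slice(None), slice(None), slice(1, shape[2] - 1))

    def realise(attempt: int) -> np.ndarray | None:
        rng = np.random.default_rng([int(seed), attempt])
        f = ndi.gaussian_filter(rng.standard_normal(shape), sigma=smoothing)
        fi = f[interior]
        lo = np.quantile(fi, max(0.0, 1.0 - 4.0 * target_bvtv))
        hi = np.quantile(fi, 1.0 - target_bvtv / 4.0)

        def masked(thr: float) -> tuple[np.ndarray, float]:
            m = f >= thr
            m[:, :, 0] = True
            m[:, :, -1] = True
            comp, _ = ndi.label(m, structure=np.ones((3, 3, 3), bool))
            plo, phi = comp[0, 0, 0], comp[0, 0, -1]
            if plo != phi:  # plates not bridged: no percolating structure
                return m, -1.0
            m &= comp == plo
            return m, float(np.count_nonzero(m[interior])) / f[interior].size

        best = None
        for _ in range(40):
            thr = 0.5 * (lo + hi)
            m, bv = masked(thr)
            if bv < 0 or bv < target_bvtv:
                hi = thr  # too sparse (or broken): lower the threshold
            else:
                lo = thr
            if bv >= 0 and abs(bv - target_bvtv) <= tolerance:
                best = m
                break
        return best

    mask = None
    for attempt in range(10):
        mask = realise(attempt)
        if mask is not None:
            break
    if mask is None:
        raise ValueError(
            f"could not realise a percolating phantom at BV/TV {target_bvtv} "
            f"within +-{tolerance}; try a larger grid"
        )

    # Smooth occupancy -> density ramp across the interface.
    d = ndi.gaussian_filter(mask.astype(np.float64), 1.0)
    bone_lo = threshold + 0.35 * (full_density - threshold)
    density = np.where(
        mask,
        bone_lo + (full_density - bone_lo) * np.clip(d, 0.0, 1.0),
        0.94 * threshold * np.clip(d, 0.0, 1.0),
    )
    return DensityImage(density, spacing)


def regularise_density(
    image: DensityImage,
    mask: BinaryMask,
    threshold: float = DEFAULT_THRESHOLD,
    full_density: float = FULL_DENSITY,
) -> DensityImage:
    """Regularise a density field against its binary mask.

    Interior bone is set to full mineral density, surface voxels keep
    their greyscale value (clipped into [threshold, full_density] so the
    binarised volume fraction exactly matches the mask) and the
    background is zeroed except for the one-voxel partial-volume shell
    face-adjacent to the bone, which keeps its sub-threshold greyscale.
    The shell is where the advancing interface accumulates density over
    successive steps; zeroing it would reset the front each step and
    suppress bone formation entirely on flat surfaces.  Binarising the
    output at the threshold reproduces the mask exactly.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask are not aligned")
    surf = extract_surface(mask).as_field()
    m = mask.values
    shell = ~m & ndi.binary_dilation(m, structure=ndi.generate_binary_structure(3, 1))
    out = np.zeros(image.shape)
    out[m] = full_density
    out[surf] = np.clip(image.values[surf], threshold, full_density)
    out[shell] = np.clip(image.values[shell], 0.0, np.nextafter(threshold, 0.0))
    return DensityImage(out, image.spacing, image.origin)


def _upwind_gradients(rho: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Godunov gradient magnitudes (grow, shrink) by one-sided differences."""
    g_grow = np.zeros_like(rho)
    g_shrink = np.zeros_like(rho)
    for ax in range(3):
        dm = np.zeros_like(rho)
        dp = np.zeros_like(rho)
        sl = [slice(None)] * 3
        sl_lo = list(sl)
        sl_hi = list(sl)
        sl_lo[ax] = slice(1, None)
        sl_hi[ax] = slice(None, -1)
        diff = (rho[tuple(sl_lo)] - rho[tuple(sl_hi)]) / h
        dm[tuple(sl_lo)] = diff
        dp[tuple(sl_hi)] = diff
        g_grow += np.minimum(dm, 0.0) ** 2 + np.maximum(dp, 0.0) ** 2
        g_shrink += np.maximum(dm, 0.0) ** 2 + np.minimum(dp, 0.0) ** 2
    return np.sqrt(g_grow), np.sqrt(g_shrink)


def advection_step(image: DensityImage, sed: np.ndarray, config: AdvectionConfig) -> DensityImage:
    """Advance the density interface one remodelling step.

    The SED field is dilated with a spherical maximum filter (sensing
    radius, >= 1 voxel), converted to a normal speed
    v = gain * (SED - set point) (zero inside the lazy zone, clamped to
    the velocity cap) and the density field is advected along its own
    gradient with a first-order upwind level-set update.  Densities are
    clamped to [0, full_density]; newly formed voxels mineralise to full
    density through the per-step regularisation of the simulation loop.
    Raises :class:`ConfigurationError` when the per-step displacement cap
    reaches one voxel (CFL stability limit).
    """
    h_um = image.spacing * 1000.0
    if config.velocity_cap * config.step_months >= h_um:
        raise ConfigurationError(
            f"velocity cap x step duration = {config.velocity_cap * config.step_months:g} um "
            f">= voxel size {h_um:g} um: unstable advection"
        )
    if sed.shape != image.shape:
        raise ValueError("SED field is not aligned with the image")

    r_vox = max(1, int(round(config.dilation_radius / h_um)))
    sed_d = ndi.maximum_filter(sed, footprint=_spherical_footprint(r_vox), mode="nearest")

    delta = sed_d - config.set_point
    gain_month = config.velocity_gain / 12.0  # um/month/MPa
    v = gain_month * delta
    v[np.abs(delta) <= config.set_point * config.lazy_half_width] = 0.0
    np.clip(v, -config.velocity_cap, config.velocity_cap, out=v)
    nfl = int(config.frozen_end_layers)
    if nfl > 0:
        v[:, :, :nfl] = 0.0
        v[:, :, image.shape[2] - nfl :] = 0.0

    step_mm = v * config.step_months / 1000.0  # interface displacement, mm
    rho = image.values
    g_grow, g_shrink = _upwind_gradients(rho, image.spacing)
    out = rho + np.maximum(step_mm, 0.0) * g_grow + np.minimum(step_mm, 0.0) * g_shrink
    np.clip(out, 0.0, config.full_density, out=out)
    return DensityImage(out, image.spacing, image.origin)


def _solve_scenario_sed(
    density: DensityImage,
    mask: BinaryMask,
    coeffs: np.ndarray,
    magnitude: float,
    config: AdvectionConfig,
) -> np.ndarray:
    """Compounded SED field for a scenario load at the given magnitude."""
    modulus_map = density.values * config.slope
    mesh = build_mesh(
        mask,
        tissue_modulus=config.tissue_modulus,
        soft_modulus=config.soft_modulus,
        poisson=config.poisson,
        modulus_map=modulus_map,
    )
    needed = tuple(d for d, c in zip(("C", "SX", "SY", "MZ", "BX", "BY"), coeffs) if c > 0)
    uls = solve_unit_loads(mesh, needed, platen_layers=config.frozen_end_layers)
    s = coeffs * magnitude**2 / 6.0
    return superpose(uls, s).sed


def run_simulation(
    phantom: DensityImage,
    scenario: str,
    magnitude: float,
    config: AdvectionConfig | None = None,
    steps: int | None = None,
) -> SimulationSeries:
    """Adapt a phantom under a scenario load for a number of steps.

    Each step regularises the density, maps it to per-element moduli,
    solves the needed unit load cases, superposes them to the scenario
    SED (which scales with magnitude squared), and advects the surface.
    Per-step formation/resorption rates are recorded from the binarised
    consecutive volumes.  Deterministic: no randomness enters the loop.
    """
    config = config or AdvectionConfig()
    n = int(steps if steps is not None else config.steps)
    coeffs = scenario_load(scenario)

    images = [phantom]
    rates: list[RemodelingRates] = []
    rho = phantom
    for k in range(n):
        mask = binarise(rho, config.threshold)
        reg = regularise_density(rho, mask, config.threshold, config.full_density)
        try:
            sed = _solve_scenario_sed(reg, mask, coeffs, magnitude, config)
        except Exception as err:
            raise RuntimeError(f"FE solve failed at remodelling step {k + 1}: {err}") from err
        rho = advection_step(reg, sed, config)
        mask_next = binarise(rho, config.threshold)
        rmap = overlay_remodeling(mask, mask_next)
        rates.append(remodeling_rates(rmap, mask.bone_volume()))
        images.append(rho)
    return SimulationSeries(images=images, scenario=scenario, magnitude=magnitude,
                           rates=rates, config=config)


def probe_rates(
    phantom: DensityImage,
    scenario: str,
    magnitude: float,
    config: AdvectionConfig,
    probe_steps: int,
    probe_burn_in: int,
) -> tuple[float, float]:
    """Mean (NRR, BFR) of a short probe run, past its initial transient.

    The first ``probe_burn_in`` steps are excluded: the random phantom is
    not load adapted, so unloaded struts are resorbed and load-bearing
    ones reinforced during an initial reorganisation, after which the
    rates settle to the level the balance search must target."""
    sim = run_simulation(phantom, scenario, magnitude, config, steps=probe_steps)
    tail = sim.rates[probe_burn_in:]
    return (
        float(np.mean([x.nrr for x in tail])),
        float(np.mean([x.bfr for x in tail])),
    )


def homeostatic_magnitude(
    phantom: DensityImage,
    scenario: str,
    config: AdvectionConfig | None = None,
    bracket: tuple[float, float] | None = None,
    tolerance: float = 0.02,
    probe_steps: int = 14,
    probe_burn_in: int = 8,
    max_probes: int = 10,
    return_evals: bool = False,
):
    """Scenario magnitude giving balanced formation and resorption.

    Bisects the magnitude on short probe simulations until the
    post-transient mean |BFR - BRR| falls below ``tolerance`` * BFR (2%
    by default, the homeostasis criterion) or the probe budget is spent,
    in which case the best-balanced magnitude seen is returned.  The net
    response is monotone in the magnitude over a sane bracket, so plain
    bisection (geometric midpoints, as the response scales with the
    squared load) converges quickly.  With no explicit ``bracket`` the
    sign change is auto-bracketed by geometric expansion around an
    initial guess placing an upper-quantile of the dilated surface SED
    at the set point; a bracket without a sign change raises
    :class:`BracketingError`.
    """
    config = config or AdvectionConfig()
    if bracket is not None and not (bracket[1] > bracket[0] >= 0):
        raise BracketingError(f"degenerate bracket {bracket}")

    evals: list[tuple[float, float, float]] = []  # (m, nrr, bfr)

    def g(m: float) -> float:
        try:
            nrr, bfr = probe_rates(phantom, scenario, m, config, probe_steps, probe_burn_in)
        except RuntimeError:
            # Structure resorbed past the percolation limit: treat as an
            # overwhelmingly negative net response.
            nrr, bfr = -1.0, 0.0
        evals.append((m, nrr, bfr))
        return nrr

    if bracket is not None:
        lo, hi = float(bracket[0]), float(bracket[1])
        if g(lo) >= 0 or g(hi) <= 0:
            raise BracketingError(
                f"bracket {bracket} does not span a sign change of the net response"
            )
    else:
        # Initial guess: scale so the mean of the load-bearing tail (top
        # 30% of the dilated surface SED) sits at the set point; much of
        # the surface of an unadapted phantom is mechanically dead, so
        # plain quantiles of the whole distribution are unreliable.
        coeffs = scenario_load(scenario)
        mask = binarise(phantom, config.threshold)
        reg = regularise_density(phantom, mask, config.threshold, config.full_density)
        base = _solve_scenario_sed(reg, mask, coeffs, 1.0, config)
        r_vox = max(1, int(round(config.dilation_radius / (phantom.spacing * 1000.0))))
        base_d = ndi.maximum_filter(base, footprint=_spherical_footprint(r_vox), mode="nearest")
        surf_sed = base_d[extract_surface(mask).as_field()]
        pos = surf_sed[surf_sed > 0]
        level = float(np.mean(np.sort(pos)[-max(1, pos.size // 3):]))
        m0 = float(np.sqrt(config.set_point / max(level, 1e-30)))
        lo = hi = m0
        s0 = g(m0)
        if s0 < 0:
            while len(evals) < max_probes:
                hi *= 3.0
                if g(hi) > 0:
                    break
                lo = hi
        else:
            while len(evals) < max_probes:
                lo /= 3.0
                if g(lo) < 0:
                    break
                hi = lo
        if not any(e[1] < 0 for e in evals) or not any(e[1] > 0 for e in evals):
            raise BracketingError("could not auto-bracket a homeostatic magnitude")
        lo = max(e[0] for e in evals if e[1] < 0)
        hi = min(e[0] for e in evals if e[1] > 0)

    m_out = None
    while len(evals) < max_probes:
        m = float(np.sqrt(lo * hi))
        nrr = g(m)
        _, _, bfr = evals[-1]
        if abs(nrr) <= tolerance * max(bfr, 1e-12):
            m_out = m
            break
        if nrr > 0:
            hi = m
        else:
            lo = m
    if m_out is None:
        best = min(evals, key=lambda e: abs(e[1]) / max(e[2], 1e-12))
        m_out = float(best[0])
    if return_evals:
        return m_out, evals
    return m_out


def subsample_series(
    series: SimulationSeries,
    correlation_threshold: float = 0.95,
    count: int = 6,
    burn_in: int = 8,
) -> np.ndarray:
    """Select time points whose consecutive Pearson correlation stays high.

    Mirrors how sparse in-vivo follow-ups are emulated from a dense
    simulation: the first ``burn_in`` steps (the initialisation
    transient) are excluded, then the largest uniform stride is chosen
    such that the Pearson correlation between consecutive selected
    greyscale volumes stays at or above the threshold, anchored at the
    final step.  The last ``count`` selected indices are returned (and
    stored on the series).  If even consecutive steps violate the
    threshold a warning is emitted and stride 1 is used.
    """
    last = series.n_steps
    if last - burn_in < count - 1:
        raise ValueError(
            f"series too short: need at least {burn_in + count - 1} steps, have {last}"
        )
    max_stride = (last - burn_in) // (count - 1)

    def correlations(idx: np.ndarray) -> list[float]:
        return [
            intensity_correlation(series.images[i], series.images[j])
            for i, j in zip(idx[:-1], idx[1:])
        ]

    chosen = None
    for stride in range(max_stride, 0, -1):
        idx = last - stride * np.arange(count - 1, -1, -1)
        if all(c >= correlation_threshold for c in correlations(idx)):
            chosen = idx
            break
    if chosen is None:
        chosen = last - np.arange(count - 1, -1, -1)
        warnings.warn(
            "consecutive scans violate the correlation threshold even at stride 1",
            stacklevel=2,
        )
    series.selected_indices = chosen
    return chosen
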
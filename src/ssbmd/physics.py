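"""Forward X-ray physics: polychromatic attenuation, scatter, noise, calibration.

The detector signal at each pixel is modelled as an energy-integrating count

    primary(x) = gain * mAs * sum_E w(E) * E * exp(-mu_soft(E)*T*a - mu_bone(E)*T*(1-a))

over a fixed-kVp (single-energy acquisition, polychromatic beam) spectrum
``w(E)``, where ``T`` is total thickness (cm) and ``a`` the soft-tissue
proportion.  Scatter is modelled as a thickness-dependent scatter-to-primary
ratio applied to a spatially smoothed primary field:

    scatter(x) = s0 * (1 - exp(-T(x)/tau)) * [G_w * primary](x)

with a Gaussian kernel of physical width ``w`` cm.  Detected counts are
Poisson distributed around primary + scatter.

The system is calibrated against step-wedge exposures by least squares on
per-band mean intensities, recovering the detector gain and the scatter
parameters (s0, tau).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares

from .phantoms import MorphologicalModel, wedge_bands

__all__ = [
    "EnergySpectrum",
    "MaterialTable",
    "ScatterModel",
    "SystemModel",
    "Radiograph",
    "CalibrationReport",
    "attenuation_coefficient",
    "simulate_radiograph",
    "calibrate_system",
    "mas_normalize",
    "default_system",
    "monoenergetic_system",
]


class ConfigurationError(ValueError):
    """Inconsistent acquisition / system configuration."""


class FittingError(RuntimeError):
    """Calibration could not be fitted (e.g. degenerate wedge)."""


# Mass attenuation coefficients mu/rho (cm^2/g) on a 10..60 keV grid, with
# coherent scattering, for water-equivalent soft tissue and cortical bone
# (plus aluminium for beam filtration).  Log-log interpolated between grid
# points.  Densities in g/cm^3; the bone value is the *assumed density of
# bone* used to turn bone thickness into aBMD and is configurable downstream.
ENERGY_GRID_KEV = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
MU_RHO_CM2G = {
    "soft": np.array([5.329, 0.8096, 0.3756, 0.2683, 0.2269, 0.2059]),
    "bone": np.array([28.51, 4.001, 1.331, 0.6655, 0.4242, 0.3148]),
    "aluminum": np.array([26.23, 3.441, 1.128, 0.5685, 0.3681, 0.2778]),
}
DENSITY_G_CM3 = {"soft": 1.0, "bone": 1.85, "aluminum": 2.699}


def _mass_attenuation(material: str, energies_kev: np.ndarray) -> np.ndarray:
    """Log-log interpolated mu/rho (cm^2/g); exact at tabulated grid points."""
    if material not in MU_RHO_CM2G:
        raise ValueError(f"unknown material {material!r}")
    e = np.atleast_1d(np.asarray(energies_kev, dtype=float))
    if np.any(e < ENERGY_GRID_KEV[0]) or np.any(e > ENERGY_GRID_KEV[-1]):
        raise ValueError("energy outside the tabulated 10-60 keV range")
    out = np.exp(
        np.interp(np.log(e), np.log(ENERGY_GRID_KEV), np.log(MU_RHO_CM2G[material]))
    )
    return out


def attenuation_coefficient(
    material: str, energy_kev: float | np.ndarray, density: float | None = None
) -> float | np.ndarray:
    """Linear attenuation coefficient (cm^-1) for ``soft`` or ``bone``."""
    rho = DENSITY_G_CM3[material] if density is None else density
    out = _mass_attenuation(material, energy_kev) * rho
    return float(out[0]) if np.isscalar(energy_kev) else out


@dataclass
class EnergySpectrum:
    """Relative fluence spectrum on a keV grid (weights sum to 1)."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.energies.shape != self.weights.shape or self.energies.ndim != 1:
            raise ValueError("energies and weights must be matching 1-D arrays")
        if np.any(self.weights < 0):
            raise ValueError("spectrum weights must be non-negative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("spectrum must have positive total weight")
        self.weights = self.weights / s

    @classmethod
    def filtered_kramers(
        cls, kvp: float = 60.0, step_kev: float = 1.0, filtration_mm_al: float = 2.5
    ) -> "EnergySpectrum":
        """Tungsten bremsstrahlung approximated by a Kramers fluence spectrum
        ~ (kVp - E)/E, hardened by an aluminium filter."""
        e = np.arange(10.0, kvp + 0.5 * step_kev, step_kev)
        e = e[e <= kvp]
        w = np.clip(kvp - e, 0.0, None) / e
        mu_al = attenuation_coefficient("aluminum", e)
        w = w * np.exp(-mu_al * filtration_mm_al / 10.0)
        return cls(e, w)

    def mean_energy(self) -> float:
        return float(self.weights @ self.energies)


@dataclass
class MaterialTable:
    """Per-material attenuation on the spectrum's energy grid."""

    energies: np.ndarray
    rho_bone: float = DENSITY_G_CM3["bone"]
    rho_soft: float = DENSITY_G_CM3["soft"]

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.rho_bone <= self.rho_soft:
            raise ValueError("bone density must exceed soft-tissue density")

    def mu_soft(self) -> np.ndarray:
        return _mass_attenuation("soft", self.energies) * self.rho_soft

    def mu_bone(self) -> np.ndarray:
        return _mass_attenuation("bone", self.energies) * self.rho_bone


@dataclass
class ScatterModel:
    """Scatter-to-primary ratio s0*(1-exp(-T/tau)) with Gaussian spreading."""

    s0: float = 0.4
    tau_cm: float = 3.0
    width_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.tau_cm <= 0 or self.width_cm <= 0:
            raise ValueError("tau_cm and width_cm must be positive")

    def spr(self, thickness: np.ndarray) -> np.ndarray:
        return self.s0 * (1.0 - np.exp(-np.asarray(thickness) / self.tau_cm))


@dataclass
class CalibrationReport:
    gain: float
    s0: float
    tau_cm: float
    residual_rms: float
    n_bands: int


@dataclass
class SystemModel:
    """Calibrated physics model of the acquisition system.

    ``gain`` converts integrated fluence-energy per pixel into detector
    counts; its default puts the unattenuated signal at a 2 mAs clinical
    exposure near 1.1e5 counts/pixel, emulating a low-noise flat-panel DR
    detector.
    """

    spectrum: EnergySpectrum = field(default_factory=EnergySpectrum.filtered_kramers)
    materials: MaterialTable | None = None
    gain: float = 1700.0
    kvp: float = 60.0
    scatter: ScatterModel = field(default_factory=ScatterModel)
    sid_cm: float = 100.0
    pixel_pitch: float = 0.05
    calibration: CalibrationReport | None = None

    def __post_init__(self) -> None:
        if self.materials is None:
            self.materials = MaterialTable(self.spectrum.energies)
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if np.any(self.spectrum.energies > self.kvp + 1e-9):
            raise ValueError("spectrum extends beyond the tube kVp")

    def spectral_terms(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(counts-per-mAs spectral weights, mu_soft(E), mu_bone(E))."""
        w_counts = self.gain * self.spectrum.weights * self.spectrum.energies
        return w_counts, self.materials.mu_soft(), self.materials.mu_bone()

    def vacuum_intensity(self, mas: float) -> float:
        """Unattenuated counts per pixel at the given mAs."""
        w_counts, _, _ = self.spectral_terms()
        return float(mas * w_counts.sum())


def default_system(pixel_pitch: float = 0.05, **kwargs) -> SystemModel:
    return SystemModel(pixel_pitch=pixel_pitch, **kwargs)


def monoenergetic_system(
    energy_kev: float = 40.0, pixel_pitch: float = 0.05, **kwargs
) -> SystemModel:
    """Single-bin spectrum; used to expose the single-energy degeneracy."""
    spec = EnergySpectrum(np.array([energy_kev]), np.array([1.0]))
    kwargs.setdefault("kvp", max(60.0, energy_kev))
    return SystemModel(spectrum=spec, pixel_pitch=pixel_pitch, **kwargs)


@dataclass
class Radiograph:
    """Simulated detector image plus acquisition metadata."""

    intensity: np.ndarray
    kvp: float
    mas: float
    fov_cm: tuple[float, float]
    sid_cm: float
    pixel_pitch: float
    noise_applied: bool

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.mas <= 0:
            raise ValueError("mAs must be positive")
        expect = (
            self.intensity.shape[0] * self.pixel_pitch,
            self.intensity.shape[1] * self.pixel_pitch,
        )
        if not np.allclose(expect, self.fov_cm, rtol=1e-6):
            raise ValueError("field of view inconsistent with grid x pixel pitch")


def expected_image(model: MorphologicalModel, system: SystemModel, mas: float) -> np.ndarray:
    """Noise-free expected counts: primary + scatter."""
    w_counts, mu_s, mu_b = system.spectral_terms()
    t = model.thickness
    ls = (t * model.alloy).ravel()
    lb = (t * (1.0 - model.alloy)).ravel()
    attn = np.exp(-(ls[:, None] * mu_s[None, :] + lb[:, None] * mu_b[None, :]))
    primary = (attn @ (mas * w_counts)).reshape(t.shape)
    spr = system.scatter.spr(t)
    smoothed = gaussian_filter(primary, system.scatter.width_cm / model.pixel_pitch, mode="constant")
    return primary + spr * smoothed


def simulate_radiograph(
    model: MorphologicalModel,
    system: SystemModel,
    mas: float = 2.0,
    noiseless: bool = False,
    seed: int | None = 0,
) -> Radiograph:
    """Simulate a radiograph of ``model`` under ``system`` at ``mas``.

    Noiseless output is deterministic; noisy output is deterministic given
    ``seed`` (Poisson counting noise on the expected counts).
    """
    if mas <= 0:
        raise ValueError("mAs must be positive")
    if not np.isclose(model.pixel_pitch, system.pixel_pitch, rtol=1e-9):
        raise ConfigurationError(
            f"model pixel pitch {model.pixel_pitch} does not match system {system.pixel_pitch}"
        )
    expected = expected_image(model, system, mas)
    if noiseless:
        intensity = expected
    else:
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(expected).astype(float)
    return Radiograph(
        intensity=intensity,
        kvp=system.kvp,
        mas=mas,
        fov_cm=model.fov_cm,
        sid_cm=system.sid_cm,
        pixel_pitch=model.pixel_pitch,
        noise_applied=not noiseless,
    )


def mas_normalize(r: Radiograph, reference_mas: float) -> Radiograph:
    """Rescale to a reference mAs (signal is linear in mAs)."""
    if reference_mas <= 0:
        raise ValueError("reference mAs must be positive")
    scale = reference_mas / r.mas
    return dataclasses.replace(r, intensity=r.intensity * scale, mas=reference_mas)


def calibrate_system(
    exposures: list[tuple[Radiograph, MorphologicalModel]],
    initial: SystemModel,
) -> SystemModel:
    """Fit gain and scatter (s0, tau) to step-wedge exposures.

    Least squares on per-band mean intensities of each wedge; the returned
    system carries a :class:`CalibrationReport`.  Raises
    :class:`FittingError` when the wedges present fewer than two distinct
    steps.
    """
    band_obs: list[float] = []
    band_defs: list[tuple[MorphologicalModel, int, int, float]] = []
    distinct: set[tuple[float, float]] = set()
    for radiograph, wedge in exposures:
        for c0, c1 in wedge_bands(wedge):
            band_obs.append(float(radiograph.intensity[:, c0:c1].mean()))
            band_defs.append((wedge, c0, c1, radiograph.mas))
            distinct.add((float(wedge.thickness[0, c0]), float(wedge.alloy[0, c0])))
    if len(distinct) < 2:
        raise FittingError("degenerate wedge: need >= 2 distinct steps to calibrate")
    obs = np.asarray(band_obs)

    def predict(log_gain: float, s0: float, log_tau: float) -> np.ndarray:
        system = dataclasses.replace(
            initial,
            gain=float(np.exp(log_gain)),
            scatter=ScatterModel(
                s0=max(s0, 0.0), tau_cm=float(np.exp(log_tau)), width_cm=initial.scatter.width_cm
            ),
        )
        out = []
        cache: dict[tuple[int, float], np.ndarray] = {}
        for wedge, c0, c1, mas in band_defs:
            key = (id(wedge), mas)
            if key not in cache:
                cache[key] = expected_image(wedge, system, mas)
            out.append(cache[key][:, c0:c1].mean())
        return np.asarray(out)

    def residuals(x: np.ndarray) -> np.ndarray:
        return (predict(*x) - obs) / np.maximum(obs, 1.0)

    x0 = np.array(
        [np.log(initial.gain), initial.scatter.s0, np.log(initial.scatter.tau_cm)]
    )
    fit = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    gain = float(np.exp(fit.x[0]))
    s0 = float(max(fit.x[1], 0.0))
    tau = float(np.exp(fit.x[2]))
    report = CalibrationReport(
        gain=gain,
        s0=s0,
        tau_cm=tau,
        residual_rms=float(np.sqrt(np.mean(fit.fun**2))),
        n_bands=len(obs),
    )
    return dataclasses.replace(
        initial,
        gain=gain,
        scatter=ScatterModel(s0=s0, tau_cm=tau, width_cm=initial.scatter.width_cm),
        calibration=report,
    )


# ---------------------------------------------------------------------------
# SystemModel I/O: versioned JSON config

SYSTEM_SCHEMA_VERSION = "ssbmd-system-1"


def save_system(path: str, system: SystemModel) -> None:
    payload = {
        "schema": SYSTEM_SCHEMA_VERSION,
        "kvp": system.kvp,
        "gain": system.gain,
        "sid_cm": system.sid_cm,
        "pixel_pitch_cm": system.pixel_pitch,
        "scatter": {
            "s0": system.scatter.s0,
            "tau_cm": system.scatter.tau_cm,
            "width_cm": system.scatter.width_cm,
        },
        "spectrum": {
            "energies_kev": system.spectrum.energies.tolist(),
            "weights": system.spectrum.weights.tolist(),
        },
        "rho_bone": system.materials.rho_bone,
        "rho_soft": system.materials.rho_soft,
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=2)


def load_system(path: str) -> SystemModel:
    with open(path) as f:
        payload = json.load(f)
    if payload.get("schema") != SYSTEM_SCHEMA_VERSION:
        raise ConfigurationError("unrecognised system config schema")
    spectrum = EnergySpectrum(
        np.asarray(payload["spectrum"]["energies_kev"]),
        np.asarray(payload["spectrum"]["weights"]),
    )
    materials = MaterialTable(
        spectrum.energies, rho_bone=payload["rho_bone"], rho_soft=payload["rho_soft"]
    )
    return SystemModel(
        spectrum=spectrum,
        materials=materials,
        gain=payload["gain"],
        kvp=payload["kvp"],
        scatter=ScatterModel(**payload["scatter"]),
        sid_cm=payload["sid_cm"],
        pixel_pitch=payload["pixel_pitch_cm"],
    )


# ---------------------------------------------------------------------------
# Radiograph I/O: 16-bit grayscale image + JSON sidecar


def write_radiograph(path_png: str, r: Radiograph) -> None:
    import imageio.v3 as iio

    peak = float(r.intensity.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    img = np.clip(r.intensity * scale, 0, 65535).astype(np.uint16)
    iio.imwrite(path_png, img)
    meta = {
        "kvp": r.kvp,
        "mas": r.mas,
        "fov_cm": list(r.fov_cm),
        "sid_cm": r.sid_cm,
        "pixel_pitch_cm": r.pixel_pitch,
        "noise_applied": r.noise_applied,
        "intensity_scale": scale,
    }
    with open(str(path_png) + ".json", "w") as f:
        json.dump(meta, f, indent=2)


def read_radiograph(path_png: str) -> Radiograph:
    import imageio.v3 as iio

    with open(str(path_png) + ".json") as f:
        meta = json.load(f)
    img = iio.imread(path_png).astype(float) / meta["intensity_scale"]
    return Radiograph(
        intensity=img,
        kvp=meta["kvp"],
        mas=meta["mas"],
        fov_cm=tuple(meta["fov_cm"]),
        sid_cm=meta["sid_cm"],
        pixel_pitch=meta["pixel_pitch_cm"],
        noise_applied=meta["noise_applied"],
    )
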
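"""Gaussian peak fitting of fluorescence emission spectra in energy space.

Well-plate emission spectra of AgN-DNA products are recorded against
wavelength (nm) but the emission bands are approximately Gaussian in
photon energy, so spectra are converted to an energy axis
(``E = hc / lambda``, ``hc = 1239.842 eV nm``) and fitted to a sum of one
to three Gaussians.  Each fitted component yields a peak wavelength
``lambda_p`` and an integrated area; areas are normalized to a control
emitter so brightness is comparable across plates.

The number of components is chosen by a nested elbow rule: components are
added (each fit warm-started from the previous one plus a new peak seeded
at the strongest unexplained local maximum) as long as the residual sum of
squares drops by at least ``rel_improvement`` (default 5%).  Components
whose height falls below ``amplitude_floor_sigma`` (default 3) times a
robust residual noise estimate are discarded.  No Jacobian correction of
intensities is applied on the wavelength-to-energy change of variable by
default (``apply_jacobian`` flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from lmfit.models import GaussianModel
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "HC_EV_NM",
    "EmissionSpectrum",
    "GaussianPeak",
    "PeakSet",
    "FitConfig",
    "to_energy",
    "fit_peaks",
    "normalize_brightness",
]

#: Planck constant times speed of light, eV·nm.
HC_EV_NM = 1239.842

_WL_MIN, _WL_MAX = 350.0, 1400.0


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single well's emission spectrum on a wavelength axis.

    ``wavelengths`` must be strictly increasing, in nm, within the
    instrument range [350, 1400] nm; intensities are arbitrary detector
    units.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        if wl.size < 10:
            raise ValueError(f"spectrum {self.well_id!r}: need >= 10 samples, got {wl.size}")
        if wl.size != it.size:
            raise ValueError("wavelengths and intensities must have equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < _WL_MIN or wl[-1] > _WL_MAX:
            raise ValueError(f"wavelengths must lie within [{_WL_MIN}, {_WL_MAX}] nm")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class GaussianPeak:
    """One fitted Gaussian emission component (parameters in energy space)."""

    center_energy: float  # eV
    amplitude: float  # peak height, detector units
    width_sigma: float  # eV
    area: float  # detector units × eV
    normalized_brightness: float = float("nan")  # area / control area

    @property
    def center_wavelength(self) -> float:
        """Peak wavelength lambda_p in nm."""
        return HC_EV_NM / self.center_energy


@dataclass(frozen=True)
class PeakSet:
    """Outcome of fitting one spectrum: 0-3 peaks plus fit diagnostics.

    Peaks are sorted by descending normalized brightness (descending area
    before normalization).  ``error`` is set instead of raising when the
    optimizer fails for every candidate component count.
    """

    peaks: tuple[GaussianPeak, ...] = ()
    fit_quality: float = float("nan")  # residual 2-norm of selected fit
    n_components_selected: int = 0
    well_id: str = ""
    error: str | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def brightest(self) -> GaussianPeak | None:
        return self.peaks[0] if self.peaks else None


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the spectral fitting procedure."""

    max_components: int = 3
    rel_improvement: float = 0.05  # elbow rule threshold on SSE reduction
    amplitude_floor_sigma: float = 3.0  # × robust noise (MAD of residuals)
    smooth_window: int = 7  # Savitzky-Golay window for peak seeding
    apply_jacobian: bool = False  # intensity Jacobian on λ→E conversion


def to_energy(spectrum: EmissionSpectrum, apply_jacobian: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Convert a wavelength-axis spectrum to an ascending energy axis.

    Returns ``(energies_eV, intensities)`` with sample order reversed so
    energy increases.  With ``apply_jacobian`` the intensities are scaled
    by ``lambda^2 / hc`` (the |d lambda / dE| Jacobian); by default raw
    counts are fitted against energy.
    """
    wl = spectrum.wavelengths
    if np.any(wl <= 0):
        raise ValueError("wavelengths must be positive to convert to energy")
    energy = HC_EV_NM / wl[::-1]
    intens = spectrum.intensities[::-1].astype(float)
    if apply_jacobian:
        intens = intens * (wl[::-1] ** 2) / HC_EV_NM
    return energy, intens


def _seed_centers(energy: np.ndarray, intens: np.ndarray, window: int) -> np.ndarray:
    """Candidate peak centers: local maxima of the smoothed trace, strongest first."""
    if intens.size >= window and window >= 5:
        smooth = savgol_filter(intens, window, 2)
    else:
        smooth = intens
    locs, _ = find_peaks(smooth)
    if locs.size == 0:
        locs = np.array([int(np.argmax(smooth))])
    order = np.argsort(smooth[locs])[::-1]
    return energy[locs[order]]


def _fit_k(energy, intens, k, seeds, prev_params):
    """Fit a k-Gaussian model, warm-starting components 1..k-1 from the previous fit."""
    model = None
    for i in range(k):
        g = GaussianModel(prefix=f"g{i}_")
        model = g if model is None else model + g
    params = model.make_params()
    span = energy[-1] - energy[0]
    sigma0 = max(span / 20.0, 1e-3)
    # a real emission band must be wider than the detector sampling step
    # (the energy axis is nonuniform, so take the coarsest step); this
    # keeps the optimizer from collapsing onto single noise spikes
    sigma_min = max(1e-4, float(np.max(np.diff(energy))))
    for i in range(k):
        pfx = f"g{i}_"
        if prev_params is not None and f"{pfx}center" in prev_params:
            center = prev_params[f"{pfx}center"].value
            sigma = prev_params[f"{pfx}sigma"].value
            amp = prev_params[f"{pfx}amplitude"].value
        else:
            center = seeds[min(i, seeds.size - 1)]
            sigma = sigma0
            j = int(np.argmin(np.abs(energy - center)))
            amp = max(intens[j], 1e-12) * sigma * np.sqrt(2 * np.pi)
        params[f"{pfx}center"].set(value=center, min=energy[0] - span * 0.05, max=energy[-1] + span * 0.05)
        params[f"{pfx}sigma"].set(value=max(sigma, sigma_min), min=sigma_min, max=span)
        params[f"{pfx}amplitude"].set(value=max(amp, 1e-12), min=0.0)
    result = model.fit(intens, params, x=energy)
    ss = float(np.sum(result.residual**2))
    return result, ss


def fit_peaks(
    spectrum: EmissionSpectrum,
    max_components: int = 3,
    config: FitConfig | None = None,
) -> PeakSet:
    """Fit a spectrum to a sum of 1-3 Gaussians in energy and extract peaks.

    Parameters
    ----------
    spectrum : EmissionSpectrum
    max_components : int
        Upper bound on the number of Gaussians, 1-3.
    config : FitConfig, optional
        Full knob set; ``max_components`` overrides the config value.

    Returns
    -------
    PeakSet
        Peaks sorted by descending area; empty when no component clears
        the amplitude floor (e.g. a flat noise trace) or when the fit
        fails (then with ``error`` set).
    """
    cfg = config or FitConfig()
    if max_components not in (1, 2, 3):
        raise ValueError("max_components must be 1, 2 or 3")
    energy, intens = to_energy(spectrum, apply_jacobian=cfg.apply_jacobian)

    if not np.any(intens > 0):
        return PeakSet(well_id=spectrum.well_id, fit_quality=0.0)

    seeds = _seed_centers(energy, intens, cfg.smooth_window)
    best_result, best_ss, best_k = None, np.inf, 0
    prev_params = None
    last_error: str | None = None
    for k in range(1, max_components + 1):
        try:
            result, ss = _fit_k(energy, intens, k, seeds, prev_params)
        except Exception as exc:  # lmfit/scipy convergence failure
            last_error = f"{type(exc).__name__}: {exc}"
            break
        if best_result is not None and ss > best_ss:
            break  # adding a component must not worsen the optimum
        if best_result is not None:
            gain = (best_ss - ss) / best_ss if best_ss > 0 else 0.0
            if gain < cfg.rel_improvement:
                break
        best_result, best_ss, best_k = result, ss, k
        prev_params = result.params
        if best_ss <= 1e-18 * float(np.sum(intens**2)):
            break  # fit is exact to machine precision; nothing left to explain

    if best_result is None:
        return PeakSet(
            well_id=spectrum.well_id,
            error=last_error or "no successful fit",
        )

    residuals = np.asarray(best_result.residual)
    mad = float(np.median(np.abs(residuals - np.median(residuals))))
    noise = 1.4826 * mad
    # floor: 3x robust noise, plus a relative term to drop machine-precision
    # ghost components from near-exact fits
    floor = max(cfg.amplitude_floor_sigma * noise, 1e-9 * float(np.max(intens)))

    peaks = []
    for i in range(best_k):
        pfx = f"g{i}_"
        area = float(best_result.params[f"{pfx}amplitude"].value)
        sigma = float(best_result.params[f"{pfx}sigma"].value)
        center = float(best_result.params[f"{pfx}center"].value)
        height = area / (sigma * np.sqrt(2 * np.pi))
        if height < floor or area <= 0 or center <= 0:
            continue
        peaks.append(
            GaussianPeak(
                center_energy=center,
                amplitude=height,
                width_sigma=sigma,
                area=area,
            )
        )
    peaks.sort(key=lambda p: p.area, reverse=True)
    return PeakSet(
        peaks=tuple(peaks),
        fit_quality=float(np.sqrt(best_ss)),
        n_components_selected=len(peaks),
        well_id=spectrum.well_id,
    )


def normalize_brightness(peaks: PeakSet, control_area: float) -> PeakSet:
    """Normalize peak areas to a control emitter's area.

    ``normalized_brightness = area / control_area`` for every peak; peaks
    are re-sorted by descending normalized brightness.
    """
    if not (control_area > 0):
        raise ValueError(f"control_area must be positive, got {control_area}")
    new = tuple(
        sorted(
            (replace(p, normalized_brightness=p.area / control_area) for p in peaks.peaks),
            key=lambda p: p.normalized_brightness,
            reverse=True,
        )
    )
    return replace(peaks, peaks=new)
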
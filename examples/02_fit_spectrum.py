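"""Fit a well-plate emission spectrum to Gaussians in energy space.

Builds a noisy two-peak spectrum (560 nm and 640 nm emitters, 2:1 area
ratio), fits 1-3 Gaussians against photon energy, and prints the
recovered peak wavelengths and control-normalized brightnesses.
"""

import numpy as np

from agndesign import EmissionSpectrum, fit_peaks, normalize_brightness
from agndesign.spectra import HC_EV_NM

grid = np.arange(400.0, 900.0, 2.0)
energy = HC_EV_NM / grid


def gaussian(lam_nm, sigma_ev, area):
    return area / (sigma_ev * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((energy - HC_EV_NM / lam_nm) / sigma_ev) ** 2
    )


rng = np.random.default_rng(0)
clean = gaussian(560.0, 0.05, 2.0) + gaussian(640.0, 0.05, 1.0)
spectrum = EmissionSpectrum(grid, clean + rng.normal(0, 0.01 * clean.max(), grid.size))

peaks = normalize_brightness(fit_peaks(spectrum), control_area=2.0)
print(f"components selected: {peaks.n_components_selected}")
for p in peaks.peaks:
    print(
        f"  lambda_p = {p.center_wavelength:7.2f} nm, "
        f"area = {p.area:.3f}, brightness vs control = {p.normalized_brightness:.3f}"
    )
# lambda_p decides the color class (Green < 580 nm < ... < NIR > 800 nm);
# brightness relative to the control emitter decides whether the peak
# counts as "bright" during training-set curation.
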
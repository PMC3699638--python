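"""Independent oracles shared across test modules.

These deliberately avoid the package's own FFT/scaling code paths.
"""

import numpy as np


def brute_force_dft_amplitude(course, tr):
    """Direct O(n^2) DFT with one-sided amplitude scaling."""
    n = len(course)
    n_bins = n // 2 + 1
    amps = np.empty(n_bins)
    for k in range(n_bins):
        c = np.sum(course * np.exp(-2j * np.pi * k * np.arange(n) / n))
        scale = 1.0 / n if (k == 0 or (n % 2 == 0 and k == n_bins - 1)) else 2.0 / n
        amps[k] = np.abs(c) * scale
    return np.fft.rfftfreq(n, d=tr), amps


def thermal_amplitude_floor_pct(sigma_pct, n, n_noise_bins=4,
                                half_window_hz=0.02, tr=0.25):
    """Expected additive thermal contribution to the pulsatility map.

    Each noise-only bin's one-sided amplitude is Rayleigh-distributed with
    mean sigma*sqrt(pi/n); the window average adds their sum scaled by
    df / (2 * half_window).
    """
    df = 1.0 / (n * tr)
    return n_noise_bins * sigma_pct * np.sqrt(np.pi / n) * df / (2 * half_window_hz)
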
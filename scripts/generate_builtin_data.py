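"""Regenerate the packaged CSV data files under src/tetracolour/data/.

Receptor sensitivities are built from the Govardovskii et al. (2000) A1
visual-pigment template (alpha + beta bands), evaluated at approximate
published average peak wavelengths for the violet-sensitive (VS) and
ultraviolet-sensitive (UVS) classes of avian colour vision. The illuminant
is a 6500 K Planck radiator in relative photon units (a stand-in for
standard noon daylight), and the background is a smooth leaf-green
reflectance curve. Unit tests never depend on these tables — they use toy
Gaussian systems — but the CLI defaults do.

Run from the repository root:  python scripts/generate_builtin_data.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

GRID = np.arange(300.0, 701.0, 1.0)
DATA_DIR = Path(__file__).resolve().parent.parent / "src" / "tetracolour" / "data"

# Approximate average peak wavelengths (nm), short -> long receptor.
PEAKS = {
    "vs": (415.0, 455.0, 508.0, 565.0),
    "uvs": (370.0, 448.0, 505.0, 565.0),
}


def pigment_template(lmax: float, wl: np.ndarray) -> np.ndarray:
    """Govardovskii A1 template: alpha band plus beta band, peak-normalised."""
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lmax
    b = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / b) ** 2))
    s = alpha + beta
    return s / s.max()


def planck_photon_irradiance(t_kelvin: float, wl: np.ndarray) -> np.ndarray:
    """Relative spectral photon irradiance of a Planck radiator."""
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    lam = wl * 1e-9
    # photon flux ~ radiance / photon energy
    spectral = 1.0 / (lam**4 * (np.exp(h * c / (lam * kb * t_kelvin)) - 1.0))
    return spectral / spectral[wl == 560.0]


def leaf_green_background(wl: np.ndarray) -> np.ndarray:
    """Smooth leaf-like reflectance: low UV, green bump near 550 nm, mild
    far-red shoulder."""
    r = (
        0.03
        + 0.12 * np.exp(-(((wl - 550.0) / 40.0) ** 2))
        + 0.10 / (1.0 + np.exp(-(wl - 697.0) / 6.0))
    )
    return r


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for key, peaks in PEAKS.items():
        cols = {"wavelength_nm": GRID}
        for i, lmax in enumerate(peaks, start=1):
            cols[f"receptor{i}_{int(lmax)}nm"] = pigment_template(lmax, GRID)
        pd.DataFrame(cols).to_csv(
            DATA_DIR / f"{key}_sensitivities.csv", index=False, float_format="%.8g"
        )
    pd.DataFrame(
        {"wavelength_nm": GRID, "irradiance_6500K": planck_photon_irradiance(6500.0, GRID)}
    ).to_csv(DATA_DIR / "illuminant_d65.csv", index=False, float_format="%.8g")
    pd.DataFrame(
        {"wavelength_nm": GRID, "leaf_green": leaf_green_background(GRID)}
    ).to_csv(DATA_DIR / "leaf_background.csv", index=False, float_format="%.8g")
    print(f"wrote data files to {DATA_DIR}")


if __name__ == "__main__":
    main()
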
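"""Small spectroscopic unit utilities (wavelengths, FFT axis limits)."""

from __future__ import annotations

from scipy import constants

__all__ = ["nm_to_wavenumber", "nyquist_limit", "axis_resolution"]

_C_CM_FS = constants.c * 1e2 * 1e-15  # speed of light in cm/fs


def nm_to_wavenumber(wavelength_nm: float) -> float:
    """Vacuum wavelength (nm) to wavenumber (cm^-1): 1e7 / lambda."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be > 0")
    return 1e7 / wavelength_nm


def nyquist_limit(dt_fs: float) -> float:
    """Nyquist wavenumber (cm^-1) of a delay scan sampled every ``dt_fs``.

    1/(2 c dt): e.g. a 0.38 fs step gives ~44,000 cm^-1.
    """
    if dt_fs <= 0:
        raise ValueError("dt must be > 0")
    return 1.0 / (2.0 * _C_CM_FS * dt_fs)


def axis_resolution(t_max_fs: float) -> float:
    """Excitation-axis resolution (cm^-1) of a scan of length ``t_max_fs``.

    Double-sided convention 1/(2 c t_max): a 197.6 fs scan gives ~84 cm^-1
    (the single-sided convention would give twice that).
    """
    if t_max_fs <= 0:
        raise ValueError("t_max must be > 0")
    return 1.0 / (2.0 * _C_CM_FS * t_max_fs)
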
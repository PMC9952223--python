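"""Unit conversions.

Internal unit system: lengths in mm, times in days, diffusivities in mm^2/day,
growth velocities in mm^3/day.  Literature diffusion coefficients for cell
migration are usually quoted in um^2/min and converted on input.
"""

#: um^2/min -> mm^2/day:  (1e-3 mm)^2 * 1440 min/day
UM2_PER_MIN_TO_MM2_PER_DAY = 1440.0e-6


def convert_diffusivity(value_um2_per_min: float) -> float:
    """Convert a diffusion coefficient from um^2/min to mm^2/day.

    Parameters
    ----------
    value_um2_per_min:
        Diffusion coefficient in um^2/min; must be non-negative.
    """
    if value_um2_per_min < 0:
        raise ValueError(f"diffusivity must be >= 0, got {value_um2_per_min}")
    return value_um2_per_min * UM2_PER_MIN_TO_MM2_PER_DAY
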
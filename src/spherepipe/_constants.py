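"""Versioned numeric constants.

``RYTOV_SC_DEFAULT`` was produced by the in-repo calibration harness
(:func:`spherepipe.calib.calibrate_rytov_sc`) with its default settings:
contrast grid x in {0.005, 0.02, 0.035, 0.05}, radii {2, 4.5, 7} um,
lambda = 550 nm, n_med = 1.335, 12 px per radius, 64^3 Born reference
volume.  The values are near-identity by construction (see the calib
module docstring); corrected fits recover the reference contrast within
0.4% and the radius within 0.1% across the grid.  Externally sourced
coefficients can be supplied per run via ``[sphere] rytov_sc_coeffs``.
"""

from .models import RytovSCCoeffs

#: calibration version (bump when the harness or its settings change)
RYTOV_SC_VERSION = 1

RYTOV_SC_DEFAULT = RytovSCCoeffs(
    c_n0=5.34568571374169e-06,
    c_n1=0.9985759461971134,
    c_r0=0.9999309493906245,
    c_r1=0.0014348443934427222,
)
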
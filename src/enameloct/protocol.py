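"""Scanning-protocol constants for the SS-OCT acquisition geometry.

The acquisition covers a 5 x 5 mm lateral field with 256 A-lines per B-scan
and a 1.85 mm in-tissue depth range (enamel refractive index 1.63).  Cropped
regions of interest are exported at a 4.4 um axial pixel pitch (the system's
axial resolution), which is the ``ps_axial`` used throughout the depth
equations.  The axial pitch is already an in-tissue distance; no further
refractive-index scaling is applied downstream.
"""

SCAN_WIDTH_UM: float = 5000.0
"""Lateral extent of one B-scan, um."""

N_ALINES: int = 256
"""Number of A-lines (lateral pixels) per full B-scan."""

DEPTH_RANGE_UM: float = 1850.0
"""Axial (in-tissue) imaging depth, um."""

N_AXIAL_PIXELS: int = 1000
"""Axial pixel count of the full (uncropped) frame."""

REFRACTIVE_INDEX: float = 1.63
"""Group refractive index of enamel used to convert optical to physical depth."""

PS_AXIAL_UM: float = 4.4
"""Axial pixel size of exported ROI frames, um/pixel (system axial resolution)."""

PS_LATERAL_UM: float = 19.5
"""Lateral pixel size, um/pixel."""

BACKGROUND_THRESHOLD_DB: float = 5.0
"""Maximum air-backscatter intensity; at or below this a pixel is background."""


def lateral_pitch_um() -> float:
    """Lateral pixel pitch implied by the scan protocol (scan width / A-lines)."""
    return SCAN_WIDTH_UM / N_ALINES
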
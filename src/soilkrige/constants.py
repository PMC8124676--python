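"""Package-wide numerical conventions."""

# Two sample locations closer than this (metres) are treated as coincident.
# Well below any plausible GPS precision; protects kriging solves.
EPS_DUP: float = 0.5

# Prediction-grid cell size (metres) used throughout unless overridden.
DEFAULT_CELL_SIZE: float = 100.0

# ESRI ASCII grid sentinel for cells outside the study region.
NODATA: float = -9999.0

# Kriging variances in [-NEG_VAR_TOL, 0) are numerical noise and clamped to 0;
# anything more negative indicates an invalid model or system and is an error.
NEG_VAR_TOL: float = 1e-8
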
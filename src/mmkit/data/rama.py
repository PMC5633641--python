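"""Coarse Ramachandran region polygons (general case).

Two-tier classification: "favoured" covers the cores of the alpha-helical and
beta-sheet basins, "allowed" adds a margin around each core plus the
left-handed helical region.  Vertices are (phi, psi) in degrees.  These are
deliberately coarse convex outlines in the style of published general-case
contours, adequate for flagging outliers; they do not claim agreement with
any specific published contour set.
"""

# Core regions.
_ALPHA = [(-145.0, -65.0), (-145.0, -10.0), (-50.0, -10.0), (-50.0, -65.0)]
_BETA = [(-170.0, 85.0), (-170.0, 180.0), (-55.0, 180.0), (-55.0, 85.0)]

# Margins (expanded cores) and the left-handed alpha region.
_ALPHA_X = [(-175.0, -85.0), (-175.0, 15.0), (-35.0, 15.0), (-35.0, -85.0)]
_BETA_X = [(-180.0, 60.0), (-180.0, 180.0), (-40.0, 180.0), (-40.0, 60.0)]
_LALPHA = [(35.0, 0.0), (35.0, 85.0), (95.0, 85.0), (95.0, 0.0)]
# Beta basin wraps through psi = -180; cover the lower strip too.
_BETA_WRAP = [(-180.0, -180.0), (-180.0, -150.0), (-40.0, -150.0), (-40.0, -180.0)]

RAMA_FAVOURED = [_ALPHA, _BETA]
RAMA_ALLOWED = [_ALPHA_X, _BETA_X, _LALPHA, _BETA_WRAP]
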
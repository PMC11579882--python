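"""Generic planar anthropometry shipped with the package.

Segment mass fractions and lengths follow the conventional generic
musculoskeletal model of a 168 cm, ~75 kg adult used throughout the gait
literature; the foot landmark offsets (heel, calcaneus centre of mass, toe
tip) are the generic-model values in metres, expressed relative to the
calcaneus CoM in the model frame (x anterior, y up, z right).  Everything
here is a default asset: callers may override any entry.
"""

from __future__ import annotations

GENERIC_HEIGHT_M = 1.68

#: fraction of total body mass per tracked segment; the pelvis "lump" is the
#: remainder (whole body minus impaired thigh+shank+foot and contralateral
#: foot), computed at scaling time so masses sum exactly.
MASS_FRACTIONS = {
    "thigh": 0.1238,
    "shank": 0.0493,
    "foot": 0.0208,
}

#: segment lengths of the generic 1.68 m model, m
SEGMENT_LENGTHS = {
    "thigh": 0.410,
    "shank": 0.411,
    "foot": 0.245,
    "pelvis_to_hip": 0.095,
}

#: foot landmark offsets relative to the calcaneus CoM, generic model, m
FOOT_LANDMARKS = {
    "heel": (0.00363314, 0.00830251, -0.00715492),
    "calc": (0.0, 0.0, 0.0),
    "toe": (0.231826, -0.0107138, -0.0071549),
}

#: ankle joint centre relative to the calcaneus CoM, generic model, m
ANKLE_OFFSET = (0.05, 0.08, 0.0)

#: sagittal foot moment of inertia about its CoM for the generic model, kg m^2
FOOT_INERTIA_Z = 0.0050
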
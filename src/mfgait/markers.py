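"""The 42-marker full-body calibration model.

An extension of the Helen Hayes marker set from 24 to 42 anatomical
landmarks, each tracked in three planes.  Serial numbers run marker-major,
plane-minor (x, y, z), giving channels 1..126; the x/y/z planes map to the
sagittal, coronal and transverse anatomical planes.
"""

from __future__ import annotations

# "R"/"L" = right/left, "A"/"P" = anterior/posterior.
MARKER_NAMES: tuple[str, ...] = (
    "R dorsum of foot",
    "L dorsum of foot",
    "R posterior aspect of the heel",
    "L posterior aspect of the heel",
    "R lateral malleoli",
    "L lateral malleoli",
    "R distal-lateral aspect of the shank",
    "L distal-lateral aspect of the shank",
    "R lateral femoral epicondyle",
    "L lateral femoral epicondyle",
    "R distal-lateral aspect of the thigh",
    "L distal-lateral aspect of the thigh",
    "R anterior superior iliac spine",
    "L anterior superior iliac spine",
    "sacral",
    "R scapular acromion",
    "L scapular acromion",
    "R lateral humeral epicondyles",
    "L lateral humeral epicondyles",
    "R dorsal wrist lines",
    "L dorsal wrist lines",
    "The superior apex of the head",
    "R temple regions",
    "L temple regions",
    "R medial malleoli",
    "L medial malleoli",
    "R medial femoral epicondyles",
    "L medial femoral epicondyles",
    "A lower thorax",
    "P lower thorax",
    "A cervical vertebra",
    "P cervical vertebra",
    "Perineum",
    "R toe",
    "L toe",
    "R heel",
    "L heel",
    "R finger tip",
    "L finger tip",
    "Front Head",
    "Rear Head",
    "R Offset",
)

PLANES: tuple[str, ...] = ("x", "y", "z")

#: anatomical reading of the coordinate planes (configurable in principle;
#: this is the conventional assignment for a forward-walking capture volume)
PLANE_ANATOMY: dict[str, str] = {"x": "sagittal", "y": "coronal", "z": "transverse"}

#: markers of the hip region (anterior superior iliac spines and sacrum)
HIP_MARKERS: tuple[str, ...] = (
    "R anterior superior iliac spine",
    "L anterior superior iliac spine",
    "sacral",
)

N_MARKERS = len(MARKER_NAMES)
N_CHANNELS = N_MARKERS * len(PLANES)

assert N_MARKERS == 42 and N_CHANNELS == 126


def channel_names() -> list[str]:
    """The 126 channel names "<marker>_<plane>" in serial order."""
    return [f"{m}_{p}" for m in MARKER_NAMES for p in PLANES]


def serial_number(marker: str, plane: str) -> int:
    """1-based serial number of a (marker, plane) channel."""
    return MARKER_NAMES.index(marker) * len(PLANES) + PLANES.index(plane) + 1
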
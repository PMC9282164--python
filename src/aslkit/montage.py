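"""Idealized 64-channel 10-20 scalp layout (BioSemi naming) plus mastoids.

Positions are schematic planar coordinates (nose up, left negative x) used
only to shape synthetic spatial topographies; they are not digitized
electrode locations and carry no units.
"""

from __future__ import annotations

import numpy as np

#: The 64 scalp labels of a BioSemi Active-Two cap in 10-20 nomenclature.
BIOSEMI64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8",
    "FC6", "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6",
    "CP4", "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

#: External reference electrodes on the mastoid processes.
MASTOIDS: tuple[str, str] = ("M1", "M2")

# Anterior-posterior row coordinate for each 10-20 row prefix.
_ROW_Y = {
    "Fp": 0.9, "AF": 0.7, "F": 0.5, "FT": 0.35, "FC": 0.25, "C": 0.0,
    "T": 0.0, "TP": -0.35, "CP": -0.25, "P": -0.5, "PO": -0.7, "O": -0.9,
    "I": -1.0,
}
# Lateral coordinate magnitude per 10-20 numeric index.
_COL_X = {0: 0.0, 1: 0.15, 2: 0.15, 3: 0.35, 4: 0.35, 5: 0.55, 6: 0.55,
          7: 0.8, 8: 0.8, 9: 0.95, 10: 0.95}


def _parse(label: str) -> tuple[str, int]:
    if label.endswith("z"):
        return label[:-1], 0
    i = len(label)
    while label[i - 1].isdigit():
        i -= 1
    return label[:i], int(label[i:])


def channel_position(label: str) -> tuple[float, float]:
    """Schematic (x, y) position of a scalp or mastoid channel."""
    if label == "M1":
        return (-1.05, -0.35)
    if label == "M2":
        return (1.05, -0.35)
    row, num = _parse(label)
    # T7/T8 are the lateral continuation of the C row.
    if row == "T":
        x = 0.8
    else:
        x = _COL_X[num]
    if num % 2 == 1 and num != 0:
        x = -x
    return (x, _ROW_Y[row])


def positions(labels) -> np.ndarray:
    """(n, 2) array of schematic positions for ``labels``."""
    return np.array([channel_position(lab) for lab in labels], float)


def spatial_weights(labels, roi_channels, sigma: float = 0.45) -> np.ndarray:
    """Gaussian topography centred on the centroid of an ROI.

    Weight is 1 at the ROI centroid and decays with schematic distance, so
    ROI electrodes carry the largest weights. Mastoids get weight 0 (they
    are reference channels, not scalp signal carriers).
    """
    pos = positions(labels)
    roi = positions(list(roi_channels))
    centroid = roi.mean(axis=0)
    d = np.linalg.norm(pos - centroid, axis=1)
    w = np.exp(-0.5 * (d / sigma) ** 2)
    for i, lab in enumerate(labels):
        if lab in MASTOIDS:
            w[i] = 0.0
    return w
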
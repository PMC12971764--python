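"""Synthetic high-density EEG channel layout.

The recording setup uses a 124-electrode cap of which 8 channels (F8, POz,
AF4, AF8, F6, FC3 and the mastoids M1/M2) are excluded for poor signal
quality, leaving 116 usable channels.  Real montage files are not required
anywhere in the pipeline: channels are placed on a schematic 2-D head grid
(front at y=+1, back at y=-1) which is sufficient to define frontal and
occipital channel groups and a nearest-neighbour graph for the surface
Laplacian.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Channels excluded from analysis for poor signal quality (incl. mastoids).
EXCLUDED_CHANNELS = ["F8", "POz", "AF4", "AF8", "F6", "FC3", "M1", "M2"]

# Rows of the schematic cap, front to back: (labels, y coordinate).
_ROWS = [
    (["Fp1", "Fpz", "Fp2"], 1.00),
    (["AFp1", "AFp2"], 0.95),
    (["AF7", "AF3", "AFz", "AF4", "AF8"], 0.90),
    (["AFF5h", "AFF3h", "AFF1h", "AFF2h", "AFF4h", "AFF6h"], 0.84),
    (["F9", "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8", "F10"], 0.76),
    (["FFC5h", "FFC3h", "FFC1h", "FFC2h", "FFC4h", "FFC6h"], 0.68),
    (["FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10"], 0.58),
    (["FTT7h", "FCC5h", "FCC3h", "FCC1h", "FCC2h", "FCC4h", "FCC6h", "FTT8h"], 0.46),
    (["T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8"], 0.32),
    (["TTP7h", "CCP5h", "CCP3h", "CCP1h", "CCP2h", "CCP4h", "CCP6h", "TTP8h"], 0.18),
    (["TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10"], 0.04),
    (["TPP7h", "CPP5h", "CPP3h", "CPP1h", "CPP2h", "CPP4h", "CPP6h", "TPP8h"], -0.10),
    (["P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10"], -0.24),
    (["PPO5h", "PPO3h", "PPO1h", "PPO2h", "PPO4h", "PPO6h"], -0.38),
    (["PO7", "PO3", "POz", "PO4", "PO8"], -0.52),
    (["POO3", "POO1", "POO2", "POO4"], -0.62),
    (["O1", "Oz", "O2"], -0.72),
    (["OI1h", "OI2h"], -0.80),
    (["I1", "Iz", "I2"], -0.88),
    (["M1", "M2"], -0.95),
]

#: y-threshold above which a channel counts as frontal; below the other, occipital.
_FRONTAL_Y = 0.55
_OCCIPITAL_Y = -0.50


def default_montage() -> pd.DataFrame:
    """Return the 124-channel schematic layout.

    Columns: ``name``, ``x``, ``y``, ``region`` (frontal / central /
    occipital / mastoid).
    """
    rows = []
    for labels, y in _ROWS:
        n = len(labels)
        xs = np.linspace(-1.0, 1.0, n) if n > 1 else np.array([0.0])
        for name, x in zip(labels, xs):
            if name in ("M1", "M2"):
                region = "mastoid"
            elif y >= _FRONTAL_Y:
                region = "frontal"
            elif y <= _OCCIPITAL_Y:
                region = "occipital"
            else:
                region = "central"
            rows.append((name, float(x), float(y), region))
    df = pd.DataFrame(rows, columns=["name", "x", "y", "region"])
    if len(df) != 124 or df["name"].duplicated().any():
        raise AssertionError("montage construction broken")
    return df


def channel_names(include_excluded: bool = True) -> list[str]:
    names = default_montage()["name"].tolist()
    if not include_excluded:
        names = [n for n in names if n not in EXCLUDED_CHANNELS]
    return names


def frontal_channels(names: list[str] | None = None) -> list[str]:
    m = default_montage()
    sel = m.loc[m["region"] == "frontal", "name"].tolist()
    if names is not None:
        sel = [n for n in sel if n in names]
    return sel


def occipital_channels(names: list[str] | None = None) -> list[str]:
    m = default_montage()
    sel = m.loc[m["region"] == "occipital", "name"].tolist()
    if names is not None:
        sel = [n for n in sel if n in names]
    return sel


#: A standard low-density 32-channel subset (none of the excluded channels).
EEG32_CHANNELS = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF7", "F7", "F3", "Fz", "F4", "F5",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8", "CP5",
    "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8", "PO3", "PO4",
    "O1", "O2",
]


def neighbor_map(names: list[str], k: int = 4) -> dict[str, list[str]]:
    """k-nearest-neighbour graph on the schematic layout (Euclidean)."""
    m = default_montage().set_index("name")
    missing = [n for n in names if n not in m.index]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    pos = m.loc[names, ["x", "y"]].to_numpy()
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    kk = min(k, len(names) - 1)
    out: dict[str, list[str]] = {}
    for i, name in enumerate(names):
        idx = np.argsort(d[i], kind="stable")[:kk]
        out[name] = [names[j] for j in idx]
    return out
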
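"""Single-cell mechanomics: sigmoidal dose-response from mechanical signal to rate.

Each cell maps the local mechanical signal (Gaussian-dilated effective
strain, epsilon) to a production or resorption rate through a Hill curve.
The half-maximum point of every curve is the sample-specific mechanostat
threshold ``mechthres`` (0.95x the median signal over trabecular bone voxels
for embedded cells, 0.45x the median over trabecular marrow voxels for
surface/marrow cells).  Orientation encodes the biology: anabolic and
anti-catabolic outputs (osteoid deposition, OPG) increase with strain;
catabolic and anti-anabolic outputs (RANKL, sclerostin, resorption) decrease
with strain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HillCurve:
    """Hill dose-response curve with half-max at ``theta``.

    increasing:  y(e) = y_max * e^h / (e^h + theta^h)
    decreasing:  y(e) = y_max * theta^h / (e^h + theta^h)

    Parameters
    ----------
    y_max : maximum single-cell rate (units of the regulated quantity per
        cell timestep).
    h : Hill coefficient, > 0; steepness of the sigmoid.
    theta : mechanostat threshold (strain units), > 0.
    increasing : orientation of the response.
    """

    y_max: float
    h: float
    theta: float
    increasing: bool = True

    def __post_init__(self):
        if self.y_max < 0:
            raise ValueError("y_max must be >= 0")
        if self.h <= 0:
            raise ValueError("Hill coefficient must be > 0")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")

    def __call__(self, eps):
        return evaluate(self, eps)


def evaluate(curve: HillCurve, eps):
    """Evaluate a Hill curve at strain ``eps`` (scalar or array, >= 0).

    Output lies in [0, y_max]; equals y_max/2 exactly at eps == theta for
    either orientation.
    """
    eps = np.asarray(eps, dtype=float)
    if np.any(eps < 0):
        raise ValueError("mechanical signal must be >= 0")
    # compute in units of theta for numerical robustness
    r = (eps / curve.theta) ** curve.h
    if curve.increasing:
        out = curve.y_max * r / (r + 1.0)
    else:
        out = curve.y_max / (r + 1.0)
    return out if out.ndim else float(out)


#: (cell kind, product) -> orientation.  True = increasing with strain.
ROLE_ORIENTATIONS = {
    ("Ot", "OPG"): True,
    ("Ot", "RANKL"): False,
    ("Ot", "Scl"): False,
    ("Ob", "OPG"): True,
    ("Ob", "RANKL"): False,
    ("lining", "OPG"): True,
    ("lining", "RANKL"): False,
    ("Ob", "osteoid"): True,
    ("Oc", "resorption"): False,
}

#: cell kinds whose curves use the bone mechanostat threshold (embedded in
#: bone); all others use the marrow threshold.
BONE_CELL_KINDS = frozenset({"Ot", "preOt"})


def build_role_table(
    rates: dict,
    mechthres_bone: float,
    mechthres_marrow: float,
) -> dict:
    """Build the (cell kind, product) -> HillCurve map.

    Parameters
    ----------
    rates : mapping ``(kind, product) -> (y_max, h)``.  Every key must be a
        known role (see :data:`ROLE_ORIENTATIONS`).
    mechthres_bone, mechthres_marrow : the sample-specific half-max strains
        for embedded (bone) and surface/marrow cells respectively.
    """
    table = {}
    for key, (y_max, h) in rates.items():
        if key not in ROLE_ORIENTATIONS:
            raise KeyError(f"unknown (cell, product) role: {key}")
        kind, _product = key
        theta = mechthres_bone if kind in BONE_CELL_KINDS else mechthres_marrow
        table[key] = HillCurve(
            y_max=y_max, h=h, theta=theta, increasing=ROLE_ORIENTATIONS[key]
        )
    return table


def curves_to_frame(table: dict, n_points: int = 200, eps_max: float = None):
    """Sample every curve of a role table onto a strain grid (for CSV
    export/plotting): columns ``eps`` plus one ``kind/product`` per role."""
    import pandas as pd

    if eps_max is None:
        eps_max = 4.0 * max(c.theta for c in table.values())
    eps = np.linspace(0.0, eps_max, n_points)
    data = {"eps": eps}
    for (kind, product), curve in sorted(table.items()):
        data[f"{kind}/{product}"] = curve(eps)
    return pd.DataFrame(data)
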
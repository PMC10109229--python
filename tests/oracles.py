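"""Independent brute-force oracles used to verify the statistical routines.

These deliberately take the dumbest correct route — explicit one-hot design
matrices and nested least-squares fits — and share no code with the package's
closed-form implementations.
"""
from __future__ import annotations

import math

import numpy as np


def split_plot_oracle(groups, Y) -> dict[str, float]:
    """Sequential sums of squares of the split-plot design by nested RSS.

    Fits the model sequence 1 -> +group -> +subject -> +period ->
    +period:group with explicit indicator design matrices and returns the
    RSS differences (group, subject-within-group, period, interaction,
    residual).
    """
    groups = np.asarray(groups)
    Y = np.asarray(Y, dtype=float)
    N, p = Y.shape
    y = Y.ravel()
    subj = np.repeat(np.arange(N), p)
    per = np.tile(np.arange(p), N)
    _, ginv = np.unique(groups, return_inverse=True)
    g = np.repeat(ginv, p)

    def onehot(codes):
        return np.eye(codes.max() + 1)[codes]

    ones = np.ones((N * p, 1))
    designs = [
        ones,
        np.hstack([ones, onehot(g)]),
        np.hstack([ones, onehot(subj)]),
        np.hstack([ones, onehot(subj), onehot(per)]),
        np.hstack([ones, onehot(subj), onehot(per), onehot(g * p + per)]),
    ]
    rss = []
    for X in designs:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss.append(float(r @ r))
    return {
        "group": rss[0] - rss[1],
        "subject(group)": rss[1] - rss[2],
        "period": rss[2] - rss[3],
        "period:group": rss[3] - rss[4],
        "residual": rss[4],
    }


def spherical_law_of_cosines_km(a, b, radius_km: float = 6371.0) -> float:
    """Great-circle distance via the spherical law of cosines (not haversine)."""
    phi1, phi2 = math.radians(a[0]), math.radians(b[0])
    dlam = math.radians(b[1] - a[1])
    cosc = (math.sin(phi1) * math.sin(phi2)
            + math.cos(phi1) * math.cos(phi2) * math.cos(dlam))
    return radius_km * math.acos(max(-1.0, min(1.0, cosc)))
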
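"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid numpy vectorisation and any code path shared with
the package: plain Python loops and math functions only.
"""
from __future__ import annotations

import math


def brute_force_features(t, x, y):
    """Naive double-loop computation of the 15 window features."""
    speeds, angles, tas = [], [], []
    disps = []
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        dx = x[i + 1] - x[i]
        dy = y[i + 1] - y[i]
        speeds.append(math.sqrt(dx * dx + dy * dy) / dt)
        disps.append((dx, dy))
    for i in range(len(disps) - 1):
        (ax, ay), (bx, by) = disps[i], disps[i + 1]
        na = math.sqrt(ax * ax + ay * ay)
        nb = math.sqrt(bx * bx + by * by)
        if na < 1e-9 or nb < 1e-9:
            ang = 0.0
        else:
            c = (ax * bx + ay * by) / (na * nb)
            ang = math.acos(max(-1.0, min(1.0, c)))
        angles.append(ang)
        tas.append(speeds[i + 1] * math.cos(ang))

    def stats(vals):
        n = len(vals)
        mean = sum(vals) / n
        var = sum((v - mean) ** 2 for v in vals) / n  # population form
        return {
            "mean": mean,
            "sd": math.sqrt(var),
            "sum": sum(vals),
            "max": max(vals),
            "min": min(vals),
        }

    out = {}
    for name, vals in (
        ("speed", speeds),
        ("turning_angle", angles),
        ("turning_angle_speed", tas),
    ):
        for stat, v in stats(vals).items():
            out[f"{name}_{stat}"] = v
    return out


def brute_force_moving_average(t, values, window_s):
    """O(n^2) centered moving average with edge truncation."""
    half = window_s / 2.0
    out = []
    for i in range(len(t)):
        members = [values[j] for j in range(len(t)) if abs(t[j] - t[i]) <= half]
        out.append(sum(members) / len(members))
    return out


def spearman_rho(a, b):
    """Textbook Spearman rho for untied vectors: 1 - 6*sum(d^2)/(n(n^2-1))."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0] * len(v)
        for rank, i in enumerate(order, start=1):
            r[i] = rank
        return r

    ra, rb = ranks(a), ranks(b)
    n = len(a)
    d2 = sum((x - y) ** 2 for x, y in zip(ra, rb))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))
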
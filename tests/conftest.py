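import numpy as np
import pandas as pd
import pytest

from geoihc.types import Intensity, Marker, ROI, Window


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def square_window():
    return Window(1000.0, 1000.0)


def make_roi(cells, window, patient_id="P1", roi_id="R1"):
    """Build an ROI from (x, y, marker, intensity) tuples."""
    df = pd.DataFrame(cells, columns=["x", "y", "marker", "intensity"])
    df["marker"] = df["marker"].map(lambda m: m.value if isinstance(m, Marker) else m)
    df["intensity"] = df["intensity"].map(
        lambda i: i.value if isinstance(i, Intensity) else i)
    return ROI(patient_id=patient_id, roi_id=roi_id, window=window, cells=df)


def arc_fraction_oracle(center, d, window, n_angles=10**6):
    """Numeric oracle for the in-window circumference fraction.

    Samples the circle at equally spaced angles and refines every
    inside/outside transition by bisection, yielding the exact arc measure
    to ~1e-12 independent of the closed-form geometry under test.
    """
    cx, cy = center
    thetas = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)

    def inside(theta):
        x = cx + d * np.cos(theta)
        y = cy + d * np.sin(theta)
        return (x >= 0) & (x <= window.width) & (y >= 0) & (y <= window.height)

    ins = inside(thetas)
    if ins.all():
        return 1.0
    flips = np.flatnonzero(ins != np.roll(ins, -1))
    crossings = []
    step = 2.0 * np.pi / n_angles
    for i in flips:
        lo, hi = thetas[i], thetas[i] + step
        lo_in = bool(ins[i])
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if bool(inside(np.array([mid]))[0]) == lo_in:
                lo = mid
            else:
                hi = mid
        crossings.append((0.5 * (lo + hi), lo_in))
    total = 0.0
    for k, (theta, was_in) in enumerate(crossings):
        if was_in:  # interval entering at previous crossing ends here
            prev = crossings[k - 1][0]
            length = theta - prev
            if length < 0:
                length += 2.0 * np.pi
            total += length
    return total / (2.0 * np.pi)


def naive_bivariate_k(pp_from, pp_to, r):
    """Double-loop Ripley's K oracle sharing only the edge-weight geometry."""
    from geoihc.spatial import arc_fraction_inside

    same = pp_from is pp_to or (
        pp_from.marker == pp_to.marker
        and np.array_equal(pp_from.points, pp_to.points))
    n_f, n_t = pp_from.n, pp_to.n
    weights = np.zeros((n_f, n_t))
    for i in range(n_f):
        for j in range(n_t):
            if same and i == j:
                continue
            dx = pp_from.points[i, 0] - pp_to.points[j, 0]
            dy = pp_from.points[i, 1] - pp_to.points[j, 1]
            dist = float(np.sqrt(dx * dx + dy * dy))
            if dist > r:
                continue
            if dist == 0.0:
                if same:
                    continue
                weights[i, j] = 1.0
            else:
                weights[i, j] = 1.0 / arc_fraction_inside(
                    (pp_from.points[i, 0], pp_from.points[i, 1]), dist,
                    pp_from.window)
    denom = n_f * (n_t - 1) if same else n_f * n_t
    return pp_from.window.area * float(np.sum(weights)) / denom


def brute_logrank(times, events, groups):
    """Risk-table log-rank oracle: explicit loop over event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    g1 = groups == labels[1]
    o_minus_e, var = 0.0, 0.0
    for u in np.unique(times[events == 1]):
        at_risk = times >= u
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == u) & (events == 1)).sum()
        d1 = ((times == u) & (events == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e * o_minus_e / var if var > 0 else 0.0
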
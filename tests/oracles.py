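"""Independent reference implementations used only as test oracles."""

from itertools import combinations

import numpy as np

MU0_OVER_4PI = 1e-7


def sarvas_field_complex_step(source_pos, moment, field_pt, center):
    """Dipole-in-sphere magnetic field via the scalar-potential route.

    Outside a spherical conductor, B = (mu0/4pi) * grad[(A . r)/F] with
    A = Q x r_q and F(r) = a (r a + r^2 - r_q . r).  The gradient is taken
    by complex-step differentiation of that scalar, which shares no code
    path with the closed-form implementation under test and is exact to
    machine precision.
    """
    center = np.asarray(center, float)
    rq = np.asarray(source_pos, float) - center
    a_vec = np.cross(np.asarray(moment, float), rq)

    def g(r):
        a = r - rq
        an = np.sqrt(np.sum(a * a))
        rn = np.sqrt(np.sum(r * r))
        f = an * (rn * an + rn**2 - rq @ r)
        return (a_vec @ r) / f

    base = np.asarray(field_pt, float) - center
    h = 1e-20
    out = np.zeros(3)
    for i in range(3):
        r = base.astype(complex)
        r[i] += 1j * h
        out[i] = g(r).imag / h
    return MU0_OVER_4PI * out


def gradiometer_signal_oracle(source_pos, moment, sensors, center):
    """Per-channel axial-gradiometer signals from the complex-step oracle."""
    out = np.zeros(sensors.n_channels)
    for ch in range(sensors.n_channels):
        bi = sarvas_field_complex_step(
            source_pos, moment, sensors.positions_inner[ch], center
        )
        bo = sarvas_field_complex_step(
            source_pos, moment, sensors.positions_outer[ch], center
        )
        out[ch] = (bi - bo) @ sensors.axes[ch]
    return out


def permutation_p_bruteforce(x, y):
    """Exact two-sided permutation p-values by enumerating all group splits."""
    x = np.atleast_2d(np.asarray(x, float))
    y = np.atleast_2d(np.asarray(y, float))
    data = np.vstack([x, y])
    n1, n = x.shape[0], data.shape[0]
    t_obs = x.mean(axis=0) - y.mean(axis=0)
    count = np.zeros(data.shape[1])
    total = 0
    for idx in combinations(range(n), n1):
        rest = [i for i in range(n) if i not in idx]
        t = data[list(idx)].mean(axis=0) - data[rest].mean(axis=0)
        count += np.abs(t) >= np.abs(t_obs) * (1.0 - 1e-9)
        total += 1
    return count / total


def bh_qvalues_reference(p):
    """Benjamini-Hochberg step-up by the textbook definition."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = running
    return q


def fisher_two_sided_bruteforce(a, b, c, d):
    """Two-sided Fisher p: sum hypergeometric probs <= observed table's."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return total
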
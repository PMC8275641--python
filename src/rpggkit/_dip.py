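"""Hartigan's dip statistic of unimodality.

The dip of an empirical distribution function F_n is the smallest sup-norm
distance between F_n and any unimodal distribution function.  It is
computed with the classic greatest-convex-minorant / least-concave-
majorant iteration over the shrinking modal interval; the result is in
[1/(2n), 1/4], reaching 1/4 for an equal two-point mixture.  Significance
is assessed by simulating the dip of uniform samples of the same size
(the asymptotically least-favourable unimodal distribution): a large
p-value means the data look strongly unimodal.
"""

from __future__ import annotations

import numpy as np


def dip_statistic(x) -> float:
    """Dip statistic of a 1-d sample (ties allowed)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    if n < 4:
        return 1.0 / (2 * n)

    # mn[j]: previous touch point of the greatest convex minorant through j
    mn = np.zeros(n, dtype=int)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj
    # mj[k]: next touch point of the least concave majorant through k
    mj = np.zeros(n, dtype=int)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (
                x[mjk] - x[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    dip = 1.0  # in units of counts; divided by 2n at the end

    while True:
        # gcm touch points from high down to low, lcm from low up to high
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(mn[gcm[-1]])
        l_gcm = len(gcm)
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(mj[lcm[-1]])
        l_lcm = len(lcm)

        d = 0.0
        ig = l_gcm - 1
        ih = l_lcm - 1
        if l_gcm != 2 or l_lcm != 2:
            ix = l_gcm - 2
            iv = 1
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    # next point along the merged walk comes from the lcm
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / (
                        x[lcmiv] - x[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 0:
                    ix = 0
                if iv > l_lcm - 1:
                    iv = l_lcm - 1
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # max deviation of F_n above the gcm within the retained stretch
        dl = 0.0
        for j in range(ig, l_gcm - 1):
            temp = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * c
                    if temp < t:
                        temp = t
            if dl < temp:
                dl = temp
        # max deviation of F_n below the lcm
        du = 0.0
        for j in range(ih, l_lcm - 1):
            temp = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                c = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (x[jj] - x[jb]) * c - (jj - jb - 1)
                    if temp < t:
                        temp = t
            if du < temp:
                du = temp

        dipnew = max(dl, du)
        if dip < dipnew:
            dip = dipnew
        if low == gcm[ig] and high == lcm[ih]:
            break
        low = gcm[ig]
        high = lcm[ih]

    return dip / (2.0 * n)


def dip_pvalue(
    x, n_boot: int = 200, rng: np.random.Generator | None = None
) -> tuple[float, float]:
    """(dip, p) with p from a uniform-sample reference of the same size.

    p is the fraction of uniform-sample dips at least as large as the
    observed one (add-one corrected); p > 0.9 indicates data more strongly
    unimodal than typical uniform noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    d = dip_statistic(x)
    boots = np.array(
        [dip_statistic(rng.uniform(size=len(x))) for _ in range(n_boot)]
    )
    p = (1.0 + np.sum(boots >= d)) / (1.0 + n_boot)
    return d, float(p)
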
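"""Hartigan dip test for unimodality of recombination-strength profiles.

When a hotspot segregates hot and cold alleles the distribution of
per-haplotype strengths tends to be bimodal; when every haplotype carries
the same allele it tends to be unimodal.  The dip statistic — the largest
sup-norm distance between the empirical CDF and the closest unimodal CDF —
separates the two regimes.  Profiles whose dip test is non-significant
(no evidence of strength variation) are filtered out before association
analysis; the operating threshold on −log10(p) is 2.473.

The dip statistic is computed with the greatest-convex-minorant /
least-concave-majorant algorithm of Hartigan & Hartigan, in exact
count units with a single final rescaling.  The p-value is Monte-Carlo,
against the standard conservative uniform(0,1) null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DipResult", "dip_statistic", "dip_pvalue", "filter_hotspots", "DIP_THRESHOLD"]

#: −log10(p) operating threshold separating variable from flat profiles.
DIP_THRESHOLD = 2.473


@dataclass(frozen=True)
class DipResult:
    """Dip statistic with its Monte-Carlo p-value."""

    dip: float
    p_value: float
    neg_log10_p: float
    n: int
    n_null: int


def dip_statistic(values: Sequence[float] | np.ndarray) -> float:
    """Hartigan & Hartigan dip statistic of a univariate sample.

    The statistic is the sup-norm distance between the empirical CDF and
    the nearest unimodal CDF, computed by iteratively shrinking a candidate
    modal interval bounded by the greatest convex minorant (below) and the
    least concave majorant (above) of the empirical CDF.  It is invariant
    under strictly increasing transforms of the data and bounded below by
    ``1/(2n)``.

    Parameters
    ----------
    values : array-like
        At least 4 finite values, not all equal.

    Raises
    ------
    ValueError
        If ``n < 4``, any value is non-finite, or the sample is degenerate
        (all values equal).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"dip statistic needs n >= 4 values, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip statistic requires finite values")
    if x[0] == x[-1]:
        raise ValueError("degenerate sample: all values equal")

    # 1-based arrays mirroring the classical algorithm; index i has ECDF
    # value i/n at x[i] and (i-1)/n just below it.
    xs = np.empty(n + 1)
    xs[1:] = x

    # Convex-minorant predecessor pointers over the full range.
    mn = np.zeros(n + 1, dtype=np.int64)
    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xs[j] - xs[mnj]) * (mnj - mnmnj) < (xs[mnj] - xs[mnmnj]) * (
                j - mnj
            ):
                break
            mn[j] = mnmnj

    # Concave-majorant successor pointers.
    mj = np.zeros(n + 1, dtype=np.int64)
    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xs[k] - xs[mjk]) * (mjk - mjmjk) < (xs[mjk] - xs[mjmjk]) * (
                k - mjk
            ):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # count units; enforces the 1/(2n) lower bound
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    while True:
        # Touch points of the GCM from high down to low, and of the LCM
        # from low up to high, restricted to the current modal interval.
        gcm[1] = high
        i = 1
        while gcm[i] > low:
            gcm[i + 1] = mn[gcm[i]]
            i += 1
        ig = l_gcm = i

        lcm[1] = low
        i = 1
        while lcm[i] < high:
            lcm[i + 1] = mj[lcm[i]]
            i += 1
        ih = l_lcm = i

        ix, iv = l_gcm - 1, 2

        # Largest gap d between the LCM (above) and GCM (below) curves.
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    # LCM touch point falls inside a GCM segment.
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xs[lcmiv] - xs[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xs[gcmix] - xs[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    # GCM touch point falls inside an LCM segment.
                    lcmiv1 = lcm[iv - 1]
                    dx = (xs[gcmix] - xs[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xs[lcmiv] - xs[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # Max deviation of the ECDF from the GCM left of the new modal
        # interval, and from the LCM right of it.
        dip_l = 0.0
        for j in range(ig, l_gcm):
            max_t = 1.0
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (xs[jj] - xs[jb]) * c
                    if max_t < t:
                        max_t = t
            if dip_l < max_t:
                dip_l = max_t

        dip_u = 0.0
        for j in range(ih, l_lcm):
            max_t = 1.0
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and xs[je] != xs[jb]:
                c = (je - jb) / (xs[je] - xs[jb])
                for jj in range(jb, je + 1):
                    t = (xs[jj] - xs[jb]) * c - (jj - jb - 1)
                    if max_t < t:
                        max_t = t
            if dip_u < max_t:
                dip_u = max_t

        dip = max(dip, dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break  # modal interval no longer shrinks: converged
        low, high = gcm[ig], lcm[ih]

    return dip / (2 * n)


# Null dip tables, keyed by (n, n_null, seed); shared across profiles so a
# batch of same-sized profiles pays for one table.
_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_table(n: int, n_null: int, seed: int) -> np.ndarray:
    key = (n, n_null, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.asarray(
            [dip_statistic(rng.random(n)) for _ in range(n_null)]
        )
    return _NULL_CACHE[key]


def dip_pvalue(
    d: float, n: int, n_null: int = 10_000, seed: int = 20150901
) -> DipResult:
    """Monte-Carlo p-value of a dip statistic under the uniform(0,1) null.

    ``p = (1 + #{D*_null >= D}) / (1 + n_null)`` with null samples of size
    ``n``; the +1 correction keeps p strictly positive.  Deterministic
    given ``seed``; the null table is cached per sample size.
    """
    if n_null < 100:
        import warnings

        warnings.warn(f"n_null={n_null} < 100 gives unstable p-values")
    null = _null_table(n, n_null, seed)
    p = (1 + int(np.count_nonzero(null >= d))) / (1 + n_null)
    return DipResult(d, p, -math.log10(p), n, n_null)


def filter_hotspots(
    profiles: Iterable,
    threshold: float = DIP_THRESHOLD,
    *,
    n_null: int = 10_000,
    seed: int = 20150901,
    use: str = "probabilities",
) -> pd.DataFrame:
    """Dip-test each profile and keep those with −log10(p) ≥ threshold.

    Since the dip statistic is scale-free, testing the probability profile
    V_p is equivalent to testing the raw strengths V_L; V_p is used.
    Degenerate profiles (all strengths equal, or fewer than 4 haplotypes)
    are dropped with reason "degenerate" rather than silently.

    Returns a report table with one row per profile:
    ``hotspot_id, dip, p, neg_log10_p, decision, reason``.
    """
    rows = []
    for prof in profiles:
        vals = prof.values(use)
        try:
            d = dip_statistic(vals)
        except ValueError:
            rows.append(
                {
                    "hotspot_id": prof.hotspot_id,
                    "dip": np.nan,
                    "p": np.nan,
                    "neg_log10_p": np.nan,
                    "decision": "drop",
                    "reason": "degenerate",
                }
            )
            continue
        res = dip_pvalue(d, vals.size, n_null=n_null, seed=seed)
        keep = res.neg_log10_p >= threshold
        rows.append(
            {
                "hotspot_id": prof.hotspot_id,
                "dip": res.dip,
                "p": res.p_value,
                "neg_log10_p": res.neg_log10_p,
                "decision": "keep" if keep else "drop",
                "reason": "" if keep else "unimodal",
            }
        )
    return pd.DataFrame(
        rows, columns=["hotspot_id", "dip", "p", "neg_log10_p", "decision", "reason"]
    )


def write_report(report: pd.DataFrame, path) -> None:
    """Write the filter report as TSV (hotspot_id, dip, p, neg_log10_p, decision)."""
    report.to_csv(path, sep="\t", index=False)
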
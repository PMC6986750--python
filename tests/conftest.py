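import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_daily_climate():
    """Three whole years of deterministic daily weather (leap year included)."""
    dates = pd.date_range("2010-01-01", "2012-12-31", freq="D")
    # rain every 3rd day: dry spells of length 2 everywhere
    precip = np.where(np.arange(len(dates)) % 3 == 0, 5.0, 0.0)
    temp = 15.0 - 10.0 * np.cos(2 * np.pi * (dates.dayofyear - 15) / 365.25)
    return pd.DataFrame({"date": dates, "tmean_c": temp, "precip_mm": precip})


def brute_force_monthly_dry_index(daily: pd.DataFrame, k: int, wet_cutoff: float = 0.0):
    """Independent day-enumeration oracle for the dry-period index.

    Walks the daily series, marks each day with the full length of the
    maximal dry run containing it, and sums per calendar month the days
    whose run length is >= k.
    """
    d = daily.sort_values("date").reset_index(drop=True)
    dry = (d["precip_mm"] <= wet_cutoff).to_numpy()
    n = len(d)
    run_len = np.zeros(n, dtype=int)
    i = 0
    while i < n:
        if dry[i]:
            j = i
            while j < n and dry[j]:
                j += 1
            run_len[i:j] = j - i
            i = j
        else:
            i += 1
    out = {}
    for i in range(n):
        if dry[i] and run_len[i] >= k:
            ts = d.loc[i, "date"]
            key = (ts.year, ts.month)
            out[key] = out.get(key, 0) + 1
    return out


def brute_force_biweight(values, c=9.0, n_iter=200):
    """Direct fixed-point iteration of the biweight location, no shortcuts."""
    x = np.asarray(values, float)
    m = float(np.median(x))
    for _ in range(n_iter):
        s = float(np.median(np.abs(x - m)))
        if s == 0:
            return m
        u = (x - m) / (c * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return m
        m = float((w * x).sum() / w.sum())
    return m
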
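"""Independent reference implementations used to check the package.

Everything here is deliberately brute-force / closed-form and shares no code
with the library paths it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

DAY_MAX = 182


def rounded_truncnorm_moments(mu: float, sd: float) -> tuple[float, float]:
    """Exact mean and SD of round(X), X ~ Normal(mu, sd) truncated to [0, 182].

    Computed from the discrete distribution: day k collects the truncated
    mass on (k-1/2, k+1/2], clipped to the support at the edges.
    """
    if sd == 0:
        return float(round(mu)), 0.0
    z = norm.cdf((DAY_MAX - mu) / sd) - norm.cdf((0 - mu) / sd)
    k = np.arange(0, DAY_MAX + 1)
    lo = np.clip(k - 0.5, 0, DAY_MAX)
    hi = np.clip(k + 0.5, 0, DAY_MAX)
    p = (norm.cdf((hi - mu) / sd) - norm.cdf((lo - mu) / sd)) / z
    mean = float((k * p).sum())
    var = float((k**2 * p).sum()) - mean**2
    return mean, float(np.sqrt(max(var, 0.0)))


def brute_force_pared_mean(
    regions: list[tuple[str, int, float]], threshold_fraction: float
) -> tuple[float, list[str]]:
    """Enumerate ranking prefixes; return the minimal qualifying one.

    regions: (region_id, n, mean) with n > 0. Ranking: ascending mean, ties
    broken by larger n then region_id.
    """
    ranked = sorted(regions, key=lambda r: (r[2], -r[1], r[0]))
    total = sum(n for _, n, _ in ranked)
    need = threshold_fraction * total
    for k in range(1, len(ranked) + 1):
        prefix = ranked[:k]
        if sum(n for _, n, _ in prefix) >= need:
            num = sum(n * m for _, n, m in prefix)
            den = sum(n for _, n, _ in prefix)
            return num / den, [rid for rid, _, _ in prefix]
    raise AssertionError("threshold unreachable")


def brute_force_weekly_counts(
    visit_rows: list[tuple[str, int, str]], window_days: int = DAY_MAX
) -> dict[int, tuple[int, int]]:
    """Recount weekly standard/EOL patients from (patient, days-before-death,
    effective intent) rows by direct per-patient/per-week enumeration."""
    n_weeks = window_days // 7
    per: dict[tuple[str, int], bool] = {}
    for pid, days_before, intent in visit_rows:
        if not 0 <= days_before <= window_days:
            continue
        week = min(max(n_weeks - days_before // 7, 1), n_weeks)
        key = (pid, week)
        per[key] = per.get(key, False) or intent == "eol"
    counts = {w: [0, 0] for w in range(1, n_weeks + 1)}
    for (_, week), is_eol in per.items():
        counts[week][1 if is_eol else 0] += 1
    return {w: (c[0], c[1]) for w, c in counts.items()}
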
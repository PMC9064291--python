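"""Summary statistics, fold changes, traversal arithmetic, and the paired
permutation test for drug-versus-control count tables.

The permutation test treats each matched category (for example: one animal's
subapical group density at one timepoint, drug versus vehicle control) as a
pair.  Under the null hypothesis of no drug effect the two labels within a
pair are exchangeable, so the null distribution of the statistic — the mean
paired difference of length-normalised counts — is generated by independently
flipping the sign of each pair's difference.  For small numbers of pairs all
2^n sign patterns are enumerated exactly; otherwise the flips are sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compartments import GroupCountRecord

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, sample SD (n-1 denominator) and SEM = SD/sqrt(n)."""

    n: int
    mean: float
    sd: float
    sem: float
    defined: bool  # False when n == 1 (SD/SEM undefined)


@dataclass(frozen=True)
class PairedPermutationResult:
    """Observed mean paired difference and its permutation p-value."""

    observed_stat: float
    n_pairs: int
    n_resamples: int
    p_value: float
    exact: bool
    seed: int | None
    alternative: str = "two-sided"
    statistic_name: str = "mean paired difference (drug - control)"


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample SD and SEM of a sequence of measurements.

    SD uses the n-1 denominator; SEM = SD / sqrt(n).  A single observation
    has undefined SD/SEM, returned as NaN with ``defined=False``.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("summarize requires at least one value")
    if v.size == 1:
        return SummaryStats(1, float(v[0]), math.nan, math.nan, defined=False)
    sd = float(np.std(v, ddof=1))
    return SummaryStats(
        n=int(v.size),
        mean=float(v.mean()),
        sd=sd,
        sem=sd / math.sqrt(v.size),
        defined=True,
    )


def sem_from_sd(sd: float, n: int) -> float:
    """SEM from a known sample SD and n."""
    if n < 2:
        raise ValueError("SEM needs n >= 2")
    return sd / math.sqrt(n)


def paired_permutation_test(
    pairs: Sequence[tuple[float, float]],
    n_resamples: int = 10_000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> PairedPermutationResult:
    """Sign-flip permutation test on paired (drug, control) values.

    The statistic is the mean of drug − control differences.  When
    ``2**n_pairs <= n_resamples`` the full sign-pattern distribution is
    enumerated and the p-value is the exact tail proportion; otherwise
    ``n_resamples`` random sign patterns are drawn and the p-value uses the
    add-one correction ``(1 + hits) / (1 + B)`` so it is never zero.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (drug, control) tuples")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if np.isnan(arr).any():
        raise ValueError("pairs contain missing values")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = arr[:, 0] - arr[:, 1]
    n = d.size
    t_obs = float(d.mean())

    exact = 2**n <= n_resamples
    if exact:
        patterns = np.arange(2**n, dtype=np.int64)
        signs = ((patterns[:, None] >> np.arange(n)) & 1) * 2 - 1
        t_null = signs @ d / n
        p = _tail_proportion(t_null, t_obs, alternative)
        b = 2**n
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        block = 200_000 // max(n, 1) + 1
        drawn = 0
        while drawn < n_resamples:
            k = min(block, n_resamples - drawn)
            signs = rng.integers(0, 2, size=(k, n)) * 2 - 1
            t_null = signs @ d / n
            hits += int(_tail_count(t_null, t_obs, alternative))
            drawn += k
        p = (1 + hits) / (1 + n_resamples)
        b = n_resamples
    return PairedPermutationResult(
        observed_stat=t_obs,
        n_pairs=n,
        n_resamples=b,
        p_value=float(p),
        exact=exact,
        seed=seed,
        alternative=alternative,
    )


def _tail_count(t_null: np.ndarray, t_obs: float, alternative: str) -> int:
    if alternative == "two-sided":
        return int((np.abs(t_null) >= abs(t_obs) - _TIE_EPS).sum())
    if alternative == "greater":
        return int((t_null >= t_obs - _TIE_EPS).sum())
    return int((t_null <= t_obs + _TIE_EPS).sum())


def _tail_proportion(t_null: np.ndarray, t_obs: float, alternative: str) -> float:
    return _tail_count(t_null, t_obs, alternative) / t_null.size


def pair_records(
    records: Sequence[GroupCountRecord],
    pair_on: Sequence[str] = ("animal_id", "timepoint", "compartment"),
    value: str = "normalized_per_100um",
) -> list[tuple[float, float]]:
    """Form (drug, control) value pairs from a count table.

    ``pair_on`` names the category key — every key must occur exactly once
    per condition.  The pairing key is deliberately an argument: whether
    pairs are per-compartment or pooled is an analysis decision.
    """
    from .compartments import records_to_frame

    df = records_to_frame(records)
    pair_on = list(pair_on)
    pivot = df.pivot_table(
        index=pair_on, columns="condition", values=value, aggfunc="sum"
    )
    for cond in ("drug", "control"):
        if cond not in pivot.columns:
            raise ValueError(f"count table has no {cond!r} records")
    if pivot[["drug", "control"]].isna().any().any():
        bad = pivot.index[pivot[["drug", "control"]].isna().any(axis=1)].tolist()
        raise ValueError(f"unpaired categories: {bad}")
    return list(zip(pivot["drug"].to_numpy(), pivot["control"].to_numpy()))


def fold_change(drug: GroupCountRecord, control: GroupCountRecord) -> float:
    """Ratio of drug to control length-normalised densities.

    Both records must describe the same compartment and timepoint; a zero
    control density has no defined ratio.
    """
    if drug.compartment != control.compartment or drug.timepoint != control.timepoint:
        raise ValueError("fold change requires matching compartment and timepoint")
    if control.normalized_per_100um <= 0:
        raise ZeroDivisionError("fold change undefined for zero control density")
    return drug.normalized_per_100um / control.normalized_per_100um


def traversal_time(distance_um: float, rate_um_per_min: float) -> float:
    """Hours needed to cover a distance at a constant rate, to 2 decimals.

    At the fastest observed migration rate this bounds from below the time a
    centriole group needs to cross the epithelium.
    """
    if rate_um_per_min <= 0:
        raise ValueError("rate must be positive")
    if distance_um < 0:
        raise ValueError("distance must be non-negative")
    return round(distance_um / rate_um_per_min / 60.0, 2)
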
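"""Estimation statistics for progeny-count comparisons.

Cumming-plot style reporting for fertility assays: the effect of a genotype
is the mean difference in adult progeny per fly against a shared control,
with a bias-corrected-and-accelerated (BCa) bootstrap 95% confidence
interval; significance is reported as the interval excluding zero.  A
label-permutation test supplies a non-parametric two-sided p-value with the
plus-one correction, so p is never exactly zero and "p < 1/(1+n_perm)" is
unattainable by construction.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectEstimate",
    "bootstrap_mean_diff",
    "permutation_test",
    "compare_to_control",
    "read_fertility_tsv",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Mean difference (test - control) with a bootstrap interval."""

    mean_diff: float
    ci_low: float
    ci_high: float
    n_boot: int
    significant: bool


def _as_counts(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} group is empty")
    return arr


def bootstrap_mean_diff(
    control: Sequence[float],
    test: Sequence[float],
    n_boot: int = 5000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> EffectEstimate:
    """BCa bootstrap interval for the mean difference test - control.

    Each group is resampled with replacement ``n_boot`` times.  Constant
    data (both groups without variation) yields the degenerate point
    interval, which the BCa machinery cannot produce on its own.
    """
    ctrl = _as_counts(control, "control")
    tst = _as_counts(test, "test")
    if ctrl.size < 2 or tst.size < 2:
        raise ValueError("both groups need at least two observations")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    diff = float(tst.mean() - ctrl.mean())
    if np.ptp(ctrl) == 0 and np.ptp(tst) == 0:
        return EffectEstimate(diff, diff, diff, n_boot, significant=diff != 0)

    def statistic(c, t, axis=-1):
        return np.mean(t, axis=axis) - np.mean(c, axis=axis)

    res = stats.bootstrap(
        (ctrl, tst),
        statistic,
        n_resamples=n_boot,
        confidence_level=ci_level,
        method="BCa",
        random_state=np.random.default_rng(seed),
    )
    lo = float(res.confidence_interval.low)
    hi = float(res.confidence_interval.high)
    return EffectEstimate(
        mean_diff=diff,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        significant=bool(lo > 0 or hi < 0),
    )


def permutation_test(
    control: Sequence[float],
    test: Sequence[float],
    n_perm: int = 10000,
    seed: int | None = None,
) -> float:
    """Two-sided label-permutation p-value for the mean difference.

    p = (1 + #{permutations with |mean diff| >= observed}) / (1 + n_perm);
    group labels are reshuffled without replacement.
    """
    ctrl = _as_counts(control, "control")
    tst = _as_counts(test, "test")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([ctrl, tst])
    n_c = ctrl.size
    observed = abs(tst.mean() - ctrl.mean())
    # Vectorized label shuffles: argsort of uniform keys is a uniform
    # permutation per row.
    keys = rng.random((n_perm, pooled.size))
    order = np.argsort(keys, axis=1)
    shuffled = pooled[order]
    diffs = np.abs(
        shuffled[:, n_c:].mean(axis=1) - shuffled[:, :n_c].mean(axis=1)
    )
    exceed = int(np.sum(diffs >= observed - 1e-12))
    return (1 + exceed) / (1 + n_perm)


def compare_to_control(
    counts: Mapping[str, Sequence[float]] | pd.DataFrame,
    control_genotype: str,
    n_boot: int = 5000,
    n_perm: int = 10000,
    seed: int | None = None,
) -> dict[str, dict]:
    """Shared-control comparison of every genotype against the control.

    Accepts either a genotype -> counts mapping or a long-format table with
    ``genotype`` and ``progeny_count`` columns.  Returns one record per
    non-control genotype: mean difference, BCa interval, significance and
    permutation p.
    """
    if isinstance(counts, pd.DataFrame):
        counts = {
            g: df["progeny_count"].to_numpy()
            for g, df in counts.groupby("genotype", sort=False)
        }
    if control_genotype not in counts:
        raise KeyError(f"control genotype {control_genotype!r} not in data")
    ctrl = counts[control_genotype]
    out: dict[str, dict] = {}
    for genotype, values in counts.items():
        if genotype == control_genotype:
            continue
        # Stable per-genotype substreams derived from the master seed.
        sub = np.random.default_rng([zlib.crc32(genotype.encode()), seed or 0])
        s1, s2 = sub.integers(2**31, size=2)
        est = bootstrap_mean_diff(ctrl, values, n_boot=n_boot, seed=int(s1))
        p = permutation_test(ctrl, values, n_perm=n_perm, seed=int(s2))
        out[genotype] = {
            "mean_diff": est.mean_diff,
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "n_boot": est.n_boot,
            "significant": est.significant,
            "permutation_p": p,
        }
    return out


def read_fertility_tsv(path: str | Path) -> pd.DataFrame:
    """Long-format fertility table: genotype, sex, progeny_count."""
    # keep_default_na: genotype labels like "null" or "NA" are real names.
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    required = {"genotype", "progeny_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fertility table missing columns: {sorted(missing)}")
    return df
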
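"""Resampling and classical statistics: the probe-label permutation null for
DMR clustering, Benjamini–Hochberg adjustment, Mann–Kendall trend, Pearson
chi-squared and the regression-slope ANOVA.

The permutation scheme shuffles probe ids over methylation value rows,
decoupling genomic coordinates from values while preserving every per-row
effect — exactly the null needed to ask whether differential probes cluster
in space more than chance allows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# multiple testing

def adjust_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values.

    ``q_i = min_{j: p_(j) >= p_i} m * p_(j) / j`` capped at 1; NaN inputs
    yield NaN outputs and do not count toward ``m``.
    """
    p_arr = np.asarray(p, dtype=float)
    q = np.full(p_arr.shape, np.nan)
    ok = ~np.isnan(p_arr)
    if ok.any():
        if (p_arr[ok] < 0).any() or (p_arr[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p_arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index)  # type: ignore[return-value]
    return q


# ---------------------------------------------------------------------------
# probe-label permutation

@dataclass
class PermutationResult:
    """Observed statistic against a permutation null distribution."""

    observed: float
    null: np.ndarray
    p: float
    B: int
    tail: str
    n_degenerate: int = 0  # replicates with zero passing probes (fraction := 0)

    def summary(self) -> dict:
        q = np.quantile(self.null, [0.0, 0.25, 0.5, 0.75, 1.0]) if self.B else []
        return {
            "observed": self.observed,
            "B": self.B,
            "tail": self.tail,
            "empirical_p": self.p,
            "null_quantiles": [float(x) for x in np.atleast_1d(q)],
            "n_degenerate": self.n_degenerate,
        }


def empirical_p(observed: float, null: np.ndarray, tail: str = "greater") -> float:
    """Add-one empirical p-value: ``(1 + exceedances) / (B + 1)``; never 0."""
    null = np.asarray(null, dtype=float)
    if tail == "greater":
        exceed = int(np.sum(null >= observed))
    elif tail == "lesser":
        exceed = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown tail: {tail!r}")
    return (1 + exceed) / (len(null) + 1)


def permute_probe_labels(experiment, rng: np.random.Generator):
    """Return a copy of the experiment with probe ids uniformly re-assigned
    to value rows (the multiset of rows is untouched)."""
    from .diffmeth import MethylationExperiment  # local: avoid import cycle

    ids = experiment.values.index.to_numpy()
    new_ids = rng.permutation(ids)
    values = experiment.values.copy()
    values.index = pd.Index(new_ids, name=experiment.values.index.name)
    return MethylationExperiment(
        values=values,
        scale=experiment.scale,
        samples=experiment.samples,
        manifest=experiment.manifest,
    )


def dmr_fraction_permutation_test(
    experiment,
    group_a: list[str],
    group_b: list[str],
    *,
    B: int = 1000,
    tail: str = "greater",
    seed: int | np.random.Generator = 0,
    q_max: float = 0.05,
    d_min: float = 0.58,
    lam: int = 1000,
    min_probes: int = 2,
) -> PermutationResult:
    """Permutation test of the inside-DMR fraction of passing probes.

    The statistic is the fraction of passing differential probes that fall
    inside distance-chained DMRs. The null repeats the identical pipeline on
    ``B`` datasets whose probe ids were randomly re-assigned to value rows.
    Because every per-row test statistic is invariant under id relabelling,
    the passing row set is computed once and only the id→coordinate mapping
    is redrawn per replicate (identical results, a fraction of the cost).

    A permuted replicate with zero passing probes contributes fraction 0
    (counted in ``n_degenerate``).
    """
    from . import diffmeth  # local import: diffmeth imports adjust_fdr from here

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exp_m = experiment.to_m()
    control = diffmeth.define_control(exp_m)
    dmps = diffmeth.call_dmps(exp_m, group_a, group_b, control, q_max=q_max, d_min=d_min)
    passing = dmps[dmps["passes"]]
    _, _, observed = diffmeth.build_dmrs(
        passing, experiment.manifest, lam=lam, min_probes=min_probes
    )

    all_ids = exp_m.values.index.to_numpy()
    row_pos = exp_m.values.index.get_indexer(passing.index)
    deltas = passing["delta_vs_control"].to_numpy()
    null = np.empty(B)
    n_degenerate = 0
    for b in range(B):
        perm = rng.permutation(all_ids)
        perm_ids = perm[row_pos]
        if len(perm_ids) == 0:
            null[b] = 0.0
            n_degenerate += 1
            continue
        perm_passing = pd.DataFrame(
            {"delta_vs_control": deltas}, index=pd.Index(perm_ids, name="probe_id")
        )
        _, _, frac = diffmeth.build_dmrs(
            perm_passing, experiment.manifest, lam=lam, min_probes=min_probes
        )
        null[b] = frac
    return PermutationResult(
        observed=float(observed),
        null=null,
        p=empirical_p(float(observed), null, tail=tail),
        B=B,
        tail=tail,
        n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# Mann–Kendall trend test

@lru_cache(maxsize=32)
def _inversion_counts(n: int) -> np.ndarray:
    """Mahonian numbers: #permutations of 1..n with k inversions, k=0..n(n-1)/2."""
    counts = np.array([1], dtype=object)
    for i in range(2, n + 1):
        counts = np.convolve(counts, np.ones(i, dtype=object))
    return counts


def _mk_s(x: np.ndarray) -> int:
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def mann_kendall(values, min_n: int = 4, exact_max_n: int = 9) -> dict:
    """Mann–Kendall trend test on an ordered series.

    ``S = sum_{i<j} sign(x_j - x_i)``; for tie-free series with
    ``n <= exact_max_n`` the p-value is exact (full permutation null via the
    inversion-count distribution), otherwise a normal approximation with
    continuity and tie correction is used.

    Returns a dict with ``s``, ``tau`` (= S / (n(n-1)/2)), two-sided ``p``,
    one-sided ``p_one_sided`` for the observed direction, ``method`` and ``n``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < min_n:
        raise ValueError(f"Mann–Kendall requires at least {min_n} data points, got {n}")
    s = _mk_s(x)
    n_pairs = n * (n - 1) // 2
    tau = s / n_pairs
    has_ties = len(np.unique(x)) < n

    if not has_ties and n <= exact_max_n:
        counts = _inversion_counts(n)
        total = counts.sum()
        # S = n_pairs - 2*inversions  =>  S >= s  <=>  inv <= (n_pairs - s)/2
        k_upper = (n_pairs - abs(s)) // 2
        p_tail = float(counts[: k_upper + 1].sum() / total)
        p_one = p_tail  # P(S' >= |s|) by symmetry of the null
        p_two = min(1.0, 2 * p_one) if s != 0 else 1.0
        method = "exact"
    else:
        _, tie_counts = np.unique(x, return_counts=True)
        var = (
            n * (n - 1) * (2 * n + 5)
            - np.sum(tie_counts * (tie_counts - 1) * (2 * tie_counts + 5))
        ) / 18.0
        if var <= 0:
            return {"s": s, "tau": tau, "p": 1.0, "p_one_sided": 1.0,
                    "method": "degenerate", "n": n}
        z = (s - np.sign(s)) / np.sqrt(var)  # continuity correction
        p_one = float(stats.norm.sf(abs(z)))
        p_two = min(1.0, 2 * p_one)
        method = "normal"
    return {"s": s, "tau": tau, "p": p_two, "p_one_sided": p_one, "method": method, "n": n}


def mann_kendall_exact_oracle(values) -> dict:
    """Brute-force exact Mann–Kendall tail by enumerating all permutations.

    Independent reference for the analytic exact branch; usable for n <= ~8.
    """
    x = np.asarray(values, dtype=float)
    s = _mk_s(x)
    hits = 0
    total = 0
    for perm in itertools.permutations(x):
        total += 1
        if _mk_s(np.asarray(perm)) >= abs(s):
            hits += 1
    return {"s": s, "p_one_sided": hits / total}


# ---------------------------------------------------------------------------
# contingency and trend-on-regression tests

def chi_squared(table) -> dict:
    """Pearson chi-squared test of independence on an r x c count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi_squared needs an r x c table with r, c >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected <= 0).any():
        raise ValueError("all expected counts must be > 0")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return {"stat": float(stat), "df": int(df), "p": float(p)}


def slope_anova(y, x) -> dict:
    """OLS slope of y on x with the regression-ANOVA F test of slope = 0."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("slope_anova needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    slope = np.sum((x - xbar) * (y - ybar)) / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    ss_res = np.sum(resid**2)
    ss_reg = slope**2 * sxx
    if ss_reg == 0:
        return {"slope": 0.0, "F": 0.0, "p": 1.0}
    if ss_res == 0:
        return {"slope": float(slope), "F": np.inf, "p": 0.0}
    f = ss_reg / (ss_res / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return {"slope": float(slope), "F": float(f), "p": p}
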
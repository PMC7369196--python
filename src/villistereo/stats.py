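"""Statistics and report assembly.

Group comparisons use the classical (pooled-variance) two-sample Student's
t-test; monotone association uses Spearman's rho with average ranks for
ties and a two-sided p from the t-approximation
``t = rho * sqrt((n - 2) / (1 - rho^2))`` on ``n - 2`` degrees of freedom
(an exact permutation p is available for small n).  Summaries are mean and
sample SD or median and range.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "students_t",
    "spearman_rho",
    "median_range",
    "mean_sd",
    "assemble_report",
    "report_to_json",
    "report_from_json",
    "plot_running_means",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test.

    ``statistic`` is ``None`` when undefined (e.g. a constant variable in a
    rank correlation); ``flags`` records degeneracies such as a p-value
    below machine precision.
    """

    method: str
    statistic: float | None
    p_value: float | None
    n: tuple[int, ...]
    df: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": list(self.n),
            "df": self.df,
            "flags": list(self.flags),
        }


def students_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_var: bool = True,
) -> TestResult:
    """Two-sample Student's t-test (pooled variance, two-sided).

    ``equal_var=False`` switches to the Welch unequal-variance form.  With
    zero pooled variance the test degenerates: equal means give t = 0,
    p = 1; unequal means are reported as significant beyond machine
    precision with a flag rather than a fabricated statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    n = (int(a.size), int(b.size))
    df = a.size + b.size - 2 if equal_var else None
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult("students_t", 0.0, 1.0, n, df=df)
        return TestResult(
            "students_t",
            math.copysign(math.inf, a.mean() - b.mean()),
            0.0,
            n,
            df=df,
            flags=("p_below_machine_precision",),
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        "students_t",
        float(res.statistic),
        float(res.pvalue),
        n,
        df=float(res.df) if hasattr(res, "df") else df,
    )


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    exact: bool = False,
) -> TestResult:
    """Spearman rank correlation with tie-averaged ranks.

    rho is the Pearson correlation of the (average) ranks; the two-sided p
    comes from the t-approximation on ``n - 2`` degrees of freedom, adequate
    at the sample sizes met here.  ``exact=True`` (n <= 10 only) replaces it
    with the exact permutation p over all rank orderings.  Constant input
    leaves rho undefined, reported as missing rather than 0.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("paired samples must have equal length")
    n = int(xa.size)
    if n < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        return TestResult(
            "spearman", None, None, (n,), flags=("undefined_constant_input",)
        )
    rho, p = sps.spearmanr(xa, ya)
    rho = float(rho)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        p = _exact_spearman_p(xa, ya, rho)
    else:
        p = float(p)
    # guard the t-approximation's open interval at |rho| = 1
    if abs(rho) >= 1.0:
        p = 0.0 if not exact else p
    return TestResult("spearman", rho, min(max(p, 0.0), 1.0), (n,), df=n - 2)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p: share of orderings with |rho| >= |observed|."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    rx_c = rx - rx.mean()
    denom_x = math.sqrt(float(rx_c @ rx_c))
    for perm in itertools.permutations(range(n)):
        ry_p = ry[list(perm)]
        ry_c = ry_p - ry_p.mean()
        denom = denom_x * math.sqrt(float(ry_c @ ry_c))
        r = float(rx_c @ ry_c) / denom
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def median_range(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max); the even-n median averages the central pair."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """(mean, sample SD); a single observation reports SD 0."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty input")
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def assemble_report(
    coverage=None,
    iep_summary: dict | None = None,
    density=None,
    profiles: Iterable | None = None,
    tests: Iterable[TestResult] | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble one JSON-serialisable report of a full analysis.

    Every section is echoed explicitly (``None`` for absent sections, never
    silently dropped) together with the configuration -- seeds, thresholds,
    volume fractions -- needed to reproduce the run.
    """
    def _maybe(obj):
        if obj is None:
            return None
        return obj.to_dict() if hasattr(obj, "to_dict") else obj

    return {
        "coverage": _maybe(coverage),
        "iep_summary": iep_summary if iep_summary is not None else None,
        "density": _maybe(density),
        "profiles": [_maybe(p) for p in profiles] if profiles is not None else None,
        "tests": [_maybe(t) for t in tests] if tests is not None else None,
        "config": config if config is not None else None,
    }


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=False)


def report_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def plot_running_means(coverage, path) -> None:
    """Plot the cumulative coverage ratio against sampled slices.

    The running mean flattening out is the adequacy check for the sampling
    intensity of the grid estimate.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    slices = [z for z, _, _ in coverage.per_slice]
    means = coverage.running_means
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(slices, [m if m is not None else np.nan for m in means], marker="o")
    ax.set_xlabel("slice index")
    ax.set_ylabel("cumulative pericyte/capillary ratio")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
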
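"""Context-induced-feeding statistics.

The headline readout is context discrimination: each animal's palatable food
intake in the trained context A minus its intake in the familiar but
untrained context B during matched test sessions.  Within-group inference on
the paired differences uses a sign-flip permutation test: under the null of
no context preference each animal's difference is symmetric around zero, so
the null distribution is built by flipping the signs of the observed
differences.  For n <= 12 all 2^n sign patterns are enumerated exactly;
above that the null is sampled with the add-one p-value estimator
p = (1 + #{|resampled mean| >= |observed mean|}) / (1 + resamples).
A conventional paired t-test is available as a parametric cross-check, and
Holm adjustment is applied when several groups are tested together.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._rng import stream_rng
from .errors import PhotocifError

EXACT_MAX_N = 12


@dataclass
class ContrastResult:
    """Result of a paired sign-flip permutation contrast."""

    diffs: np.ndarray
    mean: float
    p_value: float
    n_resamples: int          # 2**n when exact
    exact: bool
    seed: int | None = None
    degenerate: bool = False  # all-zero differences

    @property
    def n(self) -> int:
        return self.diffs.size


def context_discrimination(records: pd.DataFrame) -> pd.DataFrame:
    """Per-mouse A - B test-intake difference (g), grouped.

    Expects tidy records with columns mouse, group, phase, context, intake_g
    and exactly one test row per mouse per context.
    """
    test = records[records["phase"] == "test"]
    rows = []
    for (mouse, group), sub in test.groupby(["mouse", "group"], sort=True):
        by_ctx = sub.set_index("context")["intake_g"]
        for ctx in ("A", "B"):
            if ctx not in by_ctx.index:
                raise PhotocifError(f"mouse {mouse!r} missing test context {ctx}")
        rows.append((mouse, group, float(by_ctx["A"] - by_ctx["B"])))
    if not rows:
        raise PhotocifError("no test-phase records found")
    return pd.DataFrame(rows, columns=["mouse", "group", "diff_g"])


def paired_contrast(
    diffs: np.ndarray,
    resamples: int = 10000,
    seed: int | None = None,
    exact_max_n: int = EXACT_MAX_N,
) -> ContrastResult:
    """Two-sided sign-flip permutation test of mean(diffs) = 0.

    Exact enumeration of all 2^n sign patterns for n <= exact_max_n
    (p = #{|mean under flips| >= |observed mean|} / 2^n, the identity
    pattern included); Monte-Carlo sampling with the add-one estimator
    otherwise.  All-zero differences return p = 1 with a degeneracy flag.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise PhotocifError("need at least 2 paired differences")
    if resamples < 1:
        raise PhotocifError("resamples must be >= 1")
    obs = float(diffs.mean())
    if np.all(diffs == 0):
        return ContrastResult(diffs=diffs, mean=0.0, p_value=1.0,
                              n_resamples=0, exact=True, degenerate=True)

    if n <= exact_max_n:
        signs = np.array(
            [[1 if (pat >> k) & 1 else -1 for k in range(n)] for pat in range(2**n)],
            dtype=float,
        )
        null_means = signs @ diffs / n
        p = float(np.mean(np.abs(null_means) >= abs(obs) - 1e-12))
        return ContrastResult(diffs=diffs, mean=obs, p_value=p,
                              n_resamples=2**n, exact=True, seed=seed)

    rng = stream_rng(0 if seed is None else seed, "signflip")
    signs = rng.choice([-1.0, 1.0], size=(resamples, n))
    null_means = signs @ diffs / n
    hits = int(np.sum(np.abs(null_means) >= abs(obs) - 1e-12))
    p = (1.0 + hits) / (1.0 + resamples)
    return ContrastResult(diffs=diffs, mean=obs, p_value=p,
                          n_resamples=resamples, exact=False, seed=seed)


def paired_ttest(diffs: np.ndarray) -> tuple[float, float]:
    """Parametric cross-check: one-sample t on the paired differences."""
    res = sps.ttest_1samp(np.asarray(diffs, dtype=float), 0.0)
    return float(res.statistic), float(res.pvalue)


def group_contrasts(
    discrimination: pd.DataFrame,
    resamples: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group sign-flip contrasts with Holm adjustment across groups."""
    rows = []
    for group, sub in discrimination.groupby("group", sort=True):
        d = sub["diff_g"].to_numpy()
        res = paired_contrast(d, resamples=resamples, seed=seed)
        t_stat, t_p = paired_ttest(d) if np.ptp(d) > 0 else (np.nan, np.nan)
        rows.append((group, d.size, res.mean, d.std(ddof=1) / np.sqrt(d.size),
                     res.p_value, res.exact, t_p))
    out = pd.DataFrame(rows, columns=["group", "n", "mean_diff_g", "sem_g",
                                      "p_signflip", "exact", "p_ttest"])
    reject, p_adj, *_ = multipletests(out["p_signflip"], alpha=alpha, method="holm")
    out["p_holm"] = p_adj
    out["reject_holm"] = reject
    return out


def training_test_relation(
    training_intake: np.ndarray, outcome: np.ndarray
) -> tuple[float, float, float]:
    """OLS of a per-mouse outcome (A - B, or test intake) on mean training intake.

    Returns (slope, intercept, R^2) with R^2 = 1 - SSres/SStot.
    """
    x = np.asarray(training_intake, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size:
        raise PhotocifError("predictor and outcome lengths differ")
    if x.size < 3:
        raise PhotocifError("need at least 3 mice for a regression")
    if np.ptp(x) == 0 or x.std() == 0:
        raise PhotocifError("constant predictor; regression is degenerate")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
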
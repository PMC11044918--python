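"""Evaluation metrics and statistics: test cross-modal loss, Pearson
structural metrics, time-dependent concordance index, bootstrap confidence
intervals, and one-sided Wilcoxon signed-rank comparisons."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .vae import cross_modal_predict

__all__ = [
    "EvalReport", "c_td", "time_to_interval", "test_cross_modal_loss",
    "pcc_mean_features", "pcc_prior_decode", "bootstrap_ci", "BootstrapResult",
    "wilcoxon_one_sided",
]


def time_to_interval(time: np.ndarray, n_intervals: int = 30) -> np.ndarray:
    """Map positive times in years to 1-based yearly interval indices;
    times beyond the horizon clamp into the final interval."""
    time = np.asarray(time, float)
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    return np.minimum(np.ceil(time).astype(int), n_intervals)


def c_td(surv, times: np.ndarray, events: np.ndarray) -> float:
    """Time-dependent concordance index.

    A pair (i, j) is comparable when T_i < T_j and subject i had the event.
    The pair is concordant when the predicted cumulative survival of i,
    evaluated at the interval containing T_i, is lower than that of j at
    the same interval; ties in predicted survival earn half credit.  Unlike
    the time-constant Harrell index, the comparison uses each subject's
    full predicted survival curve.
    """
    S = surv.cumulative() if hasattr(surv, "cumulative") else np.atleast_2d(
        np.asarray(surv, float))
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    n, J = S.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if events.sum() == 0:
        raise ValueError("need at least one event")
    k = time_to_interval(times, J) - 1  # 0-based column of T_i
    concordant = 0.0
    comparable = 0
    for i in range(n):
        if events[i] != 1:
            continue
        later = times > times[i]
        m = int(later.sum())
        if m == 0:
            continue
        si = S[i, k[i]]
        sj = S[later, k[i]]
        concordant += float((sj > si).sum()) + 0.5 * float((sj == si).sum())
        comparable += m
    if comparable == 0:
        raise ValueError("no comparable pairs")
    return concordant / comparable


def test_cross_modal_loss(X_B_test: np.ndarray, X_A_test: np.ndarray,
                          enc_A, dec_B) -> tuple[float, np.ndarray]:
    """Cross-modal loss on complete test pairs.

    Returns the scalar loss (identical formula to the training-side
    cross-modal loss) together with per-sample values for paired
    signed-rank comparisons.
    """
    X_B_test = np.asarray(X_B_test, float)
    X_A_test = np.asarray(X_A_test, float)
    if X_B_test.shape[0] != X_A_test.shape[0]:
        raise ValueError("test rows must be ID-paired")
    x_hat = cross_modal_predict(X_A_test, enc_A, dec_B)
    per_sample = ((X_B_test - x_hat) ** 2).mean(axis=1)
    return float(per_sample.mean()), per_sample


def _pearson_means(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    if np.std(mean_a) == 0 or np.std(mean_b) == 0:
        raise ValueError("mean feature vector has zero variance")
    return float(stats.pearsonr(mean_a, mean_b).statistic)


def pcc_mean_features(X_B_test: np.ndarray, X_hat: np.ndarray) -> float:
    """Pearson correlation between the length-d_B mean-feature vectors of
    the real test set and the imputations."""
    X_B_test, X_hat = np.asarray(X_B_test, float), np.asarray(X_hat, float)
    if X_B_test.shape[1] != X_hat.shape[1]:
        raise ValueError("feature dimensions differ")
    return _pearson_means(X_B_test.mean(axis=0), X_hat.mean(axis=0))


def pcc_prior_decode(X_B_test: np.ndarray, dec_B, n_draws: int | None = None,
                     seed: int = 0) -> float:
    """Decode standard-normal latent draws and correlate the resulting mean
    feature vector with the real test mean — a check that the decoder keeps
    the data's structure for inputs far from any training sample.

    ``n_draws`` defaults to the test-set size so both means average
    comparable sample counts.
    """
    X_B_test = np.asarray(X_B_test, float)
    n = n_draws if n_draws is not None else len(X_B_test)
    z = np.random.default_rng(seed).standard_normal((n, dec_B.latent_dim))
    decoded = dec_B.decode_np(z)
    return _pearson_means(X_B_test.mean(axis=0), decoded.mean(axis=0))


@dataclass
class BootstrapResult:
    estimate: float
    lo: float
    hi: float
    replicates: np.ndarray

    def __post_init__(self):
        if self.lo > self.hi:
            raise ValueError("CI bounds out of order")


def bootstrap_ci(metric_fn, n_subjects: int, n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0) -> BootstrapResult:
    """Percentile bootstrap over subjects.

    ``metric_fn`` maps an index array (into the test set) to a scalar; it is
    called once on the identity for the point estimate and once per
    resample.  A replicate on which the metric fails (e.g. a resample with
    no comparable pairs) is redrawn, at most 10 times.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    estimate = float(metric_fn(np.arange(n_subjects)))
    reps = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(10):
            idx = rng.integers(n_subjects, size=n_subjects)
            try:
                reps[b] = float(metric_fn(idx))
                break
            except (ValueError, ZeroDivisionError):
                continue
        else:
            raise RuntimeError("bootstrap replicate failed 10 consecutive draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return BootstrapResult(estimate, float(lo), float(hi), reps)


def wilcoxon_one_sided(paired_a: np.ndarray, paired_b: np.ndarray,
                       alternative: str = "less") -> float:
    """One-sided Wilcoxon signed-rank p-value on paired values.

    ``alternative='less'`` tests whether a is systematically below b (use
    for losses); ``'greater'`` for metrics where higher is better.  Zero
    differences are dropped; the null is exact for n <= 25 without ties and
    a tie/continuity-corrected normal approximation otherwise.
    """
    a = np.asarray(paired_a, float)
    b = np.asarray(paired_b, float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


@dataclass
class EvalReport:
    """Bundle of the evaluation quantities for one trained configuration."""

    c_td: float | None = None
    c_td_lo: float | None = None
    c_td_hi: float | None = None
    L_CM_test: float | None = None
    pcc_imputed: float | None = None
    pcc_prior: float | None = None
    wilcoxon_p: dict = field(default_factory=dict)
    n_boot: int = 1000
    n_prior_draws: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        return cls(**json.loads(Path(path).read_text()))
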
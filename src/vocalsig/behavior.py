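"""Operant interruption behavior: the log2 odds-ratio discrimination statistic.

In the go/no-go task the subject interrupts a playback by pecking; rewarded
(Re) stimuli play on 20% of trials, nonrewarded (NoRe) on 80%.  A subject that
discriminates the vocalizers interrupts NoRe more than Re.  Performance is the
log2 odds ratio

    OR = log2(O_NoRe / O_Re)
       = log2( (p_NoRe / (1 - p_NoRe)) / (p_Re / (1 - p_Re)) )

where p_role = interrupted / total for that role.  Positive OR means targeted
interruption of the nonrewarded vocalizer; OR = 1 on the log2 scale means
"twice as likely to interrupt NoRe as Re".

Significance of the 2x2 table (role x interrupted) uses the two-sided
conditional exact (Fisher / central hypergeometric) test, with the matching
exact conditional confidence interval.  A permutation null band (interruption
outcomes shuffled over trials, preserving the role schedule and the total
interruption count) gives the 5-95% quantiles of a random odds ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from scipy.stats.contingency import odds_ratio as _exact_or

logger = logging.getLogger(__name__)

TRIAL_COLUMNS = ["trial_index", "time_s", "role", "call_type", "rendition_id", "interrupted"]


@dataclass
class ORResult:
    n_nore: int
    k_nore: int  # interrupted NoRe trials
    n_re: int
    k_re: int
    or_log2: float
    p_value: float
    ci_low: float  # log2 scale, exact conditional interval
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied to all four cells

    @property
    def p_nore(self) -> float:
        return self.k_nore / self.n_nore

    @property
    def p_re(self) -> float:
        return self.k_re / self.n_re

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _counts(trials: pd.DataFrame) -> tuple[int, int, int, int]:
    role = trials["role"].to_numpy()
    inter = trials["interrupted"].to_numpy().astype(bool)
    nore = role == "NoRe"
    re = role == "Re"
    return int(nore.sum()), int(inter[nore].sum()), int(re.sum()), int(inter[re].sum())


def or_from_counts(n_nore: int, k_nore: int, n_re: int, k_re: int) -> tuple[float, bool]:
    """log2 odds ratio from the 2x2 counts; +0.5 on all cells if any is zero."""
    a, b = k_nore, n_nore - k_nore  # NoRe interrupted / not
    c, d = k_re, n_re - k_re  # Re interrupted / not
    corrected = 0 in (a, b, c, d)
    if corrected:
        logger.info("zero cell in (%d,%d,%d,%d); Haldane-Anscombe +0.5 applied", a, b, c, d)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(np.log2((a / b) / (c / d))), corrected


def exact_or_test(trials: pd.DataFrame) -> float:
    """Two-sided conditional exact test of association between role and outcome."""
    n_nore, k_nore, n_re, k_re = _counts(trials)
    return _exact_test_from_counts(n_nore, k_nore, n_re, k_re)


def _exact_test_from_counts(n_nore: int, k_nore: int, n_re: int, k_re: int) -> float:
    table = [[k_nore, n_nore - k_nore], [k_re, n_re - k_re]]
    if min(n_nore, n_re) == 0 or k_nore + k_re in (0, n_nore + n_re):
        return 1.0  # degenerate margin
    return float(fisher_exact(table, alternative="two-sided").pvalue)


def odds_ratio(trials: pd.DataFrame) -> ORResult:
    """Whole-log odds ratio with exact test and exact conditional CI."""
    n_nore, k_nore, n_re, k_re = _counts(trials)
    if n_nore == 0 or n_re == 0:
        raise ValueError("both roles (Re and NoRe) must appear in the trial log")
    value, corrected = or_from_counts(n_nore, k_nore, n_re, k_re)
    p = _exact_test_from_counts(n_nore, k_nore, n_re, k_re)
    res = _exact_or([[k_nore, n_nore - k_nore], [k_re, n_re - k_re]], kind="conditional")
    ci = res.confidence_interval(0.95)
    lo = float(np.log2(ci.low)) if ci.low > 0 else -np.inf
    hi = float(np.log2(ci.high)) if np.isfinite(ci.high) else np.inf
    return ORResult(n_nore, k_nore, n_re, k_re, value, p, lo, hi, corrected)


def running_or(
    trials: pd.DataFrame, window_n: int = 30, step_n: int = 1
) -> tuple[pd.DataFrame, ORResult]:
    """Sliding-window OR series plus the whole-test OR.

    Windows are defined in trial counts (stable per-window sample size);
    windows missing one of the roles are skipped.
    """
    if window_n < 10:
        raise ValueError("window_n must be >= 10")
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    rows = []
    for start in range(0, len(trials) - window_n + 1, step_n):
        win = trials.iloc[start : start + window_n]
        n_nore, k_nore, n_re, k_re = _counts(win)
        if n_nore == 0 or n_re == 0:
            continue
        value, corrected = or_from_counts(n_nore, k_nore, n_re, k_re)
        rows.append({
            "window_start": start,
            "time_s": float(win["time_s"].iloc[-1]),
            "or_log2": value,
            "p_value": _exact_test_from_counts(n_nore, k_nore, n_re, k_re),
            "n_re": n_re,
            "n_nore": n_nore,
            "corrected": corrected,
        })
    return pd.DataFrame(rows), odds_ratio(trials)


@dataclass
class NullBand:
    quantiles: tuple[float, ...]  # percent points, e.g. (5, 95)
    whole: dict[float, float]  # quantile -> OR value over the whole log
    windows: pd.DataFrame | None  # per-window bands, or None


def null_band(
    trials: pd.DataFrame,
    n_perm: int = 1000,
    quantiles: tuple[float, ...] = (5.0, 95.0),
    seed: int = 0,
    window_n: int | None = None,
    step_n: int = 1,
) -> NullBand:
    """Quantiles of the OR under random interruption.

    Interruption outcomes are permuted across trials (the Re/NoRe schedule
    and the total number of interruptions are preserved) and the OR is
    recomputed for each permutation, whole-log and optionally per window.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    inter = trials["interrupted"].to_numpy().astype(int)
    is_nore = (trials["role"] == "NoRe").to_numpy()
    n = len(trials)
    whole_vals = np.empty(n_perm)
    win_starts = (
        list(range(0, n - window_n + 1, step_n)) if window_n is not None else []
    )
    win_vals = np.full((n_perm, len(win_starts)), np.nan)
    for p in range(n_perm):
        perm = inter[rng.permutation(n)]
        k_nore = int(perm[is_nore].sum())
        k_re = int(perm[~is_nore].sum())
        whole_vals[p], _ = or_from_counts(int(is_nore.sum()), k_nore, int((~is_nore).sum()), k_re)
        for w, start in enumerate(win_starts):
            sl = slice(start, start + window_n)
            nore_w = is_nore[sl]
            n_nore_w, n_re_w = int(nore_w.sum()), int((~nore_w).sum())
            if n_nore_w == 0 or n_re_w == 0:
                continue
            kn = int(perm[sl][nore_w].sum())
            kr = int(perm[sl][~nore_w].sum())
            win_vals[p, w], _ = or_from_counts(n_nore_w, kn, n_re_w, kr)
    whole = {q: float(np.percentile(whole_vals, q)) for q in quantiles}
    windows = None
    if window_n is not None:
        windows = pd.DataFrame({"window_start": win_starts})
        for q in quantiles:
            windows[f"q{q:g}"] = np.nanpercentile(win_vals, q, axis=0)
    return NullBand(tuple(quantiles), whole, windows)


def session_split(
    trials: pd.DataFrame, session_minutes: float = 30.0, n_sessions: int = 3
) -> pd.DataFrame:
    """Per-session OR over consecutive time bins from the start of the test.

    Bins are left-closed/right-open: session s covers
    [s * session_minutes, (s+1) * session_minutes) minutes.  Trials beyond the
    last session are ignored; an empty or single-role session yields NaN and
    is flagged.
    """
    rows = []
    t = trials["time_s"].to_numpy()
    for s in range(n_sessions):
        lo, hi = s * session_minutes * 60.0, (s + 1) * session_minutes * 60.0
        sess = trials[(t >= lo) & (t < hi)]
        n_nore, k_nore, n_re, k_re = _counts(sess) if len(sess) else (0, 0, 0, 0)
        if n_nore == 0 or n_re == 0:
            logger.warning("session %d empty or missing a role (%d trials)", s + 1, len(sess))
            rows.append({"session": s + 1, "n_trials": len(sess), "or_log2": np.nan,
                         "p_value": np.nan, "valid": False})
            continue
        value, _ = or_from_counts(n_nore, k_nore, n_re, k_re)
        rows.append({
            "session": s + 1,
            "n_trials": len(sess),
            "or_log2": value,
            "p_value": _exact_test_from_counts(n_nore, k_nore, n_re, k_re),
            "valid": True,
        })
    return pd.DataFrame(rows)


def first_exposure_filter(trials: pd.DataFrame, max_exposures: int = 2) -> pd.DataFrame:
    """Keep each trial only while its rendition has been heard at most
    ``max_exposures`` times (counting the trial itself)."""
    trials = trials.sort_values("trial_index")
    occurrence = trials.groupby("rendition_id").cumcount()
    return trials[occurrence < max_exposures].reset_index(drop=True)


def exposure_rank_covariates(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial exposure counts for external mixed-model analysis.

    VocRank counts prior trials with the same (role, call type) — how often the
    subject has heard this call type from this vocalizer; RendRank counts prior
    trials with the same rendition.  Both start at 0.
    """
    trials = trials.sort_values("trial_index").reset_index(drop=True)
    out = trials.copy()
    out["VocRank"] = trials.groupby(["role", "call_type"]).cumcount()
    out["RendRank"] = trials.groupby("rendition_id").cumcount()
    return out


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    if not df["time_s"].is_monotonic_increasing:
        raise ValueError("trial times must be non-decreasing")
    return df


def or_summary_table(trials: pd.DataFrame) -> pd.DataFrame:
    """OR per call type plus the all-trials row (the per-test summary CSV)."""
    rows = []
    groups = [("All", trials)] + [(ct, g) for ct, g in trials.groupby("call_type")]
    for label, g in groups:
        try:
            r = odds_ratio(g)
        except ValueError:
            continue
        rows.append({
            "call_type": label, "n_trials": len(g),
            "n_nore": r.n_nore, "k_nore": r.k_nore, "n_re": r.n_re, "k_re": r.k_re,
            "or_log2": r.or_log2, "p_value": r.p_value,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "significant": r.significant,
        })
    return pd.DataFrame(rows)
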
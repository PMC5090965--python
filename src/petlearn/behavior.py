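"""Trial-level and group-level behavioral statistics for criterion-terminated
discrimination/reversal learning.

Inputs are trial-log DataFrames (one row per trial; see
:data:`petlearn.synth.behavior.TRIAL_LOG_COLUMNS`).  Rows with an empty
``chosen_stim`` mark sessions aborted before any response; they flag the
session as aborted but are excluded from all trial-level statistics.

Conventions
-----------
* the learning criterion is evaluated per whole session against the nominal
  session size, so truncated sessions cannot spuriously attain it;
* consecutive-trial statistics (win-stay, lose-shift, side stickiness) never
  pair trials across a session boundary;
* probabilities with no qualifying pairs are NaN, not 0, and are excluded
  from group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .actigraphy import normalized_locomotor_activity  # noqa: F401  (re-export)

__all__ = [
    "ErrorsToCriterion",
    "StageSegmentation",
    "errors_to_criterion",
    "count_aborted_sessions",
    "win_stay",
    "lose_shift",
    "side_stickiness",
    "find_change_points",
    "classify_stages",
    "response_time_comparison",
    "mixed_anova",
    "fisher_lsd",
    "paired_ttest",
    "oneway_anova",
    "normalized_locomotor_activity",
    "behavior_summary",
]

_SESSION_KEYS = ["animal_id", "phase_label", "session_index"]


def _completed(trials: pd.DataFrame) -> pd.DataFrame:
    """Rows that correspond to an actual response (drops no-response rows)."""
    chosen = trials["chosen_stim"].fillna("")
    return trials[chosen.astype(str) != ""]


def _session_groups(trials: pd.DataFrame):
    keys = [k for k in _SESSION_KEYS if k in trials.columns]
    if not keys:
        return [((), trials)]
    return trials.groupby(keys, sort=True)


# ---------------------------------------------------------------------------
# errors to criterion and aborted sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorsToCriterion:
    """Error count through the criterion session (inclusive)."""

    errors: int
    attained: bool
    criterion_session: int | None

    @property
    def sqrt_errors(self) -> float:
        return float(np.sqrt(self.errors))


def errors_to_criterion(trials: pd.DataFrame, criterion: float = 0.90,
                        session_size: int = 100) -> ErrorsToCriterion:
    """Unrewarded trials accumulated until the first criterion session.

    Sessions are taken in ``session_index`` order; a session attains the
    criterion when its correct count is at least ``criterion * session_size``.
    Errors in the criterion session itself are included.  If no session
    attains the criterion, the total error count is returned with
    ``attained=False``.
    """
    done = _completed(trials)
    if done.empty:
        raise ValueError("phase contains no completed trials")
    need = criterion * session_size - 1e-9
    errors = 0
    for (_, session_df) in _session_groups(done):
        n_correct = int(session_df["rewarded"].sum())
        errors += int((session_df["rewarded"] == 0).sum())
        if n_correct >= need:
            sess = session_df["session_index"].iloc[0] if "session_index" in session_df else None
            return ErrorsToCriterion(errors, True, int(sess) if sess is not None else None)
    return ErrorsToCriterion(errors, False, None)


def count_aborted_sessions(trials: pd.DataFrame,
                           phases: list[str] | None = None) -> int:
    """Number of sessions flagged aborted (optionally restricted to phases)."""
    df = trials
    if phases is not None:
        df = df[df["phase_label"].isin(phases)]
    if df.empty:
        return 0
    keys = [k for k in _SESSION_KEYS if k in df.columns]
    per_session = df.groupby(keys)["aborted_session"].max()
    return int((per_session > 0).sum())


# ---------------------------------------------------------------------------
# consecutive-pair probabilities
# ---------------------------------------------------------------------------

def _session_pairs(trials: pd.DataFrame):
    """Yield (previous row, current row) pairs within each session."""
    for (_, session_df) in _session_groups(_completed(trials)):
        rows = list(session_df.itertuples(index=False))
        for prev, cur in zip(rows[:-1], rows[1:]):
            yield prev, cur


def win_stay(trials: pd.DataFrame) -> float:
    """P(same stimulus chosen next | previous trial rewarded); NaN if no pairs."""
    n_q = n_stay = 0
    for prev, cur in _session_pairs(trials):
        if prev.rewarded == 1:
            n_q += 1
            n_stay += int(cur.chosen_stim == prev.chosen_stim)
    return n_stay / n_q if n_q else float("nan")


def lose_shift(trials: pd.DataFrame) -> float:
    """P(other stimulus chosen next | previous trial unrewarded); NaN if no pairs."""
    n_q = n_shift = 0
    for prev, cur in _session_pairs(trials):
        if prev.rewarded == 0:
            n_q += 1
            n_shift += int(cur.chosen_stim != prev.chosen_stim)
    return n_shift / n_q if n_q else float("nan")


def _rewarded_side(row) -> str:
    """Side on which the reward-mapped stimulus was shown in this trial."""
    reward_stim = row.chosen_stim if row.rewarded == 1 else (
        row.left_stim if row.chosen_stim == row.right_stim else row.right_stim)
    return "left" if reward_stim == row.left_stim else "right"


def side_stickiness(trials: pd.DataFrame, mode: str = "simple") -> float:
    """Probability of repeating the previous trial's side.

    ``simple``: over all consecutive pairs.  ``reward_associated``: over the
    pairs in which repeating the previously touched side would have been
    rewarded (the reward-mapped stimulus sits on that side in the current
    trial).  NaN when no qualifying pairs exist.
    """
    if mode not in ("simple", "reward_associated"):
        raise ValueError("mode must be 'simple' or 'reward_associated'")
    n_q = n_rep = 0
    for prev, cur in _session_pairs(trials):
        if mode == "reward_associated" and _rewarded_side(cur) != prev.chosen_side:
            continue
        n_q += 1
        n_rep += int(cur.chosen_side == prev.chosen_side)
    return n_rep / n_q if n_q else float("nan")


# ---------------------------------------------------------------------------
# change points and learning stages
# ---------------------------------------------------------------------------

def _two_proportion_p(k1: int, n1: int, k2: int, n2: int, test: str) -> float:
    if test == "binomial" and min(n1, n2) <= 200:
        _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]],
                                  alternative="two-sided")
        return float(p)
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def find_change_points(outcomes, alpha: float = 0.05,
                       test: str = "binomial") -> list[int]:
    """Recursive change points of a binary correct/incorrect sequence.

    Within a segment, the candidate change point maximizes the deviation of
    the cumulative-correct record from the straight line joining the segment
    endpoints; it is retained iff a two-proportion test between the two
    sub-segments rejects at ``alpha`` (Fisher exact for small segments,
    chi-square for large; ``test="chi2"`` forces chi-square).  Because the
    candidate is the most extreme of all interior positions, the test p-value
    is Bonferroni-adjusted by the number of candidate positions; without this
    the familywise false-alarm rate on stationary sequences is several times
    ``alpha``.  Retained sub-segments are searched recursively.  Returned
    indices are 1-based trial numbers of the last trial of the left
    sub-segment, sorted ascending.
    """
    x = np.asarray(outcomes)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sequence of at least 2 outcomes")
    if not np.isin(x, [0, 1]).all():
        raise ValueError("outcomes must be binary (0/1)")
    x = x.astype(int)
    cum = np.concatenate([[0], np.cumsum(x)])  # cum[t] = correct in trials 1..t

    found: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        # segment spans trials lo+1 .. hi (cumulative indices lo..hi)
        n = hi - lo
        if n < 2:
            return
        t = np.arange(lo + 1, hi)
        line = cum[lo] + (cum[hi] - cum[lo]) * (t - lo) / n
        dev = np.abs(cum[t] - line)
        k = int(t[np.argmax(dev)])
        k1, n1 = cum[k] - cum[lo], k - lo
        k2, n2 = cum[hi] - cum[k], hi - k
        n_candidates = hi - lo - 1  # positions the maximum was selected over
        if _two_proportion_p(k1, n1, k2, n2, test) * n_candidates < alpha:
            found.append(k)
            recurse(lo, k)
            recurse(k, hi)

    recurse(0, x.size)
    return sorted(found)


@dataclass(frozen=True)
class StageSegmentation:
    """Partition of trials 1..n into bias, chance, and improvement stages.

    Intervals are 1-based inclusive ``(start, end)`` tuples or ``None`` when
    the stage is empty; together they cover every trial up to the criterion
    trial exactly once.
    """

    bias: tuple[int, int] | None
    chance: tuple[int, int] | None
    improvement: tuple[int, int] | None
    change_points: tuple[int, ...]
    n_trials: int

    def stage_lengths(self) -> dict[str, int]:
        def length(iv):
            return 0 if iv is None else iv[1] - iv[0] + 1
        return {"bias": length(self.bias), "chance": length(self.chance),
                "improvement": length(self.improvement)}

    def __post_init__(self) -> None:
        covered = 0
        prev_end = 0
        for iv in (self.bias, self.chance, self.improvement):
            if iv is None:
                continue
            start, end = iv
            if start != prev_end + 1 or end < start:
                raise ValueError("stage intervals must be contiguous and ordered")
            covered += end - start + 1
            prev_end = end
        if covered != self.n_trials:
            raise ValueError("stages must jointly cover trials 1..n")


def classify_stages(outcomes, change_points: list[int] | None = None,
                    alpha_bias: float = 0.01, alpha: float = 0.05,
                    bias_mode: str = "segment") -> StageSegmentation:
    """Classify trials into bias/perseveration, chance, and improvement stages.

    * bias: trials 1..b where b is the last trial whose running correct ratio
      (cumulative from trial 1) is significantly below chance by a one-sided
      exact binomial test at ``alpha_bias``; empty if never.  In the default
      ``bias_mode="segment"`` the rule is additionally capped at the end of
      the last initial change-point segment that is itself significantly
      below chance — the cumulative ratio alone recovers only slowly after a
      poor start and would otherwise stretch the bias stage far into chance
      performance.  ``bias_mode="cumulative"`` applies the running-ratio rule
      verbatim.
    * improvement: from just after the last change point whose following
      segment (to the criterion trial) is significantly above chance at
      ``alpha``, to the last trial; with no qualifying change point the whole
      sequence is tested, and the improvement stage is either everything after
      the bias stage or empty.
    * chance: whatever lies between.
    """
    if bias_mode not in ("segment", "cumulative"):
        raise ValueError("bias_mode must be 'segment' or 'cumulative'")
    x = np.asarray(outcomes).astype(int)
    n = x.size
    if change_points is None:
        change_points = find_change_points(x, alpha=alpha)
    cum = np.cumsum(x)
    t = np.arange(1, n + 1)

    # bias stage: running ratio significantly below 0.5
    p_below = stats.binom.cdf(cum, t, 0.5)
    below = np.flatnonzero(p_below < alpha_bias)
    bias_end = int(below[-1] + 1) if below.size else 0

    if bias_mode == "segment" and change_points and bias_end:
        bounds = [0, *sorted(change_points), n]
        cap = 0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            k, m = int(cum[hi - 1] - (cum[lo - 1] if lo else 0)), hi - lo
            if stats.binom.cdf(k, m, 0.5) < alpha_bias:
                cap = hi  # this segment is still below chance
            else:
                break
        bias_end = min(bias_end, cap)

    def above_chance(start: int) -> bool:
        """One-sided binomial test that trials start+1..n exceed p=0.5."""
        k = int(cum[-1] - (cum[start - 1] if start >= 1 else 0))
        m = n - start
        if m <= 0:
            return False
        return stats.binomtest(k, m, 0.5, alternative="greater").pvalue < alpha

    imp_start = 0  # 0 = no improvement stage
    for cp in sorted(change_points, reverse=True):
        if above_chance(cp):
            imp_start = cp + 1
            break
    if imp_start == 0 and not change_points and above_chance(0):
        imp_start = 1

    if imp_start:
        imp_start = max(imp_start, bias_end + 1)

    bias = (1, bias_end) if bias_end else None
    if imp_start:
        improvement = (imp_start, n)
        chance = (bias_end + 1, imp_start - 1) if imp_start > bias_end + 1 else None
    else:
        improvement = None
        chance = (bias_end + 1, n) if bias_end < n else None
    return StageSegmentation(bias=bias, chance=chance, improvement=improvement,
                             change_points=tuple(sorted(change_points)), n_trials=n)


# ---------------------------------------------------------------------------
# response times
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankTestResult:
    u: float
    p: float
    n1: int
    n2: int
    median1: float
    median2: float
    quartiles1: tuple[float, float]
    quartiles2: tuple[float, float]


def _phase_tails(trials: pd.DataFrame, tail_n: int) -> np.ndarray:
    vals = []
    for _, phase_df in _completed(trials).groupby("phase_label", sort=True):
        rt = phase_df.sort_values(["session_index", "trial_index"])["response_time_s"]
        rt = rt.dropna().to_numpy(dtype=float)
        if rt.size < tail_n:
            warnings.warn(
                f"phase has only {rt.size} trials; using all of them",
                stacklevel=3)
            vals.append(rt)
        else:
            vals.append(rt[-tail_n:])
    return np.concatenate(vals) if vals else np.array([])


def response_time_comparison(pre_trials: pd.DataFrame, post_trials: pd.DataFrame,
                             tail_n: int = 20,
                             method: str = "asymptotic") -> RankTestResult:
    """Mann-Whitney U between pooled final-trial response times.

    Each phase contributes its final ``tail_n`` completed trials; with the
    study's four novel and four reversal repeats per period this pools 160
    response times per side.  The default test is the two-sided normal
    approximation with tie correction (``method="exact"`` for small pools).
    """
    a = _phase_tails(pre_trials, tail_n)
    b = _phase_tails(post_trials, tail_n)
    if a.size == 0 or b.size == 0:
        raise ValueError("both periods must contribute response times")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return RankTestResult(u=float(res.statistic), p=float(res.pvalue),
                          n1=int(a.size), n2=int(b.size),
                          median1=float(np.median(a)), median2=float(np.median(b)),
                          quartiles1=(float(q1a), float(q3a)),
                          quartiles2=(float(q1b), float(q3b)))


# ---------------------------------------------------------------------------
# mixed three-way ANOVA (one between-, two within-subject factors)
# ---------------------------------------------------------------------------

def mixed_anova(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
                between: str = "group", within: tuple[str, str] = ("task", "repeat"),
                diagnostics: bool = True) -> pd.DataFrame:
    """Split-plot ANOVA: one between-subject and two within-subject factors.

    Requires a complete balanced design (one observation per subject x within
    cell).  Each effect is tested against its stratum error: the between
    effect against subjects-within-groups; each within main effect and its
    interaction with the between factor against the corresponding
    effect-by-subjects-within-groups term; the within-within interaction and
    the three-way interaction against the highest-order stratum.

    Returns a table with columns effect, ss, df_num, df_den, ms, F, p.  With
    ``diagnostics=True`` a Levene test across groups (on subject means) and a
    Mauchly sphericity test for each within factor with >= 3 levels are
    attached in ``DataFrame.attrs["diagnostics"]``.
    """
    w1, w2 = within
    df = data[[subject, between, w1, w2, dv]].copy()
    g_of = df.groupby(subject)[between].nunique()
    if (g_of != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    counts = df.groupby([subject, w1, w2])[dv].count()
    if (counts != 1).any() or counts.size != (
            df[subject].nunique() * df[w1].nunique() * df[w2].nunique()):
        raise ValueError("design must be complete with one observation per cell")

    y = df[dv].to_numpy(dtype=float)
    gm = y.mean()
    n_subj = df[subject].nunique()
    g = df[between].nunique()
    t = df[w1].nunique()
    r = df[w2].nunique()
    group_sizes = df.groupby(between)[subject].nunique()
    if group_sizes.nunique() > 1:
        pass  # unequal group sizes are fine for a between factor

    def ss_of(keys: list[str]) -> float:
        """N_cell-weighted SS of cell means about the grand mean."""
        cell = df.groupby(keys)[dv]
        return float((cell.count() * (cell.mean() - gm) ** 2).sum())

    ss_total = float(((y - gm) ** 2).sum())
    ss_subj = ss_of([subject])
    ss_group = ss_of([between])
    ss_subj_within = ss_subj - ss_group

    ss_w1 = ss_of([w1])
    ss_w2 = ss_of([w2])
    ss_gw1 = ss_of([between, w1]) - ss_group - ss_w1
    ss_gw2 = ss_of([between, w2]) - ss_group - ss_w2
    ss_w1_subj = ss_of([subject, w1]) - ss_subj - ss_w1 - ss_gw1
    ss_w2_subj = ss_of([subject, w2]) - ss_subj - ss_w2 - ss_gw2
    ss_w1w2 = ss_of([w1, w2]) - ss_w1 - ss_w2
    ss_gw1w2 = (ss_of([between, w1, w2]) - ss_of([between, w1]) - ss_of([between, w2])
                - ss_of([w1, w2]) + ss_group + ss_w1 + ss_w2)
    ss_resid = (ss_total - ss_subj - ss_w1 - ss_gw1 - ss_w1_subj
                - ss_w2 - ss_gw2 - ss_w2_subj - ss_w1w2 - ss_gw1w2)

    dfe_subj = n_subj - g
    rows = [
        (between.upper(), ss_group, g - 1, ss_subj_within, dfe_subj),
        (w1.upper(), ss_w1, t - 1, ss_w1_subj, (t - 1) * dfe_subj),
        (f"{between.upper()}x{w1.upper()}", ss_gw1, (g - 1) * (t - 1),
         ss_w1_subj, (t - 1) * dfe_subj),
        (w2.upper(), ss_w2, r - 1, ss_w2_subj, (r - 1) * dfe_subj),
        (f"{between.upper()}x{w2.upper()}", ss_gw2, (g - 1) * (r - 1),
         ss_w2_subj, (r - 1) * dfe_subj),
        (f"{w1.upper()}x{w2.upper()}", ss_w1w2, (t - 1) * (r - 1),
         ss_resid, (t - 1) * (r - 1) * dfe_subj),
        (f"{between.upper()}x{w1.upper()}x{w2.upper()}", ss_gw1w2,
         (g - 1) * (t - 1) * (r - 1), ss_resid, (t - 1) * (r - 1) * dfe_subj),
    ]
    out = []
    for effect, ss, dfn, ss_err, dfd in rows:
        ms = ss / dfn if dfn else np.nan
        ms_err = ss_err / dfd if dfd else np.nan
        if ss <= 1e-12 * max(ss_total, 1.0):
            f_val, p = 0.0, 1.0
        elif not np.isfinite(ms_err) or ms_err <= 0:
            f_val, p = np.inf, 0.0
        else:
            f_val = ms / ms_err
            p = float(stats.f.sf(f_val, dfn, dfd))
        out.append({"effect": effect, "ss": ss, "df_num": dfn, "df_den": dfd,
                    "ms": ms, "ms_error": ms_err, "F": f_val, "p": p})
    table = pd.DataFrame(out)

    if diagnostics:
        diag: dict[str, tuple] = {}
        subj_means = df.groupby([subject, between])[dv].mean().reset_index()
        groups_vals = [grp[dv].to_numpy() for _, grp in subj_means.groupby(between)]
        if len(groups_vals) >= 2:
            lev = stats.levene(*groups_vals)
            diag["levene"] = (float(lev.statistic), float(lev.pvalue))
        for w, k in ((w1, t), (w2, r)):
            if k >= 3:
                diag[f"mauchly_{w}"] = _mauchly(df, subject, w, dv)
        table.attrs["diagnostics"] = diag
    return table


def _mauchly(df: pd.DataFrame, subject: str, within: str, dv: str):
    """Mauchly's sphericity test (W, chi2, df, p) for one within factor.

    Computed on subject-by-level means using orthonormal contrasts, with the
    second-order Box correction to the chi-square p-value (the form used by
    ezANOVA and most repeated-measures software).
    """
    wide = df.groupby([subject, within])[dv].mean().unstack(within)
    k = wide.shape[1]
    n = wide.shape[0]
    # orthonormal contrast matrix (k-1 x k) via QR of centred identity
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k)
    c = q[:, :k - 1].T
    y = wide.to_numpy() @ c.T
    s = np.cov(y, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 1e-300, None)
    d = k - 1
    w_stat = float(np.prod(eig) / (eig.mean() ** d))
    f = 1 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(w_stat)
    ddf = d * (d + 1) // 2 - 1
    w2 = ((d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
          / (288.0 * ((n - 1) * d * f) ** 2))
    p1 = stats.chi2.sf(chi2, ddf)
    p2 = stats.chi2.sf(chi2, ddf + 4)
    p = float(p1 + w2 * (p2 - p1))
    return w_stat, float(chi2), int(ddf), p


def fisher_lsd(means: pd.Series, ns: pd.Series, ms_error: float,
               df_error: int) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons given cell means and an error MS."""
    labels = list(means.index)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            se = np.sqrt(ms_error * (1.0 / ns[a] + 1.0 / ns[b]))
            t_val = (means[a] - means[b]) / se
            p = 2.0 * stats.t.sf(abs(t_val), df_error)
            rows.append({"a": a, "b": b, "t": float(t_val),
                         "df": int(df_error), "p": float(p)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired and one-way group tests
# ---------------------------------------------------------------------------

def paired_ttest(pre, post):
    """Paired t on within-animal differences; returns (t, df, p, shapiro_p)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("paired test requires equal-length pre/post vectors")
    if pre.size < 2:
        raise ValueError("need at least 2 pairs")
    res = stats.ttest_rel(pre, post)
    diff = post - pre
    shapiro_p = float(stats.shapiro(diff).pvalue) if np.ptp(diff) > 0 else 1.0
    return float(res.statistic), int(pre.size - 1), float(res.pvalue), shapiro_p


def oneway_anova(groups: dict[str, np.ndarray], lsd: bool = True):
    """One-way ANOVA across groups with optional Fisher LSD post hoc.

    Returns ``(F, (df1, df2), p, lsd_table)``; ``lsd_table`` is None when
    ``lsd=False``.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(a.size for a in arrays)
    df1, df2 = len(arrays) - 1, n_total - len(arrays)
    res = stats.f_oneway(*arrays)
    table = None
    if lsd:
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df2
        means = pd.Series({k: a.mean() for k, a in zip(labels, arrays)})
        ns = pd.Series({k: a.size for k, a in zip(labels, arrays)})
        table = fisher_lsd(means, ns, mse, df2)
    return float(res.statistic), (df1, df2), float(res.pvalue), table


# ---------------------------------------------------------------------------
# per-animal summaries
# ---------------------------------------------------------------------------

def behavior_summary(trials: pd.DataFrame, criterion: float = 0.90,
                     session_size: int = 100,
                     alpha: float = 0.05, alpha_bias: float = 0.01) -> pd.DataFrame:
    """Per animal x phase summary of every trial-level statistic.

    Columns: errors_to_criterion, sqrt_errors, attained, aborted_sessions,
    win_stay, lose_shift, side_stick_simple, side_stick_reward, and the three
    learning-stage trial counts.
    """
    rows = []
    for (animal, phase), df in trials.groupby(["animal_id", "phase_label"], sort=True):
        done = _completed(df)
        rec: dict = {"animal_id": animal, "phase_label": phase,
                     "group": df["group"].iloc[0],
                     "task_kind": df["task_kind"].iloc[0]}
        if done.empty:
            rec.update({"errors_to_criterion": np.nan, "sqrt_errors": np.nan,
                        "attained": False})
        else:
            etc = errors_to_criterion(df, criterion, session_size)
            rec.update({"errors_to_criterion": etc.errors,
                        "sqrt_errors": etc.sqrt_errors, "attained": etc.attained})
        rec["aborted_sessions"] = count_aborted_sessions(df)
        rec["win_stay"] = win_stay(df)
        rec["lose_shift"] = lose_shift(df)
        rec["side_stick_simple"] = side_stickiness(df, "simple")
        rec["side_stick_reward"] = side_stickiness(df, "reward_associated")
        outcomes = done.sort_values(["session_index", "trial_index"])["rewarded"]
        outcomes = outcomes.to_numpy(dtype=int)
        if outcomes.size >= 2:
            seg = classify_stages(outcomes, alpha_bias=alpha_bias, alpha=alpha)
            for stage, n in seg.stage_lengths().items():
                rec[f"stage_{stage}_trials"] = n
        rows.append(rec)
    return pd.DataFrame(rows)
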
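"""Q-learning agents and the discrimination/reversal task battery.

The generative choice model is a two-option Q-learner: after choosing
stimulus ``c`` and receiving reward ``R`` in {0, 1}, only the chosen value is
updated, ``Q(c) <- (1 - alpha) Q(c) + alpha R``.  Choice is softmax over
utilities

    U(option) = beta Q(stim) + side_bias [side == right]
                + stim_stickiness [stim == previous stim]
                + side_stickiness [side == previous side]

mixed with a uniform lapse.  A per-trial abort hazard models the animal
pausing for >= 15 min, which terminates the session; aborted sessions are
flagged in the trial log.  Response times are log-normal.

The task battery mirrors the study protocol: two initial novel discriminations,
four novel:reversal pairs before the injection boundary, and four pairs after
it with the post-injection agent parameters; each phase runs daily 100-trial
sessions until a session reaches the 90%-correct criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgentParams",
    "Phase",
    "TaskDesign",
    "simulate_agent_session",
    "simulate_task_battery",
    "simulate_cohort",
    "study_design",
    "PRESETS",
    "TRIAL_LOG_COLUMNS",
]

TRIAL_LOG_COLUMNS = [
    "animal_id", "group", "phase_label", "task_kind", "session_index",
    "trial_index", "left_stim", "right_stim", "chosen_stim", "chosen_side",
    "rewarded", "response_time_s", "aborted_session", "intertrial_s",
]


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the generative choice agent (logit units for biases)."""

    alpha: float = 0.4
    beta: float = 5.0
    side_bias: float = 0.0
    stim_stickiness: float = 0.0
    side_stickiness: float = 0.0
    lapse: float = 0.0
    abort_hazard: float = 0.0
    rt_location: float = 0.0   # log-seconds
    rt_scale: float = 0.3

    def __post_init__(self) -> None:
        for name in ("alpha", "lapse", "abort_hazard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.rt_scale < 0:
            raise ValueError("rt_scale must be nonnegative")


#: Agent presets: a competent pre-injection learner; a D2R-knockdown-like
#: post-injection agent (noisier choices, more aborts, slower responses); the
#: D1R-knockdown and control groups keep the pre-injection parameters.
PRESETS: dict[str, AgentParams] = {
    "pre": AgentParams(alpha=0.4, beta=5.0, side_bias=0.2, stim_stickiness=0.2,
                       side_stickiness=0.2, lapse=0.02, abort_hazard=0.002,
                       rt_location=float(np.log(1.2)), rt_scale=0.3),
    "d2r-kd-post": AgentParams(alpha=0.4, beta=2.8, side_bias=0.2,
                               stim_stickiness=0.2, side_stickiness=0.3,
                               lapse=0.05, abort_hazard=0.005,
                               rt_location=float(np.log(2.2)), rt_scale=0.4),
}


@dataclass(frozen=True)
class Phase:
    """One task phase: a label like N7 or R7, its kind, and a stimulus pair id."""

    label: str
    kind: str            # "novel" | "reversal"
    pair: str            # stimulus pair id; stimuli are f"{pair}A"/f"{pair}B"
    period: str = "pre"  # "pre" | "post" (injection boundary)

    def __post_init__(self) -> None:
        if self.kind not in ("novel", "reversal"):
            raise ValueError("kind must be 'novel' or 'reversal'")
        if self.period not in ("pre", "post"):
            raise ValueError("period must be 'pre' or 'post'")


@dataclass(frozen=True)
class TaskDesign:
    """Ordered phases plus session-level constants."""

    phases: tuple[Phase, ...]
    trials_per_session: int = 100
    criterion: float = 0.90
    max_sessions_per_phase: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.criterion <= 1:
            raise ValueError("criterion must be in (0, 1]")
        seen_novel: set[str] = set()
        for ph in self.phases:
            if ph.kind == "novel":
                seen_novel.add(ph.pair)
            elif ph.pair not in seen_novel:
                raise ValueError(
                    f"reversal phase {ph.label!r} has no preceding novel phase "
                    f"for pair {ph.pair!r}"
                )


def study_design(trials_per_session: int = 100, criterion: float = 0.90,
                 max_sessions_per_phase: int = 15) -> TaskDesign:
    """The study protocol: N1, N2, N3:R3..N6:R6 pre; N7:R7..N10:R10 post."""
    phases: list[Phase] = [Phase("N1", "novel", "P1"), Phase("N2", "novel", "P2")]
    for i in range(3, 7):
        phases += [Phase(f"N{i}", "novel", f"P{i}"),
                   Phase(f"R{i}", "reversal", f"P{i}")]
    for i in range(7, 11):
        phases += [Phase(f"N{i}", "novel", f"P{i}", period="post"),
                   Phase(f"R{i}", "reversal", f"P{i}", period="post")]
    return TaskDesign(tuple(phases), trials_per_session, criterion,
                      max_sessions_per_phase)


def _counterbalanced_sides(stims: tuple[str, str], n_trials: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Boolean array: True where ``stims[0]`` is shown on the left.

    Each stimulus appears on the left in half the trials (the odd trial, if
    any, is assigned at random); order is a seeded shuffle.
    """
    half = n_trials // 2
    first_left = np.zeros(n_trials, dtype=bool)
    first_left[:half] = True
    if n_trials % 2:
        first_left[half] = rng.random() < 0.5
    rng.shuffle(first_left)
    return first_left


def simulate_agent_session(params: AgentParams, reward_map: dict[str, bool],
                           n_trials: int,
                           q_init: dict[str, float] | None = None,
                           seed: int | np.random.Generator | None = None,
                           prev_stim: str | None = None,
                           prev_side: str | None = None):
    """Simulate one session; returns ``(trials, aborted, q_final)``.

    ``trials`` is a list of per-trial dicts (trial-log fields from
    ``trial_index`` onward).  If the abort hazard fires before a response the
    session is truncated and ``aborted`` is True; a session aborted before its
    first response contributes zero trial dicts.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    stims = tuple(sorted(reward_map))
    if len(stims) != 2:
        raise ValueError("reward_map must cover exactly two stimuli")
    if sum(map(bool, reward_map.values())) != 1:
        raise ValueError("exactly one stimulus must be reward-mapped")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    q = dict(q_init) if q_init is not None else {s: 0.5 for s in stims}
    first_left = _counterbalanced_sides(stims, n_trials, rng)

    trials: list[dict] = []
    aborted = False
    for t in range(n_trials):
        if rng.random() < params.abort_hazard:
            aborted = True
            break
        left = stims[0] if first_left[t] else stims[1]
        right = stims[1] if first_left[t] else stims[0]
        u = {}
        for stim, side in ((left, "left"), (right, "right")):
            u[stim] = (params.beta * q[stim]
                       + (params.side_bias if side == "right" else 0.0)
                       + (params.stim_stickiness if stim == prev_stim else 0.0)
                       + (params.side_stickiness if side == prev_side else 0.0))
        d = u[left] - u[right]
        p_left = 1.0 / (1.0 + np.exp(-d))
        p_left = (1.0 - params.lapse) * p_left + params.lapse * 0.5
        choose_left = rng.random() < p_left
        chosen = left if choose_left else right
        side = "left" if choose_left else "right"
        reward = bool(reward_map[chosen])
        rt = float(rng.lognormal(params.rt_location, params.rt_scale))
        q[chosen] = (1.0 - params.alpha) * q[chosen] + params.alpha * float(reward)
        trials.append({
            "trial_index": t + 1, "left_stim": left, "right_stim": right,
            "chosen_stim": chosen, "chosen_side": side, "rewarded": int(reward),
            "response_time_s": rt, "intertrial_s": 3.0 if reward else 5.0,
        })
        prev_stim, prev_side = chosen, side
    return trials, aborted, q


def _phase_reward_map(phase: Phase) -> dict[str, bool]:
    a, b = f"{phase.pair}A", f"{phase.pair}B"
    if phase.kind == "novel":
        return {a: True, b: False}
    return {a: False, b: True}


def simulate_task_battery(design: TaskDesign, params_pre: AgentParams,
                          params_post: AgentParams,
                          seed: int | np.random.Generator | None = None,
                          animal_id: str = "M1", group: str = "control") -> pd.DataFrame:
    """Run an agent through the full battery; returns a trial-log DataFrame.

    Pre-period phases use ``params_pre`` and post-period phases
    ``params_post``.  Q-values reset to 0.5 at each novel phase and carry over
    into that pair's reversal (producing perseveration).  Each phase runs
    sessions until a session's correct count reaches
    ``criterion * trials_per_session`` or ``max_sessions_per_phase`` is hit.
    Sessions aborted before the first response appear as a single no-response
    row (empty choice fields, ``aborted_session=1``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows: list[dict] = []
    q_carry: dict[str, dict[str, float]] = {}
    need = None
    for phase in design.phases:
        params = params_post if phase.period == "post" else params_pre
        reward_map = _phase_reward_map(phase)
        q = q_carry.get(phase.pair) if phase.kind == "reversal" else None
        need = int(np.ceil(design.criterion * design.trials_per_session))
        for session in range(1, design.max_sessions_per_phase + 1):
            trials, aborted, q = simulate_agent_session(
                params, reward_map, design.trials_per_session, q_init=q, seed=rng)
            base = {
                "animal_id": animal_id, "group": group,
                "phase_label": phase.label, "task_kind": phase.kind,
                "session_index": session, "aborted_session": int(aborted),
            }
            if not trials:  # aborted before the first response
                rows.append({**base, "trial_index": 1, "left_stim": "",
                             "right_stim": "", "chosen_stim": "",
                             "chosen_side": "", "rewarded": 0,
                             "response_time_s": np.nan, "intertrial_s": np.nan})
                continue
            for tr in trials:
                rows.append({**base, **tr})
            if sum(tr["rewarded"] for tr in trials) >= need:
                break
        q_carry[phase.pair] = q
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def simulate_cohort(n_d1: int = 5, n_d2: int = 5, n_control: int = 4,
                    design: TaskDesign | None = None,
                    seed: int | np.random.Generator | None = None,
                    params_pre: AgentParams | None = None,
                    params_d2_post: AgentParams | None = None) -> pd.DataFrame:
    """The study cohort (default 5 D1R-KD + 5 D2R-KD + 4 controls).

    Only the D2R-KD group changes agent parameters after the injection
    boundary; D1R-KD and control animals keep the pre-injection parameters
    throughout, matching the study's null phenotypes.
    """
    design = design or study_design()
    pre = params_pre or PRESETS["pre"]
    d2_post = params_d2_post or PRESETS["d2r-kd-post"]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    idx = 1
    for group, n, post in (("d1r-kd", n_d1, pre), ("d2r-kd", n_d2, d2_post),
                           ("control", n_control, pre)):
        for _ in range(n):
            frames.append(simulate_task_battery(
                design, pre, post, seed=rng, animal_id=f"M{idx}", group=group))
            idx += 1
    return pd.concat(frames, ignore_index=True)
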
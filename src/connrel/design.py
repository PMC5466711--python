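"""Counterbalanced session schedules.

A serial-scanning study repeats several scan conditions (e.g. rest,
Inscapes, movie, flanker) within every session, across many sessions.
Order effects are controlled by three balance constraints on the
per-subject schedule grid:

1. every session contains each condition exactly once (row completeness);
2. each condition occupies each within-session slot equally often across
   sessions (slot balance);
3. each condition is immediately preceded, within sessions, by each other
   condition equally often (predecessor balance).

Non-rest conditions additionally rotate through a small set of stimulus
*exemplars* such that within every consecutive block of ``n_exemplars``
sessions each exemplar is used exactly once.

Schedules are found by seeded randomized backtracking over session rows
with constraint propagation; the search is exact, so a returned schedule
always verifies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudySchedule",
    "ConstraintReport",
    "InfeasibleScheduleError",
    "generate_schedule",
    "generate_cohort",
    "verify_schedule",
]

DEFAULT_CONDITIONS = ("rest", "inscapes", "movie", "flanker")
REST_LABEL = "rest"


class InfeasibleScheduleError(RuntimeError):
    """No constraint-satisfying schedule found within the search budget."""


@dataclass
class StudySchedule:
    """A per-subject assignment of (condition, exemplar) to session x slot."""

    subject_id: str
    conditions: tuple  # ordered condition labels
    condition_grid: np.ndarray  # (n_sessions, n_slots) of condition indices
    exemplar_grid: np.ndarray  # (n_sessions, n_slots) of 1-based exemplars
    n_exemplars: int = 3

    @property
    def n_sessions(self) -> int:
        return self.condition_grid.shape[0]

    @property
    def n_slots(self) -> int:
        return self.condition_grid.shape[1]

    def cell(self, session: int, slot: int):
        """(condition_label, exemplar) at 0-based session/slot."""
        c = self.condition_grid[session, slot]
        return self.conditions[c], int(self.exemplar_grid[session, slot])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.n_sessions):
            for t in range(self.n_slots):
                cond, ex = self.cell(s, t)
                rows.append((self.subject_id, s + 1, t + 1, cond, ex))
        return pd.DataFrame(
            rows, columns=["subject_id", "session", "slot", "condition",
                           "exemplar"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, conditions=None,
                   n_exemplars: int = 3) -> "StudySchedule":
        if conditions is None:
            conditions = tuple(pd.unique(df["condition"]))
        n_sessions = int(df["session"].max())
        n_slots = int(df["slot"].max())
        cond_grid = np.full((n_sessions, n_slots), -1, dtype=int)
        ex_grid = np.ones((n_sessions, n_slots), dtype=int)
        cidx = {c: i for i, c in enumerate(conditions)}
        for _, r in df.iterrows():
            if r["condition"] not in cidx:
                raise ValueError(f"unknown condition label {r['condition']!r}")
            cond_grid[int(r["session"]) - 1, int(r["slot"]) - 1] = \
                cidx[r["condition"]]
            ex_grid[int(r["session"]) - 1, int(r["slot"]) - 1] = \
                int(r["exemplar"])
        if (cond_grid < 0).any():
            raise ValueError("schedule grid has unpopulated cells")
        return cls(str(df["subject_id"].iloc[0]), tuple(conditions),
                   cond_grid, ex_grid, n_exemplars=n_exemplars)


@dataclass
class ConstraintReport:
    """Observed counts and pass/fail for every schedule constraint."""

    entries: list = field(default_factory=list)  # (name, detail, passed)

    def add(self, name: str, detail: str, passed: bool) -> None:
        self.entries.append((name, detail, bool(passed)))

    @property
    def ok(self) -> bool:
        return all(p for _, _, p in self.entries)

    def failures(self) -> list:
        return [(n, d) for n, d, p in self.entries if not p]

    def __str__(self) -> str:
        lines = []
        for name, detail, passed in self.entries:
            lines.append(f"[{'PASS' if passed else 'FAIL'}] {name}: {detail}")
        return "\n".join(lines)


def _exemplar_blocks(n_sessions: int, n_exemplars: int):
    return [range(b, b + n_exemplars)
            for b in range(0, n_sessions, n_exemplars)]


def _search_condition_grid(n_sessions, n_cond, slot_target, pred_target,
                           rng, node_budget=200_000):
    """One randomized DFS attempt; returns grid or None on budget exhaustion."""
    perms = list(itertools.permutations(range(n_cond)))
    slot_counts = np.zeros((n_cond, n_cond), dtype=int)  # [condition, slot]
    pred_counts = np.zeros((n_cond, n_cond), dtype=int)  # [predecessor, cond]
    grid = np.zeros((n_sessions, n_cond), dtype=int)
    nodes = 0

    def admissible(perm):
        for slot, c in enumerate(perm):
            if slot_counts[c, slot] + 1 > slot_target:
                return False
        for a, b in zip(perm[:-1], perm[1:]):
            if pred_counts[a, b] + 1 > pred_target:
                return False
        return True

    def apply(perm, sign):
        for slot, c in enumerate(perm):
            slot_counts[c, slot] += sign
        for a, b in zip(perm[:-1], perm[1:]):
            pred_counts[a, b] += sign

    def dfs(row):
        nonlocal nodes
        if row == n_sessions:
            return True
        order = rng.permutation(len(perms))
        for pi in order:
            perm = perms[pi]
            nodes += 1
            if nodes > node_budget:
                return False
            if admissible(perm):
                apply(perm, +1)
                grid[row] = perm
                if dfs(row + 1):
                    return True
                apply(perm, -1)
        return False

    return grid if dfs(0) else None


def generate_schedule(n_sessions: int = 12,
                      conditions=DEFAULT_CONDITIONS,
                      n_exemplars: int = 3,
                      seed: int = 0,
                      subject_id: str = "sub-01",
                      rest_label: str = REST_LABEL,
                      n_restarts: int = 10_000) -> StudySchedule:
    """Generate a schedule satisfying all counterbalancing constraints.

    Deterministic given ``seed``; different seeds may yield different valid
    schedules.  Raises :class:`InfeasibleScheduleError` when the balance
    targets are non-integral or no solution is found within the restart
    budget.
    """
    conditions = tuple(conditions)
    n_cond = len(conditions)
    if len(set(conditions)) != n_cond:
        raise ValueError("condition labels must be distinct")
    if n_cond < 2:
        raise ValueError("need at least two conditions")
    if n_sessions % n_cond:
        raise InfeasibleScheduleError(
            f"slot balance impossible: {n_sessions} sessions not divisible "
            f"by {n_cond} conditions")
    if n_exemplars > 1 and n_sessions % n_exemplars:
        raise InfeasibleScheduleError(
            f"exemplar rotation impossible: {n_sessions} sessions not "
            f"divisible by {n_exemplars} exemplars")
    slot_target = n_sessions // n_cond
    n_transitions = n_sessions * (n_cond - 1)
    n_pairs = n_cond * (n_cond - 1)
    if n_transitions % n_pairs:
        raise InfeasibleScheduleError(
            f"predecessor balance impossible: {n_transitions} transitions "
            f"cannot split evenly over {n_pairs} ordered condition pairs")
    pred_target = n_transitions // n_pairs

    root = np.random.SeedSequence([seed, n_sessions, n_cond, n_exemplars])
    for attempt, child in enumerate(root.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        grid = _search_condition_grid(n_sessions, n_cond, slot_target,
                                      pred_target, rng)
        if grid is not None:
            break
    else:
        raise InfeasibleScheduleError(
            f"no schedule satisfying slot balance (target {slot_target}) and "
            f"predecessor balance (target {pred_target}) found in "
            f"{n_restarts} restarts")

    # Exemplar rotation is independent of condition order: per non-rest
    # condition, each consecutive block of n_exemplars sessions gets a
    # random permutation of the exemplar indices.
    ex_rng = np.random.default_rng(root.spawn(n_restarts + 1)[-1])
    ex_grid = np.ones((n_sessions, n_cond), dtype=int)
    for c, label in enumerate(conditions):
        if label == rest_label or n_exemplars == 1:
            continue
        per_session = np.empty(n_sessions, dtype=int)
        for block in _exemplar_blocks(n_sessions, n_exemplars):
            per_session[list(block)] = ex_rng.permutation(n_exemplars) + 1
        for s in range(n_sessions):
            slot = int(np.where(grid[s] == c)[0][0])
            ex_grid[s, slot] = per_session[s]

    return StudySchedule(subject_id, conditions, grid, ex_grid,
                         n_exemplars=n_exemplars)


def generate_cohort(n_subjects: int, seed: int = 0, **kwargs) -> list:
    """Schedules for a cohort; subject k uses seed ``seed + k`` so exemplar
    and condition orderings vary across participants."""
    return [
        generate_schedule(seed=seed + k, subject_id=f"sub-{k + 1:02d}",
                          **kwargs)
        for k in range(n_subjects)
    ]


def verify_schedule(schedule: StudySchedule,
                    rest_label: str = REST_LABEL) -> ConstraintReport:
    """Exhaustively tally every constraint and report observed counts."""
    grid = schedule.condition_grid
    n_sessions, n_slots = grid.shape
    n_cond = len(schedule.conditions)
    report = ConstraintReport()

    if grid.min() < 0 or grid.max() >= n_cond:
        raise ValueError("malformed grid: condition index out of range")

    # 1. row completeness
    rows_ok = all(sorted(grid[s]) == list(range(n_cond))
                  for s in range(n_sessions))
    report.add("row_completeness",
               "each session contains every condition exactly once",
               rows_ok and n_slots == n_cond)

    # 2. slot balance
    slot_target = n_sessions // n_cond
    slot_counts = np.zeros((n_cond, n_slots), dtype=int)
    for s in range(n_sessions):
        for t in range(n_slots):
            slot_counts[grid[s, t], t] += 1
    report.add("slot_balance",
               f"counts {slot_counts.tolist()} (target {slot_target})",
               bool((slot_counts == slot_target).all()))

    # 3. predecessor balance
    pred_target = n_sessions * (n_slots - 1) // (n_cond * (n_cond - 1))
    pred_counts = np.zeros((n_cond, n_cond), dtype=int)
    for s in range(n_sessions):
        for t in range(n_slots - 1):
            pred_counts[grid[s, t], grid[s, t + 1]] += 1
    off_diag = pred_counts[~np.eye(n_cond, dtype=bool)]
    report.add("predecessor_balance",
               f"counts {pred_counts.tolist()} (target {pred_target})",
               bool((off_diag == pred_target).all()
                    and (np.diag(pred_counts) == 0).all()))

    # 4. exemplar rotation per block of n_exemplars sessions
    n_ex = schedule.n_exemplars
    ex_ok = True
    bad_blocks = []
    if n_ex > 1 and n_sessions % n_ex == 0:
        for c, label in enumerate(schedule.conditions):
            if label == rest_label:
                continue
            for b, block in enumerate(_exemplar_blocks(n_sessions, n_ex)):
                seen = sorted(
                    int(schedule.exemplar_grid[s, np.where(grid[s] == c)[0][0]])
                    for s in block)
                if seen != list(range(1, n_ex + 1)):
                    ex_ok = False
                    bad_blocks.append((label, b))
    report.add("exemplar_rotation",
               ("each exemplar once per consecutive "
                f"{n_ex}-session block" if ex_ok
                else f"violated in blocks {bad_blocks}"),
               ex_ok)
    return report
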
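"""Matched case-control balancing and subject-grouped 4:1:1 splitting.

Each ensemble member re-runs a stochastic greedy matching: cases are visited
in seeded random order and each takes the nearest still-unused control that
matches exactly on sex and collection site and falls within calipers on age,
mean framewise displacement and intracranial volume.  Matched pairs are then
assigned jointly to train/validation/test sets at an instance-count ratio of
approximately 4:1:1, with all instances of one subject kept in the same set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "MatchConfig",
    "BalancedSet",
    "SplitAssignment",
    "match_controls",
    "split_4_1_1",
    "balance_report",
    "records_from_frame",
]

_CALIPER_COVARIATES = ("age", "mean_fwd", "icv")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's matching covariates and scan instances."""

    subject_id: str
    group: str  # "case" | "control"
    sex: str  # "F" | "M"
    collection: str
    age: float
    mean_fwd: float
    icv: float
    instance_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in ("case", "control"):
            raise ValueError(f"group must be case/control, got {self.group!r}")
        if self.age < 0 or self.mean_fwd < 0 or self.icv <= 0:
            raise ValueError(f"invalid covariates for {self.subject_id}")
        if not self.instance_ids:
            object.__setattr__(self, "instance_ids", (f"{self.subject_id}_01",))


@dataclass(frozen=True)
class MatchConfig:
    """Caliper tolerances operationalising "statistically similar".

    ``caliper_icv`` is in units of the pooled (case+control) ICV standard
    deviation; the others are absolute.
    """

    caliper_age: float = 3.0  # years
    caliper_fwd: float = 0.1  # mm
    caliper_icv: float = 0.5  # pooled s.d. fractions
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.caliper_age, self.caliper_fwd, self.caliper_icv) <= 0:
            raise ValueError("all calipers must be > 0")


@dataclass(frozen=True)
class BalancedSet:
    pairs: tuple[tuple[str, str], ...]  # (case_id, control_id)
    unmatched_cases: tuple[str, ...]
    seed: int = 0


@dataclass(frozen=True)
class SplitAssignment:
    assignment: dict[str, str] = field(default_factory=dict)  # subject_id -> set

    def subjects_in(self, which: str) -> tuple[str, ...]:
        return tuple(s for s, w in self.assignment.items() if w == which)


def records_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    """Build SubjectRecords from a covariate table.

    Expected columns: subject_id, group, sex, collection, age, mean_fwd, icv
    and optionally instance_id (one row per instance; subject rows are
    grouped).
    """
    required = {"subject_id", "group", "sex", "collection", "age", "mean_fwd", "icv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    records = []
    for sid, g in df.groupby("subject_id", sort=True):
        first = g.iloc[0]
        inst = (
            tuple(str(x) for x in g["instance_id"])
            if "instance_id" in g.columns
            else ()
        )
        records.append(
            SubjectRecord(
                subject_id=str(sid),
                group=str(first["group"]),
                sex=str(first["sex"]),
                collection=str(first["collection"]),
                age=float(first["age"]),
                mean_fwd=float(first["mean_fwd"]),
                icv=float(first["icv"]),
                instance_ids=inst,
            )
        )
    return records


def _pooled_sd(values: np.ndarray) -> float:
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return sd if sd > 0 else 1.0


def match_controls(
    cases: list[SubjectRecord],
    controls: list[SubjectRecord],
    cfg: MatchConfig,
) -> BalancedSet:
    """Greedy nearest-neighbour caliper matching without replacement.

    Cases are processed in seeded random order; each takes the eligible
    control (exact sex and collection, within all calipers) minimising the
    normalised Euclidean distance over (age, fwd, icv).  Controls are never
    reused.  An empty control list is not an error: every case is unmatched.
    """
    if not cases:
        raise ValueError("empty case list")
    case_ids = {c.subject_id for c in cases}
    if case_ids & {c.subject_id for c in controls}:
        raise ValueError("case and control lists must be disjoint")

    everyone = cases + controls
    icv_sd = _pooled_sd(np.array([r.icv for r in everyone]))
    # calipers gate eligibility; the nearest-neighbour distance is normalised
    # by each covariate's pooled s.d. so all three weigh comparably
    calipers = np.array([cfg.caliper_age, cfg.caliper_fwd, cfg.caliper_icv * icv_sd])
    scales = np.array(
        [
            _pooled_sd(np.array([getattr(r, c) for r in everyone]))
            for c in _CALIPER_COVARIATES
        ]
    )

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(cases))
    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    ctrl_cov = np.array([[c.age, c.mean_fwd, c.icv] for c in controls]) if controls else np.empty((0, 3))
    for idx in order:
        case = cases[idx]
        best = None
        best_d = np.inf
        cv = np.array([case.age, case.mean_fwd, case.icv])
        for k, ctrl in enumerate(controls):
            if ctrl.subject_id in used:
                continue
            if ctrl.sex != case.sex or ctrl.collection != case.collection:
                continue
            delta = np.abs(ctrl_cov[k] - cv)
            if np.any(delta > calipers):
                continue
            d = float(np.sqrt(np.sum((delta / scales) ** 2)))
            if d < best_d:
                best_d = d
                best = ctrl
        if best is None:
            unmatched.append(case.subject_id)
        else:
            used.add(best.subject_id)
            pairs.append((case.subject_id, best.subject_id))
    return BalancedSet(pairs=tuple(pairs), unmatched_cases=tuple(unmatched), seed=cfg.seed)


def split_4_1_1(
    balanced: BalancedSet,
    records: list[SubjectRecord],
    seed: int,
    ratio: tuple[int, int, int] = (4, 1, 1),
) -> SplitAssignment:
    """Assign matched pairs jointly to train/validation/test at ~4:1:1.

    Quotas are in instance counts; pairs are placed in seeded random order
    into the set whose fill fraction is lowest, which keeps the realised
    instance ratio within one pair of the target.  Subject-level partition is
    guaranteed because assignment is by subject (both pair members together).
    """
    if len(balanced.pairs) < 6:
        raise ValueError(
            f"need >= 6 matched pairs to split 4:1:1, got {len(balanced.pairs)}"
        )
    by_id = {r.subject_id: r for r in records}
    n_inst = {
        p: len(by_id[p[0]].instance_ids) + len(by_id[p[1]].instance_ids)
        for p in balanced.pairs
    }
    total = sum(n_inst.values())
    names = ("train", "validation", "test")
    weights = np.array(ratio, dtype=float) / sum(ratio)
    quota = weights * total
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(balanced.pairs))
    filled = np.zeros(3)
    assignment: dict[str, str] = {}
    for idx in order:
        pair = balanced.pairs[idx]
        # lowest fill fraction relative to quota gets the next pair
        target = int(np.argmin(filled / quota))
        filled[target] += n_inst[pair]
        assignment[pair[0]] = names[target]
        assignment[pair[1]] = names[target]
    return SplitAssignment(assignment=assignment)


def balance_report(
    balanced: BalancedSet, records: list[SubjectRecord]
) -> dict[str, float | bool]:
    """Post-matching covariate balance diagnostics.

    Standardised mean difference (SMD: mean difference over pooled s.d.)
    for age, fwd and icv between matched cases and controls, plus exact
    contingency equality for sex and collection (always True by
    construction of the matcher, reported as a check).
    """
    if len(balanced.pairs) < 2:
        raise ValueError("need >= 2 pairs for a balance report")
    by_id = {r.subject_id: r for r in records}
    cases = [by_id[c] for c, _ in balanced.pairs]
    ctrls = [by_id[k] for _, k in balanced.pairs]
    out: dict[str, float | bool] = {}
    for cov in _CALIPER_COVARIATES:
        a = np.array([getattr(r, cov) for r in cases], dtype=float)
        b = np.array([getattr(r, cov) for r in ctrls], dtype=float)
        pooled = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2)
        out[f"smd_{cov}"] = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
    out["sex_exact"] = all(a.sex == b.sex for a, b in zip(cases, ctrls))
    out["collection_exact"] = all(
        a.collection == b.collection for a, b in zip(cases, ctrls)
    )
    out["n_pairs"] = len(balanced.pairs)
    return out
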
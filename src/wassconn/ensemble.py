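"""Ensemble training, prediction aggregation and ensemble-size projection.

Each ensemble member gets its own seed, and with it: a fresh stochastic
case-control matching, a fresh subject-grouped 4:1:1 split, a fresh scramble
permutation, and its own weight initialisation.  Only each member's own
test-set predictions are recorded, which structurally prevents train/test
cross-contamination.  The final score is the AUROC of per-instance
probabilities averaged over every member whose test set covered the
instance.

As members are added, the aggregated AUROC grows towards a ceiling; the
saturating curve AUROC(m) = L - a * m^(-b) (0.5 <= L <= 1, a >= 0, b > 0)
is fit to (ensemble size, AUROC) points to estimate that ceiling L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.metrics import roc_auc_score

from .encoding import EdgePermutation, Instance, encode_instance
from .matching import BalancedSet, MatchConfig, SubjectRecord, match_controls, split_4_1_1
from .nn import ModelSpec, TrainedModel, train_member

__all__ = [
    "EnsembleResult",
    "ProjectionFit",
    "run_ensemble",
    "aggregate_auroc",
    "fit_projection",
    "audit_leakage",
]


@dataclass
class MemberRecord:
    """Provenance of one trained ensemble member."""

    model_id: int
    seed: int
    model: TrainedModel
    permutation: EdgePermutation
    balanced: BalancedSet
    split_sizes: dict[str, int]
    train_subjects: frozenset[str]
    val_subjects: frozenset[str]
    test_subjects: frozenset[str]
    scaler: tuple[np.ndarray, np.ndarray] | None = None  # train-set (mean, sd)


@dataclass
class EnsembleResult:
    """Prediction table plus per-member provenance.

    ``predictions`` has columns (instance_id, model_id, prob); ``labels``
    maps instance_id -> 0/1.  Only test-set predictions are present.
    """

    predictions: pd.DataFrame
    labels: dict[str, int]
    instance_subject: dict[str, str]
    members: list[MemberRecord] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "n_members": len(self.members),
            "members": [
                {
                    "model_id": m.model_id,
                    "seed": m.seed,
                    "best_epoch": m.model.best_epoch,
                    "n_pairs": len(m.balanced.pairs),
                    "split_sizes": m.split_sizes,
                }
                for m in self.members
            ],
        }


def _encode_set(instances, subjects, inst_by_subject, perm, channels):
    xs, ys, ids = [], [], []
    for sid in sorted(subjects):
        for inst in inst_by_subject[sid]:
            sub = Instance(
                instance_id=inst.instance_id,
                subject_id=inst.subject_id,
                channels={c: inst.channels[c] for c in channels},
                label=inst.label,
            )
            xs.append(encode_instance(sub, perm, channel_order=channels))
            ys.append(1 if inst.label == "case" else 0)
            ids.append(inst.instance_id)
    return np.array(xs), np.array(ys), ids


def run_ensemble(
    records: list[SubjectRecord],
    instances: dict[str, Instance],
    n_models: int,
    spec: ModelSpec,
    match_cfg: MatchConfig,
    seed: int,
    channels: tuple[str, ...] = ("structural",),
    redraw_permutation: bool = True,
    standardize: bool = True,
) -> EnsembleResult:
    """Train ``n_models`` independent members and collect test predictions.

    ``records`` hold the matching covariates; ``instances`` map instance id
    to the channel stack.  ``channels`` selects which channels feed the
    network (e.g. structural only, functional only, or both).  With
    ``standardize`` each rectangle cell (edge) is z-scored using the
    member's training-set statistics before entering the network, so the
    filters see deviations from the cohort baseline rather than raw
    per-edge magnitudes.  Member failures (e.g. a split too small to train)
    are skipped; if every member fails a RuntimeError is raised.
    """
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    cases = [r for r in records if r.group == "case"]
    controls = [r for r in records if r.group == "control"]
    inst_by_subject: dict[str, list[Instance]] = {}
    for inst in instances.values():
        inst_by_subject.setdefault(inst.subject_id, []).append(inst)
    n_regions = next(iter(instances.values())).n_regions

    member_seeds = np.random.SeedSequence(seed).generate_state(n_models) % (2**31)
    rows = []
    members: list[MemberRecord] = []
    shared_perm = EdgePermutation(n_regions, int(member_seeds[0]))
    for m, mseed in enumerate(member_seeds):
        mseed = int(mseed)
        try:
            balanced = match_controls(
                cases, controls, MatchConfig(
                    caliper_age=match_cfg.caliper_age,
                    caliper_fwd=match_cfg.caliper_fwd,
                    caliper_icv=match_cfg.caliper_icv,
                    seed=mseed,
                ),
            )
            split = split_4_1_1(balanced, records, seed=mseed)
            perm = (
                EdgePermutation(n_regions, mseed) if redraw_permutation else shared_perm
            )
            sets = {
                w: _encode_set(instances, split.subjects_in(w), inst_by_subject,
                               perm, channels)
                for w in ("train", "validation", "test")
            }
            xtr, ytr, _ = sets["train"]
            xva, yva, _ = sets["validation"]
            xte, yte, test_ids = sets["test"]
            scaler = None
            if standardize:
                mu = xtr.mean(axis=0)
                sd = xtr.std(axis=0)
                sd[sd == 0] = 1.0
                scaler = (mu, sd)
                xtr = (xtr - mu) / sd
                xva = (xva - mu) / sd
                xte = (xte - mu) / sd
            member_spec = ModelSpec(
                n_filters=spec.n_filters, dense_units=spec.dense_units,
                n_dense=spec.n_dense, dropout=spec.dropout, epochs=spec.epochs,
                batch_size=spec.batch_size, learning_rate=spec.learning_rate,
                seed=mseed,
            )
            model = train_member(member_spec, xtr, ytr, xva, yva)
        except (ValueError, RuntimeError):
            continue
        probs = model.predict_proba(xte)
        for iid, p in zip(test_ids, probs):
            rows.append({"instance_id": iid, "model_id": m, "prob": float(p)})
        members.append(
            MemberRecord(
                model_id=m, seed=mseed, model=model, permutation=perm,
                balanced=balanced,
                split_sizes={"train": len(ytr), "validation": len(yva),
                             "test": len(yte)},
                train_subjects=frozenset(split.subjects_in("train")),
                val_subjects=frozenset(split.subjects_in("validation")),
                test_subjects=frozenset(split.subjects_in("test")),
                scaler=scaler,
            )
        )
    if not members:
        raise RuntimeError("all ensemble members failed")
    labels = {iid: (1 if inst.label == "case" else 0) for iid, inst in instances.items()}
    inst_subject = {iid: inst.subject_id for iid, inst in instances.items()}
    return EnsembleResult(
        predictions=pd.DataFrame(rows, columns=["instance_id", "model_id", "prob"]),
        labels=labels,
        instance_subject=inst_subject,
        members=members,
    )


def aggregate_auroc(
    predictions: pd.DataFrame,
    labels: dict[str, int],
    model_subset: list[int] | None = None,
) -> float:
    """AUROC of per-instance mean predicted probability.

    Each covered instance's score is the mean of its probabilities over the
    (optionally subset) models whose test set contained it; the AUROC is
    P(score_case > score_control) + 0.5 * P(tie) over all case-control
    instance pairs.
    """
    df = predictions
    if model_subset is not None:
        df = df[df["model_id"].isin(set(model_subset))]
    if df.empty:
        raise ValueError("no predictions to aggregate")
    score = df.groupby("instance_id")["prob"].mean()
    y = np.array([labels[i] for i in score.index])
    if len(np.unique(y)) < 2:
        raise ValueError("covered instances contain a single class: AUROC undefined")
    return float(roc_auc_score(y, score.to_numpy()))


def audit_leakage(result: EnsembleResult) -> bool:
    """Check no prediction came from a model trained on the same subject.

    True when, for every member, the subjects of its predicted instances are
    disjoint from its train and validation subject sets.
    """
    preds_by_model = result.predictions.groupby("model_id")["instance_id"]
    for m in result.members:
        pred_subjects = {
            result.instance_subject[i] for i in preds_by_model.get_group(m.model_id)
        } if m.model_id in preds_by_model.groups else set()
        if pred_subjects & (m.train_subjects | m.val_subjects):
            return False
    return True


@dataclass(frozen=True)
class ProjectionFit:
    """Saturating fit AUROC(m) = L - a * m^(-b)."""

    limit: float
    a: float
    b: float
    sizes: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    functional_form: str = "L - a * m**(-b)"

    def predict(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        return self.limit - self.a * m ** (-self.b)


def fit_projection(sizes, aurocs) -> ProjectionFit:
    """Least-squares fit of the hard-limit curve to (size, AUROC) points.

    The rate exponent b is profiled on a logarithmic grid: for each
    candidate b, (L, a) solve a constrained linear least-squares problem.
    Because the model degenerates as b -> 0 (a near-linear drift can mimic
    saturation with an arbitrarily inflated asymptote), the fit is made
    identifiable by a conservative tie-break: among all b whose profiled
    error is within 5% of the minimum, the largest (most saturating) b is
    chosen — the smallest asymptote the data cannot distinguish from the
    best fit.  The selected solution is then polished by bounded nonlinear
    least squares.  Deterministic given the inputs.
    """
    sizes = np.asarray(sizes, dtype=float)
    aurocs = np.asarray(aurocs, dtype=float)
    if sizes.size < 4:
        raise ValueError("need >= 4 (size, auroc) points")
    if np.any(np.diff(sizes) <= 0):
        raise ValueError("sizes must be strictly increasing")

    def f(m, L, a, b):
        return L - a * m ** (-b)

    if np.ptp(aurocs) < 1e-12:
        const = float(np.clip(aurocs[0], 0.5, 1.0))
        fitted = np.full_like(aurocs, const)
        return ProjectionFit(limit=const, a=0.0, b=1.0, sizes=sizes,
                             fitted=fitted, residuals=aurocs - fitted)

    grid = np.logspace(np.log10(0.05), np.log10(5.0), 80)
    profile = []
    for b in grid:
        x = sizes ** (-b)
        design = np.vstack([np.ones_like(x), -x]).T
        coef, *_ = np.linalg.lstsq(design, aurocs, rcond=None)
        L = float(np.clip(coef[0], 0.5, 1.0))
        a = float(max(coef[1], 0.0))
        sse = float(np.sum((L - a * x - aurocs) ** 2))
        profile.append((b, L, a, sse))
    sse_min = min(p[3] for p in profile)
    window = [p for p in profile if p[3] <= sse_min * 1.05 + 1e-12]
    b0, l0, a0, _ = window[-1]  # largest near-optimal b

    try:
        popt, _ = curve_fit(
            f, sizes, aurocs,
            p0=[np.clip(l0, 0.5 + 1e-9, 1.0 - 1e-9), max(a0, 1e-9), b0],
            bounds=([0.5, 0.0, b0 / 1.25], [1.0, np.inf, b0 * 1.25]),
            maxfev=20000,
        )
        L, a, b = (float(v) for v in popt)
    except RuntimeError:
        L, a, b = l0, a0, b0  # grid solution is already a valid fit
    fitted = f(sizes, L, a, b)
    return ProjectionFit(limit=L, a=a, b=b, sizes=sizes, fitted=fitted,
                         residuals=aurocs - fitted)
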
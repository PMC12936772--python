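"""Repeated-split stability selection and multimodal fusion.

The signature-building procedure: one quarter of the cohort is held out
as an internal test set and the model is trained on the rest; this is
repeated 8 times with fresh random splits.  Covariates selected in at
least 50% of the repeats form the final covariate set, which is refit on
the full cohort (the resulting full-cohort ROC is an apparent, i.e.
optimistic, estimate and is labelled as such).

Fusion levels for combining modalities:
  early        — concatenate raw covariate matrices and model jointly;
  intermediate — concatenate only each single-modality signature's
                 selected covariates, then model;
  late         — one column per modality holding that modality
                 signature's risk scores, then model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmr
from .bmr import Signature, predict_risk, to_signature
from .evaluation import ROCResult, roc_auc

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    n_repeats: int
    mode: str
    seed: int
    assignments: list[tuple[list[str], list[str]]]  # (train ids, test ids) per repeat


@dataclass
class SelectionTally:
    counts: dict[str, int]
    n_repeats: int
    threshold: float = 0.5


@dataclass
class RepeatOutcome:
    repeat: int
    signature: Signature
    selected: list[str]
    train_auc: float
    test_auc: float


@dataclass
class RepeatedRun:
    repeats: list[RepeatOutcome]
    tally: SelectionTally

    def auc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"repeat": r.repeat, "train_auc": r.train_auc, "test_auc": r.test_auc}
             for r in self.repeats]
        )


@dataclass
class FinalModel:
    generated: bool
    selected: list[str] = field(default_factory=list)
    signature: Signature | None = None
    result: bmr.BMRResult | None = None
    roc: ROCResult | None = None
    scores: pd.Series | None = None
    note: str = ""


def _largest_remainder(ideal: np.ndarray, total: int) -> np.ndarray:
    counts = np.floor(ideal).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def make_splits(
    cohort: pd.DataFrame,
    n_repeats: int = 8,
    test_frac: float = 0.25,
    mode: str = "balanced_train",
    seed: int = 0,
) -> SplitPlan:
    """Random train/test assignments, deterministic given the seed.

    balanced_train: the training set has equal class counts,
    train_per_class = round(n * (1 - test_frac)) // 2, remainder to test
    (with 91 non-cancer / 79 cancer and test_frac 0.25 this gives the
    64/64 train and 27/15 test composition).  proportional: the test
    fraction is stratified within each class with largest-remainder
    rounding.
    """
    if mode not in ("balanced_train", "proportional"):
        raise ValueError(f"unknown split mode {mode!r}")
    ids = cohort["patient_id"].to_numpy()
    y = cohort["outcome"].to_numpy()
    n = len(ids)
    # keyed on sorted patient ids (not row positions) so the plan is
    # invariant to row order of the cohort table
    idx_by_class = [np.sort(ids[y == c]) for c in (0, 1)]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 55]))

    if mode == "balanced_train":
        train_total = int(np.floor(n * (1 - test_frac) + 0.5))
        per_class = train_total // 2
        max_per_class = min(len(i) for i in idx_by_class)
        if per_class > max_per_class:
            raise ValueError(
                f"balanced train of {per_class} per class infeasible; "
                f"achievable maximum is {max_per_class}"
            )
        n_train = [per_class, per_class]
    else:
        ideal_test = np.array([len(i) * test_frac for i in idx_by_class])
        total_test = int(round(n * test_frac))
        n_test = _largest_remainder(ideal_test, total_test)
        n_train = [len(i) - t for i, t in zip(idx_by_class, n_test)]

    assignments = []
    for _ in range(n_repeats):
        train_ids: list[str] = []
        test_ids: list[str] = []
        for cls, cls_ids in enumerate(idx_by_class):
            perm = rng.permutation(cls_ids)
            train_ids.extend(perm[: n_train[cls]])
            test_ids.extend(perm[n_train[cls]:])
        assignments.append((sorted(train_ids), sorted(test_ids)))
    return SplitPlan(n_repeats=n_repeats, mode=mode, seed=seed, assignments=assignments)


def _fit(X: pd.DataFrame, y: pd.Series, method: str, seed: int = 0, **kwargs):
    """One signature fit; returns (signature, selected covariates)."""
    if method == "bmr":
        res = bmr.fit_bmr(X, y, **kwargs)
        return to_signature(res, provenance={"method": "bmr"}), res.selected
    if method == "enet":
        sig, _ = bmr.fit_elastic_net(X, y, seed=seed, **kwargs)
        return sig, list(sig.covariates)
    raise ValueError(f"unknown method {method!r}")


def run_repeated(
    X: pd.DataFrame, y: pd.Series, plan: SplitPlan, method: str = "bmr", **fit_kwargs
) -> RepeatedRun:
    """Fit on each repeat's training split; AUC both partitions; tally selections."""
    y = pd.Series(np.asarray(y), index=X.index) if not isinstance(y, pd.Series) else y
    counts: dict[str, int] = {}
    outcomes = []
    for k, (train_ids, test_ids) in enumerate(plan.assignments):
        try:
            sig, selected = _fit(X.loc[train_ids], y.loc[train_ids], method,
                                 seed=plan.seed + k, **fit_kwargs)
        except Exception as exc:
            raise RuntimeError(f"repeat {k}: fit failed") from exc
        for c in selected:
            counts[c] = counts.get(c, 0) + 1
        s_train = predict_risk(sig, X.loc[train_ids])
        s_test = predict_risk(sig, X.loc[test_ids])
        train_auc = _safe_auc(s_train, y.loc[train_ids])
        test_auc = _safe_auc(s_test, y.loc[test_ids])
        outcomes.append(RepeatOutcome(k, sig, selected, train_auc, test_auc))
    tally = SelectionTally(counts=counts, n_repeats=plan.n_repeats)
    return RepeatedRun(repeats=outcomes, tally=tally)


def _safe_auc(scores: pd.Series, y: pd.Series) -> float:
    arr = scores.to_numpy()
    if np.ptp(arr) == 0:
        return 0.5  # constant (e.g. intercept-only) risk score
    return roc_auc(arr, y.to_numpy()).auc


def stability_select(tally: SelectionTally) -> list[str]:
    """Covariates selected in at least `threshold` of the repeats (>= 4 of 8)."""
    need = tally.threshold * tally.n_repeats - 1e-9
    return sorted(c for c, k in tally.counts.items() if k >= need)


def final_signature(
    X_full: pd.DataFrame, y_full: pd.Series, selected: list[str], method: str = "bmr",
    seed: int = 0,
) -> FinalModel:
    """Refit the stability-selected covariates on all patients.

    Empty selection yields a 'no final model' report.  The full-cohort
    ROC of the refit signature is an apparent (optimistic) estimate.
    """
    if not selected:
        return FinalModel(generated=False, note="no final model: no covariate "
                                                "passed the stability threshold")
    y_arr = np.asarray(y_full)
    if method == "bmr":
        res = bmr.fit_bayes_logistic(X_full, y_arr, covariates=selected)
        sig = to_signature(res, provenance={"method": "bmr", "fit": "full-cohort refit",
                                            "estimate": "apparent (optimistic)"})
    else:
        sig, _ = bmr.fit_elastic_net(X_full[selected], y_arr, seed=seed)
        res = None
    scores = predict_risk(sig, X_full)
    roc = roc_auc(scores.to_numpy(), y_arr) if np.ptp(scores.to_numpy()) > 0 else None
    return FinalModel(generated=True, selected=list(selected), signature=sig,
                      result=res, roc=roc, scores=scores)


# ---------------------------------------------------------------------------
# fusion


def _prefixed_concat(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    ids = None
    for m in matrices.values():
        ids = m.index if ids is None else ids.intersection(m.index)
    if ids is None or len(ids) == 0:
        raise ValueError("matrices share no patient ids")
    seen: set[str] = set()
    parts = []
    for modality, m in matrices.items():
        part = m.loc[ids]
        rename = {c: f"{modality}:{c}" for c in part.columns if c in seen}
        seen.update(part.columns)
        parts.append(part.rename(columns=rename))
    out = pd.concat(parts, axis=1)
    out.attrs["modality"] = "fused"
    return out


def fuse_early(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Covariate-level fusion: column-concatenate raw modality matrices."""
    return _prefixed_concat(matrices)


def fuse_intermediate(
    signatures: dict[str, Signature], matrices: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Feature-level fusion: concatenate each signature's selected covariates."""
    restricted = {}
    for modality, sig in signatures.items():
        m = matrices[modality]
        missing = [c for c in sig.covariates if c not in m.columns]
        if missing:
            raise ValueError(f"{modality}: signature covariates missing: {missing}")
        restricted[modality] = m[list(sig.covariates)]
    return _prefixed_concat(restricted)


def fuse_late(
    signatures: dict[str, Signature], matrices: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Signature-level fusion: one risk-score column per modality."""
    cols = {}
    ids = None
    for modality, sig in signatures.items():
        s = predict_risk(sig, matrices[modality])
        cols[f"score_{modality}"] = s
        ids = s.index if ids is None else ids.intersection(s.index)
    out = pd.DataFrame({k: v.loc[ids] for k, v in cols.items()})
    out.attrs["modality"] = "score"
    return out


# ---------------------------------------------------------------------------
# end-to-end driver


@dataclass
class PipelineReport:
    run: RepeatedRun
    selected: list[str]
    final: FinalModel


def run_pipeline(
    X: pd.DataFrame,
    cohort: pd.DataFrame,
    n_repeats: int = 8,
    test_frac: float = 0.25,
    mode: str = "balanced_train",
    method: str = "bmr",
    seed: int = 0,
    **fit_kwargs,
) -> PipelineReport:
    """Repeated splits -> tally -> stability selection -> full-cohort refit."""
    y = cohort.set_index("patient_id").loc[X.index, "outcome"]
    plan = make_splits(cohort[cohort["patient_id"].isin(X.index)],
                       n_repeats=n_repeats, test_frac=test_frac, mode=mode, seed=seed)
    run = run_repeated(X, y, plan, method=method, **fit_kwargs)
    selected = stability_select(run.tally)
    final = final_signature(X, y, selected, method=method, seed=seed)
    return PipelineReport(run=run, selected=selected, final=final)


def write_report(report: PipelineReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.run.auc_table().to_csv(out / "repeat_aucs.csv", index=False)
    pd.Series(report.run.tally.counts, name="count").rename_axis("covariate") \
        .to_csv(out / "selection_tally.csv")
    lines = ["# Signature pipeline report", ""]
    lines.append(f"Stability-selected covariates: {report.selected or 'none'}")
    if report.final.generated:
        report.final.signature.to_json(out / "final_signature.json")
        if report.final.roc is not None:
            r = report.final.roc
            lines += [
                f"Full-cohort (apparent) AUC: {r.auc:.3f} "
                f"[{r.ci95[0]:.3f}, {r.ci95[1]:.3f}]",
                f"Youden threshold {r.youden_threshold:.4g}: "
                f"sensitivity {r.sensitivity:.2f}, specificity {r.specificity:.2f}",
            ]
    else:
        lines.append(report.final.note)
    (out / "report.md").write_text("\n".join(lines) + "\n")
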
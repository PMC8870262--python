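"""Segmentation evaluation: confusion tallies, overlap metrics, per-subject
summaries, and subject/site-aware split planning.

The eight reported metrics are Dice, sensitivity (TPR), specificity (TNR),
Jaccard, voxel overlap error (VOE), false-negative rate, false-positive
rate, and positive predictive value (PPV). Note an important quirk kept on
purpose: FNR and FPR here use the *Jaccard denominator* FN+TP+FP — not the
conventional FN/(FN+TP) and FP/(FP+TN) — so that the exact identities

    voe = 1 - jaccard,   jaccard + fnr + fpr = 1,   dice = 2J/(1+J)

hold at the single-confusion-matrix level. The conventional rates are
exposed separately as fnr_conventional / fpr_conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .exceptions import ConsistencyError
from .volume_io import Volume

METRIC_NAMES = ("dice", "tpr", "tnr", "jaccard", "voe", "fnr", "fpr", "ppv")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise classification tallies for one subject."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass(frozen=True)
class MetricReport:
    dice: float
    tpr: float
    tnr: float
    jaccard: float
    voe: float
    fnr: float
    fpr: float
    ppv: float
    fnr_conventional: float = float("nan")
    fpr_conventional: float = float("nan")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _binary(vol: Volume | np.ndarray) -> np.ndarray:
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask is not binary")
    return data.astype(bool)


def confusion_counts(pred: Volume | np.ndarray,
                     truth: Volume | np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/TN/FN between a predicted and a true binary mask."""
    p, t = _binary(pred), _binary(truth)
    if p.shape != t.shape:
        raise ConsistencyError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """Evaluate all eight formulas from one confusion matrix.

    Degenerate denominators resolve to the perfect-agreement reading:
    an empty truth with an empty prediction scores 1 on the overlap
    metrics and 0 on the error rates.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    TP, FP, TN, FN = (float(c.TP), float(c.FP), float(c.TN), float(c.FN))
    juni = FN + TP + FP  # Jaccard denominator (union of pred and truth)
    if juni == 0:
        jaccard, dice, fnr, fpr = 1.0, 1.0, 0.0, 0.0
    else:
        jaccard = TP / juni
        dice = 2 * TP / (2 * TP + FP + FN)
        fnr = FN / juni
        fpr = FP / juni
    voe = 1.0 - jaccard
    if TP + FN == 0:
        tpr = 1.0 if FP == 0 else 0.0
    else:
        tpr = TP / (TP + FN)
    tnr = 1.0 if TN + FP == 0 else TN / (TN + FP)
    if TP + FP == 0:
        ppv = 1.0 if FN == 0 else 0.0
    else:
        ppv = TP / (TP + FP)
    fnr_conv = 1.0 - tpr
    fpr_conv = 1.0 - tnr
    return MetricReport(dice=dice, tpr=tpr, tnr=tnr, jaccard=jaccard, voe=voe,
                        fnr=fnr, fpr=fpr, ppv=ppv,
                        fnr_conventional=fnr_conv, fpr_conventional=fpr_conv)


def per_subject_summary(pairs) -> dict[str, tuple[float, float]]:
    """Per-subject metrics averaged across subjects.

    Each subject's metrics come from that subject's own pooled confusion
    matrix; the summary reports the across-subject mean and sample (n-1)
    standard deviation per metric. Note the mean of per-subject Dice is not
    in general the Dice of pooled counts when subjects differ in size.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one (pred, truth) pair")
    reports = [compute_metrics(confusion_counts(p, t)) for p, t in pairs]
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[name] = (float(vals.mean()), std)
    return out


# -- split planning ---------------------------------------------------------

@dataclass
class SplitPlan:
    """Per-fold train/validation/test subject assignments."""

    folds: list[tuple[list, list, list]]
    mode: str
    seed: int

    def __post_init__(self):
        for tr, va, te in self.folds:
            pool = set(tr) | set(va) | set(te)
            if len(pool) != len(tr) + len(va) + len(te):
                raise ConsistencyError("train/validation/test sets overlap")


def _train_val(pool: list, val_fraction: float,
               rng: np.random.Generator) -> tuple[list, list]:
    pool = list(pool)
    order = rng.permutation(len(pool))
    n_val = max(1, int(round(val_fraction * len(pool)))) if len(pool) > 1 else 0
    val = [pool[i] for i in order[:n_val]]
    train = [pool[i] for i in order[n_val:]]
    return train, val


def kfold_split(subjects: list, k: int, seed: int,
                val_fraction: float = 0.2) -> SplitPlan:
    """Seeded k-fold plan: test folds of near-equal size partition the
    subjects; each fold's remaining pool splits into train and validation."""
    subjects = list(subjects)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    fold_tests = [list(chunk) for chunk in np.array_split(shuffled, k)]
    folds = []
    for i in range(k):
        test = [str(s) if isinstance(s, np.str_) else s for s in fold_tests[i]]
        pool = [s for s in shuffled if s not in test]
        train, val = _train_val(pool, val_fraction, rng)
        folds.append((train, val, test))
    return SplitPlan(folds=folds, mode="kfold", seed=int(seed))


def site_holdout_split(site_map: dict, n_test_sites: int, seed: int,
                       val_fraction: float = 0.2) -> SplitPlan:
    """Hold entire acquisition sites out for testing.

    All subjects from the sampled test sites form the test set; no held-out
    site contributes any subject to training or validation, so the plan
    measures generalization to unseen sites.
    """
    sites = sorted(set(site_map.values()))
    if n_test_sites < 1:
        raise ValueError("n_test_sites must be >= 1")
    if n_test_sites >= len(sites):
        raise ValueError(f"n_test_sites={n_test_sites} must be < {len(sites)} sites")
    rng = np.random.default_rng(seed)
    test_sites = set(rng.choice(sites, size=n_test_sites, replace=False))
    test = sorted(s for s, site in site_map.items() if site in test_sites)
    pool = sorted(s for s in site_map if s not in test)
    train, val = _train_val(pool, val_fraction, rng)
    return SplitPlan(folds=[(train, val, test)], mode="site_holdout",
                     seed=int(seed))


def plan_to_table(plan: SplitPlan, site_map: dict | None = None):
    """Serialize a split plan as a plain-text table (pandas DataFrame)."""
    import pandas as pd
    rows = []
    for fold_i, (tr, va, te) in enumerate(plan.folds):
        for role, subs in (("train", tr), ("validation", va), ("test", te)):
            for s in subs:
                rows.append({"subject": s,
                             "site": (site_map or {}).get(s, ""),
                             "fold": fold_i, "role": role})
    return pd.DataFrame(rows, columns=["subject", "site", "fold", "role"])
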
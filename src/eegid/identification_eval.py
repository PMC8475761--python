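"""Subject-identification experiments over features, splits and bands.

Three split families mirror a multi-visit biometric study:

* intra-run (RUN1..RUN3): stratified 10-fold cross-validation within one run;
* fusion runs (F-RUN1..F-RUN4): trials pooled from two or three runs, again
  10-fold CV, so every fold mixes data from the constituent runs;
* inter-run transfer (COND1..COND3): train on two runs, test on the held-out
  run — the time-robustness measurement.

The classifier is a linear-kernel maximum-margin SVM (one-vs-one, C=1) with
per-fold standardization from training statistics only. Frequency-band
selection restricts the feature tensors to one of 13 canonical ranges with
inclusive endpoints (so the 8-13 and 13-20 Hz bands share the 13 Hz bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import StateError
from .spectral_features import FEATURE_KINDS, FeatureTensor


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: int
    hi: int

    @property
    def bins(self) -> np.ndarray:
        """Integer frequencies of the band, endpoints inclusive."""
        return np.arange(self.lo, self.hi + 1)


# The canonical 13-range catalogue: theta, alpha, two beta ranges, low gamma,
# seven combined ranges, and the full 1-40 Hz band as benchmark.
BAND_CATALOGUE: tuple[BandSpec, ...] = tuple(
    BandSpec(f"{lo}-{hi}", lo, hi)
    for lo, hi in [
        (4, 7), (8, 13), (13, 20), (20, 30), (30, 40),
        (4, 20), (4, 30), (8, 20), (8, 30), (8, 40),
        (13, 30), (13, 40), (1, 40),
    ]
)

FULL_BAND = BAND_CATALOGUE[-1]


@dataclass(frozen=True)
class SplitSpec:
    name: str
    scheme: str  # INTRA_RUN | FUSION | INTER_RUN
    train_runs: tuple[str, ...]
    test_runs: tuple[str, ...] = ()
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if self.scheme == "INTER_RUN":
            if set(self.train_runs) & set(self.test_runs):
                raise ValueError("inter-run splits need disjoint train/test runs")
        elif self.test_runs:
            raise ValueError("cv schemes take no test runs")


def split_catalogue(run_ids: tuple[str, ...] = ("RUN1", "RUN2", "RUN3")) -> tuple[SplitSpec, ...]:
    """RUN1-3 intra-run CV, F-RUN1-4 fused CV, COND1-3 inter-run transfer."""
    r1, r2, r3 = run_ids
    return (
        SplitSpec("RUN1", "INTRA_RUN", (r1,)),
        SplitSpec("RUN2", "INTRA_RUN", (r2,)),
        SplitSpec("RUN3", "INTRA_RUN", (r3,)),
        SplitSpec("F-RUN1", "FUSION", (r1, r2)),
        SplitSpec("F-RUN2", "FUSION", (r1, r3)),
        SplitSpec("F-RUN3", "FUSION", (r2, r3)),
        SplitSpec("F-RUN4", "FUSION", (r1, r2, r3)),
        SplitSpec("COND1", "INTER_RUN", (r1, r2), (r3,)),
        SplitSpec("COND2", "INTER_RUN", (r1, r3), (r2,)),
        SplitSpec("COND3", "INTER_RUN", (r2, r3), (r1,)),
    )


def select_band(t: FeatureTensor, band: BandSpec) -> FeatureTensor:
    """Restrict the frequency axis to the band's bins (all else unchanged)."""
    keep = np.isin(t.freqs, band.bins)
    if not keep.any():
        raise ValueError(f"band {band.name} selects no frequency bins")
    return t.with_(data=t.data[:, :, keep], freqs=t.freqs[keep])


def make_design_matrix(t: FeatureTensor) -> tuple[np.ndarray, np.ndarray]:
    """One row per trial, flattened row-major (channel/pair then frequency)."""
    if t.transform_state != "transformed":
        raise StateError("design matrix requires a transformed tensor")
    if not t.block_averaged:
        raise StateError("design matrix requires block-averaged trials")
    X = t.data.reshape(t.n_trials, -1)
    return X, np.asarray(t.subjects)


def _classifier() -> object:
    # libsvm trains one-vs-one binary machines internally
    return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))


def cv_accuracy(X: np.ndarray, y: np.ndarray, folds: int = 10, seed: int = 0) -> float:
    """Stratified k-fold CV accuracy (percent) of the linear SVM."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs >= {folds} samples for {folds}-fold CV "
            f"(smallest class has {counts.min()})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(_classifier(), X, y, cv=cv, scoring="accuracy")
    return float(scores.mean() * 100.0)


def transfer_accuracy(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
) -> float:
    """Fit once on training trials, score on held-out-run trials (percent)."""
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train/test feature dimensionality differs")
    if set(y_train) != set(y_test):
        raise ValueError("train/test label sets differ")
    clf = _classifier()
    clf.fit(X_train, y_train)
    return float(clf.score(X_test, y_test) * 100.0)


def _subset_runs(t: FeatureTensor, runs: tuple[str, ...]) -> FeatureTensor:
    return t.select(runs=runs)


def _subset_condition(t: FeatureTensor, condition: str) -> FeatureTensor:
    return t.select(conditions=(condition,))


def run_full_evaluation(
    features: dict[str, FeatureTensor],
    splits: tuple[SplitSpec, ...] | None = None,
    bands: tuple[BandSpec, ...] | None = None,
    conditions: tuple[str, ...] = ("REO", "REC"),
    seed: int = 0,
    cv_bands_full_only: bool = True,
) -> pd.DataFrame:
    """Populate the accuracy grid over kinds x conditions x splits x bands.

    ``features`` maps feature kind to a transformed, block-averaged tensor
    holding all runs and conditions. Intra-run and fusion splits are scored
    by 10-fold CV (full band only, by default, matching the reporting layout
    of a per-run summary table); inter-run transfer splits are scored per
    band. Cells that cannot be evaluated carry NaN and a skip reason.

    Returns a long-format frame: kind, condition, split, band, accuracy, note.
    """
    splits = splits or split_catalogue()
    bands = bands or BAND_CATALOGUE
    rows = []
    for kind, tensor in features.items():
        if kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {kind!r}")
        for cond in conditions:
            t_cond = _subset_condition(tensor, cond)
            for split in splits:
                if split.scheme in ("INTRA_RUN", "FUSION"):
                    band_list = (FULL_BAND,) if cv_bands_full_only else bands
                else:
                    band_list = bands
                for band in band_list:
                    rows.append(
                        _evaluate_cell(t_cond, kind, cond, split, band, seed)
                    )
    return pd.DataFrame(rows)


def _evaluate_cell(
    t_cond: FeatureTensor,
    kind: str,
    cond: str,
    split: SplitSpec,
    band: BandSpec,
    seed: int,
) -> dict:
    row = {
        "kind": kind,
        "condition": cond,
        "split": split.name,
        "band": band.name,
        "accuracy": np.nan,
        "note": "",
    }
    try:
        t_band = select_band(t_cond, band)
        if split.scheme in ("INTRA_RUN", "FUSION"):
            X, y = make_design_matrix(_subset_runs(t_band, split.train_runs))
            row["accuracy"] = cv_accuracy(X, y, folds=split.cv_folds, seed=seed)
        else:
            Xtr, ytr = make_design_matrix(_subset_runs(t_band, split.train_runs))
            Xte, yte = make_design_matrix(_subset_runs(t_band, split.test_runs))
            row["accuracy"] = transfer_accuracy(Xtr, ytr, Xte, yte)
    except (ValueError, StateError) as exc:
        row["note"] = f"skipped: {exc}"
    return row


def report_table(report: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Pivot one feature kind's transfer cells into a bands x splits table."""
    sub = report[(report["kind"] == kind) & report["split"].str.startswith("COND")]
    return sub.pivot_table(
        index="band", columns=["condition", "split"], values="accuracy"
    )
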
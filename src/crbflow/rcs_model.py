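"""Risk classification score (RCS): logistic model, scoring, and bimodality.

The RCS combines the three FVA summaries through a logistic regression of
repair-defective ("pathogenic-like") vs repair-intact ("benign-like")
controls.  Scores are reported on the log-odds scale normalized so that the
log odds of pathogenic to benign is zero at the equal-likelihood point:

    RCS = -(beta0 + beta . z)  =  log-odds(benign vs pathogenic)

with z the centered/scaled features.  Hence model probability of a repair
defect = 0.5 exactly when RCS = 0, RCS < 0 calls the sample CR-B+
(defective), and RCS > 0 calls it CR-B- (intact).  A score of exactly 0 is
called CR-B+ (the tie favours sensitivity for a screening test; configurable).

Features are centered and scaled at fit time and the scaling is stored in
the model, so scoring is reproducible and invariant to positive affine
rescaling of any raw feature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture

from .errors import ConvergenceError, InputError
from .fva_quantify import ASSAY_FIELDS, FVAResult

MODEL_SCHEMA_VERSION = 1
PATHOGENIC_LABEL = "pathogenic-like"
BENIGN_LABEL = "benign-like"
DEFAULT_RIDGE_LAMBDA = 1.0


@dataclass
class RCSModel:
    """Fitted logistic RCS model with its feature scaling."""

    intercept: float
    coef: np.ndarray  # aligned with feature_names
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    n_train: int = 0
    seed: int = 0
    converged: bool = True
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA
    tie_call: str = "CRB_plus"  # call assigned when rcs is exactly 0

    def _z(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center) / self.scale

    def pathogenic_log_odds(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self._z(np.atleast_2d(x)) @ self.coef

    def to_json(self) -> str:
        doc = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "intercept": self.intercept,
            "coef": self.coef.tolist(),
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "metadata": {
                "n_train": self.n_train,
                "seed": self.seed,
                "converged": self.converged,
                "ridge_lambda": self.ridge_lambda,
                "tie_call": self.tie_call,
            },
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RCSModel":
        doc = json.loads(text)
        if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise InputError(
                f"unsupported model schema version {doc.get('schema_version')!r}"
            )
        meta = doc.get("metadata", {})
        return cls(
            intercept=float(doc["intercept"]),
            coef=np.asarray(doc["coef"], dtype=float),
            feature_names=tuple(doc["feature_names"]),
            center=np.asarray(doc["center"], dtype=float),
            scale=np.asarray(doc["scale"], dtype=float),
            n_train=int(meta.get("n_train", 0)),
            seed=int(meta.get("seed", 0)),
            converged=bool(meta.get("converged", True)),
            ridge_lambda=float(meta.get("ridge_lambda", DEFAULT_RIDGE_LAMBDA)),
            tie_call=str(meta.get("tie_call", "CRB_plus")),
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "RCSModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


@dataclass
class RCSResult:
    """Per-subject score and CR-B call.  call CRB_plus <=> rcs <= 0."""

    subject_id: str
    rcs: float
    call: str  # "CRB_plus" or "CRB_minus"


def _as_feature_matrix(
    data, feature_names: Sequence[str] = ASSAY_FIELDS
) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        missing = [c for c in feature_names if c not in data.columns]
        if missing:
            raise InputError(f"missing feature columns: {missing}")
        x = data.loc[:, list(feature_names)].to_numpy(dtype=float)
    else:
        rows = []
        for item in data:
            if isinstance(item, FVAResult):
                rows.append([item.features()[k] for k in feature_names])
            elif isinstance(item, dict):
                rows.append([item[k] for k in feature_names])
            else:
                rows.append(list(item))
        x = np.asarray(rows, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(feature_names):
        raise InputError(f"expected {len(feature_names)} features per subject")
    if not np.all(np.isfinite(x)):
        raise InputError("features contain non-finite values")
    return x


def fit_rcs_model(
    features,
    labels: Iterable[str],
    seed: int = 0,
    *,
    feature_names: Sequence[str] = ASSAY_FIELDS,
    ridge_lambda: float = DEFAULT_RIDGE_LAMBDA,
    max_iter: int = 1000,
) -> RCSModel:
    """Maximum-likelihood logistic fit on centered/scaled features.

    ``labels`` are ``"pathogenic-like"`` / ``"benign-like"`` strings (or
    1/0).  Classes are weighted inversely to their sizes so the intercept
    is not biased by the carrier:relative ratio of the training panel.  The
    ridge penalty (default lambda = 1 on standardized features) keeps the
    fit defined when the classes are linearly separable and keeps the
    decision boundary near the mid-point between the phenotype clusters
    when a few carriers are phenotypically intact (label noise); a
    near-maximum-likelihood fit (small lambda) lets those mislabeled
    controls drag the boundary into the intact cluster.
    """
    x = _as_feature_matrix(features, feature_names)
    y = np.array(
        [
            1 if lab in (PATHOGENIC_LABEL, 1, "1", True) else 0
            for lab in labels
        ],
        dtype=int,
    )
    if len(y) != len(x):
        raise InputError("features and labels have different lengths")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InputError("training data contain a single class")
    if min(n_pos, n_neg) < 10:
        raise InputError(
            f"need >= 10 subjects per class, got {n_pos} pathogenic-like / {n_neg} benign-like"
        )
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - center) / scale
    clf = LogisticRegression(
        C=1.0 / ridge_lambda,
        solver="lbfgs",
        max_iter=max_iter,
        tol=1e-10,
        class_weight="balanced",
        random_state=seed,
    )
    clf.fit(z, y)
    n_iter = int(np.max(clf.n_iter_))
    if n_iter >= max_iter:
        raise ConvergenceError(
            f"logistic fit did not converge within {max_iter} iterations", n_iter
        )
    return RCSModel(
        intercept=float(clf.intercept_[0]),
        coef=clf.coef_[0].astype(float),
        feature_names=tuple(feature_names),
        center=center,
        scale=scale,
        n_train=len(y),
        seed=seed,
        converged=True,
        ridge_lambda=ridge_lambda,
    )


def compute_rcs(model: RCSModel, fva) -> RCSResult:
    """Score one subject: RCS = -(pathogenic log-odds), call by sign."""
    if isinstance(fva, FVAResult):
        sid = fva.subject_id
        x = np.array([fva.features()[k] for k in model.feature_names])
    elif isinstance(fva, dict):
        sid = str(fva.get("subject_id", ""))
        x = np.array([fva[k] for k in model.feature_names], dtype=float)
    else:
        raise InputError("fva must be an FVAResult or a feature dict")
    if not np.all(np.isfinite(x)):
        raise InputError("features contain non-finite values")
    eta = float(model.pathogenic_log_odds(x)[0])
    rcs = -eta
    if rcs > 0:
        call = "CRB_minus"
    elif rcs < 0:
        call = "CRB_plus"
    else:
        call = model.tie_call
    return RCSResult(subject_id=sid, rcs=rcs, call=call)


def score_table(model: RCSModel, fva_table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of a tidy FVA table (must carry ``subject_id``)."""
    x = _as_feature_matrix(fva_table, model.feature_names)
    eta = model.pathogenic_log_odds(x)
    rcs = -eta
    call = np.where(rcs > 0, "CRB_minus", "CRB_plus")
    call[rcs == 0] = model.tie_call
    return pd.DataFrame(
        {
            "subject_id": fva_table["subject_id"].to_numpy(),
            "rcs": rcs,
            "call": call,
            "prob_pathogenic": 1.0 / (1.0 + np.exp(-eta)),
        }
    )


def _call_from_score(rcs: float, tie_call: str = "CRB_plus") -> str:
    if rcs > 0:
        return "CRB_minus"
    if rcs < 0:
        return "CRB_plus"
    return tie_call


def classify_crb(
    rcs_values, subjects: pd.DataFrame | None = None
) -> pd.DataFrame:
    """CR-B+/- counts and percentages, overall and by cohort/group.

    ``rcs_values`` may be a list of :class:`RCSResult`, a scored table from
    :func:`score_table`, or a plain sequence of RCS values (calls assigned
    by sign).  Percentages are rounded to one decimal.  ``subjects`` (a
    table with ``subject_id``, ``cohort``, ``group``) adds per-cohort and
    per-group rows.
    """
    if isinstance(rcs_values, pd.DataFrame):
        df = rcs_values.loc[:, ["subject_id", "rcs", "call"]].copy()
    else:
        rcs_values = list(rcs_values)
        if rcs_values and isinstance(rcs_values[0], RCSResult):
            df = pd.DataFrame(
                {
                    "subject_id": [r.subject_id for r in rcs_values],
                    "rcs": [r.rcs for r in rcs_values],
                    "call": [r.call for r in rcs_values],
                }
            )
        else:
            values = np.asarray(rcs_values, dtype=float)
            df = pd.DataFrame(
                {
                    "subject_id": [f"s{i + 1:04d}" for i in range(len(values))],
                    "rcs": values,
                    "call": [_call_from_score(v) for v in values],
                }
            )
    if df.empty:
        raise InputError("no RCS values supplied")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise InputError(f"duplicate subject ids: {dupes}")

    def _row(scope: str, sub: pd.DataFrame) -> dict:
        n = len(sub)
        n_plus = int((sub["call"] == "CRB_plus").sum())
        n_minus = n - n_plus
        return {
            "scope": scope,
            "n": n,
            "n_crb_plus": n_plus,
            "n_crb_minus": n_minus,
            "pct_crb_plus": round(100.0 * n_plus / n, 1),
            "pct_crb_minus": round(100.0 * n_minus / n, 1),
        }

    rows = [_row("all", df)]
    if subjects is not None:
        merged = df.merge(
            subjects.loc[:, ["subject_id", "cohort", "group"]], on="subject_id"
        )
        for cohort, sub in merged.groupby("cohort", sort=True):
            rows.append(_row(f"cohort:{cohort}", sub))
        for group, sub in merged.groupby("group", sort=True):
            rows.append(_row(f"group:{group}", sub))
    return pd.DataFrame(rows)


def assess_bimodality(rcs_values, seed: int = 0) -> dict:
    """Compare 1- vs 2-component Gaussian mixtures on the score distribution.

    Reports ``bimodal = True`` when BIC(2) < BIC(1) - 10 (a strong-evidence
    margin on the Bayesian information criterion).  Degenerate input (all
    values identical) returns ``bimodal = False`` with a note instead of
    raising.
    """
    values = np.asarray(list(rcs_values), dtype=float)
    if values.ndim != 1 or len(values) < 20:
        raise InputError("need >= 20 values to assess bimodality")
    if not np.all(np.isfinite(values)):
        raise InputError("values contain non-finite entries")
    if np.ptp(values) < 1e-12:
        return {
            "bimodal": False,
            "statistic": 0.0,
            "bic_1": float("nan"),
            "bic_2": float("nan"),
            "means": [float(values[0])],
            "note": "degenerate input: all values identical",
        }
    x = values.reshape(-1, 1)
    bics, models = [], []
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k,
            n_init=3,
            init_params="kmeans",
            random_state=seed,
            reg_covar=1e-6,
        ).fit(x)
        bics.append(float(gm.bic(x)))
        models.append(gm)
    statistic = bics[0] - bics[1]  # evidence in favour of two components
    return {
        "bimodal": bool(statistic > 10.0),
        "statistic": statistic,
        "bic_1": bics[0],
        "bic_2": bics[1],
        "means": sorted(float(m) for m in models[1].means_.ravel()),
        "note": "",
    }
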
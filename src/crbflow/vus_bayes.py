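"""Bayesian reclassification of VUS from the CR-B functional phenotype.

Two interchangeable evidence models are supported:

1. the *assay likelihood-ratio* model, where a negative (CR-B-) result
   updates the prior odds of pathogenicity by LR- = (1 - sens) / spec and a
   positive result by LR+ = sens / (1 - spec); and
2. the *odds-of-pathogenicity* (OddsPath) framework of the Bayesian-adapted
   ACMG/AMP guidelines, where evidence strengths carry fixed odds
   base^(1/8), base^(1/4), base^(1/2), base (supporting / moderate /
   strong / very strong; base 350) for pathogenic evidence and their
   reciprocals for benign evidence.

Posteriors follow the standard odds update
``posterior = odds * prior / ((odds - 1) * prior + 1)`` and are mapped to
ACMG classes with the framework's default bands (B < 0.001, LB < 0.10,
LP > 0.90, P > 0.99; band boundaries resolve toward VUS).

A likelihood ratio is mapped to an evidence strength by the *nearest* level
on the log-odds-of-pathogenicity scale (ratios within [1/base^(1/8),
base^(1/8)) are "insufficient").  With assay sensitivity 0.91 and
specificity 0.96, LR- = 0.09375 sits closest to the strong-benign level,
i.e. BS3-strength evidence.  A conventional floor-threshold mapping is
available via ``mode="threshold"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_ODDS_PATH_BASE = 350.0
STRENGTH_EXPONENTS = {
    "supporting": 0.125,
    "moderate": 0.25,
    "strong": 0.5,
    "very_strong": 1.0,
}
ACMG_CLASSES = ("B", "LB", "VUS", "LP", "P")

DEFAULT_PRIOR_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class ClassificationBands:
    """Posterior-probability bands for the five ACMG classes."""

    benign_max: float = 0.001
    likely_benign_max: float = 0.10
    likely_pathogenic_min: float = 0.90
    pathogenic_min: float = 0.99

    def __post_init__(self) -> None:
        t = (
            self.benign_max,
            self.likely_benign_max,
            self.likely_pathogenic_min,
            self.pathogenic_min,
        )
        if not all(b < a for b, a in zip(t, t[1:])):
            raise InputError(f"classification bands must be strictly increasing, got {t}")


DEFAULT_BANDS = ClassificationBands()


@dataclass
class EvidenceModel:
    """Assay-derived likelihood ratios plus the OddsPath strength scale."""

    sensitivity: float
    specificity: float
    odds_path_base: float = DEFAULT_ODDS_PATH_BASE
    lr_negative: float = field(init=False)
    lr_positive: float = field(init=False)  # inf when specificity == 1

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise InputError(f"sensitivity must be in (0, 1], got {self.sensitivity!r}")
        if not 0.0 < self.specificity <= 1.0:
            raise InputError(f"specificity must be in (0, 1], got {self.specificity!r}")
        if self.odds_path_base <= 1.0:
            raise InputError("odds_path_base must be > 1")
        self.lr_negative = (1.0 - self.sensitivity) / self.specificity
        self.lr_positive = (
            math.inf
            if self.specificity == 1.0
            else self.sensitivity / (1.0 - self.specificity)
        )

    def strength_odds(self, level: str, direction: str = "pathogenic") -> float:
        """Odds of pathogenicity for one strength level and direction."""
        try:
            exponent = STRENGTH_EXPONENTS[level]
        except KeyError:
            raise InputError(
                f"unknown strength level '{level}'; expected one of {list(STRENGTH_EXPONENTS)}"
            ) from None
        odds = self.odds_path_base**exponent
        if direction == "pathogenic":
            return odds
        if direction == "benign":
            return 1.0 / odds
        raise InputError(f"direction must be 'pathogenic' or 'benign', got {direction!r}")


def likelihood_ratios_from_assay(
    sensitivity: float,
    specificity: float,
    odds_path_base: float = DEFAULT_ODDS_PATH_BASE,
) -> EvidenceModel:
    """Build the evidence model from assay operating characteristics.

    A perfect specificity gives an infinite LR+, which is reported as
    ``inf`` and treated as very-strong pathogenic evidence (capped) rather
    than raising.
    """
    return EvidenceModel(sensitivity, specificity, odds_path_base)


def posterior_probability(prior: float, odds: float) -> float:
    """Posterior P(pathogenic) after an odds update of the prior.

    Closed form: ``odds * prior / ((odds - 1) * prior + 1)``.
    """
    if not 0.0 <= prior <= 1.0:
        raise InputError(f"prior must be in [0, 1], got {prior!r}")
    if not odds > 0:
        raise InputError(f"odds must be > 0, got {odds!r}")
    if prior in (0.0, 1.0):  # boundary priors are preserved exactly
        return prior
    if math.isinf(odds):
        return 1.0
    return odds * prior / ((odds - 1.0) * prior + 1.0)


def classify_from_posterior(
    posterior: float, bands: ClassificationBands = DEFAULT_BANDS
) -> str:
    """Map a posterior probability of pathogenicity to an ACMG class."""
    if not 0.0 <= posterior <= 1.0:
        raise InputError(f"posterior must be in [0, 1], got {posterior!r}")
    if posterior < bands.benign_max:
        return "B"
    if posterior < bands.likely_benign_max:
        return "LB"
    if posterior > bands.pathogenic_min:
        return "P"
    if posterior > bands.likely_pathogenic_min:
        return "LP"
    return "VUS"


@dataclass
class PosteriorTable:
    """Posterior and ACMG class over a prior grid, for one CR-B call."""

    table: pd.DataFrame  # columns: prior, posterior, acmg_class
    crb_call: str
    odds: float
    max_blb_prior: float | None  # largest grid prior classified B/LB


def reclassify_over_prior_grid(
    model: EvidenceModel,
    crb_call: str,
    prior_grid=DEFAULT_PRIOR_GRID,
    bands: ClassificationBands = DEFAULT_BANDS,
) -> PosteriorTable:
    """Posterior classification across a grid of prior probabilities.

    CR-B- applies the benign-direction likelihood ratio LR-, CR-B+ the
    pathogenic-direction LR+.  Returns the per-prior posteriors/classes and
    the largest grid prior whose class is B or LB.
    """
    grid = [float(p) for p in prior_grid]
    if not grid:
        raise InputError("prior grid is empty")
    if any(not 0.0 < p < 1.0 for p in grid):
        raise InputError("prior grid values must be in (0, 1)")
    if grid != sorted(grid):
        raise InputError("prior grid must be sorted ascending")
    if crb_call == "CRB_minus":
        odds = model.lr_negative
    elif crb_call == "CRB_plus":
        odds = model.lr_positive
    else:
        raise InputError(f"crb_call must be 'CRB_plus' or 'CRB_minus', got {crb_call!r}")
    rows = []
    for prior in grid:
        post = posterior_probability(prior, odds)
        rows.append(
            {"prior": prior, "posterior": post, "acmg_class": classify_from_posterior(post, bands)}
        )
    table = pd.DataFrame(rows)
    blb = table.loc[table["acmg_class"].isin(["B", "LB"]), "prior"]
    return PosteriorTable(
        table=table,
        crb_call=crb_call,
        odds=odds,
        max_blb_prior=float(blb.max()) if len(blb) else None,
    )


def evidence_strength_from_lr(
    lr: float, model: EvidenceModel | None = None, mode: str = "nearest"
) -> tuple[str, str]:
    """(direction, level) of the evidence carried by a likelihood ratio.

    ``mode="nearest"`` (default) assigns the closest strength level on the
    log-odds scale; ``mode="threshold"`` floors to the highest level whose
    odds the ratio reaches.  Ratios below the supporting level in either
    direction are ("none", "insufficient").
    """
    if not lr > 0:
        raise InputError(f"lr must be > 0, got {lr!r}")
    base = model.odds_path_base if model is not None else DEFAULT_ODDS_PATH_BASE
    if math.isinf(lr):
        return ("pathogenic", "very_strong")
    direction = "pathogenic" if lr > 1 else "benign"
    magnitude = lr if lr >= 1 else 1.0 / lr
    if magnitude < base ** STRENGTH_EXPONENTS["supporting"]:
        return ("none", "insufficient")
    if mode == "threshold":
        level = "supporting"
        for name, expo in STRENGTH_EXPONENTS.items():
            if magnitude >= base**expo:
                level = name
        return (direction, level)
    if mode != "nearest":
        raise InputError(f"mode must be 'nearest' or 'threshold', got {mode!r}")
    exponent = math.log(magnitude, base)
    level = min(
        STRENGTH_EXPONENTS, key=lambda name: abs(STRENGTH_EXPONENTS[name] - exponent)
    )
    return (direction, level)


def reclassify_variants(
    variants: pd.DataFrame,
    model: EvidenceModel,
    prior: float = 0.5,
    bands: ClassificationBands = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-variant reannotation table for VUS carriers with a CR-B call.

    ``variants`` columns: ``subject_id``, ``gene``, ``variant_class``,
    ``crb_call``.  Only CR-B- subjects are auto-reclassified (BS3-direction
    functional evidence); a CR-B+ result never upgrades a VUS, because
    establishing causality of a specific variant requires gene rescue.
    """
    required = {"subject_id", "gene", "variant_class", "crb_call"}
    missing = required - set(variants.columns)
    if missing:
        raise InputError(f"variant table missing columns: {sorted(missing)}")
    rows = []
    for _, row in variants.iterrows():
        entry = {
            "subject_id": row["subject_id"],
            "gene": row["gene"],
            "current_class": row["variant_class"],
            "crb_call": row["crb_call"],
            "prior": prior,
            "posterior": np.nan,
            "new_class": row["variant_class"],
            "note": "",
        }
        if row["variant_class"] != "VUS":
            entry["note"] = "not a VUS; unchanged"
        elif row["crb_call"] == "CRB_minus":
            post = posterior_probability(prior, model.lr_negative)
            entry["posterior"] = post
            entry["new_class"] = classify_from_posterior(post, bands)
        else:
            entry["note"] = (
                "CR-B+ does not auto-upgrade a VUS; causality requires gene rescue"
            )
        rows.append(entry)
    return pd.DataFrame(rows)
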
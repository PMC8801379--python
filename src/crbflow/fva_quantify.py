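"""Event tables -> per-sample FVA summary statistics and replicate QC.

Each sample yields three flow-variant-assay (FVA) readouts:

* ``brca1_nl`` / ``brca2_nl`` — percent of DAPI-gated nuclei whose marker
  intensity exceeds a positivity threshold, estimated as the 99th percentile
  of the matched untreated sample's distribution for that channel (so the
  untreated false-positive rate is ~1% by construction);
* ``p53_ratio`` — fold induction of the phospho-p53 : total-p53 median
  ratio in the challenged sample relative to the untreated sample.

Medians are used for the ratio channels for robustness to log-normal tails.
Replicate quality is summarized as the per-assay coefficient of variation,
CV% = 100 x sample SD (n-1) / mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GatingError, InputError, UndefinedStatisticError
DEFAULT_DAPI_THRESHOLD = 300.0
DEFAULT_POSITIVITY_PERCENTILE = 99.0
MIN_UNTREATED_EVENTS = 200

ASSAY_FIELDS = ("brca1_nl", "brca2_nl", "p53_ratio")


@dataclass
class FVAResult:
    """The three assay summaries for one (sample, replicate)."""

    subject_id: str
    cell_type: str
    day: int
    replicate_index: int
    brca1_nl: float  # percent of gated nuclei, 0-100
    brca2_nl: float  # percent of gated nuclei, 0-100
    p53_ratio: float  # unitless fold induction, > 0

    def __post_init__(self) -> None:
        for name in ("brca1_nl", "brca2_nl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise InputError(f"{name} must be in [0, 100], got {v!r}")
        if not self.p53_ratio > 0:
            raise InputError(f"p53_ratio must be > 0, got {self.p53_ratio!r}")

    def features(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ASSAY_FIELDS}


@dataclass
class ReplicateStats:
    """Per-assay replicate mean and CV% for one sample."""

    subject_id: str
    n_replicates: int
    mean: dict[str, float]
    cv_percent: dict[str, float]


def gate_nuclei(events: pd.DataFrame, dapi_threshold: float = DEFAULT_DAPI_THRESHOLD) -> pd.DataFrame:
    """Keep events with DAPI >= threshold (nuclei), preserving order.

    Raises :class:`GatingError` when no event survives, since downstream
    positive fractions would be undefined.
    """
    if events.empty:
        raise InputError("event table is empty")
    if not np.isfinite(dapi_threshold):
        if dapi_threshold == -np.inf:
            return events.copy()
        raise InputError(f"dapi_threshold must be finite or -inf, got {dapi_threshold!r}")
    gated = events.loc[events["dapi"] >= dapi_threshold].copy()
    if gated.empty:
        raise GatingError(
            f"no events with DAPI >= {dapi_threshold:g}; gating failed"
        )
    return gated


def compute_fva_summary(
    challenged: pd.DataFrame,
    untreated: pd.DataFrame,
    *,
    subject_id: str = "",
    cell_type: str = "PBMC",
    day: int = 1,
    replicate_index: int = 1,
    positivity_percentile: float = DEFAULT_POSITIVITY_PERCENTILE,
) -> FVAResult:
    """Summarize one gated (challenged, untreated) sample pair.

    Both tables must already be DAPI-gated.  The untreated table needs at
    least :data:`MIN_UNTREATED_EVENTS` events for stable threshold and
    baseline-ratio estimation.
    """
    if challenged.empty:
        raise InputError("challenged event table is empty")
    if len(untreated) < MIN_UNTREATED_EVENTS:
        raise InputError(
            f"untreated table has {len(untreated)} events; need >= {MIN_UNTREATED_EVENTS}"
        )
    if not 0.0 < positivity_percentile < 100.0:
        raise InputError("positivity_percentile must be in (0, 100)")

    nl = {}
    for channel, field in (("brca1", "brca1_nl"), ("brca2", "brca2_nl")):
        threshold = float(np.percentile(untreated[channel], positivity_percentile))
        nl[field] = 100.0 * float(np.mean(challenged[channel].to_numpy() > threshold))

    med_total_ch = float(np.median(challenged["p53_total"]))
    med_total_un = float(np.median(untreated["p53_total"]))
    med_phos_un = float(np.median(untreated["p53_phospho"]))
    if med_total_ch <= 0 or med_total_un <= 0:
        raise InputError("median total-p53 is zero; ratio undefined")
    if med_phos_un <= 0:
        raise InputError("median untreated phospho-p53 is zero; fold induction undefined")
    ratio_ch = float(np.median(challenged["p53_phospho"])) / med_total_ch
    ratio_un = med_phos_un / med_total_un
    return FVAResult(
        subject_id=subject_id,
        cell_type=cell_type,
        day=day,
        replicate_index=replicate_index,
        brca1_nl=nl["brca1_nl"],
        brca2_nl=nl["brca2_nl"],
        p53_ratio=ratio_ch / ratio_un,
    )


def replicate_cv(results: list[FVAResult]) -> ReplicateStats:
    """Per-assay mean and CV% (sample SD, n-1) over replicates of one sample."""
    if len(results) < 2:
        raise InputError("need >= 2 replicates to compute a CV")
    ids = {r.subject_id for r in results}
    if len(ids) != 1:
        raise InputError(f"replicates mix subject ids: {sorted(ids)}")
    if len({(r.cell_type, r.day) for r in results}) != 1:
        raise InputError("replicates mix cell types or days")
    means, cvs = {}, {}
    for assay in ASSAY_FIELDS:
        values = np.array([getattr(r, assay) for r in results], dtype=float)
        m = float(values.mean())
        if m == 0:
            raise UndefinedStatisticError(f"{assay}: mean of replicates is zero, CV undefined")
        means[assay] = m
        cvs[assay] = 100.0 * float(values.std(ddof=1)) / m
    return ReplicateStats(
        subject_id=results[0].subject_id,
        n_replicates=len(results),
        mean=means,
        cv_percent=cvs,
    )


def quantify_sample_pair(
    challenged: pd.DataFrame,
    untreated: pd.DataFrame,
    *,
    dapi_threshold: float = DEFAULT_DAPI_THRESHOLD,
    **meta,
) -> FVAResult:
    """Gate both tables then summarize; convenience wrapper for pipelines."""
    return compute_fva_summary(
        gate_nuclei(challenged, dapi_threshold),
        gate_nuclei(untreated, dapi_threshold),
        **meta,
    )


def results_to_frame(results: list[FVAResult]) -> pd.DataFrame:
    """FVAResult list -> tidy table (one row per sample x replicate)."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "cell_type": r.cell_type,
                "day": r.day,
                "replicate_index": r.replicate_index,
                **r.features(),
            }
            for r in results
        ]
    )
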
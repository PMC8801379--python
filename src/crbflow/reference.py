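"""Published validation-cohort confusion counts for the CR-B assays.

These are the per-cohort sensitivity/specificity fractions reported for the
three flow variant assays and the combined risk classification score (RCS)
across the Coriell cell-repository panel and the two clinic cohorts
(Montefiore, Northwell).  They serve as reference inputs for the
cohort-weighted combination arithmetic and for regression tests; no
subject-level data are included.

Northwell recruited no relatives testing negative for a familial variant,
so its specificity and accuracy are not available.
"""

from __future__ import annotations

import pandas as pd

from .performance import CohortMetrics

# cohort -> total N and per-assay (numerator, denominator) fractions.
REFERENCE_VALIDATION_COUNTS: dict[str, dict] = {
    "coriell": {
        "N": 36,
        "assays": {
            "brca1": {"sensitivity": (18, 22), "specificity": (13, 14)},
            "brca2": {"sensitivity": (20, 22), "specificity": (13, 14)},
            "p53": {"sensitivity": (20, 22), "specificity": (12, 14)},
            "rcs": {"sensitivity": (20, 22), "specificity": (14, 14)},
        },
    },
    "montefiore": {
        "N": 6,
        "assays": {
            "brca1": {"sensitivity": (2, 2), "specificity": (4, 4)},
            "brca2": {"sensitivity": (2, 2), "specificity": (3, 4)},
            "p53": {"sensitivity": (2, 2), "specificity": (3, 4)},
            "rcs": {"sensitivity": (2, 2), "specificity": (4, 4)},
        },
    },
    "northwell": {
        "N": 4,
        "assays": {
            "brca1": {"sensitivity": (3, 4), "specificity": None},
            "brca2": {"sensitivity": (3, 4), "specificity": None},
            "p53": {"sensitivity": (3, 4), "specificity": None},
            "rcs": {"sensitivity": (3, 4), "specificity": None},
        },
    },
}


def reference_cohort_metrics() -> list[CohortMetrics]:
    """The published per-cohort fractions as :class:`CohortMetrics`."""
    out = []
    for cohort, spec in REFERENCE_VALIDATION_COUNTS.items():
        out.append(CohortMetrics.from_counts(cohort, spec["N"], spec["assays"]))
    return out


def reference_calls_tables(cohort: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject call/subject tables realizing the published counts.

    Reconstructs a minimal subject roster (group-1 carriers and group-3
    relatives) and per-assay boolean calls whose confusion counts equal the
    published fractions, so the count-level arithmetic can be exercised
    through the same code path as simulated data.  Subject rows are
    synthetic; only the aggregate counts are faithful.
    """
    try:
        spec = REFERENCE_VALIDATION_COUNTS[cohort]
    except KeyError:
        raise KeyError(
            f"unknown cohort '{cohort}'; expected one of {sorted(REFERENCE_VALIDATION_COUNTS)}"
        ) from None
    assays = spec["assays"]
    any_sens = next(v["sensitivity"] for v in assays.values())
    n_carriers = any_sens[1]
    spec_counts = {a: v.get("specificity") for a, v in assays.items()}
    n_relatives = next(
        (v[1] for v in spec_counts.values() if v is not None), 0
    )
    rows_subj, rows_call = [], []
    for i in range(n_carriers):
        sid = f"{cohort}-g1-{i + 1:03d}"
        rows_subj.append({"subject_id": sid, "cohort": cohort, "group": 1})
        # carrier i tests positive for assay a iff i < published TP count
        rows_call.append(
            {"subject_id": sid}
            | {a: i < assays[a]["sensitivity"][0] for a in assays}
        )
    for i in range(n_relatives):
        sid = f"{cohort}-g3-{i + 1:03d}"
        rows_subj.append({"subject_id": sid, "cohort": cohort, "group": 3})
        rows_call.append(
            {"subject_id": sid}
            | {
                a: not (i < spec_counts[a][0]) if spec_counts[a] else False
                for a in assays
            }
        )
    return pd.DataFrame(rows_call), pd.DataFrame(rows_subj)
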
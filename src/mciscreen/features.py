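"""Feature construction: concept flags, aggregate sums, demographics, labels.

Each patient becomes one row: a binary indicator per dictionary concept
(1 if the patient has at least one non-boilerplate mention of that CUI in
their note window), three clinically specified aggregate sums over those
indicators, and demographic covariates.  The outcome label is MCI-positive
(1) when the MMSE or MoCA score at the index date is <= 26.
"""

from __future__ import annotations

import logging
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import PatientRecord
from .dictionary import ConceptDictionary
from .text_matcher import ConceptMention

logger = logging.getLogger(__name__)

MCI_SCORE_THRESHOLD = 26

#: Aggregate predictors specified on clinical judgement: which concept
#: indicators each sum pools.  FORGET deliberately appears in two sums.
SYMPTOM_SUM_CUIS = (
    "WANDER", "FORGET", "FORGETFL", "CONCENTR", "DECLINE",
    "W_DECLIN", "COMPREHE", "S_HALLUC", "RISK",
)
BEHAVIOR_SUM_CUIS = (
    "CONCERN", "CALLED", "WITHX", "S_CONCER", "W_CONCER", "REFERAL", "PLAN",
)
FORGETFUL_SUM_CUIS = ("FORGET", "FORGETFL", "FORGETX")

RACE_LEVELS = ("AmericanIndian", "Asian", "Black", "PacificIslander", "Other", "Unknown")
RACE_REFERENCE = "White"


def label_from_score(score) -> int:
    """Binary MCI label from an MMSE or MoCA score: 1 iff score <= 26.

    CASI scores are rejected — the CASI threshold (<= 85) is applied during
    index-date assignment, not labelling.
    """
    if score.instrument not in ("MMSE", "MoCA"):
        raise ValueError(f"label_from_score expects MMSE or MoCA, got {score.instrument}")
    return int(score.score <= MCI_SCORE_THRESHOLD)


def aggregate_sums(cui_flags: Mapping[str, int]) -> tuple[int, int, int]:
    """(symptom_sum, behavior_sum, forgetful_sum) over presence indicators.

    Missing CUIs count as absent.  With 0/1 flags the ranges are 0-9, 0-7
    and 0-3 by construction.
    """
    s = sum(int(cui_flags.get(c, 0)) for c in SYMPTOM_SUM_CUIS)
    b = sum(int(cui_flags.get(c, 0)) for c in BEHAVIOR_SUM_CUIS)
    f = sum(int(cui_flags.get(c, 0)) for c in FORGETFUL_SUM_CUIS)
    return s, b, f


def _check_sum_components(dictionary: ConceptDictionary) -> None:
    known = set(dictionary.cuis)
    for name, comp in (
        ("symptom", SYMPTOM_SUM_CUIS),
        ("behavior", BEHAVIOR_SUM_CUIS),
        ("forgetful", FORGETFUL_SUM_CUIS),
    ):
        unknown = [c for c in comp if c not in known]
        if unknown:
            raise ValueError(
                f"{name} sum references CUIs absent from the dictionary: {unknown}"
            )


class FeatureBuilder(TransformerMixin, BaseEstimator):
    """Assemble the model's design matrix from mentions and patient records.

    Parameters
    ----------
    dictionary : ConceptDictionary
        Defines the concept-flag columns (one per CUI, dictionary order).
    count_mode : {"presence", "occurrence"}
        ``presence`` (default) sets each concept column to 0/1 and each
        aggregate sum to the count of present component concepts, matching
        the documented 0-9 / 0-7 / 0-3 ranges.  ``occurrence`` uses raw
        mention counts instead.
    allow_missing_sum_components : bool
        By default a sum formula referencing a CUI absent from the
        dictionary is a hard error (it catches formula typos).  Set True for
        deliberately reduced dictionaries: absent components then simply
        contribute zero.
    """

    def __init__(self, dictionary: ConceptDictionary, count_mode: str = "presence",
                 allow_missing_sum_components: bool = False):
        self.dictionary = dictionary
        self.count_mode = count_mode
        self.allow_missing_sum_components = allow_missing_sum_components

    def fit(self, X=None, y=None) -> "FeatureBuilder":
        if self.count_mode not in ("presence", "occurrence"):
            raise ValueError(f"unknown count_mode: {self.count_mode!r}")
        if not self.allow_missing_sum_components:
            _check_sum_components(self.dictionary)
        self.cui_columns_ = [f"cui_{c}" for c in self.dictionary.cuis]
        self.demographic_columns_ = (
            ["age_years", "sex_male"]
            + [f"race_{r}" for r in RACE_LEVELS]
            + ["ethnicity_hispanic", "ethnicity_unknown",
               "low_income", "income_missing", "low_education", "education_missing"]
        )
        self.feature_names_out_ = (
            self.cui_columns_ + ["symptom_sum", "behavior_sum", "forgetful_sum"]
            + self.demographic_columns_
        )
        return self

    def transform(
        self,
        mentions: Iterable[ConceptMention],
        patients: Mapping[str, PatientRecord],
        index_dates: Mapping[str, "date"],
        labels: Mapping[str, int] | None = None,
    ) -> pd.DataFrame:
        """One row per patient in ``index_dates``; boilerplate mentions are dropped.

        Returns a DataFrame indexed by patient_id with the documented column
        order; if ``labels`` is given, a final ``label`` column is appended
        and patients without a label are excluded with a warning.
        """
        if not hasattr(self, "feature_names_out_"):
            self.fit()
        counts: dict[str, dict[str, int]] = {}
        for m in mentions:
            if m.boilerplate:
                continue
            if m.patient_id in index_dates:
                pc = counts.setdefault(m.patient_id, {})
                pc[m.cui] = pc.get(m.cui, 0) + 1

        rows = []
        kept_ids = []
        for pid in index_dates:
            if labels is not None and pid not in labels:
                logger.warning("patient %s has no label-defining score; excluded", pid)
                continue
            p = patients[pid]
            c = counts.get(pid, {})
            if self.count_mode == "presence":
                cui_vals = {cui: int(c.get(cui, 0) > 0) for cui in self.dictionary.cuis}
            else:
                cui_vals = {cui: c.get(cui, 0) for cui in self.dictionary.cuis}
            flags = {cui: int(v > 0) for cui, v in cui_vals.items()}
            ssum, bsum, fsum = aggregate_sums(
                flags if self.count_mode == "presence" else cui_vals
            )
            row = [cui_vals[cui] for cui in self.dictionary.cuis]
            row += [ssum, bsum, fsum]
            row += [
                p.age_at(index_dates[pid]),
                int(p.sex == "M"),
            ]
            row += [int(p.race == r) for r in RACE_LEVELS]
            row += [
                int(p.ethnicity == "Hispanic"),
                int(p.ethnicity == "Unknown"),
                int(bool(p.low_income)),
                int(p.low_income is None),
                int(bool(p.low_education)),
                int(p.low_education is None),
            ]
            rows.append(row)
            kept_ids.append(pid)

        X = pd.DataFrame(rows, index=pd.Index(kept_ids, name="patient_id"),
                         columns=self.feature_names_out_, dtype=float)
        if labels is not None:
            X["label"] = [int(labels[pid]) for pid in kept_ids]
        return X


def build_feature_matrix(
    index_dates: Mapping[str, "date"],
    mentions: Iterable[ConceptMention],
    patients: Mapping[str, PatientRecord],
    dictionary: ConceptDictionary,
    labels: Mapping[str, int] | None = None,
    count_mode: str = "presence",
    allow_missing_sum_components: bool = False,
) -> pd.DataFrame:
    """Functional wrapper over :class:`FeatureBuilder`."""
    builder = FeatureBuilder(
        dictionary, count_mode=count_mode,
        allow_missing_sum_components=allow_missing_sum_components,
    )
    return builder.fit().transform(mentions, patients, index_dates, labels)


def split_features_labels(frame: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if "label" not in frame.columns:
        raise ValueError("frame has no 'label' column")
    return frame.drop(columns="label"), frame["label"].to_numpy(dtype=int)
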
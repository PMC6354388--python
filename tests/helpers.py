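"""Small builders shared across test modules."""

import numpy as np
import pandas as pd

from geosurvey.synthetic import (
    DATASET_COLUMNS,
    GroundTruth,
    SurveyDataset,
    SurveyDesign,
    age_pmf,
)


def null_truth(graph, intercept=0.0):
    ages, _ = age_pmf()
    zeros = {l: 0.0 for l in graph.labels}
    return GroundTruth(intercept=intercept, beta={}, age_grid=ages.astype(float),
                       age_values=np.zeros(len(ages)), f_str=dict(zeros),
                       f_unstr=dict(zeros), tau2_str=1.0, tau2_unstr=1.0,
                       tau2_age=1.0)


def small_design(graph, clusters=4):
    return SurveyDesign(clusters_per_region={l: clusters for l in graph.labels})


def tiny_dataset(outcomes, **overrides):
    base = {
        "outcome": outcomes, "wave": 1, "region": "A", "cluster": "A-c1",
        "household": "h1", "age": 30, "urban": 0, "married": 1,
        "education": "none", "partner_education": "none", "wealth": "middle",
        "family_size": "small", "ethnicity": "wolof", "religion": "muslim",
        "partner_age": 40,
    }
    base.update(overrides)
    df = pd.DataFrame({c: (base[c] if isinstance(base[c], str)
                           or not np.iterable(base[c]) else list(base[c]))
                       for c in DATASET_COLUMNS})
    if df["partner_age"].dtype != "Int64":
        df["partner_age"] = df["partner_age"].astype("Int64")
    return SurveyDataset(df)
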
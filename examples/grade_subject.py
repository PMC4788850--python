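"""Assign regional and overall House-Brackmann grades.

Three regional graders (forehead, eye, mouth) are trained on a synthetic
grading cohort; the overall grade comes from the shipped concordant-triple
lookup table, with a multinomial logistic fallback for discordant
triples.
"""

import warnings

import pandas as pd

from palsykit import classifier as cl, synthetic as syn
from palsykit.features import FEATURE_NAMES

warnings.filterwarnings("ignore")

cohort = syn.generate_grading_cohort(n=240, seed=0)
model = cl.fit_grading(cohort.iloc[:180], seed=0)

subjects = {
    "normal": {n: 0.99 for n in FEATURE_NAMES},
    "mild, mouth-dominant": {**{n: 0.93 for n in FEATURE_NAMES},
                             "f7": 0.78, "f8": 0.78, "f9": 0.78},
    "severe": {n: 0.58 for n in FEATURE_NAMES},
}
for name, values in subjects.items():
    out = model.grade(pd.Series(values))
    print(
        f"{name}: regional {out['regional']} -> "
        f"overall grade {out['overall']} (via {out['mechanism']})"
    )
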
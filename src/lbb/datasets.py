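"""Bundled example data: the published 2019/2024 Xingkai Lake survey.

Two small tables ship with the package, summarising the multi-mesh
gillnet surveys of eight commercial species in Xingkai Lake:

* ``load_survey_priors`` — per species-year sample bookkeeping (length
  range, class interval, numbers measured) and the priors used for the
  fits (L_inf, Z/K, M/K, F/K, L_c, alpha);
* ``load_survey_assessment`` — the published assessment results
  (B/B0, B/BMSY, F/M, Z/K, Y/R', E, L_inf, indicator ratios, status).

They serve as worked-example inputs and as ground truth for checking
the package's arithmetic (binning rules, exploitation rate, status
classification) against published values.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_survey_priors", "load_survey_assessment"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("lbb.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_survey_priors() -> pd.DataFrame:
    """Survey bookkeeping and fitting priors, one row per species-year."""
    return _load("xingkai_survey_priors.csv")


def load_survey_assessment() -> pd.DataFrame:
    """Published assessment estimates and status, one row per species-year."""
    return _load("xingkai_survey_assessment.csv")
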
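"""Deterministic phenotype coding and study-level eligibility rules.

Covers four coding steps applied before any model is fitted:

* coffee/tea frequency categories → cups/day via category midpoints;
* TNM or SEER stage → localised / nonlocalised;
* Gleason score → low (≤6) / high (≥7) grade;
* vital status + cause of death → all-cause and prostate-cancer-specific
  event indicators, with exclusion of unknown vital status;

plus the per-study mortality eligibility filter (follow-up ≥ 90 % complete,
and ≥ 5 prostate cancer deaths for the cancer-specific analysis).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "CategoryMap",
    "DEFAULT_CATEGORY_MAP",
    "MortalityEligibility",
    "recode_cups",
    "classify_stage",
    "classify_grade",
    "resolve_mortality",
    "study_eligibility",
    "COMPLETENESS_MIN",
    "PCA_DEATHS_MIN",
]

COMPLETENESS_MIN = 0.90
PCA_DEATHS_MIN = 5

LOCALISED = "localised"
NONLOCALISED = "nonlocalised"
MISSING = "missing"


@dataclass(frozen=True)
class CategoryMap:
    """Ordered consumption categories with bounds (cups/day) and midpoints.

    ``categories`` maps label → (lower, upper); an unbounded top category has
    upper = None and is coded as lower + ``open_top_offset``. Bounded
    categories are coded at (lower + upper) / 2.
    """

    categories: dict
    open_top_offset: float = 1.0

    def __post_init__(self):
        prev_upper = -math.inf
        items = list(self.categories.items())
        for i, (label, (lo, hi)) in enumerate(items):
            if hi is not None and hi < lo:
                raise ValueError(f"category {label!r}: upper bound below lower")
            if lo < prev_upper:
                raise ValueError(f"category {label!r} overlaps its predecessor")
            if hi is None and i != len(items) - 1:
                raise ValueError("only the top category may be unbounded")
            prev_upper = lo if hi is None else hi

    def midpoint(self, label: str) -> float:
        lo, hi = self.categories[label]
        if hi is None:
            return lo + self.open_top_offset
        return (lo + hi) / 2.0


# Stand-in default (the per-study questionnaire categories are not public):
# never = 0, <1 = 0.5, 1 = 1, 2-3 = 2.5, >=4 = 5 cups/day. Overridable per study.
DEFAULT_CATEGORY_MAP = CategoryMap(
    categories={
        "never": (0.0, 0.0),
        "<1": (0.0, 1.0),
        "1": (1.0, 1.0),
        "2-3": (2.0, 3.0),
        ">=4": (4.0, None),
    },
    open_top_offset=1.0,
)


def recode_cups(label, cmap: CategoryMap = DEFAULT_CATEGORY_MAP) -> float:
    """Cups/day for a frequency-category label (category midpoint).

    Unknown labels return NaN with a warning rather than raising, so a single
    miscoded questionnaire answer does not abort a consortium run.
    """
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return float("nan")
    label = str(label).strip()
    if label not in cmap.categories:
        warnings.warn(f"unknown consumption category {label!r}; coded missing",
                      stacklevel=2)
        return float("nan")
    return cmap.midpoint(label)


_NONLOCAL_TOKENS = {"T3", "T4", "N1", "M1"}
_LOCAL_T = {"T1", "T2"}
_LOCAL_N = {"N0", "NX", None}
_LOCAL_M = {"M0", "MX", None}
_SEER = {"local": LOCALISED, "regional": NONLOCALISED, "distant": NONLOCALISED}


def _parse_tnm(tnm: str):
    t = n = m = None
    for token in str(tnm).upper().replace(",", " ").split():
        if token.startswith("T"):
            t = token
        elif token.startswith("N"):
            n = token
        elif token.startswith("M"):
            m = token
    return t, n, m


def classify_stage(tnm: Optional[str] = None, seer: Optional[str] = None) -> str:
    """Localised / nonlocalised / missing from TNM tokens or a SEER label.

    Any of T3, T4, N1, M1 ⇒ nonlocalised; else T1/T2 with N in {N0, NX,
    absent} and M in {M0, MX, absent} ⇒ localised; anything else missing.
    SEER: local ⇒ localised; regional or distant ⇒ nonlocalised. When both
    codings are present and disagree the record is coded missing with a
    warning.
    """
    def _is_blank(x):
        return x is None or (isinstance(x, float) and math.isnan(x)) or str(x).strip() == ""

    tnm_result = seer_result = None
    if not _is_blank(tnm):
        t, n, m = _parse_tnm(tnm)
        tokens = {x for x in (t, n, m) if x is not None}
        if tokens & _NONLOCAL_TOKENS:
            tnm_result = NONLOCALISED
        elif t in _LOCAL_T and n in _LOCAL_N and m in _LOCAL_M:
            tnm_result = LOCALISED
        else:
            tnm_result = MISSING
    if not _is_blank(seer):
        seer_result = _SEER.get(str(seer).strip().lower(), MISSING)

    if tnm_result is not None and seer_result is not None:
        if tnm_result != seer_result and MISSING not in (tnm_result, seer_result):
            warnings.warn(
                f"contradictory stage codings (TNM {tnm!r} vs SEER {seer!r}); "
                "coded missing", stacklevel=2)
            return MISSING
        return tnm_result if tnm_result != MISSING else seer_result
    if tnm_result is not None:
        return tnm_result
    if seer_result is not None:
        return seer_result
    return MISSING


def classify_grade(gleason) -> str:
    """Low (Gleason ≤ 6) / high (≥ 7) / missing."""
    if gleason is None or (isinstance(gleason, float) and math.isnan(gleason)):
        return MISSING
    g = float(gleason)
    if not g.is_integer() or not (2 <= g <= 10):
        warnings.warn(f"Gleason score {gleason!r} outside 2..10; coded missing",
                      stacklevel=2)
        return MISSING
    return "low" if g <= 6 else "high"


def resolve_mortality(vital_status, cause_of_death):
    """(all-cause event, PCa event, include) for one case record.

    Unknown vital status excludes the record; a death with unknown cause
    counts as an all-cause event but is assumed not to be a prostate cancer
    death.
    """
    vs = str(vital_status).strip().lower() if vital_status is not None else "unknown"
    if vs in ("unknown", "", "nan"):
        return 0, 0, False
    if vs == "alive":
        return 0, 0, True
    if vs != "dead":
        raise ValueError(f"unrecognised vital status {vital_status!r}")
    cod = str(cause_of_death).strip().lower() if cause_of_death is not None else "unknown"
    pca = 1 if cod in ("prostate cancer", "pca") else 0
    return 1, pca, True


@dataclass(frozen=True)
class MortalityEligibility:
    """Study-level eligibility for the mortality analyses."""

    study: str
    completeness: float
    pca_deaths: int
    eligible_allcause: bool
    eligible_pca: bool


def study_eligibility(summaries: Iterable[dict]) -> list[MortalityEligibility]:
    """Apply the eligibility rule to per-study follow-up summaries.

    Each summary needs ``study``, ``completeness`` (fraction of cases with
    known vital status) and ``pca_deaths``. All-cause eligibility requires
    completeness ≥ 0.90; cancer-specific additionally ≥ 5 prostate cancer
    deaths. Boundaries are inclusive.
    """
    out = []
    for s in summaries:
        complete = float(s["completeness"])
        pca_deaths = int(s["pca_deaths"])
        all_ok = complete >= COMPLETENESS_MIN
        out.append(MortalityEligibility(
            study=str(s["study"]),
            completeness=complete,
            pca_deaths=pca_deaths,
            eligible_allcause=all_ok,
            eligible_pca=all_ok and pca_deaths >= PCA_DEATHS_MIN,
        ))
    return out


def summarize_followup(cases: pd.DataFrame, study_col="study",
                       vital_col="vital_status", cause_col="cause_of_death") -> list[dict]:
    """Per-study follow-up summaries from case records."""
    rows = []
    for study, grp in cases.groupby(study_col, sort=True):
        vs = grp[vital_col].astype(str).str.strip().str.lower()
        known = vs.isin(["alive", "dead"])
        cod = grp[cause_col].astype(str).str.strip().str.lower()
        pca_deaths = int(((vs == "dead") & cod.isin(["prostate cancer", "pca"])).sum())
        rows.append({
            "study": study,
            "completeness": float(known.mean()) if len(grp) else 0.0,
            "pca_deaths": pca_deaths,
            "n_cases": int(len(grp)),
        })
    return rows
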
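"""Method-bias analysis: single-method species lists, exact tests, community coverage.

Species detected by exactly one method are tested for method bias with
Fisher's exact test on detection frequencies across all site-surveys; the
two-sided p-value follows the usual convention (sum of hypergeometric table
probabilities no larger than the observed table's).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .survey_data import SurveyDataset


@dataclass
class MethodBiasResult:
    species: str
    x_pc: int
    n_pc: int
    x_aru: int
    n_aru: int
    p_value: float
    significant: bool


def single_method_species(ds: SurveyDataset, habitat: str | None = None,
                          paired_only: bool = True) -> dict[str, pd.DataFrame]:
    """Species detected by exactly one method, with incidence counts.

    Returns ``{"PC": ..., "ARU": ...}`` where each frame has columns
    (species, n_detections).  The two lists are disjoint by construction.
    """
    base = ds.restrict_to_paired() if paired_only else ds
    sv = base.surveys_with_sites()
    if habitat is not None:
        sv = sv[sv["habitat"] == habitat]
    dets = base.detections.merge(sv[["survey_id", "method"]], on="survey_id")
    counts = dets.groupby(["species", "method"]).size().unstack(fill_value=0)
    for m in ("PC", "ARU"):
        if m not in counts:
            counts[m] = 0
    out = {}
    for m, other in (("PC", "ARU"), ("ARU", "PC")):
        only = counts[(counts[m] > 0) & (counts[other] == 0)]
        out[m] = (
            only[m].rename("n_detections").reset_index()
            .sort_values("species").reset_index(drop=True)
        )
    return out


def fisher_exact(x_a: int, n_a: int, x_b: int, n_b: int) -> float:
    """Two-sided Fisher exact p for detection frequencies x_a/n_a vs x_b/n_b."""
    for x, n in ((x_a, n_a), (x_b, n_b)):
        if x < 0 or n < 0 or x > n:
            raise ValueError("require 0 <= x <= n for both methods")
    if n_a == 0 and n_b == 0:
        raise ValueError("both methods have zero site-surveys")
    table = [[x_a, n_a - x_a], [x_b, n_b - x_b]]
    return float(_scipy_fisher(table, alternative="two-sided").pvalue)


def method_bias_table(ds: SurveyDataset, habitat: str | None = None,
                      alpha: float = 0.05,
                      paired_only: bool = True) -> pd.DataFrame:
    """Fisher-exact method-bias test for every single-method species.

    Frequencies are pooled across all site-surveys (n = total PC and ARU
    site-surveys at the included sites).
    """
    base = ds.restrict_to_paired() if paired_only else ds
    sv = base.surveys_with_sites()
    if habitat is not None:
        sv = sv[sv["habitat"] == habitat]
    n_pc = int((sv["method"] == "PC").sum())
    n_aru = int((sv["method"] == "ARU").sum())
    lists = single_method_species(ds, habitat=habitat, paired_only=paired_only)
    rows = []
    for m in ("PC", "ARU"):
        for _, rec in lists[m].iterrows():
            x_pc = int(rec["n_detections"]) if m == "PC" else 0
            x_aru = int(rec["n_detections"]) if m == "ARU" else 0
            p = fisher_exact(x_pc, n_pc, x_aru, n_aru)
            rows.append(MethodBiasResult(
                species=rec["species"], x_pc=x_pc, n_pc=n_pc,
                x_aru=x_aru, n_aru=n_aru, p_value=p,
                significant=bool(p < alpha),
            ))
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        df = pd.DataFrame(columns=["species", "x_pc", "n_pc", "x_aru", "n_aru",
                                   "p_value", "significant"])
    return df.sort_values("species").reset_index(drop=True) if len(df) else df


def percent_of_known(estimate: float, known_richness: int) -> float:
    """Asymptotic richness as a percent of the known community (capped at 100)."""
    if known_richness < 1:
        raise ValueError("known_richness must be >= 1")
    return float(min(100.0 * estimate / known_richness, 100.0))


def percent_of_known_summary(percents: dict[str, float]) -> dict:
    """Mean and range of per-habitat community-capture percentages."""
    vals = np.array(list(percents.values()), dtype=float)
    return {
        "per_habitat": dict(percents),
        "mean": float(vals.mean()),
        "range": (float(vals.min()), float(vals.max())),
    }
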
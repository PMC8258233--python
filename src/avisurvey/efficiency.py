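"""Protocol time costs and bootstrap cost-efficiency curves.

Effort combines field visitation and laboratory/sample-processing time:
recorders cost 40 min/site (covering both the deployment and retrieval
visits) plus 9 min per analyzed sample; point counts cost 20 min/site per
visit plus 7 min per count.  In mixed protocols up to two point counts ride
along with the deploy/retrieve visits for free; a third point count incurs
one extra 20-min visit.  Species returns per protocol are bootstrapped by
resampling each site's surveys with replacement and accumulating the species
union across sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey_data import SurveyDataset


@dataclass
class CostParams:
    aru_visit_min: float = 40.0
    aru_sample_min: float = 9.0
    pc_visit_min: float = 20.0
    pc_sample_min: float = 7.0
    shared_visits_cover_pcs: int = 2

    def __post_init__(self):
        if min(self.aru_visit_min, self.aru_sample_min, self.pc_visit_min,
               self.pc_sample_min, self.shared_visits_cover_pcs) < 0:
            raise ValueError("cost parameters must be non-negative")


@dataclass
class ProtocolCurve:
    """Bootstrapped return of one (n_pc, n_aru) protocol in one habitat."""

    n_pc: int
    n_aru: int
    n_sites: int
    effort_hours: float
    mean_richness: float
    se_richness: float
    percent_of_known: float


def protocol_effort_minutes(n_pc: int, n_aru: int, n_sites: int,
                            costs: CostParams | None = None) -> float:
    costs = costs or CostParams()
    if n_pc < 0 or n_aru < 0 or n_sites < 1:
        raise ValueError("counts must be non-negative and n_sites >= 1")
    if n_aru == 0:
        # PC-only: every count is its own visit
        per_site = n_pc * (costs.pc_visit_min + costs.pc_sample_min)
    else:
        per_site = costs.aru_visit_min + costs.aru_sample_min * n_aru
        if n_pc > 0:
            extra_visits = max(0, n_pc - costs.shared_visits_cover_pcs)
            per_site += costs.pc_sample_min * n_pc + costs.pc_visit_min * extra_visits
    return per_site * n_sites


def protocol_effort_hours(n_pc: int, n_aru: int, n_sites: int,
                          costs: CostParams | None = None) -> float:
    return protocol_effort_minutes(n_pc, n_aru, n_sites, costs) / 60.0


def format_hours(hours: float) -> float:
    """Report >= 10 hr to the nearest hour, below that to 0.1 hr."""
    return float(round(hours)) if hours >= 10 else round(hours, 1)


def _site_pools(ds: SurveyDataset, habitat: str):
    """Per paired site: boolean survey x species masks, split by method."""
    base = ds.restrict_to_paired()
    sv = base.surveys_with_sites()
    sv = sv[sv["habitat"] == habitat]
    if sv.empty:
        raise ValueError(f"no paired surveys in habitat {habitat!r}")
    species = sorted(
        ds.detections[ds.detections["survey_id"].isin(set(sv["survey_id"]))]["species"].unique()
    )
    sp_pos = {s: j for j, s in enumerate(species)}
    det = ds.detections[ds.detections["survey_id"].isin(set(sv["survey_id"]))]
    by_survey: dict[str, np.ndarray] = {}
    for survey_id, grp in det.groupby("survey_id"):
        v = np.zeros(len(species), dtype=bool)
        v[[sp_pos[s] for s in grp["species"]]] = True
        by_survey[survey_id] = v
    empty = np.zeros(len(species), dtype=bool)
    pools = []
    for site_id, grp in sv.groupby("site_id"):
        pc = grp[grp["method"] == "PC"]["survey_id"]
        aru = grp[grp["method"] == "ARU"]["survey_id"]
        pools.append({
            "site_id": site_id,
            "PC": np.array([by_survey.get(s, empty) for s in pc]) if len(pc)
                  else np.zeros((0, len(species)), dtype=bool),
            "ARU": np.array([by_survey.get(s, empty) for s in aru]) if len(aru)
                   else np.zeros((0, len(species)), dtype=bool),
        })
    return pools, species


def bootstrap_protocol_richness(ds: SurveyDataset, habitat: str, n_pc: int,
                                n_aru: int, B: int = 10_000,
                                seed: int | None = None,
                                pc_replacement: bool = True) -> dict:
    """Bootstrapped species richness of a (n_pc, n_aru) protocol.

    Per replicate, each paired site contributes n_pc point counts and n_aru
    recorder samples drawn with replacement from its own survey pool; the
    richness is the size of the species union across sites.  Returns the mean
    and the standard deviation of replicate richness, plus the mean as a
    percent of the known community for the habitat.
    """
    known = ds.known_community[ds.known_community["habitat"] == habitat]["species"].nunique()
    if n_pc == 0 and n_aru == 0:
        return {"mean": 0.0, "se": 0.0, "percent_of_known": 0.0,
                "n_sites": len(ds.restrict_to_paired().sites), "known_richness": known}
    rng = np.random.default_rng(seed)
    pools, species = _site_pools(ds, habitat)
    S = len(species)
    acc = np.zeros((B, S), dtype=bool)
    for pool in pools:
        for m, n_draw in (("PC", n_pc), ("ARU", n_aru)):
            if n_draw == 0:
                continue
            masks = pool[m]
            n_avail = masks.shape[0]
            if n_avail == 0:
                continue
            if pc_replacement or m == "ARU":
                idx = rng.integers(0, n_avail, size=(B, n_draw))
            else:
                k = min(n_draw, n_avail)
                idx = np.array([rng.choice(n_avail, size=k, replace=False)
                                for _ in range(B)])
            acc |= masks[idx].any(axis=1)
    rich = acc.sum(axis=1).astype(float)
    mean = float(rich.mean())
    se = float(rich.std(ddof=0))
    pct = min(100.0 * mean / known, 100.0) if known else float("nan")
    return {"mean": mean, "se": se, "percent_of_known": pct,
            "n_sites": len(pools), "known_richness": known}


def protocol_curves(ds: SurveyDataset, habitat: str, max_pc: int = 3,
                    max_aru: int = 15, B: int = 10_000,
                    seed: int | None = None,
                    costs: CostParams | None = None) -> pd.DataFrame:
    """Efficiency curves over all single- and dual-method protocols.

    Protocols: ARU-only (1..max_aru samples/site), PC-only (1..max_pc), and
    every PC+ARU combination.  Seeds are derived per protocol so any subset
    of the grid reproduces identically.
    """
    seeds = np.random.SeedSequence(seed).spawn((max_pc + 1) * (max_aru + 1))
    rows = []
    i = 0
    for n_pc in range(0, max_pc + 1):
        for n_aru in range(0, max_aru + 1):
            sub_seed = seeds[i].generate_state(1)[0]
            i += 1
            if n_pc == 0 and n_aru == 0:
                continue
            boot = bootstrap_protocol_richness(ds, habitat, n_pc, n_aru, B=B,
                                               seed=sub_seed)
            hours = protocol_effort_hours(n_pc, n_aru, boot["n_sites"], costs)
            rows.append(ProtocolCurve(
                n_pc=n_pc, n_aru=n_aru, n_sites=boot["n_sites"],
                effort_hours=hours, mean_richness=boot["mean"],
                se_richness=boot["se"], percent_of_known=boot["percent_of_known"],
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def efficiency_frontier(curves: pd.DataFrame) -> pd.DataFrame:
    """Pareto-optimal protocols: most community captured for least effort.

    A protocol is dominated when another costs no more effort and captures at
    least as much of the community, strictly better on one axis.
    """
    if len(curves) < 1:
        raise ValueError("need at least one protocol")
    keep = []
    for i, row in curves.iterrows():
        dominated = False
        for j, other in curves.iterrows():
            if i == j:
                continue
            if (other["effort_hours"] <= row["effort_hours"]
                    and other["percent_of_known"] >= row["percent_of_known"]
                    and (other["effort_hours"] < row["effort_hours"]
                         or other["percent_of_known"] > row["percent_of_known"])):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return curves.loc[keep].sort_values("effort_hours").reset_index(drop=True)
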
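"""End-to-end orchestration: simulate -> diversity -> compare -> occupancy -> efficiency.

A run is driven by a plain-dict (or YAML) config; every stochastic stage has
an explicit seed recorded in the run log, and identical config + seeds yield
a byte-identical summary JSON.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import __version__
from . import diversity as dv
from . import efficiency as eff
from . import method_comparison as mc
from . import occupancy as occ
from . import survey_data as sd
from . import synthetic_data as syn

DEFAULT_CONFIG = {
    "scenario": "BC",            # BC | Chile | null (requires input_dir)
    "input_dir": None,
    "out_dir": "out",
    "stages": ["simulate", "diversity", "compare", "efficiency"],
    "seeds": {"simulate": 1, "diversity": 2, "occupancy": 3, "efficiency": 4},
    "coverage_target": 0.97,
    "boot_diversity": 200,
    "efficiency_reps": 1000,
    "max_pc": 3,
    "max_aru": 15,
    "gof_boot": 50,
    "plots": False,
}

KNOWN_STAGES = ("simulate", "diversity", "compare", "occupancy", "efficiency")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: dict) -> str:
    # the output location is not an analysis input
    blob = json.dumps({k: v for k, v in config.items() if k != "out_dir"},
                      sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _round(x, nd=4):
    return None if x is None else round(float(x), nd)


def run(config: dict) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the machine-readable summary (also written as ``summary.json``).
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    cfg["seeds"] = {**DEFAULT_CONFIG["seeds"], **(config.get("seeds", {}) if config else {})}
    unknown = set(cfg["stages"]) - set(KNOWN_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)

    summary: dict = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seeds": cfg["seeds"],
        "stages": list(cfg["stages"]),
    }

    ds = None
    region = cfg["scenario"] or "BC"
    try:
        if "simulate" in cfg["stages"]:
            data_dir = os.path.join(out_dir, "data")
            ds = syn.generate_scenario(region, seed=cfg["seeds"]["simulate"])
            sd.write_dataset(ds, data_dir)
            summary["simulate"] = {
                "region": region,
                "site_surveys": {
                    "total": sd.tally_site_surveys(ds),
                    "ARU": sd.tally_site_surveys(ds, method="ARU"),
                    "PC": sd.tally_site_surveys(ds, method="PC"),
                },
                "n_sites": int(len(ds.sites)),
            }
        elif cfg["input_dir"]:
            ds = sd.read_dataset(cfg["input_dir"])
        else:
            raise ValueError("no data source: enable the simulate stage or set input_dir")
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", e) from e

    if "diversity" in cfg["stages"]:
        try:
            rows, fig_rows = [], []
            for habitat in sd.HABITATS:
                for pooling, meth in (("pc", "PC"), ("pooled_morning", "ARU")):
                    inc = sd.build_incidence(ds, habitat, pooling=pooling)
                    for q in (0, 1):
                        est = dv.estimate_at_coverage(
                            inc, q, cfg["coverage_target"], B=cfg["boot_diversity"],
                            seed=cfg["seeds"]["diversity"])
                        rows.append({
                            "habitat": habitat, "method": meth, "q": q, "t": est.t,
                            "estimate": _round(est.estimate), "se": _round(est.se),
                            "lo84": _round(est.ci84[0]), "hi84": _round(est.ci84[1]),
                            "lo95": _round(est.ci95[0]), "hi95": _round(est.ci95[1]),
                            "coverage": _round(est.coverage),
                            "chao2_asymptote": _round(dv.chao2(inc)),
                        })
                    for pt in dv.accumulation_curve(inc, q=0):
                        fig_rows.append({"habitat": habitat, "method": meth,
                                         "t": pt.t, "richness": _round(pt.estimate),
                                         "coverage": _round(pt.coverage)})
            div_dir = os.path.join(out_dir, "diversity")
            os.makedirs(div_dir, exist_ok=True)
            div_df = pd.DataFrame(rows)
            div_df.to_csv(os.path.join(div_dir, "estimates.csv"), index=False)
            pd.DataFrame(fig_rows).to_csv(os.path.join(div_dir, "curves.csv"), index=False)
            known = ds.known_community.groupby("habitat")["species"].nunique()
            pct = {}
            for habitat in sd.HABITATS:
                inc = sd.build_incidence(ds, habitat, pooling="pooled_morning")
                pct[habitat] = mc.percent_of_known(dv.chao2(inc), int(known[habitat]))
            summary["diversity"] = {
                "estimates": rows,
                "aru_percent_of_known": {k: _round(v, 1) for k, v in pct.items()},
                "aru_percent_of_known_mean": _round(np.mean(list(pct.values())), 1),
            }
            if cfg["plots"]:
                _plot_curves(pd.DataFrame(fig_rows), os.path.join(div_dir, "curves.png"))
        except Exception as e:  # noqa: BLE001
            raise StageError("diversity", e) from e

    if "compare" in cfg["stages"]:
        try:
            cmp_dir = os.path.join(out_dir, "compare")
            os.makedirs(cmp_dir, exist_ok=True)
            table = mc.method_bias_table(ds)
            table.to_csv(os.path.join(cmp_dir, "method_bias.csv"), index=False)
            lists = mc.single_method_species(ds)
            summary["compare"] = {
                "pc_only": int(len(lists["PC"])),
                "aru_only": int(len(lists["ARU"])),
                "significant": int(table["significant"].sum()) if len(table) else 0,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("compare", e) from e

    if "occupancy" in cfg["stages"]:
        try:
            occ_dir = os.path.join(out_dir, "occupancy")
            os.makedirs(occ_dir, exist_ok=True)
            tasks = sd.filter_families(ds)
            occ_summary = []
            for family, habitats in tasks[:cfg.get("max_families", 3)]:
                dh = occ.build_history(ds, family, habitats)
                full = occ.fit(occ.full_model(), dh, seed=cfg["seeds"]["occupancy"])
                chat = occ.estimate_chat(full, dh, n_boot=cfg["gof_boot"],
                                         seed=cfg["seeds"]["occupancy"])
                table, best, flag = occ.select_model(dh, chat,
                                                     seed=cfg["seeds"]["occupancy"])
                table.to_csv(os.path.join(occ_dir, f"{family}_selection.csv"), index=False)
                best.coef().rename("estimate").to_csv(
                    os.path.join(occ_dir, f"{family}_coefficients.csv"))
                occ_summary.append({
                    "family": family, "habitats": list(habitats),
                    "chat": _round(chat, 3), "flag": flag,
                    "best_model": None if flag else str(table.loc[0, "model"]),
                })
            summary["occupancy"] = occ_summary
        except Exception as e:  # noqa: BLE001
            raise StageError("occupancy", e) from e

    if "efficiency" in cfg["stages"]:
        try:
            eff_dir = os.path.join(out_dir, "efficiency")
            os.makedirs(eff_dir, exist_ok=True)
            effort_table = []
            all_curves = {}
            for habitat in sd.HABITATS:
                curves = eff.protocol_curves(
                    ds, habitat, max_pc=cfg["max_pc"], max_aru=cfg["max_aru"],
                    B=cfg["efficiency_reps"], seed=cfg["seeds"]["efficiency"])
                curves.to_csv(os.path.join(eff_dir, f"{habitat}_curves.csv"), index=False)
                frontier = eff.efficiency_frontier(curves)
                frontier.to_csv(os.path.join(eff_dir, f"{habitat}_frontier.csv"), index=False)
                all_curves[habitat] = curves
                n_sites = int(curves["n_sites"].iloc[0])
                for n_pc, n_aru in ((0, 1), (1, 0), (2, 0), (3, 0)):
                    hours = eff.protocol_effort_hours(n_pc, n_aru, n_sites)
                    effort_table.append({
                        "habitat": habitat, "n_pc": n_pc, "n_aru": n_aru,
                        "n_sites": n_sites, "effort_hours": _round(hours, 2),
                        "effort_hours_printed": eff.format_hours(hours),
                    })
            summary["efficiency"] = {"effort_table": effort_table}
            if cfg["plots"]:
                for habitat, curves in all_curves.items():
                    _plot_efficiency(curves, os.path.join(eff_dir, f"{habitat}_curves.png"))
        except Exception as e:  # noqa: BLE001
            raise StageError("efficiency", e) from e

    with open(os.path.join(out_dir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _plot_curves(df: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    for ax, habitat in zip(axes, sd.HABITATS):
        for meth, color in (("PC", "tab:blue"), ("ARU", "tab:red")):
            sub = df[(df["habitat"] == habitat) & (df["method"] == meth)]
            ax.plot(sub["t"], sub["richness"], color=color, label=meth)
        ax.set_title(habitat)
        ax.set_xlabel("sampling units")
    axes[0].set_ylabel("species richness")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_efficiency(curves: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for n_pc, grp in curves.groupby("n_pc"):
        grp = grp.sort_values("effort_hours")
        ax.errorbar(grp["effort_hours"], grp["percent_of_known"],
                    yerr=grp["se_richness"], label=f"{n_pc} PC", alpha=0.8)
    ax.set_xlabel("effort (hours)")
    ax.set_ylabel("% of known community")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
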
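"""End-to-end analysis of a trial log.

Assembles the full pipeline: exclusion screening, per-participant summary
measures, the rectified exponential-binomial fit with likelihood-ratio test,
profile-likelihood band, Laplace Bayes factor and range coverage, the
first-vs-second block trend tests, the within-participant object-consistency
analysis, and (when debriefing records are supplied) the explicitness
partial-correlation analysis. Each stage that cannot run on the given log
degrades to an explicit ``"skipped"`` entry rather than failing the report.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import __version__
from .bayes import DEFAULT_SCALE
from .consistency import (
    consistency_group_test,
    explicitness_partial_analysis,
    explicitness_score,
    object_consistency,
    scene_scores,
)
from .exceptions import DataError, InsufficientDataError, VisuoHapticError
from .inventory import Inventory
from .measures import block_trend_test, performance_table
from .reb import RectifiedExponentialBinomial


def participant_consistencies(
    log: pd.DataFrame, inventory: Inventory, participant_ids=None
) -> pd.DataFrame:
    """Object-consistency per participant (NaN where undefined)."""
    if participant_ids is None:
        participant_ids = sorted(log["participant_id"].unique())
    rows = []
    for pid in participant_ids:
        scores = scene_scores(log, pid, inventory)
        r, defined = object_consistency(scores)
        rows.append(
            {
                "participant_id": pid,
                "n_scenes": len(scores),
                "consistency": r,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def analyze(
    log: pd.DataFrame,
    inventory: Inventory,
    debrief: pd.DataFrame | None = None,
    n_band_samples: int = 100_000,
    alpha: float = 0.05,
    bf_scale: float = DEFAULT_SCALE,
    seed: int = 0,
    fit_seed: int = 0,
) -> dict:
    """Run every analysis stage on one experiment's trial log.

    Returns a JSON-serializable report. The model is fitted on participants
    who survive exclusion and have a defined pulling correlation.
    """
    experiment = str(log["experiment"].iloc[0])
    report: dict = {"experiment": experiment, "package_version": __version__}

    perf = performance_table(log)
    report["n_participants"] = int(len(perf))
    report["n_excluded"] = int(perf["excluded"].sum())
    report["exclusions"] = perf.loc[
        perf["excluded"], ["participant_id", "exclusion_reason"]
    ].to_dict("records")
    included = perf[~perf["excluded"]]
    usable = included[included["rho_defined"]]
    report["performance"] = {
        "mean_fraction_correct": float(included["f_c"].mean()),
        "mean_rho": float(usable["rho"].mean()) if len(usable) else None,
        "clipped_fraction": float(included["clipped_fraction"].mean()),
    }

    # rectified exponential-binomial fit
    if len(usable) >= 3 and np.ptp(usable["rho"].to_numpy()) > 0:
        model = RectifiedExponentialBinomial(
            usable["rho"].to_numpy(), usable["T_c"].to_numpy(), usable["T"].to_numpy()
        )
        res = model.fit(seed=fit_seed)
        report["refb"] = res.to_dict()
        try:
            band = res.profile_band(alpha=alpha, n_samples=n_band_samples, seed=seed)
            report["refb"]["band"] = {
                "n_retained": band.n_retained,
                "table": band.to_frame().to_dict("list"),
            }
        except VisuoHapticError as err:
            report["refb"]["band"] = {"skipped": str(err)}
        report["_refb_results"] = res  # in-memory handle, stripped on export
    else:
        report["refb"] = {"skipped": "fewer than 3 usable participants"}

    # block trend tests (performance stationarity during the tests)
    report["block_trend"] = {}
    for label, c1, c2 in (
        ("pulling_rho", "rho_block1", "rho_block2"),
        ("familiarity_fc", "f_c_block1", "f_c_block2"),
    ):
        try:
            t, df, p, bf = block_trend_test(
                included[c1].to_numpy(), included[c2].to_numpy(), bf_scale
            )
            report["block_trend"][label] = {"t": t, "df": df, "p": p, "bf10": bf}
        except (InsufficientDataError, DataError) as err:
            report["block_trend"][label] = {"skipped": str(err)}

    # within-participant object consistency
    try:
        cons = participant_consistencies(
            log, inventory, included["participant_id"].tolist()
        )
        report["consistency_table"] = cons.to_dict("records")
        mean, sem, t, df, p, bf = consistency_group_test(
            cons["consistency"].to_numpy(), bf_scale
        )
        report["consistency"] = {
            "mean": mean,
            "sem": sem,
            "t": t,
            "df": df,
            "p": p,
            "bf10": bf,
            "n_defined": int(cons["defined"].sum()),
            "n_undefined": int((~cons["defined"]).sum()),
        }
    except (VisuoHapticError, KeyError) as err:
        report["consistency"] = {"skipped": str(err)}

    # explicitness (needs both experiments for the indicator; a single log
    # falls back to a plain correlation with a warning)
    if debrief is not None:
        merged = included.merge(debrief, on="participant_id", how="inner")
        if len(merged) >= 4:
            expl = [
                explicitness_score(r.noticed, r.n_correct_pairs, r.n_true_pairs)
                for r in merged.itertuples()
            ]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ana = explicitness_partial_analysis(
                    merged["f_c"], merged["rho"], expl, merged["experiment"]
                )
            report["explicitness"] = {
                "r_full": ana.r_full,
                "p_full": ana.p_full,
                "bf_full": ana.bf_full,
                "r_partial": ana.r_partial,
                "p_partial": ana.p_partial,
                "bf_partial": ana.bf_partial,
                "variance_ratio": ana.variance_ratio,
                "n": ana.n,
                "single_experiment": ana.single_experiment,
            }
        else:
            report["explicitness"] = {"skipped": "fewer than 4 debriefed participants"}

    return report


def pooled_consistency(
    logs_and_inventories: list[tuple[pd.DataFrame, Inventory]],
    bf_scale: float = DEFAULT_SCALE,
) -> dict:
    """Pool per-participant consistency values across experiments (each value
    is computed within its own log; pooling only changes the group test)."""
    vals = []
    for log, inv in logs_and_inventories:
        perf = performance_table(log)
        keep = perf.loc[~perf["excluded"], "participant_id"].tolist()
        cons = participant_consistencies(log, inv, keep)
        vals.extend(cons["consistency"].tolist())
    mean, sem, t, df, p, bf = consistency_group_test(vals, bf_scale)
    return {"mean": mean, "sem": sem, "t": t, "df": df, "p": p, "bf10": bf, "n": df + 1}


def export_report(report: dict) -> dict:
    """Strip in-memory handles, leaving the JSON-serializable payload."""
    return {k: v for k, v in report.items() if not k.startswith("_")}
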
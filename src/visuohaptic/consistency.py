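"""Within-participant object-consistency and explicit-knowledge analyses.

Object-consistency asks whether the *same* pairs a participant treats as
objects in the familiarity test are the ones they treat as objects when
pulling. For each unique ordered two-true-pair scene of the pulling test
(12 in the visual-exposure experiment, 4 in the haptic-exposure experiment):

* haptic score: mean pulling force on the scene's break-direction trials
  minus mean force on its separate-direction trials (N);
* familiarity score: the average, over the scene's two pairs, of the fraction
  of familiarity trials containing that pair in which it was chosen.

A participant's consistency is the Pearson correlation of the two scores
across scenes — positive even for a participant acting on a consistently
*wrong* internal inventory, which is the point of the measure. Participants
at familiarity ceiling (fraction correct 1) have zero familiarity-score
variance and are flagged undefined rather than scored.

The explicitness analysis quantifies each debriefed participant's explicit
knowledge as the proportion of true pairs they correctly identified
(incorrect identifications ignored) and asks how much of the across-modality
relationship survives controlling for it: performances are residualized on
explicitness within each experiment, the indicator-adjusted correlation is
recomputed on the residuals, and the variance ratio R_partial^2 / R_full^2
gives the share of the generalisation effect attributable to implicit
transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import DEFAULT_SCALE, jzs_bf_one_sample, jzs_regression_bf
from .cohort import PHASE_FAMILIARITY, PHASE_PULL_TEST
from .exceptions import DataError, IncompleteLogError, InsufficientDataError
from .inventory import Inventory


@dataclass
class SceneScore:
    scene_id: str  # scene code of the unique ordered two-true-pair scene
    haptic_score: float  # N
    familiarity_score: float  # in [0, 1]
    n_repetitions: int


def _pair_ids_of(code: str) -> list[int]:
    return [int(part.split("@")[0]) for part in code.split(";")]


def scene_scores(
    log: pd.DataFrame, participant_id: int, inventory: Inventory
) -> list[SceneScore]:
    """Per-scene haptic and familiarity scores for one participant."""
    sub = log[log["participant_id"] == participant_id]
    pull = sub[sub["phase"] == PHASE_PULL_TEST]
    fam = sub[sub["phase"] == PHASE_FAMILIARITY]
    if len(pull) == 0 or len(fam) == 0:
        raise IncompleteLogError(
            f"participant {participant_id}: pulling-test and familiarity-test "
            "rows are both required"
        )
    true_ids = {p.pair_id for p in inventory.true_pairs}

    # fraction of familiarity trials containing each pair in which it was chosen
    def choice_fraction(pair_id: int) -> float:
        as_first = fam[fam["first_pair"] == pair_id]
        as_second = fam[fam["second_pair"] == pair_id]
        shown = len(as_first) + len(as_second)
        if shown == 0:
            return np.nan
        chosen = (as_first["choice"] == "first").sum() + (
            as_second["choice"] == "second"
        ).sum()
        return chosen / shown

    scores = []
    for code, grp in pull.groupby("scene_code", sort=True):
        pids = _pair_ids_of(code)
        if not all(pid in true_ids for pid in pids):
            continue
        b = grp["breakage_force_N"].to_numpy(float)
        f = grp["pull_force_N"].to_numpy(float)
        hard = b == b.max()
        if hard.all() or not hard.any():
            raise DataError(f"scene {code}: need both pulling directions")
        haptic = f[hard].mean() - f[~hard].mean()
        familiarity = float(np.mean([choice_fraction(pid) for pid in pids]))
        scores.append(SceneScore(code, float(haptic), familiarity, len(grp) // 2))
    return scores


def object_consistency(scores: list[SceneScore]) -> tuple[float, bool]:
    """Pearson correlation of haptic vs familiarity scores across scenes.

    Returns (correlation, defined); undefined when either score has zero
    variance (e.g. a participant at familiarity ceiling).
    """
    if len(scores) < 3:
        raise DataError("need >= 3 scenes")
    h = np.array([s.haptic_score for s in scores])
    f = np.array([s.familiarity_score for s in scores])
    if np.std(h) == 0 or np.std(f) == 0:
        return float("nan"), False
    r, _ = stats.pearsonr(h, f)
    return float(r), True


def shuffled_consistency(
    scores: list[SceneScore], rng: np.random.Generator
) -> tuple[float, bool]:
    """Consistency after permuting the scene labels of the familiarity scores
    — the inventory-shuffled null that destroys any within-participant link
    between the two modalities while preserving both marginals."""
    f = np.array([s.familiarity_score for s in scores])
    perm = rng.permutation(len(scores))
    shuffled = [
        SceneScore(s.scene_id, s.haptic_score, float(f[perm[i]]), s.n_repetitions)
        for i, s in enumerate(scores)
    ]
    return object_consistency(shuffled)


def consistency_group_test(correlations, scale_r: float = DEFAULT_SCALE):
    """One-sample t-test of the per-participant consistency values against 0
    (pooled across experiments), with the JZS Bayes factor.

    Returns (mean, sem, t, df, p, bf10) over participants whose consistency is
    defined.
    """
    vals = np.asarray(list(correlations), dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        raise InsufficientDataError("need >= 2 defined consistency values")
    mean = float(np.mean(vals))
    sem = float(stats.sem(vals))
    if np.std(vals, ddof=1) == 0:
        t, p = (0.0, 1.0) if mean == 0 else (np.inf * np.sign(mean), 0.0)
    else:
        t, p = stats.ttest_1samp(vals, 0.0)
        t, p = float(t), float(p)
    bf = jzs_bf_one_sample(t if np.isfinite(t) else 100.0, len(vals), scale_r)
    return mean, sem, t, len(vals) - 1, p, bf.bf10


# ---------------------------------------------------------------------------
# Explicitness
# ---------------------------------------------------------------------------


def explicitness_score(noticed: bool, n_correct_pairs: int, n_true_pairs: int) -> float:
    """Proportion of true pairs correctly identified at debriefing.

    Participants who noticed no pairs score 0; incorrect identifications are
    ignored, so the score errs on the side of increased explicitness.
    """
    if n_correct_pairs < 0 or n_correct_pairs > n_true_pairs:
        raise DataError("n_correct_pairs must lie in [0, n_true_pairs]")
    if not noticed:
        if n_correct_pairs != 0:
            raise DataError("participants who noticed nothing cannot have correct pairs")
        return 0.0
    return n_correct_pairs / n_true_pairs


def variance_ratio(r_full: float, r_partial: float) -> float:
    """Share of the explained variance surviving the explicitness control:
    r_partial^2 / r_full^2."""
    if r_full == 0:
        raise DataError("variance ratio undefined for r_full = 0")
    return r_partial**2 / r_full**2


@dataclass
class ExplicitnessAnalysis:
    r_full: float
    p_full: float
    bf_full: float
    r_partial: float
    p_partial: float
    bf_partial: float
    variance_ratio: float  # R_partial^2 / R_full^2
    n: int
    single_experiment: bool = False


def _indicator_adjusted_r(visual, haptic, labels) -> tuple[float, float]:
    """Correlation between visual and haptic performance allowing experiment-
    specific intercepts but a common slope: the partial correlation given the
    experiment indicator, computed on within-experiment-centred values."""
    v = np.asarray(visual, float).copy()
    h = np.asarray(haptic, float).copy()
    labels = np.asarray(labels)
    for lab in np.unique(labels):
        m = labels == lab
        v[m] -= v[m].mean()
        h[m] -= h[m].mean()
    r, _ = stats.pearsonr(v, h)
    # t-test of the haptic slope in the indicator-adjusted regression
    df = len(v) - 3
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-12))
    p = 2 * stats.t.sf(abs(t), df)
    return float(r), float(p)


def _residualize_on(y, x, labels):
    """Within each experiment, residualize y on x by least squares."""
    y = np.asarray(y, float).copy()
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    out = np.empty_like(y)
    for lab in np.unique(labels):
        m = labels == lab
        X = np.column_stack([np.ones(m.sum()), x[m]])
        beta, *_ = np.linalg.lstsq(X, y[m], rcond=None)
        out[m] = y[m] - X @ beta
    return out


def explicitness_partial_analysis(
    visual, haptic, explicitness, experiment_labels
) -> ExplicitnessAnalysis:
    """Full and explicitness-partialled visual-haptic correlation.

    ``r_full`` is the indicator-adjusted correlation between visual and haptic
    performance (common slope, experiment-specific intercepts). For
    ``r_partial``, both performances are first residualized on explicitness
    within each experiment, then the same indicator-adjusted correlation is
    computed on the residuals. ``variance_ratio = r_partial^2 / r_full^2`` is
    the share of the generalisation effect attributable to implicit transfer.
    JZS regression Bayes factors (haptic + indicator covariates) are attached.
    """
    v = np.asarray(visual, float)
    h = np.asarray(haptic, float)
    e = np.asarray(explicitness, float)
    labels = np.asarray(experiment_labels)
    if not (len(v) == len(h) == len(e) == len(labels)):
        raise DataError("all inputs must have equal length")
    if len(v) < 4:
        raise InsufficientDataError("need >= 4 participants")
    single = len(np.unique(labels)) < 2
    if single:
        import warnings

        warnings.warn("single-experiment input: falling back to plain correlation")
    n = len(v)
    r_full, p_full = _indicator_adjusted_r(v, h, labels)
    v_res = _residualize_on(v, e, labels)
    h_res = _residualize_on(h, e, labels)
    r_partial, p_partial = _indicator_adjusted_r(v_res, h_res, labels)
    n_cov = 1 if single else 2
    bf_full = jzs_regression_bf(r_full**2, n, n_cov).bf10
    bf_partial = jzs_regression_bf(r_partial**2, n, n_cov).bf10
    ratio = (r_partial**2 / r_full**2) if r_full != 0 else np.nan
    return ExplicitnessAnalysis(
        r_full=r_full,
        p_full=p_full,
        bf_full=bf_full,
        r_partial=r_partial,
        p_partial=p_partial,
        bf_partial=bf_partial,
        variance_ratio=float(ratio),
        n=n,
        single_experiment=single,
    )
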
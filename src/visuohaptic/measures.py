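"""Per-participant summary measures and sample-level screening tests.

Two per-participant summaries drive every downstream analysis:

* fraction correct ``f_c = Tc/T`` over the two-alternative familiarity trials,
* the Pearson correlation ``rho`` between the (40 N-clipped) pulling force and
  the required breakage force across pulling-test trials.

With exactly two breakage-force levels and equal trial counts, rho is
monotonically equivalent to the two-sample t statistic comparing forces at
the two levels: t^2 = rho^2 (n-2) / (1 - rho^2).

Also here: the paired first-vs-second block trend test (with its JZS Bayes
factor) and the training-based inclusion rule — a participant is retained
only with a significantly positive force/breakage correlation on the
clamp-catch training trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import DEFAULT_SCALE, jzs_bf_one_sample
from .cohort import PHASE_FAMILIARITY, PHASE_PULL_TEST, PHASE_TRAINING
from .exceptions import DataError, EmptyInputError, InsufficientDataError
from .scenes import CLAMP_CATCH


@dataclass
class ParticipantPerformance:
    participant_id: int
    f_c: float
    T_c: int
    T: int
    rho: float  # NaN when undefined
    rho_defined: bool
    f_c_block1: float = np.nan
    f_c_block2: float = np.nan
    rho_block1: float = np.nan
    rho_block2: float = np.nan
    excluded: bool = False
    exclusion_reason: str = ""
    clipped_fraction: float = 0.0


def fraction_correct(correct_flags) -> tuple[float, int, int]:
    """(f_c, Tc, T) from per-trial correctness indicators."""
    flags = np.asarray(list(correct_flags), dtype=float)
    if flags.size == 0:
        raise EmptyInputError("no familiarity trials")
    if np.any(~np.isin(flags, (0.0, 1.0))):
        raise DataError("correctness flags must be 0/1")
    tc = int(flags.sum())
    t = int(flags.size)
    return tc / t, tc, t


def pulling_correlation(forces, breakage) -> tuple[float, bool]:
    """Pearson correlation between pulling and breakage forces.

    Returns ``(rho, defined)``; when either series has zero variance the
    correlation is undefined and flagged rather than silently zeroed.
    """
    f = np.asarray(forces, dtype=float)
    b = np.asarray(breakage, dtype=float)
    if f.shape != b.shape or f.size < 3:
        raise DataError("need equal-length force series of length >= 3")
    if np.std(f) == 0 or np.std(b) == 0:
        return float("nan"), False
    r, _ = stats.pearsonr(f, b)
    return float(r), True


def rho_t_equivalence(forces, breakage) -> tuple[float, float]:
    """Two-sample t statistic across the two breakage levels, plus Pearson rho.

    Requires exactly two breakage levels with equal trial counts; then
    t^2 = rho^2 (n-2) / (1-rho^2) holds to numerical precision (the t is the
    equal-variance two-sample statistic, high-force level minus low).
    """
    f = np.asarray(forces, dtype=float)
    b = np.asarray(breakage, dtype=float)
    levels = np.unique(b)
    if len(levels) != 2:
        raise DataError("need exactly two breakage levels")
    hi, lo = f[b == levels[1]], f[b == levels[0]]
    if len(hi) != len(lo):
        raise DataError("need equal trial counts at the two levels")
    t_stat, _ = stats.ttest_ind(hi, lo, equal_var=True)
    rho, defined = pulling_correlation(f, b)
    if not defined:
        return float(t_stat), float("nan")
    return float(t_stat), rho


def block_trend_test(block1, block2, scale_r: float = DEFAULT_SCALE):
    """Paired t-test of block 2 minus block 1 performance across the cohort,
    with the JZS Bayes factor. Returns (t, df, p, bf10)."""
    b1 = np.asarray(block1, dtype=float)
    b2 = np.asarray(block2, dtype=float)
    ok = np.isfinite(b1) & np.isfinite(b2)
    b1, b2 = b1[ok], b2[ok]
    if len(b1) < 2:
        raise InsufficientDataError("need >= 2 participants with both blocks")
    diffs = b2 - b1
    if np.std(diffs, ddof=1) == 0:
        t = 0.0 if np.allclose(diffs, 0) else np.inf * np.sign(diffs.mean())
        p = 1.0 if t == 0 else 0.0
    else:
        t, p = stats.ttest_rel(b2, b1)
        t, p = float(t), float(p)
    bf = jzs_bf_one_sample(t if np.isfinite(t) else 100.0, len(b1), scale_r, paired=True)
    return t, len(b1) - 1, p, bf.bf10


def apply_exclusion(training_forces, training_breakage) -> tuple[bool, str]:
    """Training-based inclusion rule (visual-exposure experiment).

    A participant is included only with a positive Pearson correlation between
    pulling force and required breakage force on clamp-catch training trials,
    significant at two-sided p < 0.05. Returns (excluded, reason).
    """
    f = np.asarray(training_forces, dtype=float)
    b = np.asarray(training_breakage, dtype=float)
    if f.size < 3:
        return True, "too few training trials"
    if np.std(f) == 0 or np.std(b) == 0:
        return True, "undefined correlation"
    r, p = stats.pearsonr(f, b)
    if r > 0 and p < 0.05:
        return False, ""
    return True, f"training correlation r={r:.3f}, p={p:.3g}"


# ---------------------------------------------------------------------------
# Trial-log driven summaries
# ---------------------------------------------------------------------------


def participant_performance(
    log: pd.DataFrame, participant_id: int, force_cap: float = 40.0
) -> ParticipantPerformance:
    """All summary measures for one participant of a trial log."""
    sub = log[log["participant_id"] == participant_id]
    fam = sub[sub["phase"] == PHASE_FAMILIARITY]
    pull = sub[sub["phase"] == PHASE_PULL_TEST]
    if len(fam) == 0 or len(pull) == 0:
        raise DataError(f"participant {participant_id}: missing test phase")
    f_c, tc, t = fraction_correct(fam["correct"].astype(int))
    forces = pull["pull_force_N"].to_numpy(float)
    breakage = pull["breakage_force_N"].to_numpy(float)
    rho, defined = pulling_correlation(forces, breakage)

    def per_block(frame, fn):
        out = []
        for b in (0, 1):
            blk = frame[frame["block"] == b]
            out.append(fn(blk) if len(blk) else np.nan)
        return out

    fc_blocks = per_block(fam, lambda d: d["correct"].astype(int).mean())
    rho_blocks = per_block(
        pull,
        lambda d: pulling_correlation(
            d["pull_force_N"].to_numpy(float), d["breakage_force_N"].to_numpy(float)
        )[0],
    )

    train = sub[(sub["phase"] == PHASE_TRAINING) & (sub["trial_mode"] == CLAMP_CATCH)]
    if len(train):
        excluded, reason = apply_exclusion(
            train["pull_force_N"].to_numpy(float),
            train["breakage_force_N"].to_numpy(float),
        )
    else:
        excluded, reason = False, ""

    return ParticipantPerformance(
        participant_id=participant_id,
        f_c=f_c,
        T_c=tc,
        T=t,
        rho=rho,
        rho_defined=defined,
        f_c_block1=fc_blocks[0],
        f_c_block2=fc_blocks[1],
        rho_block1=rho_blocks[0],
        rho_block2=rho_blocks[1],
        excluded=excluded,
        exclusion_reason=reason,
        clipped_fraction=float(np.mean(forces >= force_cap)),
    )


def performance_table(log: pd.DataFrame, force_cap: float = 40.0) -> pd.DataFrame:
    """Per-participant summary table for a whole trial log."""
    rows = []
    for pid in sorted(log["participant_id"].unique()):
        perf = participant_performance(log, pid, force_cap)
        rows.append(vars(perf))
    df = pd.DataFrame(rows)
    df["experiment"] = log["experiment"].iloc[0]
    return df
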
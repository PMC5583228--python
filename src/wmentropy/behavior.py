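"""Behavioral scoring and session-change analysis.

The Signed Residual Time (SRT) score rewards fast correct responses and
penalizes fast errors: each trial contributes ``(2*accuracy - 1) * (mt - rt)``
where ``mt`` is the maximum allowed response time, and a subject/session
score is the sum over trials.  Timed-out or omitted responses score as
incorrect with ``rt = mt`` and hence contribute zero.

Subjects are split into high/low performers by the z-score of SRT within a
session (sample standard deviation, n-1); ``z > 0`` strictly is "high".

Training-induced change between sessions uses the symmetric percent Change
Rate ``CR = 2 (T_after - T_before) / (T_after + T_before) * 100`` so that
scores on different unit scales (SRT vs entropy) are comparable; a subject
is *consistent* when the SRT and entropy change rates share a sign.

Hand and load effects on per-cell behavior are tested with a 2x3
repeated-measures ANOVA, Greenhouse-Geisser corrected when Mauchly's test
rejects sphericity of the three-level load factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    PairingError,
    UndefinedChangeError,
)

_BEHAVIOR_COLS = ("subject", "session", "trial", "load", "hand", "accuracy", "rt", "mt")


def srt_score(trials: pd.DataFrame) -> float:
    """SRT score of one subject/session's trials: sum of (2*acc - 1)(mt - rt).

    ``trials`` needs columns ``accuracy, rt, mt``.  Missing rt (NaN) marks a
    non-response, scored as incorrect with rt = mt (zero contribution).
    """
    if len(trials) == 0:
        raise EmptyInputError("srt_score: empty trial list")
    acc = trials["accuracy"].to_numpy(dtype=float)
    rt = trials["rt"].to_numpy(dtype=float)
    mt = trials["mt"].to_numpy(dtype=float)
    missing = ~np.isfinite(rt)
    rt = np.where(missing, mt, rt)
    acc = np.where(missing, 0.0, acc)
    return float(((2.0 * acc - 1.0) * (mt - rt)).sum())


def score_table(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per subject/session SRT totals: columns ``subject, session, srt``."""
    rows = [
        {"subject": sub, "session": ses, "srt": srt_score(g)}
        for (sub, ses), g in behavior.groupby(["subject", "session"], sort=True)
    ]
    return pd.DataFrame(rows)


def zscore_group(scores: pd.DataFrame) -> pd.DataFrame:
    """Add ``z`` and ``group`` columns to one session's score table.

    z uses the sample (n-1) standard deviation; group is "high" iff z > 0
    strictly, else "low".
    """
    if len(scores) < 2:
        raise DegenerateInputError("zscore_group needs >= 2 subjects")
    x = scores["srt"].to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zscore_group: zero SRT variance in session")
    out = scores.copy()
    out["z"] = (x - x.mean()) / sd
    out["group"] = np.where(out["z"] > 0, "high", "low")
    return out


def score_and_group(behavior: pd.DataFrame) -> pd.DataFrame:
    """Score all trials and z-score/group within each session."""
    scores = score_table(behavior)
    return (
        scores.groupby("session", group_keys=False, sort=True)[scores.columns]
        .apply(zscore_group)
        .reset_index(drop=True)
    )


def cell_scores(behavior: pd.DataFrame) -> pd.DataFrame:
    """Per subject x hand x load mean trial score, for the 2x3 RM-ANOVA.

    The cell value is the *mean* per-trial signed residual time (not the
    sum), so random imbalance in how many trials fall in each cell does not
    masquerade as a condition effect.
    """
    df = behavior.copy()
    rt = df["rt"].to_numpy(dtype=float)
    missing = ~np.isfinite(rt)
    rt = np.where(missing, df["mt"], rt)
    acc = np.where(missing, 0.0, df["accuracy"])
    df["trial_score"] = (2.0 * acc - 1.0) * (df["mt"] - rt)
    return (
        df.groupby(["subject", "session", "hand", "load"], sort=True)["trial_score"]
        .mean()
        .rename("value")
        .reset_index()
    )


def rm_anova_2x3(cells: pd.DataFrame, alpha_sphericity: float = 0.05) -> pd.DataFrame:
    """2 (hand) x 3 (load) repeated-measures ANOVA on per-cell values.

    ``cells`` needs columns ``subject, hand, load, value`` with every subject
    contributing all six cells.  Returns one row per effect (hand, load,
    hand*load) with F, integer degrees of freedom, Greenhouse-Geisser
    epsilon, the p-value (GG-corrected for load and the interaction when
    Mauchly's test on the load factor rejects sphericity), and partial eta
    squared.
    """
    import pingouin as pg

    need = {"subject", "hand", "load", "value"}
    if not need.issubset(cells.columns):
        raise EmptyInputError(f"rm_anova_2x3 needs columns {sorted(need)}")
    counts = cells.groupby("subject").size()
    n_cells = cells["hand"].nunique() * cells["load"].nunique()
    if (counts != n_cells).any() or len(cells) != counts.sum():
        bad = counts[counts != n_cells].index.tolist()
        raise PairingError(f"incomplete design: subjects {bad} missing cells")

    import warnings

    with warnings.catch_warnings():
        # 0/0 F ratios in fully degenerate designs are handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(
            data=cells,
            dv="value",
            within=["hand", "load"],
            subject="subject",
            detailed=True,
            effsize="np2",
        )
    # Mauchly's test on the 3-level factor (collapsed across hand)
    collapsed = (
        cells.groupby(["subject", "load"], sort=True)["value"].mean().reset_index()
    )
    try:
        spher = pg.sphericity(collapsed, dv="value", within="load", subject="subject")
        use_gg = (not bool(spher.spher)) and (spher.pval < alpha_sphericity)
    except Exception:  # degenerate (e.g. zero-variance) designs are spherical
        use_gg = False

    rows = []
    for _, r in aov.iterrows():
        effect = r["Source"].replace(" * ", "x")
        multi_level = effect != "hand"
        eps = float(r["eps"]) if multi_level else 1.0
        F = float(r["F"])
        p = float(r["p_GG_corr"]) if (multi_level and use_gg) else float(r["p_unc"])
        np2 = float(r["np2"])
        if not np.isfinite(F) and float(r["SS"]) < 1e-12:
            # zero effect and zero error: no evidence of an effect
            F, p, np2, eps = 0.0, 1.0, 0.0, 1.0
        rows.append(
            {
                "effect": effect,
                "F": F,
                "df_num": int(r["ddof1"]),
                "df_den": int(r["ddof2"]),
                "gg_epsilon": eps,
                "p": p,
                "partial_eta_sq": np2,
            }
        )
    return pd.DataFrame(rows)


def change_rate(t_before: float, t_after: float) -> float:
    """Symmetric percent change 2(TA - TB)/(TA + TB) * 100."""
    denom = t_before + t_after
    if denom == 0:
        raise UndefinedChangeError(
            f"change rate undefined: scores {t_before} and {t_after} sum to zero"
        )
    return 2.0 * (t_after - t_before) / denom * 100.0


@dataclass
class ChangeReport:
    """Per-subject session-1 -> session-2 change rates and their agreement.

    ``table`` columns: subject, cr_srt, cr_sen, consistent.  A change-rate
    pair is consistent iff the product is strictly positive; an exact zero
    counts as inconsistent and is flagged in ``zero_flagged``.
    """

    table: pd.DataFrame
    counts: dict
    channel: str
    zero_flagged: list


def consistency_report(
    scores: pd.DataFrame, features: pd.DataFrame, channel: str
) -> ChangeReport:
    """Compare SRT and entropy change rates subject by subject.

    ``scores`` needs ``subject, session, srt`` for both sessions;
    ``features`` needs ``subject, session, channel, sen``.
    """
    sen = features[features["channel"] == channel]
    if sen.empty:
        raise PairingError(f"no entropy features for channel '{channel}'")
    rows, zero_flagged = [], []
    subjects = sorted(scores["subject"].unique())
    for sub in subjects:
        rec = {}
        for name, frame, col in (("srt", scores, "srt"), ("sen", sen, "sen")):
            pair = frame[frame["subject"] == sub]
            before = pair[pair["session"] == 1][col]
            after = pair[pair["session"] == 2][col]
            if len(before) != 1 or len(after) != 1:
                raise PairingError(
                    f"subject {sub} missing a session in the {name} table"
                )
            rec[f"cr_{name}"] = change_rate(float(before.iloc[0]), float(after.iloc[0]))
        consistent = rec["cr_srt"] * rec["cr_sen"] > 0
        if rec["cr_srt"] == 0 or rec["cr_sen"] == 0:
            zero_flagged.append(sub)
        rows.append({"subject": sub, **rec, "consistent": bool(consistent)})
    table = pd.DataFrame(rows)
    counts = {
        "increased": int((table["cr_srt"] > 0).sum()),
        "decreased": int((table["cr_srt"] < 0).sum()),
        "consistent": int(table["consistent"].sum()),
        "inconsistent": int((~table["consistent"]).sum()),
    }
    return ChangeReport(
        table=table, counts=counts, channel=channel, zero_flagged=zero_flagged
    )
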
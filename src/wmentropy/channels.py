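"""Channel fingerprints: entropy-behavior correlation maps and channel selection.

Each channel's spectral entropy is rank-correlated (Spearman) with the SRT
scores across subjects — within session 1, session 2, or the merged two
sessions (each subject-session pair one observation).  P-values are
Benjamini-Hochberg adjusted across channels and the best channel is the one
with the largest absolute coefficient.

Selecting the best channel once on the whole cohort and then evaluating a
classifier on that channel is optimistically biased (the selection sees all
subjects); the optional ``nested`` mode of downstream evaluation re-selects
within each training fold.  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PairingError, UndefinedCorrelationError

SCOPES = ("session1", "session2", "merged")


def spearman_r(x, y) -> tuple:
    """Spearman rank correlation and two-sided p (t approximation).

    Tie-free data reproduces the classical 1 - 6*sum(d^2)/(m(m^2-1))
    shortcut exactly; ties use mid-ranks (rank-based product-moment).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedCorrelationError("spearman_r needs two equal-length vectors")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the arguments")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values, alpha: float = 0.05) -> tuple:
    """Benjamini-Hochberg step-up: returns (q_values, reject_flags)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise UndefinedCorrelationError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class CorrelationMap:
    """Per-channel Spearman fingerprint for one scope.

    ``table`` columns: channel, r, p, q; ``best_channel`` attains the
    maximum |r| (ties broken by lexicographically smallest label).
    """

    table: pd.DataFrame
    scope: str
    best_channel: str
    alpha: float = 0.05


def _scope_frames(features: pd.DataFrame, scores: pd.DataFrame, scope: str):
    if scope not in SCOPES:
        raise PairingError(f"scope must be one of {SCOPES}, got '{scope}'")
    if scope == "merged":
        return features, scores
    ses = int(scope[-1])
    return features[features["session"] == ses], scores[scores["session"] == ses]


def fingerprint(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    scope: str = "merged",
    alpha: float = 0.05,
) -> CorrelationMap:
    """Correlate each channel's entropy with SRT across subjects.

    ``features``: ``subject, session, channel, sen``; ``scores``:
    ``subject, session, srt``.  In merged scope each subject-session pair is
    one observation.
    """
    feats, scs = _scope_frames(features, scores, scope)
    key = ["subject", "session"]
    merged = feats.merge(scs[key + ["srt"]], on=key, how="left", validate="m:1")
    if merged["srt"].isna().any():
        offenders = (
            merged.loc[merged["srt"].isna(), key].drop_duplicates().to_dict("records")
        )
        raise PairingError(f"subject/session pairs missing SRT scores: {offenders}")
    n_per_channel = merged.groupby("channel").size()
    if scs[key].drop_duplicates().shape[0] != n_per_channel.iloc[0]:
        extra = (
            scs[key]
            .drop_duplicates()
            .merge(feats[key].drop_duplicates(), on=key, how="left", indicator=True)
        )
        offenders = extra[extra["_merge"] == "left_only"][key].to_dict("records")
        if offenders:
            raise PairingError(f"scored subjects without features: {offenders}")

    rows = []
    for ch, g in merged.groupby("channel", sort=True):
        r, p = spearman_r(g["sen"].to_numpy(), g["srt"].to_numpy())
        rows.append({"channel": ch, "r": r, "p": p})
    table = pd.DataFrame(rows)
    q, _ = fdr_bh(table["p"].to_numpy(), alpha=alpha)
    table["q"] = q
    best_abs = table["r"].abs().max()
    candidates = sorted(table.loc[table["r"].abs() == best_abs, "channel"])
    if len(candidates) > 1:
        warnings.warn(
            f"best-channel tie among {candidates}; taking '{candidates[0]}'"
        )
    return CorrelationMap(
        table=table, scope=scope, best_channel=candidates[0], alpha=alpha
    )


def topomap(cmap: CorrelationMap, path: str, grid: int = 128) -> str:
    """Render the correlation map as an interpolated scalp image (PNG).

    Channel positions come from the standard 10-05 montage; unknown labels
    are skipped with a warning.  Rendering is deterministic for fixed
    inputs, so regenerating with the same map yields an identical file.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.interpolate import griddata

    from .montage import layout_positions

    labels = list(cmap.table["channel"])
    pos = layout_positions(labels)
    missing = [ch for ch in labels if ch not in pos]
    for ch in missing:
        warnings.warn(f"channel '{ch}' not in the bundled layout; skipped")
    used = [ch for ch in labels if ch in pos]
    if not used:
        raise PairingError("no channel labels resolvable to scalp positions")
    xy = np.array([pos[ch] for ch in used])
    vals = cmap.table.set_index("channel").loc[used, "r"].to_numpy()

    lim = np.abs(xy).max() * 1.15
    xs = np.linspace(-lim, lim, grid)
    xx, yy = np.meshgrid(xs, xs)
    if len(used) >= 4:
        field = griddata(xy, vals, (xx, yy), method="cubic")
        field = np.where(
            np.isnan(field), griddata(xy, vals, (xx, yy), method="nearest"), field
        )
    else:
        field = griddata(xy, vals, (xx, yy), method="nearest")
    field[np.hypot(xx, yy) > lim] = np.nan

    fig, ax = plt.subplots(figsize=(5, 5))
    vmax = max(np.abs(vals).max(), 1e-12)
    im = ax.imshow(
        field,
        extent=(-lim, lim, -lim, lim),
        origin="lower",
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
    )
    ax.scatter(xy[:, 0], xy[:, 1], s=8, c="k", zorder=3)
    ax.add_patch(plt.Circle((0, 0), lim, fill=False, lw=1.5))
    ax.set_axis_off()
    ax.set_title(f"Spearman r (entropy vs SRT), {cmap.scope}")
    fig.colorbar(im, ax=ax, shrink=0.8, label="r")
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
    return path
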
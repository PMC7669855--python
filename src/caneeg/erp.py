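"""Conventional sensor-level analysis of evoked responses.

Per-condition evoked averages, the sliding-window species x expression
repeated-measures ANOVA (16-ms windows stepping by 4 ms over 0–250 ms), the
rule that only runs of at least two contiguous significant windows are
reported, and planned paired-sample contrasts.

The ANOVA is a two-way within-subject (2 species x 3 expressions) design on
per-subject window-mean amplitudes, one test per channel and window. The
sums of squares are computed in closed form and vectorized over channels,
windows and simulated replicates, so null-calibration studies run at scale;
the same arithmetic is cross-checked against a general-purpose
repeated-measures ANOVA implementation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EpochsSet
from .labels import FACE_CATEGORIES, CategoryLabel, as_label

#: Condition column order used in tabular outputs.
CONDITION_ORDER = ("HH", "NH", "AH", "HD", "ND", "AD")


@dataclass
class EvokedResponse:
    """Trial-averaged waveform for one condition (or pooled set)."""

    data: np.ndarray  # (n_channels, n_samples), uV
    times: np.ndarray  # ms
    channels: list
    condition: str
    subject: str
    n_trials: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.shape != (len(self.channels), self.times.size):
            raise ValueError("evoked data shape must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("evoked data contains non-finite values")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


class EmptyConditionError(ValueError):
    """No kept trials available for a requested condition."""


def average_evoked(epochs: EpochsSet, condition) -> EvokedResponse:
    """Arithmetic mean over the kept trials of one condition.

    ``condition`` may be a single category or an iterable of categories
    (pooled). Raises :class:`EmptyConditionError` when no kept trial matches.
    """
    mask = epochs.trial_mask(condition, kept_only=True)
    n = int(mask.sum())
    if n == 0:
        raise EmptyConditionError(
            f"subject {epochs.subject}: no kept trials for condition {condition}"
        )
    if isinstance(condition, (str, CategoryLabel)):
        cond_name = as_label(condition).value
    else:
        cond_name = "+".join(as_label(c).value for c in condition)
    return EvokedResponse(
        data=epochs.data[mask].mean(axis=0),
        times=epochs.times.copy(),
        channels=list(epochs.channels),
        condition=cond_name,
        subject=epochs.subject,
        n_trials=n,
    )


def grand_average(evokeds: list) -> EvokedResponse:
    """Unweighted mean over subjects' evoked responses."""
    if not evokeds:
        raise ValueError("grand_average requires at least one evoked response")
    first = evokeds[0]
    for ev in evokeds[1:]:
        if ev.data.shape != first.data.shape or not np.allclose(ev.times, first.times):
            raise ValueError("evoked responses are not on a common grid")
    return EvokedResponse(
        data=np.mean([ev.data for ev in evokeds], axis=0),
        times=first.times.copy(),
        channels=list(first.channels),
        condition=first.condition,
        subject="grand",
        n_trials=sum(ev.n_trials for ev in evokeds),
    )


# --------------------------------------------------------------------------
# Two-way repeated-measures ANOVA, vectorized over arbitrary leading axes
# --------------------------------------------------------------------------

def rm_anova_2way(Y: np.ndarray, gg_correction: bool = False) -> dict:
    """Within-subject 2-factor ANOVA on cell scores ``Y[..., subject, a, b]``.

    Factor A (species) has the second-to-last axis, factor B (expression)
    the last. Error terms are the factor-by-subject interactions, the
    standard fully-within partition. Returns per-effect ``F`` and ``p``
    arrays over the leading axes plus degrees of freedom; with
    ``gg_correction`` the Greenhouse–Geisser epsilon (estimated from the
    subject-level covariance of the effect contrasts) deflates both df.
    """
    Y = np.asarray(Y, dtype=np.float64)
    n_sub, A, B = Y.shape[-3:]
    if n_sub < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 subjects")

    m = Y.mean(axis=(-3, -2, -1), keepdims=True)
    m_s = Y.mean(axis=(-2, -1), keepdims=True)
    m_a = Y.mean(axis=(-3, -1), keepdims=True)
    m_b = Y.mean(axis=(-3, -2), keepdims=True)
    m_ab = Y.mean(axis=-3, keepdims=True)
    m_sa = Y.mean(axis=-1, keepdims=True)
    m_sb = Y.mean(axis=-2, keepdims=True)

    ss_a = n_sub * B * np.sum((m_a - m) ** 2, axis=(-3, -2, -1))
    ss_as = B * np.sum((m_sa - m_s - m_a + m) ** 2, axis=(-3, -2, -1))
    ss_b = n_sub * A * np.sum((m_b - m) ** 2, axis=(-3, -2, -1))
    ss_bs = A * np.sum((m_sb - m_s - m_b + m) ** 2, axis=(-3, -2, -1))
    ss_ab = n_sub * np.sum((m_ab - m_a - m_b + m) ** 2, axis=(-3, -2, -1))
    ss_abs = np.sum(
        (Y - m_ab - m_sa - m_sb + m_a + m_b + m_s - m) ** 2, axis=(-3, -2, -1)
    )

    out = {}
    for name, ss_eff, ss_err, df1 in (
        ("species", ss_a, ss_as, A - 1),
        ("expression", ss_b, ss_bs, B - 1),
        ("interaction", ss_ab, ss_abs, (A - 1) * (B - 1)),
    ):
        df2 = df1 * (n_sub - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_eff / df1) / (ss_err / df2)
        eps = np.ones_like(F)
        if gg_correction and df1 > 1:
            eps = _gg_epsilon(Y, name, A, B)
        p = stats.f.sf(F, df1 * eps, df2 * eps)
        out[name] = {"F": F, "p": p, "df1": df1, "df2": df2, "epsilon": eps}
    return out


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrasts spanning the mean-free subspace."""
    q, _ = np.linalg.qr(np.eye(k) - 1.0 / k)
    return q.T[: k - 1]


def _gg_epsilon(Y: np.ndarray, effect: str, A: int, B: int) -> np.ndarray:
    """Greenhouse–Geisser epsilon for one within effect, vectorized."""
    if effect == "species":
        scores, C = Y.mean(axis=-1), _orthonormal_contrasts(A)
    elif effect == "expression":
        scores, C = Y.mean(axis=-2), _orthonormal_contrasts(B)
    else:
        scores = Y.reshape(Y.shape[:-2] + (A * B,))
        C = np.kron(_orthonormal_contrasts(A), _orthonormal_contrasts(B))
    z = np.einsum("...sk,ck->...sc", scores, C)  # contrast scores per subject
    zc = z - z.mean(axis=-2, keepdims=True)
    n_sub = z.shape[-2]
    S = np.einsum("...sc,...sd->...cd", zc, zc) / (n_sub - 1)
    tr = np.trace(S, axis1=-2, axis2=-1)
    tr2 = np.einsum("...cd,...dc->...", S, S)
    d = C.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = tr**2 / (d * tr2)
    return np.clip(np.nan_to_num(eps, nan=1.0), 1.0 / d, 1.0)


# --------------------------------------------------------------------------
# Sliding-window analysis
# --------------------------------------------------------------------------

def enumerate_windows(
    range_ms: tuple = (0.0, 250.0), window_ms: float = 16.0, step_ms: float = 4.0
) -> np.ndarray:
    """Start times of the sliding windows: ``start + window <= range_end``.

    The default grid (16-ms windows, 4-ms steps, 0–250 ms) gives 59 windows.
    """
    t0, t1 = range_ms
    starts = np.arange(t0, t1 - window_ms + 1e-9, step_ms)
    return starts


def window_means(
    evoked_stack: np.ndarray, times_ms: np.ndarray, starts: np.ndarray,
    window_ms: float,
) -> np.ndarray:
    """Mean amplitude in each half-open window; appends a window axis."""
    out = np.empty(evoked_stack.shape[:-1] + (starts.size,))
    for w, s in enumerate(starts):
        mask = (times_ms >= s) & (times_ms < s + window_ms)
        if not mask.any():
            raise ValueError(f"window starting at {s} ms contains no samples")
        out[..., w] = evoked_stack[..., mask].mean(axis=-1)
    return out


def sliding_window_anova(
    evokeds_by_subject: list,
    range_ms: tuple = (0.0, 250.0),
    window_ms: float = 16.0,
    step_ms: float = 4.0,
    gg_correction: bool = False,
) -> pd.DataFrame:
    """Species x expression ANOVA per channel and sliding window.

    Parameters
    ----------
    evokeds_by_subject
        One ``{category: EvokedResponse}`` mapping per subject, each
        containing all six face conditions.

    Returns
    -------
    DataFrame with one row per channel x window: window bounds, p- and
    F-values for the species and expression main effects and their
    interaction, and the per-condition window-mean amplitudes (uV).
    """
    for i, subj in enumerate(evokeds_by_subject):
        for cat in FACE_CATEGORIES:
            if as_label(cat) not in {as_label(c) for c in subj}:
                name = next(iter(subj.values())).subject if subj else f"#{i}"
                raise ValueError(f"subject {name}: missing condition {cat.value}")
    first = next(iter(evokeds_by_subject[0].values()))
    times, channels = first.times, first.channels
    starts = enumerate_windows(range_ms, window_ms, step_ms)

    # cells ordered (species: dog, human) x (expression: happy, neutral, aggr)
    species_order = ("dog", "human")
    expr_order = ("happy", "neutral", "aggressive")
    cell_cats = [
        next(c for c in FACE_CATEGORIES if c.species == sp and c.expression == ex)
        for sp in species_order
        for ex in expr_order
    ]
    # Y: (n_sub, 2, 3, n_ch, n_samples)
    Y = np.stack(
        [
            np.stack(
                [subj[_find(subj, cat)].data for cat in cell_cats]
            ).reshape(2, 3, len(channels), times.size)
            for subj in evokeds_by_subject
        ]
    )
    Wm = window_means(Y, times, starts, window_ms)  # (n_sub, 2, 3, n_ch, n_win)
    # -> (n_ch, n_win, n_sub, 2, 3)
    cells = np.moveaxis(Wm, (0, 1, 2), (2, 3, 4))
    res = rm_anova_2way(cells, gg_correction=gg_correction)

    n_ch, n_win = len(channels), starts.size
    rows = {
        "channel": np.repeat(channels, n_win),
        "win_start_ms": np.tile(starts, n_ch),
        "win_end_ms": np.tile(starts + window_ms, n_ch),
    }
    for eff in ("species", "expression", "interaction"):
        rows[f"F_{eff}"] = res[eff]["F"].ravel()
        rows[f"p_{eff}"] = res[eff]["p"].ravel()
    cond_means = Wm.mean(axis=0)  # (2, 3, n_ch, n_win) over subjects
    for code in CONDITION_ORDER:
        cat = as_label(code)
        i = species_order.index(cat.species)
        j = expr_order.index(cat.expression)
        rows[f"mean_{code}"] = cond_means[i, j].ravel()
    return pd.DataFrame(rows)


def _find(subj_map: dict, cat: CategoryLabel):
    for key in subj_map:
        if as_label(key) == cat:
            return key
    raise KeyError(cat)


def contiguity_filter(
    stats_df: pd.DataFrame,
    alpha: float = 0.05,
    min_run: int = 2,
    effects: tuple = ("species", "expression", "interaction"),
) -> pd.DataFrame:
    """Merge runs of >= ``min_run`` step-adjacent significant windows.

    Per channel and effect, maximal runs of consecutive windows with
    ``p < alpha`` are merged to ``[first start, last end)`` intervals;
    isolated significant windows are dropped. Output rows carry the p-value
    range over the run and the run-averaged per-condition amplitudes.
    """
    mean_cols = [c for c in stats_df.columns if c.startswith("mean_")]
    records = []
    for effect in effects:
        pcol = f"p_{effect}"
        if pcol not in stats_df.columns:
            continue
        for channel, grp in stats_df.groupby("channel", sort=False):
            grp = grp.sort_values("win_start_ms").reset_index(drop=True)
            starts_arr = grp["win_start_ms"].to_numpy()
            step = np.diff(starts_arr).min() if len(grp) > 1 else 0.0
            sig_idx = np.flatnonzero((grp[pcol] < alpha).to_numpy())
            runs, cur = [], []
            for j in sig_idx:
                step_adjacent = cur and np.isclose(
                    starts_arr[j], starts_arr[cur[-1]] + step
                )
                if step_adjacent:
                    cur.append(j)
                else:
                    if cur:
                        runs.append(cur)
                    cur = [j]
            if cur:
                runs.append(cur)
            for run_idx in runs:
                if len(run_idx) < min_run:
                    continue
                run = grp.iloc[run_idx]
                rec = {
                    "effect": effect,
                    "channel": channel,
                    "start_ms": run["win_start_ms"].iloc[0],
                    "end_ms": run["win_end_ms"].iloc[-1],
                    "n_windows": len(run),
                    "p_min": run[pcol].min(),
                    "p_max": run[pcol].max(),
                }
                for mc in mean_cols:
                    rec[mc] = run[mc].mean()
                records.append(rec)
    cols = ["effect", "channel", "start_ms", "end_ms", "n_windows",
            "p_min", "p_max", *mean_cols]
    out = pd.DataFrame.from_records(records, columns=cols)
    return out.sort_values(["effect", "channel", "start_ms"]).reset_index(drop=True)


def planned_contrast(a: np.ndarray, b: np.ndarray) -> tuple:
    """Two-sided paired-samples t test on per-subject values.

    Returns ``(t, p)`` on ``n - 1`` degrees of freedom. Degenerate zero
    variance is resolved by the sign of the mean difference: all-zero
    differences give ``t = 0, p = 1``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 subjects")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p)


def sliding_contrast(
    evokeds_a: list,
    evokeds_b: list,
    range_ms: tuple = (0.0, 250.0),
    window_ms: float = 16.0,
    step_ms: float = 4.0,
) -> pd.DataFrame:
    """Planned paired contrast (e.g. faces vs. objects) per channel/window.

    ``evokeds_a`` / ``evokeds_b`` hold one EvokedResponse per subject for
    the two (possibly pooled) condition sets, subject-aligned.
    """
    if len(evokeds_a) != len(evokeds_b):
        raise ValueError("contrast requires subject-aligned evoked lists")
    first = evokeds_a[0]
    starts = enumerate_windows(range_ms, window_ms, step_ms)
    Ya = np.stack([ev.data for ev in evokeds_a])  # (n_sub, n_ch, n_samp)
    Yb = np.stack([ev.data for ev in evokeds_b])
    Wa = window_means(Ya, first.times, starts, window_ms)
    Wb = window_means(Yb, first.times, starts, window_ms)
    rows = []
    for ci, channel in enumerate(first.channels):
        for wi, s in enumerate(starts):
            t, p = planned_contrast(Wa[:, ci, wi], Wb[:, ci, wi])
            rows.append(
                {
                    "channel": channel,
                    "win_start_ms": s,
                    "win_end_ms": s + window_ms,
                    "t": t,
                    "p": p,
                    "mean_a": Wa[:, ci, wi].mean(),
                    "mean_b": Wb[:, ci, wi].mean(),
                }
            )
    return pd.DataFrame(rows)
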
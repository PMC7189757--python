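"""Reaction-time analysis pipeline.

Exclusions and truncation, exponential detrending of RT-vs-SOA series,
amplitude spectra with permutation thresholds (max-statistic correction),
circular statistics on spectral phases, priming-window effects, block-border
jump tests, and sequential-effect regression.

RT series are per participant and congruency: the mean RT at each SOA of the
20 ms grid.  Spectral analysis runs on the detrended series (sampling
interval 20 ms, Nyquist 25 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin
import statsmodels.api as sm
from scipy import optimize, stats

from .design import SOA_STEP_MS, TaskDesign

DT_S = SOA_STEP_MS / 1000.0

#: priming-effect windows (ms, inclusive): early positive and later negative
PRIMING_WINDOWS = {"positive": (0, 60), "negative": (100, 160)}

PREMATURE_FLOOR_MS = 100.0


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(
    dataset: pd.DataFrame,
    design: TaskDesign,
    truncate_above: float | None = None,
    premature_floor_ms: float = PREMATURE_FLOOR_MS,
    sd_criterion: float = 3.0,
) -> pd.DataFrame:
    """Flag exclusions and optionally truncate long SOAs.

    Excluded are time-outs (no response or RT above the design's limit),
    premature responses (RT below ``premature_floor_ms``), and — per
    participant, on the RTs surviving those two filters — RTs outside
    ``sd_criterion`` standard deviations of the participant's mean.
    Trials with SOA above ``truncate_above`` are dropped.
    """
    out = dataset.copy()
    if truncate_above is not None:
        out = out[out["soa_ms"] <= truncate_above].reset_index(drop=True)
    rt = out["rt_ms"].to_numpy(dtype=float)
    no_resp = out["response"].isna() | (out["response"] == "none")
    timeout = no_resp | ~np.isfinite(rt) | (rt > design.rt_limit)
    premature = np.isfinite(rt) & (rt < premature_floor_ms)
    excluded = timeout | premature
    for pid, idx in out.groupby("participant").groups.items():
        sel = np.asarray(idx)
        ok = sel[~excluded[sel]]
        if ok.size < 2:
            continue
        m, sd = rt[ok].mean(), rt[ok].std(ddof=1)
        if sd > 0:
            outlier = np.abs(rt[ok] - m) > sd_criterion * sd
            excluded[ok[outlier]] = True
    out["excluded"] = np.asarray(excluded)
    return out


def mean_rt_series(dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean RT per participant x congruency x SOA over non-excluded trials."""
    ok = dataset[~dataset["excluded"] & dataset["rt_ms"].notna()]
    return (
        ok.groupby(["participant", "congruency", "soa_ms"])["rt_ms"]
        .mean()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# detrending


@dataclass
class TrendResult:
    soas: np.ndarray
    mean_rt: np.ndarray
    trend: np.ndarray
    detrended: np.ndarray
    params: tuple
    method: str  # "exponential" or "linear" fallback


def slow_trend_exponential(soas, mean_rt) -> TrendResult:
    """Least-squares slow trend RT(s) = a + c * exp(-s / tau_d).

    Initialized at a = min RT, c = range, tau_d = span/3 with tau_d bounded
    to [20 ms, 10 s]; falls back to a linear trend (flagged) if the
    exponential fit does not converge.
    """
    soas = np.asarray(soas, dtype=float)
    y = np.asarray(mean_rt, dtype=float)
    if soas.size < 6:
        raise ValueError("need at least 6 SOA points to fit a slow trend")
    span = max(soas.max() - soas.min(), SOA_STEP_MS)

    def f(s, a, c, tau):
        return a + c * np.exp(-s / tau)

    try:
        p0 = (float(y.min()), float(y.max() - y.min()) or 1.0, span / 3.0)
        popt, _ = optimize.curve_fit(
            f,
            soas,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, 20.0], [np.inf, np.inf, 10_000.0]),
            maxfev=10_000,
        )
        trend = f(soas, *popt)
        return TrendResult(soas, y, trend, y - trend, tuple(popt), "exponential")
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        coef = np.polyfit(soas, y, 1)
        trend = np.polyval(coef, soas)
        return TrendResult(soas, y, trend, y - trend, tuple(coef), "linear")


def detrended_series(
    dataset: pd.DataFrame,
) -> dict[tuple[str, str], TrendResult]:
    """Detrend each participant x congruency mean-RT series.

    Missing SOA cells (all trials excluded) are linearly interpolated onto
    the full 20 ms grid before fitting, so spectra see a complete series.
    """
    series = mean_rt_series(dataset)
    grid = np.arange(
        series["soa_ms"].min(), series["soa_ms"].max() + 1, SOA_STEP_MS, dtype=float
    )
    out = {}
    for (pid, cong), df in series.groupby(["participant", "congruency"]):
        y = np.interp(grid, df["soa_ms"].to_numpy(float), df["rt_ms"].to_numpy(float))
        out[(pid, cong)] = slow_trend_exponential(grid, y)
    return out


# ---------------------------------------------------------------------------
# spectra


def amplitude_spectrum(detrended, dt_s: float = DT_S):
    """Discrete Fourier amplitude and phase of one detrended series.

    Amplitudes are normalized 2|X_k|/N for the positive-frequency bins
    (DC excluded); returns (freqs_hz, amplitude, phase).
    """
    x = np.asarray(detrended, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("series too short for spectral analysis")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=dt_s)
    amp = 2.0 * np.abs(spec) / n
    phase = np.angle(spec)
    keep = slice(1, None) if n % 2 else slice(1, -1)  # drop DC (and Nyquist)
    return freqs[keep], amp[keep], phase[keep]


def group_spectrum(trends: dict, congruency: str):
    """Participant-mean amplitude spectrum for one congruency.

    Returns (freqs, group-mean amplitude, per-participant amplitude matrix,
    per-participant phase matrix).
    """
    amps, phases, freqs = [], [], None
    for (_, cong), tr in sorted(trends.items()):
        if cong != congruency:
            continue
        freqs, a, ph = amplitude_spectrum(tr.detrended)
        amps.append(a)
        phases.append(ph)
    if freqs is None:
        raise ValueError(f"no series with congruency {congruency!r}")
    amps = np.vstack(amps)
    return freqs, amps.mean(axis=0), amps, np.vstack(phases)


@dataclass
class PermutationThresholds:
    freqs: np.ndarray
    uncorrected: np.ndarray  # per-frequency p < .05 threshold
    corrected: float  # max over frequencies


def permutation_thresholds(
    group_detrended: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    dt_s: float = DT_S,
) -> PermutationThresholds:
    """Permutation thresholds for the group-mean amplitude spectrum.

    Each permutation shuffles every participant's detrended series across
    SOAs, recomputes the spectra, and averages across participants; the
    uncorrected threshold is the 95th percentile per frequency and the
    corrected threshold the maximum of those across frequencies.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    data = np.asarray(group_detrended, dtype=float)
    n_sub, n_soa = data.shape
    rng = np.random.default_rng(seed)
    freqs, _, _ = amplitude_spectrum(data[0], dt_s)
    null = np.empty((n_perm, freqs.size))
    for i in range(n_perm):
        shuffled = np.stack([rng.permutation(row) for row in data])
        spec = np.fft.rfft(shuffled, axis=1)
        amp = 2.0 * np.abs(spec) / n_soa
        keep = slice(1, None) if n_soa % 2 else slice(1, -1)
        null[i] = amp[:, keep].mean(axis=0)
    unc = np.percentile(null, 95.0, axis=0)
    return PermutationThresholds(freqs, unc, float(unc.max()))


def phase_difference_3_5(
    series_c, series_ic, dt_s: float = DT_S, band=(3.0, 5.0)
) -> float:
    """Circular-mean C-IC phase difference over bins centred in [3, 5] Hz."""
    f_c, _, ph_c = amplitude_spectrum(series_c, dt_s)
    f_ic, _, ph_ic = amplitude_spectrum(series_ic, dt_s)
    if not np.allclose(f_c, f_ic):
        raise ValueError("series must share a frequency grid")
    sel = (f_c >= band[0]) & (f_c <= band[1])
    if not sel.any():
        raise ValueError("no frequency bins inside the band")
    d = ph_c[sel] - ph_ic[sel]
    return float(np.angle(np.exp(1j * d).mean()))


# ---------------------------------------------------------------------------
# circular statistics


def circular_mean(angles) -> float:
    return float(np.angle(np.exp(1j * np.asarray(angles, float)).mean()))


def rayleigh_test(angles):
    """Rayleigh test of phase coherence: (mean_angle, R_bar, z, p)."""
    a = np.asarray(angles, dtype=float)
    if a.size < 3:
        raise ValueError("Rayleigh test needs at least 3 angles")
    r_bar = float(np.abs(np.exp(1j * a).mean()))
    z, p = pingouin.circ_rayleigh(a)
    return circular_mean(a), r_bar, float(z), float(p)


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood concentration of a von Mises from mean resultant length."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(groups):
    """Watson-Williams circular one-way ANOVA: (F, p).

    Tests equality of mean directions across >= 2 groups of angles, assuming
    comparable concentrations; uses the standard 1 + 3/(8 kappa) correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 3 for g in groups):
        raise ValueError("need >= 2 groups with >= 3 angles each")
    k = len(groups)
    n = sum(g.size for g in groups)
    rs = [g.size * np.abs(np.exp(1j * g).mean()) for g in groups]
    all_angles = np.concatenate(groups)
    r_tot = n * np.abs(np.exp(1j * all_angles).mean())
    rw = sum(rs) / n
    corr = 1.0 + 3.0 / (8.0 * _kappa_from_r(rw))
    num = (n - k) * (sum(rs) - r_tot)
    den = (k - 1) * (n - sum(rs))
    f_stat = corr * num / den
    p = float(stats.f.sf(f_stat, k - 1, n - k))
    return float(f_stat), p


# ---------------------------------------------------------------------------
# priming effects, jumps, sequential effects


def priming_effects(
    dataset: pd.DataFrame, windows: dict = None
) -> pd.DataFrame:
    """Mean IC - C RT difference per participant in each SOA window,
    plus a group one-sample t-test per window.

    Returns a tidy frame (participant, window, effect_ms) with group stats
    in ``.attrs["group"]``.
    """
    windows = windows or PRIMING_WINDOWS
    series = mean_rt_series(dataset)
    rows = []
    for name, (lo, hi) in windows.items():
        win = series[(series["soa_ms"] >= lo) & (series["soa_ms"] <= hi)]
        if win.empty:
            raise ValueError(f"window {name} contains no SOAs")
        per = win.pivot_table(
            index="participant", columns="congruency", values="rt_ms"
        )
        eff = per["IC"] - per["C"]
        rows.extend(
            {"participant": pid, "window": name, "effect_ms": e}
            for pid, e in eff.items()
        )
    out = pd.DataFrame(rows)
    group = {}
    for name in windows:
        e = out.loc[out["window"] == name, "effect_ms"].to_numpy()
        if e.size > 1 and e.std(ddof=1) > 0:
            t, p = stats.ttest_1samp(e, 0.0)
        else:
            t, p = math.nan, math.nan
        group[name] = {"mean_ms": float(e.mean()), "t": float(t), "p": float(p), "n": e.size}
    out.attrs["group"] = group
    return out


def border_pairs(design: TaskDesign) -> list[tuple[int, int]]:
    """(last SOA of block k, first SOA of block k+1) for adjacent SOA blocks,
    taken in ascending SOA order."""
    blocks = sorted(design.soa_blocks, key=min)
    return [
        (max(blocks[i]), min(blocks[i + 1])) for i in range(len(blocks) - 1)
    ]


def jump_tests(
    dataset: pd.DataFrame,
    design: TaskDesign,
    alpha: float = 0.05,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """One-tailed paired t-tests for RT increases across block borders.

    For each border SOA pair (s_last, s_first) and congruency, tests across
    participants whether mean RT at s_first exceeds mean RT at s_last.
    ``pairs`` overrides the design's borders (base-rate variant: the same
    SOA pairs evaluated on an unblocked design).
    """
    pairs = pairs if pairs is not None else border_pairs(design)
    if not pairs:
        raise ValueError("design has no block borders and no pairs were given")
    series = mean_rt_series(dataset)
    rows = []
    for s_last, s_first in pairs:
        for cong in ("C", "IC"):
            sub = series[series["congruency"] == cong]
            a = sub[sub["soa_ms"] == s_last].set_index("participant")["rt_ms"]
            b = sub[sub["soa_ms"] == s_first].set_index("participant")["rt_ms"]
            common = a.index.intersection(b.index)
            if common.size < 3:
                raise ValueError(f"missing SOA cells at border {(s_last, s_first)}")
            diff = (b[common] - a[common]).to_numpy()
            t, p_two = stats.ttest_1samp(diff, 0.0)
            p = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
            rows.append(
                {
                    "soa_last": s_last,
                    "soa_first": s_first,
                    "congruency": cong,
                    "mean_jump_ms": float(diff.mean()),
                    "t": float(t),
                    "p_one_tailed": float(p),
                    "significant": bool(p < alpha),
                }
            )
    return pd.DataFrame(rows)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]]
    (probability-mass rule)."""
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def sequential_regression(dataset: pd.DataFrame, n_lags: int = 3):
    """Regress current RT on the SOAs of the previous ``n_lags`` trials.

    Per participant (session order; the first ``n_lags`` trials are dropped
    as incomplete-lag cases), an OLS of RT_m on SOA_{m-1..m-3}, with the
    previous RTs and the current SOA as nuisance covariates.  Returns a
    coefficient frame and group one-sample t-tests per lagged-SOA
    coefficient in ``.attrs["group"]``.
    """
    rows = []
    for pid, df in dataset.groupby("participant"):
        df = df.sort_values("trial_index")
        rt = df["rt_ms"].to_numpy(dtype=float)
        soa = df["soa_ms"].to_numpy(dtype=float)
        cols = {"soa_current": soa}
        for lag in range(1, n_lags + 1):
            cols[f"soa_lag{lag}"] = np.roll(soa, lag)
            cols[f"rt_lag{lag}"] = np.roll(rt, lag)
        x = pd.DataFrame(cols).iloc[n_lags:]
        y = rt[n_lags:]
        keep = np.isfinite(y) & np.isfinite(x.to_numpy(float)).all(axis=1)
        if keep.sum() < x.shape[1] + 2:
            raise ValueError(f"insufficient trials for participant {pid}")
        model = sm.OLS(y[keep], sm.add_constant(x[keep])).fit()
        row = {"participant": pid}
        row.update({k: float(v) for k, v in model.params.items()})
        rows.append(row)
    out = pd.DataFrame(rows)
    group = {}
    for lag in range(1, n_lags + 1):
        beta = out[f"soa_lag{lag}"].to_numpy()
        t, p = stats.ttest_1samp(beta, 0.0)
        group[f"soa_lag{lag}"] = {
            "mean_beta": float(beta.mean()),
            "t": float(t),
            "p": float(p),
        }
    out.attrs["group"] = group
    return out


# ---------------------------------------------------------------------------
# model-prediction curves


def simulate_and_analyze(
    fit_results,
    design: TaskDesign,
    n_sims: int = 100,
    seed: int = 0,
    model: str | None = None,
):
    """Group-level model-prediction RT curves.

    For each participant's fit, simulates ``n_sims`` datasets, averages the
    per-SOA mean RT within participant, then across participants.  Returns a
    frame indexed by (congruency, soa_ms).
    """
    from .accumulate import simulate_dataset
    from .fitting import fitted_params

    rng = np.random.default_rng(seed)
    per_participant = []
    for res in fit_results:
        params = fitted_params(res, condition=design.name)
        mdl = model or res.model
        sims = []
        for _ in range(n_sims):
            ds = simulate_dataset(
                design, params, mdl, int(rng.integers(2**31)), res.participant
            )
            sims.append(
                ds.groupby(["congruency", "soa_ms"])["rt_ms"].mean()
            )
        per_participant.append(pd.concat(sims, axis=1).mean(axis=1))
    group = pd.concat(per_participant, axis=1).mean(axis=1)
    return group.rename("rt_ms").reset_index()
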
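"""Doubling-time estimation and additivity testing for growth curves.

The doubling time of an exponentially growing culture is 1/slope of
log2(OD) regressed on time during the log phase. Because plate-reader
curves include a lag and a stationary plateau, the log phase is located by
a sliding window (default 90 min): among windows whose linear fit reaches
an R^2 floor (default 0.98), the one with the maximal slope is taken —
lag and plateau segments either fail the floor or have smaller slopes.

Stimulus effects are changes in doubling time relative to an unstimulated
control. Additivity of concurrent stimuli is tested by comparing the
observed concurrent effect to the sum of the single-stimulus effects with a
two-sample Welch t-test (combined standard error = root sum of squared
component SEs), Bonferroni-corrected for the experiment's number of
comparisons. The expected-sum and the concurrent effect both reference the
same control; their correlation through the shared control mean is ignored
(a conservative independence approximation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, NoLogPhaseError
from .io import GrowthCurve


@dataclass
class DoublingTimeResult:
    condition_label: str
    doubling_time: float  # minutes; inf for non-growing cultures
    slope: float  # per-minute log2 slope
    window: tuple[float, float]
    r_squared: float
    n_points: int
    non_growing: bool = False


@dataclass
class GrowthEffect:
    """Change in doubling time vs control for one stimulus (minutes)."""

    stimulus_label: str
    effect: float
    se: float  # standard error of the mean difference
    sd: float  # replicate SD of the condition's doubling times
    n: int  # condition replicate count


def _window_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R^2 (R^2 = 1 for a zero-residual fit)."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot <= 1e-30:
        r2 = 1.0  # flat, noiseless window: the fit is exact
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def estimate_doubling_time(
    curve: GrowthCurve,
    *,
    window_minutes: float = 90.0,
    min_points: int = 10,
    r2_floor: float = 0.98,
) -> DoublingTimeResult:
    """Estimate the doubling time from the steepest log-linear window.

    Raises :class:`NoLogPhaseError` when no window of ``window_minutes``
    with >= ``min_points`` observations fits log2(OD) linearly with
    R^2 >= ``r2_floor``. A best window with non-positive slope yields a
    non-growing result (infinite doubling time) rather than an error.
    """
    t = curve.times
    y = np.log2(curve.od)
    if t.size < min_points:
        raise NoLogPhaseError(
            f"curve has {t.size} points; needs >= {min_points}"
        )
    span = float(t[-1] - t[0])
    window_minutes = min(window_minutes, span)  # short curves: whole curve
    best: tuple[float, tuple[float, float], float, int] | None = None
    for start_idx in range(t.size):
        t0 = t[start_idx]
        if t0 + window_minutes > t[-1] + 1e-9:
            break  # only full-length windows; tail stubs are unstable
        end_idx = int(np.searchsorted(t, t0 + window_minutes, side="right"))
        if end_idx - start_idx < min_points:
            continue
        tw, yw = t[start_idx:end_idx], y[start_idx:end_idx]
        slope, _, r2 = _window_fit(tw, yw)
        if r2 >= r2_floor and (best is None or slope > best[0]):
            best = (slope, (float(tw[0]), float(tw[-1])), r2, tw.size)
    if best is None:
        raise NoLogPhaseError(
            f"no {window_minutes:g}-min window reaches R^2 >= {r2_floor}"
        )
    slope, window, r2, n_pts = best
    if slope <= 1e-9:  # flat within numerical noise, or declining
        return DoublingTimeResult(
            condition_label=curve.condition_label,
            doubling_time=float("inf"),
            slope=slope,
            window=window,
            r_squared=r2,
            n_points=n_pts,
            non_growing=True,
        )
    return DoublingTimeResult(
        condition_label=curve.condition_label,
        doubling_time=1.0 / slope,
        slope=slope,
        window=window,
        r_squared=r2,
        n_points=n_pts,
    )


def stimulus_effects(
    doubling_times: dict[str, np.ndarray] | pd.DataFrame,
    control_label: str,
) -> list[GrowthEffect]:
    """Per-condition change in mean doubling time relative to the control.

    ``doubling_times`` maps condition labels to arrays of replicate doubling
    times (minutes). The standard error of each effect is the
    difference-of-means SE, sqrt(sd_c^2/n_c + sd_0^2/n_0); the replicate-
    scale spread of the condition is reported separately as ``sd``.
    """
    if isinstance(doubling_times, pd.DataFrame):
        doubling_times = {
            label: grp["doubling_time"].to_numpy(float)
            for label, grp in doubling_times.groupby("condition")
        }
    if control_label not in doubling_times:
        raise ConfigError(f"control condition {control_label!r} missing")
    ctrl = np.asarray(doubling_times[control_label], float)
    if ctrl.size < 2:
        raise ConfigError("control needs >= 2 replicates")
    ctrl_var = ctrl.var(ddof=1)
    effects = []
    for label, taus in doubling_times.items():
        if label == control_label:
            continue
        taus = np.asarray(taus, float)
        if taus.size < 2:
            raise ConfigError(f"condition {label!r} needs >= 2 replicates")
        se = float(np.sqrt(taus.var(ddof=1) / taus.size + ctrl_var / ctrl.size))
        effects.append(
            GrowthEffect(
                stimulus_label=label,
                effect=float(taus.mean() - ctrl.mean()),
                se=se,
                sd=float(taus.std(ddof=1)),
                n=int(taus.size),
            )
        )
    return effects


@dataclass
class AdditivityTestResult:
    expected_effect: float
    expected_se: float
    observed_effect: float
    observed_se: float
    t_stat: float
    df: float
    p: float
    p_adjusted: float
    additive: bool  # not rejected at 0.05 after correction


def additivity_test(
    single_effects: list[GrowthEffect],
    concurrent_effect: GrowthEffect,
    n_comparisons: int = 11,
) -> AdditivityTestResult:
    """Test whether concurrent stimulus effects are additive.

    The expected concurrent effect is the sum of the single-stimulus
    effects with combined SE sqrt(sum se_i^2); the observed concurrent
    effect is compared to it by a Welch t-test (Satterthwaite df from the
    component replicate counts), and p is Bonferroni-scaled by
    ``n_comparisons`` (capped at 1). Supports any number of single stimuli
    (k-stimulus designs).
    """
    if len(single_effects) < 2:
        raise ConfigError("need >= 2 single-stimulus effects")
    for eff in list(single_effects) + [concurrent_effect]:
        if eff.n < 2:
            raise ConfigError(f"effect {eff.stimulus_label!r} has n < 2")
    expected = float(sum(e.effect for e in single_effects))
    se_exp = float(np.sqrt(sum(e.se**2 for e in single_effects)))
    se_obs = concurrent_effect.se
    se2 = se_obs**2 + se_exp**2
    if se2 == 0.0:
        t = 0.0 if concurrent_effect.effect == expected else float("inf")
        p = 1.0 if t == 0.0 else 0.0
        df = float(concurrent_effect.n - 1)
    else:
        t = float((concurrent_effect.effect - expected) / np.sqrt(se2))
        df_components = [(e.se**2, e.n - 1) for e in single_effects]
        df_components.append((se_obs**2, concurrent_effect.n - 1))
        den = sum(v**2 / d for v, d in df_components if d > 0)
        df = float(se2**2 / den) if den > 0 else float(concurrent_effect.n - 1)
        p = float(2.0 * stats.t.sf(abs(t), df))
    p_adj = min(1.0, p * n_comparisons)
    return AdditivityTestResult(
        expected_effect=expected,
        expected_se=se_exp,
        observed_effect=concurrent_effect.effect,
        observed_se=se_obs,
        t_stat=t,
        df=df,
        p=p,
        p_adjusted=p_adj,
        additive=p_adj > 0.05,
    )


def effects_to_frame(effects: list[GrowthEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stimulus": [e.stimulus_label for e in effects],
            "effect_minutes": [e.effect for e in effects],
            "se": [e.se for e in effects],
            "sd": [e.sd for e in effects],
            "n": [e.n for e in effects],
        }
    )
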
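"""Adsorption and one-step growth analysis of phage titre series.

Adsorption follows first-order loss of free phage at host density B,
dP/dt = -k * B * P, so each timed titre gives a per-interval estimate
k_t = (2.303 / (B * t)) * log10(P0 / P_t); the reported constant is the mean
over the monotone-decay window, per replicate, then averaged across
replicates.

One-step growth reads three numbers off the total (untreated) and
chloroform-treated series sampled on a common grid: the latent period is the
first sampling time where the total titre exceeds the pre-rise baseline by a
rise factor; the eclipse period applies the same rule to the treated series;
burst size is the plateau titre divided by the baseline of infective centres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TiterSeries:
    """Timed plaque counts; ``pfu`` has shape (replicates, time points)."""

    times: np.ndarray
    pfu: np.ndarray
    treatment: str = "total"
    cell_density: float | None = None
    moi: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.pfu = np.atleast_2d(np.asarray(self.pfu, dtype=float))
        if self.pfu.shape[1] != len(self.times):
            raise ValueError("pfu columns must match time points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.pfu <= 0):
            raise ValueError("titres must be positive")

    @property
    def n_replicates(self) -> int:
        return self.pfu.shape[0]

    def mean_curve(self) -> np.ndarray:
        return self.pfu.mean(axis=0)


@dataclass
class KineticsResult:
    k: float | None = None
    k_per_replicate: list[float] = field(default_factory=list)
    k_sd: float | None = None
    eclipse_min: float | None = None
    latent_min: float | None = None
    burst: float | None = None
    burst_per_replicate: list[float] = field(default_factory=list)
    burst_sd: float | None = None
    censored: bool = False


def free_fraction(k: float, b: float, t: float) -> float:
    """Fraction of phage still free after t minutes of adsorption:
    exp(-k * b * t)."""
    return float(np.exp(-k * b * t))


def adsorption_rate(series: TiterSeries) -> KineticsResult:
    """Adsorption rate constant from free-phage decay.

    For each time point t > t0 in the monotone-decay window,
    k_t = (2.303 / (B * (t - t0))) * log10(P0 / P_t); the window runs from t0
    to the last point before the titre stops falling (the assay floor). The
    per-replicate mean k values are averaged.
    """
    if series.cell_density is None:
        raise ValueError("series metadata must include cell_density")
    if len(series.times) < 2:
        raise ValueError("need at least two time points")
    b = series.cell_density
    t = series.times
    ks: list[float] = []
    for rep in series.pfu:
        # monotone-decay window: successive strictly decreasing titres
        end = 1
        while end < len(rep) and rep[end] < rep[end - 1]:
            end += 1
        if end < 2:
            raise ValueError("no adsorption detected: titres do not decay")
        p0 = rep[0]
        kt = [
            2.303 / (b * (t[i] - t[0])) * np.log10(p0 / rep[i])
            for i in range(1, end)
        ]
        ks.append(float(np.mean(kt)))
    return KineticsResult(
        k=float(np.mean(ks)),
        k_per_replicate=ks,
        k_sd=float(np.std(ks, ddof=1)) if len(ks) > 1 else None,
    )


def _rise_index(mean_curve: np.ndarray, rise_factor: float) -> tuple[int, float]:
    """Index of the first point above rise_factor x pre-rise baseline, plus
    the baseline (mean of all pre-rise points)."""
    baseline = mean_curve[0]
    for i in range(1, len(mean_curve)):
        if mean_curve[i] > rise_factor * baseline:
            return i, float(mean_curve[:i].mean())
        baseline = mean_curve[: i + 1].mean()
    raise ValueError("no rise detected in titre series")


def one_step_analysis(
    total: TiterSeries,
    treated: TiterSeries,
    rise_factor: float = 3.0,
    plateau_tol: float = 0.10,
) -> KineticsResult:
    """Latent period, eclipse period, and burst size from a one-step
    experiment.

    The latent (total series) and eclipse (chloroform-treated series) periods
    are the first sampling times where the mean titre exceeds ``rise_factor``
    times the pre-rise baseline. The plateau is the mean of the total titres
    from the first point where the successive relative change drops below
    ``plateau_tol``; burst = plateau / baseline infective centres. If the
    series ends before stabilizing, the last point serves as the plateau and
    the result is flagged censored.
    """
    if not np.array_equal(total.times, treated.times):
        raise ValueError("total and treated series must share the time grid")
    mean_total = total.mean_curve()
    rise_idx, baseline = _rise_index(mean_total, rise_factor)
    latent = float(total.times[rise_idx])

    mean_treated = treated.mean_curve()
    try:
        ecl_idx, _ = _rise_index(mean_treated, rise_factor)
        eclipse = float(treated.times[ecl_idx])
    except ValueError:
        eclipse = latent
    eclipse = min(eclipse, latent)

    censored = False
    plateau_start = None
    for i in range(rise_idx, len(mean_total) - 1):
        change = abs(mean_total[i + 1] - mean_total[i]) / mean_total[i]
        if change < plateau_tol:
            plateau_start = i + 1 if mean_total[i + 1] > mean_total[i] else i
            break
    if plateau_start is None:
        plateau_start = len(mean_total) - 1
        censored = True
    plateau_cols = slice(plateau_start, len(mean_total))
    base_cols = slice(0, rise_idx)

    per_rep = []
    for rep_tot in total.pfu:
        per_rep.append(float(rep_tot[plateau_cols].mean() / rep_tot[base_cols].mean()))
    burst = float(mean_total[plateau_cols].mean() / baseline)
    return KineticsResult(
        eclipse_min=eclipse,
        latent_min=latent,
        burst=burst,
        burst_per_replicate=per_rep,
        burst_sd=float(np.std(per_rep, ddof=1)) if len(per_rep) > 1 else None,
        censored=censored,
    )
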
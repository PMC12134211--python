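"""Fluorescent-protein maturation kinetics from chloramphenicol chases.

After protein synthesis is blocked, already-translated but immature
protein continues to mature, so total cell fluorescence rises.  With a
single-step maturation reaction and instantaneous arrest of synthesis
at t = 0, the lineage total follows

    F(t) = c (alpha + 1 - alpha exp(-t / tau_m))

where tau_m is the maturation time, c the fluorescence at the swap and
alpha the immature/mature ratio then.  When repeated imaging bleaches
the matured protein appreciably (end-point below 85% of the peak, on
average over the lineages of one FP in one experiment), the sum of two
exponentials is used instead:

    F(t) = c [ (tau_b/(tau_b - tau_m)) (alpha + 1) exp(-t/tau_b)
               - alpha (tau_b/(tau_b - tau_m)) exp(-t/tau_m) ]

with tau_b > tau_m the characteristic bleaching time.  Maturation
times exceeding the post-swap acquisition window (300 min by default)
cannot be determined and are reported censored (">300 min").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "MatModel",
    "FitResult",
    "single_exp_value",
    "double_exp_value",
    "choose_model",
    "fit_maturation",
    "average_traces",
    "summarize_fps",
]


@dataclass(frozen=True)
class MatModel:
    """Fitted maturation-model parameters (tau in minutes)."""

    c: float
    alpha: float
    tau_m: float
    tau_b: float | None = None


@dataclass(frozen=True)
class FitResult:
    kind: str  # "single" | "double"
    model: MatModel | None
    residual_norm: float
    censored: bool
    n_points: int
    success: bool = True

    @property
    def tau_m(self) -> float:
        return self.model.tau_m if self.model else float("nan")


def single_exp_value(t, c, alpha, tau_m):
    """F(t) = c (alpha + 1 - alpha exp(-t/tau_m)); rises from c at t=0
    toward c (alpha + 1)."""
    t = np.asarray(t, dtype=float)
    return c * (alpha + 1 - alpha * np.exp(-t / tau_m))


def double_exp_value(t, c, alpha, tau_m, tau_b):
    """Two-exponential maturation-plus-bleaching model; requires
    tau_b != tau_m (singular otherwise).  Decays to 0 as t -> inf."""
    if tau_b == tau_m:
        raise ValueError("tau_b must differ from tau_m (singular model)")
    t = np.asarray(t, dtype=float)
    k = tau_b / (tau_b - tau_m)
    return c * (k * (alpha + 1) * np.exp(-t / tau_b) - alpha * k * np.exp(-t / tau_m))


def choose_model(
    traces: list[tuple[np.ndarray, np.ndarray]],
    bleach_threshold: float = 0.85,
    end_n: int = 2,
) -> str:
    """Pick "single" or "double" for one FP in one experiment.

    Computes, per trace, end-point fluorescence (mean of the last
    ``end_n`` samples, for noise robustness) over peak fluorescence
    (sample maximum); the double model is chosen iff the mean of this
    ratio over traces is strictly below ``bleach_threshold`` (i.e. the
    signal has bleached by more than 15% from the peak).
    """
    if not traces:
        raise ValueError("need at least one trace")
    ratios = []
    for _, values in traces:
        v = np.asarray(values, dtype=float)
        peak = v.max()
        end = v[-end_n:].mean()
        ratios.append(end / peak if peak != 0 else 1.0)
    return "double" if float(np.mean(ratios)) < bleach_threshold else "single"


def _initial_guess(t: np.ndarray, f: np.ndarray, t_acq: float) -> tuple[float, float, float, float]:
    c0 = max(float(f[0]), 1e-9)
    alpha0 = max(float(f[-1]) / c0 - 1.0, 0.1)
    # time of half rise
    half = (f[0] + f.max()) / 2.0
    above = np.flatnonzero(f >= half)
    tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else t_acq / 4.0
    taub0 = 2.0 * t_acq
    return c0, alpha0, tau0, taub0


def fit_maturation(
    times: np.ndarray,
    values: np.ndarray,
    kind: str = "single",
    t_acq: float = 300.0,
) -> FitResult:
    """Nonlinear least-squares fit of the post-swap rise.

    Initialisation: c0 = F(0) clamped positive; alpha0 =
    max(F_end/F_0 - 1, 0.1); tau_m0 = time of half rise; tau_b0 =
    2 t_acq.  Bounds: c > 0, alpha >= 0, tau_m > 0 and, for the double
    model, tau_b > tau_m (enforced by fitting tau_b = tau_m + delta
    with delta > 0).  Non-convergence yields a flagged failure result
    rather than an exception.  ``censored`` is set when the fitted
    tau_m exceeds the acquisition window ``t_acq``.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(values, dtype=float)
    if t.size != f.size:
        raise ValueError("times and values length mismatch")
    if t.size < 5:
        raise ValueError(f"need >= 5 post-swap points, got {t.size}")
    if not np.isfinite(f).all():
        raise ValueError("non-finite fluorescence values")
    if kind not in ("single", "double"):
        raise ValueError(f"unknown model kind {kind!r}")

    c0, alpha0, tau0, taub0 = _initial_guess(t, f, t_acq)
    tiny = 1e-9
    try:
        if kind == "single":

            def resid(p):
                return single_exp_value(t, *p) - f

            sol = least_squares(
                resid,
                x0=(c0, alpha0, tau0),
                bounds=((tiny, 0.0, tiny), (np.inf, np.inf, np.inf)),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            c, alpha, tau_m = sol.x
            model = MatModel(float(c), float(alpha), float(tau_m))
        else:

            def resid(p):
                c, alpha, tau_m, delta = p
                return double_exp_value(t, c, alpha, tau_m, tau_m + delta) - f

            sol = least_squares(
                resid,
                x0=(c0, alpha0, tau0, max(taub0 - tau0, 1.0)),
                bounds=((tiny, 0.0, tiny, tiny), (np.inf,) * 4),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            c, alpha, tau_m, delta = sol.x
            model = MatModel(float(c), float(alpha), float(tau_m), float(tau_m + delta))
    except Exception:
        return FitResult(kind, None, float("inf"), censored=False, n_points=t.size, success=False)
    if not sol.success or not np.isfinite(sol.x).all():
        return FitResult(kind, None, float("inf"), censored=False, n_points=t.size, success=False)
    return FitResult(
        kind=kind,
        model=model,
        residual_norm=float(np.linalg.norm(sol.fun)),
        censored=bool(model.tau_m > t_acq),
        n_points=t.size,
    )


def average_traces(traces: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Average lineage traces sampled on a common time grid."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = np.asarray(traces[0][0], dtype=float)
    for t, _ in traces[1:]:
        if not np.array_equal(np.asarray(t, dtype=float), t0):
            raise ValueError("traces must share the same time grid")
    vals = np.mean([np.asarray(v, dtype=float) for _, v in traces], axis=0)
    return t0, vals


def summarize_fps(
    replicate_fits: pd.DataFrame,
    min_traps: int = 5,
    min_lineages: int = 6,
    t_acq: float = 300.0,
) -> pd.DataFrame:
    """Replicate-level maturation times -> per-FP summary.

    ``replicate_fits`` columns: fp_id, replicate, tau_m, n_traps,
    n_lineages.  Replicates with fewer than ``min_traps`` decoded traps
    (i.e. not "> 4") are excluded; FPs with no qualifying replicate are
    omitted.  The summary carries the mean tau_m over qualifying
    replicates, the SEM when exactly three replicates qualify (and NaN
    otherwise), whether every qualifying replicate reached
    ``min_lineages`` lineages, and a display label that reports
    "> t_acq" for censored means.
    """
    required = {"fp_id", "replicate", "tau_m", "n_traps", "n_lineages"}
    missing = required - set(replicate_fits.columns)
    if missing:
        raise ValueError(f"replicate_fits missing columns: {sorted(missing)}")
    rows = []
    for fp, sub in replicate_fits.groupby("fp_id", sort=True):
        ok = sub[sub.n_traps >= min_traps]
        if ok.empty:
            continue
        taus = ok.tau_m.to_numpy(dtype=float)
        mean = float(taus.mean())
        sem = float(taus.std(ddof=1) / np.sqrt(len(taus))) if len(taus) == 3 else float("nan")
        rows.append(
            {
                "fp_id": fp,
                "n_replicates": len(ok),
                "tau_m_values": list(taus),
                "mean_tau_m": mean,
                "sem_tau_m": sem,
                "enough_lineages": bool((ok.n_lineages >= min_lineages).all()),
                "label": f">{t_acq:g}" if mean > t_acq else f"{mean:.1f}",
            }
        )
    return pd.DataFrame(rows)
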
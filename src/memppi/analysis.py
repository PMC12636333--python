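"""Summary analytics: generalized-logistic fits of activity vs. rescaled
temperature, the diagrammatic sign-prediction rule, and grid-experiment
drivers over tau, magnetization and inclusion radius.

The activity curve f_A(tau) is fitted with

    f_A(tau) = (R - L)/2 * tanh((tau - tau0) / (2 * dtau)) + (R + L)/2

where L and R are the left/right asymptotes, dtau the growth width (small
dtau = sharp sensitivity to the distance from criticality) and tau0 the
point of steepest activity increase.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .config import ExperimentConfig, RunConfig
from .observables import Trajectory
from .reactions import ReactionNetwork
from .simulate import run_simulation


@dataclass
class LogisticFit:
    L_asym: float = np.nan
    R_asym: float = np.nan
    delta_tau: float = np.nan
    tau0: float = np.nan
    ci95: dict = field(default_factory=dict)   # parameter -> 95% half-width
    converged: bool = False

    def predict(self, tau) -> np.ndarray:
        return logistic_activity(np.asarray(tau, dtype=float),
                                 self.L_asym, self.R_asym,
                                 self.delta_tau, self.tau0)


def logistic_activity(tau, L, R, delta_tau, tau0):
    """Generalized logistic activity curve (tanh form)."""
    return (R - L) / 2.0 * np.tanh((tau - tau0) / (2.0 * delta_tau)) + (R + L) / 2.0


def fit_logistic(tau_values, f_A_values) -> LogisticFit:
    """Nonlinear least-squares fit of the activity curve.

    Never raises on optimizer failure or degenerate (flat) data; the
    returned fit has converged=False instead.  Initialization: L=min(f),
    R=max(f), tau0 at the steepest finite-difference slope, dtau=span/4.
    """
    tau = np.asarray(tau_values, dtype=float)
    f = np.asarray(f_A_values, dtype=float)
    if tau.shape != f.shape:
        raise ValueError("tau and activity arrays must have equal length")
    if len(np.unique(tau)) < 5:
        raise ValueError("need at least 5 distinct tau points")
    order = np.argsort(tau, kind="stable")
    tau, f = tau[order], f[order]
    span = tau[-1] - tau[0]
    if np.ptp(f) < 1e-12 or span <= 0:
        return LogisticFit(L_asym=float(f.min()), R_asym=float(f.max()))
    # steepest finite-difference slope between distinct tau values
    dt = np.diff(tau)
    ok = dt > 0
    slopes = np.full(len(dt), -np.inf)
    slopes[ok] = np.abs(np.diff(f)[ok] / dt[ok])
    k = int(np.argmax(slopes))
    p0 = [float(f.min()), float(f.max()), span / 4.0,
          float(0.5 * (tau[k] + tau[k + 1]))]
    try:
        popt, pcov = curve_fit(
            lambda t, L, R, d, t0: logistic_activity(t, L, R, d, t0),
            tau, f, p0=p0,
            bounds=([-0.5, -0.5, 1e-6, tau[0] - span],
                    [1.5, 1.5, 10.0 * max(span, 1.0), tau[-1] + span]),
            maxfev=20_000)
    except (RuntimeError, ValueError):
        return LogisticFit()
    if not np.all(np.isfinite(popt)) or not np.all(np.isfinite(np.diag(pcov))):
        return LogisticFit(L_asym=popt[0], R_asym=popt[1],
                           delta_tau=popt[2], tau0=popt[3])
    half = 1.96 * np.sqrt(np.diag(pcov))
    return LogisticFit(
        L_asym=float(popt[0]), R_asym=float(popt[1]),
        delta_tau=float(popt[2]), tau0=float(popt[3]),
        ci95={"L_asym": float(half[0]), "R_asym": float(half[1]),
              "delta_tau": float(half[2]), "tau0": float(half[3])},
        converged=True)


# ---------------------------------------------------------------------------
# diagrammatic sign rule

@dataclass
class NetworkDiagram:
    """Per-pathway (activity_sign, contact_trend_sign) pairs."""

    pathway_signs: list

    def __post_init__(self) -> None:
        if not self.pathway_signs:
            raise ValueError("diagram needs at least one pathway")
        for a, t in self.pathway_signs:
            if a not in (-1, 1) or t not in (-1, 1):
                raise ValueError("signs must be +1 or -1")

    @classmethod
    def from_network(cls, network: ReactionNetwork) -> "NetworkDiagram":
        return cls(pathway_signs=list(network.pathway_signs))


def predict_sign(diagram: NetworkDiagram) -> str:
    """Predict the slope of target activity with respect to tau.

    Per-pathway products of the two signs: all +1 -> 'increasing', all -1
    -> 'decreasing', mixed -> 'indeterminate' (the rule only predicts when
    every pathway agrees).
    """
    products = {a * t for a, t in diagram.pathway_signs}
    if products == {1}:
        return "increasing"
    if products == {-1}:
        return "decreasing"
    return "indeterminate"


# ---------------------------------------------------------------------------
# grid experiments

def _point_config(base: RunConfig, tau, m, radius) -> RunConfig:
    species = list(base.species)
    if radius is not None:
        species = [dataclasses.replace(s, radius=int(radius)) for s in species]
    return replace(base, tau=float(tau), magnetization=float(m),
                   species=species)


def run_sweep_experiment(exp: ExperimentConfig,
                         trajectory_hook=None,
                         progress: bool = False) -> pd.DataFrame:
    """Run the (tau, m, radius) grid with seeded replicates.

    Returns one row per replicate: steady-state mean/SD of f_A after the
    burn-in, the achieved magnetization and the derived per-run seed.  A
    ``trajectory_hook(traj) -> dict`` can add columns (e.g. pocket
    statistics); per-point failures are recorded in an ``error`` column
    and the experiment continues.  Identical master seeds give identical
    tables.
    """
    grid = [(tau, m, r) for r in exp.radii for m in exp.ms for tau in exp.taus]
    ss = np.random.SeedSequence(exp.master_seed)
    children = ss.spawn(len(grid) * exp.replicates)
    rows = []
    idx = 0
    for tau, m, radius in grid:
        for rep in range(exp.replicates):
            seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            row = {"tau": float(tau), "m": float(m),
                   "radius": (np.nan if radius is None else int(radius)),
                   "replicate": rep, "seed": seed,
                   "f_A_mean": np.nan, "f_A_sd": np.nan,
                   "achieved_m": np.nan, "error": ""}
            try:
                cfg = _point_config(exp.base, tau, m, radius)
                traj = run_simulation(cfg, seed=seed)
                start = int(len(traj.activity) * cfg.burn_in_fraction)
                tail = traj.activity[start:]
                row["f_A_mean"] = float(np.nanmean(tail))
                row["f_A_sd"] = float(np.nanstd(tail))
                row["achieved_m"] = traj.achieved_m
                if trajectory_hook is not None:
                    row.update(trajectory_hook(traj))
            except Exception as e:  # record and continue
                row["error"] = f"{type(e).__name__}: {e}"
            rows.append(row)
            if progress:
                print(f"  tau={tau:.3f} m={m:+.2f} r={radius} rep={rep}: "
                      f"f_A={row['f_A_mean']:.3f}", flush=True)
    return pd.DataFrame(rows)


def summarize_experiment(df: pd.DataFrame) -> pd.DataFrame:
    """Per-grid-point mean/SD of the replicate steady-state activities."""
    ok = df[df["error"].fillna("") == ""]  # NaN: error column from CSV round-trip
    g = ok.groupby(["radius", "m", "tau"], dropna=False)["f_A_mean"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"mean": "f_A", "std": "f_A_sd", "count": "n"})


def fit_activity_curves(df: pd.DataFrame) -> pd.DataFrame:
    """LogisticFit of mean activity vs tau for every (radius, m) group."""
    summary = summarize_experiment(df)
    rows = []
    for (radius, m), grp in summary.groupby(["radius", "m"], dropna=False):
        fit = fit_logistic(grp["tau"].to_numpy(), grp["f_A"].to_numpy())
        rows.append({
            "radius": radius, "m": m,
            "L_asym": fit.L_asym, "R_asym": fit.R_asym,
            "delta_tau": fit.delta_tau, "tau0": fit.tau0,
            "delta_tau_ci95": fit.ci95.get("delta_tau", np.nan),
            "tau0_ci95": fit.ci95.get("tau0", np.nan),
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)
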
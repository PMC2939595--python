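"""Simulation-based posterior predictive check (PPC).

Replicate trials are simulated from a fitted model (optionally propagating
estimation uncertainty by drawing parameter vectors from the asymptotic
normal of the estimates on the transformed scale).  The summary statistic
is the arm-level mean change from baseline per 24 h at each post-baseline
visit; observed statistics are compared with the 10/50/90 % quantiles of
their replicate distribution.

A cell is "inside" when the observed value lies within [q10, q90].  For a
well-calibrated model each cell is inside with roughly the nominal 80 %
probability (more when parameter uncertainty widens the band), so a sound
PPC shows a high *fraction* of inside cells; with many cells, demanding
every single cell inside would fail a correct model by chance alone.
Both ``fraction_inside`` and the strict ``all_inside`` flag are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .nlme import FitResult
from .structural import dose_effect
from .synthetic_trial import (
    DesignSpec, GenerationError, TruthParameters, simulate_trial,
)
from .trial_data import PooledDataset


class PPCError(RuntimeError):
    pass


def observed_change_stats(data: PooledDataset, endpoint: str) -> pd.Series:
    """Mean change from baseline per 24 h by (dose, visit day > 0).

    Counts are converted to per-24 h rates (DV / DIARY_D) before the
    within-subject difference; MVV is differenced in mL.
    """
    df = data.endpoint_frame(endpoint).copy()
    if df.empty:
        raise PPCError(f"no observations for endpoint {endpoint}")
    dd = pd.to_numeric(df["DIARY_D"], errors="coerce").astype(float)
    df["RATE"] = df["DV"] / dd.where(dd.notna(), 1.0)
    base = df[df["TIME_D"] == 0].set_index("SUBJ")["RATE"]
    post = df[df["TIME_D"] > 0]
    change = post["RATE"].to_numpy() - base.reindex(post["SUBJ"]).to_numpy()
    out = (pd.DataFrame({"DOSE_MG": post["DOSE_MG"].to_numpy(),
                         "TIME_D": post["TIME_D"].to_numpy(),
                         "CHANGE": change})
           .groupby(["DOSE_MG", "TIME_D"])["CHANGE"].mean())
    out.name = "mean_change_per_24h"
    return out


def fitresult_to_truth(fit: FitResult, doses=(4, 8, 12)) -> TruthParameters:
    """Re-express fitted estimates as generator truth for one endpoint."""
    v = fit.estimates.values
    sp = fit.structural_params()
    d_eff = {int(d): float(dose_effect(d, sp.dose_params, fit.spec.dose_model))
             for d in doses}
    return TruthParameters(
        endpoint=fit.endpoint,
        baseline_typical=v["B"], bsv_omega2=v["omega2"],
        placebo_effect=v["P"], dose_effects=d_eff,
        onset_t90_days=v["T90"],
        residual_sd=v.get("sigma"),
    )


def _draw_truth(fit: FitResult, doses,
                rng: np.random.Generator, max_redraws: int = 10,
                ) -> tuple[TruthParameters, int]:
    """One parameter draw from the asymptotic normal, re-expressed as truth;
    inadmissible draws (effect fractions >= 1) are redrawn, up to a cap."""
    from .nlme import _from_unconstrained, _to_unconstrained  # internal reuse

    if fit.cov_unconstrained is None:
        raise PPCError("fit has no covariance matrix; "
                       "refit with compute_cv=True or set with_uncertainty=False")
    z_hat = np.array([
        _to_unconstrained(fit.estimates.values[n], fit.estimates.transform_of(n))
        for n in fit.free_names])
    redraws = 0
    while True:
        z = rng.multivariate_normal(z_hat, fit.cov_unconstrained)
        values = dict(fit.fixed)
        for n, zj in zip(fit.free_names, z):
            values[n] = _from_unconstrained(float(zj), fit.estimates.transform_of(n))
        try:
            trial_fit = replace(fit, estimates=fit.estimates.copy_with(**values))
            truth = fitresult_to_truth(trial_fit, doses)
            return truth, redraws
        except (ValueError, GenerationError):
            redraws += 1
            if redraws > max_redraws:
                raise PPCError(
                    f"more than {max_redraws} inadmissible parameter draws")


def simulate_replicates(fit: FitResult, design: DesignSpec, n_reps: int = 1000,
                        seed: int = 0, with_uncertainty: bool = True,
                        ) -> pd.DataFrame:
    """Replicate-trial statistics: one row per replicate, one column per
    (dose, visit) cell (mean change from baseline per 24 h)."""
    if not fit.converged:
        raise PPCError("fit has not converged")
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    doses = sorted({int(d) for s in design.studies.values()
                    for d, n in s.arms.items() if n > 0 and d > 0})
    rows = []
    for r in range(n_reps):
        if with_uncertainty:
            truth, _ = _draw_truth(fit, doses, rng)
        else:
            truth = fitresult_to_truth(fit, doses)
        rep = simulate_trial(design, {fit.endpoint: truth},
                             int(rep_seeds[r]), validate=False)
        rows.append(observed_change_stats(rep, fit.endpoint))
    return pd.DataFrame(rows).reset_index(drop=True)


@dataclass
class PPCSummary:
    """Per-cell observed statistic vs simulated 10/50/90 % quantiles."""

    table: pd.DataFrame     # index (dose, time); observed, q10, q50, q90, inside

    @property
    def fraction_inside(self) -> float:
        return float(self.table["inside"].mean())

    @property
    def all_inside(self) -> bool:
        return bool(self.table["inside"].all())


def ppc_summary(replicates: pd.DataFrame, observed: pd.Series) -> PPCSummary:
    """Empirical replicate quantiles per cell plus inside flags.

    ``replicates`` columns and ``observed`` index must describe the same
    (dose, visit) cells.
    """
    if len(replicates) < 100:
        raise PPCError("need at least 100 replicates for stable quantiles")
    rep_cells = set(map(tuple, replicates.columns))
    obs_cells = set(map(tuple, observed.index))
    if rep_cells != obs_cells:
        raise PPCError("replicate and observed cells do not match")
    q = replicates.quantile([0.1, 0.5, 0.9])
    table = pd.DataFrame({
        "observed": observed,
        "q10": q.loc[0.1].reindex(observed.index),
        "q50": q.loc[0.5].reindex(observed.index),
        "q90": q.loc[0.9].reindex(observed.index),
    })
    table["inside"] = (table["observed"] >= table["q10"]) & (
        table["observed"] <= table["q90"])
    table.index.names = ["dose_mg", "time_d"]
    return PPCSummary(table=table)


def run_ppc(fit: FitResult, data: PooledDataset, design: DesignSpec,
            n_reps: int = 1000, seed: int = 0,
            with_uncertainty: bool = True) -> PPCSummary:
    """Convenience wrapper: observed statistics + replicates + summary."""
    observed = observed_change_stats(data, fit.endpoint)
    reps = simulate_replicates(fit, design, n_reps=n_reps, seed=seed,
                               with_uncertainty=with_uncertainty)
    return ppc_summary(reps, observed)


def plot_ppc(summary: PPCSummary, path: str, title: str = "") -> None:
    """Per-dose trajectories of observed means inside the simulated
    10-90 % ribbons (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = summary.table.reset_index()
    doses = sorted(tab["dose_mg"].unique())
    fig, axes = plt.subplots(1, len(doses), figsize=(3.2 * len(doses), 3.2),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, dose in zip(axes, doses):
        cell = tab[tab["dose_mg"] == dose].sort_values("time_d")
        ax.fill_between(cell["time_d"], cell["q10"], cell["q90"],
                        alpha=0.3, label="simulated 10-90%")
        ax.plot(cell["time_d"], cell["q50"], "-", label="simulated median")
        ax.plot(cell["time_d"], cell["observed"], "k*", label="observed")
        ax.set_title(f"{dose} mg")
        ax.set_xlabel("day")
    axes[0].set_ylabel("mean change from baseline / 24 h")
    axes[0].legend(fontsize=7)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
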
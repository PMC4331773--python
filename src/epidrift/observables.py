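"""Derived statistics: gene-state summaries, gene classification,
differential expression, clone census and decay, parameter sensitivity.

All summaries are plain tidy DataFrames recomputable from the raw
trajectory tables, so every aggregate here can be cross-checked against a
direct recomputation from the per-cell exports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import ARPDefinition
from .genome import Genome
from .population import (
    EnvironmentParams,
    PopulationState,
    Trajectory,
    run_scenario,
)
from .regulation import RegulationParams, histone_stationary_distribution

__all__ = [
    "summarize_states",
    "classify_genes",
    "differential_expression",
    "CloneCensus",
    "clone_census",
    "fit_clone_decay",
    "time_to_dominance",
    "sensitivity_sweep",
    "SWEEPABLE_PARAMETERS",
]

#: default pseudocount for log-expression: 1e-3 * P_max / delta at defaults
DEFAULT_PSEUDOCOUNT = 1e-3 * 1000.0 / 0.2


def _genes_frame(source: Trajectory | pd.DataFrame) -> pd.DataFrame:
    if isinstance(source, Trajectory):
        return source.genes
    return source


def summarize_states(
    source: Trajectory | pd.DataFrame | PopulationState,
    t_min: int | None = None,
) -> pd.DataFrame:
    """Per-gene, per-environment regulatory summary (tidy).

    Means and variances of expression, H3K4me3 fraction and methylated-CpG
    fraction, averaged over cells (and over recorded times >= ``t_min`` for
    trajectories).  Adds max-normalized expression and H3K4me3 columns and
    a sorting rank by the average H3K4me3 modification in omega.
    Environments without any sampled cell are flagged via ``n = 0``.
    """
    if isinstance(source, PopulationState):
        from .population import _record_genes  # single-time aggregation

        rows: list = []
        _record_genes(source, rows)
        df = pd.DataFrame(
            rows,
            columns=[
                "t",
                "env",
                "gene",
                "n_h",
                "mean_expr",
                "var_expr",
                "mean_hm",
                "var_hm",
                "mean_meth",
                "var_meth",
                "n_cells",
            ],
        )
    else:
        df = _genes_frame(source)
    if t_min is not None:
        df = df[df["t"] >= t_min]
    grouped = (
        df.groupby(["gene", "env"], as_index=False)
        .agg(
            n_h=("n_h", "first"),
            mean_expr=("mean_expr", "mean"),
            var_expr=("var_expr", "mean"),
            mean_hm=("mean_hm", "mean"),
            var_hm=("var_hm", "mean"),
            mean_meth=("mean_meth", "mean"),
            var_meth=("var_meth", "mean"),
            n=("n_cells", "sum"),
        )
        .fillna({"n": 0})
    )
    for col in ("mean_expr", "mean_hm"):
        top = grouped[col].max()
        grouped[col + "_norm"] = grouped[col] / top if top and top > 0 else 0.0
    omega_hm = (
        grouped[grouped["env"] == "omega"].set_index("gene")["mean_hm"].fillna(0.0)
    )
    order = omega_hm.sort_values(ascending=False)
    rank = {g: i for i, g in enumerate(order.index)}
    grouped["omega_hm_rank"] = grouped["gene"].map(rank)
    return grouped


@dataclass
class ClassificationRules:
    """Thresholds for the behavioral gene classification."""

    alpha_stable_hm: float = 0.5  #: mean H3K4me3 fraction in alpha for C1
    omega_meth: float = 0.2  #: mean Omega CpG methylation marking C1a
    min_span: int = 500  #: minimum recorded time span for a stable call
    late_fraction: float = 0.5  #: use the last fraction of the record


def classify_genes(
    trajectory: Trajectory | pd.DataFrame,
    params: RegulationParams,
    rules: ClassificationRules | None = None,
) -> pd.DataFrame:
    """Behavioral C1 / C1a / C2 / C3 classification, plus the N_H shortcut.

    Behavioral rules: C3 = no nucleosomes; C1 = bistable (bimodal
    stationary chromatin law on unmethylated DNA) and stably modified in
    the niche over the late trajectory window; C1a = the C1 subset that
    acquired DNA methylation in omega; everything else (fluctuating,
    monostable, irreversibly silenced) is C2.  The N_H shortcut applies the
    class boundary C3 < 1 <= C2 <= 6 < C1 and the agreement rate between
    the two classifiers is attached to the frame (``.attrs['agreement']``).

    If the recorded span is shorter than ``rules.min_span`` the calls are
    flagged unstable (``stable = False``).
    """
    rules = rules or ClassificationRules()
    df = _genes_frame(trajectory)
    span = df["t"].max() - df["t"].min()
    stable = bool(span >= rules.min_span)
    t_late = df["t"].min() + (1 - rules.late_fraction) * span
    late = df[df["t"] >= t_late]
    out_rows = []
    for gene, sub in late.groupby("gene"):
        n_h = int(sub["n_h"].iloc[0])
        alpha_hm = sub.loc[sub["env"] == "alpha", "mean_hm"].mean()
        omega_meth = sub.loc[sub["env"] == "omega", "mean_meth"].mean()
        if n_h == 0:
            behavioral = "C3"
            bistable = False
        else:
            _, bistable = histone_stationary_distribution(n_h, 1.0, params)
            if bistable and alpha_hm >= rules.alpha_stable_hm:
                behavioral = (
                    "C1a" if omega_meth >= rules.omega_meth else "C1"
                )
            else:
                behavioral = "C2"
        if n_h == 0:
            shortcut = "C3"
        elif n_h <= 6:
            shortcut = "C2"
        else:
            shortcut = "C1"
        out_rows.append(
            {
                "gene": gene,
                "n_h": n_h,
                "bistable": bistable,
                "alpha_hm": alpha_hm,
                "omega_meth": omega_meth,
                "class_behavioral": behavioral,
                "class_nh": shortcut,
                "stable": stable,
            }
        )
    out = pd.DataFrame(out_rows)
    coarse = out["class_behavioral"].str.replace("C1a", "C1", regex=False)
    out.attrs["agreement"] = float((coarse == out["class_nh"]).mean())
    return out


def differential_expression(
    summary: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.Series:
    """Per-gene differential expression ln(alpha) - ln(omega).

    Positive values mean higher expression in the niche.  A pseudocount
    keeps silenced genes finite.
    """
    wide = summary.pivot(index="gene", columns="env", values="mean_expr")
    return np.log(wide["alpha"] + pseudocount) - np.log(wide["omega"] + pseudocount)


# ---------------------------------------------------------------------------
# clones
# ---------------------------------------------------------------------------


@dataclass
class CloneCensus:
    """Clone bookkeeping derived from a trajectory.

    ``counts``: time series of the number of surviving clones and total
    population; ``per_clone``: the long table (t, clone, size, aged
    fraction, mean generation).  Clone sizes partition the population at
    every time.
    """

    counts: pd.DataFrame
    per_clone: pd.DataFrame


def clone_census(trajectory: Trajectory | pd.DataFrame) -> CloneCensus:
    clones = (
        trajectory.clones if isinstance(trajectory, Trajectory) else trajectory
    )
    alive = clones[clones["size"] > 0]
    counts = (
        alive.groupby("t")
        .agg(
            n_clones=("clone", "nunique"),
            total_cells=("size", "sum"),
            aged_cells=(
                "size",
                lambda s: float(
                    (s * alive.loc[s.index, "aged_fraction"]).sum()
                ),
            ),
        )
        .reset_index()
    )
    return CloneCensus(counts=counts, per_clone=alive.copy())


def fit_clone_decay(
    census: CloneCensus | pd.DataFrame, start_fraction: float = 0.9
) -> float:
    """Least-squares log-log slope of clone number vs time.

    The fit window starts when the clone count first drops below
    ``start_fraction`` of its initial value (the power-law regime,
    excluding the initial plateau) and runs to the end of the record; a
    series that never leaves the plateau is fitted whole (a constant clone
    count then yields slope 0).  Under neutral competition the decay
    follows ~1/t, i.e. slope ~ -1.
    """
    counts = census.counts if isinstance(census, CloneCensus) else census
    counts = counts.sort_values("t")
    n = counts["n_clones"].to_numpy(dtype=float)
    t = counts["t"].to_numpy(dtype=float)
    initial = n[0]
    started = np.flatnonzero(n < start_fraction * initial)
    start_idx = started[0] if len(started) else 0
    window = (np.arange(len(n)) >= start_idx) & (t > 0) & (n > 0)
    if window.sum() < 3:
        raise ValueError("fewer than 3 time points in the decay window")
    slope = np.polyfit(np.log(t[window]), np.log(n[window]), 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# phenotype dominance and parameter sensitivity
# ---------------------------------------------------------------------------


def aged_fraction_series(trajectory: Trajectory) -> pd.DataFrame:
    counts = trajectory.counts
    tot = counts.groupby("t")["n"].sum()
    aged = counts[counts["phenotype"] == "aged"].groupby("t")["n"].sum()
    frac = (aged / tot).fillna(0.0)
    return frac.reset_index().rename(columns={"n": "aged_fraction"})


def time_to_dominance(
    trajectory: Trajectory, threshold: float = 0.95, sustain: int = 100
) -> float:
    """First time the aged fraction exceeds ``threshold`` and stays above
    it for at least ``sustain`` steps; NaN if dominance is never reached."""
    frac = aged_fraction_series(trajectory)
    t = frac["t"].to_numpy()
    f = frac["aged_fraction"].to_numpy()
    above = f > threshold
    for i in np.flatnonzero(above):
        horizon = t[i] + sustain
        window = (t >= t[i]) & (t <= horizon)
        if t[-1] >= horizon and bool(np.all(above[window])):
            return float(t[i])
    return float("nan")


SWEEPABLE_PARAMETERS = ("k_m", "k_d", "d_novo0", "d_main", "eps_methyl")


def sensitivity_sweep(
    genome: Genome,
    params: RegulationParams,
    env_params: EnvironmentParams,
    arp: ARPDefinition | None,
    parameter: str,
    multipliers: list[float],
    replicates: int = 5,
    steps: int = 6000,
    seed: int = 0,
    heterogeneous: bool = False,
    **run_kwargs,
) -> pd.DataFrame:
    """Run replicate 'individuals' per parameter multiplier.

    Each replicate is an independent individual (its own seed).  With
    ``heterogeneous=True`` the multipliers are instead assigned across the
    individuals of one group (modelling inter-individual differences in,
    e.g., histone methyltransferase activity); the returned table then has
    one group with mixed multipliers, for variance comparison against an
    identical-parameter group.

    Returns one row per run: multiplier, replicate, time-to-dominance,
    final compartment sizes and aged fraction.
    """
    if parameter not in SWEEPABLE_PARAMETERS:
        raise ValueError(
            f"parameter {parameter!r} is not sweepable; choose from "
            f"{SWEEPABLE_PARAMETERS}"
        )
    base = getattr(params, parameter)
    rows = []
    if heterogeneous:
        assignments = [
            (multipliers[i % len(multipliers)], i) for i in range(replicates)
        ]
    else:
        assignments = [(m, i) for m in multipliers for i in range(replicates)]
    for mult, rep in assignments:
        p_i = params.replace(**{parameter: base * mult})
        run_seed = (
            seed * 100_003 + int(round(mult * 1000)) * 1_009 + rep
        ) % (2**31)
        traj = run_scenario(
            genome,
            p_i,
            env_params,
            arp,
            steps=steps,
            seed=run_seed,
            **run_kwargs,
        )
        final = traj.counts[traj.counts["t"] == traj.counts["t"].max()]
        n_alpha = int(final[final["env"] == "alpha"]["n"].sum())
        n_omega = int(final[final["env"] == "omega"]["n"].sum())
        n_aged = int(final[final["phenotype"] == "aged"]["n"].sum())
        total = n_alpha + n_omega
        rows.append(
            {
                "parameter": parameter,
                "multiplier": mult,
                "replicate": rep,
                "seed": run_seed,
                "time_to_dominance": time_to_dominance(traj),
                "final_n_alpha": n_alpha,
                "final_n_omega": n_omega,
                "final_total": total,
                "final_aged_fraction": n_aged / total if total else np.nan,
                "status": traj.status,
            }
        )
    return pd.DataFrame(rows)
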
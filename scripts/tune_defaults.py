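"""Select the default regulation parameters.

The chromatin-layer energies and rates are free parameters of the model; this
script is how the shipped defaults in ``RegulationParams`` were chosen, and it
can be re-run to re-derive or adjust them.  The selection criteria encode the
qualitative contracts the model must satisfy:

  A. N_H = 8 genes are bistable (bimodal stationary law) at w_BS = 1, with the
     high-modification mode dominant (stable marks in quiescent cells) but
     with mode switching on accessible time scales (reversibility).
  B. N_H in {2, 4, 6} genes are NOT bistable at w_BS = 1.
  C. Once the gene's DNA is methylated (w_BS ~ 0.4, the stationary CpG level
     under full de novo pressure), the low mode dominates strongly:
     DNA methylation locks silencing.
  D. A silenced gene's fixed-point expression falls clearly below the
     phenotype threshold TS = 2 while an active gene sits far above it.
  E. In a proliferating lineage (division every ~200 steps with histone
     dilution + replication-coupled methylation), an N_H = 8 gene silences
     only after several generations (epigenetic aging is slow), while an
     N_H = 4 gene silences within a generation or two (stem-cell markers
     are lost early).

Run:  python scripts/tune_defaults.py
"""

from __future__ import annotations

import itertools
import sys

import numpy as np

sys.path.insert(0, "src")

from epidrift.regulation import (  # noqa: E402
    RegulationParams,
    denovo_rate,
    histone_stationary_distribution,
    hmt_binding_probability,
    replicate_methylation,
    step_histones,
)

TS = 2.0
GENERATION = 200  # steps per division at the default proliferation rate


def mfpt(n_h: int, w_bs: float, p: RegulationParams, a: int, b: int) -> float:
    """Mean first-passage time a -> b of the histone birth-death chain."""
    n = np.arange(n_h + 1, dtype=float)
    theta = hmt_binding_probability(n, n_h, w_bs, p)
    birth = (n_h - n) * p.k_m * theta * p.dt
    death = n * p.k_d * p.dt
    pi, _ = histone_stationary_distribution(n_h, w_bs, p)
    if a < b:
        return float(
            sum(pi[: k + 1].sum() / (birth[k] * pi[k]) for k in range(a, b))
        )
    # downward passage: mirror formula
    return float(sum(pi[k:].sum() / (death[k] * pi[k]) for k in range(b + 1, a + 1)))


def modes(pi: np.ndarray) -> list[int]:
    out = []
    for i in range(len(pi)):
        if (i == 0 or pi[i] > pi[i - 1]) and (i == len(pi) - 1 or pi[i] > pi[i + 1]):
            out.append(i)
    return out


def silenced_expression(p: RegulationParams, w_bs: float) -> float:
    theta = hmt_binding_probability(0, 8, w_bs, p)
    return p.p_max * (p.q_p / (1 + p.q_p)) * theta / p.delta


def active_expression(p: RegulationParams) -> float:
    theta = hmt_binding_probability(8, 8, 1.0, p)
    return p.p_max * (p.q_p / (1 + p.q_p)) * theta / p.delta


def lineage_silencing_time(
    p: RegulationParams, n_h: int, n_cpg: int, rng, horizon: int = 12_000
) -> float:
    """Time until a proliferating lineage silences the gene (inf if never).

    Silencing = fixed-point expression below TS, sustained one generation.
    """
    n_hm = n_h
    meth = np.zeros(n_cpg, dtype=bool)
    next_div = rng.exponential(GENERATION)
    below_since = None
    for t in range(horizon):
        w = float(np.mean(~meth))
        theta = hmt_binding_probability(n_hm, n_h, w, p)
        n_hm = step_histones(n_hm, n_h, theta, p, rng)
        e_fp = p.p_max * (p.q_p / (1 + p.q_p)) * theta / p.delta
        if e_fp < TS:
            if below_since is None:
                below_since = t
            elif t - below_since >= GENERATION:
                return float(below_since)
        else:
            below_since = None
        if t >= next_div:
            n_hm = int(rng.binomial(n_hm, 0.5))
            d = denovo_rate(n_hm, n_h, p)
            meth = replicate_methylation(meth, d, p, rng)
            next_div = t + rng.exponential(GENERATION)
    return np.inf


def scan() -> None:
    grid = itertools.product(
        [6.0, 7.0, 8.0, 9.0],          # eps_0
        [1.0, 1.5, 2.0, 2.5, 3.0],     # eps_bs
        [0.6, 0.8, 1.0, 1.2],          # eps_hm (per modified nucleosome)
        [0.1, 0.2, 0.4],               # k_m
        [0.02, 0.05, 0.1],             # k_d
    )
    candidates = []
    for eps_0, eps_bs, eps_hm, k_m, k_d in grid:
        p = RegulationParams(
            eps_0=eps_0, eps_bs=eps_bs, eps_hm=eps_hm, k_m=k_m, k_d=k_d
        )
        pi8, bi8 = histone_stationary_distribution(8, 1.0, p)
        if not bi8:
            continue
        if any(histone_stationary_distribution(nh, 1.0, p)[1] for nh in (2, 4, 6)):
            continue
        high_mass = pi8[5:].sum()
        if high_mass < 0.75:  # A: marks stable in quiescent cells
            continue
        pi8m, _ = histone_stationary_distribution(8, 0.4, p)
        if pi8m[:3].sum() < 0.90:  # C: methylation locks silencing
            continue
        if silenced_expression(p, 0.4) > 0.6 * TS:  # D
            continue
        if active_expression(p) < 50 * TS:
            continue
        t_dn = mfpt(8, 1.0, p, 7, 1)  # escape from the high mode
        t_up = mfpt(8, 1.0, p, 0, 6)  # recovery from the low mode
        if not (1_500 <= t_dn <= 1e6 and t_up <= 5_000):
            continue
        candidates.append((p, high_mass, t_dn, t_up))

    print(f"{len(candidates)} candidates pass the analytic screen")
    rng = np.random.default_rng(0)
    for p, high_mass, t_dn, t_up in candidates:
        t8 = np.array(
            [lineage_silencing_time(p, 8, 18, rng) for _ in range(24)]
        )
        t4 = np.array(
            [lineage_silencing_time(p, 4, 10, rng) for _ in range(24)]
        )
        med8 = float(np.median(t8))
        med4 = float(np.median(t4))
        frac8 = float(np.mean(np.isfinite(t8)))
        print(
            f"e0={p.eps_0} eBS={p.eps_bs} eHM={p.eps_hm} kM={p.k_m} kD={p.k_d} "
            f"| hi-mass={high_mass:.2f} T(hi->lo)={t_dn:,.0f} T(lo->hi)={t_up:,.0f} "
            f"| med T_sil(NH=8)={med8:,.0f} (frac {frac8:.2f}) med T_sil(NH=4)={med4:,.0f}"
        )


if __name__ == "__main__":
    scan()
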
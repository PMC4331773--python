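"""Per-gene regulatory kernels: transcription, H3K4me3 dynamics, DNA methylation.

The model couples three layers per gene:

1. **Transcription** — deterministic relaxation
   ``de/dt = P_max * theta_pro * Theta - delta * e`` integrated with an
   explicit Euler step; ``theta_pro`` is the thermodynamic polymerase-II
   promoter occupancy set by the TF network, ``Theta`` the binding
   probability of the H3K4 methyltransferase complex.

2. **Histone modification** — each gene's ``N_H`` cooperative nucleosomes
   carry a binary H3K4me3 mark.  Per time step, every unmodified nucleosome
   gains the mark with probability ``k_M * Theta * dt`` and every modified
   one loses it with probability ``k_D * dt``.  ``Theta`` follows a two-state
   Boltzmann (logistic) form

   ``Theta = 1 / (1 + exp(eps_0 - w_BS * eps_BS - n_HM * eps_HM))``

   where ``w_BS`` is the fraction of unmethylated CpGs (DNA binding sites)
   and ``eps_HM`` the binding free-enthalpy gain contributed by *each*
   modified nucleosome.  Energies are entered favorable-positive: larger
   ``eps_HM`` strengthens the positive read-write feedback.  Because every
   modified nucleosome contributes, the total feedback energy a gene can
   muster grows with ``N_H`` — which is exactly why bistability appears
   only above a threshold nucleosome count (see ``docs/methods.md``).

3. **DNA methylation** — changes only at replication.  A methylated CpG is
   maintained with probability ``D_main``; an unmethylated one is methylated
   de novo with probability
   ``D_novo = D_novo0 * exp(-eps_methyl * n_HM / N_H)``:
   H3K4me3 repels the de novo methyltransferase, so a fully modified gene is
   protected and a fully unmodified one is methylated at the full rate.

All kernels are vectorized: scalar arguments give scalars, array arguments
(cells x genes) give arrays drawn element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy.special import expit

from .genome import Gene, Genome

__all__ = [
    "RegulationParams",
    "ChromatinState",
    "unmethylated_fraction",
    "hmt_binding_probability",
    "step_histones",
    "histone_stationary_distribution",
    "denovo_rate",
    "replicate_methylation",
    "step_expression",
    "promoter_occupancy",
    "interaction_matrices",
]


@dataclass
class RegulationParams:
    """Parameters of the regulatory layers (rates are per ``dt``).

    The defaults were fixed once with ``scripts/tune_defaults.py`` so that,
    at these energies, genes with 8 cooperative nucleosomes are bistable
    while genes with 6 or fewer are not, reproducing the
    C3 < 1 <= C2 <= 6 < C1 class boundary; see ``docs/methods.md``.
    """

    p_max: float = 1000.0  #: maximum promoter activity
    delta: float = 0.2  #: expression degradation rate per dt
    k_m: float = 0.4  #: histone modification rate per nucleosome per dt
    k_d: float = 0.02  #: histone de-modification rate per nucleosome per dt
    eps_0: float = 8.0  #: ground enthalpy per bound HMT complex
    eps_bs: float = 2.0  #: free-enthalpy gain of DNA (unmethylated CpG) binding
    eps_hm: float = 1.0  #: free-enthalpy gain per H3K4me3-modified nucleosome
    d_main: float = 0.8  #: maintenance methylation probability at division
    d_novo0: float = 0.3  #: de novo methylation constant (fully unmodified gene)
    eps_methyl: float = 6.0  #: DNMT / modified-nucleosome repulsion energy
    q_p: float = 0.1  #: basal polymerase-II statistical weight
    dt: float = 1.0  #: computational time step

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        errors = []
        if not self.p_max > 0:
            errors.append("p_max must be > 0")
        if not self.delta > 0:
            errors.append("delta must be > 0")
        if not 0.0 <= self.k_m * self.dt <= 1.0:
            errors.append("k_m * dt must lie in [0, 1]")
        if not 0.0 <= self.k_d * self.dt <= 1.0:
            errors.append("k_d * dt must lie in [0, 1]")
        if not 0.0 <= self.d_main <= 1.0:
            errors.append("d_main must lie in [0, 1]")
        if not 0.0 <= self.d_novo0 <= 1.0:
            errors.append("d_novo0 must lie in [0, 1]")
        if self.delta * self.dt >= 1.0:
            errors.append("delta * dt must be < 1 (Euler stability)")
        if self.q_p <= 0:
            errors.append("q_p must be > 0")
        if errors:
            raise ValueError("; ".join(errors))

    def replace(self, **kw) -> "RegulationParams":
        return dc_replace(self, **kw)


@dataclass
class ChromatinState:
    """Chromatin state of one gene in one cell."""

    n_hm: int
    n_h: int
    cpg_meth: np.ndarray  # boolean vector over the gene's CpG positions

    def __post_init__(self) -> None:
        self.cpg_meth = np.asarray(self.cpg_meth, dtype=bool)
        if not 0 <= self.n_hm <= max(self.n_h, 0):
            raise ValueError("n_hm must lie in [0, N_H]")


def unmethylated_fraction(cpg_meth: np.ndarray | ChromatinState) -> float:
    """Fraction of unmethylated CpGs, w_BS; 0 for genes without CpGs.

    A gene without CpGs offers no DNA binding sites, so its w_BS is defined
    as 0 (documented convention).
    """
    if isinstance(cpg_meth, ChromatinState):
        cpg_meth = cpg_meth.cpg_meth
    cpg_meth = np.asarray(cpg_meth, dtype=bool)
    if cpg_meth.size == 0:
        return 0.0
    return float(np.mean(~cpg_meth))


def hmt_binding_probability(n_hm, n_h, w_bs, p: RegulationParams):
    """Binding probability Theta of the histone-methyltransferase complex.

    Two-state Boltzmann form, strictly increasing in both the modified
    nucleosome count ``n_hm`` and the unmethylated-CpG fraction ``w_bs``;
    each modified nucleosome contributes ``eps_hm`` to the binding free
    enthalpy.  Genes without nucleosomes (``n_h == 0``) have nothing to
    recruit to and get Theta = 0.
    """
    n_hm = np.asarray(n_hm, dtype=float)
    n_h_arr = np.asarray(n_h, dtype=float)
    w_bs = np.asarray(w_bs, dtype=float)
    theta = expit(-p.eps_0 + w_bs * p.eps_bs + n_hm * p.eps_hm)
    theta = np.where(n_h_arr > 0, theta, 0.0)
    return float(theta) if theta.ndim == 0 else theta


def step_histones(n_hm, n_h, theta, p: RegulationParams, rng: np.random.Generator):
    """One stochastic (de-)modification step of the cooperative nucleosomes.

    Each unmodified nucleosome gains the mark with probability
    ``k_M * Theta * dt``, each modified one loses it with ``k_D * dt``.
    """
    n_hm = np.asarray(n_hm, dtype=np.int64)
    n_h = np.asarray(n_h, dtype=np.int64)
    p_gain = np.asarray(p.k_m * p.dt * np.asarray(theta, dtype=float))
    if np.any(p_gain > 1.0) or p.k_d * p.dt > 1.0:
        raise ValueError("per-step (de-)modification probability exceeds 1")
    gains = rng.binomial(n_h - n_hm, p_gain)
    losses = rng.binomial(n_hm, p.k_d * p.dt)
    out = n_hm + gains - losses
    return int(out) if out.ndim == 0 else out


def histone_stationary_distribution(
    n_h: int, w_bs: float, p: RegulationParams
) -> tuple[np.ndarray, bool]:
    """Exact stationary law of the (N_H + 1)-state histone birth-death chain.

    Returns the probability vector over ``n_HM in {0..N_H}`` and a flag for
    bimodality (two local maxima, boundaries included).  Uses the
    detailed-balance product form of birth-death chains, evaluated in log
    space for robustness.
    """
    if n_h < 1:
        raise ValueError("n_h must be >= 1")
    n = np.arange(n_h + 1, dtype=float)
    theta = hmt_binding_probability(n, n_h, w_bs, p)
    birth = (n_h - n) * p.k_m * theta * p.dt  # rate 0 at n = N_H
    death = n * p.k_d * p.dt
    with np.errstate(divide="ignore"):
        log_ratio = np.log(birth[:-1]) - np.log(death[1:])
    log_pi = np.concatenate([[0.0], np.cumsum(log_ratio)])
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    pi /= pi.sum()
    return pi, _is_bimodal(pi)


def _is_bimodal(pi: np.ndarray, rel_tol: float = 1e-9) -> bool:
    """Two or more local maxima of a discrete distribution (boundaries count)."""
    n = len(pi)
    maxima = 0
    for i in range(n):
        left_ok = i == 0 or pi[i] > pi[i - 1] * (1 + rel_tol)
        right_ok = i == n - 1 or pi[i] > pi[i + 1] * (1 + rel_tol)
        if left_ok and right_ok:
            maxima += 1
    return maxima >= 2


def denovo_rate(n_hm, n_h, p: RegulationParams):
    """De novo methylation probability, suppressed by H3K4me3.

    ``D_novo = D_novo0 * exp(-eps_methyl * n_HM / N_H)``, clipped to [0, 1].
    Genes without nucleosomes use ``D_novo0`` directly (no protective mark
    exists).
    """
    n_hm = np.asarray(n_hm, dtype=float)
    n_h_arr = np.asarray(n_h, dtype=float)
    x = np.where(n_h_arr > 0, n_hm / np.maximum(n_h_arr, 1), 0.0)
    d = np.clip(p.d_novo0 * np.exp(-p.eps_methyl * x), 0.0, 1.0)
    return float(d) if d.ndim == 0 else d


def replicate_methylation(
    cpg_meth: np.ndarray, d_novo, p: RegulationParams, rng: np.random.Generator
) -> np.ndarray:
    """Methylation transition at cell division (the only time CpGs change).

    Independently per CpG: methylated stays methylated with probability
    ``D_main``; unmethylated becomes methylated with probability ``d_novo``.
    """
    cpg_meth = np.asarray(cpg_meth, dtype=bool)
    u = rng.random(cpg_meth.shape)
    return np.where(cpg_meth, u < p.d_main, u < np.asarray(d_novo))


def step_expression(e, theta_pro, theta, p: RegulationParams):
    """Explicit-Euler step of ``de/dt = P_max * theta_pro * Theta - delta * e``."""
    e = np.asarray(e, dtype=float)
    out = e + (p.p_max * np.asarray(theta_pro) * np.asarray(theta) - p.delta * e) * p.dt
    return float(out) if out.ndim == 0 else out


def expression_fixed_point(theta_pro, theta, p: RegulationParams):
    """Fixed point ``e* = P_max * theta_pro * Theta / delta`` of the Euler map."""
    out = p.p_max * np.asarray(theta_pro, dtype=float) * np.asarray(theta) / p.delta
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# promoter occupancy (thermodynamic TF-network layer)
# ---------------------------------------------------------------------------


def interaction_matrices(genome: Genome) -> tuple[np.ndarray, np.ndarray]:
    """Dense activator / repressor weight matrices W[i, j] for j -> i."""
    n = genome.n_genes
    w_act = np.zeros((n, n))
    w_rep = np.zeros((n, n))
    for g in genome.genes:
        for it in g.interactions:
            if it.sign == "activating":
                w_act[g.id, it.regulator] += it.weight
            else:
                w_rep[g.id, it.regulator] += it.weight
    return w_act, w_rep


def occupancy_from_sums(act_sum, rep_sum, p: RegulationParams):
    """Thermodynamic promoter occupancy from activator / repressor sums.

    ``theta_pro = q_P (1 + A) / (1 + R + q_P (1 + A))`` with A and R the
    expression-weighted activator and repressor sums.  Monotone increasing in
    A, decreasing in R, always in (0, 1); without interactions it reduces to
    the basal value ``q_P / (1 + q_P)``.
    """
    act_sum = np.asarray(act_sum, dtype=float)
    rep_sum = np.asarray(rep_sum, dtype=float)
    num = p.q_p * (1.0 + act_sum)
    theta = num / (1.0 + rep_sum + num)
    return float(theta) if theta.ndim == 0 else theta


def promoter_occupancy(gene: Gene, expression: np.ndarray, p: RegulationParams):
    """Polymerase-II occupancy of one gene's promoter given all expressions.

    Expression levels are normalized to ``e * delta / P_max`` (so a maximally
    expressed gene contributes weight ~1 per site) before entering the
    statistical weights.
    """
    e_norm = np.asarray(expression, dtype=float) * p.delta / p.p_max
    a = sum(
        it.weight * e_norm[it.regulator]
        for it in gene.interactions
        if it.sign == "activating"
    )
    r = sum(
        it.weight * e_norm[it.regulator]
        for it in gene.interactions
        if it.sign == "repressing"
    )
    return occupancy_from_sums(a, r, p)
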
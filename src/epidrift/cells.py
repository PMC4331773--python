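"""Individual-cell state and dynamics.

A cell carries, per gene of the shared artificial genome: an expression
level, the count of H3K4me3-modified nucleosomes, and the methylation state
of every CpG.  Cells additionally know their environment (niche ``alpha`` vs
proliferative ``omega``), clone barcode, generation (division count),
phenotype (young vs aged) and their progress toward the next division.

Time advances in discrete steps ``dt``.  Within a step the update order is
fixed: unmethylated-CpG fractions, methyltransferase binding probabilities,
stochastic histone (de-)modification, promoter occupancies from the current
expression vector, and finally the Euler expression update.  DNA methylation
is never touched here — CpGs change at replication only.

Division halves the modified-nucleosome pool binomially between the
daughters (replication-coupled histone dilution); the vacated positions are
filled by new, unmodified nucleosomes.  Each daughter's CpG states are then
redrawn with maintenance probability ``D_main`` and a de novo probability
evaluated from that daughter's *post-partition* modification state — the
dilution is what opens the time window for DNA methylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import Genome
from .regulation import (
    RegulationParams,
    denovo_rate,
    histone_stationary_distribution,
    hmt_binding_probability,
    interaction_matrices,
    occupancy_from_sums,
    replicate_methylation,
    step_expression,
    step_histones,
)

ALPHA, OMEGA = "alpha", "omega"


@dataclass
class ARPDefinition:
    """Definition of the age-related phenotype (ARP).

    A cell is *aged* while the mean expression of the three marker genes is
    strictly below the transcription threshold ``ts``; the evaluation is
    repeated every step, so phenotype switches are reversible.  The
    parameter multipliers are applied to aged cells only.
    """

    marker_gene_ids: tuple[int, int, int]
    ts: float = 2.0
    q0_mult: float = 1.0
    r_mult: float = 1.0
    rho_alpha_mult: float = 1.0
    rho_omega_mult: float = 1.0

    def validate_markers(self, genome: Genome, params: RegulationParams) -> None:
        """Markers must be bistable (C1a-capable) genes of the genome."""
        if len(self.marker_gene_ids) != 3:
            raise ValueError("exactly 3 marker genes are required")
        for gid in self.marker_gene_ids:
            gene = genome.genes[gid]
            if gene.id != gid:
                raise ValueError("genome gene ids must be positional")
            if gene.n_h < 1:
                raise ValueError(f"marker gene {gid} has no nucleosomes")
            _, bimodal = histone_stationary_distribution(gene.n_h, 1.0, params)
            if not bimodal:
                raise ValueError(
                    f"marker gene {gid} (N_H={gene.n_h}) is not bistable"
                )


@dataclass
class CellState:
    """Full regulatory and bookkeeping state of one cell."""

    expression: np.ndarray  # e_i >= 0 per gene
    n_hm: np.ndarray  # modified nucleosomes per gene
    cpg_meth: np.ndarray  # flat boolean vector over all genes' CpGs
    environment: str = ALPHA
    clone_id: int = 0
    generation: int = 0
    phenotype: str = "young"
    division_progress: float = 0.0

    def copy(self) -> "CellState":
        return CellState(
            expression=self.expression.copy(),
            n_hm=self.n_hm.copy(),
            cpg_meth=self.cpg_meth.copy(),
            environment=self.environment,
            clone_id=self.clone_id,
            generation=self.generation,
            phenotype=self.phenotype,
            division_progress=self.division_progress,
        )


class GenomeTables:
    """Precomputed per-genome arrays shared by all cells (pure cache)."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self.n_genes = genome.n_genes
        self.n_h = np.array([g.n_h for g in genome.genes], dtype=np.int64)
        self.cpg_counts = np.array([g.n_cpg for g in genome.genes], dtype=np.int64)
        self.cpg_offsets = np.concatenate([[0], np.cumsum(self.cpg_counts)])
        self.total_cpgs = int(self.cpg_offsets[-1])
        self.w_act, self.w_rep = interaction_matrices(genome)
        self.has_nuc = self.n_h > 0

    def unmethylated_fraction(self, cpg_meth: np.ndarray) -> np.ndarray:
        """Per-gene w_BS from the flat CpG vector(s); 0 for CpG-free genes.

        Accepts a 1-d vector (one cell) or a (cells x total_cpgs) matrix.
        """
        meth = np.atleast_2d(np.asarray(cpg_meth, dtype=bool))
        if self.total_cpgs == 0:
            w = np.zeros((meth.shape[0], self.n_genes))
        else:
            sums = np.add.reduceat(meth, self.cpg_offsets[:-1], axis=1)
            with np.errstate(invalid="ignore"):
                w = 1.0 - sums / np.maximum(self.cpg_counts, 1)
            w[:, self.cpg_counts == 0] = 0.0
        return w[0] if np.asarray(cpg_meth).ndim == 1 else w

    def gene_slice(self, gene_id: int) -> slice:
        return slice(int(self.cpg_offsets[gene_id]), int(self.cpg_offsets[gene_id + 1]))


def transcription_theta(theta: np.ndarray, tables: GenomeTables) -> np.ndarray:
    """Theta as it enters transcription: nucleosome-free (C3) genes are
    fully permissive (Theta = 1) since no chromatin layer gates them."""
    return np.where(tables.has_nuc, theta, 1.0)


def promoter_occupancies(
    expression: np.ndarray, tables: GenomeTables, p: RegulationParams
) -> np.ndarray:
    """Vectorized thermodynamic promoter occupancy for all genes (and cells)."""
    e_norm = np.asarray(expression, dtype=float) * p.delta / p.p_max
    act = e_norm @ tables.w_act.T
    rep = e_norm @ tables.w_rep.T
    return occupancy_from_sums(act, rep, p)


def initial_cell(
    genome: Genome | GenomeTables,
    p: RegulationParams,
    clone_id: int = 0,
    environment: str = ALPHA,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> CellState:
    """The canonical initial state: all histones modified, all CpGs
    unmethylated, expression at the fixed point of the coupled
    transcription system under those chromatin states.

    The fixed point is found by iterating the coupled map
    ``e <- P_max * theta_pro(e) * Theta / delta`` to tolerance.
    """
    tables = genome if isinstance(genome, GenomeTables) else GenomeTables(genome)
    n_hm = tables.n_h.copy()
    cpg_meth = np.zeros(tables.total_cpgs, dtype=bool)
    w = tables.unmethylated_fraction(cpg_meth)
    theta = hmt_binding_probability(n_hm, tables.n_h, w, p)
    theta_t = transcription_theta(theta, tables)

    e = np.zeros(tables.n_genes)
    for _ in range(max_iter):
        theta_pro = promoter_occupancies(e, tables, p)
        e_next = p.p_max * theta_pro * theta_t / p.delta
        if np.max(np.abs(e_next - e)) <= tol * max(1.0, np.max(np.abs(e_next))):
            e = e_next
            break
        e = e_next
    else:
        raise RuntimeError(
            "initial expression fixed-point iteration did not converge "
            f"(last max change {np.max(np.abs(e_next - e)):.3g})"
        )
    return CellState(
        expression=e,
        n_hm=n_hm,
        cpg_meth=cpg_meth,
        environment=environment,
        clone_id=clone_id,
    )


def step_cell(
    c: CellState,
    tables: GenomeTables,
    p: RegulationParams,
    rng: np.random.Generator,
) -> CellState:
    """Advance one cell by one time step (in place; returns the cell).

    DNA methylation is untouched — it changes at replication only.
    """
    w = tables.unmethylated_fraction(c.cpg_meth)
    theta = hmt_binding_probability(c.n_hm, tables.n_h, w, p)
    c.n_hm = step_histones(c.n_hm, tables.n_h, theta, p, rng)
    theta_pro = promoter_occupancies(c.expression, tables, p)
    c.expression = step_expression(
        c.expression, theta_pro, transcription_theta(theta, tables), p
    )
    return c


def partition_histones(
    n_hm: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random symmetric partition of modified nucleosomes onto daughters."""
    d1 = rng.binomial(np.asarray(n_hm, dtype=np.int64), 0.5)
    return d1, np.asarray(n_hm) - d1


def daughter_methylation(
    cpg_meth: np.ndarray,
    daughter_n_hm: np.ndarray,
    tables: GenomeTables,
    p: RegulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Replicate the CpG states for one daughter.

    The de novo probability is evaluated per gene from the daughter's
    post-partition modification state and broadcast over its CpGs.
    """
    d_novo = denovo_rate(daughter_n_hm, tables.n_h, p)
    per_cpg = np.repeat(d_novo, tables.cpg_counts)
    return replicate_methylation(cpg_meth, per_cpg, p, rng)


def attempt_division(
    c: CellState,
    r: float,
    tables: GenomeTables,
    p: RegulationParams,
    rng: np.random.Generator,
) -> tuple[CellState, CellState] | None:
    """Accumulate division progress; on crossing 1, produce two daughters.

    Progress grows by a Bernoulli unit increment with mean ``r * dt`` per
    step — a constant division hazard, so inter-division times are
    geometric with mean ``1 / r`` steps.  (A memoryless hazard, rather than
    a quasi-deterministic timer, is what keeps the stationary omega
    occupancy at the mean-field value R / q0 in the presence of
    differentiation; see docs/methods.md.)  Division is a contract
    violation in the niche (cells there are quiescent).
    """
    if c.environment != OMEGA:
        raise ValueError("attempt_division called on a quiescent (niche) cell")
    if r > 0 and rng.random() < r * p.dt:
        c.division_progress += 1.0
    if c.division_progress < 1.0:
        return None
    n1, n2 = partition_histones(c.n_hm, rng)
    daughters = []
    for n_d in (n1, n2):
        d = c.copy()
        d.n_hm = n_d
        d.cpg_meth = daughter_methylation(c.cpg_meth, n_d, tables, p, rng)
        d.generation = c.generation + 1
        d.division_progress = 0.0
        daughters.append(d)
    return daughters[0], daughters[1]


def evaluate_phenotype(c: CellState, arp: ARPDefinition | None) -> str:
    """Aged iff the mean expression of the marker genes is strictly below
    TS (a mean exactly at TS counts as young).  Without an ARP definition
    every cell is young."""
    if arp is None:
        return "young"
    mean_marker = float(np.mean(c.expression[list(arp.marker_gene_ids)]))
    c.phenotype = "aged" if mean_marker < arp.ts else "young"
    return c.phenotype
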
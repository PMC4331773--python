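"""Two-compartment stem-cell population dynamics.

Cells live in one of two environments: the niche ``alpha`` where they are
quiescent (zero proliferation), and ``omega`` where they proliferate with
rate ``R`` and differentiate (leave the system) with rate ``q = q0 * N_omega``.
Exchange between the compartments follows crowding-coupled probabilities

* ``P_alpha = rho_alpha * N_alpha`` per niche cell per step — a full niche
  pushes cells out;
* ``P_omega = rho_omega / N_omega`` per omega cell per step — the total
  inflow into the niche, ``P_omega * N_omega = rho_omega``, is constant as
  long as omega is populated.

In a stationary state these rates give the closed forms
``N_alpha* = sqrt(rho_omega / rho_alpha)`` and ``N_omega* = R / q0``.

When an age-related phenotype (ARP) is active, aged cells carry their own
multipliers on ``rho_alpha``, ``rho_omega``, ``R`` and ``q0`` and the
exchange balance is evaluated per phenotype in parallel.  Crowding terms
couple through *totals*: ``P_alpha`` scales with the total niche occupancy
(aged cells that accumulate in the niche push young cells out of it) and
the differentiation pressure scales with the total omega occupancy, while
each phenotype maintains its own constant niche inflow.

The per-step update order is fixed and config-stamped: (1) intracellular
dynamics for all cells, (2) phenotype evaluation, (3) niche exits, (4)
niche entries, (5) divisions in omega, (6) differentiation removals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .cells import (
    ALPHA,
    OMEGA,
    ARPDefinition,
    CellState,
    GenomeTables,
    initial_cell,
    promoter_occupancies,
    transcription_theta,
)
from .genome import Genome
from .regulation import (
    RegulationParams,
    denovo_rate,
    hmt_binding_probability,
    replicate_methylation,
    step_expression,
)

__all__ = [
    "EnvironmentParams",
    "PopulationState",
    "PopulationExtinct",
    "Trajectory",
    "transition_probabilities",
    "stationary_cell_numbers",
    "step_population",
    "run_scenario",
    "cell_table",
]


@dataclass
class EnvironmentParams:
    """Niche / proliferation rates (all per cell per step unless noted).

    Defaults give the reduced-scale stationary system
    ``N_alpha* = sqrt(0.1 / 0.001) = 10`` and ``N_omega* = 0.005 / 0.0005
    = 10`` with a mean inter-division time of 200 steps (~1 generation).
    """

    rho_alpha: float = 0.001  #: niche-exit coefficient (per niche cell)
    rho_omega: float = 0.1  #: total niche inflow (cells per step)
    r: float = 0.005  #: proliferation rate in omega
    q0: float = 0.0005  #: differentiation coefficient (per omega cell)

    def __post_init__(self) -> None:
        if min(self.rho_alpha, self.rho_omega, self.r, self.q0) < 0:
            raise ValueError("environment rates must be non-negative")

    def replace(self, **kw) -> "EnvironmentParams":
        return dc_replace(self, **kw)


class PopulationExtinct(RuntimeError):
    """The population died out; the simulation halts with this status."""


def transition_probabilities(
    n_alpha: int,
    n_omega: int,
    ep: EnvironmentParams,
    rho_alpha_mult: float = 1.0,
    rho_omega_mult: float = 1.0,
) -> tuple[float, float, int]:
    """Per-cell exchange probabilities (P_alpha, P_omega) plus clip count.

    ``P_omega`` is defined as 0 when omega is empty.  Probabilities are
    clipped to [0, 1]; the number of clipping events is returned as a
    parameter-health diagnostic.
    """
    p_alpha = ep.rho_alpha * rho_alpha_mult * n_alpha
    p_omega = ep.rho_omega * rho_omega_mult / n_omega if n_omega >= 1 else 0.0
    clips = int(p_alpha > 1.0) + int(p_omega > 1.0)
    return min(max(p_alpha, 0.0), 1.0), min(max(p_omega, 0.0), 1.0), clips


def stationary_cell_numbers(
    ep: EnvironmentParams,
    rho_alpha_mult: float = 1.0,
    rho_omega_mult: float = 1.0,
) -> tuple[float, float]:
    """Mean-field stationary compartment sizes.

    ``N_alpha* = sqrt(rho_omega / rho_alpha)``; ``N_omega* = R / q0``.
    """
    ra = ep.rho_alpha * rho_alpha_mult
    ro = ep.rho_omega * rho_omega_mult
    if min(ra, ro, ep.r, ep.q0) <= 0:
        raise ValueError("stationary sizes undefined for zero rates")
    return float(np.sqrt(ro / ra)), ep.r / ep.q0


class PopulationState:
    """The set of cells at time t, stored as flat arrays for speed.

    Row order is the (deterministic) cell order; every stochastic update
    draws in this order from a single generator, so identical (config,
    seed) produce identical trajectories.
    """

    def __init__(
        self,
        genome: Genome,
        params: RegulationParams,
        env_params: EnvironmentParams,
        arp: ARPDefinition | None = None,
        rng: np.random.Generator | None = None,
        force_phenotype: str | None = None,
    ):
        self.tables = GenomeTables(genome)
        self.params = params
        self.env_params = env_params
        self.arp = arp
        if arp is not None:
            arp.validate_markers(genome, params)
        if force_phenotype not in (None, "young", "aged"):
            raise ValueError("force_phenotype must be None, 'young' or 'aged'")
        self.force_phenotype = force_phenotype
        self.rng = rng if rng is not None else np.random.default_rng()
        self.t = 0
        self.clip_events = 0
        g = self.tables.n_genes
        self.e = np.zeros((0, g))
        self.n_hm = np.zeros((0, g), dtype=np.int64)
        self.meth = np.zeros((0, self.tables.total_cpgs), dtype=bool)
        self.env = np.zeros(0, dtype=np.int8)  # 0 = alpha, 1 = omega
        self.clone = np.zeros(0, dtype=np.int64)
        self.generation = np.zeros(0, dtype=np.int64)
        self.aged = np.zeros(0, dtype=bool)
        self.progress = np.zeros(0, dtype=float)
        # per-step bookkeeping (births - removals +/- transfers)
        self.last_births = 0
        self.last_removals = 0
        self.last_transfers_out = 0
        self.last_transfers_in = 0

    # -- construction ------------------------------------------------------

    def seed_cells(self, n_alpha: int, n_omega: int, n_clones: int | None = None):
        """Populate with identical initial cells, uniquely barcoded.

        All cells start in the canonical initial state (histones fully
        modified, DNA unmethylated, expression at its fixed point).  Each
        cell receives its own clone barcode unless ``n_clones`` caps them.
        """
        proto = initial_cell(self.tables, self.params)
        n = n_alpha + n_omega
        self.e = np.tile(proto.expression, (n, 1))
        self.n_hm = np.tile(proto.n_hm, (n, 1))
        self.meth = np.zeros((n, self.tables.total_cpgs), dtype=bool)
        self.env = np.array([0] * n_alpha + [1] * n_omega, dtype=np.int8)
        clones = np.arange(n) % (n_clones if n_clones else n)
        self.clone = clones.astype(np.int64)
        self.generation = np.zeros(n, dtype=np.int64)
        self.aged = np.zeros(n, dtype=bool)
        self.progress = np.zeros(n, dtype=float)
        return self

    # -- views -------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.env)

    @property
    def n_alpha(self) -> int:
        return int(np.sum(self.env == 0))

    @property
    def n_omega(self) -> int:
        return int(np.sum(self.env == 1))

    def counts(self) -> dict[str, int]:
        a, o = self.env == 0, self.env == 1
        return {
            "alpha_young": int(np.sum(a & ~self.aged)),
            "alpha_aged": int(np.sum(a & self.aged)),
            "omega_young": int(np.sum(o & ~self.aged)),
            "omega_aged": int(np.sum(o & self.aged)),
        }

    @property
    def cells(self) -> list[CellState]:
        """Materialize per-cell views (for inspection and small exports)."""
        out = []
        for i in range(self.n_cells):
            out.append(
                CellState(
                    expression=self.e[i].copy(),
                    n_hm=self.n_hm[i].copy(),
                    cpg_meth=self.meth[i].copy(),
                    environment=ALPHA if self.env[i] == 0 else OMEGA,
                    clone_id=int(self.clone[i]),
                    generation=int(self.generation[i]),
                    phenotype="aged" if self.aged[i] else "young",
                    division_progress=float(self.progress[i]),
                )
            )
        return out

    # -- helpers -----------------------------------------------------------

    def _aged_mult(self, attr: str) -> np.ndarray:
        """Per-cell multiplier for a rate, 1 for young cells."""
        if self.arp is None:
            return np.ones(self.n_cells)
        m = getattr(self.arp, attr)
        return np.where(self.aged, m, 1.0)

    def _delete(self, mask: np.ndarray) -> None:
        keep = ~mask
        self.e = self.e[keep]
        self.n_hm = self.n_hm[keep]
        self.meth = self.meth[keep]
        self.env = self.env[keep]
        self.clone = self.clone[keep]
        self.generation = self.generation[keep]
        self.aged = self.aged[keep]
        self.progress = self.progress[keep]

    # -- the update --------------------------------------------------------

    def step(self) -> "PopulationState":
        """Advance the whole population by one time step (fixed order)."""
        if self.n_cells == 0:
            raise PopulationExtinct(f"population extinct at t={self.t}")
        p, ep, tables, rng = self.params, self.env_params, self.tables, self.rng
        n = self.n_cells

        # (1) intracellular dynamics (all cells; methylation untouched)
        w = tables.unmethylated_fraction(self.meth)
        theta = hmt_binding_probability(self.n_hm, tables.n_h, w, p)
        gains = rng.binomial(tables.n_h - self.n_hm, p.k_m * p.dt * theta)
        losses = rng.binomial(self.n_hm, p.k_d * p.dt)
        self.n_hm = self.n_hm + gains - losses
        theta_pro = promoter_occupancies(self.e, tables, p)
        self.e = step_expression(
            self.e, theta_pro, transcription_theta(theta, tables), p
        )

        # (2) phenotype evaluation (continuous, hence reversible)
        if self.force_phenotype is not None:
            self.aged = np.full(n, self.force_phenotype == "aged")
        elif self.arp is not None:
            markers = list(self.arp.marker_gene_ids)
            self.aged = self.e[:, markers].mean(axis=1) < self.arp.ts
        else:
            self.aged = np.zeros(n, dtype=bool)

        # (3) niche exits: alpha -> omega, pressure from total niche crowding
        in_alpha = self.env == 0
        n_alpha = int(in_alpha.sum())
        p_exit = ep.rho_alpha * self._aged_mult("rho_alpha_mult") * n_alpha * p.dt
        self.clip_events += int(np.sum(p_exit > 1.0))
        exits = in_alpha & (rng.random(n) < np.clip(p_exit, 0.0, 1.0))
        self.env[exits] = 1
        self.last_transfers_out = int(exits.sum())

        # (4) niche entries: omega -> alpha, constant inflow per phenotype
        in_omega = self.env == 1
        p_entry = np.zeros(n)
        for aged_flag in (False, True):
            grp = in_omega & (self.aged == aged_flag)
            n_grp = int(grp.sum())
            if n_grp == 0:
                continue
            mult = (
                self.arp.rho_omega_mult if (self.arp is not None and aged_flag) else 1.0
            )
            p_entry[grp] = ep.rho_omega * mult / n_grp * p.dt
        self.clip_events += int(np.sum(p_entry > 1.0))
        entries = in_omega & (rng.random(n) < np.clip(p_entry, 0.0, 1.0))
        self.env[entries] = 0
        self.last_transfers_in = int(entries.sum())

        # (5) divisions in omega (histone dilution + methylation replication)
        # constant per-step division hazard r_eff (memoryless timer)
        in_omega = self.env == 1
        r_eff = ep.r * self._aged_mult("r_mult") * p.dt
        inc = np.where(in_omega & (rng.random(n) < r_eff), 1.0, 0.0)
        self.progress = self.progress + inc
        dividers = np.flatnonzero(in_omega & (self.progress >= 1.0))
        self.last_births = len(dividers)
        if len(dividers):
            new_rows = []
            for i in dividers:
                n1 = rng.binomial(self.n_hm[i], 0.5)
                n2 = self.n_hm[i] - n1
                m1 = self._replicate_row(self.meth[i], n1, rng)
                m2 = self._replicate_row(self.meth[i], n2, rng)
                gen = self.generation[i] + 1
                # mother row becomes daughter 1; daughter 2 is appended
                self.n_hm[i] = n1
                self.meth[i] = m1
                self.generation[i] = gen
                self.progress[i] = 0.0
                new_rows.append((self.e[i].copy(), n2, m2, gen, i))
            self.e = np.vstack([self.e] + [r[0][None, :] for r in new_rows])
            self.n_hm = np.vstack([self.n_hm] + [r[1][None, :] for r in new_rows])
            if tables.total_cpgs:
                self.meth = np.vstack([self.meth] + [r[2][None, :] for r in new_rows])
            else:
                self.meth = np.zeros((len(self.env) + len(new_rows), 0), dtype=bool)
            self.env = np.concatenate([self.env, np.ones(len(new_rows), dtype=np.int8)])
            self.clone = np.concatenate(
                [self.clone, [self.clone[r[4]] for r in new_rows]]
            )
            self.generation = np.concatenate(
                [self.generation, [r[3] for r in new_rows]]
            )
            self.aged = np.concatenate([self.aged, [self.aged[r[4]] for r in new_rows]])
            self.progress = np.concatenate([self.progress, np.zeros(len(new_rows))])

        # (6) differentiation removals (post-division omega crowding)
        in_omega = self.env == 1
        n_omega = int(in_omega.sum())
        q_cell = self.env_params.q0 * self._aged_mult("q0_mult") * n_omega * p.dt
        self.clip_events += int(np.sum(q_cell[in_omega] > 1.0))
        removals = in_omega & (self.rng.random(self.n_cells) < np.clip(q_cell, 0, 1))
        self.last_removals = int(removals.sum())
        if self.last_removals:
            self._delete(removals)

        self.t += 1
        return self

    def _replicate_row(self, meth_row, daughter_n_hm, rng):
        d_novo = denovo_rate(daughter_n_hm, self.tables.n_h, self.params)
        per_cpg = np.repeat(d_novo, self.tables.cpg_counts)
        return replicate_methylation(meth_row, per_cpg, self.params, rng)


def step_population(pop: PopulationState, *_ignored) -> PopulationState:
    """Advance ``pop`` by one step (thin functional wrapper)."""
    return pop.step()


# ---------------------------------------------------------------------------
# trajectory recording / scenario execution
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Recorded time series of a scenario run (tidy long tables)."""

    counts: pd.DataFrame  # t, env, phenotype, n
    genes: pd.DataFrame  # t, env, gene, n_h, means/vars, n_cells
    clones: pd.DataFrame  # t, clone, size, aged_fraction
    status: str = "completed"
    seed: int | None = None
    config: dict | None = None

    def save(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "counts.csv", index=False)
        self.genes.to_csv(out / "genes.csv", index=False)
        self.clones.to_csv(out / "clones.csv", index=False)

    @classmethod
    def load(cls, out_dir) -> "Trajectory":
        from pathlib import Path

        out = Path(out_dir)
        return cls(
            counts=pd.read_csv(out / "counts.csv"),
            genes=pd.read_csv(out / "genes.csv"),
            clones=pd.read_csv(out / "clones.csv"),
        )


def _record_counts(pop: PopulationState, rows: list) -> None:
    c = pop.counts()
    for env in ("alpha", "omega"):
        for phen in ("young", "aged"):
            rows.append((pop.t, env, phen, c[f"{env}_{phen}"]))


def _record_genes(pop: PopulationState, rows: list) -> None:
    tables = pop.tables
    hm_frac = pop.n_hm / np.maximum(tables.n_h, 1)
    if tables.total_cpgs:
        sums = np.add.reduceat(pop.meth, tables.cpg_offsets[:-1], axis=1)
        meth_frac = sums / np.maximum(tables.cpg_counts, 1)
    else:
        meth_frac = np.zeros_like(hm_frac)
    # C3 convention: nucleosome-free genes report zero histone/DNA levels
    hm_frac[:, ~tables.has_nuc] = 0.0
    meth_frac[:, ~tables.has_nuc] = 0.0
    for env_code, env in ((0, "alpha"), (1, "omega")):
        sel = pop.env == env_code
        n_sel = int(sel.sum())
        for g in range(tables.n_genes):
            if n_sel:
                rows.append(
                    (
                        pop.t,
                        env,
                        g,
                        int(tables.n_h[g]),
                        float(pop.e[sel, g].mean()),
                        float(pop.e[sel, g].var()),
                        float(hm_frac[sel, g].mean()),
                        float(hm_frac[sel, g].var()),
                        float(meth_frac[sel, g].mean()),
                        float(meth_frac[sel, g].var()),
                        n_sel,
                    )
                )
            else:
                rows.append(
                    (pop.t, env, g, int(tables.n_h[g])) + (np.nan,) * 6 + (0,)
                )


def _record_clones(pop: PopulationState, rows: list) -> None:
    for clone in np.unique(pop.clone):
        sel = pop.clone == clone
        rows.append(
            (
                pop.t,
                int(clone),
                int(sel.sum()),
                float(pop.aged[sel].mean()),
                float(pop.generation[sel].mean()),
            )
        )


def run_scenario(
    genome: Genome,
    params: RegulationParams,
    env_params: EnvironmentParams,
    arp: ARPDefinition | None = None,
    *,
    steps: int = 6000,
    burn_in: int = 0,
    record_every: int = 50,
    seed: int = 0,
    n_initial: tuple[int, int] = (10, 10),
    n_clones: int | None = None,
    force_phenotype: str | None = None,
    config_echo: dict | None = None,
) -> Trajectory:
    """Execute a scenario: burn-in plus recording epochs, fully reproducible.

    Records tidy time series of compartment counts, per-gene regulatory
    summaries per environment, and the clone census every ``record_every``
    steps (including t = burn_in and the final step).  If the population
    goes extinct, the trajectory is returned with ``status='extinct'``.
    """
    rng = np.random.default_rng(seed)
    pop = PopulationState(
        genome, params, env_params, arp, rng, force_phenotype=force_phenotype
    ).seed_cells(*n_initial, n_clones=n_clones)
    count_rows: list = []
    gene_rows: list = []
    clone_rows: list = []
    status = "completed"
    total = burn_in + steps
    for t in range(total + 1):
        if t >= burn_in and (t - burn_in) % record_every == 0 or t == total:
            _record_counts(pop, count_rows)
            _record_genes(pop, gene_rows)
            _record_clones(pop, clone_rows)
        if t == total:
            break
        try:
            pop.step()
        except PopulationExtinct:
            status = "extinct"
            break
    counts = pd.DataFrame(count_rows, columns=["t", "env", "phenotype", "n"])
    genes = pd.DataFrame(
        gene_rows,
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
    clones = pd.DataFrame(
        clone_rows,
        columns=["t", "clone", "size", "aged_fraction", "mean_generation"],
    )
    return Trajectory(
        counts=counts,
        genes=genes,
        clones=clones,
        status=status,
        seed=seed,
        config=config_echo,
    )


def cell_table(pop: PopulationState) -> pd.DataFrame:
    """Tidy per-cell, per-gene snapshot of the current population."""
    tables = pop.tables
    rows = []
    for i in range(pop.n_cells):
        for g in range(tables.n_genes):
            sl = tables.gene_slice(g)
            n_h = int(tables.n_h[g])
            rows.append(
                {
                    "t": pop.t,
                    "cell": i,
                    "clone": int(pop.clone[i]),
                    "env": "alpha" if pop.env[i] == 0 else "omega",
                    "phenotype": "aged" if pop.aged[i] else "young",
                    "generation": int(pop.generation[i]),
                    "gene": g,
                    "expression": float(pop.e[i, g]),
                    "n_hm": int(pop.n_hm[i, g]) if n_h else 0,
                    "meth_fraction": (
                        float(np.mean(pop.meth[i, sl])) if n_h and sl.stop > sl.start else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)
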
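# Methods

## Scope and architecture

`epidrift` couples four nested layers, each testable in isolation:

1. **genome** — an artificial genome (digit alphabet `0123`) with genes,
   nucleosome counts, CpG-analog motifs and a signed TF network;
2. **regulation** — per-gene kernels: transcription, methyltransferase
   binding, stochastic histone (de-)modification, replication-coupled DNA
   methylation;
3. **cells / population** — individual cells in a two-compartment
   niche/proliferation system with exchange, division, differentiation and
   phenotype evaluation;
4. **observables** — gene classification, heterogeneity, differential
   expression, clone census and decay fits, parameter-sensitivity sweeps.

All randomness flows through one `numpy` generator seeded per run; the
per-step update order (intracellular dynamics → phenotype → niche exits →
niche entries → divisions → differentiation) is fixed and echoed into every
run's configuration stamp, so identical (config, seed) pairs give
byte-identical trajectories.

## The artificial genome

Genes are opened at promoter-motif occurrences of an i.i.d. uniform digit
string; each gene's length is drawn uniformly from [50, 2000] bases and
truncated at the next motif, so genes never overlap and short (< 200 base)
genes arise naturally.  One nucleosome is assigned per 200 bases
(`N_H = length // 200`); the gene's own interval serves as its regulatory
region, within which occurrences of the two-digit CpG motif (`23`) are the
methylatable sites.  The TF encoded by a gene is represented by the digit
complement of its first 8 bases; it binds any site in a target gene
matching within one mismatch, the parity of the digit after the site
setting activation vs repression, and the site count setting the weight.
These constructions are deliberately minimal: they produce sparse signed
networks and the full spread of nucleosome counts, which is all the
downstream layers consume.  Real sequence models (PWMs, CpG islands) are
out of scope.

Simulation presets default to a small deterministic fixture genome with
nucleosome counts (0, 0, 2, 4, 4, 6, 8, 8, 8, 8) and exact planted CpG
counts (2·N_H + 2 per nucleosome-bearing gene), so every gene class is
populated and runs are cheap; the random-genome path (`generate_genome`,
`epidrift make-genome`) is fully supported and its default configuration
also populates all classes.

## Chromatin dynamics

Each gene's `N_H` cooperative nucleosomes carry a binary H3K4me3 mark.  Per
step, unmodified nucleosomes gain the mark with probability `k_M·Θ·Δt` and
modified ones lose it with `k_D·Δt`, where

```
Θ = 1 / (1 + exp(ε₀ − w_BS·ε_BS − n_HM·ε_HM))
```

is the two-state Boltzmann binding probability of the
methyltransferase-carrying complex; `w_BS` is the fraction of unmethylated
CpGs (zero-CpG genes contribute `w_BS = 0`; nucleosome-free genes have
`Θ = 0` for recruitment but are fully permissive, `Θ ≡ 1`, for
transcription).  Energies are favorable-positive.

**Why per-nucleosome feedback.**  Every modified nucleosome contributes
`ε_HM` to the binding enthalpy, so the total feedback energy a gene can
recruit grows with `N_H`.  This is what makes bistability an emergent
property of the nucleosome count: a normalized (fraction-based) feedback
term makes the per-step sigmoid steeper for *smaller* genes and provably
cannot produce a stable high-modification state at `N_H = 8` while keeping
`N_H ≤ 6` monostable (we grid-scanned that variant exhaustively; best
candidates held < 30% stationary mass in the high mode with escape times of
a few hundred steps).  With per-nucleosome energies the defaults give, at
`w_BS = 1`: a bimodal law at `N_H = 8` with 80% mass in the high mode,
spontaneous high→low escape in ~3·10³ steps and low→high recovery in
~7·10² steps; monostable laws at `N_H ≤ 6`.  At the methylated-DNA
operating point (`w_BS ≈ 0.4`) the low mode holds > 90% mass and recovery
times grow to ~4·10⁴ steps: DNA methylation locks silencing.

**Defaults** (per Δt): `k_M = 0.4`, `k_D = 0.02`, `ε₀ = 8`, `ε_BS = 2`,
`ε_HM = 1` (per nucleosome), selected once by `scripts/tune_defaults.py`
against five criteria: the bistability boundary between 6 and 8
nucleosomes, a dominant high mode (stable marks in quiescent cells),
methylation-locked silencing, a silenced fixed-point expression well below
the phenotype threshold, and aging time scales of a few generations for
C2 genes versus many generations for C1a genes in a proliferating lineage
(measured medians ~300 and ~1300 steps to sustained silencing at one
division per 200 steps).

## DNA methylation

CpGs change only at replication: maintained with probability
`D_main = 0.8`, gained de novo with
`D_novo = D_novo⁰·exp(−ε_methyl·n_HM/N_H)`, `D_novo⁰ = 0.3`,
`ε_methyl = 6`.  The de novo probability for each daughter is evaluated
from that daughter's *post-partition* modification state — replication
dilution is precisely what opens the methylation window.  Hemimethylation
is not tracked (one boolean per CpG).  Under constant pressure the per-CpG
level converges to `D_novo/(1 − D_main + D_novo)`, the two-state
fixed point used as an exact oracle in the tests.

## Transcription

`de/dt = P_max·θ_Pro·Θ − δ·e` is integrated by explicit Euler
(`P_max = 1000`, `δ = 0.2` per Δt; stability requires `δ·Δt < 1`).  The
promoter occupancy uses a thermodynamic two-state form,
`θ_Pro = q_P(1 + A)/(1 + R + q_P(1 + A))` with `A`/`R` the
expression-weighted activator/repressor sums (expressions normalized by
`P_max/δ`) and `q_P = 0.1` the basal polymerase weight; it is monotone in
both sums, bounded in (0, 1), and reduces to `q_P/(1 + q_P)` without
interactions.  A full statistical-weight enumeration of promoter states is
intentionally replaced by this monotone two-state contract.

## Cells, division, phenotype

Cells start with all histones modified, all CpGs unmethylated, and
expression at the fixed point of the coupled transcription system (fixed-
point iteration, checked against an independent root-finder).  Division is
a constant hazard: an Ω cell's progress accumulator gains a Bernoulli unit
increment of mean `R·Δt` per step, so inter-division times are geometric
with mean `1/R = 200` steps (~one generation).  We deliberately avoid a
quasi-deterministic division timer: with near-fixed maturation times,
differentiation interrupts the renewal process and the stationary Ω
occupancy falls ~30% below `R/q₀`; the memoryless hazard preserves the
mean-field demography.  At division the modified nucleosomes split
binomially (`n_d1 + n_d2 = n_mother`, a hard invariant), vacated positions
are filled by unmodified nucleosomes, and both daughters remain in the
population.

A cell is *aged* while the mean expression of three designated bistable
marker genes is strictly below `TS = 2`; the evaluation repeats every step,
so phenotype switches are reversible in both directions (ties count as
young).  Continuous (rather than per-division) evaluation was chosen
because phenotype rescue by spontaneous chromatin fluctuations requires the
cell to be reclassified while quiescent.

## Population dynamics

Exchange follows `P_α = ρ_α·N_α` (crowded niches expel cells) and
`P_Ω = ρ_Ω/N_Ω` (constant total inflow while Ω is populated);
differentiation removes Ω cells with probability `q₀·N_Ω` each step.
Stationary sizes: `N_α* = √(ρ_Ω/ρ_α)`, `N_Ω* = R/q₀`.  The printed
stationary formula's coefficients are read as the ρ exchange coefficients,
the only interpretation consistent with the transition probabilities.
With two phenotypes the balance runs per phenotype in parallel, with two
deliberate total-coupling choices: the niche-exit pressure uses the *total*
niche occupancy (aged cells that accumulate in the niche push young cells
out — the mechanism behind the HSC scenario), and the differentiation
pressure uses the total Ω occupancy; each phenotype keeps its own constant
niche inflow `ρ_Ω·mult_φ` against its own Ω subpopulation.  Probabilities
are clipped to [0, 1] with a clip-event counter as a parameter-health
diagnostic.  An empty population halts the run with status `extinct`.

Defaults: `ρ_α = 10⁻³`, `ρ_Ω = 0.1`, `R = 5·10⁻³`, `q₀ = 5·10⁻⁴`, i.e. the
reduced-scale system `N_α* = N_Ω* = 10`.

**Small-population caveat.**  At these reduced compartment sizes the Ω
occupancy is a noisy logistic with slow restoring (relaxation ~1/R = 200
steps) fed by an exchange flux; its time-average sits well below `R/q₀`
(≈ 6 instead of 10 at the defaults) purely through demographic noise —
the mean-field closed forms are large-N statements.  Quantitative
mean-field comparisons in the tests therefore use parameter sets with
`N* ≈ 16–30`, where both closed forms hold within 10%; the niche
occupancy, whose restoring is fast, tracks its closed form already at
`N_α* = 10`, which is why the HSC amplification ratio is clean at the
default scale.

## Scenario presets

* `no-arp-isolated` — age-independent phenotype, no exchange: the niche is
  an isolated quiescent control; used for the gene-class structure.
* `no-arp-exchange` — age-independent with exchange: neutral clonal
  competition; the clone count decays ~1/t.
* `low-differentiation` — aged cells differentiate at `q₀/3` (dominant,
  positively selected ARP; fixes in ~2·10³ steps).
* `low-proliferation` — aged cells proliferate at `4R/5` (recessive ARP;
  young cells persist several times longer).
* `hsc` — aged cells have 4.0-fold niche inflow and 0.25-fold niche exit;
  the niche fills to 4× the young occupancy while Ω stays put, and the
  phenotypes coexist for > 5·10³ steps.

**Clone-decay experiment.**  The neutral-decay measurement starts 50
uniquely barcoded founder cells (25 per compartment) with `q₀ = 2·10⁻⁴`
(`N_Ω* = 25`), keeping the niche at its usual size: lineage competition
acts in Ω, so the proliferative compartment is sized comparably to the
founder pool.  The fitted log–log slope (window opening when the clone
count first drops below 90% of the initial value) is then −0.73 ± 0.02;
the window necessarily includes the shoulder of the decay curve, where the
instantaneous slope is still shallow, so the window-averaged exponent sits
slightly below the asymptotic 1/t value.

## What the synthetic data does and does not show

The fixture genome and artificial-genome generator emulate the *structure*
the model consumes — gene classes spread over nucleosome counts, CpG
density, sparse signed regulation — not real genomic sequence, real motif
energetics, nucleosome positioning, or genome-wide methylation landscapes.
Passing tests demonstrate the internal consistency of the drift mechanism
and its population consequences at reduced scale; they say nothing about
parameter values in any real tissue.  Likewise the reduced compartment
sizes (tens of cells) compress a real stem-cell pool; time scales are
calibrated only through "200 Δt ≈ one generation".

## Numerical choices and degenerate inputs

* Stationary laws of the histone chain use the detailed-balance product
  form evaluated in log space; bimodality = two local maxima (boundaries
  included, relative tolerance 10⁻⁹).
* Probabilities are validated per step; a per-step probability above 1 is
  a parameter error, not silently clipped (population exchange is the
  documented exception, with counted clips).
* Zero-CpG genes: `w_BS = 0`.  Nucleosome-free genes: `Θ = 0` for
  recruitment, `Θ ≡ 1` for transcription, and their histone/DNA levels are
  reported as zero in all observables.
* Log-expression uses pseudocount `10⁻³·P_max/δ = 5`.
* Time-to-dominance: first time the aged fraction exceeds 0.95 and stays
  above it for 100 steps (an artifact definition; the record cadence must
  not exceed the sustain window).
* Classification needs a recorded span ≥ 500 steps, otherwise calls are
  flagged unstable.  "Stably modified in α" means a late-window mean
  H3K4me3 fraction ≥ 0.5; "acquired DNA methylation in Ω" means a
  late-window mean CpG methylation ≥ 0.2.

## Known limitations

* Single histone mark (H3K4me3) and single-boolean CpG states; no
  H3K9me3/acetylation crosstalk, no hemimethylation.
* Cells do not interact except through compartment-level crowding terms;
  no spatial niche geometry.
* Stem-cell-pool exhaustion is not modeled.
* The thermodynamic promoter model is a monotone two-state reduction, not
  a full statistical-weight enumeration; TF-network effects on the aging
  phenomenology are secondary by construction.
* Window-averaged clone-decay exponents depend on the capacity/founder
  ratio (see above); only the asymptotic regime is parameter-free.
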
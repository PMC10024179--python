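# Methods

## Model overview

The simulated system is a newly seeded melanoma micrometastasis in a closed
1 mm³ tissue block: a cubic lattice of 100×100×100 voxels with 10 µm edge,
one cell per voxel, advanced in Δt = 10 min steps for 100 days (14,400
steps). Agents are cancer cells, CTLs, DCs, macrophages, and two abstract
regulatory types (helpers ≈ CD4⁺ T/B cells, suppressors ≈ Tregs/MDSCs).
Intercellular signaling is collapsed into two surrogate cytokine
concentration fields, ENH (net immunoenhancing, e.g. IFN-γ and cytotoxic-cell
chemoattractants) and SUP (net immunosuppressive, e.g. IL-10/TGF-β/IDO),
deliberately ignoring pleiotropy.

A note on discretization: one lattice move of 10 µm per 10-min step is
1 µm/min (√3·10 µm ≈ 1.7 µm/min diagonally). A commonly quoted "maximum
speed" of 3 µm/min for this discretization does not follow from these
numbers; the model keeps one move per step and treats ~1–2 µm/min as the
effective speed cap. Similarly, 100 days at Δt = 10 min is 14,400 steps;
step counts are always derived from duration and Δt.

### Cell rules

**Cancer cells** random-walk with probability `p_migration_cancer` per step
(an occupied target swaps or both stay, 1/2 each), die with `p_death`
(leaving antigen-carrying debris), and divide `t_proliferation` steps after
their last division — but only into a vacant Moore neighbor (contact
inhibition as used by lattice models; no force mechanics). A dividing cell is
immobile that step; an enclosed cell keeps its expired timer and retries.
Antigens follow a finite-allele model with 32 indices: with `p_mutation` one
uniformly drawn allele is toggled (reverse mutations possible); a toggle that
would empty the presented set is redrawn, so every cancer cell presents ≥ 1
antigen. All seeded cells present antigen 0 (homogeneous founder clone) and
sit in a centered compact cube (5×5×5 for 125 cells), the reproducible
instance of "a compact colony at the lattice center".

**CTLs** carry one antigen specificity. Each step (unless within the
`t_kill`-step handling time of a previous kill) they probe their Moore
neighborhood in random order — randomized to avoid direction bias — and
attack the first cancer cell presenting their antigen with the kill
probability given in the README; success removes the target, deposits
debris, and immobilizes the killer for `t_kill` steps. Engaged CTLs do not
move. Otherwise they migrate: above an ENH threshold they are *activated*,
secrete ENH, and climb the ENH gradient (steepest ascent over vacant
neighbors, uniform tie-break; a flat field falls back to random walk); below
threshold they random-walk. Immune cells attempt a move every step
(`p_migration_immune` = 1). CTLs expire at `t_life_ctl` (standing in for
exhaustion/apoptosis/egress); CTL proliferation in the TME is not modeled.

**DCs** move to vacant neighbors, collect all debris at their voxel (antigen
set union), and once presenting anything leave the lattice: one signal unit
per presented antigen is pushed onto the corresponding delay queue and a
naive DC respawns at a free border voxel (population homeostasis). DC
apoptosis is not modeled. The per-departure signal magnitude is set to 1;
its physiological scale is absorbed into `r_ctl`.

**Helpers/suppressors** secrete ENH/SUP respectively at rate `r_enh`
(concentration units per minute at their voxel), random-walk, and expire at
fixed lifespans. **Macrophages** split a total budget `r_cytokine` between
ENH and SUP proportionally to the local concentration shares (positive
feedback imitating M1/M2 plasticity; an exactly neutral environment splits
50:50 — the ratio is 0/0 there and the even split is the natural M0
convention), and kill adjacent cancer cells antigen-independently using the
same kill law with their own base probability `p_base_macrophage`.
Macrophage kills also leave debris. Because macrophages are recruited
continuously but no lifespan is stated for them in the source biology, a
finite `t_life_macrophage` (default 4 days) keeps the population bounded.

### Cytokines

Both fields obey ∂c/∂t = DΔc − λc + secretion, discretized with the 7-point
Laplacian and Euler forward. Boundaries are zero-flux (closed tissue block;
immune influx is modeled by recruitment, not by cytokine boundary flux) and
degradation is first-order with a shared rate λ — the simplest term
consistent with "secretion and degradation". Each 10-min step deposits
secretion once and then runs ⌈Δt/Δt_max⌉ diffusion substeps, where
Δt_max = Δx²/(6D) is the 3D von Neumann stability bound; violating it raises
an error naming the admissible substep. Defaults D = 5 µm²/min and
λ = 0.02/min give an interaction range √(D/λ) ≈ 16 µm (1–2 voxels): these
are *effective* tissue values chosen so that cytokine action is local enough
for chemotaxis to matter on the lattice; free-solution diffusivities of
small proteins are orders of magnitude larger, but binding/consumption in
tissue sharply reduces the effective range.

### Recruitment

Each antigen has a FIFO queue of length `t_delay` (the lymph-node delay of
DC-induced clonal expansion). Per step the oldest slot is dequeued *before*
agent updates, so a signal pushed by a departing DC at step t is emitted at
step t + t_delay, exactly once; CTL recruits number r_ctl·signal per antigen
(probabilistic rounding: floor + Bernoulli on the fraction — unbiased),
helpers are recruited 1:1 with CTLs, macrophages and suppressors at ratios
`q_macrophage`, `q_suppressor` of the CTL count. Recruits appear at uniformly
random free border voxels (entry from vasculature); if no free border voxel
is found the recruit is dropped and counted — this occurs only near the
abort regime. The low-infiltration scenario divides all recruitment by 3
(`recruitment_scale` = 1/3).

### Therapy and outcomes

Anti-PD1 is the exponent g on the whole kill probability: g = 1 untreated,
g = 0.1 from `therapy_start_step` on. The parenthesization
(p_base + (1−p_base)(1−e^(−τ_ENH[ENH]))e^(−τ_SUP[SUP]))^g was chosen so that
SUP damps only the cytokine enhancement (p_kill ≥ p_base^g), all stated
monotonicities hold (↑ENH, ↓SUP), and g = 0.1 strictly increases killing, as
therapy must. Runs are labeled complete remission (0 cancer cells at the
end), emerging metastasis (> 700,000 = 70% of sites, including runs aborted
at 800,000 = 80%), else residual disease. Extinction is absorbing — with no
cancer cells there are no divisions and no new debris — so the engine stops
early once the count reaches 0; the outcome is unaffected.

### Scheduling and reproducibility

Per step: (1) secretion, (2) diffusion substeps, (3) queue advance +
recruitment, (4) agent updates in a uniformly re-shuffled order (the same
anti-bias argument as for neighbor scans). Agents created during a step act
from the next step. One RNG stream drives a replica; a fixed seed gives a
bit-identical trajectory. Replicate batches draw independent seeds and can
perturb every rate/probability/τ/duration parameter by independent
Uniform(1−f, 1+f) factors (f = 0.25 models patient diversity); lattice
geometry and Δt are never perturbed.

## Nominal values and calibration

Most nominal magnitudes (diffusivity, decay, secretion rates, probabilities)
are not pinned by published single-cell measurements at this abstraction
level. Durations use textbook scales (24 h cell cycle, 1 h kill handling,
3-day CTL residence, 3-day recruitment delay, 2-day regulatory-cell
lifespans). The remaining free magnitudes — chiefly the recruitment gain
`r_ctl`, the cytokine couplings τ, and the secretion scale — were calibrated
once by exploratory simulation against three qualitative regimes: untreated
nominal runs end in emerging metastasis almost always; treated runs with
nominal infiltration mostly reach complete remission; treated runs with
3-fold reduced infiltration respond markedly worse. These are the clinically
motivated response patterns of high- vs low-CD8-infiltrate patients, and
calibrating to them is part of the model definition, not of any test.

## Desk-scale profiles

Full-scale runs (100³, 14,400 steps) take on the order of an hour each, so
tests and the acceptance script use scaled profiles:

- **minimal** — 10³ lattice, 27 seeded cells, no immune cells; pure growth,
  used against brute-force oracles.
- **scaled** — 30³ lattice, 2,000 steps, 27 seeded cells (3×3×3), 30 DCs,
  20 macrophages; thresholds keep the full-scale proportions (abort at 80% =
  21,600 sites, metastasis at 70% = 18,900). Time constants shrink with the
  run length (t_proliferation 60, t_delay 120, t_kill 3, lifespans 200–400,
  p_death 10⁻³, r_ctl 1.5) so the growth → surveillance → response arc fits
  2,000 steps. This profile is the package's standing study condition for
  the paired experiments.
- **aggressive** — scaled with t_proliferation halved and motility doubled:
  the resistant phenotype (short replication time, moderate motility).

## Transcriptomics linkage

Differential expression is a per-gene Welch two-sample t-test on log2
expression (the simplest defensible two-group test; the interface accepts
any (logFC, p) table, so moderated tests can be substituted). Genes are
ranked by s = sign(logFC)·(−log₁₀ p) (p = 0 clamps to the smallest positive
float with a warning); ties in s break by gene identifier for determinism.
The enrichment score is the classic weighted running sum (weight exponent 1):
hits add |s|/Σ_hits|s|, misses subtract 1/(N−N_hits), ES is the value at the
maximum absolute deviation, and the leading edge contains the hits at or
beyond the extremum. The null is gene-sampling: random sets of equal size
drawn from the ranked universe (vectorized per set size), NES = ES divided
by the mean |null ES| of matching sign, p = (1 + #{|null| ≥ |ES|, same
sign})/(1 + n_same sign) — deliberately simpler than adaptive multilevel
estimators; with the default 10,000 permutations the p-value floor is
~2·10⁻⁴, adequate for α = 0.05 shortlisting. BH adjustment uses the standard
step-up procedure. Significant sets (adjusted p ≤ 0.05) map to parameters
through an editable JSON annotation (shipped default: genome instability →
p_mutation; EMT → p_migration_cancer; three cell-cycle sets →
t_proliferation; TGF-β → τ_SUP; two immune-recruitment sets → r_ctl; two
interferon sets → τ_ENH); significant unmapped sets are reported as
model-expansion candidates. When more parameters are identified than the
simulation budget affords (k_max = 5), the parameter with the weakest best
adjusted p is dropped; an optional one-at-a-time local screen can replace
that tie-break.

## Sensitivity stage

The design is a scrambled (Owen) Sobol sequence, seeded, with levels^k
points scaled to (0, 2)·nominal per axis; the open lower bound is
implemented as 10⁻⁹·nominal. Scrambling keeps points strictly inside the
cube and preserves the net's balance. Because the design is continuous while
the model quantizes durations to whole steps and caps probabilities at 1,
the engine adapter projects sampled values onto the admissible space. PRCC
rank-transforms design and outcome and correlates the residuals after
linearly removing the other rank-transformed parameters; it equals Spearman
correlation for k = 1. The metamodel is a scikit-learn CART classifier on
the three outcome labels: Gini impurity, depth ≤ 5, minimum split size 3.3%
of the training set (read as the minimum node size eligible for splitting),
80:20 train/test split, 5-fold CV on the training set, normalized split
importances. Leaves predicting emerging metastasis are compiled into
per-parameter interval conjunctions (repeated splits intersect), sorted by
leaf sample fraction — the therapy-resistance subspaces. No class
reweighting is applied.

## Synthetic data

Expression cohorts are Gaussian on log2 scale: baseline mean 5, i.i.d. noise
(default sd 0.5 log2 units), planted sets receive a mean responder shift
(default +1.5). The default cohort shape is 15 responders vs 13
non-responders, matching the pre-treatment anti-PD1 melanoma cohort the
pipeline emulates. The full linkage scenario plants 24 enriched sets (10
annotated → 6 parameters, 14 unmapped) of 50 genes each in an 8,000-gene
universe; the universe is sized so planted genes stay a modest fraction
(~15%) of the ranked list — a gene-sampling null degrades when a large share
of the universe carries planted signal, which real cohorts do not exhibit.
What passing tests on these data do **not** show: robustness to batch
effects, count noise, FPKM zero-inflation, correlated genes, or annotation
curation error — none of which are emulated.

## Numerical and implementation choices

- Simulation state is structure-of-arrays (capacity = lattice sites, since
  occupancy bounds the population); the per-step kernels are numba-compiled,
  single-threaded, with one seeded RNG stream per replica.
- Debris does not occupy the lattice (it coexists with cells; a voxel's
  debris is the union of antigen masks deposited there) and persists until
  collected.
- Border sampling for recruits/respawns is rejection sampling over the six
  faces (200 tries, then the recruit is dropped and logged).
- Durations are integers ≥ 1 step; perturbation and design sampling round
  and clamp accordingly.
- The explicit diffusion scheme refuses to run outside its stability bound
  rather than silently substepping past user-fixed `n_substeps`.

## Known limitations

Beyond the scope cuts stated above (no angiogenesis, metabolism, CTL
proliferation in the TME, immune memory; no off-lattice mechanics or cell
pushing): the finite 32-allele antigen model cannot express mutational-burden
effects; outcomes at the fixed horizon need not be steady states (some
treated runs are still mid-clearance at the scaled horizon and label as
residual disease); the scaled profile compresses time constants, so its
absolute remission fractions are not comparable to full-scale runs — only
its ordering properties (therapy helps, low infiltration hurts, aggressive
phenotypes resist) are meaningful; and the gene-set→parameter annotation
remains a manual curation step encoded as configuration.
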
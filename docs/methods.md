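# Methods

## The model

Her6 (the zebrafish Hes1 orthologue, written `h`) is a direct target of
mature miR-9 (`m`). The core circuit is an incoherent feed-forward loop:
miR-9 represses Her6 production directly and also represses an intermediate
repressor `X`, which itself represses Her6 production. With the repression
function `G(x) = 1/x` the two arms cancel exactly at steady state:

    dh/dt = alpha_h G(m) G(X) - mu_h h
    dX/dt = alpha_X G(m)      - mu_X X

so `X*(m) = alpha_X / (mu_X m)` and

    h* = alpha_h mu_X / (mu_h alpha_X),

independent of `m` — perfect adaptation. Two exact consequences shape
everything downstream:

* **Fold-change response.** Rescaling the input `m -> c m` together with
  `X -> X/c` leaves the `h` dynamics invariant, so the circuit responds only
  to relative input changes. All switching thresholds below are folds, not
  absolute levels.
* **Adaptation speed is set by the X branch.** After an input change `h`
  tracks `1/(m X)` on its fast timescale `1/mu_h`, while `X` re-equilibrates
  on `1/mu_X`; the transient dip in `h` lasts roughly `1/mu_X`.

The extended model adds a downstream target `Y` that self-activates and is
mutually repressive with Her6:

    dh/dt = alpha_h G(m) G(X) G-(Y; n1, p1)                    - mu_h h
    dX/dt = alpha_X G(m)                                       - mu_X X
    dY/dt = (alpha_Y + beta_Y G+(Y; ns, ps)) G-(h; ng, pg)     - mu_Y Y

with the activating and repressing Hill forms `G+(p) = p^n/(p0^n + p^n)` and
`G-(p) = 1 - G+(p)`. Her6 gates the whole Y production term by default; an
alternative reading in which only the basal term is gated is available as the
`gate_basal_only` configuration switch but is off by default, because the
default is the only arrangement consistent with every other repression in the
model acting multiplicatively on a production rate.

### Why a step switches and a ramp does not

At the adapted state `h ~ h*` the gate `G-(h*; pg)` is nearly closed and `Y`
sits at a repressed low level; the extended system behaves like the basic
loop. A *fast, large fold* increase of `m` drives `h` transiently down
(depth ~ 1/fold, duration ~ `1/mu_X`). If `h` stays below the escape level
long enough, the gate opens, `Y` self-activates past its unstable branch,
and the mutual repression latches `h` into a low steady state
`h_low = h* G-(Y_high; p1)`. The switch is hysteretic: holding the input
constant afterwards never restores the high state.

The escape requires a specific fixed-point geometry of the Y subsystem
(Y dynamics with `h` clamped):

* at `h = h*`: a single stable low root (`Y` repressed — the paper's stated
  parameter constraint);
* over an intermediate band of `h`: three roots (bistable);
* at `h ~ 0`: the low root has vanished in a saddle-node and only the high
  self-activated root remains, so `Y` escapes *dynamically* during a deep
  Her6 transient.

The last point is load-bearing. If the Y subsystem kept a stable low root at
`h = 0`, then (because the Her6 gate only ever scales Y production down)
`dY/dt <= (alpha_Y + beta_Y G+(Y)) - mu_Y Y` for every `h`, and `Y` started
below that root could never cross the middle branch — no input, however
sharp, could switch the system. `check_parameter_feasibility` therefore
verifies exactly the geometry above (condition C1), a unique low root at
`h = h*` with the full system's adapted fixed point within 5% of `h*` (C2),
and the existence of a finite single-step switching fold in (1, 100] (C3).
Two necessary ingredients fall out as corollaries and are tested: no
self-activation (`beta_Y = 0`) and non-cooperative self-activation (Hill
coefficient 1) both make the scalar Y subsystem monostable everywhere and
fail C1.

### Reference parameter set

No measured rates exist for this circuit; the shipped reference set was
chosen once, by requiring C1–C3 plus comfortable dynamic margins between the
inputs that must switch and those that must not, and is recorded in
`src/her6switch/data/reference.cfg`:

| parameter | value | meaning |
|---|---|---|
| alpha_h, mu_h | 2.0, 2.0 /h | Her6 production/turnover (fast, ~0.5 h) |
| alpha_X, mu_X | 0.3, 0.3 /h | X branch (slow, ~3.3 h) — sets adaptation time |
| h* | 1.0 a.u. | adapted Her6 level (unit by construction) |
| alpha_Y, beta_Y, mu_Y | 1.0, 4.0, 2.0 | Y basal/self-activated production, turnover |
| p1 (n=4) | 0.5 | Y-on-Her6 repression threshold; sets `h_low` |
| pg (n=4) | 0.5 | Her6-on-Y gate; sets the escape depth (~0.48 h*) |
| ps (n=4) | 0.7 | Y self-activation threshold |

With these values the critical single-step fold is F* ≈ 2.78; the reference
two-step input (fold 1.5 at t=20 h, then fold 4 at t=60 h) switches while the
matched ramp (same start/end values, 80 h) and the first step alone adapt,
with maximum transient deviations of ~0.14 and ~0.26 — far from the ~0.52
deviation needed to open the gate.

Units: time in hours, concentrations in arbitrary units. The paper's system
provides no molecule counts; nothing here is calibrated to absolute levels,
which is also why only fold changes matter.

## Input profiles

Profiles are piecewise constant/linear, strictly positive (required by
`G(m) = 1/m`), tile a contiguous interval, and are evaluated with a
left-continuous step convention: the *new* value applies exactly at a step
time. Evaluation outside the defined interval clamps to the boundary value,
so a simulation may run past the last segment with the input held constant.
Integration restarts at every value discontinuity so steps are never smeared
by adaptive step control; tolerances default to rtol 1e-8 / atol 1e-10
(LSODA with the analytic Jacobian — the `1/x` nonlinearity is stiff when X
is small).

Fluctuating inputs multiply a base profile by `exp(eta(t))` where `eta` is a
stationary Ornstein–Uhlenbeck process with stationary standard deviation
equal to the requested amplitude and a configurable correlation time. The
log-scale construction guarantees positivity for every seed. The path is
sampled by exact discretisation on an internal grid of one tenth of the
correlation time and interpolated linearly, making evaluation a pure
function of (t, seed).

## The locus-activation generator

The generator formalises "sequential and additive" deployment of pri-mir-9
loci minimally. Per cell and per locus, an onset time is drawn from a normal
distribution truncated at the window start (sd 1 h by default), optionally
replaced by +infinity with a per-locus never-active probability; onset is
irreversible within the window. Mature miR per cell obeys

    d(mir)/dt = sum over active loci of production_rate - decay_rate * mir,

integrated exactly (closed form) from zero at 24 hpf. Contributions add by
linearity, which the tests exploit as an oracle.

Reference conditions emulate the hindbrain arrangement: pri-mir-9-5 and
pri-mir-9-4 switch on near 30 hpf, pri-mir-9-1 near 36.5 hpf, in a 500-cell
population on a 24–48 hpf grid. The free kinetic parameters (no measured
values exist) were fixed once: mature-miR decay 1.0/h, early-locus
production 0.25 a.u./h each, late-locus production 6.0 a.u./h, a basal
mature-miR level of 1.0 a.u. from sources outside the three modelled loci
(also required to keep the model input strictly positive), early-locus
dropout 0.05 and late-locus dropout 0.15 ("most, but not all" progenitors
activate the late locus). The resulting population mean is low (~1–1.5 a.u.)
before 36 hpf, rises sharply around 37 hpf and plateaus near 7.5 a.u. — a
fold change of ~5 concentrated in ~3 h, which is fast relative to the X
branch and therefore switches the extended model, while its linearised
control does not.

Co-expression summaries count cells by number of active loci; fractions are
computed relative to precursor-positive cells only, are NaN (with the count
of positive cells reported) when no cell is positive, and sum to one
otherwise.

What the generator does *not* emulate: spatial structure along the
dorso-ventral axis, transcriptional bursting or nascent-spot counts,
cell division and progenitor-pool shrinkage, any coupling between loci
(onsets are independent), and the second population-level rise at 48 hpf,
which lies outside what three loci with onsets at 30/30/36.5 hpf can
produce. Passing tests therefore show that the *mechanism* (additive onsets
produce a decodable step) is coherent, not that these kinetics match
hindbrain measurements.

## The linearised control

The pipeline contrasts the locus-driven input with a "gradual" version of
itself. The primary construction is the least-squares straight line over the
fit window (24–42 hpf, i.e. the rise phase up to shortly after the plateau
is reached). A straight-line fit to a step-like curve, however, typically
has a near-zero or negative intercept; such a line is not a valid input
(the model requires `m > 0`) and, for a fold-change detector, a line rising
from near zero is an extreme *fold* ramp rather than a gradual input. When
the fitted line is not strictly positive the control falls back to the
straight line through the window's start and end values — the same
construction as the ramp-vs-step comparison, which shares start/end values
and duration by design. The report records which construction was used and
the fit diagnostics.

## Outcome classification

A settled trajectory (terminal |dh/dt| below 1e-6 h* per hour) is classified
**switched** if `h(t_end) < 0.5 h*` and `Y(t_end)` lies above the unstable
branch at the final input, **adapted** if `h(t_end)` is within 5% of `h*`
and `Y(t_end)` lies below it, and **undecided** otherwise (with a warning
for unsettled trajectories). The 0.5 and 5% cut-offs are package
conventions; with the reference parameters the two attractors sit at
`h/h* ~ 1.0` and `~0.0016`, so the classification is insensitive to their
exact values. The switching-threshold search brackets and bisects the
single-step fold to a relative tolerance of 1e-3 (geometric midpoints,
consistent with the fold-change symmetry).

## Seeds and reproducibility

Every stochastic component derives its generator from the single run seed by
hashing a component name (SHA-256, reduced below 2^31), so adding a
component never perturbs existing streams, and identical config + seed give
bit-identical outputs. Fluctuation experiments integrate at rtol 1e-5 with
the noise path resolved at a tenth of the correlation time — appropriate for
classifying outcomes of rough (non-smooth) inputs, where micro-tolerances
buy nothing; deterministic-input runs keep the tight defaults. The
fluctuation experiment observes 100 h of noisy input and then holds the
input constant for 60 h before classifying, because the classifier requires
a settled state and the switch's hysteresis preserves any noise-triggered
transition through the quiet tail; the time-averaged Her6 level is computed
over the noisy window only.

## Problem sizes

Default study sizes: 500 cells for population synthesis, 100 seeds for the
robustness sweep, 1500-point output grids over 150 h runs, 20 random
feasible parameter draws (log-uniform ±20% around the reference, rejecting
draws that break C1/C2) for the fixed-point cross-checks, and a 1e5-point
dense grid for the independent sign-change oracle.

## Known limitations

* The model deliberately omits her6 autorepression, transcriptional delay
  and intrinsic noise, so it cannot reproduce oscillatory Her6 expression;
  it addresses transitions between stable states only.
* `G(x) = 1/x` is singular at 0: inputs and states are constrained strictly
  positive, and integration aborts with a diagnostic rather than
  regularising the pole (the steady-state cancellation relies on the exact
  form).
* The identities of X and Y are not modelled; rates are phenomenological
  and in arbitrary units, so quantitative comparisons to measured
  expression levels are out of scope.
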
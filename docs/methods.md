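# Methods

## Detection model

The detector operates on a square trans-impedance matrix `Z` (kΩ),
`Z[i,j]` = impedance seen on contact `j` while stimulating contact `i`
in a monopolar configuration. Labels run 1 (most apical) to 16 (most
basal). Two physical facts drive the design:

* In a normal insertion, cross-impedance falls monotonically with
  distance from the stimulating contact, because the voltage field
  spreads and decays through the cochlear tissue.
* A tip fold-over places contacts `f−k` physically next to contacts
  `f+k` (fold at `f`), so rows stimulating basal to the fold decay down
  to `f` and then *rise* over the reflected limb, with near-mirror
  symmetry about `f`.

### ΔZ embedding

Each stimulation row is one observation (features = recorded
impedances). Rows are log₁₀-transformed, mean-centered per feature, and
projected onto the first two right singular vectors. The resulting
scores, joined in electrode order, approximate the array's shape up to
an affine map — which is all bend detection needs. A fold maps adjacent
physical positions to adjacent embedding positions, so the polyline
doubles back at the fold.

The interior angle at vertex `k` is the angle at point `p_k` between
the segments to `p_{k−1}` and `p_{k+1}`: 180° for straight
continuation, near 0° for a full double-back. Angles are invariant to
the PC sign convention; the convention (PC1 increasing apical→basal) is
fixed only so plots reproduce.

**Diagonal handling.** By default the main impedances are replaced by
the mean of each row's adjacent cross-impedances before PCA
(`mask_diagonal=True`). The main impedance is dominated by the
electrode–tissue access resistance, which varies idiosyncratically from
contact to contact (several kΩ spread) and carries no information about
array position; left in place, it perturbs each embedded point along
its own feature axis and can push a smooth polyline's interior angles
below the detection threshold. Raw-diagonal embedding remains available
via the flag.

### Criterion and defaults

A fold is declared when both hold:

* minimum interior angle < `angle_threshold_deg` (default **90°**) at a
  contact above `apical_guard` (default **1**). Smooth insertions
  produce angles of roughly 145–170° in simulation; folds produce 1–40°;
  90° sits in the wide gap between the two populations.
* the decay-reversal consensus agrees with the bend contact within
  `agreement_tolerance` (default **1**) contacts. Each row is scanned
  from the stimulating contact toward the apex (main impedance
  prepended as the starting height); a reversal is the first strict
  local minimum whose subsequent rise exceeds
  `reversal_guard_frac` (default **0.05**) of the row's off-diagonal
  dynamic range. The guard is measured against the off-diagonal range
  only: the 5–10 kΩ diagonal would otherwise swamp the small
  mirror-limb rises of the shortest folds. The consensus is the modal
  reversal location over rows that show one (ties break apical).

The conjunction can be relaxed to bend-only
(`require_decay_reversal=False`). Ties in the minimum angle break
toward the apical contact, where folds occur.

The mirror-symmetry score correlates cross-impedances at positions
`f±k` over rows stimulating basal to the candidate fold (Pearson,
mapped to [0,1] via `(r+1)/2`, rows needing ≥3 mirror pairs). It is
reported as evidence but never gates detection: folds at contact 2 have
too few mirror pairs for the score to be defined at all.

## QC rules

Open if main impedance > 30 kΩ; short-to-ground if < 0.5 kΩ
(comparisons strict, so exactly 30.0/0.5 passes). Partial short between
a pair when **both** orientations of their cross-impedance reach
`partial_short_ratio` (default **0.9**) of the smaller main impedance
and exceed twice either contact's row median off-diagonal. The
both-orientations requirement distinguishes a physical inter-contact
path (visible in both measurement directions) from a one-sided row
elevation such as a poor case ground; the row-local median guard keeps
globally flat matrices and whole-row elevations from being misread as
pairwise shorts. Only contacts not already flagged open/short
participate in pairing — an out-of-range main impedance makes the ratio
meaningless. The numeric form of the partial-short rule is this
package's choice; the clinical rule names the condition without a
formula.

Abort conditions: more than `max_removed` (default **3**) contacts
removed, or any cross-impedance above `firstrow_kohm` (default
**5 kΩ**) in the stimulation row of the most apical surviving contact.
When electrode 1 itself was removed the check moves to the next
surviving apical row and the substitution is logged — the condition it
screens for (case ground isolated from tissue) is not specific to one
row.

## Forward simulator

Contacts sit at 1 mm arc-length spacing along a planar spiral whose
turn rate is 10°/mm for pre-curved and 6°/mm for straight lateral-wall
presets, tightening 1.5%/mm toward the apex. The rates are capped so
the total turn stays below 180°, which makes chord distance grow
monotonically with contact separation. A real cochlea wraps ~2.5 turns;
the simulator deliberately trades anatomical wrap for the electrical
property that actually characterizes a normal insertion — monotone
cross-impedance decay — since the kernel acts on straight-line
distance. A fold at `f` reflects contacts `1..f−1` back alongside the
array, 0.35 mm laterally offset, so mirror symmetry emerges from the
geometry rather than being painted onto the matrix; simulator and
detector share no shortcut.

Impedances: `Z_ij = floor + amp·exp(−d_ij/λ)` off the diagonal,
`Z_ii = access_i + amp`, with defaults `floor` 0.5 kΩ, `amp` 1.5 kΩ,
`λ` 3 mm, `access_i ~ U(3, 8)` kΩ. These place off-diagonals in the
0.5–2 kΩ range of in-vivo recordings and diagonals at typical monopolar
contact impedances. The exponential kernel is a test harness, not a
volume-conduction model: bounded at small distance, one decay length,
log-linear falloff. The bench preset (`amp` 6, `floor` 2 kΩ) mimics the
higher impedance scale of plastic-cochlea rigs. Noise is multiplicative
log-normal, σ = 0.03 (few-percent repeatability jitter) by default.
Faults are overwritten after noise: opens draw 40–80 kΩ, shorts
0.05–0.3 kΩ, partial-short pairs are set to 0.95× the smaller main
impedance (both orientations), the air pocket scales row-1
off-diagonals ×10.

One seed drives a benchmark; per-matrix sub-seeds are `seed + index`,
so generation is reproducible and parallelizable. Benchmark folds are
drawn uniformly over contacts 2–8, families per a mix fraction
(default 50/50).

**What the simulator does not capture:** real scala geometry and
translocations, frequency-dependent electrode polarization,
longitudinal current paths along the silicone carrier, partial
insertions, and the session-to-session drift of access resistance.
Passing on simulation demonstrates the algorithm's internal logic —
that the geometric fold signature survives QC, embedding, and noise —
not clinical performance; the clinical error rates can only come from
measured cohorts.

## Statistics

Sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`; prevalence
percentages rounded half-away-from-zero to two decimals. The
two-proportion Z-test uses the pooled variance and no continuity
correction (the form under which the reference prevalence comparison
reproduces), with two-sided normal p-values; degenerate pooled
proportions (0 or 1) raise instead of returning ±∞.

## Numerical and interface choices

* PCA via `numpy.linalg.svd` on the centered matrix — no iterative
  solver, fully deterministic.
* Degenerate zero-length polyline segments contribute a 180° angle (no
  turn information) rather than NaN.
* CSV serialization uses 12 significant digits (`%.12g`), keeping
  read∘write round-trips below 1e-9 kΩ while staying byte-stable; JSON
  carries full floats plus labels, metadata, and a units field
  (`Ohm` inputs are converted to kΩ on read).
* Matrices are *not* symmetrized: measured EFIs are only approximately
  reciprocal, and the QC partial-short rule explicitly uses both
  orientations.
* Detection requires ≥5 surviving contacts; fewer cannot support bend
  analysis and raise `InsufficientContactsError`.
* A negative or QC-aborted screening is a *successful* program run
  (exit 0) with the verdict in the report; non-zero exits are reserved
  for I/O and parameter errors.

## Known limitations

* A fold exactly at contact 1 (pure tip impaction, no reflected limb)
  produces no mirror limb and is out of the detector's design range;
  `fold_at` is restricted to 2–8 in the simulator accordingly.
* The angular criterion is one consistent operationalization of
  "sharp bend in the ΔZ plot"; production clinical systems may
  implement a different but related functional.
* Benchmark problem sizes (50 normal + 50 fold matrices per run) were
  chosen to estimate 100%-scale sensitivity/specificity with zero
  observed errors at modest compute; rarer failure modes would need
  larger sweeps.
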
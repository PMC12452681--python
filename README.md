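# tfoscan

Tip fold-over screening for cochlear implant electrode arrays from
electric field imaging (EFI) trans-impedance matrices.

## The problem

A cochlear implant electrode array occasionally folds back on itself
during insertion (a **tip fold-over**, TFO), leaving apical contacts lying
next to mid-array contacts. Undetected, a fold compromises programming
and device performance; detected intraoperatively, it can be corrected on
the spot. Imaging catches folds but is slow, costly, and not routine in
every operating room — whereas an EFI measurement takes seconds on
standard clinical tooling.

An EFI measurement stimulates each of the 16 intracochlear contacts in
turn with a small monopolar current and records the voltage on every
contact; dividing by the current gives a 16×16 impedance matrix **Z**
(kΩ). The diagonal `Z[i,i]` holds the monopolar main impedances; the
off-diagonals are cross-impedances, which in a normal insertion decay
monotonically with distance from the stimulating contact. A fold breaks
that monotonicity: cross-impedances decay, rise again over the reflected
limb, and show mirror symmetry about the fold contact.

## The method

`tfoscan` implements the full screening pipeline:

1. **QC pre-processing** — contacts with main impedance above 30 kΩ
   (open) or below 0.5 kΩ (short to ground), and partial-short contact
   pairs, are removed (row and column). The detector refuses to run when
   more than three contacts are removed or any cross-impedance in the
   apical stimulation row exceeds 5 kΩ (poor case-ground contact, e.g.
   an intraoperative air pocket).
2. **ΔZ embedding** — stimulation rows of the log₁₀ matrix are projected
   onto their first two principal components (PCA via SVD after
   per-feature centering). Joined in electrode order, the scores form
   the ΔZ polyline: smooth for a normal insertion, doubled back with a
   sharp bend at the fold contact for a TFO.
3. **Detection criterion** — a fold is flagged when the minimum interior
   turning angle of the polyline is below 90° at a contact other than
   electrode 1 **and** the row-wise decay-reversal consensus (the modal
   contact where cross-impedance decay toward the apex turns into a
   rise) agrees with the bend location within one contact. A
   mirror-symmetry score about the flagged contact is reported as
   supporting evidence.
4. **Forward simulator** — contacts are placed along a spiral (tighter
   for pre-curved than straight lateral-wall arrays); a fold reflects
   the apical contacts back alongside the array; impedances follow
   `Z_ij = floor + amp·exp(−d_ij/λ)` with per-contact access resistance
   on the diagonal and multiplicative log-normal noise. Fault injection
   (opens, shorts, partial shorts, air pocket) exercises the QC rules.
5. **Cohort statistics** — sensitivity/specificity from confusion
   counts, prevalence percentages, and the pooled two-proportion Z-test
   `z = (p̂₁−p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂))` for comparing fold prevalence
   between array families.

## Worked example

Simulate a pre-curved array folded at electrode 5 with 3% measurement
noise, then screen it:

```sh
$ tfo simulate --family pre-curved --fold-at 5 --noise 0.03 --seed 7 -o fold5.csv
$ tfo detect fold5.csv
TFO detected at electrode 5
```

The JSON report that follows carries the evidence trail (abridged):

```json
{
 "tfo_detected": true,
 "fold_electrode": 5,
 "min_angle_deg": 9.157,
 "decay_reversal_electrode": 5,
 "symmetry_score": 0.9489,
 "embedding": {"variance_explained": [0.7807, 0.1767], "...": "..."},
 "notes": [
  "min interior angle 9.2 deg at electrode 5; decay-reversal consensus: 5",
  "mirror-symmetry score 0.949 about electrode 5"
 ]
}
```

Reading: the ΔZ polyline turns by 9.2° (i.e. almost fully doubles back)
at electrode 5, the impedance rows independently place the decay reversal
at electrode 5, and cross-impedances mirror about that contact with
score 0.95 — three concordant signatures of a fold at electrode 5. On a
normal insertion the same command prints `no TFO detected` with all
interior angles obtuse.

Other subcommands: `tfo benchmark` (seeded matrices + truth manifest),
`tfo batch` (score a manifest, optionally against truth), `tfo plot`
(line/log plot, heat map, ΔZ plot).

```python
from tfoscan import two_proportion_z
z, p = two_proportion_z(96, 7842, 22, 6892)   # pre-curved vs straight
# z = 6.149, p = 7.8e-10
```

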
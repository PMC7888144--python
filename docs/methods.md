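# Methods

## Model structure and assumptions

The package implements a cohort expected-value budget-impact model over a
one-year horizon from a national payer perspective. Annual surgical
procedure volumes are reduced to the neuromuscular-blockade (NMB)
population by the share of procedures using a blocking agent (NMBA), then
distributed over a decision tree with three axes:

- **block depth at reversal** — moderate (train-of-four count 1–2) vs deep
  (TOF 0, post-tetanic count 1–2), an assumed 80/20 split;
- **prior reversal strategy** — no pharmacological reversal vs
  neostigmine (+ atropine). Deep block cannot be reversed with
  neostigmine, so the (deep, neostigmine) cells exist only for bookkeeping
  with zero eligible count and never carry costs;
- **prior blocking agent** — rocuronium, or cisatracurium switched to
  rocuronium in the alternative scenario (sugammadex does not reverse
  benzylisoquinolines; a configurable share of cisatracurium use is assumed
  switchable). "Other agents" remain outside the eligible population.

Counts are rounded to the nearest integer (halves away from zero) at the
cell level; row and national aggregates are sums of rounded cells. Currency
is kept at full precision internally and rounded to cents only at
reporting, halves away from zero.

Key assumptions inherited by the base case: equal post-operative event
risks for moderate and deep block; risks independent of procedure type;
event types priced additively and independently; no discounting (one-year
horizon); no vial wastage; drug costs are final per-administration 2019
euros net of the statutory 7.5% discount (a dose-rule helper exists for
users starting from per-mg list prices; it enforces the deep dose = 2 ×
moderate dose relationship at a 75 kg reference weight).

## Parameters

| parameter | base value | unit | notes |
|---|---|---|---|
| annual procedures | 733,876 | procedures/yr | 15 procedure categories |
| NMBA use | 73.3 | % of procedures | DSA-varied |
| moderate / deep split | 80 / 20 | % | |
| no reversal / neostigmine | 68 / 32 | % | both depths |
| rocuronium share | 64 (no-rev), 43.5 (neo) | % of arm | DSA-varied |
| cisatracurium share | 25 | % of arm | 50% switchable |
| sugammadex moderate / deep | 51.34 / 102.68 | €/dose | deep = 2 × moderate |
| rocuronium; neostigmine+atropine | 1.80; 0.46 | €/dose | |
| atelectasis risk (no sug. / sug.) | 7.3 / 1.1 | % | unit cost 4,999.40 € |
| pneumonia risk (no sug. / sug.) | 4.0 / 1.9 | % | unit cost 4,449.72 € |
| calibrated offset | 307.61 | €/procedure | see reconciliation |

## Adoption calibration

The sugammadex-using population of the base case is fixed as published
annual counts (118,034 moderate/no-reversal, 81,321 moderate/neostigmine,
29,508 deep/no-reversal; 228,863 in total, with the no-reversal total split
80/20 by depth) rather than derived from an uptake fraction, because the
underlying uptake was never published. The implied uptakes are computed and
logged (~52.7% for the no-reversal rows); the neostigmine-row count
*exceeds* its eligible count derivable from the published mix (81,321 vs
77,118, implied uptake 105%), an internal inconsistency of the source
calibration. The count-versus-eligible invariant is therefore enforced as a
hard error only when `allow_count_overrun` is false; the packaged base case
sets it true and surfaces a warning in logs and run manifests. In
`fractional` mode uptakes are proper fractions in [0, 1] per reporting row.

## Offset reconciliation

The published per-procedure clinical cost offset (307.61 €) is not
reproducible from the published risks and unit costs, which give

(0.073 − 0.011) × 4,999.40 + (0.040 − 0.019) × 4,449.72 = 403.41 €.

Both readings are first-class: `offset_mode = "from_components"` computes
the 403.41 € value; `offset_mode = "calibrated"` (the base-case default)
uses the fixed 307.61 €. `calibrate_atelectasis_cost` solves for the
atelectasis unit cost implied by a target offset (3,454.29 € for 307.61 €,
holding the pneumonia component fixed). Whenever component-level
computations are needed under the calibrated mode — sensitivity analysis of
risks/costs, microsimulation — the engine substitutes that implied
atelectasis cost (`effective_events`), so the components reproduce the
calibrated offset exactly at base values and respond linearly to
perturbations; the substitution is logged as a warning. Similarly, the
published atelectasis-avoided count (13,996) is inconsistent with the
published risks, which give round(228,863 × 0.062) = 14,190; the package
reports the computed value and documents the discrepancy in its tests.

## Sensitivity analysis

One-way ±50% over six parameters: NMBA-use share, event risks (jointly,
all four), event unit costs (jointly), moderate-block sugammadex uptake,
cisatracurium switch share, and the rocuronium share in both reversal arms.
Probabilities exceeding 1 after ×1.5 are clamped to 1 with a warning
(0.733 × 1.5 → 1.0). Agent-share perturbations absorb the residual into the
"other agents" share floored at zero; if rocuronium + cisatracurium still
exceed 1 they are renormalized proportionally, with a warning, so the arm
remains a valid share vector. In `direct_counts` adoption, perturbations
that change eligible counts rescale the sugammadex counts by each row's
eligible-count ratio (holding implied uptake fixed — otherwise the NMBA
share would have no effect under the count calibration); the uptake
parameter scales the moderate-row counts directly, capped at the eligible
count only where the base count did not already exceed it. Ranks are
assigned by descending net-saving range with lexicographic tie-breaks. In
the base case the event unit costs and event risks produce identical ranges
(both scale the offset linearly; they split ranks 1–2 by float residue),
followed by moderate-block uptake, NMBA-use share, rocuronium share and the
switch share; all twelve scenarios remain cost-saving.

## Microsimulation oracle

`microsimulate` draws individual sugammadex-treated procedures from the
eligible strata proportionally to their counts, samples Bernoulli event
indicators per type under prior and sugammadex risks, and accumulates drug
and event costs; the mean sampled net saving estimates the deterministic
per-procedure average. Scenario draws are independent by default (the
unbiased, assumption-free estimator). For *validation* the package uses the
`common_random_numbers` switch: driving both scenarios with the same
uniforms yields a paired estimator of the same expectation with a several-
fold smaller Monte Carlo error, which is the sharper test of the cohort
arithmetic. The validation suites run 200,000 draws per comparison over the
base case plus 20 generated parameter sets and require agreement within 3
standard errors; note that a 3-SE bound on a correct implementation still
fails by chance in roughly 0.3% of comparisons, which is why the paired
estimator (smaller SE, same bound) is preferred for this purpose.

## Synthetic parameter generator

`generate_parameter_set` emulates the structure of the real inputs —
procedure-volume tables, a depth split, reversal-arm shares drawn and
normalized to sum to one, benefit-direction event risks
(`risk_sugammadex ≤ risk_no_sugammadex`, toggleable), positive unit costs,
fractional uptakes — with all values drawn uniformly from configurable
ranges, deterministically per seed. It does **not** emulate correlated
risks across event types, procedure-type-specific risk profiles, count
overruns, or calibrated offsets (generated sets use component offsets), so
passing property tests demonstrate the internal consistency of the engine
on structurally valid inputs, not the realism of any particular parameter
combination.

## Numerical and reporting choices

Problem sizes used by the test and validation suites — 200,000 draws per
microsimulation comparison, 20 generated parameter sets, 1,000 generator
validation seeds — keep every suite in the low seconds while leaving Monte
Carlo errors (≈ 2–6 € per-procedure SE) far below the effects being
checked. Exported tables format euros with two decimals and counts as plain
integers ('.' decimal separator, no thousands separators) so repeated runs
are byte-identical; run manifests record the config hash, code version,
offset mode, seeds and every warning emitted (calibration overrun, clamping,
offset substitution). Recomputed national euro values agree with the
published row-level tables to within 0.5% (the source worked from unrounded
internal shares and prices); the published per-procedure "average across all
procedures" row is consistent with a 773,876 denominator rather than the
733,876 total, so reports expose the all-procedures denominator as a
parameter and the acceptance tables check both readings.

## Limitations

Uniform clinical mix across procedure categories; no procedure-specific
event risks; no indirect costs, operating-room time savings or residual-
blockade sequelae beyond the two modelled events; single-year horizon
without discounting; the base-case calibration inherits the internal
inconsistencies of its source (component-vs-calibrated offset, neostigmine-
row overrun, 1-cent prior-cost discrepancy in the neostigmine row) — the
package surfaces each of them rather than resolving them silently.
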
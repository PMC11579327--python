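# Methods

## The mixing model and its assumptions

Ambient NOx over a closed air basin is treated as a single well-mixed
pool fed by four source classes — mobile, biomass burning, stationary
and biogenic soil — each carrying a characteristic δ¹⁵N-NOx signature.
The observed δ¹⁵N-NOx is the flux-weighted mean of the contributing
signatures. The inversion assumes:

* all sampled NO₂ derives from NOx (or HONO) emitted within the basin
  — any import of isotopically heavier urban NOx from upwind would make
  the soil estimates lower bounds;
* the a priori inventory is correct for every source except soil;
* source signatures are constant over a sampling period, at their
  literature means;
* δ values mix linearly in flux. Exact mixing is linear in atom
  fraction, not in δ; over the ±60‰ range involved the discrepancy is
  second order (≲0.01‰) and far below the signature uncertainties.

Solving the mass balance for the soil term gives

    E_s = (δ_obs − Σᵢ αᵢδᵢ) · E_inv / (δ_s − δ_obs).

Two estimator conventions coexist and are both exposed:

* **inventory-referenced** (the form above, with the soil term kept in
  the Σαδ): on exactly mixed data it returns E_true − α_s·E_inv, the
  soil flux *in excess of* the inventory's soil entry. This offset
  identity is enforced as a property test.
* **consistent**: E = (Σrᵢδᵢ − δ_obs·Σrᵢ)/(δ_obs − δ_s) over non-soil
  sources only, which recovers the total soil flux exactly and serves
  as the validation oracle. The two coincide when the inventory soil
  entry is zero.

Since the inventory soil entries here are 0.1–1.0 tons/d against
estimates of 5–7 tons/d, the distinction is small relative to σ but is
tracked explicitly.

**Truncation.** Months whose observed δ is heavier than the a priori
mixture yield negative E_s; these are reported as zero with a
`truncated` flag (the untruncated value and σ are preserved —
truncation is a reporting policy applied after error propagation, and
the truncated aggregate is by construction ≥ the untruncated one).

**Aggregation.** Two annual summaries are reported side by side:
inverting the campaign-mean δ (used for the Imperial record) and
averaging month-wise inversions with truncation (used for the Coachella
record, which contains one truncated month). They differ because the
inversion is convex in δ_obs; neither is canonical.

**Singular guard.** E_s diverges as δ_obs → δ_s. Observations within a
guard band (default 0.5‰) of the soil end-member raise a
`SingularityError` rather than returning an arbitrarily large number.

## Key parameters

| parameter | value | units | origin |
|---|---|---|---|
| δ_s (soil end-member) | −33.2 ± 9.6 | ‰ | literature compilation (range −59.8 to −14.2) |
| non-soil signatures | −2.5 ± 2.7, +1.0 ± 4.1, −16.5 ± 1.7 | ‰ | literature compilation |
| E_inv | 15.2 / 18.0 / 33.2 | short tons NOx d⁻¹ | 2022 CEPAM (Imperial / Coachella / basin) |
| a priori Σαδ | −5.04 / −3.11 | ‰ | cited with the inventory; see below |
| analytic noise | 0.11 | ‰ | pooled SD of the ¹⁵N reference |
| guard band | 0.5 | ‰ | numerical choice |
| cropland area | 270,500 | ha | satellite land classification, Imperial Valley |
| fertilizer N | 57,630 | short tons N yr⁻¹ | county purchases, 2022 |

**The a priori signature.** Weighting the packaged signature means by
the CEPAM proportions gives −5.84‰ (Imperial) and −3.55‰ (Coachella),
lighter than the −5.04/−3.11‰ cited alongside the inventory; the exact
signature set behind the cited values is not recoverable from the
printed tables. The pipeline therefore accepts a user-supplied a priori
override, treats the cited values as authoritative constants for
reproduction, and warns whenever an override disagrees with the
recomputed value by more than 0.1‰.

**Inventory totals.** The printed CEPAM totals (15.2, 33.2) exceed
their component sums (15.1, 33.1) by one trailing digit. Inventories
carry both; E_inv and the α's use the printed total, so α's over such
an inventory sum to component_sum/total rather than exactly 1 (the
sum-to-one invariant holds for any self-consistent inventory).

**Units.** Rates are short tons (907.185 kg) of NOx as NO₂-equivalent
mass per day, the US inventory convention; the N mass fraction
14.007/46.0055 and 365 d yr⁻¹ convert to kg N ha⁻¹ yr⁻¹. This
convention is identifiable from the published 6.7 tons/d ↔ 2.5 kg N
ha⁻¹ yr⁻¹ pairing (metric tonnes would give 2.75) and from the 1.3%
fertilizer-N fraction, which also fixes the fertilizer figure as tons
of N rather than tons of material.

## Fractionation correction

Sampled NO₂ is isotopically heavier than the emitted NOx pool because
of NO⇌NO₂ exchange. Two correction modes:

* **table** (authoritative for reproduction): per-sample additive
  Δ = δ¹⁵N-NOx − δ¹⁵N-NO₂, recovered from the paired published columns
  by `implied_corrections`; the campaign's corrections are all ≤ 0
  (−3.4 to 0.0‰, mean −1.3‰).
* **parametric**: δNOx = δNO₂ − (1 − f)·ε_eff with f the NO₂/NOx
  fraction and ε_eff an effective equilibrium fractionation, optionally
  ε_eff(T) from a polynomial in 1000/T whose coefficients are
  configuration. This mode exists for synthetic scenarios and
  sensitivity work; it is deliberately non-authoritative (no Leighton
  cycle, no diurnal structure) and no reproduction number depends on
  its constants.

There is no default correction: an unconfigured spec is an error, never
a silent zero.

## Error propagation

The published variance formula for E_s contains a dimensionally
inconsistent middle term in its soil bracket; what it evidently intends
is the first-order Taylor variance of the inversion, which is what the
package implements:

    σ²_Es = Σᵢ (αᵢE_inv/(δ_s−δ_obs))² σᵢ²
          + (α_sE_inv/(δ_s−δ_obs) + E_s/(δ_s−δ_obs))² σ_s²
          [+ ((E_inv+E_s)/(δ_s−δ_obs))² σ_obs²]

σ_obs defaults to 0 (the 0.11‰ analytic SD is an order of magnitude
below the signature SDs); draws are independent normals (no published
covariances); inventory rates are treated as exact.

A Monte-Carlo oracle (`mc_sigma_soil_source`) validates the analytic
form: draws within the singular guard band are rejected and counted,
with a warning above 1% rejection. Validation (analysis/03) shows
agreement within ~1% at 10% of the literature SDs, ~6% at 25%, and a
factor ≈5 divergence at the full σ_s = 9.6‰, where near-singular soil
draws fatten the tails. The analytic σ is therefore quoted as a lower
bound at full literature uncertainty — consistent with published ±3/±4
tons/d accompanying the 6.7/4.7 estimates being first-order values.

## Synthetic campaigns and what they show

`simulate_campaign` draws monthly observations exactly under the model
assumptions above: constant non-soil rates, a seasonal soil profile
(smooth annual cycle, optional 10–100× irrigation-pulse multipliers —
configuration, not hard-coded), signatures fixed at means or redrawn
monthly, an invertible fractionation map, and N(0, 0.11‰) analytic
noise. Defaults mirror the study conditions (`study_like_scenario`):
the 2022 CEPAM non-soil mix (12.4/0.1/1.7 tons/d), 10 months, a soil
cycle spanning ≈2–10 tons/d around a summer peak, inventory soil entry
0.9 tons/d.

`recovery_experiment` repeats simulation + estimation (seeded child
streams `(seed, rep)`), reporting bias, RMSE and the empirical coverage
of ±1.96σ analytic intervals. At study conditions the consistent
estimator's bias is statistically zero (|bias| ≲ 0.002 tons/d over 500
campaigns) with ~95% coverage; the inventory-referenced estimator shows
exactly the −α_s·E_inv offset on noise-free data.

Passing these tests shows the estimator and its error model are
self-consistent under the stated assumptions; it says nothing about
unmodelled field effects (transport into the basin, signature drift,
correlated sources), which remain the dominant unquantified systematics
for real data.

## Numerical and reporting choices

* All internal arithmetic is full double precision; ‰ and tons/d values
  are rounded only at the reporting layer (1 decimal, 2 for |x| < 1).
* Missing δ values are explicit missing (empty CSV cell → NaN → None)
  and are excluded from means with the divisor reduced.
* CSV outputs carry a `# isonox <version> | config=<hash> | seed=<n>`
  provenance comment and serialize floats at 6 significant digits.
* Degenerate inputs fail loudly: zero total flux, empty inventories,
  δ ≤ −1000‰, observations inside the singular guard band.

## Known limitations

* Linear-in-δ mixing (second-order in the δ range, see above).
* No propagation of inventory-rate uncertainty; the inventory is fixed.
* The parametric fractionation mode is a placeholder form, not a
  photochemical model.
* Monthly samples are treated as independent; real campaigns integrate
  ~40-day denuder exposures with month-level period labels.
* The descriptive NO₂–tNO₃ correlation (r ≈ 0.50 over the 18 complete
  cross-site pairs) depends on the pairing convention; per-site
  correlation is exposed by filtering the sample table.
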